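"""Effort-accuracy exchange: per-sample effort expenditure vs perceptual reliability.

The probability ``phi`` of an error-free observation is purchased through a
per-sample effort cost ``C_e`` with diminishing returns.  The map is the
hyperbolic saturating curve

    phi(C_e) = C_e / (k + C_e),

where ``k`` (in cost units) is the half-saturation constant: spending ``k``
per sample buys ``phi = 1/2``.  Perfect reliability (``phi = 1``) costs
infinitely much, so ``phi`` is restricted to ``[0, 1)`` throughout.

The functional form sits behind this module's three functions only, so an
alternative saturating curve can be swapped in without touching the rest of
the package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EffortCostParams",
    "phi_from_cost",
    "cost_from_phi",
    "per_sample_cost",
]


@dataclass(frozen=True)
class EffortCostParams:
    """Effort-cost parameters.

    Parameters
    ----------
    k : float
        Half-saturation constant of the effort-reliability curve, in the
        same fitness-cost units as ``c_effort``.  Must be positive.
    c_effort : float
        Effort expenditure per sample, ``C_e >= 0``.
    """

    k: float
    c_effort: float = 0.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.c_effort < 0:
            raise ValueError(f"c_effort must be >= 0, got {self.c_effort}")

    @property
    def phi(self) -> float:
        """Reliability bought by ``c_effort`` at this ``k``."""
        return phi_from_cost(self.c_effort, self.k)


def phi_from_cost(c_effort: float, k: float) -> float:
    """Reliability ``phi`` bought by an effort expenditure of ``c_effort``.

    Strictly increasing and concave in ``c_effort``; ``phi(0) = 0`` and
    ``phi -> 1`` as ``c_effort -> inf``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if c_effort < 0:
        raise ValueError(f"c_effort must be >= 0, got {c_effort}")
    return c_effort / (k + c_effort)


def cost_from_phi(phi: float, k: float) -> float:
    """Per-sample effort cost required to reach reliability ``phi``.

    Exact inverse of :func:`phi_from_cost`: ``C_e = k * phi / (1 - phi)``.
    Diverges as ``phi -> 1``, hence the domain ``[0, 1)``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    return k * phi / (1.0 - phi)


def per_sample_cost(c_time: float, phi: float, k: float) -> float:
    """Total fitness cost of acquiring one sample: ``C_t + C_e(phi)``.

    ``c_time`` is the baseline cost of a unit of time (predation risk,
    opportunity cost); the effort term is what reliability ``phi`` costs
    on top of it.
    """
    if c_time < 0:
        raise ValueError(f"c_time must be >= 0, got {c_time}")
    return c_time + cost_from_phi(phi, k)
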