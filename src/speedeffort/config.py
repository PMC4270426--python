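"""Flat key-value run configuration.

The configuration format is deliberately minimal and language-neutral: one
``key = value`` assignment per line, ``#`` comments, blank lines ignored.
Every key has a documented default (the default scenario); unknown keys are
an error so typos cannot silently fall back to defaults.  The fully merged
("effective") configuration can be echoed back out and re-loaded to
reproduce a run byte-for-byte.

Default scenario
----------------
Good trees drop 75% green husks, bad trees 25% (``eps_good=0.75``,
``eps_bad=0.25``), states equiprobable.  A correct decision is worth
``benefit=100`` fitness units; the effort curve half-saturates at ``k=0.2``
cost units (effort is cheap relative to the benefit, so modulating it
pays); the baseline time cost is ``c_time=0.2`` per sample, compared
against halved and doubled values and swept log-spaced over [0.02, 2].
The strategy grid is theta 0.55:0.99:0.01, phi 0:0.98:0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .effort import EffortCostParams
from .landscape import GridSpec
from .sprt import EnvironmentParams

__all__ = ["RunConfig", "load_config", "parse_kv_text"]

_COMPARE_DEFAULT = "0.1,0.2,0.4"


@dataclass(frozen=True)
class RunConfig:
    """Validated run parameters (environment, costs, grid, sweeps)."""

    eps_good: float = 0.75
    eps_bad: float = 0.25
    prior_good: float = 0.5
    benefit: float = 100.0
    c_time: float = 0.2
    k: float = 0.2
    theta_min: float = 0.55
    theta_max: float = 0.99
    theta_step: float = 0.01
    phi_min: float = 0.0
    phi_max: float = 0.98
    phi_step: float = 0.02
    n_trials: int = 10_000
    t_max: int = 10_000
    seed: int = 0
    mode: str = "oracle"
    compare_c_times: str = _COMPARE_DEFAULT
    sweep_low: float = 0.02
    sweep_high: float = 2.0
    sweep_n: int = 20

    def __post_init__(self) -> None:
        # constructing the domain objects runs their validation
        self.env()
        self.costs()
        self.grid()
        if self.sweep_n < 2 or self.sweep_low <= 0 or self.sweep_high <= self.sweep_low:
            raise ValueError(
                "sweep requires sweep_low > 0, sweep_high > sweep_low, sweep_n >= 2"
            )
        self.compare_values()

    def env(self) -> EnvironmentParams:
        return EnvironmentParams(
            eps_good=self.eps_good,
            eps_bad=self.eps_bad,
            prior_good=self.prior_good,
            benefit=self.benefit,
            c_time=self.c_time,
        )

    def costs(self) -> EffortCostParams:
        return EffortCostParams(k=self.k)

    def grid(self, **overrides) -> GridSpec:
        theta = tuple(
            np.round(np.arange(self.theta_min, self.theta_max + self.theta_step / 2, self.theta_step), 10)
        )
        phi = tuple(
            np.round(np.arange(self.phi_min, self.phi_max + self.phi_step / 2, self.phi_step), 10)
        )
        kw = dict(
            theta_values=theta,
            phi_values=phi,
            n_trials=self.n_trials,
            t_max=self.t_max,
            seed=self.seed,
            mode=self.mode,
        )
        kw.update(overrides)
        return GridSpec(**kw)

    def compare_values(self) -> list[float]:
        try:
            vals = [float(v) for v in self.compare_c_times.split(",") if v.strip()]
        except ValueError as exc:
            raise ValueError(f"compare_c_times: cannot parse {self.compare_c_times!r}") from exc
        if not vals:
            raise ValueError("compare_c_times must list at least one value")
        return vals

    def sweep_values(self) -> np.ndarray:
        return np.geomspace(self.sweep_low, self.sweep_high, self.sweep_n)

    def to_text(self) -> str:
        """The effective configuration as re-loadable key-value text."""
        lines = ["# speedeffort effective configuration"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}".replace("'", ""))
        return "\n".join(lines) + "\n"


def parse_kv_text(text: str) -> dict[str, str]:
    """Parse flat ``key = value`` text into a string dict."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ValueError(f"line {lineno}: empty key")
        if key in out:
            raise ValueError(f"line {lineno}: duplicate key {key!r}")
        out[key] = value
    return out


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a configuration file, merge defaults, validate.

    ``overrides`` (e.g. from CLI flags) take precedence over the file.
    Unknown keys raise with the offending names; missing keys fall back to
    the documented defaults.  An empty file yields all defaults.
    """
    raw: dict[str, str] = {}
    if path is not None:
        raw = parse_kv_text(Path(path).read_text())
    field_types = {f.name: f.type for f in fields(RunConfig)}
    unknown = sorted(set(raw) - set(field_types))
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
    kwargs: dict = {}
    for key, value in raw.items():
        typ = field_types[key]
        try:
            if typ == "int":
                kwargs[key] = int(value)
            elif typ == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        except ValueError as exc:
            raise ValueError(f"key {key!r}: cannot parse {value!r} as {typ}") from exc
    for key, value in overrides.items():
        if value is not None:
            kwargs[key] = value
    return RunConfig(**kwargs)
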