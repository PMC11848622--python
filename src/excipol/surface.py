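"""Dynamic surface-tension kinetics.

Early-time tensiometry transients are fitted with a one-phase
exponential decay

    gamma(t) = gamma_eq + (gamma0 - gamma_eq) * exp(-k * t)

over a configurable window (default the first 300 s) to extract the
equilibration rate constant k.  The equilibrium surface tension is read
from the tail of the raw trace (final 5% of the time axis), not from
the fitted asymptote, since the fit is restricted to early times.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TensionTrace",
    "SurfaceFit",
    "fit_exponential_decay",
    "equilibrium_tension",
    "rate_in_table_units",
    "read_tension_csv",
    "write_tension_csv",
    "fit_to_json",
]

DEFAULT_WINDOW = (0.0, 300.0)
_K_LOWER_BOUND = 1e-10


@dataclass(frozen=True)
class TensionTrace:
    """Wilhelmy-plate style surface tension series (seconds, mN/m)."""

    times: np.ndarray
    tension: np.ndarray
    label: str = ""
    concentration_wt_pct: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.tension, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "tension", g)
        if t.ndim != 1 or t.shape != g.shape:
            raise ValueError("times and tension must be 1-D and equal length")
        if t.size < 10:
            raise ValueError("trace needs at least 10 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(g)) and np.all(g > 0)):
            raise ValueError("tension must be positive and finite")


@dataclass(frozen=True)
class SurfaceFit:
    gamma0: float
    gamma_eq: float
    k: float
    fit_window: tuple[float, float]
    sse: float
    converged: bool
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


def _model(t: np.ndarray, gamma0: float, gamma_eq: float, k: float) -> np.ndarray:
    return gamma_eq + (gamma0 - gamma_eq) * np.exp(-k * t)


def fit_exponential_decay(
    trace: TensionTrace, window: tuple[float, float] = DEFAULT_WINDOW
) -> SurfaceFit:
    """Least-squares fit of (gamma0, gamma_eq, k) inside the window.

    Initialisation: gamma0 = first sample in window, gamma_eq = last
    sample in window, k = ln(2)/window-midpoint.  k is constrained
    positive; a fit that collapses onto the bound is flagged
    ``unreliable``.  A trace with no decay (constant or rising) is
    flagged ``sign_anomaly``/``degenerate`` but a fit is still returned.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive extent")
    mask = (trace.times >= lo) & (trace.times <= hi)
    t = trace.times[mask]
    g = trace.tension[mask]
    if t.size < 3:
        raise ValueError("need at least 3 samples inside the fit window")

    flags: list[str] = []
    g_first, g_last = float(g[0]), float(g[-1])
    if g_last > g_first:
        flags.append("sign_anomaly")
    if float(np.ptp(g)) < 1e-9 * max(1.0, abs(g_first)):
        # no transient at all (e.g. pure buffer): k is meaningless
        flags.append("degenerate")
        return SurfaceFit(
            gamma0=g_first,
            gamma_eq=g_last,
            k=math.nan,
            fit_window=(lo, hi),
            sse=float(np.sum((g - g.mean()) ** 2)),
            converged=False,
            flags=tuple(flags),
        )

    midpoint = lo + (hi - lo) / 2.0
    x0 = np.array([g_first, g_last, math.log(2.0) / midpoint])

    def residuals(p: np.ndarray) -> np.ndarray:
        return _model(t, *p) - g

    result = least_squares(
        residuals,
        x0,
        bounds=([-np.inf, -np.inf, _K_LOWER_BOUND], [np.inf, np.inf, np.inf]),
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=500 * 3,
    )
    gamma0, gamma_eq, k = (float(v) for v in result.x)
    if k <= _K_LOWER_BOUND * 10:
        flags.append("unreliable")
    return SurfaceFit(
        gamma0=gamma0,
        gamma_eq=gamma_eq,
        k=k,
        fit_window=(lo, hi),
        sse=float(2.0 * result.cost),
        converged=bool(result.success),
        flags=tuple(flags),
    )


def equilibrium_tension(trace: TensionTrace) -> tuple[float, float]:
    """Mean and SEM of the samples in the final 5% of the time axis."""
    t_end = float(trace.times[-1])
    tail = trace.tension[trace.times >= 0.95 * t_end]
    if tail.size < 3:
        raise ValueError("fewer than 3 samples in the trace tail")
    mean = float(tail.mean())
    sem = float(tail.std(ddof=1) / math.sqrt(tail.size))
    return mean, sem


def rate_in_table_units(fit: SurfaceFit) -> float:
    """k expressed in 10^-3 s^-1, three decimal places (table convention)."""
    if not math.isfinite(fit.k):
        raise ValueError("fit has no finite rate constant")
    return round(fit.k * 1e3, 3)


def read_tension_csv(path) -> list[TensionTrace]:
    """Read a long-format tensiometry CSV: time_s, tension_mN_m, replicate."""
    df = pd.read_csv(path)
    required = {"time_s", "tension_mN_m", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    traces = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            TensionTrace(
                times=grp["time_s"].to_numpy(),
                tension=grp["tension_mN_m"].to_numpy(),
                label=str(rep),
            )
        )
    return traces


def write_tension_csv(path, traces: Sequence[TensionTrace]) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.times,
                "tension_mN_m": tr.tension,
                "replicate": tr.label or str(i),
            }
        )
        for i, tr in enumerate(traces)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fit_to_json(fit: SurfaceFit, label: str = "") -> str:
    """Serialise a fit as the canonical JSON record."""
    record = {
        "label": label,
        "gamma0": fit.gamma0,
        "gamma_eq": fit.gamma_eq,
        "k_per_s": None if not math.isfinite(fit.k) else fit.k,
        "k_1e3_per_s": None if not math.isfinite(fit.k) else rate_in_table_units(fit),
        "window_s": list(fit.fit_window),
        "sse": fit.sse,
        "converged": fit.converged,
        "flags": list(fit.flags),
    }
    return json.dumps(record, indent=2)
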