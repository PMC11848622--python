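"""T10 aggregation-onset extraction from turbidity (A540) time series.

The onset of aggregation is the time at which absorbance first reaches
10% of its maximum rise above baseline.  The threshold is anchored to
the initial reading so a non-zero plate blank does not shift it:

    threshold = baseline + 0.10 * (max - baseline)

The crossing time is linearly interpolated between the bracketing
samples.  Curves that never cross are reported censored at the last
time point and excluded from replicate means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayCurve",
    "AggregationResult",
    "ReplicateStats",
    "t10_time",
    "aggregate_replicates",
    "fold_change",
    "read_assay_csv",
    "write_assay_csv",
]


@dataclass(frozen=True)
class AssayCurve:
    """Timestamped absorbance series for one well/replicate.

    times are in hours and strictly increasing; absorbance is the raw
    A540 reading.
    """

    times: np.ndarray
    absorbance: np.ndarray
    replicate_id: str = "0"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and absorbance must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("curve needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance must be finite")


@dataclass(frozen=True)
class AggregationResult:
    t10: float
    max_absorbance: float
    threshold_absorbance: float
    replicate_id: str
    censored: bool = False


@dataclass(frozen=True)
class ReplicateStats:
    mean: float
    sem: float | None
    n: int
    n_censored: int = 0


def t10_time(curve: AssayCurve) -> AggregationResult:
    """First threshold crossing (T10), linearly interpolated.

    A curve that starts above threshold has t10 = 0.  A flat curve
    (max == baseline) never crosses and is censored at the last time.
    """
    t = curve.times
    a = curve.absorbance
    baseline = float(a[0])
    a_max = float(a.max())
    threshold = baseline + 0.10 * (a_max - baseline)
    if a_max <= baseline:
        return AggregationResult(
            t10=float(t[-1]),
            max_absorbance=a_max,
            threshold_absorbance=threshold,
            replicate_id=curve.replicate_id,
            censored=True,
        )
    above = a >= threshold
    if above[0]:
        t10 = 0.0
    else:
        idx = int(np.argmax(above))  # first True; above[0] is False here
        t0, t1 = t[idx - 1], t[idx]
        a0, a1 = a[idx - 1], a[idx]
        t10 = float(t0 + (threshold - a0) / (a1 - a0) * (t1 - t0))
    return AggregationResult(
        t10=t10,
        max_absorbance=a_max,
        threshold_absorbance=threshold,
        replicate_id=curve.replicate_id,
    )


def aggregate_replicates(results: Sequence[AggregationResult]) -> ReplicateStats:
    """Mean and SEM of uncensored replicate T10 values.

    SEM is the sample standard deviation over sqrt(n); undefined (None)
    for n = 1.  Censored replicates are excluded and counted.
    """
    if not results:
        raise ValueError("need at least one result")
    usable = [r.t10 for r in results if not r.censored]
    n_censored = len(results) - len(usable)
    if not usable:
        raise ValueError("all replicates censored; no T10 mean available")
    n = len(usable)
    mean = float(np.mean(usable))
    sem = float(np.std(usable, ddof=1) / math.sqrt(n)) if n > 1 else None
    return ReplicateStats(mean=mean, sem=sem, n=n, n_censored=n_censored)


def fold_change(test: float, reference: float) -> float:
    """Ratio of T10 means, e.g. 24.37/12.08 = 2.02 for V-70 vs AIBN at 8 kDa."""
    if reference <= 0:
        raise ValueError("reference T10 must be positive")
    return test / reference


def read_assay_csv(path) -> list[AssayCurve]:
    """Read a long-format turbidity CSV with columns time_h, a540, replicate."""
    df = pd.read_csv(path)
    required = {"time_h", "a540", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    curves = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            AssayCurve(
                times=grp["time_h"].to_numpy(),
                absorbance=grp["a540"].to_numpy(),
                replicate_id=str(rep),
            )
        )
    return curves


def write_assay_csv(path, curves: Sequence[AssayCurve]) -> None:
    frames = [
        pd.DataFrame(
            {"time_h": c.times, "a540": c.absorbance, "replicate": c.replicate_id}
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
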