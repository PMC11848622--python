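"""Compositional dispersity index (CDI).

The per-chain composition scatter (major-monomer count on x, minor on y)
is compared with the ideal stoichiometric line through the origin whose
slope is the minor/major feed ratio.  Goodness of fit is the coefficient
of determination about that *fixed* line (no fitting):

    R^2 = 1 - sum((y_i - s*x_i)^2) / sum((y_i - mean(y))^2)

which may be negative when the line fits worse than the mean.  The CDI
is ``|1/R^2|``: 1 for a perfectly homogeneous ensemble, larger for more
compositionally disperse ones.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from excipol.copolymer_sim import ChainComposition

__all__ = [
    "CompositionScatter",
    "IdealLine",
    "CdiResult",
    "ideal_slope",
    "r_squared_about_line",
    "cdi",
    "scatter_from_chains",
    "write_cdi_csv",
]


@dataclass(frozen=True)
class CompositionScatter:
    """Per-chain (major count, minor count) pairs."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 3:
            raise ValueError("scatter needs at least 3 points")
        if (x < 0).any() or (y < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class IdealLine:
    """Origin line y = slope * x with slope = minor/major feed ratio."""

    slope: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be positive")


@dataclass(frozen=True)
class CdiResult:
    r_squared: float
    cdi: float

    def __post_init__(self) -> None:
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


def ideal_slope(major_fraction: float, minor_fraction: float) -> float:
    """Slope of the ideal composition line, minor/major.

    For the 77/23 feed this is 23/77 = 0.299 (3 d.p.).
    """
    if major_fraction <= 0:
        raise ValueError("major_fraction must be positive")
    if minor_fraction <= 0:
        raise ValueError("minor_fraction must be positive")
    if abs(major_fraction + minor_fraction - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    return minor_fraction / major_fraction


def r_squared_about_line(scatter: CompositionScatter, line: IdealLine) -> float:
    """R^2 of the scatter about the fixed origin line (may be negative)."""
    pred = line.slope * scatter.x
    ss_res = float(np.sum((scatter.y - pred) ** 2))
    ss_tot = float(np.sum((scatter.y - scatter.y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("degenerate scatter: all y-values identical")
    return 1.0 - ss_res / ss_tot


def cdi(scatter: CompositionScatter, line: IdealLine) -> CdiResult:
    """CDI = |1/R^2|; R^2 = 0 is reported as an infinite CDI, not an error."""
    r2 = r_squared_about_line(scatter, line)
    value = math.inf if r2 == 0.0 else abs(1.0 / r2)
    return CdiResult(r_squared=r2, cdi=value)


def scatter_from_chains(
    chains: Iterable[ChainComposition] | Sequence[ChainComposition],
    major_index: int = 0,
) -> CompositionScatter:
    """Build the scatter from simulated chains (major monomer on x)."""
    counts = np.array([c.counts for c in chains], dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("chains must be two-monomer compositions")
    minor_index = 1 - major_index
    return CompositionScatter(x=counts[:, major_index], y=counts[:, minor_index])


def write_cdi_csv(path, scatter: CompositionScatter, line: IdealLine, result: CdiResult) -> None:
    """One-row summary CSV: n_chains, slope, r_squared, cdi."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n_chains", "slope", "r_squared", "cdi"])
        writer.writerow([scatter.n, line.slope, result.r_squared, result.cdi])
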