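"""Stochastic generation of per-chain copolymer compositions.

Chains are grown monomer-by-monomer under the terminal model: after a
terminal unit of monomer 1 the probability of adding monomer 1 again is
``r1*f1 / (r1*f1 + f2)`` (and symmetrically for monomer 2), where ``f``
are the current feed mole fractions.  Chain lengths are drawn from a
Schulz-Zimm (Gamma) distribution parameterised so that the length
dispersity is ``D = 1 + 1/z``.

Two pool modes are supported:

``infinite_feed``
    every chain sees the initial feed composition (no drift).  This is
    exact for ideal-random systems (r1 = r2 = 1) and is the default.
``finite_pool``
    a shared monomer pool sized from ``n_chains * mean_dp /
    target_conversion`` is depleted as chains grow in randomised
    round-robin order, so non-ideal reactivity ratios produce
    compositional drift with conversion.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MonomerSpec",
    "ReactivityRatios",
    "ChainLengthModel",
    "SimConfig",
    "ChainComposition",
    "EnsembleSummary",
    "sample_chain_lengths",
    "grow_chain",
    "simulate_ensemble",
    "write_ensemble_csv",
    "read_ensemble_csv",
]

_FEED_TOL = 1e-9


@dataclass(frozen=True)
class MonomerSpec:
    """One monomer in the feed."""

    name: str
    molar_mass: float
    feed_fraction: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")
        if not 0.0 <= self.feed_fraction <= 1.0:
            raise ValueError(
                f"feed_fraction must be in [0, 1], got {self.feed_fraction}"
            )


@dataclass(frozen=True)
class ReactivityRatios:
    """Terminal-model reactivity ratios for a two-monomer system.

    ``r1 = r2 = 1`` is the ideal-random default under which chain growth
    reduces to independent Bernoulli draws at the feed composition.
    """

    r1: float = 1.0
    r2: float = 1.0

    def __post_init__(self) -> None:
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("reactivity ratios must be non-negative")

    @property
    def is_ideal(self) -> bool:
        return self.r1 == 1.0 and self.r2 == 1.0


@dataclass(frozen=True)
class ChainLengthModel:
    """Chain-length distribution: Schulz-Zimm (Gamma) or fixed length."""

    mean_dp: float
    dispersity: float = 1.0
    family: str = "schulz_zimm"

    def __post_init__(self) -> None:
        if self.mean_dp <= 0:
            raise ValueError("mean_dp must be positive")
        if self.family not in ("schulz_zimm", "fixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.dispersity < 1.0:
            raise ValueError(f"dispersity must be >= 1, got {self.dispersity}")
        if self.family == "fixed" and self.dispersity != 1.0:
            raise ValueError("family='fixed' requires dispersity == 1")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one ensemble simulation."""

    monomers: tuple[MonomerSpec, ...]
    ratios: ReactivityRatios
    length_model: ChainLengthModel
    n_chains: int
    target_conversion: float = 0.98
    pool_mode: str = "infinite_feed"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "monomers", tuple(self.monomers))
        if len(self.monomers) != 2:
            raise ValueError("exactly two monomers are supported")
        total = sum(m.feed_fraction for m in self.monomers)
        if abs(total - 1.0) > _FEED_TOL:
            raise ValueError(f"feed fractions must sum to 1, got {total}")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0.0 < self.target_conversion <= 1.0:
            raise ValueError("target_conversion must be in (0, 1]")
        if self.pool_mode not in ("infinite_feed", "finite_pool"):
            raise ValueError(f"unknown pool_mode {self.pool_mode!r}")

    @property
    def feed(self) -> tuple[float, float]:
        return (self.monomers[0].feed_fraction, self.monomers[1].feed_fraction)


@dataclass(frozen=True)
class ChainComposition:
    """Per-chain monomer counts; the atom of the CDI computation."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.length < 1:
            raise ValueError("chain length must be >= 1")

    @property
    def length(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class EnsembleSummary:
    n_chains: int
    mean_fractions: tuple[float, ...]
    mn_dp: float
    mw_dp: float
    dispersity_realized: float
    residual_pool: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.mw_dp + 1e-12 < self.mn_dp:
            raise ValueError("mw_dp must be >= mn_dp")


def sample_chain_lengths(
    model: ChainLengthModel, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` integer chain lengths (DP) from the length model.

    Schulz-Zimm lengths are Gamma with shape ``z = 1/(D-1)`` and scale
    ``mean_dp/z``, rounded to the nearest integer with a floor of 1.
    ``D = 1`` degenerates to every chain at ``round(mean_dp)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if model.family == "fixed" or model.dispersity == 1.0:
        return np.full(n, max(1, round(model.mean_dp)), dtype=np.int64)
    z = 1.0 / (model.dispersity - 1.0)
    raw = rng.gamma(shape=z, scale=model.mean_dp / z, size=n)
    return np.maximum(1, np.rint(raw)).astype(np.int64)


def _transition_probs(feed: Sequence[float], ratios: ReactivityRatios) -> tuple[float, float]:
    """P(add monomer 1 | terminal is 1), P(add monomer 1 | terminal is 2)."""
    f1, f2 = feed
    d1 = ratios.r1 * f1 + f2
    d2 = f1 + ratios.r2 * f2
    p_11 = ratios.r1 * f1 / d1 if d1 > 0 else 0.0
    p_21 = f1 / d2 if d2 > 0 else 0.0
    return p_11, p_21


def grow_chain(
    length: int,
    feed: Sequence[float],
    ratios: ReactivityRatios,
    rng: np.random.Generator,
) -> ChainComposition:
    """Grow a single chain of the given DP under the terminal model.

    The first unit is drawn with probability equal to the feed fraction;
    each subsequent unit with the terminal-model conditional probability.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    f1, f2 = feed
    if abs(f1 + f2 - 1.0) > _FEED_TOL:
        raise ValueError("feed fractions must sum to 1")
    if f1 <= 0 and f2 <= 0:
        raise ValueError("feed is all zero")
    u = rng.random(length)
    if f1 >= 1.0:
        return ChainComposition((length, 0))
    if f2 >= 1.0:
        return ChainComposition((0, length))
    p_11, p_21 = _transition_probs(feed, ratios)
    state_is_1 = bool(u[0] < f1)
    n1 = int(state_is_1)
    # sequential Markov draw; plain loop on pre-drawn uniforms
    for i in range(1, length):
        p = p_11 if state_is_1 else p_21
        state_is_1 = bool(u[i] < p)
        n1 += state_is_1
    return ChainComposition((n1, length - n1))


def _grow_vectorized(
    lengths: np.ndarray,
    feed: Sequence[float],
    ratios: ReactivityRatios,
    rng: np.random.Generator,
) -> np.ndarray:
    """All chains advance one unit per step; identical law to per-chain growth."""
    n = lengths.size
    f1 = feed[0]
    counts1 = np.zeros(n, dtype=np.int64)
    state = rng.random(n) < f1  # first unit
    counts1 += state
    if ratios.is_ideal:
        # terminal model collapses to iid Bernoulli(f1); remaining units in one draw
        counts1 += rng.binomial(lengths - 1, f1)
        return counts1
    p_11, p_21 = _transition_probs(feed, ratios)
    max_len = int(lengths.max())
    for step in range(1, max_len):
        active = lengths > step
        p = np.where(state, p_11, p_21)
        new_state = rng.random(n) < p
        state = np.where(active, new_state, state)
        counts1 += new_state & active
    return counts1


def _simulate_finite_pool(
    config: SimConfig, lengths: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Round-robin growth from a shared, depleting monomer pool.

    Returns per-chain counts of each monomer and the residual pool.
    Chains may stop short of their sampled length when the conversion
    budget runs out.
    """
    f1, f2 = config.feed
    mean_dp = config.length_model.mean_dp
    total_units = config.n_chains * mean_dp / config.target_conversion
    pool = np.array(
        [round(total_units * f1), round(total_units * f2)], dtype=np.int64
    )
    initial_pool = pool.copy()
    budget = math.floor(initial_pool.sum() * config.target_conversion)
    n = config.n_chains
    counts1 = np.zeros(n, dtype=np.int64)
    grown = np.zeros(n, dtype=np.int64)
    # terminal state per chain; -1 = chain not yet initiated
    state = np.full(n, -1, dtype=np.int64)
    order = rng.permutation(n)
    consumed = 0
    r1, r2 = config.ratios.r1, config.ratios.r2
    while consumed < budget:
        progressed = False
        for idx in order:
            if consumed >= budget:
                break
            if grown[idx] >= lengths[idx]:
                continue
            p1, p2 = float(pool[0]), float(pool[1])
            tot = p1 + p2
            if tot <= 0:
                break
            cf1, cf2 = p1 / tot, p2 / tot
            s = state[idx]
            if s == -1:
                p_add1 = cf1
            elif s == 0:
                d = r1 * cf1 + cf2
                p_add1 = r1 * cf1 / d if d > 0 else 0.0
            else:
                d = cf1 + r2 * cf2
                p_add1 = cf1 / d if d > 0 else 0.0
            add1 = rng.random() < p_add1
            if add1 and pool[0] == 0:
                add1 = False
            if not add1 and pool[1] == 0:
                add1 = True
            which = 0 if add1 else 1
            pool[which] -= 1
            counts1[idx] += add1
            grown[idx] += 1
            state[idx] = which
            consumed += 1
            progressed = True
        if not progressed:
            break
    if not np.any(grown >= 1):
        raise ValueError("pool exhausted before any chain reached length 1")
    return counts1, grown - counts1, pool


def simulate_ensemble(
    config: SimConfig,
) -> tuple[list[ChainComposition], EnsembleSummary]:
    """Simulate ``config.n_chains`` chains; reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    lengths = sample_chain_lengths(config.length_model, config.n_chains, rng)
    residual: tuple[int, ...] | None = None
    if config.pool_mode == "infinite_feed":
        counts1 = _grow_vectorized(lengths, config.feed, config.ratios, rng)
        counts2 = lengths - counts1
    else:
        counts1, counts2, pool = _simulate_finite_pool(config, lengths, rng)
        residual = tuple(int(x) for x in pool)
    keep = (counts1 + counts2) >= 1
    chains = [
        ChainComposition((int(a), int(b)))
        for a, b in zip(counts1[keep], counts2[keep])
    ]
    total_counts = np.array(
        [int(counts1[keep].sum()), int(counts2[keep].sum())], dtype=float
    )
    lens = counts1[keep] + counts2[keep]
    mn = float(lens.mean())
    mw = float((lens.astype(float) ** 2).sum() / lens.sum())
    summary = EnsembleSummary(
        n_chains=len(chains),
        mean_fractions=tuple(total_counts / total_counts.sum()),
        mn_dp=mn,
        mw_dp=mw,
        dispersity_realized=mw / mn,
        residual_pool=residual,
    )
    return chains, summary


def write_ensemble_csv(path, chains: Sequence[ChainComposition], config: SimConfig) -> None:
    """Write chains as ``chain_id,count_<m1>,count_<m2>,length``."""
    names = [m.name for m in config.monomers]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chain_id", f"count_{names[0]}", f"count_{names[1]}", "length"])
        for i, chain in enumerate(chains):
            writer.writerow([i, chain.counts[0], chain.counts[1], chain.length])


def read_ensemble_csv(path) -> list[ChainComposition]:
    """Read an ensemble CSV written by :func:`write_ensemble_csv`."""
    chains = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or len(reader.fieldnames) < 4:
            raise ValueError(f"malformed ensemble CSV: {path}")
        count_cols = [c for c in reader.fieldnames if c.startswith("count_")]
        if len(count_cols) != 2:
            raise ValueError("ensemble CSV needs exactly two count_<name> columns")
        for row in reader:
            chains.append(
                ChainComposition((int(row[count_cols[0]]), int(row[count_cols[1]])))
            )
    return chains
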