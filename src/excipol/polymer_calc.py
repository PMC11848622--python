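"""Deterministic polymer bookkeeping.

Number-average molecular weight from monomer counts, weight/mole
composition conversion, blend molecular-weight moments, and mean-count
allocation for a target Mn.  All computation is exact; rounding to the
nearest 100 g/mol happens only in the reporting layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PolymerComposition",
    "BlendComponent",
    "MONOMER_MASSES",
    "END_GROUP_MASSES",
    "mn_from_counts",
    "round_to_100",
    "wt_to_mol",
    "mol_to_wt",
    "blend_moments",
    "dp_from_target_mn",
]


def _load_mass_table() -> tuple[dict[str, float], dict[str, float]]:
    text = resources.files("excipol.data").joinpath("masses.json").read_text()
    table = json.loads(text)
    return table["monomers"], table["end_groups"]


#: monomer molar masses (g/mol) and end-group masses shipped with the package
MONOMER_MASSES, END_GROUP_MASSES = _load_mass_table()


@dataclass(frozen=True)
class PolymerComposition:
    counts: tuple[float, ...]
    molar_masses: tuple[float, ...]
    end_group_mass: float = 0.0

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.molar_masses):
            raise ValueError("counts and molar_masses must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if any(m <= 0 for m in self.molar_masses):
            raise ValueError("molar masses must be positive")
        if self.end_group_mass < 0:
            raise ValueError("end_group_mass must be non-negative")
        if all(c == 0 for c in self.counts) and self.end_group_mass == 0:
            raise ValueError("composition is empty")


@dataclass(frozen=True)
class BlendComponent:
    mn: float
    mw: float
    mass_fraction: float

    def __post_init__(self) -> None:
        if self.mn <= 0 or self.mw < self.mn:
            raise ValueError("need mw >= mn > 0")
        if not 0.0 <= self.mass_fraction <= 1.0:
            raise ValueError("mass_fraction must be in [0, 1]")


def mn_from_counts(comp: PolymerComposition) -> float:
    """Mn = sum(count_i * mass_i) + end-group mass."""
    return float(
        np.dot(comp.counts, comp.molar_masses) + comp.end_group_mass
    )


def round_to_100(mn: float) -> int:
    """Report Mn to the nearest 100 g/mol (reporting layer only)."""
    return int(round(mn / 100.0) * 100)


def wt_to_mol(
    weight_fractions: Sequence[float], molar_masses: Sequence[float]
) -> tuple[float, ...]:
    """Convert weight fractions to mole fractions: x_i ∝ w_i / m_i."""
    w = np.asarray(weight_fractions, dtype=float)
    m = np.asarray(molar_masses, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weight fractions must sum to 1")
    if (m <= 0).any():
        raise ValueError("molar masses must be positive")
    moles = w / m
    return tuple(moles / moles.sum())


def mol_to_wt(
    mole_fractions: Sequence[float], molar_masses: Sequence[float]
) -> tuple[float, ...]:
    """Inverse of :func:`wt_to_mol`."""
    x = np.asarray(mole_fractions, dtype=float)
    m = np.asarray(molar_masses, dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    if (m <= 0).any():
        raise ValueError("molar masses must be positive")
    mass = x * m
    return tuple(mass / mass.sum())


def blend_moments(
    components: Sequence[BlendComponent],
) -> tuple[float, float, float]:
    """(Mn, Mw, dispersity) of a blend mixed by mass fraction.

    Mw is mass-weighted arithmetic; Mn is the mass-weighted harmonic
    mean, since number concentration scales as w_i / Mn_i.
    """
    if not components:
        raise ValueError("need at least one component")
    w = np.array([c.mass_fraction for c in components], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mass fractions must sum to 1")
    mn = np.array([c.mn for c in components], dtype=float)
    mw = np.array([c.mw for c in components], dtype=float)
    blend_mw = float(np.dot(w, mw))
    blend_mn = float(1.0 / np.dot(w, 1.0 / mn))
    return blend_mn, blend_mw, blend_mw / blend_mn


def dp_from_target_mn(
    target_mn: float,
    weight_fractions: Sequence[float],
    molar_masses: Sequence[float],
    end_group_mass: float = 0.0,
    fixed_counts: Mapping[int, float] | None = None,
) -> tuple[float, ...]:
    """Mean per-monomer counts hitting a target Mn.

    Mass budget is ``target_mn - end_group_mass``; any ``fixed_counts``
    (index -> count, e.g. a fixed 5 hydrophobe units) are charged first,
    then the remainder is allocated across the other monomers by their
    weight fractions and divided by molar mass.  Returns real-valued
    mean counts suitable for a chain-length model.
    """
    m = np.asarray(molar_masses, dtype=float)
    w = np.asarray(weight_fractions, dtype=float)
    if w.shape != m.shape:
        raise ValueError("weight_fractions and molar_masses must align")
    budget = target_mn - end_group_mass
    if budget < 0:
        raise ValueError("target Mn below the end-group mass is infeasible")
    counts = np.zeros_like(m)
    free = np.ones(m.size, dtype=bool)
    if fixed_counts:
        for idx, cnt in fixed_counts.items():
            counts[idx] = cnt
            budget -= cnt * m[idx]
            free[idx] = False
        if budget < 0:
            raise ValueError("fixed counts exceed the target mass budget")
    w_free = w[free]
    if w_free.sum() > 0:
        alloc = budget * w_free / w_free.sum()
        counts[free] = alloc / m[free]
    elif budget > 1e-9:
        raise ValueError("mass budget left over but no free monomer to absorb it")
    return tuple(float(c) for c in counts)
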