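"""Three-regime structure-function framework and a-priori design screen.

Each excipient record carries the four measured quantities (CDI,
equilibrium surface tension, equilibration rate constant, T10).  The
framework assigns molecular-weight regimes — low (<= 8 kDa, CDI-driven),
high (>= 12 kDa, tension-driven) and intermediate (8-16 kDa,
kinetics-driven) — and fits a single-predictor ordinary least-squares
line to T10 within each regime.  Regimes deliberately overlap at the
boundaries, so a record may belong to two of them.

The design screen passes a candidate when its CDI is below ``cdi_max``
(default 3) and its rate constant is at or above ``k_min`` (default
4.3 x 10^-3 s^-1).
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExcipientRecord",
    "RegimeModel",
    "DesignCriteria",
    "ScreenVerdict",
    "REGIME_PREDICTORS",
    "MID_REGIME_LABELS",
    "assign_regimes",
    "records_in_regime",
    "fit_regime",
    "predict_t10",
    "screen_candidate",
    "read_records_csv",
    "write_records_csv",
    "model_to_json",
]

END_GROUPS = ("AIBN", "V70", "VA044", "ACVA", "CPDT", "none")

#: predictor field for each molecular-weight regime
REGIME_PREDICTORS = {
    "low_mw_cdi": "cdi",
    "high_mw_tension": "gamma_eq",
    "mid_mw_kinetics": "k_1e3_per_s",
}

#: the intermediate regime is pinned to its explicit membership list
#: (near-identical CDI and tension, differing only in kinetics)
MID_REGIME_LABELS = ("8-V70", "12-V70", "16-V70", "8-AIBN")


@dataclass(frozen=True)
class ExcipientRecord:
    """One excipient with its structural and functional read-outs."""

    label: str
    mn_kda: float | None = None
    end_group: str = "none"
    cdi: float | None = None
    gamma_eq: float | None = None
    gamma_eq_sem: float | None = None
    k_1e3_per_s: float | None = None
    k_sem: float | None = None
    t10_h: float | None = None
    t10_sem: float | None = None
    dispersity: float | None = None

    def __post_init__(self) -> None:
        if self.end_group not in END_GROUPS:
            raise ValueError(f"unknown end group {self.end_group!r}")
        for name in ("mn_kda", "cdi", "gamma_eq", "k_1e3_per_s", "t10_h"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive when present")


@dataclass(frozen=True)
class RegimeModel:
    regime: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 of a fitted line must lie in [0, 1]")

    @property
    def r_squared_percent(self) -> int:
        """R^2 as a percentage, rounded half-up to the nearest integer."""
        return int(math.floor(self.r_squared * 100.0 + 0.5))


@dataclass(frozen=True)
class DesignCriteria:
    cdi_max: float = 3.0
    k_min_1e3_per_s: float = 4.3

    def __post_init__(self) -> None:
        if self.cdi_max <= 0 or self.k_min_1e3_per_s <= 0:
            raise ValueError("criteria thresholds must be positive")


@dataclass(frozen=True)
class ScreenVerdict:
    passed: bool
    cdi_ok: bool
    kinetics_ok: bool
    quadrant: str


def assign_regimes(record: ExcipientRecord) -> set[str]:
    """Molecular-weight regime labels for a record (possibly two)."""
    if record.mn_kda is None:
        raise ValueError("record has no molecular weight")
    mn = record.mn_kda
    regimes = set()
    if mn <= 8.0:
        regimes.add("low_mw_cdi")
    if mn >= 12.0:
        regimes.add("high_mw_tension")
    if 8.0 <= mn <= 16.0:
        regimes.add("mid_mw_kinetics")
    return regimes


def records_in_regime(
    records: Sequence[ExcipientRecord], regime: str
) -> list[ExcipientRecord]:
    """Regime membership; the mid regime uses its pinned label set."""
    if regime not in REGIME_PREDICTORS:
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "mid_mw_kinetics":
        by_label = {r.label: r for r in records}
        return [by_label[lab] for lab in MID_REGIME_LABELS if lab in by_label]
    predictor = REGIME_PREDICTORS[regime]
    members = [
        r
        for r in records
        if r.mn_kda is not None
        and regime in assign_regimes(r)
        and getattr(r, predictor) is not None
        and r.t10_h is not None
    ]
    # the low/high fits characterise the end-group-matched molecular-weight
    # ladder (the V70 series); same-Mn variants with other end groups belong
    # to the kinetics regime only
    v70 = [r for r in members if r.end_group == "V70"]
    return v70 if v70 else members


def fit_regime(records: Sequence[ExcipientRecord], regime: str) -> RegimeModel:
    """OLS of T10 on the regime predictor, with intercept.

    R^2 is computed as the squared Pearson correlation, which coincides
    with the coefficient of determination for a fitted line.
    """
    members = records_in_regime(records, regime)
    predictor = REGIME_PREDICTORS[regime]
    x = np.array([getattr(r, predictor) for r in members], dtype=float)
    y = np.array([r.t10_h for r in members], dtype=float)
    if x.size < 3:
        raise ValueError(
            f"regime {regime!r} has {x.size} usable records; need at least 3"
        )
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return RegimeModel(
        regime=regime,
        predictor=predictor,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r * r),
        n=int(x.size),
    )


def predict_t10(model: RegimeModel, predictor_value: float) -> float:
    """Linear read-out; negative predictions are clamped to 0 with a warning."""
    value = model.slope * predictor_value + model.intercept
    if value < 0:
        warnings.warn(
            f"predicted T10 {value:.3g} h is negative; clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return float(value)


def screen_candidate(
    cdi: float, k_1e3_per_s: float, criteria: DesignCriteria = DesignCriteria()
) -> ScreenVerdict:
    """A-priori screen: low compositional dispersity and fast kinetics."""
    cdi_ok = cdi < criteria.cdi_max
    kinetics_ok = k_1e3_per_s >= criteria.k_min_1e3_per_s
    quadrant = ("low-CDI" if cdi_ok else "high-CDI") + (
        "/fast" if kinetics_ok else "/slow"
    )
    return ScreenVerdict(
        passed=cdi_ok and kinetics_ok,
        cdi_ok=cdi_ok,
        kinetics_ok=kinetics_ok,
        quadrant=quadrant,
    )


_CSV_COLUMNS = [
    "label",
    "mn_kda",
    "end_group",
    "gamma_eq",
    "gamma_eq_sem",
    "k_1e3_per_s",
    "k_sem",
    "cdi",
    "t10_h",
    "t10_sem",
    "dispersity",
]


def _parse_optional(value: str) -> float | None:
    value = value.strip()
    if value in ("", "NA", "N/A", "nan"):
        return None
    return float(value)


def read_records_csv(path) -> list[ExcipientRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "label" not in reader.fieldnames:
            raise ValueError(f"records CSV {path} must have a 'label' column")
        for row in reader:
            kwargs = {"label": row["label"], "end_group": row.get("end_group", "none") or "none"}
            for name in _CSV_COLUMNS:
                if name in ("label", "end_group"):
                    continue
                if name in row and row[name] is not None:
                    kwargs[name] = _parse_optional(row[name])
            records.append(ExcipientRecord(**kwargs))
    return records


def write_records_csv(path, records: Sequence[ExcipientRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                ["" if getattr(r, c) is None else getattr(r, c) for c in _CSV_COLUMNS]
            )


def model_to_json(models: Sequence[RegimeModel]) -> str:
    return json.dumps(
        [
            {
                "regime": m.regime,
                "predictor": m.predictor,
                "slope": m.slope,
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "r_squared_percent": m.r_squared_percent,
                "n": m.n,
            }
            for m in models
        ],
        indent=2,
    )
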