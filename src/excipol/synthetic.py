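"""Seeded generators for every input the analysis pipeline consumes.

Turbidity curves are logistic (flat lag, sharp rise, plateau) with
additive Gaussian noise clipped at zero; tension traces are one-phase
exponential decays with plateau noise.  Every generator is a pure
function of its parameter record, including the seed.  The re-entered
excipient summary table ships as a package fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from excipol.aggregation import AssayCurve
from excipol.structure_function import ExcipientRecord, read_records_csv
from excipol.surface import TensionTrace

__all__ = [
    "TurbidityParams",
    "TensionParams",
    "make_turbidity_curve",
    "make_tension_trace",
    "make_table4_fixture",
    "logistic_absorbance",
]


@dataclass(frozen=True)
class TurbidityParams:
    baseline: float = 0.05
    amplitude: float = 1.0
    t_mid: float = 12.0
    width: float = 0.5
    noise_sd: float = 0.0
    n_points: int = 200
    t_end: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.width <= 0:
            raise ValueError("amplitude and width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points < 2 or self.t_end <= 0:
            raise ValueError("need n_points >= 2 and t_end > 0")


@dataclass(frozen=True)
class TensionParams:
    gamma0: float = 72.0
    gamma_eq: float = 50.0
    k: float = 4.5e-3
    noise_sd: float = 0.0
    sampling_hz: float = 1.0
    t_end: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gamma0 >= self.gamma_eq > 0:
            raise ValueError("need gamma0 >= gamma_eq > 0")
        if self.k < 0 or self.noise_sd < 0:
            raise ValueError("k and noise_sd must be non-negative")
        if self.sampling_hz <= 0 or self.t_end <= 0:
            raise ValueError("sampling_hz and t_end must be positive")


def logistic_absorbance(t: np.ndarray, params: TurbidityParams) -> np.ndarray:
    """Noise-free logistic turbidity model (closed form, used by oracles too)."""
    return params.baseline + params.amplitude / (
        1.0 + np.exp(-(t - params.t_mid) / params.width)
    )


def make_turbidity_curve(params: TurbidityParams, replicate_id: str = "0") -> AssayCurve:
    """Sigmoidal aggregation curve with lag, growth, plateau and noise."""
    rng = np.random.default_rng(params.seed)
    t = np.linspace(0.0, params.t_end, params.n_points)
    a = logistic_absorbance(t, params)
    if params.noise_sd > 0:
        a = a + rng.normal(0.0, params.noise_sd, size=t.size)
    a = np.clip(a, 0.0, None)
    return AssayCurve(times=t, absorbance=a, replicate_id=replicate_id)


def make_tension_trace(params: TensionParams, label: str = "") -> TensionTrace:
    """Exponential-decay tension trace with plateau noise."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.t_end * params.sampling_hz)) + 1
    t = np.arange(n) / params.sampling_hz
    g = params.gamma_eq + (params.gamma0 - params.gamma_eq) * np.exp(-params.k * t)
    if params.noise_sd > 0:
        g = g + rng.normal(0.0, params.noise_sd, size=t.size)
    return TensionTrace(times=t, tension=np.clip(g, 1e-6, None), label=label)


def make_table4_fixture() -> list[ExcipientRecord]:
    """The re-entered excipient summary table (7 polymers + buffer control)."""
    with resources.as_file(
        resources.files("excipol.data").joinpath("table4.csv")
    ) as path:
        return read_records_csv(path)
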