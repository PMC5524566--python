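"""Instrument measures derived from population currents.

The field potential and the hemodynamic response pool the same dendritic
currents with the two orders of (sum across neurons, square over time):

* LFP power — *power of the sum*: square the summed time series, then
  average over the window. Sensitive to across-neuron synchrony.
* BOLD proxy — *sum of the power*: average each neuron's squared series
  over the window, then sum across neurons. Blind to synchrony.

Their difference is exactly the summed cross-power over ordered neuron
pairs, so ``power_of_sum = sum_of_power + cross_power`` holds identically
for any finite set of time series.

For a population whose time series are multivariate Gaussian with common
mean m, variance sigma^2 and pairwise correlation rho, both measures have
closed forms:

    BOLD      = beta * n * (m^2 + sigma^2)
    LFP power = alpha * [n * (m^2 + sigma^2) + (n^2 - n) * (m^2 + sigma^2 * rho)]

so the BOLD proxy is independent of rho while the LFP grows linearly in it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .population import PopulationCurrents


@dataclass(frozen=True)
class MeasureConfig:
    """Instrument gain constants and the power normalization.

    ``alpha_scale`` is the electrode gain applied to the summed series
    before squaring (LFP power therefore scales as alpha^2);
    ``beta_scale`` is a linear neurovascular gain on the summed power.
    ``power_convention`` chooses between the time-mean of squared samples
    (duration-invariant; a unit sinusoid has power 0.5) and the raw sum of
    squares.
    """

    alpha_scale: float = 1.0
    beta_scale: float = 1.0
    power_convention: Literal["mean", "sum"] = "mean"

    def __post_init__(self) -> None:
        if self.alpha_scale <= 0 or self.beta_scale <= 0:
            raise ValueError("gain scales must be positive")
        if self.power_convention not in ("mean", "sum"):
            raise ValueError(
                f"unknown power convention {self.power_convention!r}"
            )


def _power(x: np.ndarray, convention: str) -> np.ndarray:
    sq = np.square(x)
    return sq.mean(axis=-1) if convention == "mean" else sq.sum(axis=-1)


def lfp_timeseries(
    pc: PopulationCurrents, mc: MeasureConfig = MeasureConfig()
) -> np.ndarray:
    """Simulated electrode trace: alpha times the summed currents."""
    return mc.alpha_scale * pc.currents.sum(axis=0)


def lfp_power(pc: PopulationCurrents, mc: MeasureConfig = MeasureConfig()) -> float:
    """Power of the summed (gain-scaled) currents over the window."""
    return float(_power(lfp_timeseries(pc, mc), mc.power_convention))


def bold_proxy(pc: PopulationCurrents, mc: MeasureConfig = MeasureConfig()) -> float:
    """Summed per-neuron power — the metabolic-demand (BOLD) proxy."""
    per_neuron = _power(pc.currents, mc.power_convention)
    return float(mc.beta_scale * per_neuron.sum())


def cross_power(pc: PopulationCurrents, mc: MeasureConfig = MeasureConfig()) -> float:
    """Summed cross-power over ordered pairs of distinct neurons.

    Computed directly from the Gram matrix of the currents (not by
    subtracting sum-of-power from power-of-sum), scaled by alpha^2 to
    match the LFP-power convention.
    """
    currents = pc.currents
    norm = currents.shape[-1] if mc.power_convention == "mean" else 1
    gram = (currents @ currents.T) / norm
    return float(mc.alpha_scale**2 * (gram.sum() - np.trace(gram)))


@dataclass(frozen=True)
class GaussianPopulationSpec:
    """Equicorrelated Gaussian population: n neurons, common mean ``m``,
    variance ``sigma2`` and pairwise correlation ``rho``."""

    n: int
    m: float = 0.0
    sigma2: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        lo = -1.0 / (self.n - 1) if self.n > 1 else -1.0
        if not lo <= self.rho <= 1.0:
            raise ValueError(
                f"rho={self.rho} outside positive-semidefinite range "
                f"[{lo}, 1] for n={self.n}"
            )


def analytic_bold(spec: GaussianPopulationSpec, beta: float = 1.0) -> float:
    """Expected sum-of-power: beta * n * (m^2 + sigma^2); rho-free."""
    return beta * spec.n * (spec.m**2 + spec.sigma2)


def analytic_lfp_power(spec: GaussianPopulationSpec, alpha: float = 1.0) -> float:
    """Expected power-of-sum:
    alpha * [n*(m^2 + sigma^2) + (n^2 - n)*(m^2 + sigma^2 * rho)]."""
    n = spec.n
    return alpha * (
        n * (spec.m**2 + spec.sigma2)
        + (n**2 - n) * (spec.m**2 + spec.sigma2 * spec.rho)
    )


def analytic_cross_power(spec: GaussianPopulationSpec, alpha: float = 1.0) -> float:
    """Expected summed cross-power: alpha * (n^2 - n) * (m^2 + sigma^2*rho)."""
    return alpha * (spec.n**2 - spec.n) * (spec.m**2 + spec.sigma2 * spec.rho)


def sample_gaussian_population(
    spec: GaussianPopulationSpec,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an (n, n_samples) equicorrelated Gaussian time-series matrix."""
    if spec.rho < 0:
        raise ValueError("shared-factor sampling requires rho >= 0")
    sigma = np.sqrt(spec.sigma2)
    private = rng.standard_normal((spec.n, n_samples))
    common = rng.standard_normal(n_samples)
    return spec.m + sigma * (
        np.sqrt(spec.rho) * common[None, :] + np.sqrt(1.0 - spec.rho) * private
    )


def sweep_gaussian_surfaces(
    m_values,
    sigma_values,
    rho_values,
    n: int = 5,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> pd.DataFrame:
    """Tabulate the closed forms over a (m, sigma, rho) grid.

    ``sigma_values`` are standard deviations; the returned table carries
    one row per grid point with columns ``lfp_power``, ``bold`` and
    ``cross_power``.
    """
    rows = []
    for m, sigma, rho in itertools.product(m_values, sigma_values, rho_values):
        spec = GaussianPopulationSpec(n=n, m=m, sigma2=sigma**2, rho=rho)
        rows.append(
            {
                "m": m,
                "sigma": sigma,
                "rho": rho,
                "lfp_power": analytic_lfp_power(spec, alpha),
                "bold": analytic_bold(spec, beta),
                "cross_power": analytic_cross_power(spec, alpha),
            }
        )
    return pd.DataFrame(rows)


def measure_table(exp, mc: MeasureConfig = MeasureConfig()) -> pd.DataFrame:
    """Per-trial measure table: condition, trial, lfp_power, bold_proxy,
    cross_power."""
    rows = []
    for label, trials in exp.trials.items():
        for pc in trials:
            rows.append(
                {
                    "condition": label,
                    "trial": pc.trial_index,
                    "lfp_power": lfp_power(pc, mc),
                    "bold_proxy": bold_proxy(pc, mc),
                    "cross_power": cross_power(pc, mc),
                }
            )
    return pd.DataFrame(rows)
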