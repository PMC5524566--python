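"""Per-neuron synaptic input generators.

Three input classes drive the simulated population, each targeting one
spectral signature of the field potential:

* ``C1`` — Gaussian white noise with a small positive mean, independent
  across neurons and time. Emulates asynchronous excitatory spike arrivals;
  its variance sets the broadband (1/f^n-elevating) response level.
* ``C2`` — equicorrelated Gaussian noise band-pass filtered in the gamma
  range. Its across-neuron coherence, not its per-neuron level, varies
  between conditions, emulating synchrony-driven narrowband gamma.
* ``C3`` — equicorrelated Gaussian noise band-pass filtered in the alpha
  range, with its analytic (Hilbert) envelope added and the result negated,
  so that stronger alpha rhythms hyperpolarize: the time-average becomes
  more negative as the amplitude grows.

All generators are pure functions of (config, strengths, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import (
    C1_MEAN_DEFAULT,
    C2_SIGMA,
    C3_RHO,
    InputCondition,
    TrialConfig,
    substream,
)

#: Gamma-band pass band in Hz. The narrowband gamma rhythm peaks in the
#: 40-60 Hz range; that full range is the default band so the simulated
#: peak's core stays clear of the 55-65 Hz line-noise exclusion used in
#: spectral fitting.
GAMMA_BAND = (40.0, 60.0)

#: Alpha-band pass band in Hz.
ALPHA_BAND = (9.0, 12.0)

#: Butterworth filter order (applied forward and reverse, so the effective
#: attenuation is doubled).
FILTER_ORDER = 10

#: Zero-padding added to each side of a trial before forward-reverse
#: filtering, in seconds. One second covers >= 9 alpha cycles, enough to
#: suppress edge transients in the pass band.
FILTER_PAD_SECONDS = 1.0


@dataclass(frozen=True)
class InputSet:
    """The three component input matrices and their sum for one trial."""

    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.c1, self.c2, self.c3, self.total)}
        if len(shapes) != 1:
            raise ValueError(f"component shapes differ: {shapes}")


def _equicorrelated_normal(
    rng: np.random.Generator,
    n_neurons: int,
    n_samples: int,
    sigma: float,
    rho: float,
) -> np.ndarray:
    """Sample an equicorrelated multivariate normal via a shared factor.

    x_i = sqrt(rho) * z_common + sqrt(1 - rho) * z_i reproduces the
    equicorrelation covariance exactly for rho in [0, 1] without forming
    an n x n covariance matrix.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"equicorrelation must be in [0, 1], got {rho}")
    private = rng.standard_normal((n_neurons, n_samples))
    common = rng.standard_normal(n_samples)
    return sigma * (np.sqrt(rho) * common[None, :] + np.sqrt(1.0 - rho) * private)


def bandpass_filtfilt(
    x: np.ndarray,
    band: tuple[float, float],
    fs: float,
    order: int = FILTER_ORDER,
    pad_seconds: float = FILTER_PAD_SECONDS,
) -> np.ndarray:
    """Zero-pad, band-pass (Butterworth, forward and reverse), unpad.

    Second-order sections keep the high-order band-pass numerically stable.
    Forward-reverse application gives zero phase distortion.
    """
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    pad = int(round(pad_seconds * fs))
    xp = np.pad(np.atleast_2d(x), ((0, 0), (pad, pad)))
    y = signal.sosfiltfilt(sos, xp, axis=-1, padtype=None)
    out = y[:, pad : y.shape[-1] - pad]
    return out if x.ndim > 1 else out[0]


def gen_broadband_input(
    cfg: TrialConfig,
    c1_sigma: float,
    c1_mean: float = C1_MEAN_DEFAULT,
    rho: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Broadband input: white Gaussian noise, uncorrelated across neurons.

    ``rho`` is normally 0 (asynchronous drive); a nonzero value is only
    used by the alternative "broadband-by-correlation" model variants.
    """
    if c1_sigma < 0:
        raise ValueError(f"c1_sigma must be >= 0, got {c1_sigma}")
    if rng is None:
        rng = substream(cfg.rng_seed, "c1")
    if rho == 0.0:
        draw = rng.standard_normal((cfg.n_neurons, cfg.n_samples)) * c1_sigma
    else:
        draw = _equicorrelated_normal(
            rng, cfg.n_neurons, cfg.n_samples, c1_sigma, rho
        )
    return draw + c1_mean


def gen_gamma_input(
    cfg: TrialConfig,
    c2_coherence: float,
    c2_sigma: float = C2_SIGMA,
    band: tuple[float, float] = GAMMA_BAND,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gamma input: equicorrelated noise band-passed in the gamma range."""
    if not 0.0 <= c2_coherence <= 1.0:
        raise ValueError(
            f"c2_coherence must be in [0, 1], got {c2_coherence}"
        )
    if rng is None:
        rng = substream(cfg.rng_seed, "c2")
    raw = _equicorrelated_normal(
        rng, cfg.n_neurons, cfg.n_samples, c2_sigma, c2_coherence
    )
    return bandpass_filtfilt(raw, band, cfg.fs)


def gen_alpha_input(
    cfg: TrialConfig,
    c3_amplitude: float,
    rho: float = C3_RHO,
    band: tuple[float, float] = ALPHA_BAND,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Alpha input: inhibitory band-passed noise with envelope asymmetry.

    The analytic envelope (always nonnegative) is added to the filtered
    signal before negation, so the output's time-average is nonpositive and
    decreases as ``c3_amplitude`` grows — pulsed inhibition whose strength
    tracks the alpha rhythm's amplitude.
    """
    if c3_amplitude < 0:
        raise ValueError(f"c3_amplitude must be >= 0, got {c3_amplitude}")
    if rng is None:
        rng = substream(cfg.rng_seed, "c3")
    raw = _equicorrelated_normal(rng, cfg.n_neurons, cfg.n_samples, 1.0, rho)
    filtered = bandpass_filtfilt(raw, band, cfg.fs)
    envelope = np.abs(signal.hilbert(filtered, axis=-1))
    return -1.0 * (filtered + envelope) * c3_amplitude


@dataclass(frozen=True)
class VariantSpec:
    """Which knob (per-neuron level vs across-neuron correlation) each
    input class varies for fitting.

    The default, ``("level", "correlation", "level")``, is the main model:
    broadband and alpha vary in level, gamma in coherence. Under a
    non-default mode the corresponding strength in :class:`InputCondition`
    is reinterpreted as the varied quantity while the usual knob is held at
    its baseline value.
    """

    c1: str = "level"
    c2: str = "correlation"
    c3: str = "level"

    def __post_init__(self) -> None:
        for name in (self.c1, self.c2, self.c3):
            if name not in ("level", "correlation"):
                raise ValueError(f"unknown variant mode {name!r}")

    @property
    def is_default(self) -> bool:
        return (self.c1, self.c2, self.c3) == ("level", "correlation", "level")


#: Fixed values used when a variant holds a knob constant.
VARIANT_FIXED = {
    "c1_rho_varying_sigma": 0.3,  # sigma held here when C1 varies by correlation
    "c2_rho_fixed": 0.75,  # coherence held here when C2 varies by level
    "c3_amplitude_fixed": 1.0,  # amplitude held here when C3 varies by correlation
}


def build_input_set(
    cfg: TrialConfig,
    cond: InputCondition,
    c1_mean: float = C1_MEAN_DEFAULT,
    c2_sigma: float = C2_SIGMA,
    variant: VariantSpec | None = None,
    rng_key: tuple = (),
) -> InputSet:
    """Generate the three input components and their sum for one trial.

    Components draw from independent RNG substreams keyed by
    ``(seed, *rng_key, component)`` so each is reproducible in isolation.
    Note the gamma input's per-neuron level is fixed (``c2_sigma``) on all
    trials — the condition varies only its coherence — so a coherence of 0
    still contributes incoherent gamma-band noise; pass ``c2_sigma=0`` to
    silence it entirely.
    """
    variant = variant or VariantSpec()
    key = lambda name: substream(cfg.rng_seed, *rng_key, name)

    if variant.c1 == "level":
        c1 = gen_broadband_input(cfg, cond.c1_sigma, c1_mean, rng=key("c1"))
    else:
        c1 = gen_broadband_input(
            cfg,
            VARIANT_FIXED["c1_rho_varying_sigma"],
            c1_mean,
            rho=cond.c1_sigma,  # strength reinterpreted as correlation
            rng=key("c1"),
        )

    if variant.c2 == "correlation":
        c2 = gen_gamma_input(
            cfg, cond.c2_coherence, c2_sigma=c2_sigma, rng=key("c2")
        )
    else:
        c2 = gen_gamma_input(
            cfg,
            VARIANT_FIXED["c2_rho_fixed"],
            c2_sigma=cond.c2_coherence,  # strength reinterpreted as level
            rng=key("c2"),
        )

    if variant.c3 == "level":
        c3 = gen_alpha_input(cfg, cond.c3_amplitude, rng=key("c3"))
    else:
        c3 = gen_alpha_input(
            cfg,
            VARIANT_FIXED["c3_amplitude_fixed"],
            rho=cond.c3_amplitude,  # strength reinterpreted as correlation
            rng=key("c3"),
        )

    return InputSet(c1=c1, c2=c2, c3=c3, total=c1 + c2 + c3)
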