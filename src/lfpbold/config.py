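"""Core configuration objects shared across the simulation pipeline.

A simulated "experiment" mirrors a visual ECoG session: a population of
pyramidal-like neurons produces 1-second trials of dendritic current, with
each stimulus condition defined by the strengths of three synaptic input
classes (asynchronous broadband drive, coherence-varying gamma-band drive,
and inhibitory alpha-band drive).
"""

from __future__ import annotations

import hashlib
import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

#: Mean of the broadband (excitatory) input current. The small positive
#: offset keeps the baseline membrane state slightly depolarized so that
#: inhibitory alpha input can pull it back toward zero.
C1_MEAN_DEFAULT = 0.25

#: Per-neuron standard deviation of the broadband input in the baseline
#: (blank-screen) state.
C1_SIGMA_BASELINE = 0.3

#: Per-neuron standard deviation of the gamma-band input (fixed across
#: conditions; only the across-neuron coherence varies).
C2_SIGMA = 0.2

#: Across-neuron correlation of the alpha-band input (fixed).
C3_RHO = 0.75

#: Alpha-input amplitude of the baseline (blank) state. The blank screen is
#: the high-alpha state in visual cortex, so the baseline carries a strong
#: alpha rhythm; stimulus conditions reduce (or occasionally raise) it.
C3_AMPLITUDE_BASELINE = 1.0


@dataclass(frozen=True)
class TrialConfig:
    """Shape of a single simulated trial.

    Parameters
    ----------
    n_neurons:
        Number of neurons in the population (default 200).
    duration:
        Trial length in seconds (default 1.0).
    dt:
        Sampling step in seconds (default 0.001, i.e. millisecond sampling).
    rng_seed:
        Master seed; all randomness is a pure function of this seed plus
        the deterministic substream keys (see :func:`substream`).
    """

    n_neurons: int = 200
    duration: float = 1.0
    dt: float = 0.001
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError(f"n_neurons must be >= 1, got {self.n_neurons}")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("duration and dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                "duration/dt must be a positive integer number of samples"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt


@dataclass(frozen=True)
class InputCondition:
    """Input strengths defining one stimulus condition.

    ``c1_sigma`` is the per-neuron standard deviation of the broadband
    input, ``c2_coherence`` the pairwise correlation of the gamma-band
    input, and ``c3_amplitude`` the scale of the inhibitory alpha input.
    """

    label: str
    c1_sigma: float = C1_SIGMA_BASELINE
    c2_coherence: float = 0.0
    c3_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.c1_sigma < 0:
            raise ValueError(f"c1_sigma must be >= 0, got {self.c1_sigma}")
        if not 0.0 <= self.c2_coherence <= 1.0:
            raise ValueError(
                f"c2_coherence must be in [0, 1], got {self.c2_coherence}"
            )
        if self.c3_amplitude < 0:
            raise ValueError(
                f"c3_amplitude must be >= 0, got {self.c3_amplitude}"
            )


def baseline_condition(label: str = "blank") -> InputCondition:
    """The default baseline (blank-screen) condition.

    Broadband at its resting level, no gamma coherence, and a prominent
    alpha rhythm — the state against which all spectral components are
    measured.
    """
    return InputCondition(
        label=label,
        c1_sigma=C1_SIGMA_BASELINE,
        c2_coherence=0.0,
        c3_amplitude=C3_AMPLITUDE_BASELINE,
    )


@dataclass(frozen=True)
class PopulationConfig:
    """Population-level dynamics parameters.

    ``tau`` is the membrane (leaky-integration) time constant in seconds;
    ``burn_in`` optionally pre-equilibrates each trial by holding the first
    input sample for ``burn_in`` seconds before t=0 (default off).
    """

    tau: float = 0.010
    trial: TrialConfig = field(default_factory=TrialConfig)
    burn_in: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.tau < 5 * self.trial.dt:
            warnings.warn(
                f"tau={self.tau} is less than 5*dt={5 * self.trial.dt}; "
                "integration may be poorly resolved",
                stacklevel=2,
            )


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic RNG substream derived from a master seed and keys.

    Keys (condition labels, trial indices, component names, ...) are hashed
    with CRC-32 into the SeedSequence entropy pool, so every (seed, keys)
    combination yields an independent, reproducible stream, and streams are
    insensitive to the order in which other streams are drawn.
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def config_digest(obj) -> str:
    """Short stable hash of a (dataclass or mapping) configuration."""
    try:
        payload = asdict(obj)
    except TypeError:
        payload = obj
    text = repr(sorted(np.ravel([f"{k}={v}" for k, v in payload.items()])))
    return hashlib.sha1(text.encode("utf-8")).hexdigest()[:12]


def load_config(path) -> tuple[PopulationConfig, list[InputCondition]]:
    """Read a YAML configuration file.

    Expected keys: ``n_neurons``, ``duration_s``, ``dt_s``, ``seed``,
    ``tau_s`` (optional) and a ``conditions`` mapping of
    ``label: {c1_sigma, c2_coherence, c3_amplitude}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    trial = TrialConfig(
        n_neurons=int(raw.get("n_neurons", 200)),
        duration=float(raw.get("duration_s", 1.0)),
        dt=float(raw.get("dt_s", 0.001)),
        rng_seed=int(raw.get("seed", 0)),
    )
    pcfg = PopulationConfig(tau=float(raw.get("tau_s", 0.010)), trial=trial)
    conditions = []
    for label, knobs in (raw.get("conditions") or {}).items():
        knobs = knobs or {}
        conditions.append(
            InputCondition(
                label=str(label),
                c1_sigma=float(knobs.get("c1_sigma", C1_SIGMA_BASELINE)),
                c2_coherence=float(knobs.get("c2_coherence", 0.0)),
                c3_amplitude=float(knobs.get("c3_amplitude", 0.0)),
            )
        )
    return pcfg, conditions
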