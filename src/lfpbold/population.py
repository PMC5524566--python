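"""Leaky dendritic integration and multi-trial experiment orchestration."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import (
    InputCondition,
    PopulationConfig,
    config_digest,
    substream,
)
from .inputs import VariantSpec, build_input_set


@dataclass(frozen=True)
class PopulationCurrents:
    """Neurons x time matrix of dendritic currents for one trial."""

    currents: np.ndarray
    condition_label: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.currents)):
            raise ValueError("currents contain non-finite values")

    @property
    def n_neurons(self) -> int:
        return self.currents.shape[0]

    @property
    def n_samples(self) -> int:
        return self.currents.shape[1]


def leaky_integrate(
    total_input: np.ndarray,
    tau: float,
    dt: float,
    condition_label: str = "",
    trial_index: int = 0,
    burn_in: float = 0.0,
) -> PopulationCurrents:
    """Integrate input currents through first-order leaky dynamics.

    Solves tau * dI/dt = -I + C per neuron with the exponential-Euler
    update ``I[k+1] = I[k] * exp(-dt/tau) + C[k] * (1 - exp(-dt/tau))``,
    which is exact for piecewise-constant input and unconditionally stable.
    The result is a low-pass filtered version of the input with unit DC
    gain and cutoff near 1/(2*pi*tau).

    With ``burn_in`` > 0, the initial state is set as if the first input
    sample had been applied for that many seconds before t=0; the default
    is a zero initial condition.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    total_input = np.atleast_2d(np.asarray(total_input, dtype=float))
    if not np.all(np.isfinite(total_input)):
        raise ValueError("input contains non-finite values")
    decay = np.exp(-dt / tau)
    gain = 1.0 - decay
    # I[k] = decay * I[k-1] + gain * C[k-1]  <=>  IIR filter b=[0,g], a=[1,-decay]
    if burn_in > 0:
        # lfilter (direct form II transposed) gives y[0] = zi, so the
        # state reached by holding C[0] for burn_in seconds seeds I[0].
        i0 = total_input[:, 0] * (1.0 - np.exp(-burn_in / tau))
        currents, _ = signal.lfilter(
            [0.0, gain], [1.0, -decay], total_input, axis=-1, zi=i0[:, None]
        )
    else:
        currents = signal.lfilter(
            [0.0, gain], [1.0, -decay], total_input, axis=-1
        )
    return PopulationCurrents(
        currents=currents,
        condition_label=condition_label,
        trial_index=trial_index,
    )


@dataclass
class Experiment:
    """All trials of a simulated session, grouped by condition."""

    conditions: list[InputCondition]
    n_repeats: int
    trials: dict[str, list[PopulationCurrents]]
    provenance: dict = field(default_factory=dict)

    def condition_trials(self, label: str) -> list[PopulationCurrents]:
        return self.trials[label]

    @property
    def n_trials(self) -> int:
        return sum(len(v) for v in self.trials.values())


def simulate_trial(
    pcfg: PopulationConfig,
    cond: InputCondition,
    trial_index: int,
    seed: int | None = None,
    variant: VariantSpec | None = None,
) -> PopulationCurrents:
    """One trial: generate inputs, sum, and integrate."""
    cfg = pcfg.trial
    if seed is not None:
        cfg = type(cfg)(
            n_neurons=cfg.n_neurons,
            duration=cfg.duration,
            dt=cfg.dt,
            rng_seed=seed,
        )
    inputs = build_input_set(
        cfg, cond, variant=variant, rng_key=(cond.label, trial_index)
    )
    return leaky_integrate(
        inputs.total,
        pcfg.tau,
        cfg.dt,
        condition_label=cond.label,
        trial_index=trial_index,
        burn_in=pcfg.burn_in,
    )


def simulate_condition(
    pcfg: PopulationConfig,
    cond: InputCondition,
    n_repeats: int,
    seed: int | None = None,
    variant: VariantSpec | None = None,
) -> list[PopulationCurrents]:
    """Simulate ``n_repeats`` independent trials of one condition.

    Trial substreams are keyed by (condition label, trial index), so
    per-condition content is independent of condition ordering.
    """
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    return [
        simulate_trial(pcfg, cond, k, seed=seed, variant=variant)
        for k in range(n_repeats)
    ]


def simulate_experiment(
    pcfg: PopulationConfig,
    conditions: list[InputCondition],
    n_repeats: int = 30,
    seed: int | None = None,
    variant: VariantSpec | None = None,
) -> Experiment:
    """Simulate every condition; 8 conditions x 30 repeats by default."""
    labels = [c.label for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate condition labels: {labels}")
    trials = {
        cond.label: simulate_condition(
            pcfg, cond, n_repeats, seed=seed, variant=variant
        )
        for cond in conditions
    }
    effective_seed = pcfg.trial.rng_seed if seed is None else seed
    return Experiment(
        conditions=list(conditions),
        n_repeats=n_repeats,
        trials=trials,
        provenance={
            "seed": effective_seed,
            "config_digest": config_digest(pcfg.trial),
            "tau": pcfg.tau,
            "variant": str(variant or VariantSpec()),
        },
    )


def trial_summary_table(exp: Experiment) -> pd.DataFrame:
    """Compact per-trial summary (mean and variance of the currents)."""
    rows = []
    for label, trials in exp.trials.items():
        for pc in trials:
            rows.append(
                {
                    "condition": label,
                    "trial": pc.trial_index,
                    "mean_current": float(pc.currents.mean()),
                    "var_current": float(pc.currents.var()),
                }
            )
    return pd.DataFrame(rows)
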