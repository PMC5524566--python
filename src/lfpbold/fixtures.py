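"""Synthetic component/BOLD tables emulating visual-cortex experiments.

A scenario mimics the stimulus structure of the source experiments: four
grating conditions, three noise-pattern conditions and one blank. Gratings
drive broadband and narrowband gamma up and alpha down; noise patterns
drive broadband up with essentially no gamma and (in extrastriate-like
profiles) stronger alpha suppression; the blank is the baseline and is
exactly zero in all components.

Two built-in profiles differ the way early and extrastriate sites differ:

* ``V1-like`` — broadband is the dominant varying component across
  conditions; alpha modulation is weak and similar across stimuli.
* ``V2V3-like`` — broadband variation is modest while alpha suppression is
  deep and varies strongly (deepest for noise patterns), making alpha the
  informative predictor of BOLD.

``make_bold_table`` produces matching BOLD amplitudes either through the
full simulation pipeline (model-consistent) or independently of the
components (decoupled negative control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PopulationConfig, substream
from .inputs import VariantSpec
from .measures import MeasureConfig, bold_proxy
from .population import Experiment, simulate_experiment
from .spectral import summarize_experiment
from .calibration import conditions_from_table, invert_components

#: Component ranges (log10-power units) per condition class and profile.
#: Values are uniform-draw bounds; the blank is always exactly zero.
PROFILES = {
    "V1-like": {
        "grating": {
            "broadband": (0.20, 0.55),
            "gamma": (0.10, 0.40),
            "alpha": (-0.10, -0.02),
        },
        "noise": {
            "broadband": (0.25, 0.60),
            "gamma": (0.00, 0.04),
            "alpha": (-0.12, -0.04),
        },
    },
    # Extrastriate-like: broadband responses are present but similar
    # across stimuli (so broadband alone barely predicts BOLD), while
    # alpha suppression is deep and varies strongly, deepest for noise
    # patterns.
    "V2V3-like": {
        "grating": {
            "broadband": (0.10, 0.22),
            "gamma": (0.10, 0.40),
            "alpha": (-0.25, -0.08),
        },
        "noise": {
            "broadband": (0.12, 0.25),
            "gamma": (0.00, 0.04),
            "alpha": (-0.55, -0.30),
        },
    },
}

N_GRATINGS = 4
N_NOISE = 3

#: Default BOLD replicate noise per profile, as a fraction of the
#: across-condition spread of the simulated BOLD means. Chosen so the
#: split-half BOLD reliability of a scenario resembles early visual cortex
#: (high in V1-like sites, lower in extrastriate-like sites).
PROFILE_BOLD_NOISE_FRAC = {"V1-like": 0.35, "V2V3-like": 0.5}


@dataclass(frozen=True)
class ScenarioSpec:
    """A synthetic experiment scenario.

    ``profile`` picks the component ranges ("V1-like", "V2V3-like", or
    "custom" with explicit ``ranges``); ``bold_noise_sd`` adds Gaussian
    measurement noise to BOLD replicates (in BOLD units, default none —
    simulation trial noise already makes replicates differ); ``site``
    labels the output tables.
    """

    profile: str = "V1-like"
    n_conditions: int = N_GRATINGS + N_NOISE + 1
    bold_noise_sd: float = 0.0
    bold_noise_frac: float | None = None
    seed: int = 0
    site: str = "site0"
    ranges: dict | None = field(default=None)

    def __post_init__(self) -> None:
        if self.profile not in PROFILES and self.profile != "custom":
            raise ValueError(
                f"unknown profile {self.profile!r}; "
                f"choose from {sorted(PROFILES)} or 'custom'"
            )
        if self.profile == "custom" and self.ranges is None:
            raise ValueError("custom profile requires explicit ranges")
        if self.n_conditions != N_GRATINGS + N_NOISE + 1:
            raise ValueError(
                "scenarios use 4 gratings + 3 noise patterns + 1 blank"
            )

    @property
    def class_ranges(self) -> dict:
        return self.ranges if self.profile == "custom" else PROFILES[self.profile]

    @property
    def effective_bold_noise_frac(self) -> float:
        if self.bold_noise_frac is not None:
            return self.bold_noise_frac
        return PROFILE_BOLD_NOISE_FRAC.get(self.profile, 0.0)


def make_component_table(spec: ScenarioSpec) -> pd.DataFrame:
    """Draw one component table for a scenario (blank row exactly zero)."""
    rng = substream(spec.seed, "fixture-components", spec.profile, spec.site)
    rows = []
    classes = [("grating", i + 1) for i in range(N_GRATINGS)] + [
        ("noise", i + 1) for i in range(N_NOISE)
    ]
    for cls, i in classes:
        bounds = spec.class_ranges[cls]
        rows.append(
            {
                "site": spec.site,
                "condition": f"{cls}{i}",
                "broadband": rng.uniform(*bounds["broadband"]),
                "gamma": rng.uniform(*bounds["gamma"]),
                "alpha": rng.uniform(*bounds["alpha"]),
            }
        )
    rows.append(
        {
            "site": spec.site,
            "condition": "blank",
            "broadband": 0.0,
            "gamma": 0.0,
            "alpha": 0.0,
        }
    )
    return pd.DataFrame(rows)


def _split_halves(exp: Experiment) -> tuple[Experiment, Experiment]:
    """Even-trial and odd-trial sub-experiments (the replicate halves)."""
    halves = []
    for parity in (0, 1):
        trials = {
            label: [pc for pc in pcs if pc.trial_index % 2 == parity]
            for label, pcs in exp.trials.items()
        }
        halves.append(
            Experiment(
                conditions=exp.conditions,
                n_repeats=min(len(v) for v in trials.values()),
                trials=trials,
                provenance={**exp.provenance, "half": parity},
            )
        )
    return halves[0], halves[1]


def simulate_site(
    targets: pd.DataFrame,
    curves: dict,
    pcfg: PopulationConfig,
    seed: int = 0,
    n_repeats: int = 30,
    bold_noise_sd: float = 0.0,
    bold_noise_frac: float = 0.0,
    baseline_label: str = "blank",
    variant: VariantSpec | None = None,
    mc: MeasureConfig = MeasureConfig(),
) -> dict:
    """Model-consistent fixture for one site.

    Inverts the target components, simulates the full experiment, and
    returns per-half (even/odd trial) component and BOLD tables — the
    measured quantities a regression analysis consumes — plus the
    experiment itself. BOLD replicates can carry measurement noise, given
    either absolutely (``bold_noise_sd``) or as a fraction of the
    across-condition spread (``bold_noise_frac``), emulating the finite
    scan-to-scan reliability of real hemodynamic amplitudes.
    """
    inverted = invert_components(targets, curves)
    conditions = conditions_from_table(inverted)
    exp = simulate_experiment(
        pcfg, conditions, n_repeats=n_repeats, seed=seed, variant=variant
    )
    even, odd = _split_halves(exp)
    rng = substream(seed, "bold-noise")
    comp_rows, bold_rows = [], []
    for half_name, half_exp in (("A", even), ("B", odd)):
        # each half is summarized against the full blank condition: the
        # baseline is a shared reference (its error is common to both
        # halves and absorbed by the regression intercept), and pipelines
        # on real recordings pool far more baseline epochs than any one
        # condition's split half
        comps = summarize_experiment(
            half_exp,
            baseline_label=baseline_label,
            n_boot=0,
            mc=mc,
            baseline_experiment=exp,
        )
        comps["half"] = half_name
        comp_rows.append(comps)
        values = np.array(
            [
                np.mean(
                    [bold_proxy(pc, mc) for pc in half_exp.trials[c.label]]
                )
                for c in conditions
            ]
        )
        sd = bold_noise_sd
        if bold_noise_frac > 0:
            sd = float(np.hypot(sd, bold_noise_frac * values.std()))
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=values.shape)
        for cond, value in zip(conditions, values):
            bold_rows.append(
                {
                    "condition": cond.label,
                    "half": half_name,
                    "bold": float(value),
                }
            )
    return {
        "components": pd.concat(comp_rows, ignore_index=True),
        "bold": pd.DataFrame(bold_rows),
        "experiment": exp,
        "inverted": inverted,
    }


def make_bold_table(
    components: pd.DataFrame,
    mode: str = "model-consistent",
    noise_sd: float = 0.0,
    seed: int = 0,
    curves: dict | None = None,
    pcfg: PopulationConfig | None = None,
    n_repeats: int = 30,
) -> pd.DataFrame:
    """Per-condition BOLD table for a component table.

    ``model-consistent`` derives BOLD through the full simulator (invert
    the components, simulate, sum per-neuron power), so BOLD carries the
    model's structure; ``decoupled`` draws BOLD independently of the
    components with matched spread — the negative control under which no
    component should predict BOLD beyond chance.
    """
    if mode == "model-consistent":
        if curves is None or pcfg is None:
            raise ValueError(
                "model-consistent mode needs calibration curves and a "
                "population config"
            )
        out = simulate_site(
            components,
            curves,
            pcfg,
            seed=seed,
            n_repeats=n_repeats,
            bold_noise_sd=noise_sd,
        )
        return out["bold"]
    if mode == "decoupled":
        rng = substream(seed, "decoupled-bold")
        labels = components["condition"].tolist()
        scale = noise_sd if noise_sd > 0 else 1.0
        # one underlying BOLD value per condition (independent of the
        # components), plus replicate noise per half
        base = rng.normal(0.0, scale, size=len(labels))
        rows = []
        for half in ("A", "B"):
            jitter = rng.normal(0.0, 0.1 * scale, size=len(labels))
            for lab, v in zip(labels, base + jitter):
                rows.append({"condition": lab, "half": half, "bold": float(v)})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown mode {mode!r}")
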