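# lfpbold

Simulate local field potential (LFP) and BOLD responses from one
parameterized neuronal population, and analyze how the two measures
relate.

Field potentials and functional MRI pool neuronal activity in opposite
orders. For a population of *n* neurons with dendritic currents
*I*ᵢ(*t*), an electrode sums the currents and power is computed
afterwards, while metabolic demand — and hence the BOLD amplitude — sums
each neuron's power:

```
LFP power  =  power( Σᵢ Iᵢ(t) )            (power of the sum)
BOLD       ∝  Σᵢ power( Iᵢ(t) )            (sum of the power)
power_of_sum = sum_of_power + Σ_{i≠j} ⟨Iᵢ Iⱼ⟩   (cross-power identity)
```

For an equicorrelated Gaussian population (mean *m*, variance σ²,
pairwise correlation ρ): BOLD = β·n·(m²+σ²), while
LFP power = α·[n·(m²+σ²) + (n²−n)·(m²+σ²ρ)]. The BOLD proxy is blind to
synchrony; the LFP is dominated by it. The practical consequence —
testable in simulation and summarized by this package's analyses — is
that broadband (asynchronous, level-driven) field-potential components
track BOLD, narrowband gamma (coherence-driven) does not, and alpha
(level-driven but hyperpolarizing) anticorrelates with BOLD.

The package is aimed at researchers comparing electrophysiology
(ECoG/LFP) with fMRI: it provides the population simulator, the
spectral decomposition into broadband / narrowband-gamma / alpha
components, calibration curves that invert measured component tables
into simulation inputs, and cross-validated regression analyses of BOLD
on LFP components. Users with real recordings enter the pipeline with
pre-summarized per-condition component and BOLD tables (CSV).

## Worked example

Simulate a blank screen, a grating-like condition (broadband + gamma
coherence up, alpha down) and a noise-pattern-like condition (broadband
up, no gamma), then decompose the simulated LFP and pool the BOLD proxy:

```python
from lfpbold import (
    InputCondition, PopulationConfig, TrialConfig, baseline_condition,
    simulate_experiment, summarize_experiment, measure_table,
)

pcfg = PopulationConfig(trial=TrialConfig(n_neurons=200, rng_seed=1))
conditions = [
    baseline_condition(),                          # blank screen
    InputCondition("grating", c1_sigma=0.5, c2_coherence=0.15,
                   c3_amplitude=0.8),
    InputCondition("noise_pattern", c1_sigma=0.6, c2_coherence=0.0,
                   c3_amplitude=0.7),
]
exp = simulate_experiment(pcfg, conditions, n_repeats=30, seed=1)

components = summarize_experiment(exp, n_boot=100, seed=1)
print(components[["condition", "broadband", "gamma", "alpha"]].round(3))

bold = measure_table(exp).groupby("condition")["bold_proxy"].mean()
print((bold / bold["blank"]).round(3))
```

Output:

```
       condition  broadband  gamma  alpha
0          blank      0.000  0.000  0.000
1        grating      0.480  0.704 -0.264
2  noise_pattern      0.614 -0.112 -0.336
condition
blank            1.000
grating          1.388
noise_pattern    1.557
Name: bold_proxy, dtype: float64
```

Reading the numbers: components are log₁₀-power changes from the blank.
The grating elevates broadband power ~3× (+0.48 log units) and produces
a narrowband gamma peak (+0.70) with an alpha decrease (−0.26); the
noise pattern elevates broadband ~4× with no gamma peak (−0.11 is
estimation noise around zero). The BOLD proxy rises 39% and 56% —
ordered by the broadband (level) changes, unmoved by the gamma
(coherence) change, which is the central point of the model.

The same pipeline is scriptable from the shell:

```bash
lfpbold fixtures make --profile V1-like --seed 1 --out tables/
lfpbold calibrate --seed 1 --out calib/
lfpbold fit-targets --components tables/components.csv \
    --curves calib/curves.json --out inverted/
lfpbold predict-bold --components tables/components.csv \
    --curves calib/curves.json --seed 1 --out bold/
lfpbold analyze regress --components my_components.csv \
    --bold my_bold.csv --out results/
```

See `docs/methods.md` for the model's assumptions, parameter defaults,
calibration design and known limitations.

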