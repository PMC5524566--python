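# Methods

## The model

`lfpbold` treats the local field potential (LFP) and the BOLD amplitude as
two different poolings of the same neuronal population activity. For a
population of *n* neurons with dendritic currents *I*ᵢ(*t*) over a brief
window (order 1 s):

- the electrode sums currents first and power is taken afterwards
  (*power of the sum*):
  LFP(t) = α·Σᵢ Iᵢ(t), LFP power = power(Σᵢ Iᵢ);
- metabolic demand is per-neuron, so the hemodynamic proxy sums power
  (*sum of the power*): BOLD ∝ β·Σᵢ power(Iᵢ).

These differ exactly by the summed cross-power over ordered neuron pairs,

    power_of_sum = sum_of_power + Σ_{i≠j} ⟨Iᵢ·Iⱼ⟩,

an identity that holds for any finite set of time series and is enforced
in the test suite at near machine precision. For an equicorrelated
Gaussian population (common mean *m*, variance σ², pairwise correlation
ρ) both measures have closed forms:

    BOLD      = β·n·(m² + σ²)
    LFP power = α·[n·(m² + σ²) + (n² − n)·(m² + σ²ρ)]

so the BOLD proxy is blind to synchrony (ρ-free) while the LFP grows with
it. The package's central claim-generating machinery is the consequence:
LFP features driven by *synchrony* changes decouple from BOLD, features
driven by per-neuron *level* changes track it.

Power is by default the time-mean of squared samples, so a unit sinusoid
has power 0.5 and values are duration-invariant; a raw sum-of-squares
convention is available. The electrode gain α multiplies the summed
series before squaring (LFP power scales as α²); β scales the summed
power linearly. The closed forms above are reported with a linear α, as
the gain convention for analytic results; with the default α = β = 1 the
two conventions coincide, and all spectral components are log-power
*changes*, from which any fixed gain cancels (tested).

## Simulated population

Each trial is 1 s of 200 neurons at millisecond sampling. Three input
classes are summed per neuron and passed through a leaky integrator
(τ·dI/dt = −I + C, τ = 10 ms), discretized by exponential Euler
(`I[k+1] = I[k]·e^(−dt/τ) + C[k]·(1 − e^(−dt/τ))`), which is exact for
piecewise-constant input, unconditionally stable, has unit DC gain, and
low-passes white input into an approximately 1/f² spectrum above
~16 Hz. Trials start from I(0) = 0; an optional burn-in seeds the
integrator with the steady state of the first input sample (off by
default — with 1 s trials and τ = 10 ms the transient is confined to the
first few tens of milliseconds).

The inputs:

- **Broadband (C¹)** — i.i.d. Gaussian white noise per neuron, mean 0.25
  (net excitatory drive) and baseline standard deviation 0.3. Conditions
  vary the *variance* (the stand-in for the rate of asynchronous spike
  arrivals); across-neuron correlation is 0.
- **Gamma (C²)** — Gaussian noise with standard deviation 0.2 (fixed for
  all conditions) band-passed 40–60 Hz; conditions vary the
  *across-neuron correlation* (equicorrelation in [0, 1]). Because only
  coherence varies, a condition with zero coherence still carries
  incoherent gamma-band noise — this produces a small narrowband bump in
  the baseline spectrum, which is why broadband elevations measurably
  "mask" gamma (see calibration).
- **Alpha (C³)** — unit-variance Gaussian noise, equicorrelation 0.75,
  band-passed 9–12 Hz; the analytic (Hilbert) envelope is added and the
  result negated, then scaled by the condition's amplitude. The envelope
  asymmetry makes stronger alpha rhythms hyperpolarize the population
  (more negative time-average), which is how alpha suppresses the BOLD
  proxy (the mean contributes m² to per-neuron power).

Band-pass filtering uses a 10th-order Butterworth applied forward and
reverse (zero phase) on series zero-padded by 1 s per side (≥9 alpha
cycles, suppressing edge transients); second-order sections keep the
high-order filter stable. The gamma band defaults to 40–60 Hz — the
range the rhythm peaks over — rather than its upper half, because a
50–60 Hz peak would sit half inside the 55–65 Hz line-noise exclusion
used in spectral fitting and make the bump estimator bistable. The band
is configurable.

Equicorrelated samples are drawn by the shared-factor construction
x_i = √ρ·z_common + √(1−ρ)·z_i, exact for equicorrelation without an
n×n factorization. All randomness derives from one master seed through
keyed substreams (`(seed, condition label, trial index, component)`), so
experiments are bit-reproducible and per-condition content is invariant
to condition ordering.

The baseline ("blank screen") state is C¹ at σ = 0.3, zero gamma
coherence, and alpha amplitude 1.0: the blank is the *high-alpha* state
of visual cortex, so stimulus conditions can express alpha power
*decreases* by lowering the amplitude below baseline. The baseline
amplitude of 1.0 gives the simulated blank a prominent alpha rhythm and
leaves roughly −2.5 to +0.7 log₁₀ units of reachable alpha change,
comfortably covering the −0.5…−0.1 decreases typical of visual stimuli.

## Spectral decomposition

Per-condition LFP responses are reduced to three numbers (log₁₀-power
changes from the blank condition):

- spectra: Welch estimates with 250 ms Hann segments, 50 % overlap,
  zero-padded to a 1 Hz grid, per-segment mean removal (the summed
  currents carry a large DC offset whose window leakage would otherwise
  contaminate low frequencies); stimulus window 0–500 ms, alpha window
  250–500 ms;
- **broadband**: change in the intercept of a power-law fit
  `log₁₀P = β_bb − n·log₁₀f` over 35–200 Hz, excluding 60/120/180 ± 5 Hz
  (line-noise parity with clinical recordings; configurable), with the
  exponent *n* fixed per site from the baseline spectrum;
- **gamma**: change in the weight of a log-Gaussian bump riding on that
  line (center bounded to 35–80 Hz, width fixed at log₁₀1.1), fitted by
  bounded least squares with multi-start over centers {40, 50, 60, 70} Hz
  (single-start from the point estimate inside bootstrap loops). By
  default the component is the stimulus-minus-baseline difference of
  bump weights; the raw stimulus weight is available behind a flag;
- **alpha**: mean log₁₀ power over 8–13 Hz in the alpha window, averaged
  *across trials in log units* before differencing. Alpha-band power is
  dominated by a single coherent population rhythm with few degrees of
  freedom per 250 ms window, so per-trial estimates are heavy-tailed;
  the log of a trial-averaged power would carry a trial-count-dependent
  Jensen bias (~0.2 log units between 10- and 40-trial averages), while
  the mean of per-trial logs has a count-independent bias that cancels
  between stimulus and baseline.

Condition-specific evoked-response (ERP) removal — per-trial scalar
projection onto the condition mean — is implemented for parity with real
recordings but off by default for simulations, which have no evoked
component. Confidence intervals are 68 % percentile bootstraps over
trials (100 resamples), resampling stimulus and baseline trials
independently.

## Calibration and inversion

A calibration grid varies one input at a time and summarizes the
resulting components, then fits a monotone forward curve per component:

- broadband: `a·log₁₀((b+u)/b)` with *u* the input variance above
  baseline (σ² − 0.3²). The variance scale makes this family nearly
  exact (fitted a ≈ 1): the LFP floor is linear in input variance, so
  the log response is a log of an affine function.
- gamma: a peak-plus-floor mixture for the bump height,
  `a·[log₁₀(1 + (g₀+u)/(c·10^bb)) − log₁₀(1 + g₀/c)]`, with *u* the
  coherence, g₀ the baseline (incoherent) bump strength and c·10^bb the
  1/f floor at the prevailing broadband change bb. This captures the
  masking of the bump by broadband elevations.
- alpha: a band-power mixture `a·[log₁₀(b+u+r·10^bb) − log₁₀(b+r)]`
  with *u* the amplitude variance above baseline (amp² − 1). Here the
  floor's own elevation *raises* the measured component — broadband
  leaks into the alpha band when the alpha rhythm is weak — which a
  purely multiplicative masking form cannot represent.

All curves pass through zero at the baseline by construction (components
are measured against the same state the strengths are offsets from). A
more flexible masked-log family `a·10^(−bb/m)·log₁₀((b+u)/(b+c·bb)) + d`
is available per component, but its extra degrees of freedom overfit a
noisy grid (in testing it absorbed noise into a spurious broadband
dependence), so the mixture families are the defaults.

Grid design: 12 broadband sigmas (0.15–1.0, including points below
baseline so negative targets are invertible), 8 coherences
(log-spaced — the gamma curve is steepest near zero), 8 alpha amplitudes
(0–2.2); the gamma and alpha grids are crossed with three broadband
levels (σ ∈ {0.3, 0.55, 0.8}) to identify the floor terms. Trials per
point: 20 (broadband), 16 (gamma/alpha), with the shared baseline
reference averaged over 120 trials since its error would bias every
curve. These sizes keep the default calibration under ~2 minutes while
holding curve errors near the uncertainty of a 30-trial component
estimate.

Inversion is sequential, as in the forward construction: broadband
first (bisection on the monotone curve, tolerance 10⁻⁶), then gamma and
alpha conditional on the implied broadband level. Targets outside the
achievable range are clipped to the range endpoint and flagged (with a
10⁻³ log-unit tolerance so boundary targets are not spuriously
flagged). Predicted BOLD for a target table is the per-condition mean of
the BOLD proxy over 30 fresh trials with 68 % trial-bootstrap CIs.

Round-trip accuracy (targets → inputs → simulate → re-measure) at the
default sizes: broadband errors ~0.015, gamma ~0.05, alpha ~0.1–0.15
log₁₀ units — each at or below the half-width of the corresponding
30-trial bootstrap CI. Note a statistical consequence: because the
errors are at the CI scale, the fraction of cells whose 68 % CI covers
the target is itself near 68 % (coverage is scale-invariant and cannot
be improved by more trials); agreement to within the CI *width* is the
comparison that separates curve bias from irreducible trial noise.

### Model variants

Each input class can alternatively be fit by varying the across-neuron
correlation instead of the per-neuron level or vice versa; all eight
combinations are runnable. The default — broadband and alpha by level,
gamma by correlation — is the main model; under the default the variant
machinery reproduces the plain pipeline bit for bit. The alternatives
exist to demonstrate the synchrony logic: a correlation-driven broadband
change moves the LFP but not the BOLD proxy, and a level-driven gamma
change moves both.

## Regression analyses

BOLD amplitudes are regressed on per-condition components
(y = Xb + c + ε, ordinary least squares with intercept, no
regularization) and evaluated by split-half cross-validation: fit on one
half of the replicates (even-trial components, one BOLD replicate),
predict the held-out half, swap, and compute a single
R² = 1 − SS_res/SS_data over the concatenated held-out predictions.
Cross-validated R² spans (−∞, 1] and tends to −1 for unrelated
equal-variance prediction/data pairs, so extra predictors earn no
automatic credit. When predictions are in arbitrary units, both vectors
are mean-subtracted and divided by their vector length before R².
Reported betas come from the full-data fit (CV is used only for R²),
with percentile bootstrap CIs over conditions. The blank condition is
always included — it anchors the sign of the mean response — and its
absence triggers a warning.

The model menu runs all seven predictor subsets plus a noise-floor
control in which the training BOLD labels are permuted (mean over 20
permutations). Across sites, a predictor's sign is tested by resampling
sites 10 000 times and asking whether fewer than 2.5 % of resampled
median betas cross zero.

The per-frequency analysis correlates, for each 1 Hz bin from 1 to
200 Hz, the trial-averaged log-power change from baseline with the BOLD
change from baseline across conditions (Pearson; zero-variance bins are
returned as missing with a flag).

## Synthetic scenarios

The fixtures module emulates the stimulus structure of visual-cortex
experiments: 4 gratings, 3 noise patterns, 1 blank. Gratings raise
broadband and narrowband gamma and lower alpha; noise patterns raise
broadband with essentially no gamma; the blank is identically zero.
Two built-in profiles capture the early-vs-extrastriate contrast:
V1-like sites have broadband as the dominant varying component with weak
alpha modulation (broadband 0.20–0.60, gamma ≤ 0.4, alpha −0.12…−0.02
log units); V2V3-like sites have modest broadband ranges and deep,
variable alpha suppression (alpha to −0.55, deepest for noise patterns).
Model-consistent BOLD tables are produced by running the full pipeline
(invert → simulate → sum-of-power), optionally with Gaussian replicate
noise scaled to a fraction of the across-condition spread (defaults
0.35 / 0.5 for the two profiles), chosen so split-half BOLD reliability
resembles the regions being emulated (high early, lower extrastriate);
a decoupled mode draws BOLD independently of the components as a
negative control.

For regression fixtures, components are measured separately for the
even- and odd-trial halves (the replicates the cross-validation splits
on), but both halves are referenced to the *full* blank condition rather
than to each half's own 15-trial blank. The baseline is a shared
reference — pipelines on real recordings pool many more baseline epochs
than any single condition's split half — and referencing both halves to
the same blank makes its estimation error common mode (absorbed by the
regression intercept) instead of a train/test inconsistency: an outlier
15-trial blank draw would otherwise shift every component of one half
and destabilize the held-out predictions.

What the fixtures do *not* emulate: receptive-field geometry and
stimulus selectivity (component values are drawn uniformly within class
ranges, not computed from images), electrode placement and referencing
artifacts, trial-order and adaptation effects, hemodynamic temporal
dynamics (the BOLD proxy is a per-epoch amplitude; no HRF convolution),
or across-site correlations. Passing tests on these scenarios show that
the pipeline recovers the relationships it instantiates at realistic
noise levels — not that those relationships hold in any particular real
dataset.

## Problem sizes and determinism

Default experiment: 8 conditions × 30 repeats = 240 one-second trials of
200 neurons — the native scale of the modeled experiments; regression
checks use 9 early-like and 13 extrastriate-like simulated sites,
mirroring the emulated regions. Every stochastic step takes an explicit seed; identical
seeds give bit-identical outputs across runs on the same platform.

## Known limitations

- The alpha component estimator has ~0.1 log-unit uncertainty at 30
  trials (one coherent rhythm, few spectral degrees of freedom in a
  250 ms window); analyses that need finer alpha resolution need more
  trials per condition.
- The gamma bump fit is bounded (w ≥ 0, center in 35–80 Hz); spectra
  with bump-like curvature from other sources can register small
  spurious weights (~0.05–0.2), which largely cancel in
  stimulus-minus-baseline differences but set the gamma noise floor.
- Calibration curves are site-independent within a run; real sites with
  different gains or baselines need per-site calibration (re-run the
  grid with the site's configuration).
- The equicorrelation model of coherence has no spectral structure in
  the correlation itself (all-or-nothing band coherence); phase-lagged
  or frequency-dependent coupling is out of scope.
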