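"""Welch estimation and the power-law + log-Gaussian decomposition."""

import numpy as np
import pandas as pd
import pytest

from lfpbold.config import InputCondition, PopulationConfig, TrialConfig, baseline_condition
from lfpbold.population import simulate_experiment
from lfpbold.spectral import (
    GAMMA_SIGMA_LOG10,
    PSD,
    alpha_component,
    average_psd,
    bootstrap_components,
    fit_spectral_model,
    remove_erp,
    summarize_experiment,
    welch_psd,
)


def model_psd(bb, slope, bump_w=0.0, bump_hz=55.0):
    """Spectrum synthesized exactly from the fitted model's equation."""
    freqs = np.arange(1.0, 501.0)
    x = np.log10(freqs)
    logp = bb - slope * x
    if bump_w:
        logp = logp + bump_w * np.exp(
            -((x - np.log10(bump_hz)) ** 2) / (2 * GAMMA_SIGMA_LOG10**2)
        )
    return PSD(frequencies=freqs, power=10.0**logp)


class TestWelch:
    def test_sinusoid_peak_on_grid(self):
        t = np.arange(1000) / 1000.0
        psd = welch_psd(np.sin(2 * np.pi * 40 * t))
        assert psd.frequencies[np.argmax(psd.power)] == pytest.approx(40, abs=1)

    def test_white_noise_is_flat(self, rng):
        slopes = []
        for _ in range(100):
            psd = welch_psd(rng.standard_normal(1000))
            band = (psd.frequencies >= 10) & (psd.frequencies <= 200)
            slopes.append(
                np.polyfit(
                    np.log10(psd.frequencies[band]),
                    np.log10(psd.power[band]),
                    1,
                )[0]
            )
        assert abs(np.mean(slopes)) < 0.2

    def test_amplitude_doubling_quadruples_power(self, rng):
        x = rng.standard_normal(1000)
        p1 = welch_psd(x)
        p2 = welch_psd(2 * x)
        assert np.allclose(p2.power, 4 * p1.power, rtol=1e-10)

    def test_window_shorter_than_segment_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(rng.standard_normal(1000), window=(0.0, 0.1))

    def test_average_requires_common_grid(self, rng):
        a = welch_psd(rng.standard_normal(1000))
        b = PSD(frequencies=a.frequencies[:-1], power=a.power[:-1])
        with pytest.raises(ValueError, match="common"):
            average_psd([a, b])


class TestRemoveErp:
    def test_identical_trials_leave_no_residual(self):
        x = np.sin(np.linspace(0, 10, 500))
        trials = np.tile(x, (5, 1))
        assert np.allclose(remove_erp(trials), 0.0, atol=1e-12)

    def test_orthogonal_parts_survive(self):
        t = np.arange(1000) / 1000.0
        e = np.sin(2 * np.pi * 5 * t)
        o = np.cos(2 * np.pi * 5 * t)
        # ERP is exactly e; each trial's component orthogonal to it stays
        resid = remove_erp(np.vstack([e + o, e - o]))
        assert np.allclose(resid[0], o, atol=1e-10)
        assert np.allclose(resid[1], -o, atol=1e-10)

    def test_idempotent(self, rng):
        trials = rng.standard_normal((8, 600))
        once = remove_erp(trials)
        twice = remove_erp(once)
        assert np.allclose(once, twice, atol=1e-10)

    def test_single_trial_skipped_with_warning(self, rng):
        trials = rng.standard_normal((1, 600))
        with pytest.warns(UserWarning, match="single-trial"):
            out = remove_erp(trials)
        assert np.array_equal(out, trials)


class TestSpectralFit:
    def test_recovers_broadband_change_without_bump(self):
        base = model_psd(bb=-1.0, slope=2.0)
        stim = model_psd(bb=-0.4, slope=2.0)
        _, _, comps = fit_spectral_model(stim, base)
        assert comps["broadband"] == pytest.approx(0.6, abs=1e-3)
        assert comps["gamma"] == pytest.approx(0.0, abs=1e-3)

    def test_recovers_bump_weight_and_center(self):
        base = model_psd(bb=-1.0, slope=2.0)
        stim = model_psd(bb=-1.0, slope=2.0, bump_w=0.8, bump_hz=55.0)
        fit_stim, _, comps = fit_spectral_model(stim, base)
        assert comps["gamma"] == pytest.approx(0.8, rel=0.01)
        assert 10**fit_stim.mu_log10 == pytest.approx(55.0, rel=0.02)
        assert comps["broadband"] == pytest.approx(0.0, abs=0.01)

    def test_identical_spectra_give_zero_components(self):
        psd = model_psd(bb=-1.0, slope=2.0, bump_w=0.3)
        _, _, comps = fit_spectral_model(psd, psd)
        assert comps["broadband"] == pytest.approx(0.0, abs=1e-9)
        assert comps["gamma"] == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovered_from_baseline(self):
        base = model_psd(bb=-1.0, slope=1.7)
        fit_stim, _, _ = fit_spectral_model(base, base)
        assert fit_stim.slope_n == pytest.approx(1.7, abs=1e-6)


class TestAlphaComponent:
    def test_identical_spectra_give_zero(self):
        psd = model_psd(bb=-1.0, slope=2.0)
        assert alpha_component(psd, psd) == 0.0

    def test_tenfold_band_drop_reads_minus_one(self):
        base = model_psd(bb=-1.0, slope=2.0)
        scaled = base.power.copy()
        band = (base.frequencies >= 8) & (base.frequencies <= 13)
        scaled[band] *= 0.1
        stim = PSD(frequencies=base.frequencies, power=scaled)
        assert alpha_component(stim, base) == pytest.approx(-1.0, abs=1e-12)


def synthetic_trial_psds(rng, n_trials, scale=1.0):
    """Chi-square-distributed per-trial spectra around a power law."""
    freqs = np.arange(1.0, 501.0)
    mean_power = scale * freqs**-2.0
    return [
        PSD(
            frequencies=freqs,
            power=mean_power * rng.chisquare(4, size=freqs.size) / 4,
        )
        for _ in range(n_trials)
    ]


class TestBootstrap:
    def test_single_resample_collapses_ci(self, rng):
        stim = synthetic_trial_psds(rng, 8, scale=2.0)
        base = synthetic_trial_psds(rng, 8)
        sc = bootstrap_components(stim, base, stim, base, n_boot=1, rng=rng)
        for lo, hi in sc.ci.values():
            assert lo == hi

    def test_point_estimate_within_its_ci(self, rng):
        stim = synthetic_trial_psds(rng, 12, scale=2.0)
        base = synthetic_trial_psds(rng, 12)
        sc = bootstrap_components(stim, base, stim, base, n_boot=80, rng=rng)
        lo, hi = sc.ci["broadband"]
        assert lo <= sc.broadband <= hi

    def test_ci_narrows_with_more_trials(self):
        widths = {15: [], 60: []}
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            for n in widths:
                stim = synthetic_trial_psds(rng, n, scale=2.0)
                base = synthetic_trial_psds(rng, n)
                sc = bootstrap_components(
                    stim, base, stim, base, n_boot=40, rng=rng
                )
                lo, hi = sc.ci["broadband"]
                widths[n].append(hi - lo)
        assert np.mean(widths[60]) < np.mean(widths[15])


class TestSummarize:
    @pytest.fixture(scope="class")
    def tiny_experiment(self):
        pcfg = PopulationConfig(
            trial=TrialConfig(n_neurons=60, rng_seed=17)
        )
        conds = [
            baseline_condition(),
            InputCondition("stim", c1_sigma=0.6, c3_amplitude=1.0),
        ]
        return simulate_experiment(pcfg, conds, n_repeats=8, seed=17)

    def test_blank_against_itself_is_zero(self, tiny_experiment):
        table = summarize_experiment(tiny_experiment, n_boot=5, seed=3)
        blank = table[table.condition == "blank"].iloc[0]
        assert blank.broadband == pytest.approx(0.0, abs=1e-12)
        assert blank.gamma == pytest.approx(0.0, abs=1e-12)
        assert blank.alpha == pytest.approx(0.0, abs=1e-12)

    def test_broadband_condition_elevates_broadband(self, tiny_experiment):
        table = summarize_experiment(tiny_experiment, n_boot=0)
        stim = table[table.condition == "stim"].iloc[0]
        assert stim.broadband > 0.3

    def test_component_table_columns(self, tiny_experiment):
        table = summarize_experiment(tiny_experiment, n_boot=5, seed=3)
        for col in (
            "site",
            "condition",
            "broadband",
            "gamma",
            "alpha",
            "ci_low_broadband",
            "ci_high_alpha",
        ):
            assert col in table.columns

    def test_missing_baseline_rejected(self, tiny_experiment):
        with pytest.raises(ValueError, match="baseline"):
            summarize_experiment(tiny_experiment, baseline_label="nope")

    def test_gain_cancels_in_components(self, tiny_experiment):
        """Components are log-power changes, so the electrode gain drops out."""
        from lfpbold.measures import MeasureConfig

        a = summarize_experiment(tiny_experiment, n_boot=0)
        b = summarize_experiment(
            tiny_experiment, n_boot=0, mc=MeasureConfig(alpha_scale=3.0)
        )
        for comp in ("broadband", "gamma", "alpha"):
            assert np.allclose(a[comp], b[comp], atol=1e-9)
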