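"""Forward calibration curves, inversion, and model variants."""

import numpy as np
import pandas as pd
import pytest

from lfpbold.calibration import (
    CalibrationCurve,
    _predict_band_floor,
    _predict_log,
    _predict_peak_floor,
    conditions_from_table,
    fit_calibration_curves,
    invert_components,
)
from lfpbold.config import InputCondition, PopulationConfig, TrialConfig
from lfpbold.inputs import VariantSpec
from lfpbold.measures import bold_proxy
from lfpbold.population import simulate_condition


def synthetic_calibration_table(
    bb_params={"a": 1.1, "b": 0.10},
    gamma_params={"a": 1.4, "c": 0.02, "g0": 0.01},
    alpha_params={"a": 1.05, "b": 1.0, "r": 0.02},
):
    """A calibration table generated exactly from the curve families."""
    rows = []
    sigmas = [0.15, 0.2, 0.25, 0.3, 0.4, 0.5, 0.65, 0.8, 1.0]
    for s in sigmas:
        u = s**2 - 0.09
        rows.append(
            {
                "component": "broadband",
                "strength": s,
                "u": u,
                "bb_sigma": s,
                "broadband": _predict_log(bb_params, u),
                "gamma": 0.0,
                "alpha": 0.0,
            }
        )
    for bb_sigma in (0.3, 0.55, 0.8):
        bb = _predict_log(bb_params, bb_sigma**2 - 0.09)
        for coh in (0.0, 0.01, 0.03, 0.1, 0.3, 0.6, 1.0):
            rows.append(
                {
                    "component": "gamma",
                    "strength": coh,
                    "u": coh,
                    "bb_sigma": bb_sigma,
                    "broadband": bb,
                    "gamma": _predict_peak_floor(gamma_params, coh, bb),
                    "alpha": 0.0,
                }
            )
        for amp in (0.0, 0.3, 0.6, 1.0, 1.5, 2.2):
            u = amp**2 - 1.0
            rows.append(
                {
                    "component": "alpha",
                    "strength": amp,
                    "u": u,
                    "bb_sigma": bb_sigma,
                    "broadband": bb,
                    "gamma": 0.0,
                    "alpha": _predict_band_floor(alpha_params, u, bb),
                }
            )
    return pd.DataFrame(rows)


class TestCurveFitting:
    @pytest.fixture(scope="class")
    def curves(self):
        return fit_calibration_curves(synthetic_calibration_table())

    def test_noise_free_fit_recovers_each_curve(self, curves):
        """On data drawn exactly from the families, the fitted curves
        reproduce the generating functions to high accuracy."""
        truth = {
            "broadband": lambda u, bb: _predict_log({"a": 1.1, "b": 0.10}, u),
            "gamma": lambda u, bb: _predict_peak_floor(
                {"a": 1.4, "c": 0.02, "g0": 0.01}, u, bb
            ),
            "alpha": lambda u, bb: _predict_band_floor(
                {"a": 1.05, "b": 1.0, "r": 0.02}, u, bb
            ),
        }
        grids = {
            "broadband": np.linspace(-0.05, 0.8, 30),
            "gamma": np.linspace(0.0, 1.0, 30),
            "alpha": np.linspace(-0.9, 2.0, 30),
        }
        for name, curve in curves.items():
            assert curve.fit_residual < 0.005
            for bb in (0.0, 0.5):
                got = curve.predict(grids[name], bb=bb)
                want = truth[name](grids[name], bb)
                assert np.allclose(got, want, atol=0.01)

    def test_zero_strength_predicts_zero(self, curves):
        for name, curve in curves.items():
            assert curve.predict(0.0) == pytest.approx(0.0, abs=1e-9)

    def test_curves_monotone_over_valid_range(self, curves):
        for curve in curves.values():
            u = np.linspace(*curve.valid_range, 200)
            assert np.all(np.diff(curve.predict(u)) > 0)

    def test_nonmonotone_data_warns_but_fits(self):
        table = synthetic_calibration_table()
        flip = table[table.component == "broadband"].index[:2]
        table.loc[flip, "broadband"] = [0.5, -0.5]
        with pytest.warns(UserWarning, match="monotone"):
            fit_calibration_curves(table)


class TestInversion:
    @pytest.fixture(scope="class")
    def curves(self):
        return fit_calibration_curves(synthetic_calibration_table())

    def test_forward_then_invert_recovers_strength(self, curves):
        for name, curve in curves.items():
            lo, hi = curve.valid_range
            for u_true in np.linspace(lo + 0.05, hi - 0.05, 7):
                target = float(curve.predict(u_true, bb=0.2))
                u_hat, clipped = curve.invert(target, bb=0.2)
                assert not clipped
                assert u_hat == pytest.approx(u_true, abs=1e-3)

    def test_zero_broadband_target_maps_to_baseline_sigma(self, curves):
        table = pd.DataFrame(
            [{"condition": "blank", "broadband": 0.0, "gamma": 0.0, "alpha": 0.0}]
        )
        out = invert_components(table, curves)
        assert out.iloc[0].c1_sigma == pytest.approx(0.3, abs=1e-4)
        assert out.iloc[0].c2_coherence == pytest.approx(0.0, abs=1e-4)
        assert out.iloc[0].c3_amplitude == pytest.approx(1.0, abs=1e-4)

    def test_unreachable_target_clipped_and_flagged(self, curves):
        table = pd.DataFrame(
            [{"condition": "hot", "broadband": 50.0, "gamma": 0.0, "alpha": 0.0}]
        )
        with pytest.warns(UserWarning, match="clipped"):
            out = invert_components(table, curves)
        assert bool(out.iloc[0].clipped_broadband)
        assert out.iloc[0].c1_sigma == pytest.approx(1.0, abs=1e-6)

    def test_decreasing_curve_rejected(self):
        bad = CalibrationCurve(
            component="broadband",
            params={"a": -1.0, "b": 0.5},
            valid_range=(0.0, 1.0),
            baseline_strength=0.3,
            fit_residual=0.0,
        )
        with pytest.raises(RuntimeError, match="not increasing"):
            bad.invert(0.5)

    def test_conditions_from_table_round_trip(self):
        table = pd.DataFrame(
            [
                {
                    "condition": "x",
                    "c1_sigma": 0.4,
                    "c2_coherence": 0.2,
                    "c3_amplitude": 0.9,
                }
            ]
        )
        (cond,) = conditions_from_table(table)
        assert cond == InputCondition(
            "x", c1_sigma=0.4, c2_coherence=0.2, c3_amplitude=0.9
        )


class TestPredictBold:
    @pytest.fixture(scope="class")
    def setup(self):
        curves = fit_calibration_curves(synthetic_calibration_table())
        pcfg = PopulationConfig(trial=TrialConfig(n_neurons=60, rng_seed=41))
        targets = pd.DataFrame(
            {
                "condition": ["blank", "blank2", "bb_hi", "gamma_hi"],
                "broadband": [0.0, 0.0, 0.6, 0.0],
                "gamma": [0.0, 0.0, 0.0, 0.8],
                "alpha": [0.0, 0.0, 0.0, 0.0],
            }
        )
        from lfpbold.calibration import predict_bold_for_targets

        table = predict_bold_for_targets(
            targets, curves, pcfg, seed=41, n_repeats=8, n_boot=30
        )
        return table.set_index("condition")

    def test_blank_conditions_agree_within_ci(self, setup):
        a, b = setup.loc["blank"], setup.loc["blank2"]
        assert a.ci_low_bold <= b.bold <= a.ci_high_bold

    def test_broadband_target_raises_bold(self, setup):
        assert setup.loc["bb_hi"].bold > setup.loc["blank"].ci_high_bold

    def test_gamma_target_leaves_bold_within_ci(self, setup):
        blank, hi = setup.loc["blank"], setup.loc["gamma_hi"]
        assert blank.ci_low_bold <= hi.bold <= blank.ci_high_bold


class TestModelVariants:
    """Level-vs-correlation alternatives for each input class."""

    @staticmethod
    def _measures(variant, strength_field, lo, hi, n_trials=4):
        # alpha input off so the varied class dominates the summed signal
        pcfg = PopulationConfig(trial=TrialConfig(n_neurons=80, rng_seed=31))
        out = {}
        for level, name in ((lo, "lo"), (hi, "hi")):
            cond = InputCondition("v", c3_amplitude=0.0, **{strength_field: level})
            trials = simulate_condition(pcfg, cond, n_trials, seed=77, variant=variant)
            out[name] = {
                "lfp_var": np.mean(
                    [np.var(t.currents.sum(axis=0)) for t in trials]
                ),
                "bold": np.mean([bold_proxy(t) for t in trials]),
            }
        return out

    def test_broadband_by_correlation_moves_lfp_not_bold(self):
        variant = VariantSpec(c1="correlation")
        m = self._measures(variant, "c1_sigma", 0.0, 0.3)
        # correlated broadband drive multiplies the summed-signal
        # fluctuations but leaves each neuron's power (BOLD) alone
        assert m["hi"]["lfp_var"] > 3 * m["lo"]["lfp_var"]
        assert abs(m["hi"]["bold"] / m["lo"]["bold"] - 1.0) < 0.1

    def test_gamma_by_level_moves_bold_too(self):
        # same seed and label => identical C1/C3 draws, so the BOLD
        # difference is exactly the gamma-level contribution
        variant = VariantSpec(c2="level")
        m = self._measures(variant, "c2_coherence", 0.02, 1.0)
        assert m["hi"]["bold"] > m["lo"]["bold"] + 0.1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            VariantSpec(c1="amplitude")
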