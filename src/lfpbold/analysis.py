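"""Regression analyses relating BOLD amplitudes to LFP components.

BOLD amplitudes (simulated or supplied) are modeled as a linear function
of per-condition broadband, gamma and alpha components:

    y = X b + c + eps

evaluated by split-half cross-validation: coefficients fitted on one half
of the replicates are applied to the held-out half, and a single
coefficient of determination R^2 = 1 - SS_res/SS_data is computed over the
concatenated held-out predictions. Cross-validated R^2 spans (-inf, 1] and
tends to -1 for unrelated equal-variance prediction/data pairs, so models
with more predictors gain no automatic advantage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import substream

COMPONENTS = ("broadband", "gamma", "alpha")


@dataclass(frozen=True)
class RegressionSpec:
    """Which components predict BOLD and how the test is run."""

    predictors: tuple[str, ...] = COMPONENTS
    n_boot_beta: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("at least one predictor required")
        unknown = set(self.predictors) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")


@dataclass
class RegressionResult:
    """Betas (full-data fit), cross-validated R^2 and bootstrap CIs."""

    predictors: tuple[str, ...]
    betas: dict
    intercept: float
    r2_cv: float
    beta_ci: dict = field(default_factory=dict)
    significant: dict = field(default_factory=dict)


def r_squared(data, pred, normalize: bool = False) -> float:
    """Coefficient of determination, 1 - SS_residuals / SS_data.

    With ``normalize`` on, both vectors are mean-subtracted and divided by
    their own vector length first — the convention for predictions in
    arbitrary units. R^2 is 1 iff (normalized) prediction equals data and
    can be arbitrarily negative for held-out predictions; for unrelated
    equal-variance normalized vectors it tends to -1.
    """
    data = np.asarray(data, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if data.shape != pred.shape:
        raise ValueError("data and prediction must have equal length")
    if normalize:
        data = data - data.mean()
        pred = pred - pred.mean()
        norm_d, norm_p = np.linalg.norm(data), np.linalg.norm(pred)
        if norm_d > 0:
            data = data / norm_d
        if norm_p > 0:
            pred = pred / norm_p
    ss_data = float(np.sum((data - data.mean()) ** 2))
    ss_res = float(np.sum((data - pred) ** 2))
    if ss_data == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_data


def _half_frames(table: pd.DataFrame, value_cols) -> dict[str, pd.DataFrame]:
    """Split a table into its two replicate halves keyed 'A'/'B'.

    Tables may carry a ``half`` column with two labels; without one the
    single copy serves as both halves (no independent replicates).
    """
    if "half" in table.columns:
        halves = sorted(table["half"].unique())
        if len(halves) != 2:
            raise ValueError(f"expected exactly 2 halves, got {halves}")
        return {
            "A": table[table["half"] == halves[0]].set_index("condition")[
                list(value_cols)
            ],
            "B": table[table["half"] == halves[1]].set_index("condition")[
                list(value_cols)
            ],
        }
    base = table.set_index("condition")[list(value_cols)]
    return {"A": base, "B": base.copy()}


def _ols(X: np.ndarray, y: np.ndarray):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    fit = model.fit()
    return fit.params[0], fit.params[1:]


def fit_cv_regression(
    components: pd.DataFrame,
    bold: pd.DataFrame,
    spec: RegressionSpec = RegressionSpec(),
    blank_label: str = "blank",
    n_boot_ci: int = 1000,
    shuffle_training: bool = False,
    rng: np.random.Generator | None = None,
) -> RegressionResult:
    """Split-half cross-validated regression of BOLD on LFP components.

    ``components`` and ``bold`` are per-condition tables, optionally with
    a ``half`` column carrying two replicate halves (even/odd trial splits
    for components; independent replicates for BOLD). The model is fit on
    half A of both tables and evaluated on half B, and vice versa; R^2 is
    computed once over the concatenated held-out predictions. Betas are
    reported from the full-data fit, with percentile bootstrap CIs over
    conditions.

    ``shuffle_training`` permutes the condition assignment of the training
    BOLD values (the noise-floor control).
    """
    preds = list(spec.predictors)
    comp_halves = _half_frames(components, preds)
    bold_halves = _half_frames(bold, ["bold"])
    labels = [
        lab
        for lab in comp_halves["A"].index
        if lab in set(bold_halves["A"].index)
    ]
    if len(labels) < len(preds) + 1:
        raise ValueError(
            f"{len(labels)} shared conditions cannot constrain "
            f"{len(preds)} predictors plus an intercept"
        )
    if blank_label not in labels:
        warnings.warn(
            f"no {blank_label!r} condition: the regression loses its "
            "anchor for the sign of the mean response",
            stacklevel=2,
        )
    if rng is None:
        rng = substream(spec.seed, "cv-regression", *preds)

    y_test_all, y_pred_all = [], []
    for train, test in (("A", "B"), ("B", "A")):
        X_train = comp_halves[train].loc[labels, preds].to_numpy()
        y_train = bold_halves[train].loc[labels, "bold"].to_numpy()
        if shuffle_training:
            y_train = y_train[rng.permutation(len(y_train))]
        X_test = comp_halves[test].loc[labels, preds].to_numpy()
        y_test = bold_halves[test].loc[labels, "bold"].to_numpy()
        c, b = _ols(X_train, y_train)
        y_pred_all.append(X_test @ b + c)
        y_test_all.append(y_test)
    r2_cv = r_squared(np.concatenate(y_test_all), np.concatenate(y_pred_all))

    X_full = np.vstack(
        [comp_halves[h].loc[labels, preds].to_numpy() for h in ("A", "B")]
    )
    y_full = np.concatenate(
        [bold_halves[h].loc[labels, "bold"].to_numpy() for h in ("A", "B")]
    )
    c_full, b_full = _ols(X_full, y_full)

    n = len(labels)
    boots = {p: [] for p in preds}
    for _ in range(n_boot_ci):
        idx = rng.integers(0, n, n)
        rows = np.concatenate([idx, idx + n])
        try:
            _, b_bs = _ols(X_full[rows], y_full[rows])
        except Exception:  # singular resample
            continue
        for j, p in enumerate(preds):
            boots[p].append(b_bs[j])
    beta_ci = {
        p: (
            float(np.percentile(v, 2.5)),
            float(np.percentile(v, 97.5)),
        )
        if v
        else (np.nan, np.nan)
        for p, v in boots.items()
    }
    significant = {
        p: bool(lo > 0 or hi < 0) for p, (lo, hi) in beta_ci.items()
    }
    return RegressionResult(
        predictors=tuple(preds),
        betas={p: float(b_full[j]) for j, p in enumerate(preds)},
        intercept=float(c_full),
        r2_cv=float(r2_cv),
        beta_ci=beta_ci,
        significant=significant,
    )


def bootstrap_beta_test(
    betas_by_site: pd.DataFrame,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict[str, str | None]:
    """Sign test on the median beta across sites by site-resampling.

    ``betas_by_site`` has one row per site and one column per predictor.
    A predictor is flagged "positive" when fewer than 2.5% of resampled
    medians are <= 0, "negative" when fewer than 2.5% are >= 0, else None.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(betas_by_site)
    out: dict[str, str | None] = {}
    values = {c: betas_by_site[c].to_numpy(dtype=float) for c in betas_by_site.columns}
    idx = rng.integers(0, n, size=(n_boot, n))
    for col, v in values.items():
        medians = np.median(v[idx], axis=1)
        frac_le0 = np.mean(medians <= 0)
        frac_ge0 = np.mean(medians >= 0)
        if frac_le0 < 0.025:
            out[col] = "positive"
        elif frac_ge0 < 0.025:
            out[col] = "negative"
        else:
            out[col] = None
    return out


MODEL_MENU = (
    ("broadband",),
    ("gamma",),
    ("alpha",),
    ("broadband", "gamma"),
    ("broadband", "alpha"),
    ("gamma", "alpha"),
    ("broadband", "gamma", "alpha"),
)


def model_menu(
    components: pd.DataFrame,
    bold: pd.DataFrame,
    seed: int = 0,
    n_shuffles: int = 20,
    n_boot_ci: int = 200,
) -> pd.DataFrame:
    """Run the seven predictor-subset models plus a shuffled control.

    Returns one row per model (named by its predictor set) with the
    cross-validated R^2 and full-data betas, and a final ``shuffled`` row
    giving the noise floor: the mean R^2 of the full model refitted with
    the training BOLD labels permuted.
    """
    rows = []
    for preds in MODEL_MENU:
        res = fit_cv_regression(
            components,
            bold,
            RegressionSpec(predictors=preds, seed=seed),
            n_boot_ci=n_boot_ci,
        )
        row = {
            "model": "+".join(preds),
            "predictors": ",".join(preds),
            "r2_cv": res.r2_cv,
            "intercept": res.intercept,
        }
        for p in COMPONENTS:
            row[f"beta_{p}"] = res.betas.get(p, np.nan)
            row[f"significant_{p}"] = res.significant.get(p, False)
        rows.append(row)
    rng = substream(seed, "shuffle-control")
    shuffled = [
        fit_cv_regression(
            components,
            bold,
            RegressionSpec(predictors=COMPONENTS, seed=seed),
            n_boot_ci=0,
            shuffle_training=True,
            rng=rng,
        ).r2_cv
        for _ in range(n_shuffles)
    ]
    rows.append(
        {
            "model": "shuffled",
            "predictors": ",".join(COMPONENTS),
            "r2_cv": float(np.mean(shuffled)),
            "intercept": np.nan,
            **{f"beta_{p}": np.nan for p in COMPONENTS},
            **{f"significant_{p}": False for p in COMPONENTS},
        }
    )
    return pd.DataFrame(rows)


def per_frequency_correlation(
    power_change: pd.DataFrame,
    bold: pd.DataFrame,
    blank_label: str = "blank",
) -> pd.DataFrame:
    """Correlate per-frequency power changes with BOLD changes.

    ``power_change`` is a wide table indexed by condition with one column
    per frequency (log10 power change from baseline); ``bold`` has
    condition and bold columns. For each frequency the Pearson correlation
    across conditions between power change and BOLD change from baseline
    is returned; a zero-variance column yields NaN with ``undefined`` set.
    """
    bold = bold.set_index("condition")["bold"] if "condition" in bold else bold
    labels = [c for c in power_change.index if c in bold.index]
    y = bold.loc[labels].to_numpy(dtype=float)
    if blank_label in bold.index:
        y = y - float(bold.loc[blank_label])
    y = y - y.mean()
    rows = []
    denom_y = np.sqrt(np.sum(y**2))
    for freq in power_change.columns:
        x = power_change.loc[labels, freq].to_numpy(dtype=float)
        x = x - x.mean()
        denom = np.sqrt(np.sum(x**2)) * denom_y
        if denom == 0.0 or not np.isfinite(denom):
            rows.append(
                {"frequency": float(freq), "r": np.nan, "undefined": True}
            )
        else:
            rows.append(
                {
                    "frequency": float(freq),
                    "r": float(np.sum(x * y) / denom),
                    "undefined": False,
                }
            )
    return pd.DataFrame(rows)


def experiment_frequency_table(
    exp,
    baseline_label: str = "blank",
    f_max: float = 200.0,
    mc=None,
) -> pd.DataFrame:
    """Per-condition log10 power change from baseline on the 1 Hz grid.

    Spectra are trial-averaged stimulus-window PSDs of the simulated LFP;
    rows are conditions, columns frequencies 1..f_max Hz.
    """
    from .measures import MeasureConfig
    from .spectral import average_psd, trial_psds

    mc = mc or MeasureConfig()
    base_psd = average_psd(trial_psds(exp, baseline_label, mc)[0])
    keep = base_psd.frequencies <= f_max
    freqs = base_psd.frequencies[keep]
    rows = {}
    for cond in exp.conditions:
        psd = average_psd(trial_psds(exp, cond.label, mc)[0])
        rows[cond.label] = np.log10(psd.power[keep] / base_psd.power[keep])
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[float(f) for f in freqs]
    )
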