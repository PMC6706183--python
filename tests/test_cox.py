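"""Cox partial-likelihood fitting against independent oracles.

The oracle is a direct, loop-level transcription of the Efron partial
likelihood, maximised by grid search / simplex rather than Newton
iterations, so it shares no code path with the implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from storksurv.cox import CoxPH, cox_fit, model_r2

from .conftest import random_survival_frame


def efron_loglik_oracle(beta, X, time, event):
    """Literal Efron log partial likelihood (slow, explicit loops)."""
    beta = np.atleast_1d(np.asarray(beta, float))
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        D = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        R = [i for i in range(len(time)) if time[i] >= t]
        d = len(D)
        s_r = sum(np.exp(X[i] @ beta) for i in R)
        s_d = sum(np.exp(X[i] @ beta) for i in D)
        for i in D:
            ll += float(X[i] @ beta)
        for j in range(d):
            ll -= np.log(s_r - (j / d) * s_d)
    return ll


def _oracle_argmax_1d(X, time, event):
    res = optimize.minimize_scalar(
        lambda b: -efron_loglik_oracle([b], X, time, event),
        bounds=(-6, 6), method="bounded",
        options={"xatol": 1e-10})
    return res.x


def test_closed_form_two_to_one_hazard():
    """Three subjects, events at 1,2,3 with x=(0,1,0): beta = ln sqrt 2."""
    df = pd.DataFrame({"time_days": [1, 2, 3], "event": [1, 1, 1],
                       "x": [0.0, 1.0, 0.0]})
    fit = cox_fit(df, ["x"])
    assert fit.params["x"] == pytest.approx(np.log(np.sqrt(2)), abs=1e-8)


@pytest.mark.parametrize("seed", range(6))
def test_matches_oracle_with_ties(seed):
    """Newton estimate equals the brute-maximised Efron likelihood."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    X = rng.normal(size=(n, 1))
    time = rng.integers(1, 4, n).astype(float)  # heavy ties
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[0] = 1
    df = pd.DataFrame({"time_days": time, "event": event, "x": X[:, 0]})
    fit = cox_fit(df, ["x"])
    if fit.separation:
        pytest.skip("separated draw")
    b_star = _oracle_argmax_1d(X, time, event)
    assert fit.params["x"] == pytest.approx(b_star, abs=1e-3)


def test_matches_lifelines_stratified():
    """Cross-check coefficients/SEs against an independent library."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(3)
    df = random_survival_frame(rng, n=150, p=2, beta=[0.5, -0.3])
    df["s"] = rng.integers(0, 3, len(df))
    fit = cox_fit(df, ["x0", "x1"], strata_col="s")
    cf = lifelines.CoxPHFitter()
    cf.fit(df.rename(columns={"time_days": "T", "event": "E"}), "T", "E",
           strata=["s"], formula="x0+x1")
    np.testing.assert_allclose(fit.params.to_numpy(),
                               cf.params_.to_numpy(), atol=2e-5)
    np.testing.assert_allclose(fit.bse.to_numpy(),
                               cf.standard_errors_.to_numpy(), atol=2e-5)
    assert fit.loglik == pytest.approx(cf.log_likelihood_, abs=1e-5)


def test_single_stratum_equals_unstratified():
    rng = np.random.default_rng(5)
    df = random_survival_frame(rng, n=60, p=1, beta=[0.4])
    df["s"] = "only"
    a = cox_fit(df, ["x0"])
    b = cox_fit(df, ["x0"], strata_col="s")
    assert a.params["x0"] == pytest.approx(b.params["x0"], abs=1e-10)


def test_stratum_label_permutation_invariance():
    """Relabelling strata (keeping membership) leaves beta unchanged."""
    rng = np.random.default_rng(8)
    df = random_survival_frame(rng, n=90, p=1, beta=[0.4])
    df["s"] = rng.integers(0, 3, len(df))
    relabel = {0: "c", 1: "a", 2: "b"}
    df2 = df.assign(s=df["s"].map(relabel))
    a = cox_fit(df, ["x0"], strata_col="s")
    b = cox_fit(df2, ["x0"], strata_col="s")
    assert a.params["x0"] == pytest.approx(b.params["x0"], abs=1e-10)


def test_constant_covariate_excluded_with_warning():
    rng = np.random.default_rng(1)
    df = random_survival_frame(rng, n=30, p=1)
    df["const"] = 2.5
    with pytest.warns(UserWarning, match="constant"):
        fit = cox_fit(df, ["x0", "const"])
    assert list(fit.params.index) == ["x0"]


def test_no_events_raises():
    df = pd.DataFrame({"time_days": [1.0, 2.0], "event": [0, 0],
                       "x": [0.1, 0.2]})
    with pytest.raises(ValueError, match="no events"):
        CoxPH(df, ["x"])


def test_lr_and_wald_consistency():
    rng = np.random.default_rng(12)
    df = random_survival_frame(rng, n=200, p=1, beta=[0.8])
    fit = cox_fit(df, ["x0"])
    assert fit.lr_statistic >= 0
    assert fit.lr_statistic == pytest.approx(
        2 * (fit.loglik - fit.loglik_null))
    # strong effect: both tests should clearly reject
    assert fit.lr_pvalue < 0.01
    assert fit.wald_pvalues["x0"] < 0.01


def test_r_squared_formula_and_monotonicity():
    """Explained-variation index follows its defining formula."""
    rng = np.random.default_rng(21)
    df = random_survival_frame(rng, n=50, p=1, beta=[0.9])
    fit = cox_fit(df, ["x0"])
    n = fit.n
    expected = (1 - np.exp(-fit.lr_statistic / n)) / (
        1 - np.exp(2 * fit.loglik_null / n))
    assert model_r2(fit) == pytest.approx(expected, rel=1e-12)
    # worked numbers: n=50, loglik_null=-100, LR=20
    val = (1 - np.exp(-20 / 50)) / (1 - np.exp(2 * -100 / 50))
    assert val == pytest.approx(0.33583125, abs=1e-6)
    # monotone in LR at fixed n
    lrs = np.linspace(0, 30, 7)
    vals = [(1 - np.exp(-lr / 50)) / (1 - np.exp(-4)) for lr in lrs]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_separation_is_flagged():
    df = pd.DataFrame({"time_days": [1, 2, 3, 4.0], "event": [1, 1, 0, 0],
                       "x": [1.0, 1.0, 0.0, 0.0]})
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cox_fit(df, ["x"])
    assert fit.separation


def test_null_model_has_zero_df():
    rng = np.random.default_rng(2)
    df = random_survival_frame(rng, n=20, p=1)
    fit = CoxPH(df, []).fit()
    assert fit.df_model == 0
    assert fit.lr_statistic == 0.0
    assert fit.r_squared == 0.0


def test_adjusted_curve_centred_at_median_and_linear_slope():
    """The log relative hazard is 0 at the focus median; for a linear
    term the curve is a straight line with slope beta."""
    rng = np.random.default_rng(31)
    df = random_survival_frame(rng, n=150, p=2, beta=[0.6, -0.2])
    fit = cox_fit(df, ["x0", "x1"])
    med = float(np.median(df["x0"]))
    curve = fit.predict_log_relative_hazard("x0", grid=[med - 1, med,
                                                        med + 1])
    assert curve["log_rel_hazard"].iloc[1] == pytest.approx(0.0,
                                                            abs=1e-12)
    slope = (curve["log_rel_hazard"].iloc[2]
             - curve["log_rel_hazard"].iloc[0]) / 2
    assert slope == pytest.approx(fit.params["x0"], abs=1e-10)
    with pytest.raises(ValueError, match="focus"):
        fit.predict_log_relative_hazard("nope")
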