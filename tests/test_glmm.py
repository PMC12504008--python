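"""Between-within GLMM: design construction, AGHQ likelihood, fitting, inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from cotwin.glmm import (
    BWDesign, BetweenWithinGLMM, GLMMError, GLMMFit, ModelSpec,
    _MarginalLikelihood, build_design, decompose_exposure, fit_bw_glmm,
    marginal_loglik, wald_summary,
)


# ---------------------------------------------------------------------------
# exposure decomposition / design ladder
# ---------------------------------------------------------------------------

def _mini_cohort():
    return pd.DataFrame({
        "pair_id": [1, 1, 2, 2, 3],
        "member": [1, 2, 1, 2, 1],
        "educ3": [1.0, 3.0, 2.0, 2.0, 3.0],
        "zyg_dz": [0.0, 0.0, 1.0, 1.0, 1.0],
        "female": [1.0, 1.0, 0.0, 0.0, 1.0],
        "dementia": [1.0, 0.0, 0.0, 1.0, 0.0],
        "age_centered": [10.0, 10.0, -5.0, -5.0, 0.0],
        "study": ["A", "A", "A", "B", "B"],
        "valid": [1, 1, 1, 1, 1],
    })


def test_decompose_exposure_pairs_and_singletons():
    d = decompose_exposure(_mini_cohort())
    assert list(d["educ_between"]) == [2.0, 2.0, 2.0, 2.0, 3.0]
    assert list(d["educ_within"]) == [-1.0, 1.0, 0.0, 0.0, 0.0]


def test_between_within_reconstructs_exposure():
    d = decompose_exposure(_mini_cohort())
    np.testing.assert_allclose(d["educ_between"] + d["educ_within"], d["educ3"])


@pytest.mark.parametrize(
    "model_id, expected",
    [
        (1, {"educ3"}),
        (2, {"educ_between", "educ_within"}),
        (3, {"educ_between", "educ_within", "zyg_dz", "educ_within:zyg_dz"}),
        (4, {"educ_between", "educ_within", "zyg_dz", "educ_within:zyg_dz",
             "female"}),
        (5, {"educ_between", "educ_within", "zyg_dz", "educ_within:zyg_dz",
             "female", "female:educ_within", "female:zyg_dz",
             "female:zyg_dz:educ_within"}),
    ],
)
def test_build_design_model_ladder(model_id, expected):
    des = build_design(_mini_cohort(), ModelSpec.from_model_id(model_id))
    exposure = set(des.names) - {"intercept", "age_c"} - {
        n for n in des.names if n.startswith("study")
    }
    assert exposure == expected
    assert "age_c" in des.names and "study[B]" in des.names
    if model_id >= 4:
        assert "study[B]:female" in des.names
    else:
        assert "study[B]:female" not in des.names


def test_build_design_pair_structure():
    des = build_design(_mini_cohort(), ModelSpec.from_model_id(2))
    assert des.n_obs == 5 and des.n_pairs == 3
    assert (des.idx2 == -1).sum() == 1  # one singleton
    # within-pair deviations sum to zero within each complete pair
    w = des.X[:, des.names.index("educ_within")]
    for i1, i2 in zip(des.idx1, des.idx2):
        if i2 >= 0:
            assert w[i1] + w[i2] == 0.0


def test_unknown_model_id_rejected():
    with pytest.raises(GLMMError):
        ModelSpec.from_model_id(6)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def _single_pair_design(y=(1.0, 0.0)):
    return BWDesign(
        X=np.zeros((2, 1)), y=np.asarray(y, dtype=float), names=["intercept"],
        idx1=np.array([0]), idx2=np.array([1]), is_dz=np.array([False]),
        pair_id=np.array([1]),
    )


def test_aghq_matches_brute_force_single_pair():
    """One pair, y=(1,0), eta=0, sigma^2=1: AGHQ vs 1e5-node trapezoid."""
    des = _single_pair_design()
    ll = marginal_loglik(np.array([0.0, 0.0, 0.0]), des, n_quad=15)
    u = np.linspace(-10, 10, 100_001)
    integrand = expit(u) * (1 - expit(u)) * stats.norm.pdf(u)
    brute = np.log(np.trapezoid(integrand, u))
    assert ll == pytest.approx(brute, abs=1e-8)


def test_sigma_zero_collapses_to_bernoulli_glm(small_genetic):
    des = build_design(small_genetic, ModelSpec.from_model_id(2))
    glm = sm.GLM(des.y, des.X, family=sm.families.Binomial()).fit()
    params = np.concatenate([glm.params, [-np.inf, -np.inf]])
    assert marginal_loglik(params, des) == pytest.approx(glm.llf, abs=1e-6)


def test_loglik_additive_under_data_doubling(small_genetic):
    des = build_design(small_genetic, ModelSpec.from_model_id(2))
    n = des.n_obs
    des2 = BWDesign(
        X=np.vstack([des.X, des.X]), y=np.concatenate([des.y, des.y]),
        names=des.names,
        idx1=np.concatenate([des.idx1, des.idx1 + n]),
        idx2=np.concatenate([des.idx2, np.where(des.idx2 >= 0, des.idx2 + n, -1)]),
        is_dz=np.concatenate([des.is_dz, des.is_dz]),
        pair_id=np.concatenate([des.pair_id, des.pair_id + 10**7]),
    )
    params = np.concatenate([np.zeros(des.X.shape[1]), [0.1, -0.3]])
    assert marginal_loglik(params, des2) == pytest.approx(
        2 * marginal_loglik(params, des), rel=1e-12
    )


def test_analytic_gradient_matches_finite_differences(small_genetic):
    des = build_design(small_genetic, ModelSpec.from_model_id(3))
    ml = _MarginalLikelihood(des, n_quad=15)
    x = np.concatenate([np.full(des.X.shape[1], 0.05), [0.2, -0.1]])
    _, g = ml.value_and_grad(x)
    num = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = 1e-6
        num[i] = (
            ml.value_and_grad(x + e, want_grad=False)[0]
            - ml.value_and_grad(x - e, want_grad=False)[0]
        ) / 2e-6
    np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-5)


def test_nonfinite_parameters_rejected(small_genetic):
    des = build_design(small_genetic, ModelSpec.from_model_id(2))
    bad = np.concatenate([np.full(des.X.shape[1], np.nan), [0.0, 0.0]])
    with pytest.raises(GLMMError):
        marginal_loglik(bad, des)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fixed_zero_variance_fit_matches_logistic_regression(small_genetic):
    est = BetweenWithinGLMM(model_id=2, fix_variances=0.0).fit(small_genetic)
    des = build_design(small_genetic, ModelSpec.from_model_id(2))
    glm = sm.GLM(des.y, des.X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(est.coef_, glm.params, atol=1e-6)
    assert -est.minus2ll_ / 2 == pytest.approx(glm.llf, abs=1e-6)


def test_gaussian_identity_sigma_zero_equals_ols(small_genetic):
    est = BetweenWithinGLMM(
        model_id=2, link="gaussian", fix_variances=0.0
    ).fit(small_genetic)
    des = build_design(small_genetic, ModelSpec.from_model_id(2, "gaussian"))
    ols = np.linalg.lstsq(des.X, des.y, rcond=None)[0]
    np.testing.assert_allclose(est.coef_, ols, atol=1e-8)


def test_quadrature_stability_15_vs_25(make_harmonized):
    h = make_harmonized("genetic_confounding", 0.067, 4)  # ~2k pairs
    fa = fit_bw_glmm(h, model_id=2, n_quad=15)
    fb = fit_bw_glmm(h, model_id=2, n_quad=25)
    assert np.max(np.abs(
        fa.coef["estimate"].to_numpy() - fb.coef["estimate"].to_numpy()
    )) < 1e-4


def test_parameter_recovery_smoke(make_harmonized):
    """Direct -0.5 log-odds effect recovered by Model 2 (bias < 3 SE)."""
    h = make_harmonized("recovery", 0.1, 11)
    fit = fit_bw_glmm(h, model_id=2)
    assert fit.converged
    for name in ("educ_between", "educ_within"):
        est, se, _ = fit.coefficient(name)
        assert abs(est - (-0.5)) < 3 * se


def test_zygosity_specific_variances_recovered():
    """Known sd_MZ=1.2 / sd_DZ=0.8 pair intercepts recovered on exact data."""
    rng = np.random.default_rng(55)
    rows = []
    pid = 0
    for n, zyg, sd in ((3000, "MZ", 1.2), (3000, "DZ", 0.8)):
        b = rng.normal(0, sd, n)
        for i in range(n):
            pid += 1
            educ = rng.integers(1, 4, size=2).astype(float)
            y = (rng.random(2) < expit(-1.5 + b[i])).astype(float)
            for m in (1, 2):
                rows.append((pid, m, zyg, 0.0 if zyg == "MZ" else 1.0,
                             educ[m - 1], y[m - 1]))
    df = pd.DataFrame(rows, columns=["pair_id", "member", "zygosity", "zyg_dz",
                                     "educ3", "dementia"])
    df["age_centered"] = 0.0
    df["study"] = "S"
    df["valid"] = 1
    fit = fit_bw_glmm(df, model_id=2)
    assert fit.converged
    assert abs(fit.var_pair_MZ - 1.44) < 3 * fit.var_pair_MZ_se
    assert abs(fit.var_pair_DZ - 0.64) < 3 * fit.var_pair_DZ_se
    assert fit.var_pair_MZ > fit.var_pair_DZ


def test_wald_and_lr_pvalues_agree(make_harmonized):
    """Wald and likelihood-ratio p for the within effect agree to 1st digit."""
    import dataclasses
    from cotwin.simulate import scenario, simulate_cohort
    from cotwin.harmonize import harmonize

    ace, cfg = scenario("recovery", scale=0.15, seed=21)
    cfg = dataclasses.replace(cfg, beta_educ3=-0.18)
    h = harmonize(simulate_cohort(cfg, ace), ldi_cutoff=cfg.ldi_cutoff)
    f2 = fit_bw_glmm(h, model_id=2)
    _, _, p_wald = f2.coefficient("educ_within")
    h0 = h.copy()
    h0["educ3"] = h0.groupby("pair_id")["educ3"].transform("mean")
    f0 = fit_bw_glmm(h0, model_id=1)  # algebraically model 2 without educ_within
    p_lr = stats.chi2.sf(f0.minus2ll - f2.minus2ll, 1)
    def first_digit(p):
        s = f"{p:.0e}"
        return s[0], int(s.split("e")[1])
    assert first_digit(p_wald) == first_digit(p_lr)


def test_fit_requires_pairs_of_both_zygosities():
    df = _mini_cohort()
    df["zyg_dz"] = 0.0
    with pytest.raises(GLMMError):
        BetweenWithinGLMM(model_id=2).fit(df)


def test_sklearn_estimator_api(small_genetic):
    from sklearn.base import clone

    est = BetweenWithinGLMM(model_id=2, n_quad=9)
    assert clone(est).get_params()["n_quad"] == 9
    est.fit(small_genetic)
    proba = est.predict_proba(small_genetic)
    assert proba.shape == (int(small_genetic["valid"].sum()), 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    assert set(est.predict(small_genetic)) <= {0, 1}
    assert "significant" in est.summary().columns


# ---------------------------------------------------------------------------
# Wald summary
# ---------------------------------------------------------------------------

def _fake_fit(rows, converged=True):
    names = list(rows)
    est = np.array([rows[n][0] for n in names])
    se = np.array([rows[n][1] for n in names])
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    p[se == 0] = 1.0
    coef = pd.DataFrame({"estimate": est, "se": se, "z": z, "p": p}, index=names)
    return GLMMFit(
        model_id=3, link="logit", coef=coef, var_pair_MZ=1.0, var_pair_MZ_se=0.1,
        var_pair_DZ=1.0, var_pair_DZ_se=0.1, scale_MZ=1.0, scale_DZ=1.0,
        minus2ll=0.0, n_obs=10, n_pairs=5, converged=converged, n_quad=15,
        grad_norm=0.0, separation=False,
    )


def test_wald_summary_significance_flags():
    fit = _fake_fit({
        "educ_within:zyg_dz": (-0.26, 0.10),   # z = -2.6 -> p ~ 0.0093
        "educ_within": (0.13, 0.09),           # z ~ 1.44 -> p ~ 0.149
        "zyg_dz": (0.0, 0.5),                  # p = 1
    })
    tab = wald_summary(fit, alpha=0.05)
    assert tab.loc["educ_within:zyg_dz", "p"] == pytest.approx(0.0093, abs=5e-4)
    assert bool(tab.loc["educ_within:zyg_dz", "significant"])
    assert tab.loc["educ_within", "p"] == pytest.approx(0.149, abs=5e-3)
    assert not bool(tab.loc["educ_within", "significant"])
    assert tab.loc["zyg_dz", "p"] == pytest.approx(1.0)


def test_wald_summary_refuses_unconverged():
    with pytest.raises(GLMMError):
        wald_summary(_fake_fit({"educ_within": (0.1, 0.1)}, converged=False))
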