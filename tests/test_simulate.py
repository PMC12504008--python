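"""Twin-cohort simulator: closed-form correlations, phenotype mapping, determinism."""

import numpy as np
import pytest
from scipy import stats

from cotwin.simulate import (
    ACEParams, CohortConfig, StudyStratum, CohortError, ConfigError,
    _ISCED_CUM_PROBS, TABLE1_PAIR_COUNTS,
    draw_pair_components, expected_twin_correlation, liabilities_to_phenotypes,
    simulate_cohort, scenario, write_cohort_csv,
)

BAL = dict(a2_edu=0.5, c2_edu=0.2, e2_edu=0.3, a2_dem=0.5, c2_dem=0.2, e2_dem=0.3)


@pytest.mark.parametrize(
    "kw, trait, zyg, expected",
    [
        (dict(a2_edu=1, c2_edu=0, e2_edu=0), "edu", "MZ", 1.0),
        (dict(a2_edu=0, c2_edu=0, e2_edu=1), "edu", "DZ", 0.0),
        (dict(a2_edu=0.5, c2_edu=0.2, e2_edu=0.3), "edu", "DZ", 0.45),
        (dict(a2_dem=0.6, c2_dem=0.15, e2_dem=0.25), "dem", "MZ", 0.75),
    ],
)
def test_expected_twin_correlation_closed_forms(kw, trait, zyg, expected):
    ace = ACEParams(**kw)
    assert expected_twin_correlation(ace, trait, zyg) == pytest.approx(expected)


@pytest.mark.parametrize("zyg, expected", [("MZ", 0.7), ("DZ", 0.45)])
def test_empirical_twin_correlation_matches_closed_form(zyg, expected):
    """Monte-Carlo liability correlations agree with a^2+c^2 / 0.5a^2+c^2."""
    ace = ACEParams(**BAL)
    rng = np.random.default_rng(10)
    liab = draw_pair_components(ace, zyg, rng, 100_000)
    r = np.corrcoef(liab.edu_liab_1, liab.edu_liab_2)[0, 1]
    mc_se = (1 - expected**2) / np.sqrt(100_000)
    assert abs(r - expected) < 3 * mc_se


def test_mz_correlation_exceeds_dz_when_heritable():
    ace = ACEParams(**BAL)
    rng = np.random.default_rng(11)
    mz = draw_pair_components(ace, "MZ", rng, 100_000)
    dz = draw_pair_components(ace, "DZ", rng, 100_000)
    r_mz = np.corrcoef(mz.dem_liab_1, mz.dem_liab_2)[0, 1]
    r_dz = np.corrcoef(dz.dem_liab_1, dz.dem_liab_2)[0, 1]
    assert r_mz > r_dz + 3 * (2.0 / np.sqrt(100_000))


def test_cross_trait_covariance_closed_form():
    """Within-person edu-dem correlation equals aE*aD*rA + cE*cD*rC + eE*eD*rE."""
    ace = ACEParams(a2_edu=0.6, c2_edu=0.2, e2_edu=0.2,
                    a2_dem=0.4, c2_dem=0.3, e2_dem=0.3, rA=0.8)
    expected = 0.8 * np.sqrt(0.6 * 0.4)
    rng = np.random.default_rng(12)
    liab = draw_pair_components(ace, "MZ", rng, 100_000)
    r = np.corrcoef(liab.edu_liab_1, liab.dem_liab_1)[0, 1]
    assert expected == pytest.approx(0.392, abs=1e-3)
    assert abs(r - expected) < 0.01


def test_causal_path_adds_to_dementia_liability():
    ace = ACEParams(**BAL, beta_causal=-0.4)
    rng = np.random.default_rng(13)
    liab = draw_pair_components(ace, "DZ", rng, 100_000)
    # cov(edu, dem) = rho + beta = -0.4 here (rho = 0)
    cov = np.cov(liab.edu_liab_1, liab.dem_liab_1)[0, 1]
    assert cov == pytest.approx(-0.4, abs=0.02)
    # variance inflation 1 + beta^2 documented (no restandardization)
    assert np.var(liab.dem_liab_1) == pytest.approx(1.16, abs=0.02)


@pytest.mark.parametrize(
    "kw",
    [
        dict(a2_edu=0.5, c2_edu=0.2, e2_edu=0.2),      # does not sum to 1
        dict(a2_edu=-0.1, c2_edu=0.6, e2_edu=0.5),     # negative component
        dict(rA=1.2),                                   # |r| > 1
    ],
)
def test_invalid_ace_params_rejected(kw):
    with pytest.raises(ConfigError):
        ACEParams(**kw)


def test_pair_covariance_is_psd_and_structured():
    ace = ACEParams(**BAL, rA=-0.8, beta_causal=0.2)
    for zyg in ("MZ", "DZ"):
        cov = ace.pair_covariance(zyg)
        assert np.linalg.eigvalsh(cov).min() > -1e-12
        assert np.allclose(cov, cov.T)


def test_isced_threshold_extremes():
    cfg = CohortConfig()
    rng = np.random.default_rng(0)
    out = liabilities_to_phenotypes(
        np.array([-10.0, 10.0]), np.zeros(2), cfg, np.array([70.0, 70.0]),
        np.zeros(2), np.array(["clinical", "clinical"]), rng,
    )
    assert out["isced9"][0] == 0  # below all thresholds
    assert out["isced9"][1] == 8  # above all 8 thresholds


def test_isced_marginal_distribution_matches_thresholds():
    """Chi-square GOF of ISCED categories against normal-CDF increments."""
    ace = ACEParams(**BAL)
    rng = np.random.default_rng(14)
    liab = draw_pair_components(ace, "MZ", rng, 50_000)
    cfg = CohortConfig()
    edu = np.concatenate([liab.edu_liab_1, liab.edu_liab_2])
    out = liabilities_to_phenotypes(
        edu, np.zeros_like(edu), cfg, np.full(edu.size, 70.0),
        np.zeros(edu.size), np.full(edu.size, "clinical"), rng,
    )
    cum = np.array((0.0,) + _ISCED_CUM_PROBS + (1.0,))
    probs = np.diff(cum)
    obs = np.bincount(out["isced9"].astype(int), minlength=9)
    chi2, p = stats.chisquare(obs, probs * edu.size)
    assert p > 0.001


def test_ldi_stratum_dementia_is_deterministic_cutoff():
    cfg = CohortConfig(ldi_noise_sd=0.0)
    rng = np.random.default_rng(1)
    dem_liab = rng.standard_normal(2000)
    out = liabilities_to_phenotypes(
        np.zeros(2000), dem_liab, cfg, np.full(2000, 70.0), np.zeros(2000),
        np.full(2000, "ldi"), rng,
    )
    np.testing.assert_array_equal(
        out["dementia"], (out["ldi"] < cfg.ldi_cutoff).astype(float)
    )


def test_onset_age_bounds():
    cfg = CohortConfig(alpha_dem=5.0)  # force near-certain dementia
    rng = np.random.default_rng(2)
    ages = np.full(500, 80.0)
    out = liabilities_to_phenotypes(
        np.zeros(500), np.zeros(500), cfg, ages, np.zeros(500),
        np.full(500, "clinical"), rng,
    )
    cases = out["dementia"] == 1
    assert cases.sum() > 400
    assert (out["onset_age"][cases] >= cfg.onset_floor).all()
    assert (out["onset_age"][cases] <= 80.0).all()


def test_simulate_cohort_record_counts():
    cfg = CohortConfig(
        n_pairs_by_type={p: 1 for p in TABLE1_PAIR_COUNTS}, n_singletons=0
    )
    df = simulate_cohort(cfg, ACEParams())
    assert len(df) == 10
    assert df["pair_id"].nunique() == 5


def test_simulate_cohort_table1_one_percent_scale():
    ace, cfg = scenario("table1_like", scale=0.01, seed=5)
    assert cfg.n_pairs_total == 299 and cfg.n_singletons == 3
    df = simulate_cohort(cfg, ace)
    assert len(df) == 2 * 299 + 3 == 601


def test_simulate_cohort_structure():
    ace, cfg = scenario("table1_like", scale=0.02, seed=6)
    df = simulate_cohort(cfg, ace)
    pairs = df[df.groupby("pair_id")["pair_id"].transform("size") == 2]
    g = pairs.groupby("pair_id")
    # pair members share study and (for same-sex pairs) sex
    assert (g["study"].nunique() == 1).all()
    same_sex = g.first()["same_sex"] == 1
    assert (g["female"].nunique()[same_sex] == 1).all()
    assert (g["female"].nunique()[~same_sex] == 2).all()
    # opposite-sex pairs are DZ only
    assert (g.first().loc[~same_sex, "zygosity"].dropna() == "DZ").all()
    assert (g["age"].nunique() == 1).any()  # shared assessment age unless onset differs


def test_simulate_cohort_deterministic(tmp_path):
    ace, cfg = scenario("table1_like", scale=0.01, seed=7)
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_csv(simulate_cohort(cfg, ace), a, truth=True)
    write_cohort_csv(simulate_cohort(cfg, ace), b, truth=True)
    assert a.read_bytes() == b.read_bytes()


def test_zero_pairs_rejected():
    cfg = CohortConfig(n_pairs_by_type={p: 0 for p in TABLE1_PAIR_COUNTS},
                       n_singletons=0)
    with pytest.raises(CohortError):
        simulate_cohort(cfg, ACEParams())


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        CohortConfig(isced_thresholds=tuple(range(8))[::-1])
    with pytest.raises(ConfigError):
        CohortConfig(missing_rates={"isced9": 1.5})
    with pytest.raises(ConfigError):
        StudyStratum("bad", ascertainment="mystery")


def test_null_scenario_has_no_education_dementia_association():
    """With no causal path and no confounding, the marginal log-odds is ~0."""
    import statsmodels.api as sm

    ace, cfg = scenario("null", scale=1.674, seed=41)  # ~50k pairs
    df = simulate_cohort(cfg, ace)
    educ3 = np.where(df["isced9"] <= 2, 1.0, np.where(df["isced9"] <= 5, 2.0, 3.0))
    X = sm.add_constant(np.column_stack([educ3, df["age"] - 60, df["female"]]))
    fit = sm.GLM(df["dementia"].to_numpy(), X, family=sm.families.Binomial()).fit()
    assert abs(fit.params[1]) < 3 * fit.bse[1]
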