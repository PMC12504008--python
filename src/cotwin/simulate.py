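"""Synthetic twin-cohort generation under a bivariate ACE liability model.

Generates cohorts of monozygotic (MZ) and dizygotic (DZ) twin pairs in which an
ordinal educational-attainment phenotype (ISCED, 9 categories) and a binary
dementia phenotype arise from correlated latent liabilities.  Each liability is
decomposed into additive genetic (A), shared environmental (C) and nonshared
environmental (E) components; confounding between the traits is induced through
the cross-trait component correlations (rA, rC, rE), and a direct causal path
from the education liability to the dementia liability is available through
``beta_causal``.

The generator exists to provide cohorts with *known ground truth* for testing
the co-twin control analysis chain: within-pair A-component correlation is 1
for MZ and 0.5 for DZ pairs, the C component is shared, and E is independent
across co-twins, so the classical twin-correlation closed forms (a2 + c2 for
MZ, 0.5*a2 + c2 for DZ) hold exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ACEParams",
    "StudyStratum",
    "CohortConfig",
    "PairLiabilities",
    "CohortError",
    "ConfigError",
    "PAIR_TYPES",
    "TABLE1_PAIR_COUNTS",
    "TABLE1_N_SINGLETONS",
    "DEFAULT_ISCED_THRESHOLDS",
    "expected_twin_correlation",
    "draw_pair_components",
    "liabilities_to_phenotypes",
    "simulate_cohort",
    "scenario",
    "write_cohort_csv",
    "read_cohort_csv",
]

PAIR_TYPES = ("MZF", "MZM", "DZF", "DZM", "DZOS")

# Five pair-type counts and singleton count of the full analytic sample the
# generator emulates (29,869 complete pairs + 289 singletons = 60,027 rows).
TABLE1_PAIR_COUNTS = {"MZF": 4123, "MZM": 5317, "DZF": 5973, "DZM": 6503, "DZOS": 7953}
TABLE1_N_SINGLETONS = 289

# Eight ordered cutpoints on the standard-normal education liability mapping to
# ISCED categories 0-8; the implied category probabilities give a 9-category
# mean of ~2.9, matching a predominantly low/mid-education older cohort.
_ISCED_CUM_PROBS = (0.08, 0.30, 0.50, 0.65, 0.80, 0.88, 0.93, 0.97)
DEFAULT_ISCED_THRESHOLDS = tuple(float(stats.norm.ppf(p)) for p in _ISCED_CUM_PROBS)

REGISTRY_SOURCES = ("registry_NPR", "registry_OPR", "registry_PDR", "registry_CDR")
# Recorded registry age lags true onset (validation-derived offsets).
REGISTRY_AGE_OFFSETS = {
    "registry_NPR": 5.0,
    "registry_OPR": 5.0,
    "registry_PDR": 5.0,
    "registry_CDR": 7.0,
}

COHORT_COLUMNS = [
    "pair_id", "member", "zygosity", "same_sex", "female", "black", "study",
    "age", "birth_year", "isced9", "ldi", "dementia", "onset_age",
    "ascertainment", "true_edu_liab", "true_dem_liab",
]


class CohortError(ValueError):
    """Raised for unusable cohort requests (e.g. zero pairs)."""


class ConfigError(ValueError):
    """Raised when a simulator configuration violates its invariants."""


@dataclass(frozen=True)
class ACEParams:
    """Standardized variance components of the bivariate liability model.

    ``a2_* + c2_* + e2_*`` must equal 1 for each trait.  ``rA``, ``rC`` and
    ``rE`` are the cross-trait correlations of the respective components and
    drive genetic / shared-environmental / nonshared confounding between
    education and dementia liabilities.  ``beta_causal`` is a direct
    liability-scale path from education to dementia, added without
    restandardization (the dementia liability variance becomes
    1 + beta^2 + 2*beta*rho; see docs/methods.md).
    """

    a2_edu: float = 0.4
    c2_edu: float = 0.35
    e2_edu: float = 0.25
    a2_dem: float = 0.6
    c2_dem: float = 0.1
    e2_dem: float = 0.3
    rA: float = 0.0
    rC: float = 0.0
    rE: float = 0.0
    beta_causal: float = 0.0

    def __post_init__(self) -> None:
        for trait in ("edu", "dem"):
            comps = [getattr(self, f"{k}2_{trait}") for k in "ace"]
            if any(c < 0 for c in comps):
                raise ConfigError(f"negative variance component for {trait}: {comps}")
            if abs(sum(comps) - 1.0) > 1e-12:
                raise ConfigError(
                    f"variance components for {trait} must sum to 1, got {sum(comps)!r}"
                )
        for name in ("rA", "rC", "rE"):
            if abs(getattr(self, name)) > 1.0:
                raise ConfigError(f"|{name}| must be <= 1")
        for zyg in ("MZ", "DZ"):
            cov = self.pair_covariance(zyg)
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ConfigError(f"implied {zyg} pair covariance is not PSD")

    def loading(self, comp: str, trait: str) -> float:
        """Path loading (square root of the variance component)."""
        return float(np.sqrt(getattr(self, f"{comp}2_{trait}")))

    def cross_trait_cov(self) -> float:
        """Within-person education-dementia liability covariance, causal path excluded."""
        return (
            self.loading("a", "edu") * self.loading("a", "dem") * self.rA
            + self.loading("c", "edu") * self.loading("c", "dem") * self.rC
            + self.loading("e", "edu") * self.loading("e", "dem") * self.rE
        )

    def pair_covariance(self, zygosity: str) -> np.ndarray:
        """Implied 4x4 covariance of (edu1, dem1, edu2, dem2), causal path included."""
        k = _genetic_sharing(zygosity)
        aE, aD = self.loading("a", "edu"), self.loading("a", "dem")
        cE, cD = self.loading("c", "edu"), self.loading("c", "dem")
        rho_within = self.cross_trait_cov()
        rho_cross = k * aE * aD * self.rA + cE * cD * self.rC
        r_edu = k * self.a2_edu + self.c2_edu
        r_dem = k * self.a2_dem + self.c2_dem
        base = np.array(
            [
                [1.0, rho_within, r_edu, rho_cross],
                [rho_within, 1.0, rho_cross, r_dem],
                [r_edu, rho_cross, 1.0, rho_within],
                [rho_cross, r_dem, rho_within, 1.0],
            ]
        )
        b = self.beta_causal
        lift = np.eye(4)
        lift[1, 0] = b
        lift[3, 2] = b
        return lift @ base @ lift.T


@dataclass(frozen=True)
class StudyStratum:
    """One study stratum: age distribution, ascertainment mode and sampling weight."""

    label: str
    weight: float = 1.0
    age_mean: float = 72.0
    age_sd: float = 10.0
    age_min: float = 50.0
    age_max: float = 105.0
    ascertainment: str = "clinical"  # clinical | registry | ldi
    p_black: float = 0.0
    assess_year: int = 2000

    def __post_init__(self) -> None:
        if self.ascertainment not in ("clinical", "registry", "ldi"):
            raise ConfigError(f"unknown ascertainment mode {self.ascertainment!r}")
        if self.weight <= 0:
            raise ConfigError("study weight must be positive")
        if not 0.0 <= self.p_black <= 1.0:
            raise ConfigError("p_black must be in [0, 1]")
        if self.age_min >= self.age_max:
            raise ConfigError("age_min must be below age_max")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout and measurement model for :func:`simulate_cohort`.

    ``alpha_dem`` / ``lambda_dem`` define the logistic risk model on the
    dementia liability used in clinical and registry strata; ``beta_educ3`` is
    an optional direct log-odds effect of the observed 3-category education
    score (centred at 2), and ``pair_sd_mz`` / ``pair_sd_dz`` inject an
    explicit logit-scale shared pair intercept.  LDI strata assign dementia
    deterministically by the ``ldi_cutoff`` threshold (lower LDI = impaired).
    """

    n_pairs_by_type: Mapping[str, int] = field(
        default_factory=lambda: dict(TABLE1_PAIR_COUNTS)
    )
    n_singletons: int = TABLE1_N_SINGLETONS
    studies: Sequence[StudyStratum] = field(
        default_factory=lambda: (StudyStratum("S1"),)
    )
    isced_thresholds: Sequence[float] = DEFAULT_ISCED_THRESHOLDS
    ldi_loc: float = 6.5
    ldi_scale: float = 1.2
    ldi_noise_sd: float = 0.5
    ldi_cutoff: float = 4.8
    alpha_dem: float = -3.8
    lambda_dem: float = 2.0
    beta_age: float = 0.08
    beta_female: float = 0.3
    beta_educ3: float = 0.0
    pair_sd_mz: float = 0.0
    pair_sd_dz: float = 0.0
    onset_floor: float = 65.0
    registry_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "registry_NPR": 0.6, "registry_OPR": 0.2,
            "registry_PDR": 0.1, "registry_CDR": 0.1,
        }
    )
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for ptype in self.n_pairs_by_type:
            if ptype not in PAIR_TYPES:
                raise ConfigError(f"unknown pair type {ptype!r}")
        if any(n < 0 for n in self.n_pairs_by_type.values()) or self.n_singletons < 0:
            raise ConfigError("pair/singleton counts must be >= 0")
        thr = np.asarray(self.isced_thresholds, dtype=float)
        if thr.size != 8 or not np.all(np.diff(thr) > 0):
            raise ConfigError("isced_thresholds must be 8 strictly increasing values")
        if self.ldi_noise_sd < 0:
            raise ConfigError("ldi_noise_sd must be >= 0")
        if not self.studies:
            raise ConfigError("at least one study stratum is required")
        for fieldname, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missing rate for {fieldname!r} not in [0, 1]")
        if abs(sum(self.registry_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("registry source probabilities must sum to 1")

    @property
    def n_pairs_total(self) -> int:
        return int(sum(self.n_pairs_by_type.values()))


@dataclass(frozen=True)
class PairLiabilities:
    """Standard-normal-scale liabilities for both members of a set of pairs."""

    edu_liab_1: np.ndarray
    edu_liab_2: np.ndarray
    dem_liab_1: np.ndarray
    dem_liab_2: np.ndarray


def _genetic_sharing(zygosity: str) -> float:
    if zygosity == "MZ":
        return 1.0
    if zygosity == "DZ":
        return 0.5
    raise ConfigError(f"unknown zygosity {zygosity!r}")


def expected_twin_correlation(ace: ACEParams, trait: str, zygosity: str) -> float:
    """Closed-form within-pair liability correlation: a2 + c2 (MZ) or 0.5 a2 + c2 (DZ).

    Applies to the base (pre-causal-path) liabilities; with ``beta_causal != 0``
    the realized dementia-liability correlation also involves the education
    components (see :meth:`ACEParams.pair_covariance`).
    """
    if trait not in ("edu", "dem"):
        raise ConfigError(f"unknown trait {trait!r}")
    k = _genetic_sharing(zygosity)
    return k * getattr(ace, f"a2_{trait}") + getattr(ace, f"c2_{trait}")


def _correlated_normals(rng: np.random.Generator, r: float, n: int):
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z2


def draw_pair_components(
    ace: ACEParams, zygosity: str, rng: np.random.Generator, n_pairs: int = 1
) -> PairLiabilities:
    """Draw liabilities for ``n_pairs`` twin pairs of the given zygosity.

    The A component correlates 1.0 (MZ) or 0.5 (DZ) across co-twins, C is
    identical within a pair, E is independent across co-twins; cross-trait
    component correlations equal rA, rC, rE.  The causal path adds
    ``beta_causal * edu_liab`` to each member's dementia liability.
    """
    _genetic_sharing(zygosity)  # validates the zygosity label
    if zygosity == "MZ":
        aE, aD = _correlated_normals(rng, ace.rA, n_pairs)
        aE1, aD1 = aE, aD
        aE2, aD2 = aE, aD
    else:  # DZ: half common, half segregating genetic variance
        cE_g, cD_g = _correlated_normals(rng, ace.rA, n_pairs)
        s1E, s1D = _correlated_normals(rng, ace.rA, n_pairs)
        s2E, s2D = _correlated_normals(rng, ace.rA, n_pairs)
        rt = np.sqrt(0.5)
        aE1, aD1 = rt * (cE_g + s1E), rt * (cD_g + s1D)
        aE2, aD2 = rt * (cE_g + s2E), rt * (cD_g + s2D)
    cE, cD = _correlated_normals(rng, ace.rC, n_pairs)
    e1E, e1D = _correlated_normals(rng, ace.rE, n_pairs)
    e2E, e2D = _correlated_normals(rng, ace.rE, n_pairs)

    la_e, lc_e, le_e = (ace.loading(c, "edu") for c in "ace")
    la_d, lc_d, le_d = (ace.loading(c, "dem") for c in "ace")
    edu1 = la_e * aE1 + lc_e * cE + le_e * e1E
    edu2 = la_e * aE2 + lc_e * cE + le_e * e2E
    dem1 = la_d * aD1 + lc_d * cD + le_d * e1D + ace.beta_causal * edu1
    dem2 = la_d * aD2 + lc_d * cD + le_d * e2D + ace.beta_causal * edu2
    return PairLiabilities(edu1, edu2, dem1, dem2)


def liabilities_to_phenotypes(
    edu_liab: np.ndarray,
    dem_liab: np.ndarray,
    cfg: CohortConfig,
    age: np.ndarray,
    female: np.ndarray,
    ascertainment_mode: np.ndarray,
    rng: np.random.Generator,
    extra_logit: np.ndarray | float = 0.0,
) -> dict:
    """Map liabilities to observed phenotypes for a vector of individuals.

    Returns ``isced9`` (count of thresholds strictly below the education
    liability), ``ldi`` (affine transform of the negated dementia liability
    plus Gaussian noise, so lower LDI = greater dementia likelihood),
    ``dementia`` (Bernoulli logistic risk in clinical/registry strata,
    deterministic LDI cutoff in LDI strata) and ``onset_age`` for cases
    (uniform between ``onset_floor`` and the assessment age).
    """
    edu_liab = np.asarray(edu_liab, dtype=float)
    dem_liab = np.asarray(dem_liab, dtype=float)
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=float)
    mode = np.asarray(ascertainment_mode)
    n = edu_liab.size

    thr = np.asarray(cfg.isced_thresholds, dtype=float)
    isced9 = np.searchsorted(thr, edu_liab, side="left").astype(float)

    noise = rng.normal(0.0, cfg.ldi_noise_sd, n) if cfg.ldi_noise_sd > 0 else 0.0
    ldi = cfg.ldi_loc + cfg.ldi_scale * (-dem_liab) + noise

    # 3-category collapse of ISCED feeds the optional direct log-odds effect.
    educ3 = np.where(isced9 <= 2, 1.0, np.where(isced9 <= 5, 2.0, 3.0))
    eta = (
        cfg.alpha_dem
        + cfg.lambda_dem * dem_liab
        + cfg.beta_age * (age - 60.0)
        + cfg.beta_female * female
        + cfg.beta_educ3 * (educ3 - 2.0)
        + extra_logit
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    risk_dem = (rng.random(n) < p).astype(float)
    ldi_dem = (ldi < cfg.ldi_cutoff).astype(float)
    dementia = np.where(mode == "ldi", ldi_dem, risk_dem)

    lo = np.minimum(cfg.onset_floor, age)
    onset = lo + rng.random(n) * (age - lo)
    onset_age = np.where(dementia == 1.0, onset, np.nan)
    return {"isced9": isced9, "ldi": ldi, "dementia": dementia, "onset_age": onset_age}


def _pair_type_attrs(ptype: str) -> tuple[str, int]:
    zyg = "MZ" if ptype.startswith("MZ") else "DZ"
    same_sex = 0 if ptype == "DZOS" else 1
    return zyg, same_sex


def simulate_cohort(cfg: CohortConfig, ace: ACEParams) -> pd.DataFrame:
    """Simulate a full twin cohort table (2 rows per pair + singleton rows).

    Deterministic given ``cfg.seed``: randomness flows from a single
    SeedSequence, spawned into fixed per-stage sub-streams.
    """
    if cfg.n_pairs_total == 0:
        raise CohortError("zero pairs requested: cannot simulate an empty cohort")

    ss = np.random.SeedSequence(cfg.seed)
    keys = ["comp_" + p for p in PAIR_TYPES] + [
        "comp_single", "assign", "pheno", "pairb", "missing", "sex_os",
    ]
    streams = dict(zip(keys, (np.random.default_rng(s) for s in ss.spawn(len(keys)))))

    # --- pair-level frame -------------------------------------------------
    ptypes, zygs, same_sexes = [], [], []
    edu1_l, edu2_l, dem1_l, dem2_l = [], [], [], []
    for ptype in PAIR_TYPES:
        n = int(cfg.n_pairs_by_type.get(ptype, 0))
        if n == 0:
            continue
        zyg, ss_flag = _pair_type_attrs(ptype)
        liab = draw_pair_components(ace, zyg, streams["comp_" + ptype], n)
        ptypes += [ptype] * n
        zygs += [zyg] * n
        same_sexes += [ss_flag] * n
        edu1_l.append(liab.edu_liab_1)
        edu2_l.append(liab.edu_liab_2)
        dem1_l.append(liab.dem_liab_1)
        dem2_l.append(liab.dem_liab_2)

    n_pairs = len(ptypes)
    edu1 = np.concatenate(edu1_l)
    edu2 = np.concatenate(edu2_l)
    dem1 = np.concatenate(dem1_l)
    dem2 = np.concatenate(dem2_l)
    is_single = np.zeros(n_pairs, dtype=bool)

    if cfg.n_singletons > 0:
        counts = np.array([cfg.n_pairs_by_type.get(p, 0) for p in PAIR_TYPES], float)
        probs = counts / counts.sum()
        alloc = streams["comp_single"].multinomial(cfg.n_singletons, probs)
        for ptype, n in zip(PAIR_TYPES, alloc):
            if n == 0:
                continue
            zyg, ss_flag = _pair_type_attrs(ptype)
            liab = draw_pair_components(ace, zyg, streams["comp_single"], int(n))
            ptypes += [ptype] * int(n)
            zygs += [zyg] * int(n)
            same_sexes += [ss_flag] * int(n)
            edu1 = np.concatenate([edu1, liab.edu_liab_1])
            edu2 = np.concatenate([edu2, liab.edu_liab_2])
            dem1 = np.concatenate([dem1, liab.dem_liab_1])
            dem2 = np.concatenate([dem2, liab.dem_liab_2])
            is_single = np.concatenate([is_single, np.ones(int(n), dtype=bool)])

    n_units = len(ptypes)
    ptypes = np.asarray(ptypes)
    zygs = np.asarray(zygs)
    same_sexes = np.asarray(same_sexes)
    pair_ids = np.arange(1, n_units + 1)

    # study assignment, ages (shared within pair), race
    rng_a = streams["assign"]
    weights = np.array([s.weight for s in cfg.studies], float)
    study_idx = rng_a.choice(len(cfg.studies), size=n_units, p=weights / weights.sum())
    age_mean = np.array([s.age_mean for s in cfg.studies])[study_idx]
    age_sd = np.array([s.age_sd for s in cfg.studies])[study_idx]
    age_lo = np.array([s.age_min for s in cfg.studies])[study_idx]
    age_hi = np.array([s.age_max for s in cfg.studies])[study_idx]
    age_pair = np.clip(rng_a.normal(age_mean, age_sd), age_lo, age_hi)
    p_black = np.array([s.p_black for s in cfg.studies])[study_idx]
    black_pair = (rng_a.random(n_units) < p_black).astype(int)
    assess_year = np.array([s.assess_year for s in cfg.studies])[study_idx]
    study_lab = np.array([s.label for s in cfg.studies])[study_idx]
    mode_pair = np.array([s.ascertainment for s in cfg.studies])[study_idx]

    # sexes: member-level; DZOS member order randomized
    fem1 = np.where(ptypes == "MZF", 1, np.where(ptypes == "DZF", 1, 0))
    fem2 = fem1.copy()
    os_mask = ptypes == "DZOS"
    os_first_female = streams["sex_os"].random(n_units) < 0.5
    fem1 = np.where(os_mask, os_first_female.astype(int), fem1)
    fem2 = np.where(os_mask, 1 - os_first_female.astype(int), fem2)

    # explicit logit-scale pair intercept (zygosity-specific SD)
    pair_sd = np.where(zygs == "DZ", cfg.pair_sd_dz, cfg.pair_sd_mz)
    pair_b = streams["pairb"].standard_normal(n_units) * pair_sd

    # --- expand to member level ------------------------------------------
    keep2 = ~is_single
    def _stack(a1, a2):
        return np.concatenate([np.asarray(a1), np.asarray(a2)[keep2]])

    member = np.concatenate([np.ones(n_units, int), np.full(keep2.sum(), 2, int)])
    rec = {
        "pair_id": _stack(pair_ids, pair_ids),
        "member": member,
        "zygosity": _stack(zygs, zygs),
        "same_sex": _stack(same_sexes, same_sexes),
        "female": _stack(fem1, fem2),
        "black": _stack(black_pair, black_pair),
        "study": _stack(study_lab, study_lab),
        "age": _stack(age_pair, age_pair),
    }
    mode = _stack(mode_pair, mode_pair)
    extra = _stack(pair_b, pair_b)
    edu = _stack(edu1, edu2)
    dem = _stack(dem1, dem2)
    assess = _stack(assess_year, assess_year)

    phen = liabilities_to_phenotypes(
        edu, dem, cfg, rec["age"], rec["female"], mode, streams["pheno"], extra
    )
    n_rec = edu.size

    # ascertainment labels and registry age distortion
    asc = np.where(mode == "ldi", "ldi", "clinical").astype(object)
    demented = phen["dementia"] == 1.0
    age_final = rec["age"].astype(float).copy()
    onset_final = phen["onset_age"].copy()
    reg_case = (mode == "registry") & demented
    if reg_case.any():
        srcs = list(cfg.registry_probs)
        p = np.array([cfg.registry_probs[s] for s in srcs])
        drawn = streams["pheno"].choice(len(srcs), size=int(reg_case.sum()), p=p)
        asc[reg_case] = np.array(srcs, dtype=object)[drawn]
        offsets = np.array([REGISTRY_AGE_OFFSETS[s] for s in srcs])[drawn]
        onset_final[reg_case] = onset_final[reg_case] + offsets
    clin_case = (mode == "clinical") & demented
    age_final[clin_case] = onset_final[clin_case]
    age_final[reg_case] = onset_final[reg_case]

    df = pd.DataFrame(rec)
    df["age"] = age_final
    df["birth_year"] = (assess - np.round(age_final)).astype(int)
    df["isced9"] = phen["isced9"]
    df["ldi"] = phen["ldi"]
    df["dementia"] = phen["dementia"]
    df["onset_age"] = onset_final
    df["ascertainment"] = asc
    df["true_edu_liab"] = edu
    df["true_dem_liab"] = dem

    # field-wise missingness
    rng_m = streams["missing"]
    for fieldname, rate in cfg.missing_rates.items():
        if rate <= 0:
            continue
        mask = rng_m.random(n_rec) < rate
        if fieldname == "zygosity":
            df.loc[mask, "zygosity"] = np.nan
        elif fieldname in ("isced9", "ldi", "dementia", "age", "onset_age"):
            df.loc[mask, fieldname] = np.nan
        else:
            raise ConfigError(f"missingness not supported for field {fieldname!r}")

    df = df.sort_values(["pair_id", "member"], kind="stable").reset_index(drop=True)
    return df[COHORT_COLUMNS]


def _scaled_pairs(scale: float) -> dict:
    return {p: max(1, round(n * scale)) for p, n in TABLE1_PAIR_COUNTS.items()}


def scenario(
    name: str,
    scale: float = 1.0,
    seed: int = 0,
    ascertainment: str | None = None,
) -> tuple[ACEParams, CohortConfig]:
    """Named generative scenarios with known ground truth.

    - ``table1_like``: descriptive cohort mimicking the mixed-ascertainment
      consortium structure, mild genetic + shared-environmental confounding,
      modest missingness.
    - ``null``: no education-dementia association of any kind; dementia risk
      driven by explicit logit-scale pair intercepts (exactly the fitted
      model's null; used for type-I calibration).
    - ``recovery``: as ``null`` plus a direct log-odds effect of -0.5 per
      education category (fitted model correctly specified; used for
      parameter recovery).
    - ``quasi_causal``: direct log-odds effect of -0.5 with familial
      clustering of dementia but no cross-trait confounding.
    - ``genetic_confounding``: rA = -0.8, no causal path (education appears
      protective purely through shared additive-genetic factors).
    - ``shared_env_confounding``: rC = -0.8, no causal path.

    ``ascertainment`` forces a single stratum of the given mode ('clinical',
    'registry' or 'ldi'); scenarios default to the mode noted below.
    """
    pairs = _scaled_pairs(scale)
    n_single = max(0, round(TABLE1_N_SINGLETONS * scale))
    base_cfg = dict(n_pairs_by_type=pairs, n_singletons=n_single, seed=seed)

    def single_study(mode: str) -> tuple[StudyStratum, ...]:
        return (StudyStratum("S1", ascertainment=mode),)

    if name == "table1_like":
        ace = ACEParams(rA=-0.4, rC=-0.2)
        studies = (
            StudyStratum("registry_like", weight=0.60, age_mean=73.6, age_sd=9.8,
                         ascertainment="registry"),
            StudyStratum("ldi_like", weight=0.25, age_mean=67.0, age_sd=11.6,
                         ascertainment="ldi"),
            StudyStratum("clinical_like", weight=0.15, age_mean=74.7, age_sd=5.7,
                         ascertainment="clinical"),
        )
        cfg = CohortConfig(
            **base_cfg,
            studies=single_study(ascertainment) if ascertainment else studies,
            missing_rates={"isced9": 0.02, "ldi": 0.05, "dementia": 0.01,
                           "zygosity": 0.01, "age": 0.005},
        )
    elif name == "null":
        ace = ACEParams()
        cfg = CohortConfig(
            **base_cfg, studies=single_study(ascertainment or "clinical"),
            lambda_dem=0.0, pair_sd_mz=1.2, pair_sd_dz=0.8, alpha_dem=-2.5,
        )
    elif name == "recovery":
        ace = ACEParams()
        cfg = CohortConfig(
            **base_cfg, studies=single_study(ascertainment or "clinical"),
            lambda_dem=0.0, pair_sd_mz=1.2, pair_sd_dz=0.8, alpha_dem=-2.5,
            beta_educ3=-0.5,
        )
    elif name == "quasi_causal":
        ace = ACEParams()
        cfg = CohortConfig(
            **base_cfg, studies=single_study(ascertainment or "clinical"),
            beta_educ3=-0.5, alpha_dem=-3.2,
        )
    elif name == "genetic_confounding":
        ace = ACEParams(a2_edu=0.6, c2_edu=0.2, e2_edu=0.2, rA=-0.8)
        cfg = CohortConfig(
            **base_cfg, studies=single_study(ascertainment or "clinical"),
            alpha_dem=-3.2,
        )
    elif name == "shared_env_confounding":
        ace = ACEParams(a2_edu=0.6, c2_edu=0.2, e2_edu=0.2,
                        a2_dem=0.3, c2_dem=0.4, e2_dem=0.3, rC=-0.8)
        cfg = CohortConfig(
            **base_cfg, studies=single_study(ascertainment or "clinical"),
            alpha_dem=-3.2,
        )
    else:
        raise ConfigError(f"unknown scenario {name!r}")
    return ace, cfg


def write_cohort_csv(df: pd.DataFrame, path, truth: bool = False) -> None:
    """Write a cohort table to CSV; truth columns are dropped unless ``truth``."""
    out = df if truth else df.drop(columns=["true_edu_liab", "true_dem_liab"],
                                   errors="ignore")
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
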