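"""Inferential decision rules and discordant-pair sensitivity analyses.

The between-within model ladder yields a categorical interpretation of the
education-dementia association:

- a significant, protective (negative) within-pair effect in MZ twins
  (pi_2 with the zygosity interaction in the model) -> ``quasi_causal``;
- otherwise a significant between-pair effect (pi_1) indicates familial
  confounding, resolved by the educ-within x zygosity interaction (pi_4):
  significant -> ``genetic_confounding``, null -> ``shared_env_confounding``;
  with no zygosity model available the verdict stays ``familial_unspecified``;
- no significant exposure effect anywhere -> ``no_association``.

The discordant-pair sensitivity analysis tabulates, per sample and zygosity,
twin pairs discordant for dementia in which the non-demented co-twin survived
past the affected twin's onset age, comparing how often the demented twin had
the higher versus the lower education (exact binomial sign test).  A variant
additionally admits both-affected pairs whose onsets are at least ``min_gap``
years apart, treating the later-onset twin as the control (does education
delay onset?).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GLMMFit

__all__ = [
    "ConfoundingVerdict",
    "DiscordantPairRecord",
    "InterpretError",
    "classify_confounding",
    "find_discordant_pairs",
    "sign_test",
    "delayed_onset_variant",
    "discordant_frequency_table",
]

VERDICTS = (
    "quasi_causal",
    "genetic_confounding",
    "shared_env_confounding",
    "familial_unspecified",
    "no_association",
)


class InterpretError(ValueError):
    pass


@dataclass(frozen=True)
class ConfoundingVerdict:
    verdict: str
    alpha: float
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise InterpretError(f"unknown verdict {self.verdict!r}")


@dataclass(frozen=True)
class DiscordantPairRecord:
    pair_id: int
    zygosity: str
    study: str
    affected_member: int
    onset_age: float
    control_survived: bool
    education_comparison: str  # affected_higher | control_higher | equal
    delayed_onset: bool = False


def _coef(fit: GLMMFit, name: str):
    if name not in fit.coef.index:
        return None
    est, se, p = fit.coefficient(name)
    return {"estimate": est, "se": se, "p": p}


def classify_confounding(
    model2_fit: GLMMFit, model3_fit: GLMMFit | None, alpha: float = 0.05
) -> ConfoundingVerdict:
    """Classify the association pattern from the Model 2 (and 3) fits.

    Deterministic function of the coefficient estimates, their two-sided
    Wald p-values and the stated alpha.  Refuses unconverged fits.
    """
    if not model2_fit.converged or (model3_fit is not None and not model3_fit.converged):
        raise InterpretError("classification refused: unconverged model fit")

    pi1 = _coef(model2_fit, "educ_between")
    pi2_m2 = _coef(model2_fit, "educ_within")
    pi2 = _coef(model3_fit, "educ_within") if model3_fit is not None else pi2_m2
    pi4 = _coef(model3_fit, "educ_within:zyg_dz") if model3_fit is not None else None
    if pi1 is None or pi2_m2 is None:
        raise InterpretError("model 2 fit lacks the between/within decomposition")

    evidence = {"pi_1": pi1, "pi_2": pi2, "pi_2_model2": pi2_m2, "pi_4": pi4}

    def sig(c):
        return c is not None and c["p"] < alpha

    if sig(pi2) and pi2["estimate"] < 0:
        verdict = "quasi_causal"
    elif sig(pi1):
        if pi4 is None:
            verdict = "familial_unspecified"
        elif sig(pi4):
            verdict = "genetic_confounding"
        else:
            verdict = "shared_env_confounding"
    else:
        verdict = "no_association"
    return ConfoundingVerdict(verdict=verdict, alpha=alpha, evidence=evidence)


def find_discordant_pairs(df: pd.DataFrame) -> list:
    """Dementia-discordant pairs whose control outlived the affected twin's onset.

    Requires exactly one demented member with a known onset age; the
    non-demented co-twin's age (last seen / censoring age) must exceed that
    onset age.  Education is compared on the 9-category ISCED code.
    """
    need = df.dropna(subset=["dementia"])
    need = need[need["zygosity"].isin(["MZ", "DZ"])]
    sizes = need.groupby("pair_id")["pair_id"].transform("size")
    need = need[sizes == 2].sort_values("pair_id", kind="stable")

    pid = need["pair_id"].to_numpy()
    dem = need["dementia"].to_numpy(dtype=float)
    onset = need["onset_age"].to_numpy(dtype=float)
    age = need["age"].to_numpy(dtype=float)
    isced = need["isced9"].to_numpy(dtype=float)
    zyg = need["zygosity"].to_numpy(dtype=object)
    study = (need["study"].to_numpy(dtype=object) if "study" in need.columns
             else np.full(len(need), "all", dtype=object))
    member = need["member"].to_numpy()

    a, b = np.arange(0, len(need), 2), np.arange(1, len(need), 2)
    out = []
    for i, j in zip(a, b):
        if dem[i] + dem[j] != 1.0:
            continue
        aff, ctl = (i, j) if dem[i] == 1.0 else (j, i)
        if not np.isfinite(onset[aff]) or not np.isfinite(age[ctl]):
            continue
        if age[ctl] <= onset[aff]:
            continue
        if np.isfinite(isced[aff]) and np.isfinite(isced[ctl]):
            if isced[aff] > isced[ctl]:
                comp = "affected_higher"
            elif isced[aff] < isced[ctl]:
                comp = "control_higher"
            else:
                comp = "equal"
        else:
            comp = "equal"
        out.append(DiscordantPairRecord(
            pair_id=int(pid[i]), zygosity=str(zyg[i]), study=str(study[i]),
            affected_member=int(member[aff]), onset_age=float(onset[aff]),
            control_survived=True, education_comparison=comp,
        ))
    return out


def sign_test(n_affected_higher: int, n_control_higher: int) -> float:
    """Two-sided exact binomial sign test against p = 0.5 (doubling rule, capped at 1)."""
    if n_affected_higher < 0 or n_control_higher < 0:
        raise InterpretError("counts must be non-negative")
    n = n_affected_higher + n_control_higher
    if n == 0:
        raise InterpretError("sign test requires at least one unequal pair")
    k = min(n_affected_higher, n_control_higher)
    p = 2.0 * stats.binom.cdf(k, n, 0.5)
    if n_affected_higher == n_control_higher:
        p = 1.0
    return float(min(p, 1.0))


def delayed_onset_variant(df: pd.DataFrame, min_gap: float = 5.0) -> tuple:
    """Discordant set augmented with both-affected pairs of onset gap >= min_gap.

    The later-onset twin is treated as the control.  Returns the augmented
    record list and the sign-test p-value over unequal-education pairs.
    """
    if min_gap <= 0:
        raise InterpretError("min_gap must be positive")
    records = find_discordant_pairs(df)

    need = df.dropna(subset=["dementia"])
    need = need[need["zygosity"].isin(["MZ", "DZ"])]
    sizes = need.groupby("pair_id")["pair_id"].transform("size")
    need = need[sizes == 2].sort_values("pair_id", kind="stable")
    pid = need["pair_id"].to_numpy()
    dem = need["dementia"].to_numpy(dtype=float)
    onset = need["onset_age"].to_numpy(dtype=float)
    isced = need["isced9"].to_numpy(dtype=float)
    zyg = need["zygosity"].to_numpy(dtype=object)
    study = (need["study"].to_numpy(dtype=object) if "study" in need.columns
             else np.full(len(need), "all", dtype=object))
    member = need["member"].to_numpy()

    a, b = np.arange(0, len(need), 2), np.arange(1, len(need), 2)
    for i, j in zip(a, b):
        if dem[i] + dem[j] != 2.0:
            continue
        if not (np.isfinite(onset[i]) and np.isfinite(onset[j])):
            continue
        if abs(onset[i] - onset[j]) < min_gap:
            continue
        aff, ctl = (i, j) if onset[i] < onset[j] else (j, i)
        if np.isfinite(isced[aff]) and np.isfinite(isced[ctl]):
            if isced[aff] > isced[ctl]:
                comp = "affected_higher"
            elif isced[aff] < isced[ctl]:
                comp = "control_higher"
            else:
                comp = "equal"
        else:
            comp = "equal"
        records.append(DiscordantPairRecord(
            pair_id=int(pid[i]), zygosity=str(zyg[i]), study=str(study[i]),
            affected_member=int(member[aff]), onset_age=float(onset[aff]),
            control_survived=True, education_comparison=comp, delayed_onset=True,
        ))
    n_aff = sum(r.education_comparison == "affected_higher" for r in records)
    n_ctl = sum(r.education_comparison == "control_higher" for r in records)
    p = sign_test(n_aff, n_ctl) if (n_aff + n_ctl) > 0 else float("nan")
    return records, p


def discordant_frequency_table(records) -> pd.DataFrame:
    """Per (study, zygosity) frequencies and sign-test p-values."""
    rows = []
    key = lambda r: (r.study, r.zygosity)
    groups: dict = {}
    for r in records:
        groups.setdefault(key(r), []).append(r)
    for (study, zyg), recs in sorted(groups.items()):
        n_aff = sum(r.education_comparison == "affected_higher" for r in recs)
        n_ctl = sum(r.education_comparison == "control_higher" for r in recs)
        n_eq = sum(r.education_comparison == "equal" for r in recs)
        p = sign_test(n_aff, n_ctl) if (n_aff + n_ctl) > 0 else float("nan")
        rows.append({
            "study": study, "zygosity": zyg, "n_pairs": len(recs),
            "affected_higher": n_aff, "control_higher": n_ctl,
            "equal_education": n_eq, "sign_test_p": p,
        })
    return pd.DataFrame(rows)
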