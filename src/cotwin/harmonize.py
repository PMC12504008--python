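"""Variable-construction rules producing the analysis-ready cohort.

Implements the harmonization conventions of the consortium analysis:

- ISCED education (9 categories, 0-8) collapsed to three categories
  (0-2 -> 1, 3-5 -> 2, 6-8 -> 3) for the genetic models;
- registry-ascertained dementia onset ages corrected for diagnostic lag
  (-5 years for patient/outpatient/drug registers, -7 for cause-of-death);
- age capped at 90 and centred at 60;
- dementia operationalized as clinical diagnosis where available, otherwise
  by an LDI cutoff (lower LDI = greater dementia likelihood);
- zygosity coded DZ = 1 / MZ = 0, female = 1 / male = 0, Black = 1 / non-Black = 0.

Records missing zygosity, ISCED, dementia status or age are flagged invalid
with a reason code and retained (no rows are dropped), enabling a
flowchart-style exclusion accounting.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizationError",
    "REGISTRY_AGE_CORRECTIONS",
    "collapse_isced",
    "adjust_registry_onset_age",
    "cap_and_center_age",
    "operationalize_dementia",
    "CohortHarmonizer",
    "harmonize",
    "exclusion_report",
]

AGE_CAP = 90.0
AGE_CENTER = 60.0

# Years subtracted from recorded registry age to approximate true onset.
REGISTRY_AGE_CORRECTIONS = {
    "registry_NPR": 5.0,
    "registry_OPR": 5.0,
    "registry_PDR": 5.0,
    "registry_CDR": 7.0,
}
NON_REGISTRY_SOURCES = ("clinical", "ldi")

REQUIRED_FIELDS = ("zygosity", "isced9", "dementia", "age")


class HarmonizationError(ValueError):
    """Raised on values outside the harmonization rules' domains."""


def collapse_isced(isced9):
    """Collapse 9-category ISCED (0-8) to the 3-category education score.

    0-2 -> 1 (lower secondary or less), 3-5 -> 2 (upper secondary through
    short-cycle tertiary), 6-8 -> 3 (bachelor's degree or higher).
    Accepts scalars or arrays; NaN propagates.
    """
    arr = np.asarray(isced9, dtype=float)
    finite = np.isfinite(arr)
    vals = arr[finite]
    if ((vals < 0) | (vals > 8) | (vals != np.round(vals))).any():
        raise HarmonizationError("isced9 values must be integers in 0..8")
    out = np.full(arr.shape, np.nan)
    out[finite] = np.where(vals <= 2, 1.0, np.where(vals <= 5, 2.0, 3.0))
    if np.isscalar(isced9) or isinstance(isced9, numbers.Number):
        return float(out) if np.isnan(out) else int(out)
    return out


def adjust_registry_onset_age(age, source: str):
    """Correct a recorded registry age for diagnostic lag.

    NPR/OPR/PDR sources subtract 5 years, CDR subtracts 7; clinical and LDI
    ascertainment are returned unchanged.  Unknown source labels raise.
    """
    if source in REGISTRY_AGE_CORRECTIONS:
        return age - REGISTRY_AGE_CORRECTIONS[source]
    if source in NON_REGISTRY_SOURCES:
        return age
    raise HarmonizationError(f"unknown ascertainment source {source!r}")


def cap_and_center_age(age):
    """Cap age at 90 years and centre at 60: returns (age_capped, age_centered)."""
    arr = np.asarray(age, dtype=float)
    if (arr[np.isfinite(arr)] <= 0).any():
        raise HarmonizationError("age must be positive")
    capped = np.minimum(arr, AGE_CAP)
    centered = capped - AGE_CENTER
    if np.isscalar(age) or isinstance(age, numbers.Number):
        return float(capped), float(centered)
    return capped, centered


def operationalize_dementia(clinical_dx, ldi, cutoff):
    """Dementia status: clinical diagnosis where present, else LDI cutoff.

    A present clinical diagnosis (0/1) is returned as-is.  Otherwise, if an
    LDI score is present, dementia = 1 iff LDI is strictly below the cutoff
    (lower LDI indicates greater dementia likelihood).  Missing both -> NaN.
    """
    dx = np.asarray(clinical_dx, dtype=float)
    ldi_a = np.asarray(ldi, dtype=float)
    scalar = dx.ndim == 0
    dx, ldi_a = np.atleast_1d(dx), np.atleast_1d(ldi_a)
    use_ldi = np.isnan(dx) & np.isfinite(ldi_a)
    if use_ldi.any() and not np.isfinite(cutoff):
        raise HarmonizationError("finite LDI cutoff required when LDI is used")
    out = dx.copy()
    out[use_ldi] = (ldi_a[use_ldi] < cutoff).astype(float)
    return float(out[0]) if scalar else out


class CohortHarmonizer:
    """Transformer applying all harmonization rules to a raw cohort table.

    Parameters
    ----------
    ldi_cutoff : float
        Dementia threshold on the LDI scale (study-calibrated; lower LDI side
        is classified as demented).

    ``transform`` conserves row count, adds ``educ3``, ``zyg_dz``,
    ``age_raw``, ``age_capped``, ``age_centered``, ``valid`` and
    ``exclusion_reason`` columns, and is idempotent: derived columns are
    always recomputed from the preserved raw inputs.
    """

    def __init__(self, ldi_cutoff: float = 4.8):
        self.ldi_cutoff = ldi_cutoff

    def get_params(self, deep: bool = True) -> dict:
        return {"ldi_cutoff": self.ldi_cutoff}

    def set_params(self, **params) -> "CohortHarmonizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "CohortHarmonizer":
        # Stateless; present for pipeline compatibility.
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        first_pass = "age_raw" not in df.columns
        if first_pass:
            df["age_raw"] = df["age"].astype(float)
            if "onset_age" in df.columns:
                df["onset_age_raw"] = df["onset_age"].astype(float)

        # dementia: clinical dx where present, LDI cutoff otherwise
        dx_src = "dementia_raw" if "dementia_raw" in df.columns else "dementia"
        if "dementia_raw" not in df.columns:
            df["dementia_raw"] = df["dementia"].astype(float)
        ldi = df["ldi"].astype(float) if "ldi" in df.columns else np.full(len(df), np.nan)
        df["dementia"] = operationalize_dementia(
            df[dx_src].astype(float).to_numpy(), np.asarray(ldi), self.ldi_cutoff
        )

        # registry onset-age correction (applies to registry-ascertained cases)
        age = df["age_raw"].astype(float).to_numpy().copy()
        onset = (
            df["onset_age_raw"].astype(float).to_numpy().copy()
            if "onset_age_raw" in df.columns else np.full(len(df), np.nan)
        )
        if "ascertainment" in df.columns:
            src = df["ascertainment"].astype(object).to_numpy()
            for label, corr in REGISTRY_AGE_CORRECTIONS.items():
                m = (src == label) & (df["dementia"].to_numpy() == 1.0)
                age[m] -= corr
                onset[m] -= corr
        unknown = (
            set(df["ascertainment"].dropna().unique())
            - set(REGISTRY_AGE_CORRECTIONS) - set(NON_REGISTRY_SOURCES)
            if "ascertainment" in df.columns else set()
        )
        if unknown:
            raise HarmonizationError(f"unknown ascertainment sources {sorted(unknown)}")

        finite = np.isfinite(age)
        capped = np.full(len(df), np.nan)
        centered = np.full(len(df), np.nan)
        capped[finite], centered[finite] = cap_and_center_age(age[finite])
        df["age"] = np.where(finite, age, np.nan)
        df["age_capped"] = capped
        df["age_centered"] = centered
        if "onset_age" in df.columns:
            df["onset_age"] = onset

        df["educ3"] = collapse_isced(df["isced9"].astype(float).to_numpy())
        zyg = df["zygosity"].astype(object)
        df["zyg_dz"] = np.where(
            zyg == "DZ", 1.0, np.where(zyg == "MZ", 0.0, np.nan)
        )

        # validity flag mirroring the participant-flowchart exclusions
        reasons = []
        missing = {
            "zygosity": df["zyg_dz"].isna().to_numpy(),
            "isced9": df["isced9"].isna().to_numpy(),
            "dementia": df["dementia"].isna().to_numpy(),
            "age": ~np.isfinite(capped),
        }
        for i in range(len(df)):
            r = [k for k, m in missing.items() if m[i]]
            reasons.append("+".join(r) if r else "")
        df["exclusion_reason"] = reasons
        df["valid"] = (df["exclusion_reason"] == "").astype(int)
        return df


def harmonize(df: pd.DataFrame, ldi_cutoff: float = 4.8) -> pd.DataFrame:
    """Functional wrapper over :class:`CohortHarmonizer`."""
    return CohortHarmonizer(ldi_cutoff=ldi_cutoff).fit(df).transform(df)


def exclusion_report(df: pd.DataFrame) -> pd.DataFrame:
    """Counts of records by exclusion reason (flowchart-style ledger)."""
    if "exclusion_reason" not in df.columns:
        raise HarmonizationError("cohort is not harmonized")
    counts = df["exclusion_reason"].replace("", "none (analytic)").value_counts()
    return counts.rename_axis("reason").reset_index(name="n_records")
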