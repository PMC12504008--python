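"""Education-discrepant pair analysis of within-pair dementia-likelihood differences.

Twin pairs are "discrepant" on educational attainment when the two members do
not share the same 9-category ISCED code.  For every discrepant pair the
within-pair LDI difference is computed as LDI(higher-educated member) minus
LDI(lower-educated member); since lower LDI indicates greater dementia
likelihood, a positive mean difference means the better-educated member looks
less demented.  Differences are summarized per pair type (MZF, MZM, DZF, DZM,
DZOS) with a matched t-test, alongside a comparison set of *unrelated* pairs
built by randomly matching individuals on sex and birth year without
replacement (UNF, UNM).

Under pure familial confounding the expected attenuation ordering is
|unrelated| > |DZ| > |MZ|, with the MZ difference centred at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchedPair",
    "PairedTestResult",
    "MatchingReport",
    "DiscrepancyError",
    "find_discrepant_pairs",
    "match_unrelated",
    "paired_t_test",
    "diff_by_group",
    "plot_diffs",
]

PAIR_TYPE_ORDER = ["UNM", "UNF", "DZOS", "DZM", "DZF", "MZM", "MZF"]


class DiscrepancyError(ValueError):
    pass


@dataclass(frozen=True)
class MatchedPair:
    """One education-discrepant pair, ordered so ``member_hi`` has higher ISCED."""

    member_hi: int            # row index into the source table
    member_lo: int
    pair_type: str            # MZF | MZM | DZF | DZM | DZOS | UNF | UNM
    ldi_diff: float           # LDI(hi) - LDI(lo)
    isced_hi: int
    isced_lo: int


@dataclass(frozen=True)
class PairedTestResult:
    """Matched (one-sample) t-test of within-pair differences."""

    n: int
    mean_diff: float
    se: float
    t_stat: float
    df: int
    p_two_sided: float
    degenerate: bool = False


@dataclass(frozen=True)
class MatchingReport:
    n_matched_pairs: int
    n_discrepant: int
    n_not_discrepant: int
    n_unmatched: int


def _twin_pair_type(zygosity: str, same_sex, female) -> str:
    if zygosity == "DZ" and not same_sex:
        return "DZOS"
    suffix = "F" if female else "M"
    return f"{zygosity}{suffix}"


def find_discrepant_pairs(df: pd.DataFrame) -> list:
    """Identify twin pairs with unequal ISCED9 and both members' LDI known.

    Pairs whose members share the same ISCED category are excluded.  Each
    returned pair is tagged with its twin pair type and carries the
    LDI(higher ISCED) - LDI(lower ISCED) difference.
    """
    need = df.dropna(subset=["isced9", "ldi"])
    need = need[need["zygosity"].isin(["MZ", "DZ"])]
    sizes = need.groupby("pair_id")["pair_id"].transform("size")
    need = need[sizes == 2].sort_values("pair_id", kind="stable")

    idx = need.index.to_numpy()
    isced = need["isced9"].to_numpy(dtype=float).astype(int)
    ldi = need["ldi"].to_numpy(dtype=float)
    zyg = need["zygosity"].to_numpy(dtype=object)
    same_sex = need["same_sex"].to_numpy()
    female = need["female"].to_numpy()

    a, b = np.arange(0, len(need), 2), np.arange(1, len(need), 2)
    discrepant = isced[a] != isced[b]
    out = []
    for i, j in zip(a[discrepant], b[discrepant]):
        hi, lo = (i, j) if isced[i] > isced[j] else (j, i)
        ptype = _twin_pair_type(zyg[hi], bool(same_sex[i]), bool(female[hi]))
        out.append(MatchedPair(
            member_hi=int(idx[hi]), member_lo=int(idx[lo]), pair_type=ptype,
            ldi_diff=float(ldi[hi] - ldi[lo]),
            isced_hi=int(isced[hi]), isced_lo=int(isced[lo]),
        ))
    return out


def match_unrelated(
    df: pd.DataFrame, seed: int, max_attempts: int = 100
) -> tuple:
    """Randomly pair unrelated individuals matched on sex and birth year.

    Every individual with an LDI score enters the pool once; within each
    (sex, birth year) stratum records are shuffled with the seeded RNG and
    paired consecutively, re-shuffling (up to ``max_attempts``) while any
    pairing falls within the same family.  Matched pairs that are not
    education-discrepant, and individuals left unmatched, are excluded from
    the returned list but tallied in the :class:`MatchingReport`.
    """
    rng = np.random.default_rng(seed)
    pool = df.dropna(subset=["ldi", "female", "birth_year"])
    pos = pool.index.to_numpy()
    fam_all = pool["pair_id"].to_numpy()
    isced_all = pool["isced9"].to_numpy(dtype=float)
    ldi_all = pool["ldi"].to_numpy(dtype=float)
    fem_all = pool["female"].to_numpy()
    strata = pd.Series(np.arange(len(pool)), index=pool.index).groupby(
        [pool["female"], pool["birth_year"]], sort=True
    )
    pairs: list = []
    n_unmatched = 0
    n_not_discrepant = 0
    for (_, _), members in strata:
        loc = members.to_numpy()
        if loc.size < 2:
            n_unmatched += loc.size
            continue
        fam = fam_all[loc]
        k = (loc.size // 2) * 2
        perm = rng.permutation(loc.size)
        for _ in range(max_attempts):
            f = fam[perm[:k]]
            if not np.any(f[0::2] == f[1::2]):
                break
            perm = rng.permutation(loc.size)
        n_unmatched += loc.size - k
        sel = loc[perm[:k]]
        a, b = sel[0::2], sel[1::2]
        same_fam = fam_all[a] == fam_all[b]  # possible after max_attempts
        n_unmatched += 2 * int(same_fam.sum())
        a, b = a[~same_fam], b[~same_fam]
        ia, ib = isced_all[a], isced_all[b]
        known = np.isfinite(ia) & np.isfinite(ib)
        disc = known & (ia != ib)
        n_not_discrepant += int((known & ~disc).sum()) + int((~known).sum())
        for i, j in zip(a[disc], b[disc]):
            hi, lo = (i, j) if isced_all[i] > isced_all[j] else (j, i)
            ptype = "UNF" if fem_all[hi] else "UNM"
            pairs.append(MatchedPair(
                member_hi=int(pos[hi]), member_lo=int(pos[lo]), pair_type=ptype,
                ldi_diff=float(ldi_all[hi] - ldi_all[lo]),
                isced_hi=int(max(isced_all[i], isced_all[j])),
                isced_lo=int(min(isced_all[i], isced_all[j])),
            ))
    report = MatchingReport(
        n_matched_pairs=len(pairs) + n_not_discrepant,
        n_discrepant=len(pairs),
        n_not_discrepant=n_not_discrepant,
        n_unmatched=n_unmatched,
    )
    return pairs, report


def paired_t_test(diffs) -> PairedTestResult:
    """Matched t-test: t = mean / (sd / sqrt(n)), two-sided Student-t p-value."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise DiscrepancyError("paired t-test requires at least 2 differences")
    if not np.isfinite(d).all():
        raise DiscrepancyError("differences must be finite")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(n, mean, 0.0, float("nan"), n - 1,
                                float("nan"), degenerate=True)
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(n, mean, float(se), float(t), n - 1, float(p))


def diff_by_group(pairs) -> pd.DataFrame:
    """Per-pair-type matched t-test table of within-pair LDI differences."""
    rows = []
    by_type: dict = {}
    for p in pairs:
        by_type.setdefault(p.pair_type, []).append(p.ldi_diff)
    for ptype in PAIR_TYPE_ORDER:
        if ptype not in by_type:
            continue
        d = np.asarray(by_type[ptype])
        if d.size >= 2:
            r = paired_t_test(d)
        else:
            r = PairedTestResult(d.size, float(d.mean()) if d.size else np.nan,
                                 np.nan, np.nan, max(d.size - 1, 0), np.nan,
                                 degenerate=True)
        rows.append({
            "pair_type": ptype, "n": r.n, "mean_diff": r.mean_diff, "se": r.se,
            "t": r.t_stat, "df": r.df, "p": r.p_two_sided,
            "degenerate": r.degenerate,
        })
    return pd.DataFrame(rows).set_index("pair_type")


def plot_diffs(table: pd.DataFrame, path) -> None:
    """Bar chart of mean within-pair LDI differences with SE bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [t for t in PAIR_TYPE_ORDER if t in table.index]
    t = table.loc[order]
    colors = {"M": "#4878CF", "F": "#F5A26B", "S": "#6ACC65"}
    bar_colors = [colors["S"] if x == "DZOS" else colors[x[-1]] for x in order]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(order, t["mean_diff"], yerr=t["se"], color=bar_colors, capsize=4)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("Mean LDI difference (higher - lower educated)")
    ax.set_xlabel("Pair type")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
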