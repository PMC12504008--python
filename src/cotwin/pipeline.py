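"""End-to-end orchestration: simulate -> harmonize -> discrepancy -> fit -> classify.

Also provides the sample-accounting report (participant-flowchart arithmetic):
total individuals = 2 x complete pairs + singletons, the share of
education-discrepant pairs among pairs with both members' ISCED/LDI/zygosity
known, per-pair-type counts, and exclusion counts by reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


import pandas as pd
import yaml

from . import __version__
from .simulate import scenario, simulate_cohort, write_cohort_csv, read_cohort_csv
from .harmonize import harmonize, exclusion_report
from .discrepancy import find_discrepant_pairs, match_unrelated, diff_by_group
from .glmm import fit_bw_glmm, wald_summary, GLMMFit
from .interpret import (
    classify_confounding, find_discordant_pairs, delayed_onset_variant,
    discordant_frequency_table,
)

__all__ = [
    "RunConfig",
    "AccountingReport",
    "PipelineError",
    "accounting",
    "accounting_identities",
    "run_pipeline",
    "fit_models",
    "write_fits",
    "read_fit",
    "table_report",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run; all randomness flows from ``seed``."""

    scenario: str = "table1_like"
    scale: float = 0.05
    seed: int = 0
    ldi_cutoff: float = 4.8
    models: tuple = (1, 2, 3, 4)
    alpha: float = 0.05
    link: str = "logit"
    n_quad: int = 15
    min_gap: float = 5.0
    truth_columns: bool = False
    stages: tuple = ("simulate", "harmonize", "discrepancy", "fit", "classify",
                     "sensitivity")
    input_csv: str | None = None   # skip simulation, harmonize this table instead

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise PipelineError(f"unknown config key {k!r}")
            if isinstance(getattr(cfg, k), tuple) and isinstance(v, (list, tuple)):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AccountingReport:
    n_individuals: int
    n_complete_pairs: int
    n_singletons: int
    n_pairs_both_known: int
    n_discrepant_pairs: int
    pct_discrepant: float
    pair_type_counts: dict = field(default_factory=dict)
    pair_type_pcts: dict = field(default_factory=dict)
    exclusions_by_reason: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_individuals != 2 * self.n_complete_pairs + self.n_singletons:
            raise PipelineError("accounting identity violated: individuals")
        if self.n_pairs_both_known > 0:
            expect = 100.0 * self.n_discrepant_pairs / self.n_pairs_both_known
            if abs(expect - self.pct_discrepant) > 1e-9:
                raise PipelineError("accounting identity violated: pct_discrepant")

    def to_text(self) -> str:
        lines = [
            f"individuals: {self.n_individuals}",
            f"complete pairs: {self.n_complete_pairs}",
            f"singletons: {self.n_singletons}",
            f"pairs with both members' ISCED/LDI/zygosity known: "
            f"{self.n_pairs_both_known}",
            f"education-discrepant pairs: {self.n_discrepant_pairs} "
            f"({self.pct_discrepant:.1f}%)",
        ]
        for pt, n in self.pair_type_counts.items():
            pct = self.pair_type_pcts.get(pt, float("nan"))
            lines.append(f"pairs {pt}: {n} ({pct:.1f}%)")
        for reason, n in self.exclusions_by_reason.items():
            lines.append(f"excluded [{reason}]: {n}")
        return "\n".join(lines) + "\n"


def accounting_identities(
    n_complete_pairs: int,
    n_singletons: int,
    n_discrepant_pairs: int,
    n_pairs_both_known: int,
) -> dict:
    """Exact arithmetic of the sample-accounting identities.

    ``n_individuals = 2 * pairs + singletons`` and
    ``pct_discrepant = 100 * discrepant / eligible`` (full precision; display
    rounds to one decimal).
    """
    if min(n_complete_pairs, n_singletons, n_discrepant_pairs,
           n_pairs_both_known) < 0:
        raise PipelineError("counts must be non-negative")
    n_individuals = 2 * n_complete_pairs + n_singletons
    pct = (100.0 * n_discrepant_pairs / n_pairs_both_known
           if n_pairs_both_known else 0.0)
    return {
        "n_individuals": n_individuals,
        "pct_discrepant": pct,
        "pct_discrepant_display": round(pct, 1),
    }


def _twin_pair_type(zyg: str, same_sex, female) -> str:
    if zyg == "DZ" and not same_sex:
        return "DZOS"
    return f"{zyg}{'F' if female else 'M'}"


def accounting(df: pd.DataFrame) -> AccountingReport:
    """Sample-accounting report on a (preferably harmonized) cohort table."""
    if df.empty:
        return AccountingReport(0, 0, 0, 0, 0, 0.0)
    sizes = df.groupby("pair_id")["pair_id"].transform("size")
    n_complete_pairs = int((sizes == 2).sum() // 2)
    n_singletons = int((sizes == 1).sum())
    n_individuals = len(df)

    known = df.dropna(subset=["isced9", "ldi"])
    known = known[known["zygosity"].isin(["MZ", "DZ"])]
    ksizes = known.groupby("pair_id")["pair_id"].transform("size")
    both = known[ksizes == 2].sort_values("pair_id", kind="stable")
    n_both = len(both) // 2
    isced = both["isced9"].to_numpy(dtype=float)
    n_disc = int((isced[0::2] != isced[1::2]).sum())
    pct = 100.0 * n_disc / n_both if n_both else 0.0

    pairs = df[sizes == 2].sort_values(["pair_id", "member"], kind="stable")
    first = pairs.iloc[0::2]
    ptypes = [
        _twin_pair_type(z, s, f) if z in ("MZ", "DZ") else "unknown_zygosity"
        for z, s, f in zip(first["zygosity"], first["same_sex"], first["female"])
    ]
    counts = pd.Series(ptypes).value_counts().to_dict()
    pcts = {k: 100.0 * v / n_complete_pairs for k, v in counts.items()}

    exclusions = {}
    if "exclusion_reason" in df.columns:
        vc = df.loc[df["exclusion_reason"] != "", "exclusion_reason"].value_counts()
        exclusions = vc.to_dict()

    report = AccountingReport(
        n_individuals=n_individuals,
        n_complete_pairs=n_complete_pairs,
        n_singletons=n_singletons,
        n_pairs_both_known=n_both,
        n_discrepant_pairs=n_disc,
        pct_discrepant=pct,
        pair_type_counts=counts,
        pair_type_pcts=pcts,
        exclusions_by_reason=exclusions,
    )
    report.validate()
    return report


# ---------------------------------------------------------------------------
# model-fit persistence and reporting
# ---------------------------------------------------------------------------

def fit_models(df: pd.DataFrame, models, link="logit", n_quad=15, alpha=0.05,
               **kwargs) -> dict:
    fits = {}
    for mid in models:
        fits[int(mid)] = fit_bw_glmm(df, model_id=int(mid), link=link,
                                     n_quad=n_quad, alpha=alpha, **kwargs)
    return fits


def write_fits(fits: dict, outdir: Path, alpha: float = 0.05) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    var_rows = []
    for mid, fit in fits.items():
        tab = wald_summary(fit, alpha=alpha).reset_index(names="name")
        tab.to_csv(outdir / f"model{mid}_coefficients.csv", index=False)
        meta = {
            "model_id": fit.model_id, "link": fit.link, "minus2ll": fit.minus2ll,
            "n_obs": fit.n_obs, "n_pairs": fit.n_pairs, "n_quad": fit.n_quad,
            "converged": fit.converged, "grad_norm": fit.grad_norm,
            "separation": fit.separation,
            "var_pair_MZ": fit.var_pair_MZ, "var_pair_MZ_se": fit.var_pair_MZ_se,
            "var_pair_DZ": fit.var_pair_DZ, "var_pair_DZ_se": fit.var_pair_DZ_se,
            "scale_MZ": fit.scale_MZ, "scale_DZ": fit.scale_DZ,
        }
        (outdir / f"model{mid}_meta.json").write_text(json.dumps(meta, indent=1))
        var_rows.append({"model_id": mid, **{k: meta[k] for k in (
            "var_pair_MZ", "var_pair_MZ_se", "var_pair_DZ", "var_pair_DZ_se",
            "scale_MZ", "scale_DZ", "minus2ll")}})
    pd.DataFrame(var_rows).to_csv(outdir / "variance_components.csv", index=False)
    (outdir / "model_table.txt").write_text(table_report(fits))


def read_fit(outdir: Path, model_id: int) -> GLMMFit:
    outdir = Path(outdir)
    tab = pd.read_csv(outdir / f"model{model_id}_coefficients.csv").set_index("name")
    tab.index.name = None
    meta = json.loads((outdir / f"model{model_id}_meta.json").read_text())
    return GLMMFit(
        model_id=meta["model_id"], link=meta["link"],
        coef=tab[["estimate", "se", "z", "p"]],
        var_pair_MZ=meta["var_pair_MZ"], var_pair_MZ_se=meta["var_pair_MZ_se"],
        var_pair_DZ=meta["var_pair_DZ"], var_pair_DZ_se=meta["var_pair_DZ_se"],
        scale_MZ=meta["scale_MZ"], scale_DZ=meta["scale_DZ"],
        minus2ll=meta["minus2ll"], n_obs=meta["n_obs"], n_pairs=meta["n_pairs"],
        converged=meta["converged"], n_quad=meta["n_quad"],
        grad_norm=meta["grad_norm"], separation=meta["separation"],
    )


def table_report(fits: dict) -> str:
    """Side-by-side coefficient table across models (regression-table shape)."""
    names: list = []
    for fit in fits.values():
        for n in fit.coef.index:
            if n not in names:
                names.append(n)
    mids = sorted(fits)
    width = 22
    head = "parameter".ljust(26) + "".join(f"Model {m}".rjust(width) for m in mids)
    lines = [head, "-" * len(head)]
    for n in names:
        cells = []
        for m in mids:
            fit = fits[m]
            if n in fit.coef.index:
                est, se, p = fit.coefficient(n)
                star = "*" if p < 0.05 else ""
                cells.append(f"{est:.2f}({se:.2f}){star}".rjust(width))
            else:
                cells.append("".rjust(width))
        lines.append(n.ljust(26) + "".join(cells))
    lines.append("-" * len(head))
    for label, attr in (("MZ pair variance", "var_pair_MZ"),
                        ("DZ pair variance", "var_pair_DZ"),
                        ("MZ dispersion", "scale_MZ"),
                        ("DZ dispersion", "scale_DZ"),
                        ("-2 log likelihood", "minus2ll")):
        row = label.ljust(26)
        for m in mids:
            row += f"{getattr(fits[m], attr):.2f}".rjust(width)
        lines.append(row)
    lines.append("* p < 0.05 (two-sided Wald)")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Run the requested stages, writing all artifacts under ``outdir``.

    Deterministic: identical config (including seed) reproduces identical
    outputs.  A provenance log records the package version, seed and config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(cfg.stages)
    log: list = [
        f"cotwin {__version__}",
        f"seed: {cfg.seed}",
        f"config_hash: {cfg.config_hash()}",
        f"config: {json.dumps(asdict(cfg), sort_keys=True, default=str)}",
    ]

    def fail(stage, exc):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    cohort = None
    if "simulate" in stages and cfg.input_csv is None:
        try:
            ace, sim_cfg = scenario(cfg.scenario, scale=cfg.scale,
                                    seed=_stage_seed(cfg.seed, "simulate"))
            cohort = simulate_cohort(sim_cfg, ace)
            write_cohort_csv(cohort, outdir / "cohort.csv", truth=cfg.truth_columns)
            log.append(f"simulate: {len(cohort)} records "
                       f"({cohort['pair_id'].nunique()} pair ids)")
        except Exception as exc:
            fail("simulate", exc)
    elif cfg.input_csv is not None:
        cohort = read_cohort_csv(cfg.input_csv)
        log.append(f"input: {cfg.input_csv} ({len(cohort)} records)")

    harmonized = None
    if "harmonize" in stages and cohort is not None:
        try:
            harmonized = harmonize(cohort, ldi_cutoff=cfg.ldi_cutoff)
            write_cohort_csv(harmonized, outdir / "harmonized.csv",
                             truth=cfg.truth_columns)
            exclusion_report(harmonized).to_csv(
                outdir / "exclusions.csv", index=False)
            rep = accounting(harmonized)
            (outdir / "accounting.txt").write_text(
                f"# seed {cfg.seed} config {cfg.config_hash()}\n" + rep.to_text())
            log.append(f"harmonize: {int(harmonized['valid'].sum())} analytic records")
        except Exception as exc:
            fail("harmonize", exc)

    analysis = harmonized if harmonized is not None else cohort
    if "discrepancy" in stages and analysis is not None:
        try:
            twin_pairs = find_discrepant_pairs(analysis)
            un_pairs, match_rep = match_unrelated(
                analysis, seed=_stage_seed(cfg.seed, "match"))
            table = diff_by_group(twin_pairs + un_pairs)
            table.to_csv(outdir / "discrepancy.csv")
            (outdir / "matching_report.txt").write_text(
                f"matched pairs: {match_rep.n_matched_pairs}\n"
                f"discrepant unrelated pairs: {match_rep.n_discrepant}\n"
                f"not discrepant (excluded): {match_rep.n_not_discrepant}\n"
                f"unmatched individuals: {match_rep.n_unmatched}\n")
            log.append(f"discrepancy: {len(twin_pairs)} twin pairs, "
                       f"{len(un_pairs)} unrelated pairs")
        except Exception as exc:
            fail("discrepancy", exc)

    fits = None
    if "fit" in stages and analysis is not None:
        try:
            fits = fit_models(analysis, cfg.models, link=cfg.link,
                              n_quad=cfg.n_quad, alpha=cfg.alpha)
            write_fits(fits, outdir / "fits", alpha=cfg.alpha)
            log.append("fit: models " + ",".join(str(m) for m in sorted(fits)))
        except Exception as exc:
            fail("fit", exc)

    if "classify" in stages and fits is not None and 2 in fits:
        try:
            verdict = classify_confounding(fits[2], fits.get(3), alpha=cfg.alpha)
            payload = {"verdict": verdict.verdict, "alpha": verdict.alpha,
                       "evidence": verdict.evidence, "seed": cfg.seed,
                       "config_hash": cfg.config_hash()}
            (outdir / "verdict.json").write_text(json.dumps(payload, indent=1))
            log.append(f"classify: {verdict.verdict}")
        except Exception as exc:
            fail("classify", exc)

    if "sensitivity" in stages and analysis is not None:
        try:
            records = find_discordant_pairs(analysis)
            discordant_frequency_table(records).to_csv(
                outdir / "discordant_pairs.csv", index=False)
            variant, p_var = delayed_onset_variant(analysis, min_gap=cfg.min_gap)
            discordant_frequency_table(variant).to_csv(
                outdir / "discordant_pairs_delayed.csv", index=False)
            log.append(f"sensitivity: {len(records)} discordant pairs "
                       f"(delayed-onset variant p = {p_var:.4g})")
        except Exception as exc:
            fail("sensitivity", exc)

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return outdir
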