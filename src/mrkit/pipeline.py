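"""Full-study orchestration: many exposures against one or more outcomes.

For every exposure the pipeline selects genome-wide-significant,
LD-independent instruments, substitutes proxies for instruments the outcome
study lacks, harmonizes effect alleles, runs the configured estimators
(IVW as the primary analysis; MR-Egger with its pleiotropy-intercept test,
simple and weighted medians as sensitivity analyses), computes
leave-one-out and instrument-strength diagnostics, and classifies each
exposure-outcome association as significant / suggestive / null against a
Bonferroni-corrected family threshold. Exposures significant on the
primary outcome are re-run against each secondary outcome with the same
instrument set, and — when a cross-trait table is supplied — re-run after
excluding multi-trait variants. When at least two exposures are
significant, a multivariable MR jointly estimates their direct effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diagnostics as diag
from .estimators import MRResult, egger, ivw, median_estimator, mvmr
from .ld import read_ld_long
from .select import (
    CrossTraitTable,
    SelectionParams,
    clump_audit,
    filter_significant,
    find_proxy,
    ld_clump,
    remove_cross_trait,
)
from .sumstats import HarmonizedInstrumentSet, harmonize, read_sumstats

__all__ = [
    "StudyConfig",
    "AssociationCall",
    "bonferroni_threshold",
    "classify",
    "run_study",
]

log = logging.getLogger("mrkit")

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NULL = "null"

_FLOAT_FMT = "%.10g"


@dataclass
class TraitSource:
    name: str
    path: str
    trait_type: str


@dataclass
class StudyConfig:
    """Everything needed to run a multi-exposure MR study."""

    exposures: list[TraitSource]
    outcomes: list[TraitSource]  # first entry is the primary (pooled) outcome
    panel: str
    selection: SelectionParams = field(default_factory=SelectionParams)
    alpha_family: float = 0.05
    methods: tuple[str, ...] = ("ivw", "egger", "simple_median", "weighted_median")
    cross_trait: str | None = None
    palindromic_maf_limit: float = 0.42
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    run_mvmr: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("study needs at least one exposure and one outcome")
        if not (0 < self.alpha_family < 1):
            raise ValueError("alpha_family must lie in (0, 1)")

    @staticmethod
    def from_yaml(path) -> "StudyConfig":
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh)
        sel = raw.get("selection", {})
        return StudyConfig(
            exposures=[TraitSource(**e) for e in raw["exposures"]],
            outcomes=[TraitSource(**o) for o in raw["outcomes"]],
            panel=raw["panel"],
            selection=SelectionParams(
                p_threshold=float(sel.get("p_threshold", 5e-8)),
                clump_r2=float(sel.get("clump_r2", 0.01)),
                proxy_r2_min=float(sel.get("proxy_r2_min", 0.9)),
            ),
            alpha_family=float(raw.get("alpha_family", 0.05)),
            methods=tuple(raw.get("methods", ("ivw", "egger", "simple_median", "weighted_median"))),
            cross_trait=raw.get("cross_trait"),
            palindromic_maf_limit=float(raw.get("palindromic_maf_limit", 0.42)),
            ivw_model=raw.get("ivw_model", "multiplicative_random"),
            n_boot=int(raw.get("n_boot", 1000)),
            run_mvmr=bool(raw.get("run_mvmr", True)),
            seed=int(raw.get("seed", 0)),
        )

    @staticmethod
    def from_manifest(manifest: dict, **overrides) -> "StudyConfig":
        """Build a config from a make_study_fixture manifest."""
        cfg = StudyConfig(
            exposures=[
                TraitSource(e["name"], e["path"], e["trait_type"])
                for e in manifest["exposures"]
            ],
            outcomes=[
                TraitSource(
                    manifest["outcome"]["name"],
                    manifest["outcome"]["path"],
                    manifest["outcome"]["trait_type"],
                )
            ],
            panel=manifest["panel"],
            cross_trait=manifest.get("cross_trait"),
            seed=manifest.get("seed", 0),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass(frozen=True)
class AssociationCall:
    """Verdict for one exposure-outcome pair based on the primary (IVW) p."""

    exposure: str
    outcome: str
    primary: MRResult
    verdict: str
    bonferroni_p: float
    alpha: float


def bonferroni_threshold(alpha_family: float, n_exposures: int) -> float:
    """Family-wise threshold alpha / number of exposures tested."""
    if n_exposures < 1:
        raise ValueError("n_exposures must be >= 1")
    return alpha_family / n_exposures


def classify(p: float, bonferroni_p: float, alpha: float = 0.05) -> str:
    """significant (p < bonferroni), suggestive (bonferroni <= p < alpha), null."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if p < bonferroni_p:
        return SIGNIFICANT
    if p < alpha:
        return SUGGESTIVE
    return NULL


def _result_row(exposure, outcome, analysis, method, res: MRResult, verdict="", extra=None):
    row = {
        "exposure": exposure,
        "outcome": outcome,
        "analysis": analysis,
        "method": method,
        "n_snps": res.n_snps,
        "estimate": res.estimate,
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pvalue": res.pvalue,
        "or": res.odds_ratio,
        "or_ci_low": res.or_ci_low,
        "or_ci_high": res.or_ci_high,
        "verdict": verdict,
    }
    if extra:
        row.update(extra)
    return row


def _fmt(value) -> str:
    if value is None or value == "":
        return "NA" if value is None else ""
    if isinstance(value, float):
        return _FLOAT_FMT % value
    return str(value)


_MASTER_COLUMNS = [
    "exposure", "outcome", "analysis", "method", "n_snps", "estimate", "se",
    "ci_low", "ci_high", "pvalue", "or", "or_ci_low", "or_ci_high", "verdict",
]


def _write_tsv(rows: list[dict], columns: list[str], path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c, "")) for c in columns) + "\n")


def _analyse_pair(
    hset: HarmonizedInstrumentSet,
    config: StudyConfig,
    seed: int,
    exposure: str,
    outcome: str,
    analysis: str,
    bonf_p: float,
    rows: list[dict],
) -> MRResult:
    """Run every configured estimator on one harmonized pair; returns the IVW."""
    primary = ivw(hset, model=config.ivw_model)
    verdict = classify(primary.pvalue, bonf_p, config.alpha_family)
    rows.append(_result_row(exposure, outcome, analysis, primary.method, primary, verdict))
    if "egger" in config.methods and hset.n_snps >= 3:
        eg = egger(hset)
        rows.append(_result_row(exposure, outcome, analysis, "egger", eg.slope))
        rows.append(
            {
                "exposure": exposure, "outcome": outcome, "analysis": analysis,
                "method": "egger_intercept", "n_snps": hset.n_snps,
                "estimate": eg.intercept, "se": eg.intercept_se,
                "ci_low": eg.intercept - 1.96 * eg.intercept_se,
                "ci_high": eg.intercept + 1.96 * eg.intercept_se,
                "pvalue": eg.intercept_pvalue,
                "or": None, "or_ci_low": None, "or_ci_high": None, "verdict": "",
            }
        )
    if hset.n_snps >= 3:
        if "simple_median" in config.methods:
            res = median_estimator(hset, "simple", n_boot=config.n_boot, seed=seed)
            rows.append(_result_row(exposure, outcome, analysis, res.method, res))
        if "weighted_median" in config.methods:
            res = median_estimator(hset, "inverse_variance", n_boot=config.n_boot, seed=seed + 1)
            rows.append(_result_row(exposure, outcome, analysis, res.method, res))
    return primary


def run_study(config: StudyConfig, out_dir) -> dict:
    """Execute the full study; write the master TSV and per-exposure audits.

    Returns a report dict with the association calls, per-exposure stage
    counts, and paths of everything written. Fully reproducible for a given
    config and seed. Exposures whose instruments all fail selection or
    harmonization are recorded as ``no_instruments`` and the run continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    audit_dir = out_dir / "audit"
    audit_dir.mkdir(exist_ok=True)

    panel = read_ld_long(config.panel)
    outcome_tables = {
        o.name: read_sumstats(o.path, o.name, o.trait_type) for o in config.outcomes
    }
    primary_outcome = config.outcomes[0]
    xtab = CrossTraitTable.from_tsv(config.cross_trait) if config.cross_trait else None

    bonf_p = bonferroni_threshold(config.alpha_family, len(config.exposures))
    rows: list[dict] = []
    calls: list[AssociationCall] = []
    counts: dict[str, dict] = {}
    instruments_by_exposure: dict[str, list[str]] = {}
    exposure_tables = {}
    significant: list[str] = []

    for idx, exp_src in enumerate(config.exposures):
        seed_e = int(config.seed * 100003 + idx * 101) % (2**31 - 1)
        exp_table = read_sumstats(exp_src.path, exp_src.name, exp_src.trait_type)
        exposure_tables[exp_src.name] = exp_table
        exp_audit = audit_dir / exp_src.name
        exp_audit.mkdir(exist_ok=True)

        sig_ids = filter_significant(exp_table, config.selection.p_threshold)
        in_panel = [s for s in sig_ids if s in panel]
        pvals = {r.variant_id: r.pvalue for r in exp_table.records}
        clumped = ld_clump({s: pvals[s] for s in in_panel}, panel, config.selection.clump_r2)

        # Selection audit: kept / clumped_by / below_threshold / not_in_panel.
        status = clump_audit({s: pvals[s] for s in in_panel}, panel, config.selection.clump_r2)
        audit_rows = []
        for r in exp_table.records:
            vid = r.variant_id
            if vid not in set(sig_ids):
                st = "below_threshold"
            elif vid not in panel:
                st = "not_in_panel"
            else:
                st = status.get(vid, "below_threshold")
            audit_rows.append({"variant_id": vid, "status": st})
        _write_tsv(audit_rows, ["variant_id", "status"], exp_audit / "selection.tsv")

        # Proxy substitution for instruments missing from the primary outcome.
        outcome_ids = set(outcome_tables[primary_outcome.name].ids())
        exposure_ids = set(exp_table.ids())
        instruments: list[str] = []
        n_proxied = 0
        for vid in clumped:
            if vid in outcome_ids:
                instruments.append(vid)
                continue
            proxy = find_proxy(
                vid, sorted(outcome_ids & exposure_ids), panel, config.selection.proxy_r2_min
            )
            if proxy is not None and proxy not in instruments:
                instruments.append(proxy)
                n_proxied += 1
            else:
                instruments.append(vid)  # harmonization records the drop

        hset = harmonize(
            exp_table,
            outcome_tables[primary_outcome.name],
            instruments,
            config.palindromic_maf_limit,
        )
        hset.audit_frame().to_csv(exp_audit / "harmonization.tsv", sep="\t", index=False)
        counts[exp_src.name] = {
            "significant": len(sig_ids),
            "clumped": len(clumped),
            "proxied": n_proxied,
            "harmonized": hset.n_snps,
            "dropped": len(hset.dropped),
        }
        log.info(
            "%s: %d significant, %d post-clump, %d proxied, %d harmonized, %d dropped",
            exp_src.name, len(sig_ids), len(clumped), n_proxied, hset.n_snps,
            len(hset.dropped),
        )

        if hset.n_snps == 0:
            rows.append(
                {
                    "exposure": exp_src.name, "outcome": primary_outcome.name,
                    "analysis": "primary", "method": "no_instruments", "n_snps": 0,
                    "estimate": None, "se": None, "ci_low": None, "ci_high": None,
                    "pvalue": None, "or": None, "or_ci_low": None, "or_ci_high": None,
                    "verdict": "no_instruments",
                }
            )
            continue
        instruments_by_exposure[exp_src.name] = [v.variant_id for v in hset.variants]

        primary = _analyse_pair(
            hset, config, seed_e, exp_src.name, primary_outcome.name, "primary", bonf_p, rows
        )
        verdict = classify(primary.pvalue, bonf_p, config.alpha_family)
        calls.append(
            AssociationCall(exp_src.name, primary_outcome.name, primary, verdict,
                            bonf_p, config.alpha_family)
        )
        if verdict == SIGNIFICANT:
            significant.append(exp_src.name)

        if hset.n_snps >= 2:
            loo = diag.leave_one_out(hset, threshold=config.alpha_family, ivw_model=config.ivw_model)
            loo_rows = [
                {
                    "excluded_id": vid, "estimate": r.estimate, "se": r.se,
                    "pvalue": r.pvalue, "flag": "driven_by" if vid in loo.flagged else "",
                }
                for vid, r in loo.results
            ]
            _write_tsv(loo_rows, ["excluded_id", "estimate", "se", "pvalue", "flag"],
                       exp_audit / "leave_one_out.tsv")

        d = diag.instrument_diagnostics(hset, exposure_table=exp_table)
        _write_tsv(
            [{"exposure": exp_src.name, "n": d.n, "k": d.k, "r2_total": d.r2_total,
              "f_stat": d.f_stat}],
            ["exposure", "n", "k", "r2_total", "f_stat"],
            exp_audit / "diagnostics.tsv",
        )

        # Cross-trait sensitivity: rerun without multi-trait variants.
        if xtab is not None:
            kept = remove_cross_trait(instruments_by_exposure[exp_src.name], xtab)
            if 0 < len(kept) < hset.n_snps:
                sub = harmonize(exp_table, outcome_tables[primary_outcome.name], kept,
                                config.palindromic_maf_limit)
                if sub.n_snps > 0:
                    _analyse_pair(sub, config, seed_e + 7, exp_src.name,
                                  primary_outcome.name, "cross_trait_sensitivity",
                                  bonf_p, rows)

    # Significant exposures re-examined on each secondary outcome with the
    # instrument set selected against the primary outcome.
    for exp_name in significant:
        exp_table = exposure_tables[exp_name]
        for out_src in config.outcomes[1:]:
            sub = harmonize(
                exp_table, outcome_tables[out_src.name],
                instruments_by_exposure[exp_name], config.palindromic_maf_limit,
            )
            if sub.n_snps == 0:
                continue
            _analyse_pair(sub, config, config.seed + 13, exp_name, out_src.name,
                          "sub_outcome", bonf_p, rows)

    # Multivariable MR over the significant exposures (union of instruments,
    # restricted to SNPs with effects available for every exposure and the
    # outcome under one allele convention).
    if config.run_mvmr and len(significant) >= 2:
        mv_rows = _run_mvmr(significant, exposure_tables, outcome_tables[primary_outcome.name],
                            instruments_by_exposure, config)
        rows.extend(mv_rows)

    master_path = out_dir / "master_results.tsv"
    _write_tsv(rows, _MASTER_COLUMNS, master_path)

    return {
        "master_tsv": str(master_path),
        "audit_dir": str(audit_dir),
        "bonferroni_p": bonf_p,
        "calls": calls,
        "counts": counts,
        "significant": significant,
        "rows": rows,
    }


def _run_mvmr(significant, exposure_tables, outcome_table, instruments_by_exposure, config):
    from .sumstats import SummaryStatsTable

    union: list[str] = []
    for name in significant:
        for vid in instruments_by_exposure[name]:
            if vid not in union:
                union.append(vid)

    def _aligned(ref_rec, table):
        """Beta/se of ``table``'s record for ref_rec's variant, expressed on
        ref_rec's effect allele; None when absent or unresolvable."""
        anchor = SummaryStatsTable("anchor", "continuous", [ref_rec])
        h = harmonize(anchor, table, [ref_rec.variant_id], config.palindromic_maf_limit)
        if h.n_snps == 0:
            return None
        v = h.variants[0]
        return v.beta_outcome, v.se_outcome

    usable, X_rows, y, sy = [], [], [], []
    for vid in union:
        ref = exposure_tables[significant[0]].get(vid)
        if ref is None or outcome_table.get(vid) is None:
            continue
        exp_betas = [ref.beta]
        ok = True
        for name in significant[1:]:
            a = _aligned(ref, exposure_tables[name])
            if a is None:
                ok = False
                break
            exp_betas.append(a[0])
        out_aligned = _aligned(ref, outcome_table)
        if not ok or out_aligned is None:
            continue
        usable.append(vid)
        X_rows.append(exp_betas)
        y.append(out_aligned[0])
        sy.append(out_aligned[1])
    K = len(significant)
    if len(usable) <= K:
        log.info("MVMR skipped: %d usable SNPs for %d exposures", len(usable), K)
        return []
    results = mvmr(np.array(X_rows), np.array(y), np.array(sy),
                   exposure_names=list(significant),
                   binary_outcome=outcome_table.trait_type == "binary")
    return [
        _result_row(name, outcome_table.trait_name, "mvmr", "mvmr", res)
        for name, res in results
    ]
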