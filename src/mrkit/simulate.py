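"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works entirely at the summary level. For SNP j with minor
allele frequency f_j:

* true exposure effect  gamma_j ~ Normal(0, gamma_sd^2);
* direct (pleiotropic) outcome effect alpha_j, zero for valid instruments
  and sign(gamma_j) * Normal(mu_alpha, sigma_alpha^2) for the invalid
  fraction — directional pleiotropy (mu_alpha != 0) acts along the
  exposure-increasing allele, the standard InSIDE setup; balanced
  pleiotropy (mu_alpha = 0) is unchanged by the sign factor;
* true outcome effect   Gamma_j = beta * gamma_j + alpha_j, where beta is
  the causal effect of the exposure on the outcome (log odds ratio per SD
  of exposure for a binary outcome);
* observed effects are the truths plus independent Gaussian estimation
  noise with the standard-GWAS standard errors on the standardized-genotype
  scale, se_x = 1/sqrt(2 n_x f(1-f)) for the exposure and
  se_y = 1/sqrt(2 n_y f(1-f)) (continuous outcome) or
  se_y = 1/sqrt(2 n_y f(1-f) phi(1-phi)) (binary outcome with case
  fraction phi).

Exposure and outcome noise are independent, matching a two-sample design
with non-overlapping samples. No significance selection happens at
generation time — winner's curse enters only through downstream instrument
selection, so its bias can be measured.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .ld import LDPanel, write_ld_long
from .sumstats import SummaryStatsTable, VariantAssociation, write_sumstats

__all__ = [
    "SimulationConfig",
    "simulate_ld_panel",
    "simulate_two_sample",
    "simulate_replicates",
    "simulate_mvmr_data",
    "make_study_fixture",
    "exposure_se",
    "outcome_se",
]

# Non-palindromic ordered allele pairs; palindromic pairs (A/T, G/C) are
# appended so that roughly 1/3 of simulated variants are strand-ambiguous.
_ALLELE_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
]


@dataclass
class SimulationConfig:
    """Ground-truth description of one simulated exposure/outcome pair."""

    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.45)
    # Strong-instrument regime by default (per-SNP F of several hundred at
    # n_exposure = 1e5), emulating the post-selection instruments that MR
    # estimators actually consume; the generator itself never selects.
    gamma_sd: float = 0.15
    beta_causal: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    outcome_type: str = "continuous"  # continuous | binary
    case_fraction: float = 0.5
    ld_blocks: list[tuple[int, float]] | None = None
    n_ref: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "none":
            if self.pleiotropy_sd != 0 or self.pleiotropy_mean != 0:
                raise ValueError("pleiotropy none requires mu_alpha = sigma_alpha = 0")
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0:
            raise ValueError("balanced pleiotropy requires mu_alpha = 0")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError("outcome_type must be continuous|binary")
        if self.outcome_type == "binary" and not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1) for a binary outcome")

    @property
    def n_invalid(self) -> int:
        raw = self.invalid_fraction * self.n_snps
        k = int(round(raw))
        if abs(raw - k) > 1e-9:
            warnings.warn(
                f"invalid_fraction*n_snps = {raw} is not integral; rounding to {k}",
                stacklevel=2,
            )
        return k


def exposure_se(maf: np.ndarray, n: int) -> np.ndarray:
    """Per-allele SE for a continuous trait on the standardized scale."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def outcome_se(maf: np.ndarray, n: int, outcome_type: str, case_fraction: float) -> np.ndarray:
    """Per-allele SE; binary traits scale by 1/sqrt(phi(1-phi)) on log odds."""
    se = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
    if outcome_type == "binary":
        se = se / math.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def simulate_replicates(config: SimulationConfig, n_replicates: int, rng=None):
    """Vectorized draws of (gamma_hat, se_x, Gamma_hat, se_y) plus truth.

    Returns a dict of (n_replicates, n_snps) arrays; the workhorse behind
    both the table generator and the Monte-Carlo calibration studies.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    R, J = n_replicates, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=(R, J))
    gamma = rng.normal(0.0, config.gamma_sd, size=(R, J))
    alpha = np.zeros((R, J))
    k = config.n_invalid
    if k > 0 and config.pleiotropy_mode != "none":
        # Direct effects are stated relative to the exposure-increasing
        # allele, so a nonzero mean pushes every invalid instrument's
        # outcome effect in one direction.
        raw = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=(R, k))
        alpha[:, :k] = np.where(gamma[:, :k] >= 0, raw, -raw)
    Gamma = config.beta_causal * gamma + alpha
    se_x = exposure_se(maf, config.n_exposure)
    se_y = outcome_se(maf, config.n_outcome, config.outcome_type, config.case_fraction)
    gamma_hat = rng.normal(gamma, se_x)
    Gamma_hat = rng.normal(Gamma, se_y)
    return {
        "maf": maf,
        "gamma": gamma,
        "alpha": alpha,
        "Gamma": Gamma,
        "gamma_hat": gamma_hat,
        "se_x": se_x,
        "Gamma_hat": Gamma_hat,
        "se_y": se_y,
        "beta": config.beta_causal,
    }


def simulate_ld_panel(
    config: SimulationConfig,
    rng=None,
    ids: list[str] | None = None,
    mafs: np.ndarray | None = None,
) -> LDPanel:
    """Simulate a reference genotype panel and its empirical LD structure.

    Haplotypes within a block come from a latent Gaussian with AR(1)
    correlation rho^|i-j|, thresholded at each variant's minor-allele
    frequency; dosages are the sum of two independent haplotypes, so every
    variant is in Hardy-Weinberg equilibrium. r2 is the squared empirical
    dosage correlation; blocks are independent so cross-block r2 is exactly
    zero in the panel.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    blocks_spec = config.ld_blocks or [(1, 0.0)] * config.n_snps
    total = sum(size for size, _rho in blocks_spec)
    if total != config.n_snps:
        raise ValueError(f"ld_blocks sizes sum to {total}, expected n_snps={config.n_snps}")
    for _size, rho in blocks_spec:
        if not (0 <= rho < 1):
            raise ValueError("each block rho must lie in [0, 1)")

    if ids is None:
        ids = [f"rs{j + 1:06d}" for j in range(config.n_snps)]
    if mafs is None:
        # Variants in tight LD share their frequency (one draw per block):
        # mismatched thresholds would otherwise attenuate the dosage
        # correlation well below the latent rho.
        mafs = np.empty(config.n_snps)
        start = 0
        for size, rho in blocks_spec:
            block_maf = rng.uniform(config.maf_range[0], config.maf_range[1])
            if rho == 0:
                mafs[start : start + size] = rng.uniform(
                    config.maf_range[0], config.maf_range[1], size=size
                )
                mafs[start] = block_maf
            else:
                mafs[start : start + size] = block_maf
            start += size

    blocks = []
    start = 0
    for size, rho in blocks_spec:
        block_ids = ids[start : start + size]
        block_maf = np.asarray(mafs[start : start + size])
        dosage = _ar1_dosages(rng, config.n_ref, size, rho, block_maf)
        if size == 1:
            r = np.ones((1, 1))
        else:
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(dosage, rowvar=False)
            r = np.nan_to_num(r, nan=0.0)
            np.fill_diagonal(r, 1.0)
        r2 = np.clip(r**2, 0.0, 1.0)
        blocks.append((list(block_ids), r2, r))
        start += size
    return LDPanel(blocks=blocks)


def _ar1_dosages(rng, n_ref: int, size: int, rho: float, maf: np.ndarray) -> np.ndarray:
    """Two thresholded AR(1)-Gaussian haplotypes summed to {0,1,2} dosages."""
    thresh = stats.norm.ppf(1.0 - maf)  # P(z > thresh) = maf
    dosage = np.zeros((n_ref, size))
    for _hap in range(2):
        z = np.empty((n_ref, size))
        z[:, 0] = rng.standard_normal(n_ref)
        for j in range(1, size):
            z[:, j] = rho * z[:, j - 1] + math.sqrt(1 - rho**2) * rng.standard_normal(n_ref)
        dosage += (z > thresh[None, :]).astype(float)
    return dosage


def simulate_two_sample(config: SimulationConfig, rng=None, id_prefix: str = "rs"):
    """Generate one (exposure, outcome) pair of summary tables plus the truth.

    The outcome table re-expresses a random subset of variants with swapped
    allele labels and/or the complementary strand (betas and frequencies
    adjusted accordingly), so harmonization is exercised end to end while
    the underlying effects stay fixed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    J = config.n_snps
    draw = simulate_replicates(config, 1, rng=rng)
    maf = draw["maf"][0]
    gamma_hat, se_x = draw["gamma_hat"][0], draw["se_x"][0]
    Gamma_hat, se_y = draw["Gamma_hat"][0], draw["se_y"][0]

    ids = [f"{id_prefix}{j + 1:06d}" for j in range(J)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=J)
    p_exp = 2.0 * stats.norm.sf(np.abs(gamma_hat / se_x))
    p_out = 2.0 * stats.norm.sf(np.abs(Gamma_hat / se_y))
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    exp_records, out_records = [], []
    representation = rng.integers(0, 4, size=J)  # 0 same, 1 swap, 2 strand, 3 both
    for j in range(J):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        exp_records.append(
            VariantAssociation(
                variant_id=ids[j], chrom="1", pos=1000 * (j + 1),
                effect_allele=ea, other_allele=oa, eaf=float(maf[j]),
                beta=float(gamma_hat[j]), se=float(se_x[j]),
                pvalue=float(max(p_exp[j], 5e-324)), n=config.n_exposure,
            )
        )
        rep = representation[j]
        b, f = float(Gamma_hat[j]), float(maf[j])
        ea_o, oa_o = ea, oa
        if rep in (1, 3):  # swapped allele labels
            ea_o, oa_o = oa_o, ea_o
            b, f = -b, 1.0 - f
        if rep in (2, 3):  # reported on the complementary strand
            ea_o, oa_o = comp[ea_o], comp[oa_o]
        out_records.append(
            VariantAssociation(
                variant_id=ids[j], chrom="1", pos=1000 * (j + 1),
                effect_allele=ea_o, other_allele=oa_o, eaf=f,
                beta=b, se=float(se_y[j]),
                pvalue=float(max(p_out[j], 5e-324)), n=config.n_outcome,
            )
        )

    exposure = SummaryStatsTable("exposure", "continuous", exp_records)
    outcome = SummaryStatsTable("outcome", config.outcome_type, out_records)
    truth = {
        "beta": config.beta_causal,
        "ids": ids,
        "gamma": draw["gamma"][0].tolist(),
        "alpha": draw["alpha"][0].tolist(),
        "maf": maf.tolist(),
    }
    return exposure, outcome, truth


def simulate_mvmr_data(
    n_snps: int,
    betas: list[float],
    gamma_sd: float = 0.05,
    maf_range: tuple[float, float] = (0.05, 0.45),
    n_exposure: int = 100_000,
    n_outcome: int = 100_000,
    outcome_type: str = "continuous",
    case_fraction: float = 0.5,
    seed: int = 0,
):
    """Shared-instrument data for multivariable MR with known direct effects.

    Each of J SNPs carries an independent true effect on each of the K
    exposures (Normal(0, gamma_sd^2)); the outcome effect is the linear
    combination Gamma_j = sum_k beta_k gamma_jk plus estimation noise.
    Returns observed (J, K) exposure effects, outcome effects and SEs plus
    the truth.
    """
    rng = np.random.default_rng(seed)
    K = len(betas)
    maf = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    gamma = rng.normal(0.0, gamma_sd, size=(n_snps, K))
    Gamma = gamma @ np.asarray(betas)
    se_x = exposure_se(maf, n_exposure)
    se_y = outcome_se(maf, n_outcome, outcome_type, case_fraction)
    gamma_hat = rng.normal(gamma, se_x[:, None])
    Gamma_hat = rng.normal(Gamma, se_y)
    return {
        "gamma_hat": gamma_hat,
        "se_x": se_x,
        "Gamma_hat": Gamma_hat,
        "se_y": se_y,
        "gamma": gamma,
        "betas": list(betas),
        "maf": maf,
    }


# ---------------------------------------------------------------------------
# Multi-exposure study fixture
# ---------------------------------------------------------------------------

# True causal effects cycle through this pattern so a study fixture always
# mixes positive, negative and null exposures.
_BETA_PATTERN = [0.25, 0.0, -0.25, 0.0, 0.35, 0.0, -0.15, 0.15, 0.0, 0.0]

#: LD layout per exposure: tight pairs (proxy sources) then independent SNPs.
#: Latent rho = 0.999 yields empirical dosage r2 around 0.93, comfortably
#: above the 0.9 proxy threshold.
_FIXTURE_BLOCKS = [(2, 0.999)] * 10 + [(1, 0.0)] * 25
_FIXTURE_J = sum(s for s, _ in _FIXTURE_BLOCKS)


def make_study_fixture(
    n_exposures: int,
    seed: int,
    out_dir,
    n_exposure_samples: int = 100_000,
    n_outcome_cases: int = 10_754,
    n_outcome_controls: int = 306_882,
) -> dict:
    """Write a complete synthetic study to disk and return its manifest.

    Emulates a many-exposure MR study against one shared binary outcome:
    each exposure gets its own LD-blocked SNP set and summary table; the
    outcome table stacks all exposures' outcome-side rows (sample sizes
    default to a 10,754-case / 306,882-control disease GWAS); a small number
    of instrument SNPs are withheld from the outcome table so the pipeline
    must fall back to LD proxies; a cross-trait table marks a few SNPs as
    associated with two exposures.

    Returns a manifest dict with all paths, the per-exposure true causal
    effects, and the study-level sample sizes; a JSON copy is written next
    to the tables. Byte-identical across runs with the same arguments.
    """
    if n_exposures < 1:
        raise ValueError("n_exposures must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_outcome = n_outcome_cases + n_outcome_controls
    phi = n_outcome_cases / n_outcome
    exposures = []
    outcome_records = []
    panel_blocks = []
    truth = {}
    withheld: dict[str, list[str]] = {}
    xtab_rows = []

    for e in range(n_exposures):
        name = f"exposure_{e + 1:02d}"
        beta = _BETA_PATTERN[e % len(_BETA_PATTERN)]
        cfg = SimulationConfig(
            n_snps=_FIXTURE_J,
            maf_range=(0.05, 0.40),
            gamma_sd=0.05,
            beta_causal=beta,
            n_exposure=n_exposure_samples,
            n_outcome=n_outcome,
            outcome_type="binary",
            case_fraction=phi,
            ld_blocks=list(_FIXTURE_BLOCKS),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sub_rng = np.random.default_rng(cfg.seed)
        exp_table, out_table, pair_truth = simulate_two_sample(
            cfg, rng=sub_rng, id_prefix=f"rs{e + 1:02d}"
        )
        exp_table.trait_name = name
        # Panel frequencies are drawn afresh (block-shared): a reference
        # panel is a different sample from either GWAS.
        panel = simulate_ld_panel(cfg, rng=sub_rng, ids=pair_truth["ids"])
        panel_blocks.extend(panel.blocks)

        # Withhold the lead SNP of the first two tight LD pairs from the
        # outcome table: the pipeline must recover them through proxies.
        withheld_ids = [pair_truth["ids"][0], pair_truth["ids"][2]]
        withheld[name] = withheld_ids
        out_table.records = [r for r in out_table.records if r.variant_id not in withheld_ids]
        outcome_records.extend(out_table.records)

        exp_path = out_dir / f"{name}.tsv"
        write_sumstats(exp_table, exp_path)
        exposures.append({"name": name, "path": str(exp_path), "trait_type": "continuous",
                          "beta_true": beta})
        truth[name] = pair_truth

        # Every fifth exposure shares one SNP with a second trait.
        if e % 5 == 0:
            xtab_rows.append((pair_truth["ids"][4], name, "shared_trait"))

    outcome_table = SummaryStatsTable("outcome_disease", "binary", outcome_records)
    outcome_path = out_dir / "outcome_disease.tsv"
    write_sumstats(outcome_table, outcome_path)

    panel_path = out_dir / "ld_panel.tsv"
    write_ld_long(LDPanel(blocks=panel_blocks), panel_path)

    xtab_path = out_dir / "cross_trait.tsv"
    with open(xtab_path, "wt") as fh:
        fh.write("variant_id\ttrait\n")
        for vid, t1, t2 in xtab_rows:
            fh.write(f"{vid}\t{t1}\n{vid}\t{t2}\n")

    manifest = {
        "seed": seed,
        "n_exposures": n_exposures,
        "exposures": exposures,
        "outcome": {"name": "outcome_disease", "path": str(outcome_path),
                    "trait_type": "binary", "n_cases": n_outcome_cases,
                    "n_controls": n_outcome_controls},
        "panel": str(panel_path),
        "cross_trait": str(xtab_path),
        "withheld_from_outcome": withheld,
        "truth": truth,
    }
    with open(out_dir / "truth.json", "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
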