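"""Instrument-strength and sensitivity diagnostics.

Instrument strength is summarized by the variance in the exposure explained
by each SNP, r2_j = beta_j^2 / (se_j^2 (n - 2) + beta_j^2), summed over
approximately independent (post-clumping) instruments, and by the
F-statistic F = r2 (n - k - 1) / (k (1 - r2)). Leave-one-out re-estimates
the pooled causal effect with each instrument excluded in turn and flags
exclusions that move the association across the significance threshold —
the signature of a result driven by a single outlying or pleiotropic
variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .estimators import MRResult, ivw
from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "InstrumentDiagnostics",
    "LeaveOneOutResult",
    "snp_r2",
    "total_r2",
    "f_statistic",
    "instrument_diagnostics",
    "leave_one_out",
]

_R2_CEIL = 1.0 - 1e-9


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Per-instrument and total variance explained plus the F-statistic."""

    r2_per_snp: tuple[float, ...]
    r2_total: float
    f_stat: float
    n: int
    k: int


@dataclass
class LeaveOneOutResult:
    """IVW re-estimates with each instrument excluded in turn."""

    results: list[tuple[str, MRResult]]
    full_result: MRResult
    flagged: list[str]


def snp_r2(beta: float, se: float, n: int) -> float:
    """Variance in the trait explained by one SNP.

    r2 = beta^2 / (se^2 (n - 2) + beta^2); approaches the squared
    correlation between genotype and trait for a simple regression on n
    samples.
    """
    if n <= 2:
        raise ValueError("snp_r2 requires n > 2")
    if se <= 0:
        raise ValueError("snp_r2 requires se > 0")
    b2 = beta * beta
    return b2 / (se * se * (n - 2) + b2)


def total_r2(betas, ses, ns) -> float:
    """Sum of per-SNP r2 over (assumed independent) instruments.

    The additive rule can exceed 1 on invalid input; the sum is clamped just
    below 1 with a warning so the downstream F-statistic stays defined.
    """
    total = 0.0
    for b, s, n in zip(betas, ses, ns):
        total += snp_r2(b, s, n)
    if total >= 1.0:
        warnings.warn(
            f"summed instrument r2 = {total:.4f} >= 1; clamping — instruments "
            "are unlikely to be independent",
            stacklevel=2,
        )
        total = _R2_CEIL
    return total


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F-statistic: r2 (n - k - 1) / (k (1 - r2))."""
    if not (0 <= r2_total < 1):
        raise ValueError("r2_total must lie in [0, 1)")
    if k < 1 or n <= k + 1:
        raise ValueError("f_statistic requires n > k + 1 >= 2")
    return r2_total * (n - k - 1) / (k * (1.0 - r2_total))


def instrument_diagnostics(
    hset: HarmonizedInstrumentSet,
    exposure_table=None,
    n_fallback: int | None = None,
) -> InstrumentDiagnostics:
    """Strength diagnostics for a harmonized instrument set.

    Per-SNP sample sizes are looked up in ``exposure_table`` when provided;
    instruments without a lookup use ``n_fallback`` (or the per-exposure
    maximum n). The reported F-statistic uses the maximum n, the standard
    single-n form of the strength formula.
    """
    k = hset.n_snps
    if k == 0:
        raise ValueError("no instruments")
    ns = []
    for v in hset.variants:
        rec = exposure_table.get(v.variant_id) if exposure_table is not None else None
        ns.append(rec.n if rec is not None else None)
    known = [n for n in ns if n is not None]
    fallback = n_fallback if n_fallback is not None else (max(known) if known else None)
    if fallback is None:
        raise ValueError("exposure sample size required (no table n and no fallback)")
    ns = [n if n is not None else fallback for n in ns]
    r2s = tuple(
        snp_r2(v.beta_exposure, v.se_exposure, n) for v, n in zip(hset.variants, ns)
    )
    r2t = total_r2(
        [v.beta_exposure for v in hset.variants],
        [v.se_exposure for v in hset.variants],
        ns,
    )
    n_used = max(ns)
    return InstrumentDiagnostics(r2s, r2t, f_statistic(r2t, n_used, k), n_used, k)


def leave_one_out(
    hset: HarmonizedInstrumentSet,
    threshold: float = 0.05,
    ivw_model: str = "multiplicative_random",
) -> LeaveOneOutResult:
    """IVW with each instrument excluded; flag threshold-crossing exclusions.

    A variant is flagged when the full-set association is significant
    (p < threshold) but removing that single variant makes it not so — the
    pattern of an association driven by one instrument.
    """
    J = hset.n_snps
    if J < 2:
        raise ValueError("leave-one-out requires at least 2 instruments")
    full = ivw(hset, model=ivw_model)
    results: list[tuple[str, MRResult]] = []
    flagged: list[str] = []
    for i, v in enumerate(hset.variants):
        sub = HarmonizedInstrumentSet(
            exposure_name=hset.exposure_name,
            outcome_name=hset.outcome_name,
            variants=hset.variants[:i] + hset.variants[i + 1 :],
            outcome_type=hset.outcome_type,
        )
        res = ivw(sub, model=ivw_model)
        results.append((v.variant_id, res))
        if full.pvalue < threshold <= res.pvalue:
            flagged.append(v.variant_id)
    return LeaveOneOutResult(results=results, full_result=full, flagged=flagged)
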