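"""Instrument selection: significance filtering, LD clumping, proxies.

Instruments for an exposure are its genome-wide-significant variants
(p < 5e-8 by default), pruned to pairwise near-independence (r2 < 0.01) by
greedy clumping that keeps the lowest-p variant of each correlated group.
Instruments missing from the outcome study can be replaced by a proxy in
high LD (r2 > 0.9), and variants known to associate with more than one
trait can be excluded as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ld import LDPanel
from .sumstats import SummaryStatsTable

__all__ = [
    "SelectionParams",
    "CrossTraitTable",
    "filter_significant",
    "ld_clump",
    "find_proxy",
    "remove_cross_trait",
]


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds governing instrument selection.

    Defaults follow the standard conventions: genome-wide significance at
    p < 5e-8, independence at pairwise r2 < 0.01, proxies at r2 > 0.9.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    proxy_r2_min: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 <= self.clump_r2 < self.proxy_r2_min <= 1):
            raise ValueError("need 0 <= clump_r2 < proxy_r2_min <= 1")


@dataclass
class CrossTraitTable:
    """variant_id -> set of trait names the variant is known to associate with."""

    mapping: dict[str, set[str]] = field(default_factory=dict)

    @staticmethod
    def from_tsv(path) -> "CrossTraitTable":
        """Load from a two-column TSV (variant_id, trait), one pair per row."""
        mapping: dict[str, set[str]] = {}
        with open(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["variant_id", "trait"]:
                raise ValueError("cross-trait table must have columns variant_id, trait")
            for line in fh:
                vid, trait = line.rstrip("\n").split("\t")[:2]
                mapping.setdefault(vid, set()).add(trait)
        return CrossTraitTable(mapping)


def filter_significant(table: SummaryStatsTable, p_threshold: float = 5e-8) -> list[str]:
    """Ids with p strictly below the threshold, in input order."""
    return [r.variant_id for r in table.records if r.pvalue < p_threshold]


def ld_clump(
    candidates: Mapping[str, float] | Sequence[tuple[str, float]],
    panel: LDPanel,
    clump_r2: float = 0.01,
) -> list[str]:
    """Greedy LD clumping of (variant_id, p-value) candidates.

    Candidates are visited in ascending p (ties broken by lexicographic id);
    each accepted variant discards every remaining candidate with
    r2 >= ``clump_r2`` against it. The retained set is therefore pairwise
    r2 < clump_r2, and every discarded variant is correlated with some
    retained one. The result depends only on the p-values, ids and panel,
    not on input order.
    """
    items = list(candidates.items()) if isinstance(candidates, Mapping) else list(candidates)
    missing = [vid for vid, _p in items if vid not in panel]
    if missing:
        raise KeyError(f"clump candidates absent from LD panel: {missing[:5]}")
    queue = sorted(items, key=lambda kv: (kv[1], kv[0]))
    kept: list[str] = []
    alive = {vid for vid, _ in queue}
    for vid, _p in queue:
        if vid not in alive:
            continue
        kept.append(vid)
        alive.discard(vid)
        for other in list(alive):
            if panel.r2(vid, other) >= clump_r2:
                alive.discard(other)
    return kept


def clump_audit(
    candidates: Mapping[str, float],
    panel: LDPanel,
    clump_r2: float = 0.01,
) -> dict[str, str]:
    """Per-candidate status: ``kept`` or ``clumped_by:<retained id>``."""
    kept = ld_clump(candidates, panel, clump_r2)
    status = {vid: "kept" for vid in kept}
    order = sorted(candidates.items(), key=lambda kv: (kv[1], kv[0]))
    kept_in_order = [vid for vid, _ in order if vid in status]
    for vid, _p in order:
        if vid in status:
            continue
        for anchor in kept_in_order:
            if panel.r2(anchor, vid) >= clump_r2:
                status[vid] = f"clumped_by:{anchor}"
                break
    return status


def find_proxy(
    missing_id: str,
    outcome_ids: Iterable[str],
    panel: LDPanel,
    proxy_r2_min: float = 0.9,
) -> str | None:
    """Best available proxy for an instrument absent from the outcome study.

    Among outcome-present panel variants with r2(missing, candidate)
    strictly above ``proxy_r2_min``, returns the one with maximal r2 (ties
    broken by lexicographically smallest id); None when nothing qualifies.
    """
    if missing_id not in panel:
        raise KeyError(f"{missing_id!r} absent from LD panel")
    best: tuple[float, str] | None = None
    for cand in outcome_ids:
        if cand == missing_id or cand not in panel:
            continue
        r2 = panel.r2(missing_id, cand)
        if r2 > proxy_r2_min:
            key = (-r2, cand)
            if best is None or key < best:
                best = key
    return None if best is None else best[1]


def remove_cross_trait(ids: Sequence[str], xtab: CrossTraitTable) -> list[str]:
    """Drop ids known to associate with more than one trait.

    Ids absent from the table are retained: the table records positive
    evidence of multi-trait association, and absence of evidence keeps the
    variant.
    """
    return [vid for vid in ids if len(xtab.mapping.get(vid, ())) <= 1]
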