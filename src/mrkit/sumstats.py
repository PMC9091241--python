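"""GWAS summary-statistics tables: reading, validation, writing, harmonization.

A summary-statistics table holds one row per variant with the per-allele
effect estimate (log-odds units for binary traits), its standard error,
p-value, allele pair, effect-allele frequency and sample size. Harmonization
aligns an exposure table and an outcome table onto a single effect-allele
convention so that per-variant (gamma_hat, Gamma_hat) pairs can be fed to
ratio-based causal estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryStatsTable",
    "HarmonizedInstrumentSet",
    "DEFAULT_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: GWAS-SSF-like header names accepted without an explicit column map.
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "variant_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

#: Sentinel used on disk for a missing effect-allele frequency.
NA_SENTINEL = "NA"


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's estimated association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int

    def is_valid(self) -> bool:
        """Field-level invariants; rows failing these are dropped on read."""
        if self.effect_allele not in _VALID_ALLELES:
            return False
        if self.other_allele not in _VALID_ALLELES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not (self.se > 0) or not math.isfinite(self.se):
            return False
        if not math.isfinite(self.beta):
            return False
        if not (0 < self.pvalue <= 1):
            return False
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return False
        if self.pos < 1 or self.n <= 2:
            return False
        return True

    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryStatsTable:
    """An ordered, id-unique collection of variant associations for one trait."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    records: list[VariantAssociation] = field(default_factory=list)
    ancestry_label: str = "EUR"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate variant_id in table {self.trait_name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index().get(variant_id)

    def _index(self) -> dict[str, VariantAssociation]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.records):
            self._idx = {r.variant_id: r for r in self.records}
        return self._idx

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view in the canonical column dialect."""
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "chromosome": [r.chrom for r in self.records],
                "base_pair_location": [r.pos for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "effect_allele_frequency": [
                    math.nan if r.eaf is None else r.eaf for r in self.records
                ],
                "beta": [r.beta for r in self.records],
                "standard_error": [r.se for r in self.records],
                "p_value": [r.pvalue for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


# Actions recorded per variant during harmonization.
UNCHANGED = "unchanged"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
STRAND_AND_SIGN_FLIPPED = "strand_flipped_and_sign_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_UNMATCHED = "dropped_unmatched"

_DROP_ACTIONS = (DROPPED_PALINDROMIC, DROPPED_UNMATCHED)


@dataclass(frozen=True)
class HarmonizedVariant:
    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None
    action: str


@dataclass
class HarmonizedInstrumentSet:
    """Per-variant aligned exposure/outcome effects sharing one effect allele.

    Only retained (non-dropped) variants enter estimators; dropped variants
    are kept in ``dropped`` for auditing.
    """

    exposure_name: str
    outcome_name: str
    variants: list[HarmonizedVariant] = field(default_factory=list)
    dropped: list[HarmonizedVariant] = field(default_factory=list)
    outcome_type: str = "binary"

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        import numpy as np

        bx = np.array([v.beta_exposure for v in self.variants], dtype=float)
        sx = np.array([v.se_exposure for v in self.variants], dtype=float)
        by = np.array([v.beta_outcome for v in self.variants], dtype=float)
        sy = np.array([v.se_outcome for v in self.variants], dtype=float)
        return bx, sx, by, sy

    def audit_frame(self) -> pd.DataFrame:
        rows = [
            {"variant_id": v.variant_id, "action": v.action}
            for v in list(self.variants) + list(self.dropped)
        ]
        return pd.DataFrame(rows, columns=["variant_id", "action"])


def _parse_float(value, *, allow_missing: bool = False) -> float | None:
    if value is None:
        return None if allow_missing else math.nan
    s = str(value).strip()
    if s == "" or s.upper() in ("NA", "NAN", "."):
        return None if allow_missing else math.nan
    try:
        return float(s)
    except ValueError:
        return None if allow_missing else math.nan


def read_sumstats(
    path,
    trait_name: str,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
    ancestry_label: str = "EUR",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    The delimiter (tab or comma) is sniffed from the header line. Alleles are
    uppercased; only single-base alleles (SNVs) are accepted — rows carrying
    indels or invalid fields are dropped and counted in ``n_dropped``.

    Raises
    ------
    ValueError
        If a mapped mandatory column is missing from the header, or if no
        valid rows remain after filtering.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    with open(path, "rt") as fh:
        header_line = fh.readline()
    sep = "\t" if header_line.count("\t") >= header_line.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for field_name, col in cols.items():
        if col not in df.columns:
            raise ValueError(
                f"missing mandatory column {col!r} (for field {field_name!r}) in {path}"
            )

    records: list[VariantAssociation] = []
    seen: set[str] = set()
    n_dropped = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        try:
            rec = VariantAssociation(
                variant_id=str(row_d[cols["variant_id"]]).strip(),
                chrom=str(row_d[cols["chrom"]]).strip(),
                pos=int(float(row_d[cols["pos"]])),
                effect_allele=str(row_d[cols["effect_allele"]]).strip().upper(),
                other_allele=str(row_d[cols["other_allele"]]).strip().upper(),
                eaf=_parse_float(row_d[cols["eaf"]], allow_missing=True),
                beta=float(row_d[cols["beta"]]),
                se=float(row_d[cols["se"]]),
                pvalue=float(row_d[cols["pvalue"]]),
                n=int(float(row_d[cols["n"]])),
            )
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        if not rec.is_valid() or rec.variant_id in seen:
            n_dropped += 1
            continue
        seen.add(rec.variant_id)
        records.append(rec)

    if not records:
        raise ValueError(f"no valid rows in {path} ({n_dropped} dropped)")
    return SummaryStatsTable(
        trait_name=trait_name,
        trait_type=trait_type,
        records=records,
        ancestry_label=ancestry_label,
        n_dropped=n_dropped,
    )


def write_sumstats(table: SummaryStatsTable, path) -> None:
    """Write a table in the canonical tab-delimited dialect.

    Missing eaf is written as ``NA`` so that read(write(t)) round-trips
    field-by-field. An empty table is an error.
    """
    if len(table.records) == 0:
        raise ValueError("refusing to write an empty summary-statistics table")
    with open(path, "wt") as fh:
        fh.write("\t".join(DEFAULT_COLUMNS[k] for k in DEFAULT_COLUMNS) + "\n")
        for r in table.records:
            eaf = NA_SENTINEL if r.eaf is None else repr(r.eaf)
            fh.write(
                "\t".join(
                    [
                        r.variant_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        eaf,
                        repr(r.beta),
                        repr(r.se),
                        repr(r.pvalue),
                        str(r.n),
                    ]
                )
                + "\n"
            )


def _classify_match(exp: VariantAssociation, out: VariantAssociation) -> str | None:
    """How the outcome allele pair relates to the exposure pair, or None."""
    ea, oa = exp.effect_allele, exp.other_allele
    if (out.effect_allele, out.other_allele) == (ea, oa):
        return "same"
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return "swapped"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (out.effect_allele, out.other_allele) == (cea, coa):
        return "strand"
    if (out.effect_allele, out.other_allele) == (coa, cea):
        return "strand_swapped"
    return None


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    snp_ids: Sequence[str],
    palindromic_maf_limit: float = 0.42,
) -> HarmonizedInstrumentSet:
    """Align exposure and outcome effects onto the exposure's effect allele.

    For each id in ``snp_ids`` (which must all be present in the exposure
    table) the outcome record is looked up by variant id and oriented:

    * identical allele pair — kept as is;
    * swapped alleles — outcome beta negated, eaf replaced by 1 - eaf;
    * strand-complement pair — kept (optionally with the sign flip above);
    * palindromic pair (A/T or G/C) — allele labels cannot resolve strand,
      so the variant is retained only when both effect-allele frequencies
      (after any label-driven flip) fall on the same side of 0.5 and both
      minor-allele frequencies are below ``palindromic_maf_limit``; it is
      dropped when either frequency is missing or equal to 0.5;
    * absent from the outcome, or an unmatchable allele pair — dropped.

    Drops are recorded, never raised.
    """
    if not (0 < palindromic_maf_limit < 0.5):
        raise ValueError("palindromic_maf_limit must lie in (0, 0.5)")
    missing = [s for s in snp_ids if exposure.get(s) is None]
    if missing:
        raise ValueError(f"snp_ids not in exposure table: {missing[:5]}")

    hset = HarmonizedInstrumentSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
    )
    for sid in snp_ids:
        exp = exposure.get(sid)
        out = outcome.get(sid)

        def drop(action: str) -> None:
            hset.dropped.append(
                HarmonizedVariant(sid, exp.beta, exp.se, math.nan, math.nan, exp.eaf, action)
            )

        if out is None:
            drop(DROPPED_UNMATCHED)
            continue
        match = _classify_match(exp, out)
        if match is None:
            drop(DROPPED_UNMATCHED)
            continue

        beta_out = out.beta
        eaf_out = out.eaf
        if match in ("swapped", "strand_swapped"):
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out

        if exp.is_palindromic():
            # Strand flips are invisible for A/T and G/C pairs; frequency is
            # the only evidence of orientation.
            if exp.eaf is None or eaf_out is None:
                drop(DROPPED_PALINDROMIC)
                continue
            if exp.eaf == 0.5 or eaf_out == 0.5:
                drop(DROPPED_PALINDROMIC)
                continue
            same_side = (exp.eaf < 0.5) == (eaf_out < 0.5)
            maf_exp = min(exp.eaf, 1 - exp.eaf)
            maf_out = min(eaf_out, 1 - eaf_out)
            if not same_side or maf_exp >= palindromic_maf_limit or maf_out >= palindromic_maf_limit:
                drop(DROPPED_PALINDROMIC)
                continue
            action = UNCHANGED if match == "same" else SIGN_FLIPPED
        else:
            action = {
                "same": UNCHANGED,
                "swapped": SIGN_FLIPPED,
                "strand": STRAND_FLIPPED,
                "strand_swapped": STRAND_AND_SIGN_FLIPPED,
            }[match]

        hset.variants.append(
            HarmonizedVariant(
                variant_id=sid,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                eaf=exp.eaf,
                action=action,
            )
        )
    return hset
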