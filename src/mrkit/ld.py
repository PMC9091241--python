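"""Reference-panel linkage-disequilibrium structure.

An :class:`LDPanel` stores squared correlations (r2) between variants, used
for clumping instruments to pairwise independence and for finding proxy
variants. Panels here are block-structured: within a block r2 is dense,
across blocks it is exactly zero — the natural shape for both simulated
panels and the long-format on-disk representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LDPanel", "read_ld_long", "write_ld_long", "read_ld_matrix", "write_ld_matrix"]


@dataclass
class LDPanel:
    """Variant-by-variant squared-correlation structure.

    ``blocks`` is a list of (ids, r2_submatrix, signed_r_submatrix or None);
    variants in different blocks have r2 = 0. ``signed_r`` carries the sign
    of the dosage correlation where a genotype panel was available, used to
    orient proxy alleles.
    """

    blocks: list[tuple[list[str], np.ndarray, np.ndarray | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._loc: dict[str, tuple[int, int]] = {}
        for b, (ids, r2, _r) in enumerate(self.blocks):
            r2 = np.asarray(r2, dtype=float)
            if r2.shape != (len(ids), len(ids)):
                raise ValueError("r2 submatrix shape does not match block ids")
            if not np.allclose(r2, r2.T, atol=1e-8):
                raise ValueError("r2 submatrix must be symmetric")
            if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
                raise ValueError("r2 diagonal must be 1")
            if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
                raise ValueError("r2 entries must lie in [0, 1]")
            for i, vid in enumerate(ids):
                if vid in self._loc:
                    raise ValueError(f"duplicate variant {vid!r} in LD panel")
                self._loc[vid] = (b, i)

    @property
    def ids(self) -> list[str]:
        return [vid for ids, _, _ in self.blocks for vid in ids]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._loc

    def __len__(self) -> int:
        return len(self._loc)

    def r2(self, id_a: str, id_b: str) -> float:
        """Squared correlation between two panel variants (0 across blocks)."""
        ba, ia = self._loc[id_a]
        bb, ib = self._loc[id_b]
        if ba != bb:
            return 0.0
        return float(self.blocks[ba][1][ia, ib])

    def signed_r(self, id_a: str, id_b: str) -> float | None:
        """Dosage correlation with sign, or None if no genotypes backed the panel."""
        ba, ia = self._loc[id_a]
        bb, ib = self._loc[id_b]
        if ba != bb:
            return 0.0
        r = self.blocks[ba][2]
        return None if r is None else float(r[ia, ib])

    def r2_matrix(self, ids: list[str]) -> np.ndarray:
        """Dense pairwise r2 submatrix for a list of panel variants."""
        missing = [i for i in ids if i not in self._loc]
        if missing:
            raise KeyError(f"variants absent from LD panel: {missing[:5]}")
        m = np.zeros((len(ids), len(ids)))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if j < i:
                    m[i, j] = m[j, i]
                else:
                    m[i, j] = self.r2(a, b)
        return m

    def block_members(self, variant_id: str) -> list[str]:
        b, _ = self._loc[variant_id]
        return list(self.blocks[b][0])

    @staticmethod
    def from_matrix(ids: list[str], r2: np.ndarray, signed_r: np.ndarray | None = None) -> "LDPanel":
        """Build a one-block panel from a dense matrix."""
        return LDPanel(blocks=[(list(ids), np.asarray(r2, dtype=float),
                                None if signed_r is None else np.asarray(signed_r, dtype=float))])


def write_ld_long(panel: LDPanel, path) -> None:
    """Write the within-block upper triangle as TSV (id_a, id_b, r2, r_signed).

    Cross-block pairs are implicitly zero. Self pairs (r2 = 1) are included
    so block membership and variant order survive a round trip.
    """
    with open(path, "wt") as fh:
        fh.write("block\tid_a\tid_b\tr2\tr_signed\n")
        for b, (ids, r2, r) in enumerate(panel.blocks):
            for i in range(len(ids)):
                for j in range(i, len(ids)):
                    rs = "NA" if r is None else repr(float(r[i, j]))
                    fh.write(f"{b}\t{ids[i]}\t{ids[j]}\t{float(r2[i, j])!r}\t{rs}\n")


def read_ld_long(path) -> LDPanel:
    df = pd.read_csv(path, sep="\t", dtype={"block": int, "id_a": str, "id_b": str})
    blocks = []
    for _b, sub in df.groupby("block", sort=True):
        ids: list[str] = []
        for vid in pd.concat([sub["id_a"], sub["id_b"]]):
            if vid not in ids:
                ids.append(vid)
        idx = {v: i for i, v in enumerate(ids)}
        n = len(ids)
        r2 = np.eye(n)
        has_sign = not sub["r_signed"].astype(str).str.upper().eq("NA").any()
        r = np.eye(n) if has_sign else None
        for row in sub.itertuples(index=False):
            i, j = idx[row.id_a], idx[row.id_b]
            r2[i, j] = r2[j, i] = float(row.r2)
            if r is not None:
                r[i, j] = r[j, i] = float(row.r_signed)
        blocks.append((ids, r2, r))
    return LDPanel(blocks=blocks)


def write_ld_matrix(panel: LDPanel, path) -> None:
    """Dense id-headed r2 matrix TSV (quadratic in panel size)."""
    ids = panel.ids
    m = panel.r2_matrix(ids)
    df = pd.DataFrame(m, index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="variant_id", float_format="%.10g")


def read_ld_matrix(path) -> LDPanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDPanel.from_matrix([str(c) for c in df.columns], df.to_numpy(dtype=float))
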