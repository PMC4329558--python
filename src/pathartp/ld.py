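"""Pairwise linkage disequilibrium and independent-signal grouping.

r² here is the squared Pearson correlation of minor-allele dosages over
pairwise-complete observations (composite, phase-free LD), conventionally
computed among controls so disease association cannot masquerade as LD.
Significant SNPs are grouped into independent signals by single-linkage
clustering of the graph whose edges join pairs with r² at or above a
threshold (0.8 by default; the boundary value counts as high LD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class LdMatrix:
    """Symmetric r² matrix (nan where undefined) with SNP labels."""

    snp_ids: list[str]
    r2: np.ndarray
    controls_only: bool = True

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix shape does not match snp_ids")

    def lookup(self, a: str, b: str) -> float:
        i, j = self.snp_ids.index(a), self.snp_ids.index(b)
        return float(self.r2[i, j])

    def to_long_table(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(len(self.snp_ids)):
            for j in range(i + 1, len(self.snp_ids)):
                out.append((self.snp_ids[i], self.snp_ids[j], float(self.r2[i, j])))
        return out


def r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete observations.

    Invariant to which allele is counted (2 - g gives the same value).
    Returns nan when either SNP is monomorphic in the complete pairs or
    fewer than two complete pairs exist.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_matrix(
    dosages: np.ndarray, snp_ids: list[str], subset_mask: np.ndarray | None = None
) -> LdMatrix:
    """All-pairs r² on a sample subset (typically the controls)."""
    X = np.asarray(dosages, dtype=float)
    if subset_mask is not None:
        X = X[np.asarray(subset_mask, dtype=bool)]
    m = X.shape[1]
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = r2(X[:, i], X[:, i])
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = r2(X[:, i], X[:, j])
    return LdMatrix(list(snp_ids), out)


def independent_signals(
    snp_ids: list[str], ld: LdMatrix, threshold: float = 0.8
) -> list[list[str]]:
    """Group SNPs into signals: connected components of the r² >= t graph.

    Single linkage — one qualifying pair merges two groups. Components are
    returned in order of each group's first SNP in the input list.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        return []
    idx = [ld.snp_ids.index(s) for s in snp_ids]
    sub = ld.r2[np.ix_(idx, idx)]
    with np.errstate(invalid="ignore"):
        adj = csr_matrix(np.nan_to_num(sub, nan=-1.0) >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[str]] = {}
    for snp, lab in zip(snp_ids, labels):
        clusters.setdefault(int(lab), []).append(snp)
    return [clusters[k] for k in sorted(clusters, key=lambda k: snp_ids.index(clusters[k][0]))]


def write_ld_table(ld: LdMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for a, b, v in ld.to_long_table():
            fh.write(f"{a}\t{b}\t{v:.6g}\n")
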