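"""Adaptive rank truncated product (ARTP) gene- and pathway-level tests.

The rank truncated product statistic for a truncation point j is the
negative log product of the j smallest p-values in a unit (gene or
pathway). ARTP evaluates the statistic at several candidate truncation
points, converts each into an estimated p-value against a permutation null,
takes the minimum over truncation points (MinP), and adjusts that adaptive
minimization with the same permutations: the reported p-value is the
fraction of rows (observed row pooled with the B permuted rows) whose MinP
is at least as extreme as the observed one.

Counting conventions, fixed so the floor arithmetic is exact:

* per-truncation estimated p of row b:  #{b' : S(b') >= S(b)} / (B + 1);
* adjusted p:  #{b : MinP(b) <= MinP(0)} / (B + 1);
* hence every adjusted p >= 1/(B+1), attained exactly when the observed
  MinP is the unique strict minimum (5.00e-05 at B = 20,000).

The pathway test reuses the SAME permutation ensemble: for every row b each
gene's MinP-derived estimated p is computed treating row b as the reference
within the pool, and the RTP/MinP machinery is applied across genes. No
second layer of permutation is generated.

Case/control labels are shuffled within study strata so each study's
case/control ratio is preserved under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .annotation import GeneSnpMap
from .association import CovariateDesign, fit_null_logistic, score_test_pvalues
from .dataset import PathwayModel


# ---------------------------------------------------------------------------
# Truncation sets
# ---------------------------------------------------------------------------

def validate_truncation(points: Sequence[int], n_items: int) -> tuple[int, ...]:
    """Check a candidate truncation set against the number of items combined."""
    pts = tuple(int(j) for j in points)
    if not pts:
        raise ValueError("truncation set is empty")
    if any(j < 1 for j in pts):
        raise ValueError(f"truncation points must be positive: {pts}")
    if any(b >= a for a, b in zip(pts[1:], pts)):
        raise ValueError(f"truncation points must be strictly increasing: {pts}")
    if pts[-1] > n_items:
        raise ValueError(
            f"largest truncation point {pts[-1]} exceeds {n_items} items"
        )
    return pts


def default_truncation(n_items: int, cap: int = 10) -> tuple[int, ...]:
    """Default candidate set {1, 2, ..., min(n_items, cap)}."""
    return tuple(range(1, min(n_items, cap) + 1))


def clip_truncation(points: Sequence[int] | None, n_items: int) -> tuple[int, ...]:
    """Adapt a configured set to a unit: drop points beyond n_items."""
    if points is None:
        return default_truncation(n_items)
    kept = tuple(j for j in points if j <= n_items)
    return validate_truncation(kept if kept else (n_items,), n_items)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def rtp_statistic(pvalues: Sequence[float], j: int) -> float:
    """-sum of log of the j smallest p-values (larger = more significant)."""
    p = np.asarray(pvalues, dtype=float)
    if not 1 <= j <= p.size:
        raise ValueError(f"truncation point {j} outside 1..{p.size}")
    if np.any(p <= 0):
        raise ValueError("rank truncated product requires p-values > 0")
    return float(-np.sum(np.log(np.sort(p)[:j])))


def _rtp_rows(p_matrix: np.ndarray, points: tuple[int, ...]) -> np.ndarray:
    """RTP statistics per row and truncation point: shape (rows, len(points))."""
    if np.any(p_matrix <= 0):
        raise ValueError("p-value matrix contains non-positive entries")
    neglog_sorted = -np.log(np.sort(p_matrix, axis=1))
    cum = np.cumsum(neglog_sorted, axis=1)
    return cum[:, [j - 1 for j in points]]


def _estimated_p_columns(S: np.ndarray) -> np.ndarray:
    """Per-column estimated p: share of rows with statistic >= this row's."""
    R = S.shape[0]
    out = np.empty_like(S)
    for k in range(S.shape[1]):
        col = S[:, k]
        order = np.sort(col)
        count_lt = np.searchsorted(order, col, side="left")
        out[:, k] = (R - count_lt) / R
    return out


def _count_le(values: np.ndarray) -> np.ndarray:
    """For each entry, #{entries <= it} / len — the adjusted-p counting rule."""
    order = np.sort(values)
    return np.searchsorted(order, values, side="right") / values.size


@dataclass
class ArtpResult:
    """Adjusted p-value for one unit (gene or pathway) with diagnostics."""

    unit_name: str
    p_adjusted: float
    best_truncation: int
    per_truncation: dict[int, float]
    n_items: int
    B: int

    @property
    def floor(self) -> float:
        return 1.0 / (self.B + 1)


def min_attainable_p(B: int) -> float:
    """Permutation floor 1/(B+1) under the pooled-counting convention."""
    return 1.0 / (B + 1)


def artp_adjusted_p(
    p_matrix: np.ndarray,
    truncation: Sequence[int] | None = None,
    unit_name: str = "unit",
) -> ArtpResult:
    """ARTP adjusted p-value for one unit from its (B+1) x L p-value matrix.

    Row 0 must hold the observed-label p-values; rows 1..B the permuted
    ones. See module docstring for the counting conventions.
    """
    P = np.asarray(p_matrix, dtype=float)
    if P.ndim != 2 or P.shape[1] == 0:
        raise ValueError("unit has no items to combine")
    points = clip_truncation(truncation, P.shape[1])
    minp, shat0 = _unit_minp(P, points)
    p_adj = float(_count_le(minp)[0])
    k_best = int(np.argmin(shat0))
    return ArtpResult(
        unit_name=unit_name,
        p_adjusted=p_adj,
        best_truncation=points[k_best],
        per_truncation={j: float(s) for j, s in zip(points, shat0)},
        n_items=P.shape[1],
        B=P.shape[0] - 1,
    )


def _unit_minp(P: np.ndarray, points: tuple[int, ...]):
    """MinP per row plus the observed row's per-truncation estimated p."""
    S = _rtp_rows(P, points)
    shat = _estimated_p_columns(S)
    return shat.min(axis=1), shat[0]


# ---------------------------------------------------------------------------
# Permutation ensemble
# ---------------------------------------------------------------------------

@dataclass
class PermutationEnsemble:
    """Per-permutation per-SNP p-values shared by all gene/pathway tests.

    ``p_matrix`` has B+1 rows: row 0 the observed labels, rows 1..B the
    stratified relabelings (or, for exhaustive ensembles, every distinct
    relabeling with the observed one first).
    """

    p_matrix: np.ndarray
    snp_ids: list[str]
    seed: int | None = None
    strata: np.ndarray | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.p_matrix.ndim != 2 or self.p_matrix.shape[1] != len(self.snp_ids):
            raise ValueError("p_matrix shape does not match snp_ids")
        if np.any(self.p_matrix <= 0) or np.any(self.p_matrix > 1):
            raise ValueError("ensemble p-values must lie in (0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def B(self) -> int:
        return self.p_matrix.shape[0] - 1

    def columns(self, snp_ids: Iterable[str]) -> np.ndarray:
        return self.p_matrix[:, [self._index[s] for s in snp_ids]]


def _stratum_indices(strata: np.ndarray | None, n: int) -> list[np.ndarray]:
    if strata is None:
        return [np.arange(n)]
    strata = np.asarray(strata)
    return [np.flatnonzero(strata == s) for s in pd.unique(strata)]


def _design_constant_within_strata(X: np.ndarray, groups: list[np.ndarray]) -> bool:
    return all(np.allclose(X[idx], X[idx[0]]) for idx in groups)


def build_ensemble(
    dosage_matrix: np.ndarray,
    status: np.ndarray,
    design: CovariateDesign | None = None,
    B: int = 20_000,
    seed: int | None = None,
    strata: np.ndarray | None = None,
    snp_ids: Sequence[str] | None = None,
) -> PermutationEnsemble:
    """Score-test p-values for the observed labels and B stratified shuffles.

    When the null design is constant within each permutation stratum (e.g.
    intercept only, or study indicators with study-stratified shuffling) the
    null fitted probabilities are invariant under relabeling, and the whole
    ensemble reduces to one matrix product. Otherwise the covariates-only
    logistic null is refit for every permutation.
    """
    G = np.asarray(dosage_matrix, dtype=float)
    y = np.asarray(status, dtype=float)
    n, m = G.shape
    X = design.matrix if design is not None else np.ones((n, 1))
    snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(m)]

    groups = _stratum_indices(strata, n)
    for idx in groups:
        if len(np.unique(y[idx])) < 2:
            warnings.warn(
                "a permutation stratum contains a single outcome class; "
                "its shuffles are no-ops",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    P = np.empty((B + 1, m))
    mu0 = fit_null_logistic(X, y)

    if _design_constant_within_strata(X, groups):
        # fast path: mu and the score variance are permutation-invariant
        col_mean = np.nanmean(G, axis=0)
        Gi = np.where(np.isnan(G), np.where(np.isnan(col_mean), 0.0, col_mean), G)
        w = mu0 * (1.0 - mu0)
        XtWX = X.T @ (X * w[:, None])
        XtWG = X.T @ (Gi * w[:, None])
        sol = np.linalg.solve(XtWX, XtWG)
        V = np.einsum("ij,ij->j", Gi * w[:, None], Gi) - np.einsum(
            "ij,ij->j", XtWG, sol
        )
        Y = np.empty((n, B + 1))
        Y[:, 0] = y
        for b in range(1, B + 1):
            Y[:, b] = _stratified_shuffle(y, groups, rng)
        U = Gi.T @ (Y - mu0[:, None])  # m x (B+1)
        good = V > 1e-12
        stat = np.zeros_like(U)
        stat[good] = U[good] ** 2 / V[good, None]
        from scipy import stats as _st

        P[:] = np.clip(_st.chi2.sf(stat, df=1).T, np.finfo(float).tiny, 1.0)
    else:
        P[0] = score_test_pvalues(G, y, design, mu=mu0)
        for b in range(1, B + 1):
            yb = _stratified_shuffle(y, groups, rng)
            P[b] = score_test_pvalues(G, yb, design)

    return PermutationEnsemble(P, snp_ids, seed=seed, strata=strata)


def _stratified_shuffle(
    y: np.ndarray, groups: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    yb = y.copy()
    for idx in groups:
        yb[idx] = y[idx][rng.permutation(len(idx))]
    return yb


def build_exhaustive_ensemble(
    dosage_matrix: np.ndarray,
    status: np.ndarray,
    design: CovariateDesign | None = None,
    snp_ids: Sequence[str] | None = None,
) -> PermutationEnsemble:
    """Ensemble over every distinct case/control relabeling (small n only).

    Row 0 is the observed labeling; the remaining rows are the other
    C(n, n_cases) - 1 assignments. Replaces random permutation so ARTP
    results are exactly reproducible by direct enumeration.
    """
    G = np.asarray(dosage_matrix, dtype=float)
    y = np.asarray(status, dtype=int)
    n, m = G.shape
    n_cases = int(y.sum())
    labelings = [np.flatnonzero(y).tolist()] + [
        list(c)
        for c in combinations(range(n), n_cases)
        if list(c) != np.flatnonzero(y).tolist()
    ]
    snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(m)]
    P = np.empty((len(labelings), m))
    for b, case_idx in enumerate(labelings):
        yb = np.zeros(n)
        yb[case_idx] = 1.0
        P[b] = score_test_pvalues(G, yb, design)
    return PermutationEnsemble(P, snp_ids, exhaustive=True)


# ---------------------------------------------------------------------------
# Gene- and pathway-level tests on a shared ensemble
# ---------------------------------------------------------------------------

def artp_gene_p(
    ensemble: PermutationEnsemble,
    gene_snp_map: GeneSnpMap | Mapping[str, Sequence[str]],
    gene_names: Iterable[str] | None = None,
    truncation: Sequence[int] | None = None,
) -> dict[str, ArtpResult]:
    """ARTP adjusted p-value for each gene from the shared ensemble."""
    snps_by_gene = _snps_by_gene(gene_snp_map)
    names = list(gene_names) if gene_names is not None else list(snps_by_gene)
    out = {}
    for g in names:
        snps = snps_by_gene.get(g, [])
        if not snps:
            continue
        out[g] = artp_adjusted_p(ensemble.columns(snps), truncation, unit_name=g)
    return out


def artp_pathway_p(
    ensemble: PermutationEnsemble,
    gene_snp_map: GeneSnpMap | Mapping[str, Sequence[str]],
    pathway: PathwayModel,
    gene_truncation: Sequence[int] | None = None,
    pathway_truncation: Sequence[int] | None = None,
) -> tuple[ArtpResult, dict[str, ArtpResult]]:
    """Two-stage ARTP pathway test on the shared ensemble.

    Stage 1 turns every permutation row into a per-gene estimated p-value
    (each row acting as its own reference within the pool); stage 2 applies
    the RTP/MinP machinery across genes. Genes without SNPs in the ensemble
    are skipped (they contribute no evidence). Returns the pathway result
    and the per-gene results computed from the same ensemble.
    """
    snps_by_gene = _snps_by_gene(gene_snp_map)
    genes = [g for g in pathway.genes if snps_by_gene.get(g)]
    if not genes:
        raise ValueError(
            f"no gene in pathway {pathway.pathway_name!r} has mapped SNPs"
        )
    R = ensemble.B + 1
    gene_p_rows = np.empty((R, len(genes)))
    gene_results: dict[str, ArtpResult] = {}
    for gi, g in enumerate(genes):
        P = ensemble.columns(snps_by_gene[g])
        points = clip_truncation(gene_truncation, P.shape[1])
        minp, shat0 = _unit_minp(P, points)
        p_rows = _count_le(minp)
        gene_p_rows[:, gi] = p_rows
        k_best = int(np.argmin(shat0))
        gene_results[g] = ArtpResult(
            unit_name=g,
            p_adjusted=float(p_rows[0]),
            best_truncation=points[k_best],
            per_truncation={j: float(s) for j, s in zip(points, shat0)},
            n_items=P.shape[1],
            B=ensemble.B,
        )

    pathway_result = artp_adjusted_p(
        gene_p_rows, pathway_truncation, unit_name=pathway.pathway_name
    )
    pathway_result.n_items = len(genes)
    return pathway_result, gene_results


def leave_gene_out(
    ensemble: PermutationEnsemble,
    gene_snp_map: GeneSnpMap | Mapping[str, Sequence[str]],
    pathway: PathwayModel,
    gene_names: Iterable[str],
    gene_truncation: Sequence[int] | None = None,
    pathway_truncation: Sequence[int] | None = None,
) -> tuple[ArtpResult, dict[str, ArtpResult]]:
    """Pathway ARTP after removing genes AND all SNPs mapped to them.

    A SNP shared between an excluded and a retained gene is removed from
    both (the sensitivity analysis removes the signal, not just the gene
    label). The SAME ensemble columns are reused for what remains.
    """
    removed = set(gene_names)
    unknown = removed - set(pathway.genes)
    if unknown:
        warnings.warn(f"excluded genes not in pathway: {sorted(unknown)}",
                      stacklevel=2)
    snps_by_gene = _snps_by_gene(gene_snp_map)
    dropped_snps = {
        s for g in removed for s in snps_by_gene.get(g, [])
    }
    pruned = {
        g: [s for s in snps if s not in dropped_snps]
        for g, snps in snps_by_gene.items()
        if g not in removed
    }
    remaining = tuple(g for g in pathway.genes if g not in removed and pruned.get(g))
    if not remaining:
        raise ValueError("leave-gene-out removed every populated gene")
    sub_pathway = PathwayModel(pathway.pathway_name, remaining)
    return artp_pathway_p(
        ensemble, pruned, sub_pathway, gene_truncation, pathway_truncation
    )


def _snps_by_gene(
    gene_snp_map: GeneSnpMap | Mapping[str, Sequence[str]]
) -> Mapping[str, Sequence[str]]:
    if isinstance(gene_snp_map, GeneSnpMap):
        return gene_snp_map.snps_by_gene
    return gene_snp_map


class ArtpTest(BaseEstimator):
    """Gene- and pathway-level ARTP test as a fitted estimator.

    Parameters
    ----------
    gene_snp_map : mapping of gene name -> list of SNP ids (or GeneSnpMap)
    pathway : PathwayModel or iterable of gene names
    B : permutation count (default 20,000)
    seed : RNG seed for the stratified shuffles
    gene_truncation, pathway_truncation : candidate truncation sets
        (defaults {1..min(L,10)} per unit)

    ``fit(X, y, design=, strata=, snp_ids=)`` builds the shared permutation
    ensemble and computes every gene's and the pathway's adjusted p-value;
    results land in ``gene_results_`` (DataFrame), ``pathway_result_`` and
    ``ensemble_``.
    """

    def __init__(
        self,
        gene_snp_map=None,
        pathway=None,
        B: int = 20_000,
        seed: int | None = None,
        gene_truncation: Sequence[int] | None = None,
        pathway_truncation: Sequence[int] | None = None,
    ) -> None:
        self.gene_snp_map = gene_snp_map
        self.pathway = pathway
        self.B = B
        self.seed = seed
        self.gene_truncation = gene_truncation
        self.pathway_truncation = pathway_truncation

    def fit(self, X, y, design=None, strata=None, snp_ids=None):
        if self.gene_snp_map is None:
            raise ValueError("gene_snp_map is required")
        snps_by_gene = _snps_by_gene(self.gene_snp_map)
        pathway = self.pathway
        if pathway is None:
            pathway = PathwayModel("pathway", tuple(snps_by_gene))
        elif not isinstance(pathway, PathwayModel):
            pathway = PathwayModel("pathway", tuple(pathway))

        self.ensemble_ = build_ensemble(
            X, y, design=design, B=self.B, seed=self.seed,
            strata=strata, snp_ids=snp_ids,
        )
        self.pathway_result_, gene_results = artp_pathway_p(
            self.ensemble_, snps_by_gene, pathway,
            self.gene_truncation, self.pathway_truncation,
        )
        self.gene_results_ = pd.DataFrame(
            [
                {
                    "gene": g,
                    "p_artp": r.p_adjusted,
                    "n_snps": r.n_items,
                    "best_truncation": r.best_truncation,
                }
                for g, r in gene_results.items()
            ]
        ).set_index("gene")
        self.gene_results_raw_ = gene_results
        return self
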