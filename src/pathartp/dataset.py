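"""Core in-memory containers for case-control genotype analyses.

Genotypes are stored as a dense ``float64`` matrix of minor-allele dosages
(samples x SNPs) with ``numpy.nan`` marking missing calls; this keeps every
downstream operation a plain vectorised array computation while preserving
the distinction between a missing call and a homozygous-major genotype.

Coordinates are 1-based inclusive throughout, following the PLINK .bim
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in dosage matrices.
MISSING = np.nan

CASE = "case"
CONTROL = "control"


@dataclass
class SampleMeta:
    """Per-sample metadata: outcome, design covariates, optional extras.

    ``status`` is ``"case"`` or ``"control"``. ``extra_covariates`` holds
    named real-valued covariates (e.g. principal components) keyed by name.
    """

    sample_id: str
    status: str
    study: str = "study1"
    sex: str = "unknown"
    age_stratum: str = "all"
    extra_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in (CASE, CONTROL):
            raise ValueError(
                f"status must be {CASE!r} or {CONTROL!r}, got {self.status!r}"
            )

    @property
    def is_case(self) -> bool:
        return self.status == CASE


@dataclass
class SnpMeta:
    """Per-SNP metadata. ``position`` is 1-based; alleles must differ."""

    snp_id: str
    chromosome: str
    position: int
    allele_minor: str
    allele_major: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.allele_minor == self.allele_major:
            raise ValueError(
                f"{self.snp_id}: minor and major allele are both {self.allele_minor!r}"
            )


@dataclass
class GeneModel:
    """A gene as a stranded genomic interval, 1-based inclusive."""

    gene_name: str
    chromosome: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_name}: start {self.start} > end {self.end}"
            )


@dataclass
class PathwayModel:
    """A named ordered set of gene names."""

    pathway_name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if len(genes) == 0:
            raise ValueError(f"pathway {self.pathway_name!r} has no genes")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if list(genes).count(g) > 1})
            raise ValueError(
                f"pathway {self.pathway_name!r} lists duplicate genes: {dupes}"
            )
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_name: str) -> bool:
        return gene_name in self.genes


class GenotypeDataset:
    """Samples x SNPs minor-allele dosage matrix with aligned metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_snps)
        Minor-allele counts in {0, 1, 2} with ``nan`` for missing calls.
    samples : sequence of SampleMeta
    snps : sequence of SnpMeta
    """

    def __init__(
        self,
        dosages: np.ndarray,
        samples: Sequence[SampleMeta],
        snps: Sequence[SnpMeta],
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        if dosages.shape != (len(samples), len(snps)):
            raise ValueError(
                f"dosage matrix {dosages.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs"
            )
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(dosages[~valid])
            raise ValueError(f"dosages contain values outside {{0,1,2,nan}}: {bad}")
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample identifiers")
        snp_ids = [s.snp_id for s in snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise ValueError("duplicate SNP identifiers")
        self.dosages = dosages
        self.samples = list(samples)
        self.snps = list(snps)
        self._snp_index = {sid: i for i, sid in enumerate(snp_ids)}
        self._sample_index = {sid: i for i, sid in enumerate(sample_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def status(self) -> np.ndarray:
        """Binary outcome vector: 1 for cases, 0 for controls."""
        return np.array([1 if s.is_case else 0 for s in self.samples], dtype=int)

    @property
    def is_control(self) -> np.ndarray:
        return self.status == 0

    def snp_column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._snp_index[snp_id]]

    def snp_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.snps], dtype=np.int64)

    def snp_chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps], dtype=object)

    # -- subsetting ----------------------------------------------------------
    def subset_samples(self, mask_or_ids) -> "GenotypeDataset":
        idx = self._as_sample_indices(mask_or_ids)
        return GenotypeDataset(
            self.dosages[idx, :],
            [self.samples[i] for i in idx],
            list(self.snps),
        )

    def subset_snps(self, mask_or_ids) -> "GenotypeDataset":
        idx = self._as_snp_indices(mask_or_ids)
        return GenotypeDataset(
            self.dosages[:, idx],
            list(self.samples),
            [self.snps[i] for i in idx],
        )

    def _as_sample_indices(self, mask_or_ids) -> np.ndarray:
        return _as_indices(mask_or_ids, self._sample_index, self.n_samples)

    def _as_snp_indices(self, mask_or_ids) -> np.ndarray:
        return _as_indices(mask_or_ids, self._snp_index, self.n_snps)

    # -- convenience ---------------------------------------------------------
    def covariate_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame (index = sample_id)."""
        rows = []
        for s in self.samples:
            row = {
                "status": s.status,
                "study": s.study,
                "sex": s.sex,
                "age_stratum": s.age_stratum,
            }
            row.update(s.extra_covariates)
            rows.append(row)
        return pd.DataFrame(rows, index=pd.Index(self.sample_ids, name="sample_id"))

    def equals(self, other: "GenotypeDataset") -> bool:
        if self.sample_ids != other.sample_ids or self.snp_ids != other.snp_ids:
            return False
        if not np.array_equal(self.dosages, other.dosages, equal_nan=True):
            return False
        return all(a == b for a, b in zip(self.snps, other.snps)) and all(
            a == b for a, b in zip(self.samples, other.samples)
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.dosages.copy(),
            [replace(s, extra_covariates=dict(s.extra_covariates)) for s in self.samples],
            [replace(s) for s in self.snps],
        )

    def __repr__(self) -> str:
        n_cases = int(self.status.sum())
        return (
            f"GenotypeDataset({self.n_samples} samples "
            f"[{n_cases} cases / {self.n_samples - n_cases} controls], "
            f"{self.n_snps} SNPs)"
        )


def _as_indices(mask_or_ids, index: dict[str, int], n: int) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape != (n,):
            raise ValueError(f"boolean mask length {arr.shape} != {n}")
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        return arr.astype(np.intp)
    return np.array([index[str(x)] for x in arr], dtype=np.intp)


def orient_to_minor(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip dosage columns so each counts the minor allele.

    The allele frequency is computed on all samples (cases and controls
    combined). Columns with counted-allele frequency > 0.5 are replaced by
    ``2 - dosage``; ties at 0.5 are left as-is.

    Returns
    -------
    (oriented, flipped) : the oriented matrix and a boolean per-SNP flag
        marking which columns were flipped.
    """
    dosages = np.asarray(dosages, dtype=float)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flipped = freq > 0.5
    oriented = dosages.copy()
    oriented[:, flipped] = 2.0 - oriented[:, flipped]
    return oriented, flipped


def allele_frequency(dosage_column: np.ndarray) -> float:
    """Frequency of the counted allele over non-missing calls."""
    col = np.asarray(dosage_column, dtype=float)
    called = ~np.isnan(col)
    if not called.any():
        raise ValueError("allele frequency undefined: all calls missing")
    return float(col[called].sum() / (2.0 * called.sum()))
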