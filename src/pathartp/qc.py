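"""SNP- and sample-level genotype quality control.

Filters, applied in a fixed order with strict inequalities:

1. samples with SNP completion rate < 94% are removed;
2. SNPs with call rate < 90% (on retained samples);
3. SNPs with minor allele frequency < 5% (cases and controls combined);
4. SNPs deviating from Hardy-Weinberg equilibrium in controls at p < 1e-4,
   by the exact conditional test (enumeration of heterozygote counts given
   the allele totals), not the chi-square approximation.

Each removed item is recorded with a single primary reason: the first
filter, in the order above, that it fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .dataset import GenotypeDataset


@dataclass
class QcThresholds:
    """Exclusion thresholds; all comparisons are strict (< removes)."""

    snp_call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    sample_completion_min: float = 0.94

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "maf_min", "hwe_p_min",
                     "sample_completion_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QcReport:
    """Per-item QC statistics, pass/fail flags and step-by-step counts."""

    snp_stats: pd.DataFrame  # index snp_id: call_rate, maf, hwe_p, removed, reason
    sample_stats: pd.DataFrame  # index sample_id: completion, removed
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps_retained(self) -> int:
        return int((~self.snp_stats["removed"]).sum())

    @property
    def n_samples_retained(self) -> int:
        return int((~self.sample_stats["removed"]).sum())

    def summary(self) -> dict[str, int]:
        return dict(self.counts)


def snp_call_rate(dosage_column: np.ndarray) -> float:
    """Fraction of samples with a non-missing call at this SNP."""
    col = np.asarray(dosage_column, dtype=float)
    if col.size == 0:
        raise ValueError("call rate undefined for an empty column")
    return float(np.mean(~np.isnan(col)))


def minor_allele_frequency(dosage_column: np.ndarray) -> float:
    """MAF = min(f, 1-f) with f the dosage-implied allele frequency.

    Computed over non-missing calls on all samples supplied (cases and
    controls combined, when given the full column).
    """
    col = np.asarray(dosage_column, dtype=float)
    called = ~np.isnan(col)
    n = int(called.sum())
    if n == 0:
        raise ValueError("MAF undefined: all calls missing")
    f = float(col[called].sum() / (2 * n))
    return min(f, 1.0 - f)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one. The
    heterozygote count distribution is

        P(h) ∝ 2^h / (h! * n_AA(h)! * n_aa(h)!)

    over counts h with the parity of the minor-allele total.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("HWE test undefined with zero genotyped individuals")
    n_minor = 2 * n_hom_minor + n_het

    hs = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    logp = (
        hs * np.log(2.0)
        - gammaln(hs + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hs == n_het)[0]]
    # tolerance guards float ties between analytically equal probabilities
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalue_from_column(dosage_column: np.ndarray) -> float:
    """Exact HWE p from a dosage column (nan-aware)."""
    col = np.asarray(dosage_column, dtype=float)
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise ValueError("HWE test undefined: no genotyped individuals")
    return hwe_exact_test(
        int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
    )


class GenotypeQC(BaseEstimator):
    """Quality-control filter as a fitted estimator.

    ``fit(X, y)`` takes the samples x SNPs dosage matrix (nan = missing) and
    the binary status vector (1 = case, 0 = control; controls drive the HWE
    test) and computes per-sample and per-SNP statistics, masks and a
    :class:`QcReport`. ``transform(X)`` applies both masks, so the output has
    fewer rows as well as fewer columns than the input — a deliberate
    departure from column-only transformers, since sample exclusion is part
    of the procedure.

    Parameters mirror :class:`QcThresholds`; ``None`` disables a filter.
    """

    def __init__(
        self,
        snp_call_rate_min: float | None = 0.90,
        maf_min: float | None = 0.05,
        hwe_p_min: float | None = 1e-4,
        sample_completion_min: float | None = 0.94,
    ) -> None:
        self.snp_call_rate_min = snp_call_rate_min
        self.maf_min = maf_min
        self.hwe_p_min = hwe_p_min
        self.sample_completion_min = sample_completion_min

    def fit(self, X, y, sample_ids=None, snp_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be 2-D with one status per row")
        if not (y == 0).any():
            raise ValueError("HWE filtering requires at least one control")
        n, m = X.shape
        sample_ids = list(sample_ids) if sample_ids is not None else [
            f"sample{i}" for i in range(n)
        ]
        snp_ids = list(snp_ids) if snp_ids is not None else [
            f"snp{j}" for j in range(m)
        ]

        missing = np.isnan(X)
        completion = 1.0 - missing.mean(axis=1) if m else np.ones(n)
        thr = self.sample_completion_min
        sample_removed = completion < thr if thr is not None else np.zeros(n, bool)
        keep_s = ~sample_removed

        Xk = X[keep_s]
        yk = y[keep_s]
        called = ~np.isnan(Xk)
        n_kept = int(keep_s.sum())
        call_rate = called.mean(axis=0) if n_kept else np.zeros(m)

        with np.errstate(invalid="ignore"):
            f = np.nansum(Xk, axis=0) / np.maximum(2.0 * called.sum(axis=0), 1.0)
        maf = np.minimum(f, 1.0 - f)
        maf[called.sum(axis=0) == 0] = 0.0

        controls = Xk[yk == 0]
        hwe_p = np.ones(m)
        for j in range(m):
            col = controls[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                hwe_p[j] = np.nan
                continue
            hwe_p[j] = hwe_exact_test(
                int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
            )

        reason = np.array([""] * m, dtype=object)
        snp_removed = np.zeros(m, dtype=bool)
        steps = [
            ("call_rate", call_rate, self.snp_call_rate_min),
            ("maf", maf, self.maf_min),
            ("hwe", hwe_p, self.hwe_p_min),
        ]
        counts = {
            "input_samples": n,
            "input_snps": m,
            "removed_sample_completion": int(sample_removed.sum()),
        }
        for name, stat, threshold in steps:
            if threshold is None:
                counts[f"removed_{name}"] = 0
                continue
            with np.errstate(invalid="ignore"):
                fails = (stat < threshold) & ~snp_removed
            fails &= ~np.isnan(stat)
            reason[fails] = name
            snp_removed |= fails
            counts[f"removed_{name}"] = int(fails.sum())
        counts["retained_samples"] = n_kept
        counts["retained_snps"] = int((~snp_removed).sum())

        self.sample_mask_ = keep_s
        self.snp_mask_ = ~snp_removed
        self.report_ = QcReport(
            snp_stats=pd.DataFrame(
                {
                    "call_rate": call_rate,
                    "maf": maf,
                    "hwe_p": hwe_p,
                    "removed": snp_removed,
                    "reason": reason,
                },
                index=pd.Index(snp_ids, name="snp_id"),
            ),
            sample_stats=pd.DataFrame(
                {
                    "completion": completion,
                    "removed": sample_removed,
                    "reason": np.where(sample_removed, "completion", ""),
                },
                index=pd.Index(sample_ids, name="sample_id"),
            ),
            counts=counts,
        )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[np.ix_(self.sample_mask_, self.snp_mask_)]

    def fit_transform(self, X, y, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def apply_qc(
    dataset: GenotypeDataset, thresholds: QcThresholds | None = None
) -> tuple[GenotypeDataset, QcReport]:
    """Filter a dataset with :class:`GenotypeQC` and return it with the report."""
    thresholds = thresholds or QcThresholds()
    qc = GenotypeQC(
        snp_call_rate_min=thresholds.snp_call_rate_min,
        maf_min=thresholds.maf_min,
        hwe_p_min=thresholds.hwe_p_min,
        sample_completion_min=thresholds.sample_completion_min,
    ).fit(
        dataset.dosages,
        dataset.status,
        sample_ids=dataset.sample_ids,
        snp_ids=dataset.snp_ids,
    )
    filtered = dataset.subset_samples(qc.sample_mask_).subset_snps(qc.snp_mask_)
    return filtered, qc.report_
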