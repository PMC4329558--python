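import itertools
import math

import numpy as np
import pytest

from pathartp.qc import (
    GenotypeQC,
    QcThresholds,
    apply_qc,
    hwe_exact_test,
    minor_allele_frequency,
    snp_call_rate,
)


def enumeration_hwe_oracle(n_hom_major, n_het, n_hom_minor):
    """Brute-force exact HWE p: enumerate heterozygote counts with the same
    allele totals using exact rational probabilities."""
    from fractions import Fraction
    from math import factorial

    n = n_hom_major + n_het + n_hom_minor
    n_minor = 2 * n_hom_minor + n_het
    probs = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        probs[h] = Fraction(2**h, factorial(h) * factorial(hom_min) * factorial(hom_maj))
    total = sum(probs.values())
    p_obs = probs[n_het]
    return float(sum(v for v in probs.values() if v <= p_obs) / total)


class TestCallRateAndMaf:
    def test_call_rate_boundary_is_strict(self):
        col = np.array([0.0] * 9 + [np.nan])
        assert snp_call_rate(col) == pytest.approx(0.90)
        qc = GenotypeQC(maf_min=None, hwe_p_min=None, sample_completion_min=None)
        qc.fit(np.column_stack([col]), np.array([1] * 5 + [0] * 5))
        assert qc.snp_mask_[0]  # exactly 0.90 is retained (< removes)

    def test_call_rate_below_threshold_removed(self):
        col = np.array([0.0] * 8 + [np.nan] * 2)
        assert snp_call_rate(col) == pytest.approx(0.80)
        qc = GenotypeQC(maf_min=None, hwe_p_min=None, sample_completion_min=None)
        qc.fit(np.column_stack([col]), np.array([1] * 5 + [0] * 5))
        assert not qc.snp_mask_[0]
        assert qc.report_.snp_stats["reason"].iloc[0] == "call_rate"

    def test_all_missing_column(self):
        col = np.full(10, np.nan)
        assert snp_call_rate(col) == 0.0
        with pytest.raises(ValueError):
            minor_allele_frequency(col)

    def test_maf_arithmetic(self):
        assert minor_allele_frequency(np.array([0.0, 1, 2, 2])) == pytest.approx(0.375)

    def test_monomorphic_maf_zero(self):
        assert minor_allele_frequency(np.zeros(4)) == 0.0

    def test_maf_exact_boundary_retained(self):
        # 1 minor allele in 10 individuals = MAF 0.05 exactly
        col = np.array([1.0] + [0.0] * 9)
        assert minor_allele_frequency(col) == pytest.approx(0.05)
        qc = GenotypeQC(snp_call_rate_min=None, hwe_p_min=None,
                        sample_completion_min=None)
        qc.fit(np.column_stack([col]), np.array([1] * 5 + [0] * 5))
        assert qc.snp_mask_[0]


class TestHweExact:
    def test_all_hom_major_no_evidence(self):
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_matches_enumeration_oracle_spot(self):
        assert hwe_exact_test(4, 4, 4) == pytest.approx(
            enumeration_hwe_oracle(4, 4, 4), abs=1e-12
        )

    def test_extreme_het_excess_below_cut(self):
        assert hwe_exact_test(0, 40, 0) < 1e-4

    def test_zero_genotyped_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_exhaustive_sweep_total_le_30(self):
        """Exact test equals the enumeration oracle for every triple n<=30."""
        for n in range(1, 31):
            for a, b in itertools.combinations_with_replacement(range(n + 1), 2):
                c = n - a - b
                if c < 0:
                    continue
                got = hwe_exact_test(a, b, c)
                want = enumeration_hwe_oracle(a, b, c)
                assert got == pytest.approx(want, rel=1e-9), (a, b, c)


class TestApplyQc:
    def test_engineered_fixture_reason_codes(self, qc_fixture):
        ds, manifest = qc_fixture
        filtered, report = apply_qc(ds, QcThresholds())
        removed = report.snp_stats[report.snp_stats["removed"]]
        assert dict(removed["reason"]) == manifest["removed_snps"]
        assert len(removed) == manifest["n_removed_snps"]
        assert filtered.snp_ids == manifest["retained_snps"]
        bad = report.sample_stats[report.sample_stats["removed"]]
        assert list(bad.index) == manifest["removed_samples"]

    def test_counts_reconcile(self, qc_fixture):
        ds, _ = qc_fixture
        _, report = apply_qc(ds)
        c = report.counts
        assert c["retained_samples"] + c["removed_sample_completion"] == c["input_samples"]
        assert (
            c["retained_snps"] + c["removed_call_rate"] + c["removed_maf"]
            + c["removed_hwe"] == c["input_snps"]
        )

    def test_disabled_thresholds_identity(self, qc_fixture):
        ds, _ = qc_fixture
        filtered, report = apply_qc(
            ds, QcThresholds(0.0, 0.0, 0.0, 0.0)
        )
        assert filtered.equals(ds)
        assert report.n_snps_retained == ds.n_snps

    def test_sample_completion_boundary_retained(self):
        # 47/50 SNPs called = 0.94 exactly -> retained (strict <)
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(10, 50)).astype(float)
        X[0, :3] = np.nan
        qc = GenotypeQC(snp_call_rate_min=None, maf_min=None, hwe_p_min=None)
        qc.fit(X, np.array([1] * 5 + [0] * 5))
        assert qc.sample_mask_[0]
        X[0, 3] = np.nan  # 46/50 = 0.92 -> removed
        qc.fit(X, np.array([1] * 5 + [0] * 5))
        assert not qc.sample_mask_[0]

    def test_idempotent(self, qc_fixture):
        ds, _ = qc_fixture
        once, _ = apply_qc(ds)
        twice, report2 = apply_qc(once)
        assert twice.equals(once)
        assert report2.counts["retained_snps"] == once.n_snps

    def test_requires_a_control(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="control"):
            GenotypeQC().fit(X, np.ones(4, dtype=int))

    def test_maf_after_orientation_at_most_half(self, rng):
        from conftest import random_dataset

        ds = random_dataset(np.random.default_rng(11), n=60, m=20,
                            maf_low=0.2, maf_high=0.5)
        _, report = apply_qc(ds, QcThresholds(0.0, 0.0, 0.0, 0.0))
        assert (report.snp_stats["maf"] <= 0.5 + 1e-12).all()
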