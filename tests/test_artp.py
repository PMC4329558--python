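import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathartp.annotation import map_snps_to_genes
from pathartp.artp import (
    ArtpTest,
    artp_adjusted_p,
    artp_pathway_p,
    build_ensemble,
    build_exhaustive_ensemble,
    default_truncation,
    leave_gene_out,
    min_attainable_p,
    rtp_statistic,
    validate_truncation,
)
from pathartp.dataset import PathwayModel
from pathartp.simulate import (
    BlockConfig,
    EffectSnp,
    SimulationConfig,
    block_gene_models,
    simulate_cohort,
)
from bruteforce import brute_adjusted_p, brute_pathway_p


class TestRtpStatistic:
    def test_single_smallest(self):
        assert rtp_statistic([0.01, 0.5, 0.9], 1) == pytest.approx(-np.log(0.01))

    def test_all_ones_full_truncation(self):
        assert rtp_statistic([1.0, 1.0, 1.0], 3) == 0.0

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            rtp_statistic([0.0, 0.5], 1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        ps=st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1,
                    max_size=8),
        j=st.integers(1, 8),
    )
    def test_appending_p_of_one_never_changes(self, ps, j):
        j = min(j, len(ps))
        assert rtp_statistic(ps + [1.0], j) == pytest.approx(
            rtp_statistic(ps, j), rel=1e-12
        )

    def test_truncation_validation(self):
        with pytest.raises(ValueError):
            validate_truncation([2, 2, 3], 5)
        with pytest.raises(ValueError):
            validate_truncation([1, 6], 5)
        assert default_truncation(248) == tuple(range(1, 11))
        assert default_truncation(3) == (1, 2, 3)


class TestEnsemble:
    def test_deterministic_given_seed(self, exhaustive8):
        X, y = exhaustive8.dosages, exhaustive8.status
        a = build_ensemble(X, y, B=10, seed=5)
        b = build_ensemble(X, y, B=10, seed=5)
        assert np.array_equal(a.p_matrix, b.p_matrix)
        c = build_ensemble(X, y, B=10, seed=6)
        assert not np.array_equal(a.p_matrix, c.p_matrix)

    def test_row_zero_is_observed_score_test(self, exhaustive8):
        from pathartp.association import score_test_pvalues

        X, y = exhaustive8.dosages, exhaustive8.status
        ens = build_ensemble(X, y, B=20, seed=1)
        assert np.allclose(ens.p_matrix[0], score_test_pvalues(X, y), atol=1e-12)

    def test_exhaustive_has_70_rows(self, exhaustive8):
        ens = build_exhaustive_ensemble(exhaustive8.dosages, exhaustive8.status)
        assert ens.p_matrix.shape[0] == 70  # C(8,4)

    def test_large_b_matches_exhaustive_per_snp_p(self, exhaustive8):
        """Monte-Carlo per-SNP permutation p agrees with the exact exhaustive
        value within 3 binomial standard errors."""
        X, y = exhaustive8.dosages, exhaustive8.status
        exact = build_exhaustive_ensemble(X, y)
        B = 4000
        mc = build_ensemble(X, y, B=B, seed=11)
        for j in range(X.shape[1]):
            p_obs = exact.p_matrix[0, j]
            exact_p = np.mean(exact.p_matrix[:, j] <= p_obs + 1e-12)
            mc_p = np.mean(mc.p_matrix[:, j] <= p_obs + 1e-12)
            se = np.sqrt(exact_p * (1 - exact_p) / (B + 1))
            assert abs(mc_p - exact_p) <= 3 * se + 1e-9

    def test_degenerate_stratum_warns(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.3, (10, 3)).astype(float)
        y = np.array([1] * 5 + [0] * 5)
        strata = np.array(["a"] * 5 + ["b"] * 5)  # stratum a all cases
        with pytest.warns(UserWarning, match="single outcome class"):
            build_ensemble(X, y, B=5, seed=0, strata=strata)

    def test_stratified_shuffle_preserves_study_ratios(self):
        rng = np.random.default_rng(1)
        n = 40
        X = rng.binomial(2, 0.3, (n, 2)).astype(float)
        strata = np.array(["a"] * 20 + ["b"] * 20)
        y = np.array([1] * 15 + [0] * 5 + [1] * 5 + [0] * 15)
        # slow-path design: a covariate varying within strata
        from pathartp.association import CovariateDesign

        z = rng.normal(size=n)
        design = CovariateDesign(np.column_stack([np.ones(n), z]),
                                 ["intercept", "z"])
        ens = build_ensemble(X, y, design=design, B=8, seed=3, strata=strata)
        assert ens.p_matrix.shape == (9, 2)
        assert np.all((ens.p_matrix > 0) & (ens.p_matrix <= 1))


class TestArtpGene:
    def test_single_snp_single_truncation_reduces_to_permutation_p(self):
        rng = np.random.default_rng(10)
        col = rng.uniform(0.001, 1.0, size=201)[:, None]
        res = artp_adjusted_p(col, truncation=(1,))
        simple = np.mean(col[:, 0] <= col[0, 0])
        assert res.p_adjusted == pytest.approx(simple, abs=1e-15)

    def test_exhaustive_oracle_equality_three_snp_gene(self, exhaustive8):
        X, y = exhaustive8.dosages[:, :3], exhaustive8.status
        ens = build_exhaustive_ensemble(X, y)
        res = artp_adjusted_p(ens.p_matrix)
        want = brute_adjusted_p([list(r) for r in ens.p_matrix])
        assert res.p_adjusted == want  # exact equality

    def test_floor(self):
        B = 200
        rng = np.random.default_rng(2)
        P = rng.uniform(0.01, 1, (B + 1, 4))
        P[0] = 1e-12  # observed row uniquely extreme
        res = artp_adjusted_p(P)
        assert res.p_adjusted == pytest.approx(min_attainable_p(B))
        assert res.p_adjusted >= 1.0 / (B + 1)

    def test_monotone_in_observed_pvalues(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(0.001, 1, (101, 5))
        base = artp_adjusted_p(P).p_adjusted
        P2 = P.copy()
        P2[0] = P2[0] ** 0.25  # shift observed p toward 1
        assert artp_adjusted_p(P2).p_adjusted >= base

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            artp_adjusted_p(np.empty((5, 0)))


class TestArtpPathway:
    def _exhaustive_setup(self, exhaustive8):
        ds = exhaustive8
        ens = build_exhaustive_ensemble(ds.dosages, ds.status,
                                        snp_ids=ds.snp_ids)
        gmap = {f"GENE{i}": ds.snp_ids[2 * i:2 * i + 2] for i in range(3)}
        pathway = PathwayModel("pw", tuple(gmap))
        return ds, ens, gmap, pathway

    def test_one_gene_pathway_reduces_to_gene_p(self, exhaustive8):
        ds, ens, gmap, _ = self._exhaustive_setup(exhaustive8)
        one = PathwayModel("pw", ("GENE0",))
        pres, gres = artp_pathway_p(ens, {"GENE0": gmap["GENE0"]}, one)
        assert pres.p_adjusted == gres["GENE0"].p_adjusted

    def test_exhaustive_oracle_equality_full_pathway(self, exhaustive8):
        ds, ens, gmap, pathway = self._exhaustive_setup(exhaustive8)
        pres, gres = artp_pathway_p(ens, gmap, pathway)
        cols = [[ds.snp_ids.index(s) for s in gmap[g]] for g in pathway.genes]
        want_p, want_gene_rows = brute_pathway_p(
            [list(r) for r in ens.p_matrix], cols
        )
        assert pres.p_adjusted == want_p  # exact equality
        for gi, g in enumerate(pathway.genes):
            assert gres[g].p_adjusted == want_gene_rows[0][gi]

    def test_estimator_interface(self, exhaustive8):
        ds = exhaustive8
        gmap = {f"GENE{i}": ds.snp_ids[2 * i:2 * i + 2] for i in range(3)}
        est = ArtpTest(gene_snp_map=gmap, B=50, seed=9).fit(
            ds.dosages, ds.status, snp_ids=ds.snp_ids
        )
        assert set(est.gene_results_.index) == set(gmap)
        assert 0 < est.pathway_result_.p_adjusted <= 1
        assert est.get_params()["B"] == 50


class TestLeaveGeneOut:
    def _planted(self):
        cfg = SimulationConfig(
            n_cases=150, n_controls=150,
            blocks=[BlockConfig(3, (0.25, 0.35), 0.2) for _ in range(4)],
            effect_snps=[EffectSnp(0, 1, 2.5)],
            seed=21,
        )
        ds, truth = simulate_cohort(cfg)
        genes, pathway = block_gene_models(cfg)
        gmap = map_snps_to_genes(ds.snps, genes)
        ens = build_ensemble(ds.dosages, ds.status, B=300, seed=4,
                             snp_ids=ds.snp_ids)
        return ds, ens, gmap, pathway, truth

    def test_excluding_gene_leaves_others_unchanged(self):
        ds, ens, gmap, pathway, _ = self._planted()
        _, before = artp_pathway_p(ens, gmap, pathway)
        _, after = leave_gene_out(ens, gmap, pathway, ["GENE3"])
        for g in ("GENE0", "GENE1", "GENE2"):
            assert after[g].p_adjusted == before[g].p_adjusted

    def test_excluding_planted_gene_raises_pathway_p(self):
        ds, ens, gmap, pathway, truth = self._planted()
        full, gres = artp_pathway_p(ens, gmap, pathway)
        assert gres["GENE0"].p_adjusted == min(r.p_adjusted for r in gres.values())
        reduced, _ = leave_gene_out(ens, gmap, pathway, ["GENE0"])
        assert reduced.p_adjusted > full.p_adjusted

    def test_shared_snp_removed_from_both_genes(self, exhaustive8):
        ds = exhaustive8
        ens = build_exhaustive_ensemble(ds.dosages, ds.status,
                                        snp_ids=ds.snp_ids)
        shared = ds.snp_ids[2]
        gmap = {
            "A": ds.snp_ids[:2] + [shared],
            "B": [shared] + ds.snp_ids[3:4],
            "C": ds.snp_ids[4:6],
        }
        pathway = PathwayModel("pw", ("A", "B", "C"))
        _, gres = leave_gene_out(ens, gmap, pathway, ["A"])
        assert "A" not in gres
        assert gres["B"].n_items == 1  # shared SNP gone from B too

    def test_removing_all_genes_rejected(self, exhaustive8):
        ds = exhaustive8
        ens = build_exhaustive_ensemble(ds.dosages, ds.status,
                                        snp_ids=ds.snp_ids)
        gmap = {"A": ds.snp_ids[:2]}
        with pytest.raises(ValueError):
            leave_gene_out(ens, gmap, PathwayModel("pw", ("A",)), ["A"])
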