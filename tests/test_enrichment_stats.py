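import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats


from synviab import cohort_classify as cc
from synviab import enrichment_stats as es
from synviab.cytoband_cna import build_call_matrix

from .oracles import bh_step_up, fisher_two_sided, hypergeom_upper_tail


class TestBHAdjust:
    def test_worked_example(self):
        q = es.bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert es.bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_one(self):
        assert (es.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_step_up_definition_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            q = es.bh_adjust(p)
            assert np.allclose(q, bh_step_up(list(p)), atol=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, sm, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_monotone_and_permutation_invariant(self, pvals, rnd):
        p = np.array(pvals)
        q = es.bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        q_perm = es.bh_adjust(p[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            es.bh_adjust([0.5, 1.5])


class TestFisherKernels:
    def test_margin_lookup_matches_scipy(self):
        for n_case, n_ctrl, m in [(10, 10, 10), (5, 9, 3), (12, 4, 8),
                                  (7, 7, 0), (3, 3, 6)]:
            support, p = es.two_sided_fisher_from_margins(n_case, n_ctrl, m)
            for a, pv in zip(support, p):
                table = [[a, n_case - a], [m - a, n_ctrl - (m - a)]]
                assert pv == pytest.approx(stats.fisher_exact(table)[1],
                                           abs=1e-12)

    def test_against_enumeration_oracle_small_margins(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        assert es.fisher_test_2x2(a, b, c, d) == pytest.approx(
                            fisher_two_sided(a, b, c, d), abs=1e-10)


class TestEnrichment:
    def test_planted_bands_recovered(self, default_sim):
        bundle, truth = default_sim
        groups = cc.group_map(bundle.samples)
        m = build_call_matrix(bundle)
        res = es.fisher_cytoband_enrichment(m, groups, "deletion")
        flagged = set(res.loc[res["enriched"], "band"])
        assert truth.enriched_cytobands <= flagged
        planted = res[res["band"].isin(truth.enriched_cytobands)]
        assert (planted["case_freq"] > planted["control_freq"]).all()
        # spot-check p against the exact oracle on five planted bands
        for row in planted.head(5).itertuples():
            assert row.p == pytest.approx(
                fisher_two_sided(row.a, row.b, row.c, row.d), abs=1e-10)

    def test_unaltered_band_not_enriched(self, default_sim):
        bundle, _ = default_sim
        groups = cc.group_map(bundle.samples)
        m = build_call_matrix(bundle)
        res = es.fisher_cytoband_enrichment(m, groups, "amplification")
        assert (res["p"] == 1.0).all()
        assert not res["enriched"].any()

    def test_toy_counts(self):
        assert es.fisher_test_2x2(8, 2, 2, 8) == pytest.approx(0.0230, abs=5e-5)


class TestPermuteFixedMargins:
    def test_all_ones_matrix_is_fixed_point(self):
        mat = np.ones((4, 5), dtype=np.int8)
        outs = list(es.permute_fixed_margins(mat, 10, seed=0))
        assert all((o == mat).all() for o in outs)

    def test_two_by_two_reaches_both_states(self):
        mat = np.array([[1, 0], [0, 1]], dtype=np.int8)
        seen = set()
        for o in es.permute_fixed_margins(mat, 1000, seed=1, burn_in=4, thin=2):
            assert (o.sum(0) == 1).all() and (o.sum(1) == 1).all()
            seen.add(tuple(o.ravel()))
        assert seen == {(1, 0, 0, 1), (0, 1, 1, 0)}

    def test_margins_preserved_on_random_matrix(self):
        rng = np.random.default_rng(7)
        mat = (rng.random((60, 40)) < 0.25).astype(np.int8)
        for o in es.permute_fixed_margins(mat, 50, seed=2):
            assert (o.sum(axis=0) == mat.sum(axis=0)).all()
            assert (o.sum(axis=1) == mat.sum(axis=1)).all()
            assert np.isin(o, (0, 1)).all()

    def test_non_binary_matrix_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            list(es.permute_fixed_margins(np.array([[2, 0], [0, 1]]), 1, 0))


class TestEmpiricalP:
    def test_add_one_formula(self):
        assert es.empirical_p_from_counts(0, 999) == pytest.approx(0.001)
        assert es.empirical_p_from_counts(999, 999) == pytest.approx(1.0)

    def test_all_ones_matrix_p_is_one(self):
        mat = np.ones((6, 8), dtype=np.int8)
        res = es.permutation_empirical_p(mat, case_cols=np.arange(4),
                                         n_perm=50, seed=0)
        assert res.empirical_p == 1.0

    def test_fast_lookup_agrees_with_full_fisher(self, small_sim):
        bundle, _ = small_sim
        groups = cc.group_map(bundle.samples)
        m = build_call_matrix(bundle)
        res_fisher = es.fisher_cytoband_enrichment(m, groups, "deletion")
        res_perm = es.permutation_empirical_p(m, groups, n_perm=5, seed=0)
        assert res_perm.observed == int(res_fisher["enriched"].sum())

    def test_reused_threshold_mode_runs(self, small_sim):
        bundle, _ = small_sim
        groups = cc.group_map(bundle.samples)
        m = build_call_matrix(bundle)
        res = es.permutation_empirical_p(m, groups, n_perm=20, seed=1,
                                         recompute_bh=False)
        assert 0 < res.empirical_p <= 1


class TestGenesetOverlap:
    def test_identical_sets_p_one(self):
        u = {f"g{i}" for i in range(30)}
        k, tail, two = es.geneset_overlap_test(u, u, u)
        assert k == 30 and tail == pytest.approx(1.0)

    def test_disjoint_sets_tail_one(self):
        u = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(10, 20)}
        k, tail, _ = es.geneset_overlap_test(a, b, u)
        assert k == 0 and tail == pytest.approx(1.0)

    def test_overlap_matches_enumerated_tail(self):
        u = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(5, 25)}
        k, tail, _ = es.geneset_overlap_test(a, b, u)
        assert k == 5
        assert tail == pytest.approx(hypergeom_upper_tail(5, 100, 10, 20),
                                     rel=1e-10)

    def test_empty_universe_fatal(self):
        with pytest.raises(ValueError, match="universe"):
            es.geneset_overlap_test(set(), set(), set())


class TestGenesInEnrichedLoci:
    def _setup(self):
        import pandas as pd
        bands = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 200],
            "name": ["1q1", "1q2"], "stain": ["", ""]})
        results = pd.DataFrame({"band": ["1q1", "1q2"],
                                "enriched": [True, False]})
        return bands, results

    def test_gene_inside_enriched_band_included(self):
        import pandas as pd
        bands, results = self._setup()
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [50],
                              "gene": ["A"]})
        assert es.genes_in_enriched_loci(results, genes, bands) == {"A"}

    def test_straddling_gene_included(self):
        import pandas as pd
        bands, results = self._setup()
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [150],
                              "gene": ["B"]})
        assert es.genes_in_enriched_loci(results, genes, bands) == {"B"}

    def test_no_enriched_bands_empty(self):
        import pandas as pd
        bands, results = self._setup()
        results["enriched"] = False
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [50],
                              "gene": ["A"]})
        assert es.genes_in_enriched_loci(results, genes, bands) == set()

    def test_gene_on_unknown_chromosome_skipped(self, caplog):
        import logging
        import pandas as pd
        bands, results = self._setup()
        genes = pd.DataFrame({"chrom": ["chr9"], "start": [10], "end": [50],
                              "gene": ["C"]})
        with caplog.at_level(logging.WARNING, logger="synviab"):
            out = es.genes_in_enriched_loci(results, genes, bands)
        assert out == set() and "skipped" in caplog.text
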