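import math

import numpy as np
import pandas as pd
import pytest

from synviab import SimulationConfig, simulate_dataset
from synviab import cohort_classify as cc
from synviab import expression_tcs as tcs
from synviab.cytoband_cna import build_call_matrix


class TestDichotomize:
    def test_strictly_below_median(self):
        expr = pd.DataFrame([[1, 2, 3, 4]], index=["g"],
                            columns=list("abcd"))
        low = tcs.dichotomize_expression(expr)
        assert list(low.loc["g"]) == [True, True, False, False]

    def test_constant_gene_has_no_low_samples(self):
        expr = pd.DataFrame([[5, 5, 5, 5]], index=["g"], columns=list("abcd"))
        assert not tcs.dichotomize_expression(expr).loc["g"].any()

    def test_two_samples(self):
        expr = pd.DataFrame([[0, 10]], index=["g"], columns=["a", "b"])
        assert list(tcs.dichotomize_expression(expr).loc["g"]) == [True, False]

    def test_even_distinct_values_split_in_half(self):
        rng = np.random.default_rng(1)
        vals = rng.permutation(np.arange(10, dtype=float))
        expr = pd.DataFrame([vals], index=["g"],
                            columns=[f"s{i}" for i in range(10)])
        assert tcs.dichotomize_expression(expr).loc["g"].sum() == 5

    def test_ties_at_median_assign_fewer_than_half_low(self):
        expr = pd.DataFrame([[1, 2, 2, 2, 3, 4]], index=["g"],
                            columns=list("abcdef"))
        assert tcs.dichotomize_expression(expr).loc["g"].sum() < 3


def _toy(gene_low, deletion, groups):
    """Helper: one-gene low/high matrix + deletion series + groups."""
    samples = list(deletion)
    low = pd.DataFrame([[gene_low[s] for s in samples]], index=["g"],
                       columns=samples)
    dele = pd.Series({s: deletion[s] for s in samples}, dtype=float)
    return low, dele, groups


class TestComputeTCS:
    def test_worked_example_four_of_five(self):
        """Five deletion-bearing case tumors, four below the cohort median."""
        deletion = {f"c{i}": 1.0 for i in range(5)}
        deletion.update({f"k{i}": 0.0 for i in range(5)})
        lowness = {f"c{i}": i < 4 for i in range(5)}
        lowness.update({f"k{i}": False for i in range(5)})
        groups = {f"c{i}": "case" for i in range(5)}
        groups.update({f"k{i}": "control" for i in range(5)})
        low, dele, groups = _toy(lowness, deletion, groups)
        g = tcs.compute_tcs("g", low, dele, groups)
        assert g.tcs == pytest.approx(0.8)
        assert g.n_case_deleted == 5

    def test_below_minimum_deleted_is_missing(self):
        deletion = {f"c{i}": float(i < 4) for i in range(8)}
        deletion.update({"k0": 0.0})
        lowness = {s: True for s in deletion}
        groups = {f"c{i}": "case" for i in range(8)}
        groups["k0"] = "control"
        low, dele, groups = _toy(lowness, deletion, groups)
        g = tcs.compute_tcs("g", low, dele, groups)
        assert g.tcs is None and g.passes is False

    def test_normalization_ratio(self):
        # 4/5 deleted cases low; 3/10 non-deleted controls low
        deletion = {f"c{i}": 1.0 for i in range(5)}
        deletion.update({f"k{i}": 0.0 for i in range(10)})
        lowness = {f"c{i}": i < 4 for i in range(5)}
        lowness.update({f"k{i}": i < 3 for i in range(10)})
        groups = {f"c{i}": "case" for i in range(5)}
        groups.update({f"k{i}": "control" for i in range(10)})
        low, dele, groups = _toy(lowness, deletion, groups)
        g = tcs.compute_tcs("g", low, dele, groups)
        assert g.control_tcs == pytest.approx(0.3)
        assert g.normalized_tcs == pytest.approx(0.8 / 0.3)
        assert g.passes is True

    def test_zero_control_tcs_gives_infinity(self):
        deletion = {f"c{i}": 1.0 for i in range(5)}
        deletion.update({f"k{i}": 0.0 for i in range(5)})
        lowness = {f"c{i}": True for i in range(5)}
        lowness.update({f"k{i}": False for i in range(5)})
        groups = {f"c{i}": "case" for i in range(5)}
        groups.update({f"k{i}": "control" for i in range(5)})
        low, dele, groups = _toy(lowness, deletion, groups)
        g = tcs.compute_tcs("g", low, dele, groups)
        assert g.normalized_tcs == math.inf and g.passes is True

    def test_threshold_boundaries_are_strict(self):
        # tcs = 0.70 exactly: 7 low of 10 deleted -> fails
        deletion = {f"c{i}": 1.0 for i in range(10)}
        deletion.update({f"k{i}": 0.0 for i in range(10)})
        lowness = {f"c{i}": i < 7 for i in range(10)}
        lowness.update({f"k{i}": i < 1 for i in range(10)})
        groups = {f"c{i}": "case" for i in range(10)}
        groups.update({f"k{i}": "control" for i in range(10)})
        low, dele, groups = _toy(lowness, deletion, groups)
        g = tcs.compute_tcs("g", low, dele, groups)
        assert g.tcs == pytest.approx(0.7) and g.passes is False

    def test_missing_cells_drop_from_both_sides(self):
        deletion = {f"c{i}": 1.0 for i in range(5)}
        deletion["c5"] = np.nan
        deletion.update({f"k{i}": 0.0 for i in range(4)})
        deletion["k4"] = np.nan
        lowness = {s: True for s in deletion}
        groups = {f"c{i}": "case" for i in range(6)}
        groups.update({f"k{i}": "control" for i in range(5)})
        low, dele, groups = _toy(lowness, deletion, groups)
        g = tcs.compute_tcs("g", low, dele, groups)
        assert g.n_case_deleted == 5  # the NaN case does not count


class TestGeneDeletionStatus:
    def test_midpoint_rule(self, small_sim):
        bundle, _ = small_sim
        m = build_call_matrix(bundle)
        gene = bundle.genes.iloc[0]
        status = tcs.gene_deletion_status(gene, m, bundle.cytobands)
        band_row = 0  # first gene sits in the first band by construction
        expected = m.deletion_matrix()[band_row].astype(float)
        assert np.allclose(status.to_numpy(), expected, equal_nan=True)

    def test_straddling_gene_follows_midpoint(self):
        import synviab.cytoband_cna as cna
        bands = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 100],
                              "end": [100, 200], "name": ["1q1", "1q2"],
                              "stain": ["", ""]})
        status = np.array([[cna.DELETED], [cna.NEUTRAL]], dtype=np.int8)
        m = cna.CytobandCallMatrix(bands=["1q1", "1q2"], samples=["S"],
                                   cn=np.array([[1.0], [2.0]]), status=status)
        gene = {"chrom": "chr1", "start": 80, "end": 130, "gene": "A"}
        # midpoint 105 -> second band -> not deleted
        out = tcs.gene_deletion_status(gene, m, bands)
        assert out["S"] == 0.0

    def test_midpoint_outside_bands_missing(self):
        import synviab.cytoband_cna as cna
        bands = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                              "name": ["1q1"], "stain": [""]})
        m = cna.CytobandCallMatrix(bands=["1q1"], samples=["S"],
                                   cn=np.array([[2.0]]),
                                   status=np.array([[cna.NEUTRAL]],
                                                   dtype=np.int8))
        gene = {"chrom": "chr1", "start": 500, "end": 600, "gene": "A"}
        assert tcs.gene_deletion_status(gene, m, bands).isna().all()


class TestSelection:
    def test_empty_restriction_empty_result(self):
        df = pd.DataFrame({"gene": ["a"], "passes": [True]})
        assert tcs.select_consistent_genes(df, set()) == set()

    def test_noiseless_selection_equals_truth(self, noiseless_sim):
        bundle, truth = noiseless_sim
        groups = cc.group_map(bundle.samples)
        m = build_call_matrix(bundle)
        table = tcs.tcs_table(bundle.expression, bundle.genes, m,
                              bundle.cytobands, groups)
        selected = set(table.loc[table["passes"], "gene"])
        assert selected == truth.coupled_genes

    def test_no_effect_keeps_false_pass_rate_low(self):
        cfg = SimulationConfig(seed=31, expr_effect=0.0)
        bundle, _ = simulate_dataset(cfg)
        groups = cc.group_map(bundle.samples)
        m = build_call_matrix(bundle)
        table = tcs.tcs_table(bundle.expression, bundle.genes, m,
                              bundle.cytobands, groups)
        assert table["passes"].mean() <= 0.05


def test_table_matches_scalar_path(small_sim):
    bundle, _ = small_sim
    groups = cc.group_map(bundle.samples)
    m = build_call_matrix(bundle)
    table = tcs.tcs_table(bundle.expression, bundle.genes, m,
                          bundle.cytobands, groups).set_index("gene")
    low = tcs.dichotomize_expression(bundle.expression)
    for _, gene in bundle.genes.sample(12, random_state=0).iterrows():
        dele = tcs.gene_deletion_status(gene, m, bundle.cytobands)
        g = tcs.compute_tcs(gene["gene"], low, dele, groups)
        row = table.loc[gene["gene"]]
        assert g.n_case_deleted == row["n_case_deleted"]
        if g.tcs is None:
            assert np.isnan(row["tcs"])
        else:
            assert g.tcs == pytest.approx(row["tcs"])
            if g.normalized_tcs is not None:
                assert (row["normalized_tcs"] == g.normalized_tcs
                        or row["normalized_tcs"] == pytest.approx(
                            g.normalized_tcs))
        assert bool(row["passes"]) == g.passes
    assert ((table["tcs"].dropna() >= 0) & (table["tcs"].dropna() <= 1)).all()
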