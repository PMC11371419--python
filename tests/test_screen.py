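"""Within-gene FDR, screen ingestion, matrix assembly, bias check."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoconverge.phylo import TimeTree, branch_key
from ecoconverge.screen import (
    SelectionMatrix,
    apply_fdr,
    bh_adjust,
    branch_bias_check,
    branch_metadata,
    build_selection_matrix,
    fdr_within_gene,
    read_screen_results,
)


def bh_oracle(p):
    """Direct step-up formula: q(i) = min_{j>=i} p(j)*m/j on sorted p."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        q[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_pos, m)), 1.0
        )
    return q


class TestBH:
    def test_single_value(self):
        assert fdr_within_gene([0.01]) == [0.01]

    def test_worked_example(self):
        assert fdr_within_gene([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])

    def test_equal_p_fixed_point(self):
        assert fdr_within_gene([0.5] * 4) == pytest.approx([0.5] * 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_within_gene([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_within_gene([0.2, 1.2])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_step_up_oracle(self, p):
        assert bh_adjust(p).tolist() == pytest.approx(bh_oracle(p), abs=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            q_sm = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(q_sm, abs=1e-12)


def _toy_tree_and_meta():
    tree = TimeTree.from_newick("((A:1,B:1):2,(C:2,D:2):1);")
    eco = {"A": "gleaner", "B": "trawler", "C": "gleaner", "D": "outgroup"}
    return tree, branch_metadata(tree, eco)


class TestReaders:
    def test_tsv_reader(self, tmp_path):
        tree, _ = _toy_tree_and_meta()
        path = tmp_path / "screen.tsv"
        path.write_text("gene\tbranch\tp\ng1\tA\t0.01\ng1\tA|B\t0.4\ng2\tZ\t0.2\n")
        records, unresolved = read_screen_results([path], tree)
        assert len(records) == 2
        assert unresolved == [("g2", "Z")]

    def test_native_json_reader(self, tmp_path):
        tree, _ = _toy_tree_and_meta()
        payload = {
            "input": {"file name": "g7"},
            "branch attributes": {
                "0": {
                    "A": {"Uncorrected P-value": 0.001, "Corrected P-value": 0.004},
                    "B": {"Uncorrected P-value": 0.8, "Corrected P-value": 1.0},
                    "A|B": {"Uncorrected P-value": 0.2, "Corrected P-value": 0.4},
                    "C": {"other": 1},
                    "D": {"Uncorrected P-value": 0.5, "Corrected P-value": 0.9},
                    "Node99": {"Uncorrected P-value": 0.3},
                }
            },
        }
        path = tmp_path / "g7.json"
        path.write_text(json.dumps(payload))
        records, unresolved = read_screen_results([path], tree, dialect="native")
        assert len(records) == 4  # C has no p; Node99 unresolved
        assert ("g7", "Node99") in unresolved
        corrected, _ = read_screen_results([path], tree, dialect="native", use_corrected=True)
        assert {round(p, 3) for _, _, p in corrected} == {0.004, 1.0, 0.4, 0.9}

    def test_round_trip_synthetic_writer(self, small_sim, tmp_path):
        from ecoconverge.synth import write_dataset

        paths = write_dataset(small_sim, tmp_path)
        records, unresolved = read_screen_results([paths["screen"]], small_sim.tree)
        assert not unresolved
        original = {(g, b): p for g, b, p in small_sim.screen_records}
        recovered = {(g, b): p for g, b, p in records}
        assert set(recovered) == set(original)
        for key, p in recovered.items():
            assert p == pytest.approx(original[key], rel=1e-6)


class TestMatrix:
    def test_threshold_call(self):
        tree, meta = _toy_tree_and_meta()
        # p = (0.02, 0.06) -> BH q = (0.04, 0.06); at alpha 0.05 only the
        # first branch is called
        records = [("g1", frozenset("A"), 0.02), ("g1", frozenset("B"), 0.06)]
        calls = apply_fdr(records, alpha=0.05)
        by_branch = {branch_key(c.branch): c for c in calls}
        assert by_branch["A"].q == pytest.approx(0.04)
        assert by_branch["B"].q == pytest.approx(0.06)
        assert by_branch["A"].selected and not by_branch["B"].selected

    def test_absent_distinct_from_not_selected(self):
        tree, meta = _toy_tree_and_meta()
        calls = apply_fdr([("g1", frozenset("A"), 0.001)])
        matrix = build_selection_matrix(calls, meta, genes=["g1", "g_empty"])
        assert matrix.data.loc["g1", "A"] == 1.0
        assert np.isnan(matrix.data.loc["g1", "B"])
        assert matrix.data.loc["g_empty"].isna().all()

    def test_fdr_stays_within_gene(self):
        # one gene with many high p-values must not drag down another
        # gene's single strong signal
        records = [("hot", frozenset("A"), 0.001)] + [
            ("cold", fs, 0.9)
            for fs in (frozenset("B"), frozenset("C"), frozenset("D"))
        ]
        calls = apply_fdr(records, alpha=0.05)
        assert {c.gene: c.selected for c in calls if c.gene == "hot"}["hot"]
        q_cold = [c.q for c in calls if c.gene == "cold"]
        assert q_cold == pytest.approx([0.9, 0.9, 0.9])

    def test_selected_counts_match_recount(self, small_sim):
        matrix = small_sim.matrix
        calls = apply_fdr(small_sim.screen_records, alpha=small_sim.config.alpha)
        counts = {}
        for c in calls:
            if c.selected:
                counts[branch_key(c.branch)] = counts.get(branch_key(c.branch), 0) + 1
        for key in matrix.branch_keys:
            assert int((matrix.data[key] == 1.0).sum()) == counts.get(key, 0)

    def test_order_permutation_invariance(self, small_sim, rng):
        records = list(small_sim.screen_records)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        m1 = build_selection_matrix(
            apply_fdr(records), small_sim.matrix.meta, genes=small_sim.matrix.genes
        )
        m2 = build_selection_matrix(
            apply_fdr(shuffled), small_sim.matrix.meta, genes=small_sim.matrix.genes
        )
        pd.testing.assert_frame_equal(m1.data.sort_index(), m2.data.sort_index())

    def test_tsv_round_trip(self, small_sim, tmp_path):
        path = tmp_path / "matrix.tsv"
        small_sim.matrix.to_tsv(path)
        back = SelectionMatrix.from_tsv(path, small_sim.matrix.meta)
        pd.testing.assert_frame_equal(back.data, small_sim.matrix.data)


class TestBiasCheck:
    def test_perfectly_proportional(self):
        tree, meta = _toy_tree_and_meta()
        # craft counts: selected = 0.5 * tested exactly
        genes = [f"g{i}" for i in range(8)]
        data = pd.DataFrame(np.nan, index=genes, columns=list(meta.index))
        tested_per_branch = [2, 4, 6, 8, 4, 6]
        for j, key in enumerate(data.columns):
            t = tested_per_branch[j]
            for i in range(t):
                data.iloc[i, j] = 1.0 if i < t // 2 else 0.0
        fit = branch_bias_check(SelectionMatrix(data, meta))
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        tree, meta = _toy_tree_and_meta()
        genes = [f"g{i}" for i in range(6)]
        data = pd.DataFrame(np.nan, index=genes, columns=list(meta.index))
        for j, key in enumerate(data.columns):
            for i in range(j + 1):
                data.iloc[i, j] = 0.0
        fit = branch_bias_check(SelectionMatrix(data, meta))
        assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.p == 1.0

    def test_matches_normal_equations(self, small_sim):
        fit = branch_bias_check(small_sim.matrix)
        x = small_sim.matrix.data.notna().sum(axis=0).to_numpy(float)
        y = (small_sim.matrix.data == 1.0).sum(axis=0).to_numpy(float)
        n = x.size
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        ss_res = ((y - intercept - slope * x) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)
        assert fit.df == (1, n - 2)
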