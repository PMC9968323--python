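"""Ancestry deconvolution: similarity, assignment, forest, decay, saturation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epilineage import (
    CellFingerprint,
    SimConfig,
    assign_ancestors,
    build_forest,
    pairwise_similarity,
    saturation_curve,
    similarity_decay,
    simulate_experiment,
)
from epilineage.lineage import fingerprints_from_table


def fp(cell_id, barcodes, tp="Day0"):
    return CellFingerprint(cell_id, tp, frozenset(barcodes))


class TestPairwiseSimilarity:
    def test_partial_overlap(self):
        rec = pairwise_similarity(fp("a", {"b1", "b2", "b3"}), fp("b", {"b1", "b2"}, "Day5"))
        assert rec.shared == 2
        assert rec.jaccard == pytest.approx(2 / 3)
        assert rec.containment_in_child == pytest.approx(1.0)

    def test_identical_sets(self):
        rec = pairwise_similarity(fp("a", {"x", "y"}), fp("b", {"x", "y"}, "Day5"))
        assert (rec.shared, rec.jaccard, rec.containment_in_child) == (2, 1.0, 1.0)

    def test_disjoint_sets_are_all_zero(self):
        rec = pairwise_similarity(fp("a", {"x"}), fp("b", {"y"}, "Day5"))
        assert (rec.shared, rec.jaccard, rec.containment_in_child) == (0, 0.0, 0.0)

    def test_empty_fingerprint_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_similarity(fp("a", set()), fp("b", {"x"}, "Day5"))

    @settings(max_examples=100, deadline=None)
    @given(
        st.frozensets(st.integers(0, 30), min_size=1, max_size=15),
        st.frozensets(st.integers(0, 30), min_size=1, max_size=15),
    )
    def test_bounds_hold_for_any_fingerprints(self, a, b):
        rec = pairwise_similarity(fp("a", map(str, a)), fp("b", map(str, b), "Day5"))
        assert rec.shared <= min(len(a), len(b))
        assert 0.0 <= rec.jaccard <= rec.containment_in_child <= 1.0
        if a == b:
            assert rec.jaccard == 1.0
        if not a & b:
            assert rec.shared == 0 and rec.jaccard == 0.0


class TestAssignAncestors:
    def test_unique_best_is_assigned(self):
        earlier = [fp("X", set("abcdef")), fp("Y", set("uvwxyz"))]
        later = [fp("c1", set("abcde"), "Day5")]
        a = assign_ancestors(earlier, later, min_shared=3, min_margin=1)
        assert a.records["c1"].ancestor == "X"
        assert a.records["c1"].status == "assigned"

    def test_exact_tie_is_ambiguous(self):
        earlier = [fp("X", set("abcdmn")), fp("Y", set("abcdpq"))]
        later = [fp("c1", set("abcd"), "Day5")]
        a = assign_ancestors(earlier, later, min_shared=3, min_margin=1)
        assert a.records["c1"].ancestor is None
        assert a.records["c1"].status == "ambiguous"

    def test_below_threshold_recorded(self):
        earlier = [fp("X", set("ab")), fp("Y", set("yz"))]
        later = [fp("c1", set("ax"), "Day5")]
        a = assign_ancestors(earlier, later, min_shared=3, min_margin=1)
        assert a.records["c1"].status == "below_threshold"

    def test_identical_timepoints_rejected(self):
        with pytest.raises(ValueError):
            assign_ancestors([fp("X", {"a"})], [fp("c1", {"a"}, "Day0")])

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_exhaustive_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"b{i}" for i in range(40)]
        earlier = [
            fp(f"E{i}", rng.choice(pool, size=rng.integers(3, 15), replace=False))
            for i in range(8)
        ]
        later = [
            fp(f"L{i}", rng.choice(pool, size=rng.integers(1, 10), replace=False), "Day5")
            for i in range(32)
        ]
        min_shared, min_margin = 2, 1
        result = assign_ancestors(earlier, later, min_shared, min_margin)
        for child in later:
            # oracle: enumerate all candidates with plain set arithmetic
            scores = []
            for anc in earlier:
                shared = len(anc.barcodes & child.barcodes)
                jac = shared / len(anc.barcodes | child.barcodes)
                scores.append((shared, jac, anc.cell_id))
            scores.sort(key=lambda t: (-t[0], -t[1], t[2]))
            best_shared, best_jac, best_id = scores[0]
            runner_shared = scores[1][0]
            expected = None
            if best_shared >= min_shared and best_shared - runner_shared >= min_margin:
                if (scores[1][0], scores[1][1]) != (best_shared, best_jac):
                    expected = best_id
            assert result.records[child.cell_id].ancestor == expected

    def test_recovers_true_founders_on_reference_simulation(self, reference_tracing_run):
        _config, lineage, observations, sampled_generation = reference_tracing_run
        earlier = [
            fp(c, observations[c], "Day0")
            for c, g in sampled_generation.items()
            if g == 0 and observations[c]
        ]
        later = [
            fp(c, observations[c], "Day5")
            for c, g in sampled_generation.items()
            if g == 4 and observations[c]
        ]
        result = assign_ancestors(earlier, later, min_shared=3, min_margin=2)
        assigned = result.assigned
        assert assigned
        correct = sum(
            1 for child, rec in assigned.items() if lineage.founder_of(child) == rec.ancestor
        )
        assert correct / len(assigned) >= 0.95

    def test_unassigned_fraction_grows_as_capture_drops(self):
        fractions = []
        for capture in (1.0, 0.8, 0.6, 0.4):
            config = SimConfig(
                n_founders=8,
                episomes_per_founder=50,
                replication_prob=0.0,
                capture_efficiency=capture,
                reads_per_cell=1,
                seed=29,
            )
            _lin, obs, gens, _b = simulate_experiment(config, 4, [0, 4])
            earlier = [fp(c, obs[c], "Day0") for c, g in gens.items() if g == 0 and obs[c]]
            later = [fp(c, obs[c], "Day5") for c, g in gens.items() if g == 4 and obs[c]]
            result = assign_ancestors(earlier, later, min_shared=3, min_margin=2)
            n_later = len(later)
            unassigned = n_later - len(result.assigned)
            fractions.append((unassigned / n_later, n_later))
        for (f1, n1), (f2, n2) in zip(fractions, fractions[1:]):
            se = math.sqrt(f1 * (1 - f1) / n1 + f2 * (1 - f2) / n2)
            assert f2 >= f1 - 3 * se


class TestBuildForest:
    def _toy_assignments(self):
        earlier = [fp("A1", set("abcdef")), fp("A2", set("uvwxyz"))]
        later = [
            fp("B1", set("abcd"), "Day5"),
            fp("B2", set("cdef"), "Day5"),
            fp("B3", set("wxyz"), "Day5"),
        ]
        return assign_ancestors(earlier, later, min_shared=3, min_margin=1)

    def test_toy_forest_has_correct_edges(self):
        forest = build_forest([self._toy_assignments()], ["Day0", "Day5"])
        assert forest.edges == [("A1", "B1"), ("A1", "B2"), ("A2", "B3")]
        for anc, child in forest.edges:
            assert forest.timepoint_of(anc) == "Day0"
            assert forest.timepoint_of(child) == "Day5"

    def test_three_timepoint_chains_compose(self):
        a01 = assign_ancestors(
            [fp("A", set("abcdef"), "Day0")],
            [fp("B", set("abcd"), "Day7")],
            min_shared=3,
            min_margin=1,
        )
        a12 = assign_ancestors(
            [fp("B", set("abcd"), "Day7")],
            [fp("C", set("abc"), "Day14")],
            min_shared=3,
            min_margin=1,
        )
        forest = build_forest([a01, a12], ["Day0", "Day7", "Day14"])
        assert forest.edges == [("A", "B"), ("B", "C")]

    def test_backwards_edge_rejected(self):
        forest = build_forest([self._toy_assignments()], ["Day0", "Day5"])
        with pytest.raises(ValueError):
            forest.add_edge("B1", "A1")

    def test_conflicting_parents_rejected(self):
        forest = build_forest([self._toy_assignments()], ["Day0", "Day5"])
        with pytest.raises(ValueError):
            forest.add_edge("A2", "B1")

    def test_every_node_has_at_most_one_parent(self, reference_tracing_run):
        _config, _lineage, observations, sampled_generation = reference_tracing_run
        earlier = [fp(c, observations[c], "Day0") for c, g in sampled_generation.items()
                   if g == 0 and observations[c]]
        later = [fp(c, observations[c], "Day5") for c, g in sampled_generation.items()
                 if g == 4 and observations[c]]
        result = assign_ancestors(earlier, later, min_shared=3, min_margin=2)
        forest = build_forest([result], ["Day0", "Day5"])
        assert max((forest.graph.in_degree(n) for n in forest.graph), default=0) <= 1

    def test_newick_export_round_trips_node_names(self):
        forest = build_forest([self._toy_assignments()], ["Day0", "Day5"])
        newick = forest.to_newick()
        assert newick == ["(B1,B2)A1;", "(B3)A2;"]


class TestSimilarityDecay:
    def test_single_pair_record(self):
        a = assign_ancestors(
            [fp("A", {"b1", "b2"})],
            [fp("B", {"b1"}, "Day5")],
            min_shared=1,
            min_margin=1,
        )
        records, summary = similarity_decay([a])
        assert len(records) == 1
        assert records.loc[0, "jaccard"] == pytest.approx(0.5)
        assert summary.loc[0, "n_pairs"] == 1

    def test_containment_decreases_with_depth(self):
        means = []
        for depth in (1, 2, 3, 4):
            config = SimConfig(
                n_founders=16,
                episomes_per_founder=60,
                replication_prob=0.0,
                reads_per_cell=1,
                seed=37 + depth,
            )
            _lin, obs, gens, _b = simulate_experiment(config, depth, [0, depth])
            earlier = [fp(c, obs[c], "Day0") for c, g in gens.items() if g == 0 and obs[c]]
            later = [fp(c, obs[c], "Later") for c, g in gens.items()
                     if g == depth and obs[c]]
            result = assign_ancestors(earlier, later, min_shared=1, min_margin=1)
            records, _ = similarity_decay([result])
            # ancestor containment of the child set falls as barcodes decay
            frac = records["shared"] / records["size_ancestor"]
            means.append((frac.mean(), frac.sem()))
        for (m1, s1), (m2, s2) in zip(means, means[1:]):
            assert m2 <= m1 + 3 * (s1 + s2)

    def test_empty_assignments_give_header_only_export(self):
        records, summary = similarity_decay([])
        assert records.empty and summary.empty
        assert "jaccard" in records.columns


class TestSaturationCurve:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["cell_id", "barcode", "umi_count"])

    def test_full_fraction_counts_all_traceable_cells(self):
        table = self._table(
            [("c1", "b1", 1), ("c1", "b2", 1), ("c2", "b3", 1)]
        )
        curve = saturation_curve(table, [1.0], reps=2, min_barcodes_per_cell=2, seed=0)
        # only c1 holds >= 2 distinct barcodes in the full table
        assert curve.loc[0, "mean_traced_cells"] == 1

    def test_single_barcode_cells_follow_hypergeometric_expectation(self):
        n_cells = 2000
        table = self._table([(f"c{i}", f"b{i}", 1) for i in range(n_cells)])
        f = 0.3
        curve = saturation_curve(table, [f], reps=20, seed=41)
        expected = math.floor(f * n_cells)  # each kept barcode traces its one cell
        assert curve.loc[0, "mean_traced_cells"] == expected
        assert curve.loc[0, "sd_traced_cells"] == 0.0

    def test_mean_is_monotone_in_fraction(self, lossless_run):
        _config, _lineage, _obs, _gens, batch = lossless_run
        truth = batch.truth.copy()
        table = (
            truth.groupby(["cell_id", "barcode"])["umi"]
            .nunique()
            .reset_index(name="umi_count")
        )
        curve = saturation_curve(table, [0.2, 0.4, 0.6, 0.8, 1.0], reps=5, seed=43)
        for i in range(len(curve) - 1):
            tol = 3 * (curve.loc[i, "sd_traced_cells"] + curve.loc[i + 1, "sd_traced_cells"])
            assert curve.loc[i + 1, "mean_traced_cells"] >= curve.loc[i, "mean_traced_cells"] - tol

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve(self._table([("c1", "b1", 1)]), [0.0, 1.0], seed=0)

    def test_same_seed_reproduces_curve(self, lossless_run):
        _config, _lineage, _obs, _gens, batch = lossless_run
        table = (
            batch.truth.groupby(["cell_id", "barcode"])["umi"]
            .nunique()
            .reset_index(name="umi_count")
        )
        a = saturation_curve(table, [0.5, 1.0], reps=3, seed=7)
        b = saturation_curve(table, [0.5, 1.0], reps=3, seed=7)
        assert a.equals(b)


class TestFingerprintsFromTable:
    def test_builds_one_fingerprint_per_labelled_cell(self):
        table = pd.DataFrame(
            [("c1", "b1", 2), ("c1", "b2", 1), ("c2", "b3", 1)],
            columns=["cell_id", "barcode", "umi_count"],
        )
        fps = fingerprints_from_table(table, {"c1": "Day0"})
        assert len(fps) == 1
        assert fps[0].barcodes == {"b1", "b2"}
        assert fps[0].umi_counts == {"b1": 2, "b2": 1}
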