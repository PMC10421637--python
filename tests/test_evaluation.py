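import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcabench.evaluation import (
    contact_map_codes,
    false_positive_topology,
    rmse_report,
    roc_curve,
    threshold_by_closest_to_ideal,
    threshold_by_positive_count,
)
from dcabench.graph_ensemble import CouplingMatrix, pair_topology
from dcabench.inference import InferredCouplings, ScoredPairs


def scored(scores, labels):
    scores = np.asarray(scores, dtype=float)
    n_pairs = len(scores)
    pairs = np.array([(0, k + 1) for k in range(n_pairs)])
    return ScoredPairs(pairs, scores, np.asarray(labels, dtype=bool), "test")


def brute_force_auc(scores, labels):
    """Oracle: pairwise win counting with ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        assert roc_curve(scored([3, 2, 1], [1, 0, 0])).auc == 1.0

    def test_complete_ties(self):
        assert roc_curve(scored([5, 5, 5, 5], [1, 0, 1, 0])).auc == 0.5

    def test_mixed_case(self):
        # one win and one loss against the single negative
        assert roc_curve(scored([1, 2, 3], [1, 0, 1])).auc == 0.5

    def test_curve_endpoints_and_monotonicity(self, rng):
        s = scored(rng.normal(size=50), rng.random(50) < 0.3)
        curve = roc_curve(s)
        assert curve.tpr[0] == 0 and curve.fpr[0] == 0
        assert curve.tpr[-1] == 1 and curve.fpr[-1] == 1
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve(scored([1, 2], [1, 1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, size=60).astype(float)  # heavy ties
        labels = rng.random(60) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        s = scored(scores, labels)
        ours = roc_curve(s).auc
        assert ours == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=40),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, raw, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(raw), max_size=len(raw))
        )
        if all(labels) or not any(labels):
            labels[0] = not labels[0]
        base = roc_curve(scored(raw, labels)).auc
        # doubling is exactly monotone in floating point (ties preserved too)
        transformed = [2.0 * x for x in raw]
        assert roc_curve(scored(transformed, labels)).auc == pytest.approx(base, abs=1e-9)


class TestThresholdByPositiveCount:
    def test_perfect_ranking(self):
        rep = threshold_by_positive_count(scored([4, 3, 2, 1], [1, 1, 0, 0]), 2)
        assert rep.tpr == 1.0 and rep.fpr == 0.0

    def test_fp_equals_fn(self, rng):
        for trial in range(20):
            scores = rng.integers(0, 4, size=30).astype(float)
            labels = rng.random(30) < 0.3
            n_true = int(labels.sum())
            if n_true in (0, 30):
                continue
            rep = threshold_by_positive_count(
                scored(scores, labels), n_true, seed=trial
            )
            assert rep.num_false_positives == rep.num_false_negatives
            assert int(rep.predictions.sum()) == n_true

    def test_all_tied_hypergeometric_expectation(self):
        # all scores equal, predict half: expected tpr = 1/2 under random ties
        n = 20
        labels = np.array([True] * 6 + [False] * 14)
        tprs = [
            threshold_by_positive_count(scored([1.0] * n, labels), 10, seed=s).tpr
            for s in range(400)
        ]
        assert np.mean(tprs) == pytest.approx(0.5, abs=0.05)

    def test_too_many_positives_raises(self):
        with pytest.raises(ValueError):
            threshold_by_positive_count(scored([1, 2], [1, 0]), 3)


class TestThresholdByClosestToIdeal:
    def test_perfect_validation(self):
        val = scored([4, 3, 2, 1], [1, 1, 0, 0])
        rep = threshold_by_closest_to_ideal(val, val)
        assert rep.metadata["validation_fpr"] == 0.0
        assert rep.metadata["validation_tpr"] == 1.0
        assert rep.tpr == 1.0 and rep.fpr == 0.0

    def test_worked_instance_tie_rule(self):
        # equal-distance candidates (0, .5) and (.5, 1): lower threshold wins
        val = scored([0.9, 0.8, 0.4, 0.1], [1, 0, 1, 0])
        rep = threshold_by_closest_to_ideal(val, val)
        assert 0.1 < rep.threshold <= 0.4
        assert rep.metadata["validation_distance"] == pytest.approx(0.5)
        assert (rep.metadata["validation_fpr"], rep.metadata["validation_tpr"]) == (0.5, 1.0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[0], labels[1] = True, False
        val = scored(scores, labels)
        test = scored(rng.normal(size=40), rng.random(40) < 0.4)
        test.labels[0], test.labels[1] = True, False
        rep1 = threshold_by_closest_to_ideal(val, val)
        val2 = scored(np.tanh(scores) * 2 + 5, labels)
        rep2 = threshold_by_closest_to_ideal(val2, val2)
        assert rep1.tpr == rep2.tpr and rep1.fpr == rep2.fpr

    def test_lp_metric_configurable(self):
        val = scored([0.9, 0.8, 0.4, 0.1], [1, 0, 1, 0])
        rep = threshold_by_closest_to_ideal(val, val, p=1.0)
        assert "p" in rep.metadata and rep.metadata["p"] == 1.0

    def test_single_class_validation_raises(self):
        val = scored([1, 2], [1, 1])
        test = scored([1, 2], [1, 0])
        with pytest.raises(ValueError):
            threshold_by_closest_to_ideal(val, test)


class TestSplit:
    def test_partition_and_fractions(self, rng):
        s = scored(rng.normal(size=100), rng.random(100) < 0.5)
        val, test = s.split(0.2, seed=1)
        assert val.num_pairs == 20 and test.num_pairs == 80
        seen = {tuple(p) for p in val.pairs} | {tuple(p) for p in test.pairs}
        assert len(seen) == 100

    def test_split_determinism(self, rng):
        s = scored(rng.normal(size=50), rng.random(50) < 0.5)
        v1, _ = s.split(0.3, seed=9)
        v2, _ = s.split(0.3, seed=9)
        assert np.array_equal(v1.pairs, v2.pairs)


class TestRmseReport:
    def _couplings(self, mat, T=1.0):
        return InferredCouplings(
            beta_couplings=np.asarray(mat) / T, regularization_used=0.0, temperature_assumed=T
        )

    def test_exact_recovery(self, small_er_graph):
        inferred = self._couplings(small_er_graph.entries.astype(float))
        assert rmse_report(inferred, small_er_graph).rmse == 0.0

    def test_uniform_offset(self, small_er_graph):
        inferred = self._couplings(small_er_graph.entries.astype(float) + 0.5)
        assert rmse_report(inferred, small_er_graph).rmse == pytest.approx(0.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_class_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        entries = np.zeros((n, n), dtype=np.int8)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < 0.4
        entries[iu[mask], ju[mask]] = 1
        entries |= entries.T
        truth = CouplingMatrix(entries)
        est = rng.normal(size=(n, n))
        est = 0.5 * (est + est.T)
        rep = rmse_report(self._couplings(est), truth)
        if all(v > 0 for v in rep.count_by_class.values()):
            assert rep.check_identity() < 1e-12


class TestFalsePositiveTopology:
    def test_point_mass_on_constructed_fp(self):
        from dcabench.fixtures import planted_motif_graph

        J, anchors = planted_motif_graph([5])
        topo = pair_topology(J)
        pairs = np.array([t.pair for t in topo])
        labels = np.array([t.label for t in topo])
        predictions = np.array([tuple(p) == anchors[0] for p in pairs])
        from dcabench.evaluation import ClassificationReport

        rep = ClassificationReport(
            threshold=0.0, tpr=0.0, fpr=0.0, positive_rate=0.0, overprediction=0.0,
            predictions=predictions, pairs=pairs, labels=labels,
        )
        out = false_positive_topology(rep, topo)
        assert out.fp_histogram == {5: 1.0}
        assert not out.empty

    def test_no_distance2_fp_flags_empty(self):
        from dcabench.fixtures import planted_motif_graph

        J, _ = planted_motif_graph([3])
        topo = pair_topology(J)
        pairs = np.array([t.pair for t in topo])
        labels = np.array([t.label for t in topo])
        from dcabench.evaluation import ClassificationReport

        rep = ClassificationReport(
            threshold=0.0, tpr=0.0, fpr=0.0, positive_rate=0.0, overprediction=0.0,
            predictions=np.zeros(len(topo), dtype=bool), pairs=pairs, labels=labels,
        )
        out = false_positive_topology(rep, topo)
        assert out.empty and out.fp_histogram == {}
        assert sum(out.baseline_histogram.values()) == pytest.approx(1.0)

    def test_random_guessing_matches_baseline(self, rng):
        from dcabench.fixtures import planted_motif_graph
        from dcabench.evaluation import ClassificationReport

        J, _ = planted_motif_graph([1, 2, 3, 4, 5] * 3)
        topo = pair_topology(J)
        pairs = np.array([t.pair for t in topo])
        labels = np.array([t.label for t in topo])
        # exchangeable predictions: aggregated histograms should agree roughly
        agg_fp = {}
        for s in range(50):
            predictions = rng.random(len(topo)) < 0.5
            rep = ClassificationReport(
                threshold=0.0, tpr=0.0, fpr=0.0, positive_rate=0.5, overprediction=0.0,
                predictions=predictions, pairs=pairs, labels=labels,
            )
            out = false_positive_topology(rep, topo)
            for k, v in out.fp_counts.items():
                agg_fp[k] = agg_fp.get(k, 0) + v
        base = out.baseline_counts
        total_fp = sum(agg_fp.values())
        total_base = sum(base.values())
        for k in base:
            assert agg_fp.get(k, 0) / total_fp == pytest.approx(
                base[k] / total_base, abs=0.08
            )


class TestContactMap:
    def test_codes(self):
        s = scored([4, 3, 2, 1], [1, 0, 1, 0])
        rep = threshold_by_positive_count(s, 2)
        codes = contact_map_codes(rep, n=5)
        assert codes[0, 1] == 1  # highest score, true edge -> TP
        assert codes[0, 2] == 2  # second score, non-edge -> FP
        assert codes[0, 3] == 3  # true edge below threshold -> FN
        assert codes[0, 4] == 0
        assert np.array_equal(codes, codes.T)
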