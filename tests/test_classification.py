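"""psi similarity, argmin prediction, LOOCV, aggregation and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import facekin as fk
from facekin.classification import WORDS, ConfusionMatrix, default_aggregation_maps

AGG = default_aggregation_maps()


class TestPsi:
    def test_identical_vectors_zero(self):
        v = np.random.default_rng(0).normal(size=1000)
        assert fk.psi(v, v) == 0.0

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(-50, 50))
    def test_constant_offset_identity(self, c):
        v = np.linspace(-1, 1, 1000)
        assert fk.psi(v, v + c) == pytest.approx(c * c, rel=1e-9, abs=1e-12)

    def test_explicit_loop_oracle(self):
        rng = np.random.default_rng(1)
        p, t = rng.normal(size=1000), rng.normal(size=1000)
        acc = 0.0
        for a, b in zip(p, t):
            acc += (a - b) ** 2
        assert fk.psi(p, t) == pytest.approx(acc / 1000, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fk.psi(np.zeros(1000), np.zeros(999))


class TestPredictWord:
    def _profiles(self, values):
        return {w: np.full(10, v) for w, v in values.items()}

    def test_exact_profile_match(self):
        profiles = self._profiles({w: i for i, w in enumerate(WORDS)})
        tests = {"Ham": profiles["Ham"].copy()}
        assert fk.predict_word(tests, profiles)["Ham"] == "Ham"

    def test_all_identical_profiles_tie_to_first_word(self):
        profiles = {w: np.zeros(10) for w in WORDS}
        out = fk.predict_word({"Show": np.ones(10)}, profiles)
        assert out["Show"] == WORDS[0] == "Ba"

    def test_three_word_toy_hand_psi(self):
        order = ("Ba", "Map", "Ham")
        profiles = self._profiles({"Ba": 0.0, "Map": 3.0, "Ham": 5.0})
        # test trace constant 3.9: psi = 15.21, 0.81, 1.21 -> Map
        out = fk.predict_word({"Ba": np.full(10, 3.9)}, profiles, order)
        assert out["Ba"] == "Map"

    def test_missing_profile_rejected(self):
        profiles = {w: np.zeros(10) for w in WORDS[:-1]}
        with pytest.raises(KeyError, match=WORDS[-1]):
            fk.predict_word({}, profiles)


class TestLoocv:
    def test_hand_traced_three_participant_cohort(self):
        """N=3, 3 words, constant traces: confusion matches the hand trace."""
        order = ("Ba", "Map", "Ham")
        vals = {
            "p1": {"Ba": 0.0, "Map": 10.0, "Ham": 20.0},
            "p2": {"Ba": 1.0, "Map": 11.0, "Ham": 21.0},
            "p3": {"Ba": 5.0, "Map": 9.0, "Ham": 14.0},
        }
        traces = {p: {w: np.full(8, v) for w, v in d.items()} for p, d in vals.items()}
        cm = fk.loocv_classify(traces, order)
        # hand computation: constant traces give psi = (profile - trace)^2;
        # only p3's "Ham"=14 lands nearer the others' "Map" profile (10.5)
        expect = np.array([[3, 0, 0], [0, 3, 0], [0, 1, 2]])
        np.testing.assert_array_equal(cm.counts, expect)
        assert cm.total == 9

    def test_separable_cohort_is_diagonal(self):
        rng = np.random.default_rng(4)
        templates = {w: rng.normal(size=50) * 5 for w in WORDS}
        traces = {
            f"p{i}": {w: templates[w] + rng.normal(0, 0.01, 50) for w in WORDS}
            for i in range(5)
        }
        cm = fk.loocv_classify(traces)
        assert np.all(cm.counts == np.diag([5] * 20))
        assert 100 * fk.compute_metrics(cm).average_f1 == pytest.approx(100.0)

    def test_needs_three_participants(self):
        traces = {f"p{i}": {w: np.zeros(5) for w in WORDS} for i in range(2)}
        with pytest.raises(ValueError, match="at least 3"):
            fk.loocv_classify(traces)

    def test_missing_word_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(6)
        traces = {f"p{i}": {w: rng.normal(size=20) for w in WORDS} for i in range(4)}
        del traces["p0"]["Show"]
        with caplog.at_level("WARNING"):
            cm = fk.loocv_classify(traces)
        assert cm.total == 4 * 20 - 1
        assert any("Show" in r.message for r in caplog.records)


class TestAggregation:
    def test_identity_map_unchanged(self):
        rng = np.random.default_rng(0)
        labels = ("a", "b", "c")
        cm = ConfusionMatrix(labels, rng.integers(0, 10, (3, 3)))
        ident = fk.AggregationMap({l: l for l in labels}, labels)
        np.testing.assert_array_equal(fk.aggregate_confusion(cm, ident).counts, cm.counts)

    def test_within_class_mass_stays_in_class(self):
        counts = np.zeros((20, 20), dtype=int)
        counts[WORDS.index("Ba"), WORDS.index("Map")] = 7  # both class 1
        cm = ConfusionMatrix(WORDS, counts)
        agg = fk.aggregate_confusion(cm, AGG["class"])
        assert agg.counts[0, 0] == 7
        assert agg.total == 7

    def test_random_matrix_against_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            cm = ConfusionMatrix(WORDS, rng.integers(0, 6, (20, 20)))
            got = fk.aggregate_confusion(cm, AGG["class"])
            mapping = AGG["class"].mapping
            order = AGG["class"].label_order
            expect = np.zeros((5, 5), dtype=int)
            for i, wi in enumerate(WORDS):
                for j, wj in enumerate(WORDS):
                    if wi == "Papa" or wj == "Papa":
                        continue
                    expect[order.index(mapping[wi]), order.index(mapping[wj])] += cm.counts[i, j]
            np.testing.assert_array_equal(got.counts, expect)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_total_conservation_bookkeeping(self, seed):
        """Aggregation only drops observations involving excluded labels."""
        rng = np.random.default_rng(seed)
        cm = ConfusionMatrix(WORDS, rng.integers(0, 4, (20, 20)))
        agg = fk.aggregate_confusion(cm, AGG["class"])
        k = WORDS.index("Papa")
        dropped = cm.counts[k, :].sum() + cm.counts[:, k].sum() - cm.counts[k, k]
        assert agg.total == cm.total - dropped
        grp = fk.aggregate_confusion(cm, AGG["group"])
        assert grp.total == cm.total  # Papa reincluded at group level

    def test_unmapped_label_rejected(self):
        cm = ConfusionMatrix(("Ba", "nonword"), np.eye(2, dtype=int))
        with pytest.raises(KeyError, match="nonword"):
            fk.aggregate_confusion(cm, AGG["class"])


class TestMetrics:
    def test_worked_class_level_rows(self):
        """Published worked example: per-class counts reproduce R/P/F1 to 2 dp."""
        t = fk.metrics_from_counts(
            tp=[6, 3, 2, 4, 2, 17], fp=[10, 9, 7, 6, 8, 40], fn=[0, 1, 1, 1, 1, 4],
            labels=["1", "2", "3", "4", "5", "ALL"],
        ).table
        np.testing.assert_allclose(t["R"].round(2), [1.00, 0.75, 0.67, 0.80, 0.67, 0.81])
        np.testing.assert_allclose(t["P"].round(2), [0.38, 0.25, 0.22, 0.40, 0.20, 0.30])
        np.testing.assert_allclose(t["F1"].round(2), [0.55, 0.38, 0.33, 0.53, 0.31, 0.44])

    def test_zero_division_guards(self):
        t = fk.metrics_from_counts(tp=[0], fp=[0], fn=[5], labels=["x"]).table
        assert t.loc["x", "R"] == 0.0
        assert t.loc["x", "P"] == 0.0
        assert t.loc["x", "F1"] == 0.0

    def test_against_sklearn_oracle(self):
        """compute_metrics agrees with the standard metrics implementation."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(12)
        labels = ("a", "b", "c", "d")
        for _ in range(100):
            counts = rng.integers(0, 8, (4, 4))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(labels, counts)
            got = fk.compute_metrics(cm).table
            y_true, y_pred = [], []
            for i, li in enumerate(labels):
                for j, lj in enumerate(labels):
                    y_true += [li] * counts[i, j]
                    y_pred += [lj] * counts[i, j]
            p, r, f1, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=list(labels), zero_division=0
            )
            np.testing.assert_allclose(got["P"], p, atol=1e-12)
            np.testing.assert_allclose(got["R"], r, atol=1e-12)
            np.testing.assert_allclose(got["F1"], f1, atol=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_micro_identities(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 5, (6, 6))
        counts[0, 0] += 1
        cm = ConfusionMatrix(tuple("abcdef"), counts)
        t = fk.compute_metrics(cm).table
        assert t["TP"].sum() + t["FN"].sum() == cm.total
        assert t["FP"].sum() == t["FN"].sum()
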