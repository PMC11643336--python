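"""LOSO plan, micro F1, report plumbing, and Sammon mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import moveprof as mp
from moveprof import evaluate as ev


class TestLosoPlan:
    def test_fold_structure(self):
        plan = ev.make_loso_plan(["S2", "S0", "S1"], n_repeats=4, seed=1)
        assert len(plan.folds) == 3
        held = [f[0] for f in plan.folds]
        assert held == ["S0", "S1", "S2"]  # each subject held out exactly once
        for held_out, train in plan.folds:
            assert held_out not in train
            assert set(train) | {held_out} == {"S0", "S1", "S2"}
        assert len(plan.repeat_seeds) == 4

    def test_32_subjects_640_fold_evaluations(self):
        plan = ev.make_loso_plan([f"S{i}" for i in range(32)], n_repeats=20, seed=0)
        assert len(plan.folds) * len(plan.repeat_seeds) == 640

    def test_two_subjects_two_folds(self):
        assert len(ev.make_loso_plan(["a", "b"], 1, 0).folds) == 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            ev.make_loso_plan(["only"], 1, 0)

    def test_duplicate_subjects_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ev.make_loso_plan(["a", "a", "b"], 1, 0)

    def test_repeat_seeds_deterministic(self):
        p1 = ev.make_loso_plan(["a", "b"], 5, seed=9)
        p2 = ev.make_loso_plan(["a", "b"], 5, seed=9)
        assert p1.repeat_seeds == p2.repeat_seeds
        assert all(0 <= s < 2**31 for s in p1.repeat_seeds)


class TestMicroF1:
    def test_perfect(self):
        assert ev.micro_f1(["a", "b", "c"], ["a", "b", "c"]) == 1.0

    def test_hand_pooled_confusion_oracle(self):
        # 10 items, 7 correct: micro F1 = pooled TP / N = 0.7
        t = ["a"] * 4 + ["b"] * 3 + ["c"] * 3
        p = ["a", "a", "b", "a", "b", "b", "c", "c", "c", "a"]
        correct = sum(x == y for x, y in zip(t, p))
        assert correct == 7
        assert ev.micro_f1(t, p) == pytest.approx(0.7)

    def test_constant_prediction_uniform_truth(self):
        t = ["a", "b", "c"] * 4
        assert ev.micro_f1(t, ["a"] * 12) == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.micro_f1(["a"], ["a", "b"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
                    min_size=1, max_size=40))
    def test_equals_accuracy_on_single_label_tasks(self, pairs):
        t = [a for a, _ in pairs]
        p = [b for _, b in pairs]
        acc = np.mean([a == b for a, b in pairs])
        assert ev.micro_f1(t, p) == pytest.approx(acc)


@pytest.fixture(scope="module")
def toy():
    """Separable toy table: evaluation plumbing checks only."""
    rng = np.random.default_rng(0)
    rows = []
    names = [f"f{i}" for i in range(5)]
    i = 0
    for s in range(4):
        for m_idx, m in enumerate(("PUSH", "GST", "WHLC")):
            for g_idx, g in enumerate(("low", "high")):
                for _ in range(6):
                    feats = rng.standard_normal(5) * 0.2
                    feats[0] += 2.5 * m_idx
                    feats[1] += 2.5 * g_idx
                    rows.append({"repetition_id": f"r{i}", "subject_id": f"S{s}",
                                 "movement": m, "side": "right", "grade": g,
                                 **dict(zip(names, feats))})
                    i += 1
    return mp.FeatureTable(data=pd.DataFrame(rows), feature_names=names)


class TestReports:

    def test_movement_report_structure(self, toy):
        cfg = ev.EvalConfig(n_repeats=2, seed=0)
        rep = ev.evaluate_movement_id(toy, cfg)
        assert len(rep.per_repeat_f1) == 2
        # confusion row sums equal true-class counts (pooled over repeats)
        counts = toy.data["movement"].value_counts()
        for m in counts.index:
            assert rep.confusion.loc[m].sum() == counts[m] * 2
        # micro F1 recomputable from pooled confusion
        pooled = np.diag(rep.confusion).sum() / rep.confusion.to_numpy().sum()
        assert pooled == pytest.approx(np.mean(rep.per_repeat_f1), abs=0.05)
        assert rep.f1_mean > 0.9

    def test_single_repeat_sd_zero(self, toy):
        rep = ev.evaluate_movement_id(toy, ev.EvalConfig(n_repeats=1, seed=0))
        assert rep.f1_sd == 0.0

    def test_report_reproducible(self, toy):
        cfg = ev.EvalConfig(n_repeats=2, seed=7)
        r1 = ev.evaluate_movement_id(toy, cfg)
        r2 = ev.evaluate_movement_id(toy, cfg)
        assert r1.per_repeat_f1 == r2.per_repeat_f1
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_proficiency_overall_at_least_repetition_when_separable(self, toy):
        cfg = ev.EvalConfig(n_repeats=1, seed=0)
        reps = ev.evaluate_proficiency(toy, cfg, include_unified=False)
        for name, r in reps.items():
            assert r.overall_f1_mean >= r.f1_mean - 0.05

    def test_misrouting_table_trivial_cases(self):
        # zero misclassifications -> only the TOTAL row with n=0
        df = pd.DataFrame({
            "movement": ["PUSH", "GST"], "pred_movement": ["PUSH", "GST"],
            "grade": ["low", "high"], "pred_grade": ["low", "high"],
            "repetition_id": ["a", "b"], "subject_id": ["s", "s"], "side": ["right"] * 2,
        })
        t = ev.misrouting_robustness(df)
        assert len(t) == 1 and t.iloc[0]["n"] == 0
        # a misrouted rep with matching grade counts as correct
        df.loc[1, "pred_movement"] = "PUSH"
        t = ev.misrouting_robustness(df)
        row = t[t["true_movement"] == "GST"].iloc[0]
        assert row["n"] == 1 and row["n_correct_grade"] == 1


class TestSammon:
    def test_exact_embedding_recovers_configuration(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 2))
        Y, stress, flagged = ev.sammon_project(X, target_dim=2, seed=0)
        assert not flagged
        assert stress < 1e-6
        # distances preserved up to rigid motion
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(Y), pdist(X), rtol=1e-3)

    def test_tetrahedron_not_flat_embeddable(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                      [0.5, np.sqrt(3) / 6, np.sqrt(2 / 3)]])
        _, stress, _ = ev.sammon_project(X, target_dim=2, seed=0)
        assert stress > 1e-4

    def test_descent_beats_pca_initialization(self):
        from scipy.spatial.distance import pdist, squareform
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 5))
        Y, stress, _ = ev.sammon_project(X, target_dim=2, seed=0)
        D = squareform(pdist(X))
        Y0 = PCA(2, random_state=0).fit_transform(X)
        E0 = squareform(pdist(Y0))
        c = D[np.triu_indices(20, 1)].sum()
        iu = np.triu_indices(20, 1)
        stress0 = np.sum((D[iu] - E0[iu]) ** 2 / D[iu]) / c
        assert stress <= stress0

    def test_duplicates_flagged_and_handled(self):
        X = np.vstack([np.zeros(3), np.zeros(3), np.eye(3)])
        Y, stress, flagged = ev.sammon_project(X, target_dim=2, seed=1)
        assert flagged
        assert np.isfinite(Y).all() and np.isfinite(stress)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 4))
        Y1, s1, _ = ev.sammon_project(X, 2, seed=5)
        Y2, s2, _ = ev.sammon_project(X, 2, seed=5)
        np.testing.assert_array_equal(Y1, Y2)
        assert s1 == s2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ev.sammon_project(np.zeros((2, 3)), target_dim=2)
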