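"""mRMR vs brute-force MID oracle, selection-rule arithmetic, cascade contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest

import moveprof as mp
from moveprof import modeling as md

# ---------------------------------------------------------------------------
# Independent brute-force oracle for the MID criterion


def oracle_discretize(col, bins=3):
    if np.ptp(col) == 0:
        return np.zeros(len(col), dtype=int)
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), col, side="right")


def oracle_mi(a, b):
    """Plain-counting mutual information of two discrete sequences."""
    mi = 0.0
    n = len(a)
    for va in np.unique(a):
        for vb in np.unique(b):
            pxy = np.mean((a == va) & (b == vb))
            if pxy > 0:
                mi += pxy * np.log(pxy / (np.mean(a == va) * np.mean(b == vb)))
    return mi


def oracle_mrmr(df, label, names, bins=3):
    """Exhaustive greedy MID: at each step score every remaining feature."""
    codes = {f: oracle_discretize(df[f].to_numpy(), bins) for f in names}
    y = df[label].to_numpy()
    _, y = np.unique(y, return_inverse=True)
    const = [f for f in names if np.ptp(df[f].to_numpy()) == 0]
    live = [f for f in names if f not in const]
    selected = []
    while live:
        best, best_score = None, -np.inf
        for f in live:  # registry order = tie-break order
            rel = oracle_mi(codes[f], y)
            red = np.mean([oracle_mi(codes[f], codes[s]) for s in selected]) if selected else 0.0
            score = rel - red
            if score > best_score + 1e-15:
                best, best_score = f, score
        selected.append(best)
        live.remove(best)
    return selected + const


class TestMrmr:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 120, 6
        y = rng.integers(0, 3, n)
        df = pd.DataFrame({f"f{j}": rng.standard_normal(n) + (j % 3 == 0) * y
                           for j in range(d)})
        df["label"] = y
        names = [f"f{j}" for j in range(d)]
        assert md.mrmr_rank(df, "label", feature_names=names) == \
            oracle_mrmr(df, "label", names)

    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(5)
        n = 200
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({"copy": y + rng.normal(0, 0.01, n),
                           "n1": rng.standard_normal(n),
                           "n2": rng.standard_normal(n), "label": y})
        assert md.mrmr_rank(df, "label", feature_names=["n1", "copy", "n2"])[0] == "copy"

    def test_duplicate_penalized_below_weak_independent_feature(self):
        rng = np.random.default_rng(7)
        n = 400
        y = rng.integers(0, 2, n)
        inf1 = y + rng.normal(0, 0.05, n)
        df = pd.DataFrame({"inf1": inf1, "inf2": inf1,
                           "weak": 0.4 * y + rng.standard_normal(n), "label": y})
        names = ["inf1", "inf2", "weak"]
        ranking = md.mrmr_rank(df, "label", feature_names=names)
        assert ranking == oracle_mrmr(df, "label", names)
        assert ranking.index("inf2") > ranking.index("weak")

    def test_constant_feature_ranked_last_not_dropped(self):
        rng = np.random.default_rng(9)
        n = 100
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({"c": np.full(n, 3.0), "w": y + rng.normal(0, 0.5, n),
                           "label": y})
        ranking = md.mrmr_rank(df, "label", feature_names=["c", "w"])
        assert ranking == ["w", "c"]

    def test_single_feature_table(self):
        df = pd.DataFrame({"only": [1.0, 2.0, 3.0, 4.0], "label": [0, 0, 1, 1]})
        assert md.mrmr_rank(df, "label", feature_names=["only"]) == ["only"]

    def test_single_class_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0], "label": [1, 1]})
        with pytest.raises(ValueError, match="2 classes"):
            md.mrmr_rank(df, "label", feature_names=["a", "b"])


class TestSelectFeatureCount:
    def _run(self, curve, threshold=0.95):
        names = [f"f{i}" for i in range(len(curve))]
        df = pd.DataFrame({n: [0.0] for n in names})
        return md.select_feature_count(
            df, names, lambda t, feats: curve[len(feats) - 1], threshold=threshold)

    def test_spec_arithmetic_example(self):
        sel = self._run([0.50, 0.80, 0.95, 0.96])
        assert sel.chosen_k == 3  # 0.95 >= 0.95*0.96 = 0.912; 0.80 < 0.912

    def test_max_at_k1(self):
        assert self._run([0.9, 0.9, 0.9]).chosen_k == 1

    def test_selection_invariant_checked(self):
        for curve in ([0.2, 0.5, 0.7, 1.0], [1.0, 0.9, 0.8], [0.0, 0.0, 0.5]):
            sel = self._run(list(curve))
            cutoff = sel.threshold * sel.reference_score
            assert sel.curve[sel.k_grid.index(sel.chosen_k)] >= cutoff
            for k, s in zip(sel.k_grid, sel.curve):
                if k < sel.chosen_k:
                    assert s < cutoff
            sel.check()

    def test_evaluator_failure_carries_partial_curve(self):
        names = ["a", "b", "c"]
        df = pd.DataFrame({n: [0.0] for n in names})

        def evaluator(t, feats):
            if len(feats) == 3:
                raise RuntimeError("boom")
            return 0.5

        with pytest.raises(RuntimeError, match="k=3") as exc:
            md.select_feature_count(df, names, evaluator)
        assert exc.value.partial_curve == [(1, 0.5), (2, 0.5)]

    def test_planted_informative_features_selected_small(self):
        """5 planted features among 50 noise ones -> chosen_k stays small."""
        rng = np.random.default_rng(11)
        n = 300
        y = rng.integers(0, 3, n)
        data = {f"noise{j}": rng.standard_normal(n) for j in range(45)}
        for j in range(5):
            data[f"signal{j}"] = y + rng.normal(0, 0.3, n)
        df = pd.DataFrame(data)
        df["label"] = y
        names = [c for c in df.columns if c != "label"]
        ranking = md.mrmr_rank(df, "label", feature_names=names)
        sel = md.select_feature_count(
            df, ranking, md.oob_evaluator(0, label_column="label"),
            k_grid=[1, 2, 3, 4, 5, 6, 8, 10, 15, 50])
        assert sel.chosen_k <= 10


class TestDiscretizeScore:
    @pytest.mark.parametrize("value,grade", [(2.5, "low"), (3.0, "medium"), (4.0, "high")])
    def test_boundary_rule(self, value, grade):
        assert md.discretize_score(value) == grade

    def test_invalid_granularity_rejected(self):
        with pytest.raises(Exception):
            md.discretize_score(3.25)


def _toy_table(n_per=30, seed=0, movements=("PUSH", "GST"), grades=("low", "high")):
    """Small feature table with separable structure for model tests."""
    rng = np.random.default_rng(seed)
    rows = []
    names = [f"f{i}" for i in range(6)]
    i = 0
    for subj in ("S00", "S01", "S02", "S03"):
        for m_idx, m in enumerate(movements):
            for g_idx, g in enumerate(grades):
                for _ in range(n_per // len(grades)):
                    feats = rng.standard_normal(6) * 0.3
                    feats[0] += 3 * m_idx
                    feats[1] += 3 * g_idx
                    rows.append({"repetition_id": f"r{i}", "subject_id": subj,
                                 "movement": m, "side": "right", "grade": g,
                                 **dict(zip(names, feats))})
                    i += 1
    df = pd.DataFrame(rows)
    return mp.FeatureTable(data=df, feature_names=names)


def _full_selection(names):
    return md.SelectionResult(ranking=list(names), k_grid=[len(names)],
                              curve=[1.0], chosen_k=len(names), threshold=0.95,
                              reference_score=1.0)


class TestForests:
    def test_retrain_same_seed_identical_predictions(self):
        table = _toy_table()
        sel = _full_selection(table.feature_names)
        m1 = md.train_movement_classifier(table, sel, seed=42)
        m2 = md.train_movement_classifier(table, sel, seed=42)
        probe = table.data.sample(20, random_state=0)
        assert list(m1.predict(probe)) == list(m2.predict(probe))
        assert m1.oob_micro_f1 == m2.oob_micro_f1

    def test_forest_size_and_oob_recorded(self):
        table = _toy_table()
        m = md.train_movement_classifier(table, _full_selection(table.feature_names), 1)
        assert m.forest.n_estimators == 100
        assert 0 <= m.oob_micro_f1 <= 1

    def test_single_movement_rejected(self):
        table = _toy_table(movements=("PUSH",))
        with pytest.raises(ValueError, match="2 movement classes"):
            md.train_movement_classifier(table, _full_selection(table.feature_names), 0)

    def test_missing_grades_rejected(self):
        table = _toy_table()
        table.data.loc[0, "grade"] = ""
        with pytest.raises(ValueError, match="grade"):
            md.train_proficiency_bank(table, {"PUSH": _full_selection(table.feature_names)}, 0)

    def test_single_grade_movement_flagged_degenerate(self):
        table = _toy_table(grades=("high",))
        bank = md.train_proficiency_bank(
            table, {m: _full_selection(table.feature_names) for m in ("PUSH", "GST")}, 0)
        assert bank.degenerate == {"PUSH": True, "GST": True}


@pytest.fixture(scope="module")
def scorer():
    table = _toy_table(n_per=40, seed=3)
    sel = _full_selection(table.feature_names)
    clf = md.train_movement_classifier(table, sel, seed=0)
    bank = md.train_proficiency_bank(table, {m: sel for m in ("PUSH", "GST")}, 0)
    return table, md.HierarchicalScorer(movement_model=clf, bank=bank)


class TestHierarchicalRouting:

    def test_grade_comes_from_predicted_movements_model(self, scorer):
        table, sc = scorer
        preds = sc.score(table.data)
        assert len(preds) == len(table.data)
        for (m, g), (_, row) in zip(preds, table.data.iterrows()):
            direct = sc.bank.predict_grade(m, table.data.loc[[row.name]])[0]
            assert g == direct  # routing contract: bank[predicted movement]

    def test_forced_true_routing_equals_direct_bank(self, scorer):
        table, sc = scorer
        for m in ("PUSH", "GST"):
            sub = table.data[table.data["movement"] == m]
            direct = sc.bank.predict_grade(m, sub)
            routed = [g for _, g in sc.score(sub)]
            pred_m = sc.movement_model.predict(sub)
            agree = pred_m == m
            assert (np.asarray(routed)[agree] == direct[agree]).all()

    def test_empty_input_empty_output(self, scorer):
        table, sc = scorer
        assert sc.score(table.data.iloc[0:0]) == []


class TestAggregateMajority:
    @pytest.mark.parametrize("grades,expected", [
        (["high", "high", "high"], "high"),
        (["low", "low", "high", "medium"], "low"),
        (["low", "low", "high", "high"], "low"),      # tie -> lower grade
        (["medium", "high", "medium", "high"], "medium"),
        (["high"], "high"),
    ])
    def test_examples(self, grades, expected):
        assert md.aggregate_majority(grades) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            md.aggregate_majority([])

    def test_equals_exhaustive_counting_all_multisets_to_size_5(self):
        """Against an independent exhaustive-count oracle with the documented
        lower-grade tie-break, over every multiset of size <= 5."""
        order = {"low": 0, "medium": 1, "high": 2}
        for size in range(1, 6):
            for combo in itertools.combinations_with_replacement(
                    ["low", "medium", "high"], size):
                counts = {g: combo.count(g) for g in order}
                best = max(counts.values())
                expected = min((g for g, c in counts.items() if c == best),
                               key=lambda g: order[g])
                assert md.aggregate_majority(list(combo)) == expected
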