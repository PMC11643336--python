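"""Leave-one-subject-out evaluation, metrics, misrouting analysis, Sammon maps.

Validation is leave-one-subject-out (LOSO): each fold trains on all subjects
but one and tests on the held-out subject, so no person-specific information
leaks into the test predictions. Folds are deterministic; the configured
repeats re-seed only the Random Forest training (and the selection evaluator),
which is the only source of run-to-run variability. With
``selection_mode="nested"`` (default) the mRMR ranking and the 95% rule are
recomputed inside every training fold; ``"paper"`` performs selection once on
the full table before cross-validation, which is cheaper but lets the
held-out subject influence feature choice.

Two metrics are reported for proficiency: the repetition-level micro F1 over
individual repetitions, and the overall micro F1 after majority-voting a
single grade per (subject, movement, side) — the unit experts actually score.
Micro F1 equals plain accuracy for single-label multiclass tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score

from .modeling import (
    HierarchicalScorer,
    SelectionResult,
    aggregate_majority,
    mrmr_rank,
    oob_evaluator,
    select_feature_count,
    train_movement_classifier,
    train_proficiency_bank,
    train_unified_model,
)
from .session_io import GRADES, FeatureTable

__all__ = [
    "LosoPlan",
    "EvalConfig",
    "EvaluationReport",
    "make_loso_plan",
    "micro_f1",
    "evaluate_movement_id",
    "evaluate_proficiency",
    "evaluate_hierarchical",
    "misrouting_robustness",
    "sammon_project",
]


@dataclass(frozen=True)
class LosoPlan:
    """Ordered LOSO folds plus one deterministic seed per repeat."""

    subjects: tuple[str, ...]
    folds: tuple[tuple[str, tuple[str, ...]], ...]
    repeat_seeds: tuple[int, ...]


def make_loso_plan(subjects, n_repeats: int = 20, seed: int = 0) -> LosoPlan:
    subjects = [str(s) for s in subjects]
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    ordered = tuple(sorted(subjects))
    folds = tuple(
        (held_out, tuple(s for s in ordered if s != held_out)) for held_out in ordered
    )
    ss = np.random.SeedSequence(seed)
    repeat_seeds = tuple(int(x) % (2**31) for x in ss.generate_state(n_repeats))
    return LosoPlan(subjects=ordered, folds=folds, repeat_seeds=repeat_seeds)


def micro_f1(true_labels, predicted_labels) -> float:
    """Micro-averaged F1 (pooled TP/FP/FN); equals accuracy for single-label
    multiclass predictions. Returned as a fraction in [0, 1]."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    if len(t) == 0:
        raise ValueError("empty label set")
    return float(f1_score(t, p, average="micro"))


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation protocol knobs."""

    n_repeats: int = 20
    seed: int = 0
    selection_mode: str = "nested"   # "nested" | "paper"
    threshold: float = 0.95
    mrmr_top_k: int = 40             # greedy mRMR search depth on wide tables
    k_grid: tuple[int, ...] | None = None  # None -> auto

    def grid_for(self, n_features: int) -> list[int]:
        if self.k_grid is not None:
            return [k for k in self.k_grid if k <= n_features] or [n_features]
        if n_features <= 24:
            return list(range(1, n_features + 1))
        ks = [1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 25, 30, 40]
        return [k for k in ks if k <= min(self.mrmr_top_k, n_features)]


@dataclass
class EvaluationReport:
    """Metrics of one evaluated task, aggregated over LOSO repeats."""

    task: str
    per_repeat_f1: list[float]
    confusion: pd.DataFrame          # pooled over repeats; rows = true class
    per_class: pd.DataFrame          # precision/recall per class (+undefined flag)
    chosen_k: list[int] = field(default_factory=list)
    overall_per_repeat_f1: list[float] | None = None
    overall_confusion: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def f1_mean(self) -> float:
        return float(np.mean(self.per_repeat_f1))

    @property
    def f1_sd(self) -> float:
        return float(np.std(self.per_repeat_f1, ddof=1)) if len(self.per_repeat_f1) > 1 else 0.0

    @property
    def overall_f1_mean(self) -> float | None:
        if self.overall_per_repeat_f1 is None:
            return None
        return float(np.mean(self.overall_per_repeat_f1))

    @property
    def overall_f1_sd(self) -> float | None:
        if self.overall_per_repeat_f1 is None:
            return None
        if len(self.overall_per_repeat_f1) > 1:
            return float(np.std(self.overall_per_repeat_f1, ddof=1))
        return 0.0


def _confusion(true_labels, pred_labels, classes) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        if p not in cm.columns:  # prediction outside the class set: count as error
            cm.loc[t, cm.columns[0]] += 0
            continue
        cm.loc[t, p] += 1
    return cm


def _per_class(cm: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for c in cm.index:
        tp = cm.loc[c, c]
        predicted = cm[c].sum()
        actual = cm.loc[c].sum()
        rows.append({
            "class": c,
            "precision": tp / predicted if predicted else 0.0,
            "recall": tp / actual if actual else 0.0,
            "undefined_precision": bool(predicted == 0),
            "undefined_recall": bool(actual == 0),
        })
    return pd.DataFrame(rows).set_index("class")


def _fold_frames(table: FeatureTable, plan: LosoPlan):
    df = table.data
    for held_out, train_subjects in plan.folds:
        yield held_out, df[df["subject_id"].isin(train_subjects)], df[df["subject_id"] == held_out]


def _fold_selection(train_df: pd.DataFrame, table: FeatureTable, label: str,
                    config: EvalConfig, seed: int) -> SelectionResult:
    ranking = mrmr_rank(train_df, label, feature_names=table.feature_names,
                        top_k=config.mrmr_top_k)
    grid = config.grid_for(len(ranking))
    return select_feature_count(
        train_df, ranking, oob_evaluator(seed, label_column=label),
        threshold=config.threshold, k_grid=grid, evaluator_seed=seed,
    )


def _subtable(table: FeatureTable, df: pd.DataFrame) -> FeatureTable:
    return FeatureTable(data=df.reset_index(drop=True),
                        feature_names=table.feature_names, hash=table.hash)


def evaluate_movement_id(table: FeatureTable, config: EvalConfig | None = None,
                         ) -> EvaluationReport:
    """LOSO evaluation of the 6-class movement-identification model."""
    cfg = config or EvalConfig()
    plan = make_loso_plan(table.data["subject_id"].unique(), cfg.n_repeats, cfg.seed)
    classes = sorted(table.data["movement"].unique())
    flags: list[str] = []

    # selection: once globally ("paper") or once per fold ("nested"); repeats
    # re-seed only model training.
    sel_seed = plan.repeat_seeds[0]
    if cfg.selection_mode == "paper":
        global_sel = _fold_selection(table.data, table, "movement", cfg, sel_seed)
        fold_sel = {ho: global_sel for ho, _, _ in _fold_frames(table, plan)}
    else:
        fold_sel = {ho: _fold_selection(tr, table, "movement", cfg, sel_seed)
                    for ho, tr, _ in _fold_frames(table, plan)}

    per_repeat = []
    pooled_true: list = []
    pooled_pred: list = []
    for rseed in plan.repeat_seeds:
        rt, rp = [], []
        for held_out, train_df, test_df in _fold_frames(table, plan):
            if set(test_df["movement"]) - set(train_df["movement"]):
                flags.append(f"fold {held_out}: test contains unseen movement")
            clf = train_movement_classifier(_subtable(table, train_df),
                                            fold_sel[held_out], seed=rseed)
            rt.extend(test_df["movement"].tolist())
            rp.extend(clf.predict(test_df).tolist())
        per_repeat.append(micro_f1(rt, rp))
        pooled_true.extend(rt)
        pooled_pred.extend(rp)

    cm = _confusion(pooled_true, pooled_pred, classes)
    return EvaluationReport(
        task="movement_id", per_repeat_f1=per_repeat, confusion=cm,
        per_class=_per_class(cm),
        chosen_k=[fold_sel[ho].chosen_k for ho, _, _ in _fold_frames(table, plan)],
        flags=flags,
    )


def _overall_vote(df: pd.DataFrame, pred_col: str) -> pd.DataFrame:
    """Majority-vote one grade per (subject, movement, side)."""
    rows = []
    for (subj, mov, side), g in df.groupby(["subject_id", "movement", "side"], sort=True):
        rows.append({
            "subject_id": subj, "movement": mov, "side": side,
            "true": g["grade"].iloc[0],
            "pred": aggregate_majority(list(g[pred_col])),
        })
    return pd.DataFrame(rows)


def evaluate_proficiency(table: FeatureTable, config: EvalConfig | None = None,
                         movements: list[str] | None = None,
                         include_unified: bool = True,
                         ) -> dict[str, EvaluationReport]:
    """LOSO evaluation of the per-movement proficiency models (and the unified
    model), each reported at repetition level and at majority-vote level."""
    cfg = config or EvalConfig()
    df = table.data
    if (df["grade"].astype(str) == "").any():
        raise ValueError("grade labels missing")
    movements = movements or sorted(df["movement"].unique())
    plan = make_loso_plan(df["subject_id"].unique(), cfg.n_repeats, cfg.seed)
    sel_seed = plan.repeat_seeds[0]
    reports: dict[str, EvaluationReport] = {}

    tasks: list[tuple[str, pd.DataFrame]] = [(m, df[df["movement"] == m]) for m in movements]
    if include_unified:
        tasks.append(("unified", df))

    for name, tdf in tasks:
        flags: list[str] = []
        excluded = tdf.groupby(["subject_id", "movement", "side"])["grade"].count()
        if (excluded == 0).any():
            flags.append("subject-movement with zero scored repetitions excluded")
        if cfg.selection_mode == "paper":
            sel_all = _fold_selection(tdf, table, "grade", cfg, sel_seed)
        fold_sel: dict[str, SelectionResult] = {}
        per_repeat, per_repeat_overall = [], []
        pooled = []
        for ri, rseed in enumerate(plan.repeat_seeds):
            preds = []
            for held_out, train_subjects in plan.folds:
                tr = tdf[tdf["subject_id"].isin(train_subjects)]
                te = tdf[tdf["subject_id"] == held_out]
                if te.empty:
                    continue
                if len(np.unique(tr["grade"])) < 2:
                    flags.append(f"fold {held_out}: single training grade (degenerate)")
                if held_out not in fold_sel:
                    fold_sel[held_out] = (sel_all if cfg.selection_mode == "paper"
                                          else _fold_selection(tr, table, "grade", cfg, sel_seed))
                sel = fold_sel[held_out]
                if name == "unified":
                    bank = train_unified_model(_subtable(table, tr), sel, seed=rseed)
                    model, feats = bank.unified, bank.unified_features
                else:
                    bank = train_proficiency_bank(_subtable(table, tr), {name: sel}, seed=rseed)
                    model, feats = bank.models[name], bank.features[name]
                p = model.predict(te[feats].to_numpy(dtype=float))
                sub = te[["subject_id", "movement", "side", "grade"]].copy()
                sub["pred"] = p
                preds.append(sub)
            rep_df = pd.concat(preds, ignore_index=True)
            per_repeat.append(micro_f1(rep_df["grade"], rep_df["pred"]))
            vote = _overall_vote(rep_df, "pred")
            per_repeat_overall.append(micro_f1(vote["true"], vote["pred"]))
            pooled.append(rep_df)
            if ri == 0:
                first_vote = vote
        pooled_df = pd.concat(pooled, ignore_index=True)
        cm = _confusion(pooled_df["grade"], pooled_df["pred"], GRADES)
        ov_cm = _confusion(first_vote["true"], first_vote["pred"], GRADES)
        reports[name] = EvaluationReport(
            task=f"proficiency_{name}", per_repeat_f1=per_repeat,
            confusion=cm, per_class=_per_class(cm),
            chosen_k=[s.chosen_k for s in fold_sel.values()],
            overall_per_repeat_f1=per_repeat_overall, overall_confusion=ov_cm,
            flags=sorted(set(flags)),
        )
    return reports


def evaluate_hierarchical(table: FeatureTable, config: EvalConfig | None = None,
                          ) -> pd.DataFrame:
    """Run the full cascade under LOSO (single repeat): per repetition, the
    predicted movement routes to that movement's proficiency model.

    Returns a frame with true/predicted movement and true/predicted grade for
    every repetition."""
    cfg = config or EvalConfig()
    df = table.data
    plan = make_loso_plan(df["subject_id"].unique(), 1, cfg.seed)
    seed = plan.repeat_seeds[0]
    out = []
    for held_out, train_df, test_df in _fold_frames(table, plan):
        tr = _subtable(table, train_df)
        mv_sel = _fold_selection(train_df, table, "movement", cfg, seed)
        clf = train_movement_classifier(tr, mv_sel, seed=seed)
        selections = {
            m: _fold_selection(train_df[train_df["movement"] == m], table, "grade", cfg, seed)
            for m in sorted(train_df["movement"].unique())
        }
        bank = train_proficiency_bank(tr, selections, seed=seed)
        scorer = HierarchicalScorer(movement_model=clf, bank=bank)
        preds = scorer.score(test_df)
        sub = test_df[["repetition_id", "subject_id", "movement", "side", "grade"]].copy()
        sub["pred_movement"] = [m for m, _ in preds]
        sub["pred_grade"] = [g for _, g in preds]
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def misrouting_robustness(hier_preds: pd.DataFrame) -> pd.DataFrame:
    """Grade correctness on movement-misclassified repetitions.

    For each (true movement, predicted movement != true), counts how many
    repetitions still received the correct grade from the *wrong* movement's
    proficiency model. Includes a TOTAL row."""
    mis = hier_preds[hier_preds["movement"] != hier_preds["pred_movement"]]
    rows = []
    for (tm, pm), g in mis.groupby(["movement", "pred_movement"], sort=True):
        rows.append({"true_movement": tm, "predicted_movement": pm,
                     "n": len(g), "n_correct_grade": int((g["grade"] == g["pred_grade"]).sum())})
    total = {"true_movement": "TOTAL", "predicted_movement": "", "n": len(mis),
             "n_correct_grade": int((mis["grade"] == mis["pred_grade"]).sum())}
    cols = ["true_movement", "predicted_movement", "n", "n_correct_grade"]
    return pd.DataFrame(rows + [total], columns=cols)


# ---------------------------------------------------------------------------
# Sammon mapping


def _sammon_stress(D: np.ndarray, E: np.ndarray, c: float) -> float:
    iu = np.triu_indices_from(D, k=1)
    d, e = D[iu], E[iu]
    return float(np.sum((d - e) ** 2 / d) / c)


def sammon_project(X: np.ndarray, target_dim: int = 2, seed: int = 0,
                   max_iter: int = 500, tol: float = 1e-6,
                   ) -> tuple[np.ndarray, float, bool]:
    """Sammon mapping: a nonlinear projection minimizing distance distortion
    stress E = (1/sum d_ij) * sum (d_ij - D_ij)^2 / d_ij.

    Starts from the PCA projection and descends the analytic gradient with
    step halving, so the stress never increases across accepted iterations.
    Duplicate points are epsilon-regularized and flagged.

    Returns (coordinates, final_stress, duplicates_flagged).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if target_dim not in (2, 3):
        raise ValueError("target_dim must be 2 or 3")
    if n < target_dim + 1:
        raise ValueError("need at least target_dim + 1 points")
    D = squareform(pdist(X))
    eps = 1e-8 * max(D.max(), 1.0)
    flagged = bool((D[np.triu_indices(n, 1)] < eps).any())
    D = np.where(D < eps, eps, D)
    np.fill_diagonal(D, 0.0)
    c = float(D[np.triu_indices(n, 1)].sum())

    rng = np.random.default_rng(seed)
    Y = PCA(n_components=target_dim, random_state=0).fit_transform(X)
    if flagged:  # break exact ties so gradients are finite
        Y = Y + 1e-9 * rng.standard_normal(Y.shape)

    def embedded(Yc):
        E = squareform(pdist(Yc))
        return np.where(E < eps, eps, E)

    E = embedded(Y)
    stress = _sammon_stress(D, E, c)
    lr = 0.3
    for _ in range(max_iter):
        Dm = D.copy()
        np.fill_diagonal(Dm, 1.0)
        Em = E.copy()
        np.fill_diagonal(Em, 1.0)
        W = (D - E) / (Dm * Em)
        np.fill_diagonal(W, 0.0)
        grad = -2.0 / c * ((W.sum(axis=1)[:, None]) * Y - W @ Y)
        gnorm = np.abs(grad).max()
        if gnorm == 0:
            break
        step = lr / gnorm * max(np.abs(Y).max(), 1e-12)
        accepted = False
        for _ in range(30):
            Y_new = Y - step * grad
            E_new = embedded(Y_new)
            s_new = _sammon_stress(D, E_new, c)
            if s_new <= stress:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        improvement = stress - s_new
        Y, E, stress = Y_new, E_new, s_new
        lr = min(lr * 1.1, 1.0)
        if improvement < tol * max(stress, 1e-12):
            break
    return Y, stress, flagged
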