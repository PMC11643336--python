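"""Feature selection and the hierarchical Random Forest cascade.

Selection is minimum-redundancy-maximum-relevance (mRMR) with the additive
MID criterion: features are greedily ranked by mutual information with the
label minus their mean mutual information with already-selected features.
Continuous features are discretized into 3 equal-frequency bins for the MI
estimates. The number of features kept is the smallest k whose score curve
reaches 95% of the score obtained with the full feature set.

The cascade is: a 6-class movement classifier (Random Forest, 100 trees,
out-of-bag accuracy estimate) routes each repetition to that movement's
3-class proficiency model; a subject's overall grade for a movement is the
majority vote over its repetitions, with ties broken toward the lower grade
(the conservative choice for a balance-training context). No class
rebalancing is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .session_io import GRADES, FeatureTable, GrossCompetencyScore

__all__ = [
    "discretize_score",
    "mrmr_rank",
    "SelectionResult",
    "select_feature_count",
    "MovementClassifier",
    "ProficiencyModelBank",
    "HierarchicalScorer",
    "train_movement_classifier",
    "train_proficiency_bank",
    "train_unified_model",
    "score_repetitions",
    "aggregate_majority",
]

N_TREES = 100
_GRADE_ORDER = {g: i for i, g in enumerate(GRADES)}  # low < medium < high


def discretize_score(value: float) -> str:
    """Grade of a gross-competency score: <3 low, [3,4) medium, >=4 high."""
    return GrossCompetencyScore(movement="RTP", side="n/a", value=value).grade


# ---------------------------------------------------------------------------
# mRMR


def _discretize_columns(X: np.ndarray, bins: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency discretization per column. Returns (codes, is_constant)."""
    n, d = X.shape
    codes = np.zeros((n, d), dtype=np.int64)
    const = np.zeros(d, dtype=bool)
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    for j in range(d):
        col = X[:, j]
        if np.ptp(col) == 0:
            const[j] = True
            continue
        edges = np.unique(np.quantile(col, qs))
        codes[:, j] = np.searchsorted(edges, col, side="right")
    return codes, const


def _mi_from_joint(joint: np.ndarray) -> float:
    """Mutual information (nats) from a joint count table."""
    n = joint.sum()
    if n == 0:
        return 0.0
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    return float(np.nansum(terms))


def _mi_one_vs_many(code: np.ndarray, onehot: np.ndarray, n_levels: int,
                    d: int, levels: int) -> np.ndarray:
    """MI between one coded column and all d coded columns (via one-hot)."""
    a = np.zeros((len(code), n_levels))
    a[np.arange(len(code)), code] = 1.0
    joint = a.T @ onehot  # (n_levels, d*levels)
    out = np.empty(d)
    for j in range(d):
        out[j] = _mi_from_joint(joint[:, j * levels:(j + 1) * levels])
    return out


def mrmr_rank(table: FeatureTable | pd.DataFrame, label_column: str,
              feature_names: list[str] | None = None, bins: int = 3,
              top_k: int | None = None) -> list[str]:
    """Greedy mRMR (additive MID) ranking of features against a label.

    Deterministic given the table; ties are broken by registry order.
    Zero-variance features carry zero relevance and are appended at the end of
    the ranking (never dropped). ``top_k`` truncates the greedy search; the
    remaining features are appended in relevance order.
    """
    if isinstance(table, FeatureTable):
        df = table.data
        names = feature_names or table.feature_names
    else:
        df = table
        names = feature_names or [c for c in df.columns if c != label_column]
    if len(names) < 1:
        raise ValueError("need at least one feature")
    y = df[label_column].to_numpy()
    if len(np.unique(y)) < 2 and len(names) > 1:
        raise ValueError("label must have at least 2 classes")
    X = df[names].to_numpy(dtype=float)
    codes, const = _discretize_columns(X, bins=bins)
    _, y_codes = np.unique(y, return_inverse=True)
    n_y = int(y_codes.max()) + 1
    d = len(names)

    onehot = np.zeros((len(X), d * bins))
    onehot[np.repeat(np.arange(len(X)), d),
           np.tile(np.arange(d) * bins, len(X)) + codes.reshape(-1)] = 1.0

    relevance = _mi_one_vs_many(y_codes, onehot, n_y, d, bins)
    relevance[const] = 0.0

    live = [j for j in range(d) if not const[j]]
    k_max = len(live) if top_k is None else min(top_k, len(live))
    selected: list[int] = []
    redundancy_sum = np.zeros(d)
    for _ in range(k_max):
        if not selected:
            scores = relevance
        else:
            scores = relevance - redundancy_sum / len(selected)
        best, best_score = None, -np.inf
        for j in live:
            if scores[j] > best_score + 1e-15:
                best, best_score = j, scores[j]
        selected.append(best)
        live.remove(best)
        mi_new = _mi_one_vs_many(codes[:, best], onehot, bins, d, bins)
        redundancy_sum += mi_new
    # truncated search: append remaining live features by relevance, then constants
    rest = sorted(live, key=lambda j: (-relevance[j], j))
    tail = [j for j in range(d) if const[j]]
    order = selected + rest + tail
    return [names[j] for j in order]


# ---------------------------------------------------------------------------
# 95%-of-full-set selection rule


@dataclass
class SelectionResult:
    """Score curve over nested feature subsets and the chosen size.

    ``chosen_k`` is the smallest evaluated k whose score reaches
    ``threshold * reference_score``, where the reference is the score with the
    full feature set (the largest evaluated k).
    """

    ranking: list[str]
    k_grid: list[int]
    curve: list[float]
    chosen_k: int
    threshold: float
    reference_score: float
    evaluator_seed: int | None = None

    @property
    def selected_features(self) -> list[str]:
        return self.ranking[: self.chosen_k]

    def check(self) -> None:
        cutoff = self.threshold * self.reference_score
        for k, s in zip(self.k_grid, self.curve):
            if k < self.chosen_k and s >= cutoff:
                raise AssertionError(f"curve({k})={s} >= cutoff but chosen_k={self.chosen_k}")
            if k == self.chosen_k and s < cutoff:
                raise AssertionError(f"curve(chosen_k)={s} < cutoff {cutoff}")


def select_feature_count(table: FeatureTable | pd.DataFrame, ranking: list[str],
                         evaluator, threshold: float = 0.95,
                         k_grid: list[int] | None = None,
                         evaluator_seed: int | None = None) -> SelectionResult:
    """Choose the smallest prefix of ``ranking`` reaching 95% of the full-set
    score.

    ``evaluator(table, features) -> micro F1``. The curve is evaluated on
    ``k_grid`` (default: every k from 1 to len(ranking)); the largest grid
    point is the full-set reference K. An evaluator failure aborts with the
    partial curve attached to the raised error.
    """
    K = len(ranking)
    grid = sorted(set(k_grid)) if k_grid else list(range(1, K + 1))
    if grid[-1] != K:
        grid.append(K)
    if grid[0] < 1 or grid[-1] > K:
        raise ValueError("k_grid out of range")
    curve: list[float] = []
    for k in grid:
        try:
            curve.append(float(evaluator(table, ranking[:k])))
        except Exception as e:
            err = RuntimeError(f"evaluator failed at k={k}: {e}")
            err.partial_curve = list(zip(grid[: len(curve)], curve))  # type: ignore[attr-defined]
            raise err from e
    reference = curve[-1]
    cutoff = threshold * reference
    chosen_k = next(k for k, s in zip(grid, curve) if s >= cutoff)
    result = SelectionResult(ranking=list(ranking), k_grid=grid, curve=curve,
                             chosen_k=chosen_k, threshold=threshold,
                             reference_score=reference, evaluator_seed=evaluator_seed)
    result.check()
    return result


def oob_evaluator(seed: int, n_trees: int = N_TREES, label_column: str = "movement"):
    """Default selection evaluator: out-of-bag micro F1 of a Random Forest
    restricted to the candidate features."""

    def evaluate(table: FeatureTable | pd.DataFrame, features: list[str]) -> float:
        df = table.data if isinstance(table, FeatureTable) else table
        X = df[features].to_numpy(dtype=float)
        y = df[label_column].to_numpy()
        rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                    random_state=seed, n_jobs=1)
        rf.fit(X, y)
        return float(rf.oob_score_)  # accuracy == micro F1 for single-label tasks

    return evaluate


# ---------------------------------------------------------------------------
# Models


@dataclass
class MovementClassifier:
    forest: RandomForestClassifier
    selected_features: list[str]
    classes: list[str]
    seed: int
    oob_micro_f1: float
    registry_hash: str = ""

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(X[self.selected_features].to_numpy(dtype=float))


@dataclass
class ProficiencyModelBank:
    """One 3-class forest per movement, each with its own feature subset."""

    models: dict[str, RandomForestClassifier]
    features: dict[str, list[str]]
    degenerate: dict[str, bool]
    seed: int
    registry_hash: str = ""
    unified: RandomForestClassifier | None = None
    unified_features: list[str] = field(default_factory=list)

    def predict_grade(self, movement: str, X: pd.DataFrame) -> np.ndarray:
        model = self.models[movement]
        return model.predict(X[self.features[movement]].to_numpy(dtype=float))


@dataclass
class HierarchicalScorer:
    """Movement classifier routing to per-movement proficiency models."""

    movement_model: MovementClassifier
    bank: ProficiencyModelBank

    def score(self, X: pd.DataFrame) -> list[tuple[str, str]]:
        return score_repetitions(self, X)


def _fit_forest(X: np.ndarray, y: np.ndarray, seed: int) -> RandomForestClassifier:
    rf = RandomForestClassifier(n_estimators=N_TREES, oob_score=True,
                                random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


def train_movement_classifier(table: FeatureTable, selection: SelectionResult,
                              seed: int) -> MovementClassifier:
    """100-tree Random Forest over the selected features, labeled by movement."""
    df = table.data
    y = df["movement"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need >= 2 movement classes, got {list(classes)}")
    thin = [str(c) for c, n in zip(classes, counts) if n < 2]
    if thin:
        raise ValueError(f"movement classes with < 2 samples: {thin}")
    feats = selection.selected_features
    rf = _fit_forest(df[feats].to_numpy(dtype=float), y, seed)
    return MovementClassifier(forest=rf, selected_features=feats,
                              classes=[str(c) for c in rf.classes_], seed=seed,
                              oob_micro_f1=float(rf.oob_score_),
                              registry_hash=table.hash)


def train_proficiency_bank(table: FeatureTable,
                           selections: dict[str, SelectionResult],
                           seed: int) -> ProficiencyModelBank:
    """One 3-class forest per movement with its own selected features.

    Class imbalance is left as-is. A movement whose training data carries a
    single grade is still trained but flagged degenerate.
    """
    df = table.data
    if (df["grade"].astype(str) == "").any():
        raise ValueError("grade labels missing for some repetitions")
    models: dict[str, RandomForestClassifier] = {}
    feats: dict[str, list[str]] = {}
    degenerate: dict[str, bool] = {}
    for movement, sel in selections.items():
        sub = df[df["movement"] == movement]
        if sub.empty:
            raise ValueError(f"no repetitions for movement {movement}")
        y = sub["grade"].to_numpy()
        f = sel.selected_features
        models[movement] = _fit_forest(sub[f].to_numpy(dtype=float), y, seed)
        feats[movement] = f
        degenerate[movement] = len(np.unique(y)) < 2
    return ProficiencyModelBank(models=models, features=feats, degenerate=degenerate,
                                seed=seed, registry_hash=table.hash)


def train_unified_model(table: FeatureTable, selection: SelectionResult,
                        seed: int, bank: ProficiencyModelBank | None = None,
                        ) -> ProficiencyModelBank:
    """Train the single grade model over all movements; attaches to ``bank``
    if given (returns a bank either way)."""
    df = table.data
    f = selection.selected_features
    rf = _fit_forest(df[f].to_numpy(dtype=float), df["grade"].to_numpy(), seed)
    if bank is None:
        bank = ProficiencyModelBank(models={}, features={}, degenerate={}, seed=seed,
                                    registry_hash=table.hash)
    bank.unified = rf
    bank.unified_features = f
    return bank


def score_repetitions(scorer: HierarchicalScorer, X: pd.DataFrame,
                      table_hash: str | None = None) -> list[tuple[str, str]]:
    """Predict (movement, grade) for each repetition.

    The movement is predicted first; the *predicted* movement's proficiency
    model then assigns the grade — routing never peeks at the true movement,
    so a misrouted repetition is graded by the wrong movement's model.
    """
    if table_hash is not None and scorer.movement_model.registry_hash \
            and table_hash != scorer.movement_model.registry_hash:
        raise ValueError("feature registry hash mismatch between scorer and table")
    if len(X) == 0:
        return []
    movements = scorer.movement_model.predict(X)
    grades = np.empty(len(X), dtype=object)
    for m in np.unique(movements):
        idx = np.nonzero(movements == m)[0]
        grades[idx] = scorer.bank.predict_grade(str(m), X.iloc[idx])
    return list(zip(movements.tolist(), grades.tolist()))


def aggregate_majority(grades: list[str]) -> str:
    """Modal grade over one subject's repetitions of one movement; ties break
    toward the lower grade."""
    if not grades:
        raise ValueError("cannot aggregate an empty set of predictions")
    unknown = set(grades) - set(GRADES)
    if unknown:
        raise ValueError(f"unknown grades {sorted(unknown)}")
    counts = {g: 0 for g in GRADES}
    for g in grades:
        counts[g] += 1
    best = max(counts.values())
    for g in GRADES:  # ordered low -> high, so the first maximal count wins
        if counts[g] == best:
            return g
    raise AssertionError("unreachable")
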