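"""End-to-end glue: session -> filtered channels -> repetitions -> features.

These helpers chain the preprocessing, segmentation, and extraction stages for
whole sessions and cohorts, using only information real recordings would have
(markers and expert scores); generator ground truth is consulted only by the
separate segmentation-accuracy helper.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureSpec, default_registry, extract_table
from .preprocess import FilterConfig, filter_session
from .segment import SegmentConfig, segment_session
from .session_io import FeatureTable, Session, registry_hash


def session_features(session: Session,
                     registry: list[FeatureSpec] | None = None,
                     filter_config: FilterConfig | None = None,
                     segment_config: SegmentConfig | None = None,
                     expected_counts: dict[int, int] | None = None,
                     ) -> tuple[FeatureTable, list]:
    """Full single-session pipeline. Returns (feature table, segmentation results).

    Grades come from the session's expert scores, discretized; repetitions of
    unscored (movement, side) blocks carry an empty grade.
    """
    registry = registry if registry is not None else default_registry()
    filtered = filter_session(session, filter_config)
    results = segment_session(session, filtered, segment_config, expected_counts)
    reps = [r for res in results for r in res.repetitions]
    grades = {}
    for r in reps:
        score = session.score_for(r.movement, r.side)
        if score is not None:
            grades[r.repetition_id] = score.grade
    table = extract_table(reps, filtered, registry, grades)
    return table, results


def cohort_features(sessions: list[Session],
                    registry: list[FeatureSpec] | None = None,
                    filter_config: FilterConfig | None = None,
                    segment_config: SegmentConfig | None = None,
                    ) -> tuple[FeatureTable, pd.DataFrame]:
    """Pipeline over a cohort. Returns (pooled table, per-block review frame)."""
    registry = registry if registry is not None else default_registry()
    names = [s.name for s in registry]
    frames = []
    review_rows = []
    for session in sessions:
        table, results = session_features(session, registry, filter_config, segment_config)
        frames.append(table.data)
        for res in results:
            if res.repetitions:
                r0 = res.repetitions[0]
                review_rows.append({
                    "subject_id": r0.subject_id, "movement": r0.movement,
                    "side": r0.side, "block_index": r0.block_index,
                    "n_repetitions": len(res.repetitions),
                    "needs_review": res.needs_review, "reason": res.review_reason,
                })
    data = pd.concat(frames, ignore_index=True)
    return (FeatureTable(data=data, feature_names=names, hash=registry_hash(names)),
            pd.DataFrame(review_rows))


def segmentation_accuracy(sessions: list[Session],
                          filter_config: FilterConfig | None = None,
                          segment_config: SegmentConfig | None = None,
                          ) -> dict:
    """Compare automatic segmentation against generator ground truth.

    Returns block-level count accuracy and, on blocks with the correct count,
    the absolute boundary errors in seconds.
    """
    n_blocks = 0
    n_correct = 0
    errors: list[float] = []
    for session in sessions:
        if not session.truth:
            raise ValueError(f"session {session.subject_id} carries no ground truth")
        filtered = filter_session(session, filter_config)
        results = segment_session(session, filtered, segment_config)
        truth = pd.DataFrame(session.truth)
        for bi, res in enumerate(results):
            tb = truth[truth["block_index"] == bi].sort_values("rep_index")
            n_blocks += 1
            if len(res.repetitions) != len(tb):
                continue
            n_correct += 1
            rate = res.repetitions[0].rate_hz if res.repetitions else 32.0
            for rep, (_, row) in zip(res.repetitions, tb.iterrows()):
                errors.append(abs(rep.start / rate - row["start_s"]))
                errors.append(abs(rep.end / rate - row["end_s"]))
    return {
        "n_blocks": n_blocks,
        "count_accuracy": n_correct / n_blocks if n_blocks else float("nan"),
        "boundary_errors_s": np.asarray(errors),
        "max_boundary_error_s": float(np.max(errors)) if errors else float("nan"),
    }
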