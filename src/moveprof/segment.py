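"""Session -> movement blocks -> individual repetitions.

Movement blocks come straight from the technician-placed markers. Inside a
block, repetitions are separated by the brief pauses subjects take between
the end of one execution and the start of the next; in the angular-velocity
magnitude these pauses show up as sustained near-zero ("zero crossing")
intervals. True zeros never occur in noisy data, so a pause is operationalized
as a maximal interval where a smoothed gyro-magnitude envelope stays below a
threshold (default 10 deg/s) for a minimum duration (default 0.2 s).
Repetition boundaries are placed at pause midpoints.

A count mismatch against an expected repetition count is never silently
forced: the result is flagged for manual review, mirroring the manual
confirmation step of the original protocol, and boundaries can be replaced
from an override file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import FilteredChannelSet

__all__ = [
    "SegmentConfig",
    "MovementBlock",
    "PauseEvent",
    "Repetition",
    "SegmentationResult",
    "split_movements",
    "velocity_envelope",
    "detect_pauses",
    "segment_repetitions",
    "segment_session",
]


@dataclass(frozen=True)
class SegmentConfig:
    """Thresholds for pause detection; all values are design choices."""

    threshold_dps: float = 10.0
    min_pause_s: float = 0.2
    min_repetition_s: float = 1.0
    smooth_window_s: float = 0.25
    envelope_placements: tuple[str, ...] = ("l_wrist", "r_wrist")
    boundary: str = "midpoint"  # "midpoint" | "minimum"


@dataclass
class MovementBlock:
    """One marker's worth of working-rate samples across all placements."""

    subject_id: str
    movement: str
    side: str
    block_index: int
    start_s: float
    end_s: float
    rate_hz: float
    channels: dict[str, FilteredChannelSet]  # sliced to the block
    start_sample: int  # offset of the block in the working-rate session


@dataclass(frozen=True)
class PauseEvent:
    start: int  # samples, block-relative
    end: int    # exclusive
    mean_magnitude: float

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Repetition:
    subject_id: str
    movement: str
    side: str
    block_index: int
    rep_index: int
    start: int  # working-rate samples, session-relative
    end: int    # exclusive
    rate_hz: float
    source: str = "marker+auto"  # or "manual-override"

    @property
    def repetition_id(self) -> str:
        return (f"{self.subject_id}:{self.movement}:{self.side}:"
                f"b{self.block_index}:r{self.rep_index}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.rate_hz


@dataclass
class SegmentationResult:
    repetitions: list[Repetition]
    needs_review: bool = False
    review_reason: str = ""
    pauses: list[PauseEvent] = field(default_factory=list)


def _slice_channels(channels: dict[str, FilteredChannelSet], i0: int, i1: int,
                    ) -> dict[str, FilteredChannelSet]:
    out = {}
    for p, fc in channels.items():
        out[p] = FilteredChannelSet(
            placement=p, rate_hz=fc.rate_hz, t=fc.t[i0:i1],
            lp={k: v[i0:i1] for k, v in fc.lp.items()},
            bp={k: v[i0:i1] for k, v in fc.bp.items()},
        )
    return out


def split_movements(session, filtered: dict[str, FilteredChannelSet]) -> list[MovementBlock]:
    """Cut the filtered session into one block per marker; samples outside
    markers are discarded. Markers are in seconds so they survive the rate
    change from acquisition to working rate."""
    if not filtered:
        raise ValueError("no filtered channels supplied")
    any_fc = next(iter(filtered.values()))
    rate = any_fc.rate_hz
    n = len(any_fc.t)
    t0 = float(any_fc.t[0])
    blocks: list[MovementBlock] = []
    for bi, m in enumerate(sorted(session.markers, key=lambda mk: mk.start_s)):
        i0 = int(round((m.start_s - t0) * rate))
        i1 = int(round((m.end_s - t0) * rate))
        if i0 < 0 or i1 > n:
            raise ValueError(
                f"marker {m.movement}/{m.side} [{m.start_s}, {m.end_s}] s "
                f"extends beyond the {n / rate:.2f} s working-rate signal"
            )
        blocks.append(MovementBlock(
            subject_id=session.subject_id, movement=m.movement, side=m.side,
            block_index=bi, start_s=m.start_s, end_s=m.end_s, rate_hz=rate,
            channels=_slice_channels(filtered, i0, i1), start_sample=i0,
        ))
    return blocks


def velocity_envelope(block: MovementBlock,
                      placements: tuple[str, ...] = ("l_wrist", "r_wrist"),
                      smooth_window_s: float = 0.25) -> np.ndarray:
    """Non-negative angular-speed envelope of a block.

    Euclidean norm of each requested placement's low-pass gyro vector,
    smoothed with a centered moving average (a monotone low-pass FIR: no
    ringing below the pause threshold), averaged over placements.
    """
    envs = []
    for p in placements:
        if p not in block.channels:
            raise KeyError(f"placement {p!r} not present in block")
        gyro = block.channels[p].lp["gyro"]
        envs.append(np.linalg.norm(gyro, axis=1))
    env = np.mean(envs, axis=0)
    win = max(1, int(round(smooth_window_s * block.rate_hz)))
    if win > 1:
        kernel = np.ones(win) / win
        pad = win // 2
        padded = np.pad(env, pad, mode="edge")
        env = np.convolve(padded, kernel, mode="same")[pad:pad + len(env)]
    return env


def detect_pauses(envelope: np.ndarray, threshold_dps: float = 10.0,
                  min_pause_s: float = 0.2, rate_hz: float = 32.0) -> list[PauseEvent]:
    """Maximal sub-threshold intervals of the envelope lasting >= min_pause_s."""
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        return []
    below = env < threshold_dps
    # edges of runs of True
    diff = np.diff(below.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(env))
    min_len = int(np.ceil(min_pause_s * rate_hz))
    pauses = []
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            pauses.append(PauseEvent(start=int(s), end=int(e),
                                     mean_magnitude=float(env[s:e].mean())))
    return pauses


def segment_repetitions(block: MovementBlock, pauses: list[PauseEvent],
                        expected_count: int | None = None,
                        config: SegmentConfig | None = None,
                        envelope: np.ndarray | None = None) -> SegmentationResult:
    """Cut a block into repetitions at pause midpoints.

    Leading/trailing fragments shorter than the configured minimum repetition
    duration are dropped. If ``expected_count`` is given and the recovered
    count differs, the result is returned flagged for manual review rather
    than silently coerced.
    """
    cfg = config or SegmentConfig()
    n = len(next(iter(block.channels.values())).t)
    min_rep = int(round(cfg.min_repetition_s * block.rate_hz))

    if cfg.boundary == "minimum" and envelope is not None:
        cuts = [int(p.start + np.argmin(envelope[p.start:p.end])) for p in pauses]
    else:
        cuts = [p.mid for p in pauses]
    edges = [0] + sorted(cuts) + [n]

    reps: list[Repetition] = []
    for i0, i1 in zip(edges[:-1], edges[1:]):
        if i1 - i0 < min_rep:
            continue  # sub-minimum fragment (e.g. leading/trailing sliver)
        reps.append(Repetition(
            subject_id=block.subject_id, movement=block.movement, side=block.side,
            block_index=block.block_index, rep_index=len(reps),
            start=block.start_sample + i0, end=block.start_sample + i1,
            rate_hz=block.rate_hz,
        ))
    needs_review = False
    reason = ""
    if not reps:
        needs_review, reason = True, "no repetitions recovered"
    elif expected_count is not None and len(reps) != expected_count:
        needs_review = True
        reason = f"expected {expected_count} repetitions, found {len(reps)}"
    return SegmentationResult(repetitions=reps, needs_review=needs_review,
                              review_reason=reason, pauses=pauses)


def segment_session(session, filtered: dict[str, FilteredChannelSet],
                    config: SegmentConfig | None = None,
                    expected_counts: dict[int, int] | None = None,
                    ) -> list[SegmentationResult]:
    """Full segmentation of a session: one SegmentationResult per marker block."""
    cfg = config or SegmentConfig()
    results = []
    for block in split_movements(session, filtered):
        env = velocity_envelope(block, cfg.envelope_placements, cfg.smooth_window_s)
        pauses = detect_pauses(env, cfg.threshold_dps, cfg.min_pause_s, block.rate_hz)
        expected = (expected_counts or {}).get(block.block_index)
        results.append(segment_repetitions(block, pauses, expected, cfg, envelope=env))
    return results


def apply_overrides(result: SegmentationResult, overrides: dict[str, tuple[float, float]],
                    rate_hz: float) -> SegmentationResult:
    """Replace repetition boundaries from a manual-override map
    (repetition_id -> (start_s, end_s), session-relative seconds)."""
    reps = []
    for r in result.repetitions:
        if r.repetition_id in overrides:
            s, e = overrides[r.repetition_id]
            r = replace(r, start=int(round(s * rate_hz)), end=int(round(e * rate_hz)),
                        source="manual-override")
        reps.append(r)
    return SegmentationResult(repetitions=reps, needs_review=False,
                              review_reason="", pauses=result.pauses)
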