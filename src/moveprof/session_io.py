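"""Data model and on-disk formats for multi-sensor IMU sessions.

A *session* is one subject's recording: thirteen body-worn 9-axis IMUs
(tri-axial accelerometer in g, gyroscope in deg/s, magnetometer in gauss),
movement start/end markers, and expert gross-competency scores. Sessions are
stored as one CSV per sensor plus a JSON manifest; feature tables as CSV with
an embedded registry hash; trained models as joblib bundles.

All readers validate: every documented invariant violation raises a typed
error rather than being clipped or silently repaired.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

__all__ = [
    "PLACEMENTS",
    "BILATERAL_SITES",
    "MOVEMENTS",
    "GRADES",
    "ACCEL_RANGE_G",
    "GYRO_RANGE_DPS",
    "MAG_RANGE_G",
    "SessionFormatError",
    "IncompleteSessionError",
    "RangeError",
    "SchemaError",
    "ImuChannelSet",
    "MovementMarker",
    "GrossCompetencyScore",
    "Session",
    "FeatureTable",
    "read_session",
    "write_session",
    "read_feature_table",
    "write_feature_table",
    "save_model_bundle",
    "load_model_bundle",
    "registry_hash",
]

#: The 13 body sites of the full-body montage. Bilateral sites carry l_/r_ tags.
PLACEMENTS: tuple[str, ...] = (
    "chest",
    "abdomen",
    "sacrum",
    "l_upper_arm",
    "r_upper_arm",
    "l_wrist",
    "r_wrist",
    "l_thigh",
    "r_thigh",
    "l_shank",
    "r_shank",
    "l_ankle",
    "r_ankle",
)

BILATERAL_SITES: tuple[str, ...] = ("upper_arm", "wrist", "thigh", "shank", "ankle")

#: The six protocol movements. RTP is performed in a single (symmetric) variant;
#: the other five are practiced with both right and left foot forward.
MOVEMENTS: tuple[str, ...] = ("RTP", "PUSH", "GST", "WHLC", "BKTS", "GR")

GRADES: tuple[str, ...] = ("low", "medium", "high")

# Hardware full-scale ranges the sensors were configured to.
ACCEL_RANGE_G = 4.0
GYRO_RANGE_DPS = 2000.0
MAG_RANGE_G = 1.9

_CSV_COLUMNS = [
    "t_s",
    "ax_g", "ay_g", "az_g",
    "gx_dps", "gy_dps", "gz_dps",
    "mx_G", "my_G", "mz_G",
]
_FLOAT_FMT = "%.6f"


class SessionFormatError(ValueError):
    """Malformed session data (non-monotone time, bad marker, bad schema)."""


class IncompleteSessionError(SessionFormatError):
    """A session is missing one or more of the 13 required placements."""


class RangeError(SessionFormatError):
    """A sample exceeds the configured sensor full-scale range."""


class SchemaError(ValueError):
    """A feature table on disk does not match the feature registry."""


def _as_f64(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise SessionFormatError(f"{name} must be an (n, 3) array, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise SessionFormatError(f"{name} contains non-finite samples")
    return arr


@dataclass
class ImuChannelSet:
    """One sensor's synchronized tri-axial accel/gyro/mag series.

    Units are fixed at g / deg/s / gauss so the hardware range invariants
    (±4 g, ±2000 deg/s, ±1.9 G) are meaningful. Time is seconds from session
    start and must be strictly increasing.
    """

    placement: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.accel = _as_f64(self.accel, "accel")
        self.gyro = _as_f64(self.gyro, "gyro")
        self.mag = _as_f64(self.mag, "mag")
        n = len(self.t)
        if self.t.ndim != 1:
            raise SessionFormatError("t must be 1-D")
        for name, arr in (("accel", self.accel), ("gyro", self.gyro), ("mag", self.mag)):
            if len(arr) != n:
                raise SessionFormatError(
                    f"{self.placement}: {name} length {len(arr)} != time length {n}"
                )
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise SessionFormatError(f"{self.placement}: time base not strictly increasing")
        if self.rate_hz <= 0:
            raise SessionFormatError(f"{self.placement}: rate_hz must be positive")
        self._check_range("accel", self.accel, ACCEL_RANGE_G)
        self._check_range("gyro", self.gyro, GYRO_RANGE_DPS)
        self._check_range("mag", self.mag, MAG_RANGE_G)

    def _check_range(self, name: str, arr: np.ndarray, limit: float) -> None:
        bad = np.abs(arr) > limit
        if bad.any():
            i, ax = np.argwhere(bad)[0]
            raise RangeError(
                f"{self.placement}/{name}: sample {i} axis {ax} is "
                f"{arr[i, ax]:+.4f}, beyond full-scale ±{limit}"
            )

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.t, self.accel, self.gyro, self.mag]),
            columns=_CSV_COLUMNS,
        )


@dataclass(frozen=True)
class MovementMarker:
    """A technician-placed movement block: [start_s, end_s) within the session."""

    movement: str
    side: str  # "left" | "right" | "n/a"
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENTS:
            raise SessionFormatError(f"unknown movement label {self.movement!r}")
        if self.side not in ("left", "right", "n/a"):
            raise SessionFormatError(f"invalid side {self.side!r}")
        if not self.start_s < self.end_s:
            raise SessionFormatError(
                f"marker {self.movement}/{self.side}: start {self.start_s} >= end {self.end_s}"
            )


def _valid_score_value(value: float) -> bool:
    return 0.0 <= value <= 5.0 and float(value * 2).is_integer()


@dataclass(frozen=True)
class GrossCompetencyScore:
    """Expert gross-competency score: 0-5 in 0.5 steps, discretized to a grade.

    Grade rule: value < 3 -> low; 3 <= value < 4 -> medium; value >= 4 -> high.
    """

    movement: str
    side: str
    value: float

    def __post_init__(self) -> None:
        if not _valid_score_value(self.value):
            raise SessionFormatError(
                f"score {self.value} invalid: must be in 0..5 with 0.5 granularity"
            )

    @property
    def grade(self) -> str:
        if self.value < 3.0:
            return "low"
        if self.value < 4.0:
            return "medium"
        return "high"


@dataclass
class Session:
    """One subject's full recording: 13 channel sets + markers + scores.

    ``truth`` optionally carries generator ground truth (repetition boundaries
    and grades) as a list of plain dicts; it round-trips through the manifest.
    """

    subject_id: str
    channels: dict[str, ImuChannelSet]
    markers: list[MovementMarker] = field(default_factory=list)
    scores: list[GrossCompetencyScore] = field(default_factory=list)
    truth: list[dict] | None = None

    def __post_init__(self) -> None:
        missing = set(PLACEMENTS) - set(self.channels)
        if missing:
            raise IncompleteSessionError(
                f"session {self.subject_id}: missing placements {sorted(missing)}"
            )
        extra = set(self.channels) - set(PLACEMENTS)
        if extra:
            raise SessionFormatError(f"unknown placements {sorted(extra)}")
        # markers must not overlap and must lie inside every channel's time base
        marks = sorted(self.markers, key=lambda m: m.start_s)
        for a, b in zip(marks, marks[1:]):
            if b.start_s < a.end_s:
                raise SessionFormatError(
                    f"overlapping markers {a.movement}/{a.side} and {b.movement}/{b.side}"
                )
        if marks:
            t_end = min(cs.t[-1] for cs in self.channels.values())
            t_start = max(cs.t[0] for cs in self.channels.values())
            if marks[0].start_s < t_start or marks[-1].end_s > t_end + 1e-9:
                raise SessionFormatError("marker extends beyond recorded signal")
        keys = [(s.movement, s.side) for s in self.scores]
        if len(keys) != len(set(keys)):
            raise SessionFormatError("duplicate score for a (movement, side) pair")

    def score_for(self, movement: str, side: str) -> GrossCompetencyScore | None:
        for s in self.scores:
            if s.movement == movement and s.side == side:
                return s
        return None


# ---------------------------------------------------------------------------
# Session CSV/JSON round-trip


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write one CSV per sensor plus ``manifest.json``; returns the manifest path.

    Output is canonical (fixed float format, sorted JSON keys) so identical
    sessions produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for placement in PLACEMENTS:  # fixed order -> stable manifest
        cs = session.channels[placement]
        fname = f"{placement}.csv"
        cs.to_frame().to_csv(out / fname, index=False, float_format=_FLOAT_FMT)
        files[placement] = fname
    manifest = {
        "subject_id": session.subject_id,
        "rate_hz": {p: session.channels[p].rate_hz for p in PLACEMENTS},
        "files": files,
        "markers": [
            {"movement": m.movement, "side": m.side, "start_s": m.start_s, "end_s": m.end_s}
            for m in session.markers
        ],
        "scores": [
            {"movement": s.movement, "side": s.side, "value": s.value}
            for s in session.scores
        ],
    }
    if session.truth is not None:
        manifest["truth"] = session.truth
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def read_session(manifest_path: str | Path) -> Session:
    """Read and fully validate a session from its JSON manifest."""
    path = Path(manifest_path)
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SessionFormatError(f"manifest {path} is not valid JSON: {e}") from e
    files = manifest.get("files", {})
    missing = set(PLACEMENTS) - set(files)
    if missing:
        raise IncompleteSessionError(
            f"manifest lists {len(files)} sensors; missing {sorted(missing)}"
        )
    channels: dict[str, ImuChannelSet] = {}
    for placement in PLACEMENTS:
        fpath = path.parent / files[placement]
        if not fpath.exists():
            raise IncompleteSessionError(f"referenced file {fpath} does not exist")
        df = pd.read_csv(fpath)
        if list(df.columns) != _CSV_COLUMNS:
            raise SessionFormatError(f"{fpath}: expected columns {_CSV_COLUMNS}")
        channels[placement] = ImuChannelSet(
            placement=placement,
            t=df["t_s"].to_numpy(),
            accel=df[["ax_g", "ay_g", "az_g"]].to_numpy(),
            gyro=df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(),
            mag=df[["mx_G", "my_G", "mz_G"]].to_numpy(),
            rate_hz=float(manifest.get("rate_hz", {}).get(placement, 100.0)),
        )
    markers = [MovementMarker(**m) for m in manifest.get("markers", [])]
    scores = [GrossCompetencyScore(**s) for s in manifest.get("scores", [])]
    return Session(
        subject_id=str(manifest["subject_id"]),
        channels=channels,
        markers=markers,
        scores=scores,
        truth=manifest.get("truth"),
    )


# ---------------------------------------------------------------------------
# Feature tables

_LABEL_COLUMNS = ["repetition_id", "subject_id", "movement", "side", "grade"]


def registry_hash(feature_names: list[str] | tuple[str, ...]) -> str:
    """Stable hash of a feature registry (names in registry order)."""
    h = hashlib.sha256("\n".join(feature_names).encode())
    return h.hexdigest()[:16]


@dataclass
class FeatureTable:
    """Repetitions x features with label columns, tied to a registry version.

    ``data`` has columns ``repetition_id, subject_id, movement, side, grade``
    followed by the registry's feature columns in registry order.
    """

    data: pd.DataFrame
    feature_names: list[str]
    hash: str = ""

    def __post_init__(self) -> None:
        if not self.hash:
            self.hash = registry_hash(self.feature_names)
        expected = _LABEL_COLUMNS + list(self.feature_names)
        got = list(self.data.columns)
        if set(got) != set(expected):
            unknown = set(got) - set(expected)
            missing = set(expected) - set(got)
            raise SchemaError(
                f"feature table schema mismatch: unknown={sorted(unknown)}, "
                f"missing={sorted(missing)}"
            )
        if got != expected:  # restore canonical column order
            self.data = self.data[expected]
        vals = self.data[self.feature_names].to_numpy(dtype=float)
        if len(vals) and not np.all(np.isfinite(vals)):
            raise SchemaError("feature table contains non-finite values")

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    def __len__(self) -> int:
        return len(self.data)


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"#registry_hash={table.hash}\n")
        table.data.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_feature_table(path: str | Path, feature_names: list[str]) -> FeatureTable:
    """Read a feature table; column order on disk may be permuted, the
    canonical registry order is restored. Unknown columns raise SchemaError."""
    path = Path(path)
    stored_hash = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#registry_hash="):
            stored_hash = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    expected_hash = registry_hash(feature_names)
    if stored_hash and stored_hash != expected_hash:
        raise SchemaError(
            f"feature table was extracted with registry {stored_hash}, "
            f"current registry is {expected_hash}"
        )
    present = [c for c in feature_names if c in df.columns]
    df = df.astype({c: float for c in present})
    return FeatureTable(data=df, feature_names=list(feature_names), hash=expected_hash)


# ---------------------------------------------------------------------------
# Model bundles


def save_model_bundle(bundle: dict, path: str | Path) -> Path:
    """Serialize a trained model bundle (model, selected features, registry
    hash, training seed) with joblib."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    required = {"registry_hash", "selected_features", "seed"}
    missing = required - set(bundle)
    if missing:
        raise ValueError(f"model bundle missing keys {sorted(missing)}")
    joblib.dump(bundle, path, compress=3)
    return path


def load_model_bundle(path: str | Path) -> dict:
    return joblib.load(path)
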