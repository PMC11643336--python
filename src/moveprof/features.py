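"""Per-repetition feature vector: spectral, orientation, and cross-correlation.

The default registry reconstructs the 378-feature set from its stated
families:

* spectral — per sensor (13) x modality (accel, gyro) x axis (3) x statistic
  (dominant frequency, mean frequency) x band (lowpass, bandpass) = 312;
* orientation — per sensor (13): mean pitch, mean roll, pitch range,
  roll range from the low-pass accelerometer = 52;
* cross-correlation — normalized peak and signed lag of the band-pass gyro
  magnitude for 7 limb pairs (the four ankle-wrist pairs that capture
  inter-limb synchrony, the two bilateral pairs, and chest-sacrum) = 14.

312 + 52 + 14 = 378. The registry is data (an ordered list of specs keyed by
name), so alternative reconstructions are drop-in. Magnetometer channels are
excluded from the default registry.

Spectra use a Hann-windowed periodogram over the full repetition (repetitions
are short, so no segment averaging), zero-padded to a 0.05 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .segment import Repetition
from .session_io import PLACEMENTS, registry_hash

__all__ = [
    "FeatureSpec",
    "FeatureVector",
    "default_registry",
    "dominant_frequency",
    "mean_frequency",
    "orientation_metrics",
    "xcorr_features",
    "extract_features",
    "extract_table",
]

XCORR_PAIRS: tuple[tuple[str, str], ...] = (
    ("r_ankle", "r_wrist"),
    ("r_ankle", "l_wrist"),
    ("l_ankle", "r_wrist"),
    ("l_ankle", "l_wrist"),
    ("r_ankle", "l_ankle"),
    ("r_wrist", "l_wrist"),
    ("chest", "sacrum"),
)

FREQ_GRID_HZ = 0.05
MIN_SAMPLES = 32


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature: family + what it is computed from."""

    name: str
    family: str                     # "spectral" | "orientation" | "xcorr"
    placements: tuple[str, ...]
    modality: str = ""              # "accel" | "gyro"
    axis: int = -1
    band: str = ""                  # "lowpass" | "bandpass"
    statistic: str = ""


def default_registry() -> list[FeatureSpec]:
    """The canonical ordered 378-entry feature registry."""
    specs: list[FeatureSpec] = []
    axes = "xyz"
    for p in PLACEMENTS:
        for modality in ("accel", "gyro"):
            for ax in range(3):
                for band in ("lowpass", "bandpass"):
                    for stat in ("domfreq", "meanfreq"):
                        specs.append(FeatureSpec(
                            name=f"{p}_{modality}_{axes[ax]}_{band}_{stat}",
                            family="spectral", placements=(p,), modality=modality,
                            axis=ax, band=band, statistic=stat,
                        ))
    for p in PLACEMENTS:
        for stat in ("pitch_mean", "roll_mean", "pitch_range", "roll_range"):
            specs.append(FeatureSpec(
                name=f"{p}_orient_{stat}", family="orientation",
                placements=(p,), modality="accel", band="lowpass", statistic=stat,
            ))
    for a, b in XCORR_PAIRS:
        for stat in ("peak", "lag"):
            specs.append(FeatureSpec(
                name=f"xcorr_{a}__{b}_{stat}", family="xcorr",
                placements=(a, b), modality="gyro", band="bandpass", statistic=stat,
            ))
    return specs


def registry_names(registry: list[FeatureSpec] | None = None) -> list[str]:
    return [s.name for s in (registry if registry is not None else default_registry())]


def registry_to_yaml(registry: list[FeatureSpec], path) -> None:
    import yaml

    entries = [
        {"name": s.name, "family": s.family, "placements": list(s.placements),
         "modality": s.modality, "axis": s.axis, "band": s.band,
         "statistic": s.statistic}
        for s in registry
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def registry_from_yaml(path) -> list[FeatureSpec]:
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    specs = [FeatureSpec(name=e["name"], family=e["family"],
                         placements=tuple(e["placements"]), modality=e.get("modality", ""),
                         axis=e.get("axis", -1), band=e.get("band", ""),
                         statistic=e.get("statistic", ""))
             for e in entries]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("registry feature names must be unique")
    return specs


@dataclass
class FeatureVector:
    """One repetition's complete feature vector in registry order."""

    repetition_id: str
    values: dict[str, float]
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Primitives


def _psd(series: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(series, dtype=float)
    nfft = max(len(x), int(np.ceil(rate_hz / FREQ_GRID_HZ)))
    f, p = sp_signal.periodogram(x, fs=rate_hz, window="hann",
                                 nfft=nfft, detrend="constant")
    return f, p


def dominant_frequency(series: np.ndarray, rate_hz: float) -> tuple[float, bool]:
    """Frequency of the PSD maximum over (0, rate/2].

    Returns (frequency_hz, flagged); a zero-power series yields the 0 Hz
    sentinel with the flag set. Resolution is the 0.05 Hz zero-padding grid.
    """
    if len(series) < MIN_SAMPLES:
        raise ValueError(f"series too short for spectral features ({len(series)} samples)")
    f, p = _psd(series, rate_hz)
    p = p[1:]  # exclude DC bin
    f = f[1:]
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        return 0.0, True
    return float(f[int(np.argmax(p))]), False


def mean_frequency(series: np.ndarray, rate_hz: float) -> tuple[float, bool]:
    """Power-weighted spectral centroid sum(f*P)/sum(P) over (0, rate/2]."""
    if len(series) < MIN_SAMPLES:
        raise ValueError(f"series too short for spectral features ({len(series)} samples)")
    f, p = _psd(series, rate_hz)
    p = p[1:]
    f = f[1:]
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        return 0.0, True
    return float((f * p).sum() / total), False


def orientation_metrics(lowpass_accel: np.ndarray) -> tuple[tuple[float, float, float, float], bool]:
    """Pitch/roll statistics from the gravity direction of low-pass accel.

    Convention: pitch = atan2(-ax, sqrt(ay^2 + az^2)), roll = atan2(ay, az),
    both in degrees. Returns ((mean pitch, mean roll, pitch range, roll range),
    flagged). If the gravity magnitude is weak (< 0.5 g sustained) the metrics
    are still computed from the normalized direction but the flag is set.
    """
    a = np.asarray(lowpass_accel, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected (n, 3) accelerometer array")
    norm = np.linalg.norm(a, axis=1)
    flagged = bool(np.mean(norm < 0.5) > 0.5)
    safe = np.where(norm > 1e-9, norm, 1.0)[:, None]
    u = a / safe
    pitch = np.degrees(np.arctan2(-u[:, 0], np.hypot(u[:, 1], u[:, 2])))
    roll = np.degrees(np.arctan2(u[:, 1], u[:, 2]))
    out = (float(pitch.mean()), float(roll.mean()),
           float(pitch.max() - pitch.min()), float(roll.max() - roll.min()))
    return out, flagged


def xcorr_features(series_a: np.ndarray, series_b: np.ndarray, rate_hz: float,
                   max_lag_s: float = 2.0) -> tuple[float, float, bool]:
    """Normalized cross-correlation peak and its signed lag in seconds.

    Positive lag means ``series_b`` lags behind ``series_a``. Peak ties are
    broken toward the smallest |lag|, then toward the negative lag. A
    zero-variance input yields the (0, 0) sentinel with the flag set.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    n = len(a)
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = a.std(), b.std()
    if sa <= 1e-12 or sb <= 1e-12:
        return 0.0, 0.0, True
    cc = sp_signal.correlate(b, a, mode="full") / (n * sa * sb)
    lags = sp_signal.correlation_lags(n, n, mode="full")
    max_lag = int(round(max_lag_s * rate_hz))
    keep = np.abs(lags) <= max_lag
    cc, lags = cc[keep], lags[keep]
    peak = np.max(np.abs(cc))
    # candidates within float tolerance of the peak magnitude
    cand = np.nonzero(np.abs(cc) >= peak - 1e-12)[0]
    cand = sorted(cand, key=lambda i: (abs(int(lags[i])), int(lags[i])))
    i = cand[0]
    return float(cc[i]), float(lags[i] / rate_hz), False


# ---------------------------------------------------------------------------
# Vector assembly


def _gyro_mag_bp(fc, sl: slice) -> np.ndarray:
    return np.linalg.norm(fc.bp["gyro"][sl], axis=1)


def extract_features(repetition: Repetition, filtered: dict, registry: list[FeatureSpec],
                     max_lag_s: float = 2.0) -> FeatureVector:
    """Compute the full registry-ordered feature vector for one repetition.

    ``filtered`` maps placement -> FilteredChannelSet at the working rate
    (session-relative sample indexing). Sentinel uses are recorded in
    ``flags``; all values are finite.
    """
    sl = slice(repetition.start, repetition.end)
    n = repetition.end - repetition.start
    if n < MIN_SAMPLES:
        raise ValueError(
            f"repetition {repetition.repetition_id} too short: {n} samples"
        )
    rate = repetition.rate_hz
    values: dict[str, float] = {}
    flags: set[str] = set()

    psd_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    orient_cache: dict[str, tuple] = {}
    mag_cache: dict[str, np.ndarray] = {}

    for spec in registry:
        if spec.family == "spectral":
            p = spec.placements[0]
            key = (p, spec.modality, spec.axis, spec.band)
            if key not in psd_cache:
                fc = filtered[p]
                arr = (fc.lp if spec.band == "lowpass" else fc.bp)[spec.modality]
                psd_cache[key] = _psd(arr[sl, spec.axis], rate)
            f, pw = psd_cache[key]
            pw1, f1 = pw[1:], f[1:]
            total = pw1.sum()
            if total <= 0 or not np.isfinite(total):
                values[spec.name] = 0.0
                flags.add(spec.name)
            elif spec.statistic == "domfreq":
                values[spec.name] = float(f1[int(np.argmax(pw1))])
            else:
                values[spec.name] = float((f1 * pw1).sum() / total)
        elif spec.family == "orientation":
            p = spec.placements[0]
            if p not in orient_cache:
                orient_cache[p] = orientation_metrics(filtered[p].lp["accel"][sl])
            (pm, rm, pr, rr), flagged = orient_cache[p]
            values[spec.name] = {"pitch_mean": pm, "roll_mean": rm,
                                 "pitch_range": pr, "roll_range": rr}[spec.statistic]
            if flagged:
                flags.add(spec.name)
        elif spec.family == "xcorr":
            a, b = spec.placements
            for p in (a, b):
                if p not in mag_cache:
                    mag_cache[p] = _gyro_mag_bp(filtered[p], sl)
            if spec.statistic == "peak":
                peak, lag, flagged = xcorr_features(mag_cache[a], mag_cache[b], rate, max_lag_s)
                values[spec.name] = peak
                values[spec.name.removesuffix("peak") + "lag"] = lag
                if flagged:
                    flags.add(spec.name)
            else:
                if spec.name not in values:  # peak spec always precedes lag in registry
                    peak, lag, flagged = xcorr_features(mag_cache[a], mag_cache[b], rate, max_lag_s)
                    values[spec.name] = lag
                    if flagged:
                        flags.add(spec.name)
        else:
            raise ValueError(f"unknown feature family {spec.family!r}")

    return FeatureVector(repetition_id=repetition.repetition_id, values=values, flags=flags)


def extract_table(repetitions: list[Repetition], filtered: dict,
                  registry: list[FeatureSpec] | None = None,
                  grades: dict[str, str] | None = None):
    """Extract a FeatureTable for a list of repetitions of one session.

    ``grades`` maps repetition_id -> grade label; missing grades become "".
    """
    import pandas as pd

    from .session_io import FeatureTable

    reg = registry if registry is not None else default_registry()
    names = [s.name for s in reg]
    rows = []
    for rep in repetitions:
        vec = extract_features(rep, filtered, reg)
        row = {
            "repetition_id": rep.repetition_id,
            "subject_id": rep.subject_id,
            "movement": rep.movement,
            "side": rep.side,
            "grade": (grades or {}).get(rep.repetition_id, ""),
        }
        row.update(vec.values)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["repetition_id", "subject_id", "movement",
                                     "side", "grade"] + names)
    return FeatureTable(data=df, feature_names=names, hash=registry_hash(names))
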