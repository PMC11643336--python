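"""Synthetic cohorts of labeled multi-sensor IMU sessions.

The generator emulates the statistical structure the pipeline assumes about
repetitive Tai Chi-style exercise so every downstream stage can be exercised
without recorded data:

* six movement archetypes (RTP, PUSH, GST, WHLC, BKTS, GR) built as sums of
  phase-locked harmonics of a slow fundamental (0.2-0.5 Hz) per body site,
  axis, and modality, plus orientation-consistent gravity on the
  accelerometer and a rotated constant field on the magnetometer;
* deliberately confusable GST/WHLC templates (shared base template, the
  degree of divergence set by ``overlap``), reproducing the one pair of
  movements that shares common motion patterns;
* repetitions separated by brief low-angular-velocity pauses, with ground
  truth boundaries stored using the segmenter's pause-midpoint convention;
* three proficiency grades expressed as degradation: band-limited (2-6 Hz)
  "jerk" noise, per-repetition tempo jitter, amplitude variability, and
  inter-limb coordination (phase) errors — all strictly decreasing from
  low to high grade;
* per-subject random effects (tempo, amplitude, posture, phase) so subjects
  differ systematically and leave-one-subject-out validation is meaningful.

Everything is a pure function of (archetypes, profiles, config, seed):
identical inputs give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .session_io import (
    ACCEL_RANGE_G,
    GYRO_RANGE_DPS,
    MAG_RANGE_G,
    GRADES,
    MOVEMENTS,
    PLACEMENTS,
    GrossCompetencyScore,
    ImuChannelSet,
    MovementMarker,
    RangeError,
    Session,
)

__all__ = [
    "RangeViolationError",
    "SiteTemplate",
    "MovementArchetype",
    "ProficiencyProfile",
    "CohortConfig",
    "default_profiles",
    "build_default_archetypes",
    "generate_subject",
    "generate_cohort",
    "PAUSE_FLOOR_DPS",
]

RAW_RATE_HZ = 100.0
#: During generated pauses the smoothed gyro-magnitude envelope stays below this.
PAUSE_FLOOR_DPS = 6.0

_EDGE_MARGIN_S = 0.1   # quiet margin inside each marker before/after the reps
_TAPER_S = 0.3         # Tukey taper bringing motion to rest at rep edges
_REST_GAP_S = 3.0      # unmarked rest between movement blocks
_WHITE_GYRO_SD = 1.5   # deg/s
_WHITE_ACCEL_SD = 0.02  # g
_WHITE_MAG_SD = 0.01   # gauss
_MAG_FIELD = np.array([0.25, 0.0, 0.45])  # gauss, world frame

_MIRROR = {p: p for p in PLACEMENTS}
_MIRROR.update({f"l_{s}": f"r_{s}" for s in ("upper_arm", "wrist", "thigh", "shank", "ankle")})
_MIRROR.update({f"r_{s}": f"l_{s}" for s in ("upper_arm", "wrist", "thigh", "shank", "ankle")})

_REGION = {
    "chest": "trunk", "abdomen": "trunk", "sacrum": "trunk",
    "l_upper_arm": "arm", "r_upper_arm": "arm",
    "l_wrist": "wrist", "r_wrist": "wrist",
    "l_thigh": "thigh", "r_thigh": "thigh",
    "l_shank": "shank", "r_shank": "shank",
    "l_ankle": "ankle", "r_ankle": "ankle",
}


class RangeViolationError(RangeError):
    """A configuration would drive samples beyond the sensor full-scale range."""


@dataclass(frozen=True)
class SiteTemplate:
    """Harmonic template of one body site for one archetype.

    ``gyro_amp``/``accel_amp`` are per-axis fundamental amplitudes (deg/s, g);
    harmonics k=2,3 are scaled by the archetype's relative amplitudes.
    ``phase_offset`` is the site's inter-limb coordination phase (radians).
    """

    gyro_amp: tuple[float, float, float]
    accel_amp: tuple[float, float, float]
    phases: tuple[float, float, float]
    phase_offset: float
    pitch_mean: float  # degrees
    roll_mean: float
    pitch_sway: float
    roll_sway: float


@dataclass(frozen=True)
class MovementArchetype:
    """One movement's kinematic signature: tempo, harmonics, coordination,
    orientation. ``rep_cycles`` fundamental cycles constitute one repetition."""

    name: str
    fundamental_hz: float
    harmonic_rel: tuple[float, float]  # relative amplitude of harmonics 2 and 3
    jerk_scale: float                  # archetype multiplier on grade jerk noise
    sites: dict[str, SiteTemplate]
    rep_cycles: int = 2
    coord_scale: float = 1.0           # archetype multiplier on grade phase noise
    #: Body sites where execution quality is expressed: grade-dependent jerk
    #: noise is injected only here (proportional to the site's motion
    #: amplitude), mirroring that sloppiness shows on the limbs doing the work.
    skill_sites: tuple[str, ...] = PLACEMENTS

    def __post_init__(self) -> None:
        if not (0.05 <= self.fundamental_hz < 4.0):
            raise ValueError(f"{self.name}: fundamental {self.fundamental_hz} Hz "
                             "must lie below the 4 Hz analysis band")
        missing = set(PLACEMENTS) - set(self.sites)
        if missing:
            raise ValueError(f"{self.name}: missing site templates {sorted(missing)}")

    @property
    def coordination(self) -> dict[str, float]:
        return {p: t.phase_offset for p, t in self.sites.items()}

    @property
    def rep_duration_s(self) -> float:
        return self.rep_cycles / self.fundamental_hz

    def validate_ranges(self, headroom_gyro: float = 60.0, headroom_accel: float = 0.4) -> None:
        """Reject templates whose worst-case amplitudes (all harmonics in phase,
        plus gravity and noise headroom) exceed the sensor full-scale ranges."""
        hsum = 1.0 + sum(self.harmonic_rel)
        for p, t in self.sites.items():
            g_peak = max(t.gyro_amp) * hsum + headroom_gyro
            if g_peak > GYRO_RANGE_DPS:
                raise RangeViolationError(
                    f"{self.name}/{p}: worst-case gyro {g_peak:.0f} deg/s exceeds "
                    f"full scale ±{GYRO_RANGE_DPS}")
            a_peak = max(t.accel_amp) * hsum + 1.0 + headroom_accel
            if a_peak > ACCEL_RANGE_G:
                raise RangeViolationError(
                    f"{self.name}/{p}: worst-case accel {a_peak:.2f} g exceeds "
                    f"full scale ±{ACCEL_RANGE_G}")


@dataclass(frozen=True)
class ProficiencyProfile:
    """Grade-dependent degradation parameters.

    All four parameters strictly decrease from low to high grade, and the
    high-grade values stay positive (no noiseless signals).
    """

    grade: str
    jerk_noise_sd: float        # deg/s, band-limited 2-6 Hz, scaled per archetype
    tempo_jitter_cv: float      # CV of the per-repetition period
    amplitude_cv: float         # CV of the per-repetition amplitude factor
    coordination_error_sd: float  # radians of per-rep, per-site phase noise

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        for f in ("jerk_noise_sd", "tempo_jitter_cv", "amplitude_cv",
                  "coordination_error_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")


def default_profiles() -> dict[str, ProficiencyProfile]:
    """Default degradation per grade (stated assumptions, not estimates)."""
    profiles = {
        "low": ProficiencyProfile("low", jerk_noise_sd=14.0, tempo_jitter_cv=0.10,
                                  amplitude_cv=0.15, coordination_error_sd=0.45),
        "medium": ProficiencyProfile("medium", jerk_noise_sd=7.0, tempo_jitter_cv=0.05,
                                     amplitude_cv=0.08, coordination_error_sd=0.22),
        "high": ProficiencyProfile("high", jerk_noise_sd=2.5, tempo_jitter_cv=0.02,
                                   amplitude_cv=0.03, coordination_error_sd=0.08),
    }
    for lo, hi in (("low", "medium"), ("medium", "high")):
        for f in ("jerk_noise_sd", "tempo_jitter_cv", "amplitude_cv",
                  "coordination_error_sd"):
            assert getattr(profiles[lo], f) > getattr(profiles[hi], f)
    return profiles


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of a synthetic cohort."""

    n_subjects: int = 8
    movements: tuple[str, ...] = MOVEMENTS
    repetitions_per_movement: int = 6
    unilateral_movements: tuple[str, ...] = ("RTP",)
    pause_duration_s: float = 0.5
    class_proportions: tuple[float, float, float] = (0.375, 0.25, 0.375)  # low/med/high
    seed: int = 0
    overlap: float = 0.66  # GST/WHLC template similarity in [0, 1)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (LOSO requires it)")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        unknown = set(self.movements) - set(MOVEMENTS)
        if unknown:
            raise ValueError(f"unknown movements {sorted(unknown)}")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if self.repetitions_per_movement < 1:
            raise ValueError("repetitions_per_movement must be >= 1")
        if self.pause_duration_s <= 0:
            raise ValueError("pause_duration_s must be positive")


# ---------------------------------------------------------------------------
# Archetype construction

_ARCH_PARAMS: dict[str, dict] = {
    # f0 in Hz; gyro scales in deg/s per region; accel in g; orientation per
    # region as (pitch, roll) degrees; sway in degrees; coord: l/r phase law.
    "RTP": dict(f0=0.27, seed=101, harm=(0.30, 0.10), jerk_scale=1.2, coord_scale=0.8, accel=0.15,
                skill=("l_wrist", "r_wrist", "l_upper_arm", "r_upper_arm"),
                scales=dict(wrist=55, arm=40, ankle=12, shank=10, thigh=15, trunk=18),
                orient=dict(trunk=(4, 0), arm=(22, 4), wrist=(32, 8),
                            thigh=(8, 2), shank=(4, 1), ankle=(2, 0)),
                sway=12.0, coord=0.0),
    "PUSH": dict(f0=0.42, seed=102, harm=(0.45, 0.15), jerk_scale=1.5, coord_scale=0.8, accel=0.22,
                 skill=("l_wrist", "r_wrist", "chest", "abdomen"),
                 scales=dict(wrist=70, arm=52, ankle=18, shank=16, thigh=22, trunk=26),
                 orient=dict(trunk=(14, 2), arm=(45, 6), wrist=(55, 10),
                             thigh=(15, 4), shank=(8, 2), ankle=(4, 1)),
                 sway=16.0, coord=0.0),
    "GST": dict(f0=0.33, seed=103, harm=(0.40, 0.20), jerk_scale=1.1, coord_scale=1.0, accel=0.20,
                skill=("l_wrist", "r_wrist", "l_upper_arm", "r_upper_arm"),
                scales=dict(wrist=60, arm=46, ankle=22, shank=20, thigh=24, trunk=30),
                orient=dict(trunk=(8, 6), arm=(28, 12), wrist=(38, 16),
                            thigh=(12, 6), shank=(6, 3), ankle=(3, 2)),
                sway=14.0, coord=np.pi),
    # WHLC is derived from GST's base template (see build_default_archetypes)
    "WHLC": dict(f0=0.365, seed=103, harm=(0.40, 0.20), jerk_scale=1.1, coord_scale=1.1, accel=0.20,
                 skill=("l_wrist", "r_wrist", "l_upper_arm", "r_upper_arm"),
                 perturb_seed=104,
                 scales=dict(wrist=60, arm=46, ankle=22, shank=20, thigh=24, trunk=30),
                 orient=dict(trunk=(8, 6), arm=(28, 12), wrist=(38, 16),
                             thigh=(12, 6), shank=(6, 3), ankle=(3, 2)),
                 sway=14.0, coord=np.pi),
    "BKTS": dict(f0=0.50, seed=105, harm=(0.55, 0.25), jerk_scale=2.2, coord_scale=1.2, accel=0.28,
                 skill=("l_thigh", "r_thigh", "l_shank", "r_shank", "l_ankle", "r_ankle"),
                 scales=dict(wrist=62, arm=45, ankle=40, shank=36, thigh=30, trunk=22),
                 orient=dict(trunk=(6, 1), arm=(18, 8), wrist=(25, 12),
                             thigh=(22, 6), shank=(14, 4), ankle=(8, 2)),
                 sway=10.0, coord=np.pi),
    "GR": dict(f0=0.22, seed=106, harm=(0.25, 0.05), jerk_scale=1.1, coord_scale=1.4, accel=0.12,
               skill=("l_thigh", "r_thigh", "l_shank", "r_shank", "sacrum"),
               scales=dict(wrist=45, arm=35, ankle=28, shank=30, thigh=35, trunk=15),
               orient=dict(trunk=(2, 0), arm=(40, 5), wrist=(55, 8),
                           thigh=(35, 5), shank=(20, 3), ankle=(10, 2)),
               sway=8.0, coord=0.0),
}


def _draw_sites(params: dict, rng: np.random.Generator) -> dict[str, SiteTemplate]:
    sites: dict[str, SiteTemplate] = {}
    for p in PLACEMENTS:
        region = _REGION[p]
        base = params["scales"][region]
        gyro_amp = tuple(base * rng.uniform(0.6, 1.4, 3))
        accel_amp = tuple(params["accel"] * rng.uniform(0.5, 1.5, 3))
        # staggered axis phases keep the 3-axis gyro norm from dipping mid-rep
        ph0 = rng.uniform(0, 2 * np.pi)
        phases = (ph0, ph0 + 2.09, ph0 + 4.19)
        op, orr = params["orient"][region]
        pitch_mean = op + rng.normal(0, 4.0)
        roll_mean = orr + rng.normal(0, 3.0)
        sway = params["sway"]
        pitch_sway = sway * rng.uniform(0.6, 1.4)
        roll_sway = 0.6 * sway * rng.uniform(0.6, 1.4)
        offset = (params["coord"] if p.startswith("l_") else 0.0) + rng.normal(0, 0.15)
        sites[p] = SiteTemplate(
            gyro_amp=gyro_amp, accel_amp=accel_amp, phases=phases,
            phase_offset=offset, pitch_mean=pitch_mean, roll_mean=roll_mean,
            pitch_sway=pitch_sway, roll_sway=roll_sway,
        )
    return sites


def build_default_archetypes(overlap: float = 0.66) -> dict[str, MovementArchetype]:
    """The six default archetypes.

    GST and WHLC are built from the same base template; WHLC then diverges by
    an amount controlled by ``1 - overlap`` (amplitudes, phases, posture), and
    by a small fundamental-tempo difference, so the pair is distinguishable in
    principle but confusable in practice.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    archetypes: dict[str, MovementArchetype] = {}
    for name, params in _ARCH_PARAMS.items():
        rng = np.random.default_rng(params["seed"])
        sites = _draw_sites(params, rng)
        if name == "WHLC":
            d = 1.0 - overlap
            prng = np.random.default_rng(params["perturb_seed"])
            perturbed = {}
            for p, t in sites.items():
                perturbed[p] = SiteTemplate(
                    gyro_amp=tuple(a * (1 + d * prng.normal(0, 0.35)) for a in t.gyro_amp),
                    accel_amp=tuple(a * (1 + d * prng.normal(0, 0.35)) for a in t.accel_amp),
                    phases=tuple(ph + d * prng.normal(0, 0.8) for ph in t.phases),
                    phase_offset=t.phase_offset + d * prng.normal(0, 0.3),
                    pitch_mean=t.pitch_mean + d * prng.normal(0, 10.0),
                    roll_mean=t.roll_mean + d * prng.normal(0, 8.0),
                    pitch_sway=t.pitch_sway * (1 + d * prng.normal(0, 0.3)),
                    roll_sway=t.roll_sway * (1 + d * prng.normal(0, 0.3)),
                )
            sites = perturbed
        arch = MovementArchetype(
            name=name, fundamental_hz=params["f0"], harmonic_rel=params["harm"],
            jerk_scale=params["jerk_scale"], coord_scale=params.get("coord_scale", 1.0),
            sites=sites, skill_sites=tuple(params.get("skill", PLACEMENTS)),
        )
        arch.validate_ranges()
        archetypes[name] = arch
    return archetypes


# ---------------------------------------------------------------------------
# Signal synthesis


@dataclass(frozen=True)
class _SubjectEffects:
    tempo_mult: float
    amp_mult: float
    pitch_off: float
    roll_off: float
    site_phase: dict[str, float]


def _draw_subject_effects(rng: np.random.Generator) -> _SubjectEffects:
    return _SubjectEffects(
        tempo_mult=float(np.clip(1 + rng.normal(0, 0.05), 0.88, 1.12)),
        amp_mult=float(np.clip(1 + rng.normal(0, 0.08), 0.75, 1.25)),
        pitch_off=float(rng.normal(0, 3.0)),
        roll_off=float(rng.normal(0, 3.0)),
        site_phase={p: float(rng.normal(0, 0.2)) for p in PLACEMENTS},
    )


def _gravity(pitch_deg: np.ndarray, roll_deg: np.ndarray) -> np.ndarray:
    """Sensor-frame gravity (in g) for given pitch/roll, matching the
    orientation-metrics convention pitch=atan2(-ax, hypot(ay,az)), roll=atan2(ay,az)."""
    p = np.radians(pitch_deg)
    r = np.radians(roll_deg)
    return np.column_stack([-np.sin(p), np.sin(r) * np.cos(p), np.cos(r) * np.cos(p)])


def _world_to_sensor(pitch_deg: np.ndarray, roll_deg: np.ndarray,
                     v: np.ndarray) -> np.ndarray:
    """Rotate a constant world-frame vector into the sensor frame per sample."""
    p = np.radians(pitch_deg)
    r = np.radians(roll_deg)
    cp, sp = np.cos(p), np.sin(p)
    cr, sr = np.cos(r), np.sin(r)
    vx, vy, vz = v
    # Rx(roll)^T @ Ry(pitch)^T @ v
    x1 = cp * vx - sp * vz
    z1 = sp * vx + cp * vz
    return np.column_stack([x1, cr * vy + sr * z1, -sr * vy + cr * z1])


def _mirror_template(t: SiteTemplate) -> SiteTemplate:
    return replace(t, roll_mean=-t.roll_mean, roll_sway=t.roll_sway)


def _site_template(arch: MovementArchetype, site: str, side: str) -> SiteTemplate:
    if side == "left":
        return _mirror_template(arch.sites[_MIRROR[site]])
    return arch.sites[site]


def _jerk_noise(n: int, sd: float, rng: np.random.Generator, rate: float) -> np.ndarray:
    """Band-limited (2-6 Hz) unit-variance noise scaled to sd; shape (n, 3)."""
    white = rng.standard_normal((n, 3))
    sos = sp_signal.butter(4, [2.0, 6.0], btype="bandpass", fs=rate, output="sos")
    f = sp_signal.sosfilt(sos, white, axis=0)
    s = f.std(axis=0)
    s[s <= 0] = 1.0
    return f / s * sd


def _synth_block(arch: MovementArchetype, profile: ProficiencyProfile,
                 fx: _SubjectEffects, side: str, n_reps: int, pause_s: float,
                 rng: np.random.Generator, rate: float = RAW_RATE_HZ):
    """Synthesize one movement block.

    Returns (signals, boundaries_s) where signals maps placement ->
    (accel, gyro, mag) arrays for the block, and boundaries_s are the n_reps+1
    repetition boundaries (block-relative seconds, pause-midpoint convention).
    """
    base_T = arch.rep_duration_s * fx.tempo_mult
    periods = base_T * (1 + profile.tempo_jitter_cv
                        * np.clip(rng.standard_normal(n_reps), -2, 2))
    amps = fx.amp_mult * (1 + profile.amplitude_cv
                          * np.clip(rng.standard_normal(n_reps), -2, 2))
    coord_err = rng.normal(0, profile.coordination_error_sd * arch.coord_scale,
                           size=(n_reps, len(PLACEMENTS)))

    margin_n = int(round(_EDGE_MARGIN_S * rate))
    pause_n = int(round(pause_s * rate))
    rep_n = [int(round(T * rate)) for T in periods]

    # segment layout: margin | rep0 | pause | rep1 | ... | rep_{k-1} | margin
    seg_lengths = [margin_n]
    for i, nr in enumerate(rep_n):
        seg_lengths.append(nr)
        if i < n_reps - 1:
            seg_lengths.append(pause_n)
    seg_lengths.append(margin_n)
    n_total = sum(seg_lengths)

    # per-rep phase/window arrays shared by all sites
    rep_theta = []
    rep_win = []
    for nr, T in zip(rep_n, periods):
        tau = np.arange(nr) / rate
        rep_theta.append(2 * np.pi * arch.rep_cycles * tau / T)
        alpha = min(0.9, 2 * _TAPER_S / T)
        rep_win.append(sp_signal.windows.tukey(nr, alpha=alpha))

    harmonics = (1.0,) + arch.harmonic_rel
    signals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for si, site in enumerate(PLACEMENTS):
        t = _site_template(arch, site, side)
        gyro = np.zeros((n_total, 3))
        pitch = np.full(n_total, t.pitch_mean + fx.pitch_off)
        roll = np.full(n_total, t.roll_mean + fx.roll_off)
        # slow postural wander: nobody holds a frozen posture, so per-rep
        # orientation means vary within a session by a few degrees
        tt = np.arange(n_total) / rate
        fw = rng.uniform(0.015, 0.05)
        aw = rng.uniform(2.5, 5.0)
        ph = rng.uniform(0, 2 * np.pi, 4)
        pitch = pitch + aw * np.sin(2 * np.pi * fw * tt + ph[0]) \
            + 0.6 * aw * np.sin(2 * np.pi * 2.3 * fw * tt + ph[1])
        roll = roll + 0.7 * aw * np.sin(2 * np.pi * 1.4 * fw * tt + ph[2]) \
            + 0.4 * aw * np.sin(2 * np.pi * 3.1 * fw * tt + ph[3])
        dyn_acc = np.zeros((n_total, 3))
        pos = margin_n
        for r in range(n_reps):
            nr = rep_n[r]
            th = rep_theta[r] + t.phase_offset + fx.site_phase[site] + coord_err[r, si]
            w = rep_win[r]
            for ax in range(3):
                g = np.zeros(nr)
                a = np.zeros(nr)
                for h, rel in enumerate(harmonics, start=1):
                    ph = t.phases[ax] + (h - 1) * 1.3
                    g += rel * np.sin(h * th + ph)
                    a += rel * np.sin(h * th + ph + 0.5)
                gyro[pos:pos + nr, ax] = amps[r] * t.gyro_amp[ax] * g * w
                dyn_acc[pos:pos + nr, ax] = amps[r] * t.accel_amp[ax] * a * w
            pitch[pos:pos + nr] += t.pitch_sway * np.sin(th + t.phases[0]) * w
            roll[pos:pos + nr] += t.roll_sway * np.sin(th + t.phases[1]) * w
            pos += nr + (pause_n if r < n_reps - 1 else 0)

        accel = _gravity(pitch, roll) + dyn_acc
        mag = _world_to_sensor(pitch, roll, _MAG_FIELD)

        canonical = _MIRROR[site] if side == "left" else site
        if canonical in arch.skill_sites:
            jerk_sd = (profile.jerk_noise_sd * arch.jerk_scale
                       * float(np.mean(t.gyro_amp)) / 50.0)
        else:
            jerk_sd = 0.25 * profile.jerk_noise_sd  # residual whole-body sloppiness
        active = np.zeros(n_total)
        pos = margin_n
        for r in range(n_reps):
            active[pos:pos + rep_n[r]] = rep_win[r]
            pos += rep_n[r] + (pause_n if r < n_reps - 1 else 0)
        jg = _jerk_noise(n_total, jerk_sd, rng, rate) * active[:, None]
        ja = jg * (0.0025 / 1.0)  # accel jerk tracks gyro jerk at 2.5 mg per deg/s

        gyro = gyro + jg + rng.normal(0, _WHITE_GYRO_SD, (n_total, 3))
        accel = accel + ja + rng.normal(0, _WHITE_ACCEL_SD, (n_total, 3))
        mag = mag + rng.normal(0, _WHITE_MAG_SD, (n_total, 3))
        signals[site] = (accel, gyro, mag)

    # ground-truth boundaries: block edges and pause midpoints, in seconds
    boundaries = [0.0]
    pos = margin_n
    for r in range(n_reps - 1):
        pos += rep_n[r]
        boundaries.append((pos + pause_n / 2) / rate)
        pos += pause_n
    boundaries.append(n_total / rate)
    return signals, boundaries


def generate_subject(archetypes: dict[str, MovementArchetype],
                     profile: ProficiencyProfile | dict[str, ProficiencyProfile],
                     config: CohortConfig, seed,
                     subject_id: str = "S00") -> Session:
    """Generate one subject's full session.

    ``profile`` is either a single ProficiencyProfile applied to every
    movement or a map movement -> profile. Ground-truth repetition boundaries
    and grades are attached as ``session.truth``. Bit-identical output for
    identical arguments.
    """
    if not archetypes:
        raise ValueError("archetype set must be non-empty")
    for arch in archetypes.values():
        arch.validate_ranges()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    fx = _draw_subject_effects(rng)

    movements = [m for m in config.movements if m in archetypes]
    if set(config.movements) - set(archetypes):
        raise ValueError(f"archetypes missing for {sorted(set(config.movements) - set(archetypes))}")

    blocks: list[tuple[str, str, dict, list[float]]] = []
    for m in movements:
        prof = profile[m] if isinstance(profile, dict) else profile
        sides = ("n/a",) if m in config.unilateral_movements else ("right", "left")
        for side in sides:
            sig, bounds = _synth_block(
                archetypes[m], prof, fx, side, config.repetitions_per_movement,
                config.pause_duration_s, rng,
            )
            blocks.append((m, side, sig, bounds))

    rate = RAW_RATE_HZ
    gap_n = int(round(_REST_GAP_S * rate))
    lead_n = int(round(2.0 * rate))

    # assemble the full-session arrays per placement
    chunks: dict[str, list[np.ndarray]] = {p: [] for p in PLACEMENTS}

    def rest_chunk(site: str, n: int) -> np.ndarray:
        pitch = np.full(n, fx.pitch_off)
        roll = np.full(n, fx.roll_off)
        acc = _gravity(pitch, roll) + rng.normal(0, _WHITE_ACCEL_SD, (n, 3))
        gyr = rng.normal(0, _WHITE_GYRO_SD, (n, 3))
        mag = _world_to_sensor(pitch, roll, _MAG_FIELD) + rng.normal(0, _WHITE_MAG_SD, (n, 3))
        return np.hstack([acc, gyr, mag])

    markers: list[MovementMarker] = []
    truth: list[dict] = []
    cursor = lead_n
    for p in PLACEMENTS:
        chunks[p].append(rest_chunk(p, lead_n))
    for bi, (m, side, sig, bounds) in enumerate(blocks):
        n_block = len(sig[PLACEMENTS[0]][0])
        start_s = cursor / rate
        end_s = (cursor + n_block) / rate
        markers.append(MovementMarker(movement=m, side=side, start_s=start_s, end_s=end_s))
        for r in range(config.repetitions_per_movement):
            truth.append({
                "movement": m, "side": side, "block_index": bi, "rep_index": r,
                "start_s": round(start_s + bounds[r], 6),
                "end_s": round(start_s + bounds[r + 1], 6),
                "grade": (profile[m] if isinstance(profile, dict) else profile).grade,
            })
        for p in PLACEMENTS:
            acc, gyr, mag = sig[p]
            chunks[p].append(np.hstack([acc, gyr, mag]))
        cursor += n_block
        for p in PLACEMENTS:
            chunks[p].append(rest_chunk(p, gap_n))
        cursor += gap_n

    n_samples = sum(len(c) for c in chunks[PLACEMENTS[0]])
    t = np.arange(n_samples) / rate
    channels = {}
    for p in PLACEMENTS:
        arr = np.vstack(chunks[p])
        # clip the (rare) noise excursions rather than violate sensor ranges
        acc = np.clip(arr[:, 0:3], -ACCEL_RANGE_G, ACCEL_RANGE_G)
        gyr = np.clip(arr[:, 3:6], -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
        mag = np.clip(arr[:, 6:9], -MAG_RANGE_G, MAG_RANGE_G)
        channels[p] = ImuChannelSet(placement=p, t=t, accel=acc, gyro=gyr,
                                    mag=mag, rate_hz=rate)

    scores: list[GrossCompetencyScore] = []
    grade_values = {"low": (0.0, 2.5), "medium": (3.0, 3.5), "high": (4.0, 5.0)}
    for m in movements:
        prof = profile[m] if isinstance(profile, dict) else profile
        lo, hi = grade_values[prof.grade]
        choices = np.arange(lo, hi + 0.25, 0.5)
        value = float(rng.choice(choices))
        sides = ("n/a",) if m in config.unilateral_movements else ("right", "left")
        for side in sides:
            scores.append(GrossCompetencyScore(movement=m, side=side, value=value))

    return Session(subject_id=subject_id, channels=channels, markers=markers,
                   scores=scores, truth=truth)


def _allocate_grades(config: CohortConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Stratified grade allocation: per movement, grade counts follow the
    configured proportions up to rounding (largest remainder), assignment to
    subjects shuffled by the seeded RNG. Guarantees every grade is represented
    whenever n_subjects * proportion rounds to >= 1."""
    n = config.n_subjects
    props = np.asarray(config.class_proportions, dtype=float)
    out: dict[str, list[str]] = {}
    for m in config.movements:
        raw = props * n
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        while counts.sum() < n:
            i = int(np.argmax(rem))
            counts[i] += 1
            rem[i] = -1
        grades = sum(([g] * c for g, c in zip(GRADES, counts)), [])
        out[m] = list(rng.permutation(grades))
    return out


def generate_cohort(config: CohortConfig,
                    archetypes: dict[str, MovementArchetype] | None = None,
                    profiles: dict[str, ProficiencyProfile] | None = None,
                    ) -> tuple[list[Session], pd.DataFrame]:
    """Generate a full cohort plus its ground-truth table.

    Returns (sessions, truth) where ``truth`` has one row per
    (subject, movement, side, repetition) with grade and boundary columns.
    """
    archs = archetypes if archetypes is not None else build_default_archetypes(config.overlap)
    profs = profiles if profiles is not None else default_profiles()
    alloc_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    grade_by_subject_movement = _allocate_grades(config, alloc_rng)

    sessions: list[Session] = []
    rows: list[dict] = []
    for i in range(config.n_subjects):
        subject_id = f"S{i:02d}"
        per_movement = {m: profs[grade_by_subject_movement[m][i]] for m in config.movements}
        session = generate_subject(
            archs, per_movement, config,
            seed=np.random.SeedSequence([config.seed, i]), subject_id=subject_id,
        )
        sessions.append(session)
        for tr in session.truth:
            rows.append({"subject_id": subject_id, **tr})
    truth = pd.DataFrame(rows, columns=["subject_id", "movement", "side", "block_index",
                                        "rep_index", "start_s", "end_s", "grade"])
    return sessions, truth
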