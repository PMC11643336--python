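"""Rate conversion and band splitting for IMU channels.

Every feature downstream operates on one of two variants of each channel at
the 32 Hz working rate: a low-pass series (<= 4 Hz; suited to static
orientation and alignment) and a band-pass series (0.1-4 Hz; the dynamic
movement content with the DC/gravity component removed). Both variants come
from a 4th-order Chebyshev Type I design (0.5 dB passband ripple) applied
forward-backward, so the overall response is zero-phase with squared
magnitude. Nothing in the protocol carries signal content above 4 Hz.

Note on gain: an even-order Chebyshev I has its ripple minimum at DC, so a
constant input emerges scaled by 10**(-ripple_db/10) after the
forward-backward pass (~0.891 at the default 0.5 dB). Orientation features
use atan2 ratios, so this uniform scaling cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "FilterConfig",
    "FilteredChannelSet",
    "resample",
    "lowpass",
    "bandpass",
    "filter_channels",
]

WORKING_RATE_HZ = 32.0


@dataclass(frozen=True)
class FilterConfig:
    """Band-splitting configuration.

    The filter family/ripple/phase handling and the resampling method are
    design choices, not protocol facts, so all of them are exposed here.
    ``cascade_bandpass`` realizes the band-pass as high-pass + low-pass in
    series instead of a single band-pass design.
    """

    working_rate_hz: float = WORKING_RATE_HZ
    family: str = "cheby1"          # "cheby1" | "cheby2" | "butter"
    ripple_db: float = 0.5
    order: int = 4
    lp_cutoff_hz: float = 4.0
    band_low_hz: float = 0.1
    band_high_hz: float = 4.0
    zero_phase: bool = True
    cascade_bandpass: bool = False
    allow_upsample: bool = False


def _design(order: int, ripple_db: float, family: str, Wn, btype: str, fs: float):
    if family == "cheby1":
        return signal.cheby1(order, ripple_db, Wn, btype=btype, fs=fs, output="sos")
    if family == "cheby2":
        # ripple_db reinterpreted as stopband attenuation for Type II
        return signal.cheby2(order, max(ripple_db, 20.0), Wn, btype=btype, fs=fs, output="sos")
    if family == "butter":
        return signal.butter(order, Wn, btype=btype, fs=fs, output="sos")
    raise ValueError(f"unknown filter family {family!r}")


def _apply(sos, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if zero_phase:
        # reflect padding of one settling length keeps edge transients bounded
        padlen = min(len(x) - 1, 3 * (2 * len(sos) + 1) * 8)
        return signal.sosfiltfilt(sos, x, padlen=padlen)
    return signal.sosfilt(sos, x)


def resample(series: np.ndarray, from_hz: float, to_hz: float = WORKING_RATE_HZ,
             *, allow_upsample: bool = False) -> np.ndarray:
    """Polyphase rational resampling with the default Kaiser anti-alias window.

    Only downsampling is performed by the pipeline (100 -> 32 Hz uses the
    ratio 8/25); upsampling requests are rejected unless explicitly allowed.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.shape[-1] < 2:
        raise ValueError("series must have at least 2 samples")
    if to_hz > from_hz and not allow_upsample:
        raise ValueError(f"upsampling {from_hz} -> {to_hz} Hz is outside the configured policy")
    if to_hz == from_hz:
        return series.copy()
    frac = Fraction(to_hz / from_hz).limit_denominator(1000)
    # line padding keeps DC and slow trends intact at the series edges
    return signal.resample_poly(series, frac.numerator, frac.denominator,
                                axis=-1, padtype="line")


def lowpass(series: np.ndarray, rate_hz: float, cutoff: float = 4.0,
            order: int = 4, *, config: FilterConfig | None = None) -> np.ndarray:
    """Low-pass variant of a series (static orientation / alignment content)."""
    cfg = config or FilterConfig()
    if cutoff >= rate_hz / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rate_hz / 2} Hz)")
    sos = _design(order, cfg.ripple_db, cfg.family, cutoff, "lowpass", rate_hz)
    return _apply(sos, series, cfg.zero_phase)


def bandpass(series: np.ndarray, rate_hz: float, low: float = 0.1, high: float = 4.0,
             order: int = 4, *, config: FilterConfig | None = None) -> np.ndarray:
    """Band-pass variant of a series (dynamic movement content, DC removed)."""
    cfg = config or FilterConfig()
    if not (0 < low < high < rate_hz / 2):
        raise ValueError(f"band edges ({low}, {high}) must satisfy 0 < low < high < Nyquist")
    if cfg.cascade_bandpass:
        hp = _design(order, cfg.ripple_db, cfg.family, low, "highpass", rate_hz)
        lp = _design(order, cfg.ripple_db, cfg.family, high, "lowpass", rate_hz)
        return _apply(lp, _apply(hp, series, cfg.zero_phase), cfg.zero_phase)
    sos = _design(order, cfg.ripple_db, cfg.family, [low, high], "bandpass", rate_hz)
    return _apply(sos, series, cfg.zero_phase)


@dataclass
class FilteredChannelSet:
    """One sensor at the working rate with low-pass and band-pass variants.

    ``lp``/``bp`` map modality ("accel" | "gyro") to (n, 3) arrays.
    ``t`` is the working-rate time base in seconds from session start.
    """

    placement: str
    rate_hz: float
    t: np.ndarray
    lp: dict[str, np.ndarray] = field(default_factory=dict)
    bp: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for d in (self.lp, self.bp):
            for k, v in d.items():
                if len(v) != n:
                    raise ValueError(f"{self.placement}/{k}: length mismatch with time base")


def filter_channels(channel_set, config: FilterConfig | None = None) -> FilteredChannelSet:
    """Resample one sensor's accel/gyro to the working rate and band-split.

    The magnetometer is resampled but not band-split (no default feature uses
    it); it is carried in ``lp['mag']`` unfiltered at the working rate.
    """
    cfg = config or FilterConfig()
    out_lp: dict[str, np.ndarray] = {}
    out_bp: dict[str, np.ndarray] = {}
    n_out = None
    for modality in ("accel", "gyro"):
        raw = getattr(channel_set, modality)
        cols = [
            resample(raw[:, ax], channel_set.rate_hz, cfg.working_rate_hz,
                     allow_upsample=cfg.allow_upsample)
            for ax in range(3)
        ]
        arr = np.column_stack(cols)
        n_out = len(arr)
        out_lp[modality] = np.column_stack(
            [lowpass(arr[:, ax], cfg.working_rate_hz, cfg.lp_cutoff_hz, cfg.order, config=cfg)
             for ax in range(3)]
        )
        out_bp[modality] = np.column_stack(
            [bandpass(arr[:, ax], cfg.working_rate_hz, cfg.band_low_hz, cfg.band_high_hz,
                      cfg.order, config=cfg)
             for ax in range(3)]
        )
    mag = np.column_stack(
        [resample(channel_set.mag[:, ax], channel_set.rate_hz, cfg.working_rate_hz,
                  allow_upsample=cfg.allow_upsample)
         for ax in range(3)]
    )
    out_lp["mag"] = mag
    t0 = float(channel_set.t[0])
    t = t0 + np.arange(n_out) / cfg.working_rate_hz
    return FilteredChannelSet(
        placement=channel_set.placement, rate_hz=cfg.working_rate_hz,
        t=t, lp=out_lp, bp=out_bp,
    )


def filter_session(session, config: FilterConfig | None = None) -> dict[str, FilteredChannelSet]:
    """Band-split every placement of a session. Returns placement -> variants."""
    return {p: filter_channels(cs, config) for p, cs in sorted(session.channels.items())}
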