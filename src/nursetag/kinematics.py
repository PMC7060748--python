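"""Raw-rate tag streams to whale-frame 10 Hz series with ODBA and strokes.

Processing order mirrors field practice: decimate everything to the
analysis rate, rotate tag-frame axes into the whale frame using a calm
calibration window, split acceleration into static (gravity) and dynamic
parts with a centred running mean, then derive ODBA, orientation angles
and fluke-stroke times.

ODBA is the L1 norm of the dynamic acceleration; fluke strokes are counted
one per full oscillation of the band-passed dorsoventral signal using a
Schmitt trigger (positive-going zero crossing armed by a prior excursion
below the negative threshold), which is robust to the amplitude modulation
seen during nursing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import CalibrationError, ParameterError, RateError
from .io_core import TagRecord

GRAVITY = 9.81

#: Default static/dynamic separation window (s); at least twice a ~4 s
#: humpback stroke period.
DEFAULT_WINDOW_S = 5.0

#: Default stroke-detection band (Hz) bracketing humpback fluking rates.
DEFAULT_BAND = (0.1, 0.6)

#: Default Schmitt-trigger hysteresis threshold (m/s^2).
DEFAULT_AMP_THRESHOLD = 0.05


@dataclass
class ProcessedRecord:
    """A 10 Hz whale-frame record with derived kinematic series."""

    record: TagRecord
    static_acc: np.ndarray    # (n, 3)
    dynamic_acc: np.ndarray   # (n, 3)
    odba: np.ndarray          # (n,)
    pitch: np.ndarray         # (n,) rad, nose-up positive
    roll: np.ndarray          # (n,) rad
    stroke_times: np.ndarray  # (k,) s

    @property
    def fs(self) -> float:
        return self.record.fs

    @property
    def t(self) -> np.ndarray:
        return self.record.t

    @property
    def depth(self) -> np.ndarray:
        return self.record.depth


# ---------------------------------------------------------------------------
# Decimation
# ---------------------------------------------------------------------------

def _decimate_channel(x: np.ndarray, q: int) -> np.ndarray:
    if q == 1:
        return x.copy()
    if x.ndim == 1:
        return signal.resample_poly(x, up=1, down=q, padtype="line")
    return np.column_stack(
        [signal.resample_poly(x[:, j], up=1, down=q, padtype="line")
         for j in range(x.shape[1])])


def decimate_record(record: TagRecord, target_fs: float = 10.0) -> TagRecord:
    """Anti-alias filter and subsample every channel to ``target_fs``.

    ``record.fs`` must be an integer multiple of ``target_fs``.
    """
    ratio = record.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise RateError(
            f"fs {record.fs} is not an integer multiple of {target_fs}")
    q = int(round(ratio))
    m = record.n_samples // q
    kwargs = {}
    for name in ("acc", "depth", "speed", "mag", "gyro"):
        v = getattr(record, name)
        kwargs[name] = None if v is None else _decimate_channel(v, q)[:m]
    return record.replace(fs=float(target_fs), **kwargs)


# ---------------------------------------------------------------------------
# Whale-frame correction
# ---------------------------------------------------------------------------

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto unit vector ``b``."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def correct_to_whale_frame(record: TagRecord,
                           calib_window: tuple[float, float],
                           *, g_rtol: float = 0.20
                           ) -> tuple[TagRecord, np.ndarray]:
    """Rotate tri-axial channels so the calm-window mean maps to (0, 0, -g).

    ``calib_window`` is a (start_s, end_s) interval during which the animal
    is assumed level and unaccelerated (typically logging at the surface).
    Returns the corrected record and the 3x3 rotation applied.
    """
    i0 = max(record.index_of(calib_window[0]), 0)
    i1 = min(record.index_of(calib_window[1]), record.n_samples)
    if i1 - i0 < 2:
        raise CalibrationError("calibration window holds fewer than 2 samples")
    mean_f = record.acc[i0:i1].mean(axis=0)
    mag = float(np.linalg.norm(mean_f))
    if abs(mag - GRAVITY) > g_rtol * GRAVITY:
        raise CalibrationError(
            f"calibration-window mean specific force {mag:.2f} m/s^2 "
            f"differs from g by more than {g_rtol:.0%} "
            "(window not level/unaccelerated?)")
    rot = _rotation_between(mean_f / mag, np.array([0.0, 0.0, -1.0]))
    kwargs = {}
    for name in ("acc", "mag", "gyro"):
        v = getattr(record, name)
        kwargs[name] = None if v is None else v @ rot.T
    return record.replace(**kwargs), rot


# ---------------------------------------------------------------------------
# Static/dynamic split, ODBA, orientation
# ---------------------------------------------------------------------------

def split_static_dynamic(acc: np.ndarray, fs: float,
                         window_s: float = DEFAULT_WINDOW_S
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Centred running-mean gravity estimate; dynamic = acc - static."""
    w = int(round(window_s * fs))
    if w < 3:
        raise ParameterError(
            f"separation window of {w} samples is too short (< 3)")
    static = ndimage.uniform_filter1d(acc, size=w, axis=0, mode="nearest")
    return static, acc - static


def compute_odba(dynamic_acc: np.ndarray) -> np.ndarray:
    """Overall dynamic body acceleration: L1 norm across the three axes."""
    return np.sum(np.abs(dynamic_acc), axis=1)


def compute_orientation(static_acc: np.ndarray, *, g_rtol: float = 0.5
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pitch and roll from the static (gravity) vector.

    pitch = asin(surge / |static|), nose-up positive;
    roll = atan2(sway, -heave).  Samples whose static magnitude strays
    more than ``g_rtol`` from g are flagged undefined (returned mask).
    """
    norm = np.linalg.norm(static_acc, axis=1)
    undefined = (norm < (1 - g_rtol) * GRAVITY) | (norm > (1 + g_rtol) * GRAVITY)
    safe = np.where(norm > 1e-12, norm, 1.0)
    pitch = np.arcsin(np.clip(static_acc[:, 0] / safe, -1.0, 1.0))
    roll = np.arctan2(static_acc[:, 1], -static_acc[:, 2])
    pitch[norm <= 1e-12] = np.nan
    roll[norm <= 1e-12] = np.nan
    return pitch, roll, undefined


# ---------------------------------------------------------------------------
# Fluke-stroke detection
# ---------------------------------------------------------------------------

def detect_fluke_strokes(series: np.ndarray, fs: float,
                         amp_threshold: float = DEFAULT_AMP_THRESHOLD,
                         band: tuple[float, float] = DEFAULT_BAND,
                         t0: float = 0.0) -> np.ndarray:
    """Stroke times from an oscillatory series (heave dynamic acc or pitch).

    The series is band-pass filtered, then one stroke is counted per full
    oscillation: a positive-going zero crossing is recorded when the signal
    subsequently rises above ``+amp_threshold``, re-armed only after the
    signal has dipped below ``-amp_threshold``.  The trigger starts armed,
    so an oscillation beginning at a rising zero is counted.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ParameterError(f"band {band} invalid for fs {fs}")
    x = np.asarray(series, dtype=float)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)

    above = y > amp_threshold
    below = y < -amp_threshold
    t = t0 + np.arange(len(y)) / fs
    times = []
    armed = True
    last_upcross: float | None = None
    sgn = y > 0
    for i in range(1, len(y)):
        if not sgn[i - 1] and sgn[i]:
            denom = y[i] - y[i - 1]
            frac = -y[i - 1] / denom if denom != 0 else 0.0
            last_upcross = t[i - 1] + frac / fs
        if below[i]:
            armed = True
        elif above[i] and armed:
            armed = False
            times.append(last_upcross if last_upcross is not None else t[i])
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def process_record(record: TagRecord, *, target_fs: float = 10.0,
                   calib_window: tuple[float, float] | None = None,
                   window_s: float = DEFAULT_WINDOW_S,
                   band: tuple[float, float] = DEFAULT_BAND,
                   amp_threshold: float = DEFAULT_AMP_THRESHOLD,
                   stroke_signal: str = "heave") -> ProcessedRecord:
    """Full chain: decimate, (optionally) frame-correct, split, derive.

    ``stroke_signal`` selects the series driving stroke detection:
    ``"heave"`` (dorsoventral dynamic acceleration, default) or
    ``"pitch"`` (threshold then in radians).
    """
    rec10 = decimate_record(record, target_fs) if record.fs != target_fs \
        else record
    if calib_window is not None:
        rec10, _ = correct_to_whale_frame(rec10, calib_window)
    static, dynamic = split_static_dynamic(rec10.acc, rec10.fs, window_s)
    odba = compute_odba(dynamic)
    pitch, roll, _ = compute_orientation(static)
    if stroke_signal == "heave":
        series = dynamic[:, 2]
    elif stroke_signal == "pitch":
        series = pitch
    else:
        raise ParameterError(f"unknown stroke signal {stroke_signal!r}")
    strokes = detect_fluke_strokes(series, rec10.fs, amp_threshold, band,
                                   t0=rec10.t0)
    return ProcessedRecord(record=rec10, static_acc=static,
                           dynamic_acc=dynamic, odba=odba,
                           pitch=pitch, roll=roll, stroke_times=strokes)
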