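"""Breath-to-breath dive detection and three-phase partitioning.

A dive is a maximal excursion below a surface threshold that reaches a
minimum depth.  Each dive splits into:

* **descending** — surface to the *first* attainment of maximum depth;
* **ascending** — the maximal suffix after maximum depth along which depth
  never rises more than an excursion limit (default 10 m, less than an
  adult body length) above the running minimum, ending at the surface;
* **horizontal** — whatever lies between (possibly empty, as in V-dives).

Pitch is deliberately not used: a nursing calf's pitch is confounded by
the act of nursing itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

PHASES = ("descending", "horizontal", "ascending")

DEFAULT_SURFACE_THRESHOLD_M = 1.0
DEFAULT_MIN_DIVE_DEPTH_M = 5.0
DEFAULT_ASCENT_EXCURSION_LIMIT_M = 10.0

#: Depth-sensor resolution: samples within this of the dive maximum count
#: as having attained it (guards against anti-alias ripple on flat bottoms).
DEFAULT_DEPTH_TOL_M = 0.05


@dataclass(frozen=True)
class DiveInterval:
    """One detected dive with interpolated threshold-crossing times."""

    dive_id: int
    start_s: float
    end_s: float
    i0: int        # first sample with depth > threshold
    i1: int        # one past the last such sample
    max_depth_m: float


def detect_dives(depth: np.ndarray, fs: float,
                 surface_threshold_m: float = DEFAULT_SURFACE_THRESHOLD_M,
                 min_dive_depth_m: float = DEFAULT_MIN_DIVE_DEPTH_M,
                 t0: float = 0.0) -> list[DiveInterval]:
    """Maximal intervals with depth above threshold reaching the minimum depth.

    Start/end times are linearly interpolated threshold crossings (clamped
    to the record limits when the trace begins or ends submerged).
    """
    depth = np.asarray(depth, dtype=float)
    sub = depth > surface_threshold_m
    if not sub.any():
        return []
    edges = np.diff(sub.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if sub[0]:
        starts.insert(0, 0)
    if sub[-1]:
        ends.append(len(depth))
    dives = []
    for i0, i1 in zip(starts, ends):
        dmax = float(depth[i0:i1].max())
        if dmax < min_dive_depth_m:
            continue
        if i0 > 0:
            f = (surface_threshold_m - depth[i0 - 1]) / (depth[i0] - depth[i0 - 1])
            t_start = t0 + (i0 - 1 + f) / fs
        else:
            t_start = t0
        if i1 < len(depth):
            f = (depth[i1 - 1] - surface_threshold_m) / (depth[i1 - 1] - depth[i1])
            t_end = t0 + (i1 - 1 + f) / fs
        else:
            t_end = t0 + (len(depth) - 1) / fs
        dives.append(DiveInterval(dive_id=len(dives), start_s=t_start,
                                  end_s=t_end, i0=i0, i1=i1, max_depth_m=dmax))
    return dives


def _earliest_valid_ascent(seg: np.ndarray, imax: int, limit: float,
                           depth_tol: float) -> int:
    """Earliest valid ascent start index after the (first) maximum depth.

    Index ``s`` starts a valid ascent iff depth has begun to decrease at
    ``s`` (``seg[s] < seg[s-1]`` and ``seg[s]`` below the dive maximum by
    more than the sensor tolerance; a flat bottom is not yet an ascent)
    and the suffix from ``s`` never rises more than ``limit`` above its
    running minimum.  The excursion condition alone is monotone in ``s``
    (dropping the front element can only raise running minima, loosening
    the constraint), so its earliest satisfying index is found by binary
    search; the decrease conditions are then met by a forward scan.
    """
    def excursion_ok(s: int) -> bool:
        suffix = seg[s:]
        runmin = np.minimum.accumulate(suffix)
        return bool(np.all(suffix <= runmin + limit))

    lo, hi = imax + 1, len(seg) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if excursion_ok(mid):
            hi = mid
        else:
            lo = mid + 1
    dmax = seg.max()
    for s in range(lo, len(seg)):
        if seg[s] < seg[s - 1] and seg[s] < dmax - depth_tol:
            return s
    raise ValidationError("no descent towards the surface after maximum depth")


def classify_phases(depth: np.ndarray, fs: float, dive: DiveInterval,
                    ascent_excursion_limit_m: float = DEFAULT_ASCENT_EXCURSION_LIMIT_M,
                    t0: float = 0.0,
                    depth_tol_m: float = DEFAULT_DEPTH_TOL_M) -> list[dict]:
    """Partition one dive into contiguous descending/horizontal/ascending rows.

    ``depth_tol_m`` is the sensor resolution: descending ends at the first
    sample within that tolerance of the dive maximum (``0`` for the exact
    first attainment).
    """
    seg = np.asarray(depth[dive.i0:dive.i1], dtype=float)
    if len(seg) < 2:
        raise ValidationError(f"dive {dive.dive_id}: too short to classify")
    # first attainment of max depth, to sensor resolution
    imax = int(np.argmax(seg >= seg.max() - depth_tol_m))
    if imax == len(seg) - 1:
        raise ValidationError(
            f"dive {dive.dive_id}: maximum depth at the final sample, "
            "no ascent to classify")
    s_asc = _earliest_valid_ascent(seg, imax, ascent_excursion_limit_m,
                                   depth_tol_m)

    t_desc_end = t0 + (dive.i0 + imax) / fs
    # the ascent interval opens at the sample preceding the first decrease,
    # so an immediate ascent (s_asc == imax + 1) leaves no horizontal phase
    t_asc_start = t0 + (dive.i0 + s_asc - 1) / fs
    rows = [dict(dive_id=dive.dive_id, phase="descending",
                 start_s=dive.start_s, end_s=t_desc_end,
                 max_depth_m=dive.max_depth_m)]
    if t_asc_start > t_desc_end:
        rows.append(dict(dive_id=dive.dive_id, phase="horizontal",
                         start_s=t_desc_end, end_s=t_asc_start,
                         max_depth_m=dive.max_depth_m))
    rows.append(dict(dive_id=dive.dive_id, phase="ascending",
                     start_s=t_asc_start, end_s=dive.end_s,
                     max_depth_m=dive.max_depth_m))
    return rows


class DivePhaseTable:
    """Per-dive phase intervals with fast time-to-phase lookup."""

    def __init__(self, rows: list[dict] | pd.DataFrame):
        df = pd.DataFrame(rows, columns=["dive_id", "phase", "start_s",
                                         "end_s", "max_depth_m"])
        df = df.sort_values(["start_s"]).reset_index(drop=True)
        if not df.empty:
            if not df["phase"].isin(PHASES).all():
                raise ValidationError("unknown phase label in table")
            if (df["end_s"] < df["start_s"]).any():
                raise ValidationError("phase interval with negative duration")
        self.df = df
        self._starts = df["start_s"].to_numpy()
        self._ends = df["end_s"].to_numpy()
        self._phases = df["phase"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def phase_of(self, t: float) -> str:
        """Phase containing time ``t`` (closed-open), or ``"surface"``."""
        i = int(np.searchsorted(self._starts, t, side="right")) - 1
        if i >= 0 and t < self._ends[i]:
            return str(self._phases[i])
        return "surface"

    def intervals(self, phase: str) -> list[tuple[float, float]]:
        sel = self.df[self.df["phase"] == phase]
        return list(zip(sel["start_s"], sel["end_s"]))

    def dominant_phase(self, start_s: float, end_s: float) -> str:
        """Phase with the largest overlap with [start_s, end_s)."""
        best, best_len = "surface", 0.0
        for phase in PHASES:
            for s, e in self.intervals(phase):
                ov = min(e, end_s) - max(s, start_s)
                if ov > best_len:
                    best, best_len = phase, ov
        return best


def build_phase_table(depth: np.ndarray, fs: float,
                      surface_threshold_m: float = DEFAULT_SURFACE_THRESHOLD_M,
                      min_dive_depth_m: float = DEFAULT_MIN_DIVE_DEPTH_M,
                      ascent_excursion_limit_m: float = DEFAULT_ASCENT_EXCURSION_LIMIT_M,
                      t0: float = 0.0,
                      depth_tol_m: float = DEFAULT_DEPTH_TOL_M) -> DivePhaseTable:
    """Detect dives and classify every one of them."""
    rows: list[dict] = []
    for dive in detect_dives(depth, fs, surface_threshold_m,
                             min_dive_depth_m, t0):
        rows.extend(classify_phases(depth, fs, dive,
                                    ascent_excursion_limit_m, t0,
                                    depth_tol_m))
    return DivePhaseTable(rows)
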