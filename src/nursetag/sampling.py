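"""Randomized, phase-matched, non-overlapping 30 s segment selection.

Nursing events enter the analysis at their true durations; non-nursing
baselines are fixed-length windows drawn separately for every dive phase
in which an individual nursed: a uniform random start time is drawn over
the deployment, then the scan moves forward to the first window that lies
entirely inside one contiguous interval of the requested phase and
overlaps no nursing, probable-nursing or poor-video interval and no
previously selected window.  The 30 s default window is the mean nursing
duration (23 s) plus one standard deviation (7 s).

Feasibility is checked exactly: the maximum number of disjoint windows in
the admissible time is the sum over free intervals of floor(length/window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv
from .dive_phases import DivePhaseTable
from .errors import InfeasibleSamplingError, ValidationError
from .io_core import EventLog, TagRecord
from .kinematics import ProcessedRecord

#: Event types excluded from non-nursing sampling (and from analysis).
EXCLUDED_EVENT_TYPES = ("nursing", "probable_nursing", "poor_video")

DEFAULT_WINDOW_S = 30.0
DEFAULT_N_CALF = 15
DEFAULT_N_MOTHER = 9
MAX_DRAWS = 100_000


@dataclass(frozen=True)
class AnalysisSegment:
    """One analysis segment: a nursing event or a sampled baseline window."""

    deployment_id: str
    role: str
    start_s: float
    end_s: float
    phase: str
    is_nursing: bool
    source: str          # "event" or "sampled"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValidationError("segment duration must be positive")


def _free_intervals(phase_intervals: list[tuple[float, float]],
                    exclusions: list[tuple[float, float]]
                    ) -> list[tuple[float, float]]:
    return iv.subtract(phase_intervals, exclusions)


def max_disjoint_windows(free: list[tuple[float, float]],
                         window_s: float) -> int:
    """Exact packing bound: disjoint windows fit greedily left to right."""
    return int(sum(int((e - s) // window_s) for s, e in free))


def _first_admissible_start(free: list[tuple[float, float]],
                            window_s: float, u: float) -> float | None:
    """Earliest admissible window start >= u, or None."""
    for s, e in sorted(free):
        start = max(s, u)
        if start + window_s <= e:
            return start
    return None


def sample_nonnursing(record: ProcessedRecord | TagRecord,
                      phases: DivePhaseTable,
                      events: EventLog, phase: str, n: int,
                      window_s: float = DEFAULT_WINDOW_S,
                      seed: int | np.random.Generator = 0,
                      extra_exclusions: list[tuple[float, float]] | None = None
                      ) -> list[AnalysisSegment]:
    """Draw ``n`` disjoint non-nursing windows inside the requested phase.

    Emulates the field procedure: uniform random start time over the
    deployment, then forward scan to the first admissible window.
    Reproducible given ``seed`` (an int or an existing Generator).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rec = record.record if isinstance(record, ProcessedRecord) else record
    dep = rec.deployment_id
    phase_ivs = phases.intervals(phase)
    if not phase_ivs:
        raise ValidationError(f"phase {phase!r} absent from phase table")
    exclusions = list(events.subset(dep, list(EXCLUDED_EVENT_TYPES))
                      .df[["start_s", "end_s"]].itertuples(index=False, name=None))
    if extra_exclusions:
        exclusions.extend(extra_exclusions)

    free0 = _free_intervals(phase_ivs, exclusions)
    capacity = max_disjoint_windows(free0, window_s)
    if capacity < n:
        raise InfeasibleSamplingError(n, capacity)

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t_lo = rec.t0
    t_hi = rec.t0 + rec.duration_s
    chosen: list[tuple[float, float]] = []
    draws = 0
    while len(chosen) < n:
        free = _free_intervals(phase_ivs, exclusions + chosen)
        if not any(e - s >= window_s for s, e in free):
            achievable = len(chosen)
            raise InfeasibleSamplingError(n, achievable)
        draws += 1
        if draws > MAX_DRAWS:
            achievable = len(chosen) + max_disjoint_windows(free, window_s)
            raise InfeasibleSamplingError(n, min(achievable, capacity))
        u = rng.uniform(t_lo, t_hi)
        start = _first_admissible_start(free, window_s, u)
        if start is None:
            continue
        chosen.append((start, start + window_s))

    return [AnalysisSegment(deployment_id=dep, role=rec.role, start_s=s,
                            end_s=e, phase=phase, is_nursing=False,
                            source="sampled")
            for s, e in sorted(chosen)]


@dataclass(frozen=True)
class SamplingConfig:
    window_s: float = DEFAULT_WINDOW_S
    n_calf: int = DEFAULT_N_CALF
    n_mother: int = DEFAULT_N_MOTHER
    seed: int = 0
    pairing: dict[str, str] = field(default_factory=dict)  # mother -> calf


def _nursing_segments(dep: str, role: str, events: EventLog,
                      phases: DivePhaseTable) -> list[AnalysisSegment]:
    out = []
    for s, e in events.intervals(dep, "nursing"):
        out.append(AnalysisSegment(
            deployment_id=dep, role=role, start_s=s, end_s=e,
            phase=phases.dominant_phase(s, e), is_nursing=True,
            source="event"))
    return out


def build_segment_table(records: dict[str, ProcessedRecord],
                        phase_tables: dict[str, DivePhaseTable],
                        events: EventLog,
                        config: SamplingConfig = SamplingConfig()
                        ) -> list[AnalysisSegment]:
    """Nursing segments plus per-phase sampled baselines for all deployments.

    Calves contribute every logged nursing event and ``n_calf`` sampled
    windows per dive phase in which that calf nursed.  A tagged mother's
    nursing segments are the timestamps of her calf's events copied onto
    her own record (taken from the log if annotated there, otherwise from
    the paired calf via ``config.pairing``), with ``n_mother`` sampled
    windows per phase nursed in.  Deployments without nursing contribute
    nothing.
    """
    segments: list[AnalysisSegment] = []
    for k, dep in enumerate(sorted(records)):
        rec = records[dep]
        role = rec.record.role
        phases = phase_tables[dep]
        nursing = _nursing_segments(dep, role, events, phases)
        if role == "mother" and not nursing and dep in config.pairing:
            calf_dep = config.pairing[dep]
            t_end = rec.record.t0 + rec.record.duration_s
            for s, e in events.intervals(calf_dep, "nursing"):
                if s >= rec.record.t0 and e <= t_end:
                    nursing.append(AnalysisSegment(
                        deployment_id=dep, role=role, start_s=s, end_s=e,
                        phase=phases.dominant_phase(s, e), is_nursing=True,
                        source="event"))
        if not nursing:
            continue
        segments.extend(nursing)
        n_per_phase = config.n_calf if role == "calf" else config.n_mother
        # exclude the copied nursing times even if absent from this
        # deployment's own log rows
        extra = [(seg.start_s, seg.end_s) for seg in nursing]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, k]))
        for phase in sorted({seg.phase for seg in nursing}):
            segments.extend(sample_nonnursing(
                rec, phases, events, phase, n_per_phase,
                window_s=config.window_s, seed=rng, extra_exclusions=extra))
    return segments
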