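"""Seeded synthetic mother/calf tag deployments with ground truth.

The generator emulates the statistical structure the analysis assumes:

* dive cycles (surface, constant-rate descent, flat bottom, constant-rate
  ascent, optionally a re-descent excursion on the ascent);
* dorsoventral (heave-axis) sinusoidal fluke stroking at a baseline gait
  frequency, with optional gliding bouts, plus white sensor noise;
* a gravity component consistent with the instantaneous pitch implied by
  the depth slope and swimming speed;
* nursing events during which a calf's stroke frequency and amplitude are
  scaled **up** and a mother's scaled **down** relative to baseline, with
  default effect sizes matching the observed field magnitudes
  (calf ODBA x1.5, calf FSR x1.7, mother x0.3).

Depth is synthesised at the accelerometer rate, subsampled to the pressure
-sensor rate and linearly interpolated back, so the depth channel carries
only pressure-sensor bandwidth while all channels stay equal length.

Everything is deterministic given the :class:`SimConfig` (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io_core import EventLog, TagRecord, make_event_log

GRAVITY = 9.81  # m/s^2

SURFACE = "surface"
DESCENDING = "descending"
HORIZONTAL = "horizontal"
ASCENDING = "ascending"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiveSpec:
    """One dive cycle: surface interval then a trapezoid (or V) dive.

    ``excursion_m`` > 0 inserts a re-descent of that many metres partway up
    the ascent (starting once the whale has ascended ``excursion_at_frac``
    of the way back to the surface); used to exercise the ascent rule.
    """

    surface_s: float
    descent_rate: float   # m/s
    max_depth: float      # m
    bottom_s: float
    ascent_rate: float    # m/s
    excursion_m: float = 0.0
    excursion_at_frac: float = 0.5

    @property
    def descent_s(self) -> float:
        return self.max_depth / self.descent_rate

    @property
    def ascent_s(self) -> float:
        return (self.max_depth + 2 * self.excursion_m) / self.ascent_rate

    @property
    def cycle_s(self) -> float:
        return self.surface_s + self.descent_s + self.bottom_s + self.ascent_s


@dataclass(frozen=True)
class GaitConfig:
    """Baseline fluking gait.

    ``stroke_amp`` is the peak dorsoventral dynamic acceleration of one
    stroke cycle; with the default noise level the baseline mean ODBA lands
    near 0.2 m/s^2, inside the 0.12-0.28 m/s^2 range typical of travelling
    humpback mother-calf pairs.
    """

    stroke_freq_hz: float = 0.25
    stroke_amp: float = 0.25      # m/s^2
    glide_fraction: float = 0.0   # fraction of each gait bout spent gliding
    bout_period_s: float = 60.0   # glide/stroke alternation period


@dataclass(frozen=True)
class EffectConfig:
    """Multiplicative nursing effects on gait frequency (FSR) and amplitude."""

    calf_fsr_multiplier: float = 1.7
    calf_odba_multiplier: float = 1.5
    mother_fsr_multiplier: float = 0.3
    mother_odba_multiplier: float = 0.3

    def for_role(self, role: str) -> tuple[float, float]:
        """(fsr_multiplier, amplitude_multiplier) for the given role."""
        if role == "calf":
            return self.calf_fsr_multiplier, self.calf_odba_multiplier
        return self.mother_fsr_multiplier, self.mother_odba_multiplier


_DEFAULT_PLAN = (
    DiveSpec(surface_s=60.0, descent_rate=1.0, max_depth=30.0,
             bottom_s=120.0, ascent_rate=1.0),
) * 4


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    duration_s: float | None = None          # None: inferred from dive_plan
    fs_hi: float = 400.0
    fs_depth: float = 10.0
    dive_plan: tuple[DiveSpec, ...] = _DEFAULT_PLAN
    gait: GaitConfig = field(default_factory=GaitConfig)
    nursing_events: tuple[tuple[float, float], ...] = ()   # (start_s, duration_s)
    effect: EffectConfig = field(default_factory=EffectConfig)
    noise_sd: float = 0.02        # m/s^2 per axis
    speed_base: float = 1.4       # m/s
    speed_ripple_frac: float = 0.1
    seafloor_m: float = 200.0

    @property
    def total_duration_s(self) -> float:
        plan_s = sum(d.cycle_s for d in self.dive_plan)
        return plan_s if self.duration_s is None else self.duration_s

    @property
    def n_hi(self) -> int:
        return int(round(self.total_duration_s * self.fs_hi))

    def validate(self) -> None:
        eff = self.effect
        if min(eff.calf_fsr_multiplier, eff.calf_odba_multiplier) < 0 or \
           min(eff.mother_fsr_multiplier, eff.mother_odba_multiplier) < 0:
            raise ConfigError("effect multipliers must be non-negative")
        ratio = self.fs_hi / self.fs_depth
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigError("fs_hi must be an integer multiple of fs_depth")
        for d in self.dive_plan:
            if d.max_depth + d.excursion_m > self.seafloor_m:
                raise ConfigError(
                    f"dive to {d.max_depth + d.excursion_m} m exceeds "
                    f"seafloor at {self.seafloor_m} m")
            if d.max_depth <= 0 or d.descent_rate <= 0 or d.ascent_rate <= 0:
                raise ConfigError("dive depths and rates must be positive")
        if self.duration_s is not None and \
           self.duration_s < sum(d.cycle_s for d in self.dive_plan) - 1e-9:
            raise ConfigError("duration_s shorter than the dive plan")
        ev = sorted(self.nursing_events)
        for (s1, d1), (s2, _) in zip(ev, ev[1:]):
            if s2 < s1 + d1:
                raise ConfigError("nursing events overlap")
        dives = self.dive_intervals()
        for s, d in ev:
            if d <= 0:
                raise ConfigError("nursing duration must be positive")
            if not any(ds <= s and s + d <= de for ds, de in dives):
                raise ConfigError(
                    f"nursing event [{s}, {s + d}) lies outside every dive")

    def dive_intervals(self) -> list[tuple[float, float]]:
        """Planned (submerged) intervals, one per dive cycle."""
        out, t = [], 0.0
        for d in self.dive_plan:
            start = t + d.surface_s
            out.append((start, t + d.cycle_s))
            t += d.cycle_s
        return out


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    events: EventLog                 # nursing intervals
    phase_labels: np.ndarray         # per hi-rate sample, plan-based
    stroke_times: np.ndarray         # zero-upcrossing times of the clean gait
    fs: float
    dive_intervals: list[tuple[float, float]]
    config: SimConfig

    def stroke_count(self, start_s: float, end_s: float) -> int:
        return int(np.sum((self.stroke_times >= start_s)
                          & (self.stroke_times < end_s)))

    def expected_mean_odba(self, amplitude_multiplier: float = 1.0) -> float:
        """Analytic mean ODBA of sinusoidal heave stroking plus noise.

        mean|A sin| = 2A/pi on the heave axis; each noisy axis adds
        sigma*sqrt(2/pi).
        """
        cfg = self.config
        active = 1.0 - cfg.gait.glide_fraction
        return (2.0 * cfg.gait.stroke_amp * amplitude_multiplier / np.pi * active
                + 3.0 * cfg.noise_sd * np.sqrt(2.0 / np.pi))


# ---------------------------------------------------------------------------
# Depth profile
# ---------------------------------------------------------------------------

def _depth_breakpoints(config: SimConfig) -> tuple[list[float], list[float],
                                                   list[tuple[float, float, str]]]:
    """Piecewise-linear (time, depth) breakpoints plus labelled segments."""
    ts, zs = [0.0], [0.0]
    segments: list[tuple[float, float, str]] = []
    t = 0.0

    def add(dt: float, z_end: float, label: str) -> None:
        nonlocal t
        if dt <= 0:
            return
        segments.append((t, t + dt, label))
        t += dt
        ts.append(t)
        zs.append(z_end)

    for d in config.dive_plan:
        add(d.surface_s, 0.0, SURFACE)
        add(d.descent_s, d.max_depth, DESCENDING)
        add(d.bottom_s, d.max_depth, HORIZONTAL)
        if d.excursion_m > 0:
            z_turn = d.max_depth * (1.0 - d.excursion_at_frac)
            add((d.max_depth - z_turn) / d.ascent_rate, z_turn, ASCENDING)
            add(d.excursion_m / d.ascent_rate, z_turn + d.excursion_m, ASCENDING)
            add((z_turn + d.excursion_m) / d.ascent_rate, 0.0, ASCENDING)
        else:
            add(d.ascent_s, 0.0, ASCENDING)
    total = config.total_duration_s
    if total > t + 1e-9:
        add(total - t, 0.0, SURFACE)
    return ts, zs, segments


def simulate_depth_profile(config: SimConfig) -> tuple[np.ndarray, GroundTruth]:
    """Hi-rate depth trace plus plan-based phase labels and dive intervals."""
    config.validate()
    ts, zs, segments = _depth_breakpoints(config)
    n = config.n_hi
    t = np.arange(n) / config.fs_hi
    depth = np.interp(t, ts, zs)
    labels = np.full(n, SURFACE, dtype="<U10")
    for s, e, lab in segments:
        i0 = int(np.ceil(s * config.fs_hi - 1e-9))
        i1 = int(np.ceil(e * config.fs_hi - 1e-9))
        labels[i0:i1] = lab
    truth = GroundTruth(events=make_event_log([]), phase_labels=labels,
                        stroke_times=np.empty(0), fs=config.fs_hi,
                        dive_intervals=config.dive_intervals(), config=config)
    return depth, truth


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _active_mask(t: np.ndarray, gait: GaitConfig) -> np.ndarray:
    """Deterministic stroke/glide alternation: stroke first, then glide."""
    if gait.glide_fraction <= 0:
        return np.ones_like(t, dtype=bool)
    if gait.glide_fraction >= 1:
        return np.zeros_like(t, dtype=bool)
    frac = np.mod(t, gait.bout_period_s) / gait.bout_period_s
    return frac < (1.0 - gait.glide_fraction)


def _baseline_stroke(t: np.ndarray, gait: GaitConfig) -> np.ndarray:
    """Clean heave-axis stroke signal before nursing modulation."""
    return gait.stroke_amp * np.sin(2 * np.pi * gait.stroke_freq_hz * t) \
        * _active_mask(t, gait)


def _upcross_times(signal: np.ndarray, t: np.ndarray,
                   active: np.ndarray | None = None) -> np.ndarray:
    """Linear-interpolated positive-going zero-crossing times."""
    s = np.sign(signal)
    idx = np.flatnonzero((s[:-1] <= 0) & (s[1:] > 0))
    if active is not None:
        idx = idx[active[idx] & active[idx + 1]]
    if idx.size == 0:
        return np.empty(0)
    frac = -signal[idx] / (signal[idx + 1] - signal[idx])
    return t[idx] + frac * (t[1] - t[0])


def simulate_kinematics(depth: np.ndarray, config: SimConfig,
                        deployment_id: str = "sim-00",
                        role: str = "calf") -> tuple[TagRecord, GroundTruth]:
    """Tri-axial acceleration, speed and depth channels from a depth trace.

    Acceleration = gravity component for the pitch implied by depth slope
    and speed, plus heave-axis stroking, plus Gaussian noise (seeded from
    ``config.seed``; the role name is mixed in so paired deployments get
    independent noise).
    """
    config.validate()
    n = depth.shape[0]
    fs = config.fs_hi
    t = np.arange(n) / fs
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _role_key(role)]))

    stroke = _baseline_stroke(t, config.gait)
    speed = config.speed_base * (
        1.0 + config.speed_ripple_frac
        * np.sin(2 * np.pi * config.gait.stroke_freq_hz * t))

    # pitch follows the dive geometry at the mean swimming speed; the
    # stroke-locked speed ripple must not bleed into the gravity component
    dzdt = np.gradient(depth) * fs
    pitch = -np.arcsin(np.clip(dzdt / max(config.speed_base, 1e-6), -1.0, 1.0))
    static = np.column_stack([GRAVITY * np.sin(pitch),
                              np.zeros(n),
                              -GRAVITY * np.cos(pitch)])
    dynamic = np.column_stack([np.zeros(n), np.zeros(n), stroke])
    noise = rng.normal(0.0, config.noise_sd, size=(n, 3)) \
        if config.noise_sd > 0 else np.zeros((n, 3))
    acc = static + dynamic + noise

    # pressure sensor runs at fs_depth: subsample then interpolate back
    step = int(round(fs / config.fs_depth))
    depth_lo = depth[::step]
    t_lo = t[::step]
    depth_ch = np.interp(t, t_lo, depth_lo)

    record = TagRecord(deployment_id=deployment_id, role=role, fs=fs,
                       acc=acc, depth=depth_ch, speed=speed)
    active = _active_mask(t, config.gait)
    strokes = _upcross_times(np.sin(2 * np.pi * config.gait.stroke_freq_hz * t),
                             t, active)
    _, truth = simulate_depth_profile(config)
    truth.stroke_times = strokes
    return record, truth


def _role_key(role: str) -> int:
    return 0 if role == "calf" else 1


# ---------------------------------------------------------------------------
# Nursing modulation
# ---------------------------------------------------------------------------

def embed_nursing(record: TagRecord, config: SimConfig,
                  truth: GroundTruth | None = None
                  ) -> tuple[TagRecord, GroundTruth]:
    """Scale gait frequency/amplitude inside nursing windows, role-dependent.

    The clean baseline stroke component is reconstructed from the config
    (it is deterministic), subtracted inside each nursing window and
    replaced by a frequency- and amplitude-scaled version that is
    phase-continuous at the window start.  Noise is untouched, so unit
    multipliers reproduce the input record exactly.
    """
    config.validate()
    n = record.n_samples
    fs = record.fs
    t = np.arange(n) / fs
    gait = config.gait
    fsr_mult, amp_mult = config.effect.for_role(record.role)

    dives = config.dive_intervals()
    for s, d in config.nursing_events:
        if not any(ds <= s and s + d <= de for ds, de in dives):
            raise ConfigError(f"nursing event [{s}, {s + d}) outside every dive")

    acc = record.acc.copy()
    base_clean = _baseline_stroke(t, gait)
    active = _active_mask(t, gait)
    stroke_times = list(_upcross_times(
        np.sin(2 * np.pi * gait.stroke_freq_hz * t), t, active))

    for s, d in config.nursing_events:
        i0, i1 = int(np.ceil(s * fs - 1e-9)), int(np.ceil((s + d) * fs - 1e-9))
        tw = t[i0:i1]
        phi0 = 2 * np.pi * gait.stroke_freq_hz * s
        if fsr_mult > 0:
            phase = phi0 + 2 * np.pi * gait.stroke_freq_hz * fsr_mult * (tw - s)
            new = gait.stroke_amp * amp_mult * np.sin(phase) * active[i0:i1]
            new_strokes = _upcross_times(np.sin(phase), tw, active[i0:i1])
        else:
            new = np.zeros_like(tw)
            new_strokes = np.empty(0)
        acc[i0:i1, 2] += new - base_clean[i0:i1]
        stroke_times = [x for x in stroke_times if not (s <= x < s + d)]
        stroke_times.extend(new_strokes)

    events = make_event_log(
        [(record.deployment_id, "nursing", s, s + d)
         for s, d in config.nursing_events])
    out = record.replace(acc=acc)
    if truth is None:
        _, truth = simulate_depth_profile(config)
    truth.events = events
    truth.stroke_times = np.sort(np.asarray(stroke_times))
    return out, truth


def simulate_deployment(config: SimConfig, deployment_id: str = "sim-00",
                        role: str = "calf") -> tuple[TagRecord, GroundTruth]:
    """Full generator: depth profile -> kinematics -> nursing modulation."""
    depth, _ = simulate_depth_profile(config)
    record, truth = simulate_kinematics(depth, config, deployment_id, role)
    return embed_nursing(record, config, truth)


def simulate_pair(config: SimConfig, base_id: str = "sim-00"
                  ) -> dict[str, tuple[TagRecord, GroundTruth]]:
    """Calf and mother deployments sharing one dive plan and nursing times."""
    calf = simulate_deployment(config, f"{base_id}-calf", role="calf")
    mother = simulate_deployment(config, f"{base_id}-mother", role="mother")
    return {"calf": calf, "mother": mother}


# ---------------------------------------------------------------------------
# Study-structure builder
# ---------------------------------------------------------------------------

#: Dive-phase category of each nursing event per reference deployment,
#: with the event duration in seconds.
STUDY_EVENT_PLAN: dict[str, list[tuple[str, float]]] = {
    "mn170612-30": [(DESCENDING, 15), (HORIZONTAL, 31), (HORIZONTAL, 18)],
    "mn170613-40": [(DESCENDING, 35), (DESCENDING, 20), (HORIZONTAL, 27)],
    "mn180620-40": [(DESCENDING, 27), (HORIZONTAL, 22), (HORIZONTAL, 28),
                    (HORIZONTAL, 18)],
    "mn180831-30": [(ASCENDING, 13)],
}

#: Mother deployment paired with each calf deployment (where a mother was
#: tagged) and the indices of the calf events the mother's record covers.
STUDY_PAIRING: dict[str, tuple[str, tuple[int, ...]]] = {
    "mn170613-40": ("mn170613-20", (0, 2)),
    "mn180831-30": ("mn180831-20", (0,)),
}


def study_config(deployment_id: str, seed: int, *, fs_hi: float = 40.0,
                 n_dives: int = 10) -> SimConfig:
    """SimConfig for one reference-structure deployment.

    ``n_dives`` trapezoid dives (60 m at 0.5 m/s descent and ascent,
    180 s bottom, 45 s surface) give ample contiguous time in every phase
    (four disjoint 30 s windows per descent/ascent, six per bottom);
    nursing events are placed mid-phase in successive dives with the phase
    category and duration of the corresponding observed event.
    """
    spec = DiveSpec(surface_s=45.0, descent_rate=0.5, max_depth=60.0,
                    bottom_s=180.0, ascent_rate=0.5)
    plan = (spec,) * n_dives
    events = []
    for i, (phase, dur) in enumerate(STUDY_EVENT_PLAN[deployment_id]):
        cycle0 = i * spec.cycle_s
        if phase == DESCENDING:
            p0, p1 = spec.surface_s, spec.surface_s + spec.descent_s
        elif phase == HORIZONTAL:
            p0 = spec.surface_s + spec.descent_s
            p1 = p0 + spec.bottom_s
        else:
            p0 = spec.surface_s + spec.descent_s + spec.bottom_s
            p1 = p0 + spec.ascent_s
        mid = cycle0 + 0.5 * (p0 + p1)
        events.append((round(mid - dur / 2.0, 1), float(dur)))
    return SimConfig(seed=seed, fs_hi=fs_hi, dive_plan=plan,
                     nursing_events=tuple(events))


def simulate_study(seed: int, *, fs_hi: float = 40.0, n_dives: int = 10
                   ) -> dict[str, tuple[TagRecord, GroundTruth]]:
    """All six reference-structure deployments (4 calves, 2 mothers)."""
    out: dict[str, tuple[TagRecord, GroundTruth]] = {}
    for k, dep in enumerate(sorted(STUDY_EVENT_PLAN)):
        cfg = study_config(dep, seed + k, fs_hi=fs_hi, n_dives=n_dives)
        out[dep] = simulate_deployment(cfg, dep, role="calf")
        if dep in STUDY_PAIRING:
            mom_id, idx = STUDY_PAIRING[dep]
            mom_cfg = replace(
                cfg, nursing_events=tuple(cfg.nursing_events[i] for i in idx))
            out[mom_id] = simulate_deployment(mom_cfg, mom_id, role="mother")
    return out
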