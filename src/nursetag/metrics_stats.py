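"""Segment kinematics, the nursing x phase mixed model, and event budgets.

Per segment: depth statistics, mean speed, mean ODBA, fluke-stroke rate
(strokes in the segment divided by its duration) and circular means of
the orientation angles.

The behavioural comparison fits, per response (mean ODBA or FSR), a linear
mixed model ``response ~ nursing * phase`` with a random intercept per
individual (deployment), phase coded sum-to-zero so the nursing
coefficient is the phase-averaged nursing effect.  Significance uses a
Wald F with 1 numerator df and denominator df
``n - rank(X) - (n_individuals - 1)`` — the residual df after charging
both the fixed effects and the between-individual contrasts, which is the
convention that yields F(1, 107) for 116 segments over four individuals
with a full 2 x 3 design.  No Satterthwaite correction is applied; this
is an approximation, adequate at these sample sizes.

Budgets: per-deployment nursing time against good-quality video, proximity
time outside nursing by exact interval arithmetic, and shortest gaps
between nursing and maternal foraging events.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from . import intervals as iv
from .errors import ParameterError, ValidationError
from .io_core import FORAGING_TYPES, EventLog
from .kinematics import ProcessedRecord
from .sampling import AnalysisSegment


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def circular_mean(angles: Sequence[float] | np.ndarray) -> float:
    """Mean angle via mean sine/cosine; result in (-pi, pi].

    Raises if the mean resultant vector is (numerically) zero, where the
    mean direction is undefined.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ParameterError("circular mean of an empty set is undefined")
    ms, mc = np.mean(np.sin(a)), np.mean(np.cos(a))
    if np.hypot(ms, mc) < 1e-12:
        raise ParameterError("mean resultant length ~ 0: undefined mean angle")
    ang = float(np.arctan2(ms, mc))
    return np.pi if ang == -np.pi else ang


# ---------------------------------------------------------------------------
# Segment metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentMetrics:
    deployment_id: str
    role: str
    start_s: float
    end_s: float
    phase: str
    is_nursing: bool
    source: str
    min_depth: float
    max_depth: float
    mean_depth: float
    mean_speed: float | None
    mean_odba: float
    fsr: float
    circ_mean_pitch: float
    circ_mean_roll: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def segment_metrics(segment: AnalysisSegment,
                    processed: ProcessedRecord) -> SegmentMetrics:
    """Kinematic summary of one segment over samples in [start_s, end_s)."""
    rec = processed.record
    i0 = rec.index_of(segment.start_s)
    i1 = rec.index_of(segment.end_s)
    i0, i1 = max(i0, 0), min(i1, rec.n_samples)
    if i1 - i0 < 2:
        raise ValidationError(
            f"segment [{segment.start_s}, {segment.end_s}) covers fewer "
            "than 2 samples")
    depth = processed.depth[i0:i1]
    n_strokes = int(np.sum((processed.stroke_times >= segment.start_s)
                           & (processed.stroke_times < segment.end_s)))
    return SegmentMetrics(
        deployment_id=segment.deployment_id, role=segment.role,
        start_s=segment.start_s, end_s=segment.end_s, phase=segment.phase,
        is_nursing=segment.is_nursing, source=segment.source,
        min_depth=float(depth.min()), max_depth=float(depth.max()),
        mean_depth=float(depth.mean()),
        mean_speed=(None if rec.speed is None
                    else float(rec.speed[i0:i1].mean())),
        mean_odba=float(processed.odba[i0:i1].mean()),
        fsr=n_strokes / segment.duration_s,
        circ_mean_pitch=circular_mean(processed.pitch[i0:i1]),
        circ_mean_roll=circular_mean(processed.roll[i0:i1]))


def metrics_table(segments: Sequence[AnalysisSegment],
                  processed: Mapping[str, ProcessedRecord]) -> pd.DataFrame:
    """Segment metrics for a batch, as a DataFrame (one row per segment)."""
    rows = [segment_metrics(s, processed[s.deployment_id]).__dict__
            for s in segments]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed-effects comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    response: str
    n_segments: int
    nursing_effect: float      # phase-averaged nursing - non-nursing
    se: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    random_intercept_var: float
    fixed_effects: "pd.Series"
    converged: bool


def fit_nursing_model(metrics: pd.DataFrame, response: str
                      ) -> ComparisonResult:
    """Mixed model ``response ~ nursing * phase`` + random intercept/individual.

    ``metrics`` needs columns ``deployment_id``, ``phase``, ``is_nursing``
    and the response.  Requires at least two individuals and both nursing
    states; a single phase level is allowed (the phase terms then drop).
    """
    df = metrics.copy()
    if response not in df.columns:
        raise ValidationError(f"response {response!r} not in metrics")
    df = df.dropna(subset=[response])
    if df["deployment_id"].nunique() < 2:
        raise ValidationError("need >= 2 individuals for a mixed model")
    if df["is_nursing"].nunique() < 2:
        raise ValidationError("need both nursing and non-nursing segments")
    df["nursing"] = df["is_nursing"].astype(int)
    df["resp"] = df[response].astype(float)

    if df["phase"].nunique() > 1:
        formula = "resp ~ nursing * C(phase, Sum)"
    else:
        formula = "resp ~ nursing"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["deployment_id"])
        fit = None
        # the default optimizer can hit a singular profiled Hessian on
        # small unbalanced designs; Powell is slower but robust
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=True, method=method)
            except np.linalg.LinAlgError:
                continue
            fit = cand
            if cand.converged:
                break
        if fit is None:
            raise ValidationError("mixed model failed to fit")
        params = fit.fe_params
        name = "nursing"
        est = float(params[name])
        se = float(fit.bse_fe[name])
    n = len(df)
    rank = np.linalg.matrix_rank(model.exog)
    g = df["deployment_id"].nunique()
    df_den = n - rank - (g - 1)
    if df_den <= 0:
        raise ValidationError("non-positive denominator df")
    f_stat = (est / se) ** 2 if se > 0 else 0.0
    p = float(stats.f.sf(f_stat, 1, df_den))
    return ComparisonResult(
        response=response, n_segments=n, nursing_effect=est, se=se,
        f_stat=float(f_stat), df_num=1, df_den=int(df_den), p_value=p,
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        fixed_effects=params, converged=bool(fit.converged))


# ---------------------------------------------------------------------------
# Budgets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NursingBudget:
    deployment_id: str
    n_events: int
    mean_duration_s: float
    total_nursing_s: float
    good_video_s: float
    percent_of_good_video: float


def nursing_budget(events: EventLog, deployment_id: str,
                   good_video_s: float) -> NursingBudget:
    """Event count, mean/total duration and percent of good-quality video."""
    if good_video_s <= 0:
        raise ValidationError("good_video_s must be positive")
    ivs = events.intervals(deployment_id, "nursing")
    durations = [e - s for s, e in ivs]
    total = float(sum(durations))
    return NursingBudget(
        deployment_id=deployment_id, n_events=len(ivs),
        mean_duration_s=(total / len(ivs)) if ivs else 0.0,
        total_nursing_s=total, good_video_s=good_video_s,
        percent_of_good_video=100.0 * total / good_video_s)


@dataclass(frozen=True)
class ProximityBudget:
    deployment_id: str
    proximity_s: float
    nursing_s: float
    proximity_nonnursing_s: float
    good_video_s: float
    percent_nonnursing_proximity: float   # of good video
    percent_nursing_of_proximity: float
    remainder_s: float                    # good video outside proximity+nursing


def proximity_budget(events: EventLog, deployment_id: str,
                     good_video_s: float) -> ProximityBudget:
    """Proximity time outside nursing, by exact interval arithmetic."""
    prox = events.intervals(deployment_id, "proximity")
    nurs = events.intervals(deployment_id, "nursing")
    prox_len = iv.total_length(prox)
    nurs_len = iv.total_length(nurs)
    nonnurs = iv.total_length(iv.subtract(prox, nurs))
    union = iv.total_length(iv.merge(list(prox) + list(nurs)))
    return ProximityBudget(
        deployment_id=deployment_id, proximity_s=prox_len,
        nursing_s=nurs_len, proximity_nonnursing_s=nonnurs,
        good_video_s=good_video_s,
        percent_nonnursing_proximity=100.0 * nonnurs / good_video_s,
        percent_nursing_of_proximity=(100.0 * nurs_len / prox_len
                                      if prox_len > 0 else 0.0),
        remainder_s=good_video_s - union)


def nursing_foraging_gaps(events: EventLog,
                          deployment_id: str | None = None) -> pd.DataFrame:
    """Shortest gap from each nursing event to any maternal foraging event.

    Gaps are between closed intervals (0 when overlapping).  Deployments
    with no foraging annotations yield NaN gaps (undetermined).
    Columns: deployment_id, start_s, end_s, gap_s.
    """
    deps = [deployment_id] if deployment_id else events.deployments()
    rows = []
    for dep in deps:
        nurs = events.intervals(dep, "nursing")
        forg = events.intervals(dep, list(FORAGING_TYPES))
        for s, e in nurs:
            if not forg:
                gap = np.nan
            else:
                gap = min(max(fs_ - e, s - fe, 0.0) for fs_, fe in forg)
            rows.append(dict(deployment_id=dep, start_s=s, end_s=e, gap_s=gap))
    return pd.DataFrame(rows, columns=["deployment_id", "start_s",
                                       "end_s", "gap_s"])


# ---------------------------------------------------------------------------
# Report formatting
# ---------------------------------------------------------------------------

def round_seconds(x: float) -> int:
    """Round to whole seconds, half to even (banker's rounding)."""
    return int(np.round(x))


def report_tables(metrics: pd.DataFrame,
                  results: Sequence[ComparisonResult],
                  budgets: Sequence[NursingBudget],
                  out_dir: str | Path,
                  metadata: dict | None = None) -> dict[str, Path]:
    """Write deployment-budget, per-event and per-phase comparison tables.

    Durations are reported in whole seconds (half-to-even), percentages to
    two decimals, speeds to one decimal.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    budget_df = pd.DataFrame([
        dict(individual_id=b.deployment_id, n_events=b.n_events,
             mean_duration_s=round_seconds(b.mean_duration_s),
             total_nursing_s=round_seconds(b.total_nursing_s),
             good_video_h=round(b.good_video_s / 3600.0, 1),
             percent_nursing=round(b.percent_of_good_video, 2))
        for b in budgets])
    paths["budget"] = out_dir / "nursing_budget.tsv"
    budget_df.to_csv(paths["budget"], sep="\t", index=False)

    ev_cols = ["deployment_id", "role", "phase", "is_nursing", "start_s",
               "end_s", "mean_speed", "mean_odba", "fsr", "min_depth",
               "max_depth", "mean_depth"]
    events_df = metrics.reindex(columns=ev_cols).copy()
    if "mean_speed" in events_df:
        events_df["mean_speed"] = events_df["mean_speed"].round(1)
    for col in ("mean_odba", "fsr"):
        events_df[col] = events_df[col].round(4)
    paths["segments"] = out_dir / "segment_metrics.tsv"
    events_df.to_csv(paths["segments"], sep="\t", index=False)

    if len(metrics):
        comp = (metrics.groupby(["role", "phase", "is_nursing"])
                [["mean_odba", "fsr"]].mean().round(4).reset_index())
    else:
        comp = pd.DataFrame(columns=["role", "phase", "is_nursing",
                                     "mean_odba", "fsr"])
    paths["comparison"] = out_dir / "phase_comparison.tsv"
    comp.to_csv(paths["comparison"], sep="\t", index=False)

    model_df = pd.DataFrame([
        dict(response=r.response, n=r.n_segments,
             nursing_effect=round(r.nursing_effect, 5),
             F=round(r.f_stat, 5), df_num=r.df_num, df_den=r.df_den,
             p=float(f"{r.p_value:.3g}"))
        for r in results])
    paths["models"] = out_dir / "model_results.tsv"
    model_df.to_csv(paths["models"], sep="\t", index=False)

    meta = dict(metadata or {})
    paths["metadata"] = out_dir / "run_metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths
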