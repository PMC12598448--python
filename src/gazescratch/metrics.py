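"""Differential looking scores, preregistered exclusions, and aggregation.

The differential looking score (DLS) of a phase is

    DLS = (T_obj - T_nonobj) / (T_obj + T_nonobj)

where ``T_obj`` is the fixation time spent in the two object-containing
quadrants and ``T_nonobj`` the time in the other two; it ranges over
[-1, 1] and is undefined (NaN) when there was no on-screen looking.  A
fixation belongs to the quadrant containing its centroid, and a fixation
straddling a phase boundary contributes its within-phase portion to each
phase.

The exploratory disruption-phase variant removes from ``T_obj`` the time of
fixations landing on already-uncovered object parts, leaving the
denominator unchanged, so it can only be smaller than the standard score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fixations import Fixation
from .simulator import TrialRecord, VisibleRegion, visible_object_region
from .stimuli import AOILayout, _OBJECT_QUADRANTS

__all__ = [
    "TrialMetrics",
    "SubjectSummary",
    "looking_times",
    "compute_dls",
    "exploratory_dls",
    "split_half_contingent",
    "apply_trial_exclusions",
    "aggregate_subjects",
    "compute_trial_metrics",
    "trial_metrics_frame",
    "subject_summary_frame",
]

PHASES = ("baseline", "contingent", "disruption")


def looking_times(fixations: Sequence[Fixation], layout: AOILayout, condition: str,
                  window: tuple[float, float]) -> tuple[float, float]:
    """Object / non-object looking time (ms) inside a half-open phase window.

    Membership is decided by the fixation centroid; durations are clipped to
    the window.  Centroids off the screen contribute to neither term.
    """
    obj_quads = set(_OBJECT_QUADRANTS[condition])
    t_obj = 0.0
    t_non = 0.0
    for fix in fixations:
        dur = fix.overlap_ms(window)
        if dur <= 0:
            continue
        quad = layout.quadrant_of(fix.centroid_x, fix.centroid_y)
        if quad is None:
            continue
        if quad in obj_quads:
            t_obj += dur
        else:
            t_non += dur
    return t_obj, t_non


def _dls(t_obj: float, t_non: float) -> float:
    total = t_obj + t_non
    if total <= 0:
        return math.nan
    return (t_obj - t_non) / total


def compute_dls(fixations: Sequence[Fixation], layout: AOILayout, condition: str,
                window: tuple[float, float]) -> float:
    """Standard DLS for one phase window; NaN when nothing was looked at."""
    return _dls(*looking_times(fixations, layout, condition, window))


def exploratory_dls(fixations: Sequence[Fixation], layout: AOILayout, condition: str,
                    trial: TrialRecord, visible: VisibleRegion | None = None,
                    denominator_excludes_visible: bool = False) -> float:
    """Disruption-phase DLS discounting looks to already-visible object parts.

    Fixations whose centroid falls on an uncovered part of an object
    rectangle are subtracted from the object-quadrant looking time.  By
    default the denominator keeps the raw total, so the score is bounded
    above by the standard DLS; ``denominator_excludes_visible=True`` removes
    that time from the denominator as well.
    """
    window = trial.schedule.windows()["disruption"]
    if visible is None:
        visible = visible_object_region(trial.cover_at_disruption, trial.stimulus)
    t_obj, t_non = looking_times(fixations, layout, condition, window)
    t_visible = 0.0
    obj_quads = set(_OBJECT_QUADRANTS[condition])
    for fix in fixations:
        dur = fix.overlap_ms(window)
        if dur <= 0:
            continue
        quad = layout.quadrant_of(fix.centroid_x, fix.centroid_y)
        if quad in obj_quads and visible.contains(fix.centroid_x, fix.centroid_y):
            t_visible += dur
    denom = t_obj + t_non - (t_visible if denominator_excludes_visible else 0.0)
    if denom <= 0:
        return math.nan
    return (t_obj - t_visible - t_non) / denom


def split_half_contingent(fixations: Sequence[Fixation], layout: AOILayout,
                          condition: str, schedule) -> tuple[float, float]:
    """DLS of the first and second half of the *realized* contingent phase.

    The midpoint is halfway between the contingent onset and the realized
    stop time; fixation durations are clipped at it.
    """
    a, b = schedule.windows()["contingent"]
    mid = 0.5 * (a + b)
    return (
        compute_dls(fixations, layout, condition, (a, mid)),
        compute_dls(fixations, layout, condition, (mid, b)),
    )


@dataclass
class TrialMetrics:
    """Per-trial looking times, the DLS family and exclusion flags."""

    participant_id: str
    trial_id: str
    condition: str
    age_days: int = 0

    t_stop_ms: float = math.nan
    end_reason: str = ""
    uncovered_fraction: float = math.nan

    look_obj_baseline_ms: float = 0.0
    look_nonobj_baseline_ms: float = 0.0
    look_obj_contingent_ms: float = 0.0
    look_nonobj_contingent_ms: float = 0.0
    look_obj_disruption_ms: float = 0.0
    look_nonobj_disruption_ms: float = 0.0
    n_fixations_disruption: int = 0

    dls_baseline: float = math.nan
    dls_contingent: float = math.nan
    dls_disruption: float = math.nan
    dls_contingent_first_half: float = math.nan
    dls_contingent_second_half: float = math.nan
    dls_disruption_exploratory: float = math.nan

    excluded_baseline: bool = False
    excluded_contingent_disruption: bool = False
    excluded_disruption_only: bool = False
    exclusion_reasons: str = ""

    def look_total_ms(self, phase: str) -> float:
        return (getattr(self, f"look_obj_{phase}_ms")
                + getattr(self, f"look_nonobj_{phase}_ms"))

    def phase_valid(self, phase: str) -> bool:
        """Whether this trial contributes to the analysis of a phase."""
        if self.excluded_baseline:
            return False
        if phase == "baseline":
            return True
        if self.excluded_contingent_disruption:
            return False
        if phase == "contingent":
            return True
        return not self.excluded_disruption_only


def compute_trial_metrics(fixations: Sequence[Fixation], trial: TrialRecord,
                          layout: AOILayout, participant_id: str = "",
                          trial_id: str = "", age_days: int = 0,
                          denominator_excludes_visible: bool = False) -> TrialMetrics:
    """Assemble all per-trial scores from detected fixations and the trial record."""
    condition = trial.stimulus.condition
    windows = trial.schedule.windows()
    m = TrialMetrics(
        participant_id=participant_id,
        trial_id=trial_id,
        condition=condition,
        age_days=age_days,
        t_stop_ms=trial.schedule.t_stop,
        end_reason=trial.end_reason,
        uncovered_fraction=trial.uncovered_fraction,
    )
    for phase in PHASES:
        t_obj, t_non = looking_times(fixations, layout, condition, windows[phase])
        setattr(m, f"look_obj_{phase}_ms", t_obj)
        setattr(m, f"look_nonobj_{phase}_ms", t_non)
        setattr(m, f"dls_{phase}", _dls(t_obj, t_non))
    m.dls_contingent_first_half, m.dls_contingent_second_half = split_half_contingent(
        fixations, layout, condition, trial.schedule
    )
    m.dls_disruption_exploratory = exploratory_dls(
        fixations, layout, condition, trial,
        denominator_excludes_visible=denominator_excludes_visible,
    )
    m.n_fixations_disruption = sum(
        1 for f in fixations if f.overlap_ms(windows["disruption"]) > 0
    )
    return m


def apply_trial_exclusions(metrics: TrialMetrics, trial: TrialRecord | None = None,
                           min_baseline_look_ms: float = 1000.0,
                           min_contingent_look_ms: float = 10000.0,
                           stop_fraction: float = 0.20) -> TrialMetrics:
    """Apply the preregistered trial-level exclusion rules in place.

    * baseline on-screen looking < 1 s -> the whole trial is excluded;
    * the contingent (and hence disruption) phase is kept only for engaged
      trials: contingent looking >= 10 s *or* the stop fraction was reached;
    * the disruption phase additionally requires at least one fixation.

    Idempotent: reasons are recomputed from the stored looking times, so
    re-application leaves the flags unchanged.
    """
    reasons = []
    end_reason = trial.end_reason if trial is not None else metrics.end_reason
    reached = end_reason == "fraction_reached"

    metrics.excluded_baseline = metrics.look_total_ms("baseline") < min_baseline_look_ms
    if metrics.excluded_baseline:
        reasons.append("baseline_looking_below_1s")

    engaged = metrics.look_total_ms("contingent") >= min_contingent_look_ms or reached
    metrics.excluded_contingent_disruption = not engaged
    if not engaged:
        reasons.append("contingent_disengaged")

    metrics.excluded_disruption_only = metrics.n_fixations_disruption == 0
    if metrics.excluded_disruption_only:
        reasons.append("no_disruption_fixation")

    metrics.exclusion_reasons = ";".join(reasons)
    return metrics


@dataclass
class SubjectSummary:
    """Condition-wise and pooled subject-level DLS means."""

    participant_id: str
    age_days: int
    n_valid_trials_drop: int
    n_valid_trials_rise: int
    included: bool
    #: subject-level value per score: unweighted mean of the two condition means
    dls: dict[str, float] = field(default_factory=dict)
    dls_by_condition: dict[str, dict[str, float]] = field(default_factory=dict)


_SCORES = (
    "dls_baseline",
    "dls_contingent",
    "dls_disruption",
    "dls_contingent_first_half",
    "dls_contingent_second_half",
    "dls_disruption_exploratory",
)

_SCORE_PHASE = {
    "dls_baseline": "baseline",
    "dls_contingent": "contingent",
    "dls_contingent_first_half": "contingent",
    "dls_contingent_second_half": "contingent",
    "dls_disruption": "disruption",
    "dls_disruption_exploratory": "disruption",
}


def aggregate_subjects(metrics: Iterable[TrialMetrics],
                       min_trials_per_condition: int = 2) -> list[SubjectSummary]:
    """Average trial DLS per condition and subject; pool as mean of condition means.

    A trial enters a score's condition mean only when it is valid for that
    score's phase (exclusion flags) and the score is defined.  Undefined
    trials drop out rather than contributing zero.  A subject is included
    when each condition retains at least ``min_trials_per_condition``
    contributed trials (trials surviving the whole-trial baseline rule).
    """
    by_subject: dict[str, list[TrialMetrics]] = {}
    for m in metrics:
        by_subject.setdefault(m.participant_id, []).append(m)

    out: list[SubjectSummary] = []
    for pid in sorted(by_subject):
        trials = by_subject[pid]
        contributed = {
            cond: sum(1 for m in trials
                      if m.condition == cond and not m.excluded_baseline)
            for cond in ("drop", "rise")
        }
        summary = SubjectSummary(
            participant_id=pid,
            age_days=trials[0].age_days,
            n_valid_trials_drop=contributed["drop"],
            n_valid_trials_rise=contributed["rise"],
            included=all(v >= min_trials_per_condition for v in contributed.values()),
        )
        for score in _SCORES:
            phase = _SCORE_PHASE[score]
            cond_means = {}
            for cond in ("drop", "rise"):
                vals = [
                    getattr(m, score) for m in trials
                    if m.condition == cond and m.phase_valid(phase)
                    and not math.isnan(getattr(m, score))
                ]
                cond_means[cond] = float(np.mean(vals)) if vals else math.nan
            summary.dls_by_condition[score] = cond_means
            defined = [v for v in cond_means.values() if not math.isnan(v)]
            summary.dls[score] = float(np.mean(defined)) if defined else math.nan
        out.append(summary)
    return out


# ---------------------------------------------------------------------------
# tabular views


def trial_metrics_frame(metrics: Sequence[TrialMetrics]) -> pd.DataFrame:
    """Long-format table, one row per trial x phase."""
    rows = []
    for m in metrics:
        base = {
            "participant_id": m.participant_id,
            "trial_id": m.trial_id,
            "condition": m.condition,
            "age_days": m.age_days,
            "t_stop_ms": m.t_stop_ms,
            "end_reason": m.end_reason,
            "uncovered_fraction": m.uncovered_fraction,
            "exclusion_reasons": m.exclusion_reasons,
        }
        for phase in PHASES:
            row = dict(base)
            row.update(
                phase=phase,
                look_obj_ms=getattr(m, f"look_obj_{phase}_ms"),
                look_nonobj_ms=getattr(m, f"look_nonobj_{phase}_ms"),
                dls=getattr(m, f"dls_{phase}"),
                dls_first_half=(m.dls_contingent_first_half
                                if phase == "contingent" else math.nan),
                dls_second_half=(m.dls_contingent_second_half
                                 if phase == "contingent" else math.nan),
                dls_exploratory=(m.dls_disruption_exploratory
                                 if phase == "disruption" else math.nan),
                phase_valid=m.phase_valid(phase),
            )
            rows.append(row)
    columns = [
        "participant_id", "trial_id", "condition", "age_days", "phase",
        "t_stop_ms", "end_reason", "uncovered_fraction", "look_obj_ms",
        "look_nonobj_ms", "dls", "dls_first_half", "dls_second_half",
        "dls_exploratory", "phase_valid", "exclusion_reasons",
    ]
    return pd.DataFrame(rows, columns=columns)


def subject_summary_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id,
            "age_days": s.age_days,
            "n_valid_trials_drop": s.n_valid_trials_drop,
            "n_valid_trials_rise": s.n_valid_trials_rise,
            "included": s.included,
        }
        for score in _SCORES:
            row[score] = s.dls[score]
        rows.append(row)
    return pd.DataFrame(rows)
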