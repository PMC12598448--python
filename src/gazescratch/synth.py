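"""Synthetic infant-like gaze data with known ground truth.

Each trial is an alternating fixation/saccade event stream sampled at the
tracker rate (120 Hz).  Every fixation targets the union of the two object
quadrants with a phase-specific probability ``p`` and the complementary
quadrants otherwise; the target point is uniform within the chosen region
(inset by a small margin so positional jitter cannot flip its quadrant),
and samples are jittered around it.  During the nominal contingent window
``p`` ramps linearly from a start to an end value, emulating within-trial
learning of the contingency; an age slope shifts the disruption-phase bias,
emulating the developmental effect.  Tracker loss is modeled as i.i.d.
invalid samples.

Under this model the expected differential looking score of a phase with
constant bias ``p`` is exactly ``2p - 1`` (fixation durations are i.i.d.
and independent of the target), which is what the parameter-recovery tests
exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import Rect
from .io import GazeRecording, GazeSample
from .stimuli import AOILayout, StimulusSpec, build_aoi_layout, generate_stimulus_set

__all__ = ["SynthParams", "synth_trial", "synth_cohort"]


@dataclass(frozen=True)
class SynthParams:
    """Ground-truth generative parameters of the synthetic cohort.

    The object-bias probabilities are the chance that a newly started
    fixation targets an object quadrant, per phase; the contingent phase
    ramps linearly from start to end.  ``age_slope`` shifts the disruption
    bias per day of age relative to the cohort's reference age.
    """

    p_obj_baseline: float = 0.64
    p_obj_contingent_start: float = 0.55
    p_obj_contingent_end: float = 0.65
    p_obj_disruption: float = 0.60
    fixation_median_ms: float = 300.0
    fixation_sigma: float = 0.5
    saccade_gap_ms: float = 50.0
    missing_rate: float = 0.10
    sample_rate_hz: float = 120.0
    age_slope: float = 0.0
    age_ref_days: float = 250.0
    jitter_px: float = 5.0
    #: margin (px) keeping fixation targets away from AOI borders
    target_margin_px: float = 6.0

    def __post_init__(self) -> None:
        for name in ("p_obj_baseline", "p_obj_contingent_start",
                     "p_obj_contingent_end", "p_obj_disruption", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.p_obj_contingent_end < self.p_obj_contingent_start:
            raise ValueError("contingent ramp must be non-decreasing "
                             "(p_obj_contingent_end >= p_obj_contingent_start)")

    def constant(self, p: float) -> "SynthParams":
        """Copy with every phase bias fixed to ``p`` (for calibration runs)."""
        return replace(self, p_obj_baseline=p, p_obj_contingent_start=p,
                       p_obj_contingent_end=p, p_obj_disruption=p, age_slope=0.0)


def _phase_p(t_ms: float, params: SynthParams, p_disruption: float,
             baseline_ms: float, transition_ms: float,
             contingent_cap_ms: float) -> float:
    """Object-bias probability for a fixation starting at ``t_ms`` (nominal phases)."""
    c0 = baseline_ms + transition_ms
    c1 = c0 + contingent_cap_ms
    if t_ms < c0:
        return params.p_obj_baseline
    if t_ms < c1:
        frac = (t_ms - c0) / contingent_cap_ms
        return (params.p_obj_contingent_start
                + frac * (params.p_obj_contingent_end - params.p_obj_contingent_start))
    return p_disruption


def _sample_point(rects: tuple[Rect, ...], margin: float,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Uniform point within a union of rectangles, inset by ``margin``."""
    areas = np.array([max(r.width - 2 * margin, 1e-9) * max(r.height - 2 * margin, 1e-9)
                      for r in rects])
    r = rects[rng.choice(len(rects), p=areas / areas.sum())]
    x = rng.uniform(r.x0 + margin, r.x1 - margin)
    y = rng.uniform(r.y0 + margin, r.y1 - margin)
    return x, y


def synth_trial(stimulus: StimulusSpec, params: SynthParams,
                rng: np.random.Generator,
                layout: AOILayout | None = None,
                age_days: float | None = None,
                baseline_ms: float = 5000.0, transition_ms: float = 3000.0,
                contingent_cap_ms: float = 30000.0, disruption_ms: float = 5000.0,
                participant_id: str = "synth", trial_id: str = "t1") -> GazeRecording:
    """Generate one full-length trial trace (baseline through disruption cap).

    The trace covers the *nominal* maximal trial (default 43 s); the
    contingent-phase learning ramp runs over the nominal 30-s window.  The
    gaze-contingent simulator later decides the realized stop time.
    Deterministic given ``rng`` state.
    """
    if layout is None:
        layout = build_aoi_layout(1920, 1080, 0.5572, stimulus.condition)
    p_dis = params.p_obj_disruption
    if age_days is not None and params.age_slope != 0.0:
        p_dis = float(np.clip(
            p_dis + params.age_slope * (age_days - params.age_ref_days), 0.0, 1.0))

    total_ms = baseline_ms + transition_ms + contingent_cap_ms + disruption_ms
    dt = 1000.0 / params.sample_rate_hz
    times = np.arange(0.0, total_ms + 0.5 * dt, dt)
    n = len(times)
    xs = np.empty(n)
    ys = np.empty(n)

    obj = layout.object_aois(stimulus.condition)
    non = layout.nonobject_aois(stimulus.condition)
    mu_log = math.log(params.fixation_median_ms)

    # first pass: alternating fixation / saccade events covering the trace
    events = []  # (fix_start, fix_end, target)
    t = 0.0
    while t < total_ms:
        p = _phase_p(t, params, p_dis, baseline_ms, transition_ms, contingent_cap_ms)
        region = obj if rng.random() < p else non
        target = _sample_point(region, params.target_margin_px, rng)
        dur = float(rng.lognormal(mu_log, params.fixation_sigma))
        events.append((t, t + dur, target))
        t += dur + params.saccade_gap_ms

    # second pass: fill samples; saccade samples glide linearly between the
    # surrounding fixation targets
    i = 0
    for k, (start, end, target) in enumerate(events):
        while i < n and times[i] < end:
            xs[i], ys[i] = target
            i += 1
        nxt = events[k + 1][2] if k + 1 < len(events) else target
        sac_end = end + params.saccade_gap_ms
        while i < n and times[i] < sac_end:
            frac = (times[i] - end) / params.saccade_gap_ms
            xs[i] = target[0] + frac * (nxt[0] - target[0])
            ys[i] = target[1] + frac * (nxt[1] - target[1])
            i += 1
    while i < n:  # trailing samples hold the last target
        xs[i], ys[i] = events[-1][2]
        i += 1

    # jitter and validity
    jitter = rng.normal(0.0, params.jitter_px / 2.0, size=(n, 2))
    jitter = np.clip(jitter, -params.jitter_px, params.jitter_px)
    xs = np.clip(xs + jitter[:, 0], 0.0, layout.screen_w - 1e-6)
    ys = np.clip(ys + jitter[:, 1], 0.0, layout.screen_h - 1e-6)
    valid = rng.random(n) >= params.missing_rate

    samples = [GazeSample(float(times[k]), float(xs[k]), float(ys[k]), bool(valid[k]))
               for k in range(n)]
    return GazeRecording(
        participant_id=participant_id, trial_id=trial_id,
        age_days=int(age_days if age_days is not None else params.age_ref_days),
        samples=samples,
    )


def synth_cohort(n_subjects: int, trials_per_subject: int,
                 age_range_days: tuple[int, int], params: SynthParams, seed: int,
                 screen_w: float = 1920, screen_h: float = 1080,
                 object_area_fraction: float = 0.5572,
                 n_pairs: int = 16) -> tuple[list[tuple[GazeRecording, StimulusSpec]], pd.DataFrame]:
    """Generate a cohort of recordings with its ground-truth table.

    Subject ages are uniform over ``age_range_days``; each subject sees one
    counterbalanced stimulus set (alternating drop/rise), subjects
    alternating between sets A and B.  Returns ``(recording, stimulus)``
    pairs plus a per-trial ground-truth DataFrame of the biases used.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    specs = generate_stimulus_set(
        n_pairs, n_pairs, rng_seed=seed, screen_w=screen_w, screen_h=screen_h,
        object_area_fraction=object_area_fraction,
    )
    from .stimuli import presentation_order

    layouts = {c: build_aoi_layout(screen_w, screen_h, object_area_fraction, c)
               for c in ("drop", "rise")}
    age_ref = 0.5 * (age_range_days[0] + age_range_days[1])
    params = replace(params, age_ref_days=age_ref)

    data: list[tuple[GazeRecording, StimulusSpec]] = []
    truth_rows = []
    for s in range(n_subjects):
        pid = f"s{s + 1:03d}"
        age = int(rng.integers(age_range_days[0], age_range_days[1] + 1))
        ordered = presentation_order(specs, "A" if s % 2 == 0 else "B")
        for trial_idx in range(trials_per_subject):
            spec = ordered[trial_idx % len(ordered)]
            tid = f"{pid}_tr{trial_idx + 1:02d}"
            rec = synth_trial(
                spec, params, rng, layout=layouts[spec.condition],
                age_days=age, participant_id=pid, trial_id=tid,
            )
            data.append((rec, spec))
            p_dis = float(np.clip(
                params.p_obj_disruption
                + params.age_slope * (age - params.age_ref_days), 0.0, 1.0))
            truth_rows.append({
                "participant_id": pid, "trial_id": tid, "age_days": age,
                "condition": spec.condition,
                "p_obj_baseline": params.p_obj_baseline,
                "p_obj_contingent_start": params.p_obj_contingent_start,
                "p_obj_contingent_end": params.p_obj_contingent_end,
                "p_obj_disruption": p_dis,
            })
    return data, pd.DataFrame(truth_rows)
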