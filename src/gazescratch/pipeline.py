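"""End-to-end orchestration: data -> trials -> fixations -> scores -> stats.

:func:`run_pipeline` executes the full analysis on either a synthetic
cohort or an external gaze CSV directory, writes every intermediate table,
and returns a :class:`RunReport` mirroring the analysis outputs: per-phase
group differential looking scores, directed Bayes factors with their
evidence categories, the split-half learning comparison, the exploratory
disruption score, age correlations, and the exclusion accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes
from .config import RunConfig
from .errors import FormatError
from .io import read_gaze_table, write_gaze_table, write_metrics_table
from .metrics import (aggregate_subjects, apply_trial_exclusions,
                      compute_trial_metrics, subject_summary_frame)
from .fixations import detect_fixations
from .simulator import simulate_trial
from .stimuli import build_aoi_layout, generate_stimulus_set
from .synth import SynthParams, synth_cohort

__all__ = ["RunReport", "run_pipeline", "make_synth_params"]

logger = logging.getLogger("gazescratch")

_SCORE_LABELS = {
    "dls_baseline": "baseline DLS",
    "dls_contingent": "contingent DLS",
    "dls_disruption": "disruption DLS",
    "dls_disruption_exploratory": "exploratory disruption DLS",
}


@dataclass
class RunReport:
    """Structured summary of one pipeline run."""

    table_paths: dict = field(default_factory=dict)
    #: per score: {mean, sd, se, n}
    group_dls: dict = field(default_factory=dict)
    #: per score: {bf10, evidence, rhat, method}
    bf_results: dict = field(default_factory=dict)
    split_half: dict = field(default_factory=dict)
    phase_comparisons: dict = field(default_factory=dict)
    age_correlations: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)

    def to_text(self) -> str:
        lines = ["gaze-scratch pipeline report", "=" * 32]
        ex = self.exclusions
        lines.append(
            f"trials recorded {ex.get('trials_recorded')}, excluded "
            f"{ex.get('trials_excluded')} (rate {ex.get('exclusion_rate', float('nan')):.2f}); "
            f"subjects recorded {ex.get('subjects_recorded')}, retained "
            f"{ex.get('subjects_included')}"
        )
        lines.append("")
        lines.append("group differential looking scores (included subjects):")
        for score, s in self.group_dls.items():
            label = _SCORE_LABELS.get(score, score)
            lines.append(
                f"  {label:32s} M = {s['mean']: .3f}  SD = {s['sd']:.3f}  "
                f"SE = {s['se']:.3f}  n = {s['n']}"
            )
        lines.append("")
        lines.append("Bayes factors (directed, DLS > 0):")
        for score, b in self.bf_results.items():
            label = _SCORE_LABELS.get(score, score)
            rhat = f", rhat = {b['rhat']:.3f}" if b.get("rhat") else ""
            lines.append(
                f"  {label:32s} BF10 = {b['bf10']:.3f}{rhat}  [{b['evidence']}]"
            )
        if self.split_half:
            sh = self.split_half
            lines.append("")
            lines.append(
                "split-half contingent (second > first): "
                f"M_first = {sh['mean_first']:.3f}, M_second = {sh['mean_second']:.3f}, "
                f"BF10 = {sh['bf10']:.3f} [{sh['evidence']}]"
            )
        if self.phase_comparisons:
            lines.append("")
            lines.append("paired phase comparisons (two-sided):")
            for name, b in self.phase_comparisons.items():
                lines.append(f"  {name:32s} BF10 = {b['bf10']:.3f} [{b['evidence']}]")
        if self.age_correlations:
            lines.append("")
            lines.append("age correlations (Kendall tau-b, directed positive):")
            for phase, c in self.age_correlations.items():
                lines.append(
                    f"  {phase:12s} tau = {c['tau']: .3f}  BF10 = {c['bf10']:.3f} "
                    f"[{c['evidence']}]"
                )
        return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def make_synth_params(config: RunConfig) -> SynthParams:
    return SynthParams(
        p_obj_baseline=config.p_obj_baseline,
        p_obj_contingent_start=config.p_obj_contingent_start,
        p_obj_contingent_end=config.p_obj_contingent_end,
        p_obj_disruption=config.p_obj_disruption,
        fixation_median_ms=config.fixation_median_ms,
        fixation_sigma=config.fixation_sigma,
        saccade_gap_ms=config.saccade_gap_ms,
        missing_rate=config.missing_rate,
        sample_rate_hz=config.sample_rate_hz,
        age_slope=config.age_slope,
        jitter_px=config.jitter_px,
    )


def _load_csv_dataset(config: RunConfig):
    """External mode: gaze.csv + stimuli.csv in ``config.data_dir``."""
    data_dir = Path(config.data_dir)
    recordings = read_gaze_table(data_dir / "gaze.csv")
    stim_df = pd.read_csv(data_dir / "stimuli.csv", dtype={"trial_id": str})
    if "trial_id" not in stim_df.columns or "condition" not in stim_df.columns:
        raise FormatError("stimuli.csv must carry trial_id and condition columns")
    cond_of = dict(zip(stim_df["trial_id"], stim_df["condition"]))
    specs = generate_stimulus_set(
        config.n_pairs, config.n_backgrounds, rng_seed=config.seed,
        screen_w=config.screen_w, screen_h=config.screen_h,
        object_area_fraction=config.object_area_fraction,
        object_box_frac=config.object_box_frac,
    )
    spec_by_cond = {}
    for s in specs:
        spec_by_cond.setdefault(s.condition, s)
    pairs = []
    for rec in recordings:
        if rec.trial_id not in cond_of:
            raise FormatError(f"stimuli.csv lacks a row for trial {rec.trial_id!r}")
        pairs.append((rec, spec_by_cond[cond_of[rec.trial_id]]))
    return pairs


def _one_sample_test(values: np.ndarray, config: RunConfig, seed: int,
                     direction: str = "greater") -> bayes.BayesResult:
    if config.bf_method == "rank":
        return bayes.rank_bf_one_sample(
            values, direction=direction, prior_scale=config.prior_scale,
            n_chains=config.mcmc_chains, n_iter=config.mcmc_iter,
            burnin=config.mcmc_burnin, seed=seed,
            rhat_threshold=config.rhat_threshold,
        )
    return bayes.jzs_bf_one_sample(values, direction=direction,
                                   prior_scale=config.prior_scale)


def _bf_dict(result: bayes.BayesResult) -> dict:
    return {
        "bf10": result.bf10,
        "evidence": result.evidence,
        "method": result.method,
        "rhat": result.rhat,
        "converged": result.converged,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Run every stage in order and return the assembled report.

    Stage order: data acquisition -> trial simulation -> fixation detection
    -> trial metrics -> exclusions -> subject aggregation -> Bayesian stats.
    With ``out_dir`` set, all intermediate tables plus the report (JSON and
    text) are written there; re-running with the same config and seed
    reproduces them byte for byte.
    """
    report = RunReport(seed=config.seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    # --- stage 1: data -----------------------------------------------------
    if config.data_source == "synthetic":
        params = make_synth_params(config)
        dataset, truth = synth_cohort(
            config.n_subjects, config.trials_per_subject,
            (config.age_min_days, config.age_max_days), params, config.seed,
            screen_w=config.screen_w, screen_h=config.screen_h,
            object_area_fraction=config.object_area_fraction,
            n_pairs=config.n_pairs,
        )
        if out_path is not None:
            truth.to_csv(out_path / "ground_truth.csv", index=False)
    elif config.data_source == "csv":
        dataset = _load_csv_dataset(config)
    else:
        raise ValueError(f"unknown data_source {config.data_source!r}")
    logger.info("stage data: %d recordings", len(dataset))

    layouts = {c: build_aoi_layout(config.screen_w, config.screen_h,
                                   config.object_area_fraction, c)
               for c in ("drop", "rise")}

    # --- stages 2-5: per-trial simulation, fixations, metrics, exclusions --
    all_metrics = []
    for rec, spec in dataset:
        trial = simulate_trial(
            rec, spec, square_px=config.cover_square_px,
            stop_fraction=config.stop_fraction,
            contingent_cap_ms=config.contingent_cap_ms,
            baseline_ms=config.baseline_ms, transition_ms=config.transition_ms,
            disruption_ms=config.disruption_ms,
            screen_w=config.screen_w, screen_h=config.screen_h,
            uncover_radius_cells=config.uncover_radius_cells,
        )
        fixations = detect_fixations(
            rec.samples, max_dispersion_px=config.max_dispersion_px,
            min_duration_ms=config.min_fixation_ms,
            max_gap_samples=config.max_gap_samples,
        )
        m = compute_trial_metrics(
            fixations, trial, layouts[spec.condition],
            participant_id=rec.participant_id, trial_id=rec.trial_id,
            age_days=rec.age_days,
            denominator_excludes_visible=config.exploratory_denominator_excludes_visible,
        )
        apply_trial_exclusions(
            m, trial, min_baseline_look_ms=config.min_baseline_look_ms,
            min_contingent_look_ms=config.min_contingent_look_ms,
            stop_fraction=config.stop_fraction,
        )
        all_metrics.append(m)
    logger.info("stage metrics: %d trials scored", len(all_metrics))

    # --- stage 6: aggregation ---------------------------------------------
    summaries = aggregate_subjects(
        all_metrics, min_trials_per_condition=config.min_trials_per_condition)
    included = [s for s in summaries if s.included]
    logger.info("stage aggregate: %d subjects, %d included",
                len(summaries), len(included))

    n_trials = len(all_metrics)
    n_excluded = sum(
        1 for m in all_metrics
        if m.excluded_baseline or m.excluded_contingent_disruption
        or m.excluded_disruption_only
    )
    report.exclusions = {
        "trials_recorded": n_trials,
        "trials_excluded": n_excluded,
        "exclusion_rate": n_excluded / n_trials if n_trials else math.nan,
        "trials_excluded_baseline": sum(1 for m in all_metrics if m.excluded_baseline),
        "trials_excluded_contingent": sum(
            1 for m in all_metrics if m.excluded_contingent_disruption),
        "trials_excluded_disruption_only": sum(
            1 for m in all_metrics if m.excluded_disruption_only),
        "subjects_recorded": len(summaries),
        "subjects_included": len(included),
    }

    # --- stage 7: statistics ----------------------------------------------
    def subject_values(score: str) -> np.ndarray:
        vals = [s.dls[score] for s in included if not math.isnan(s.dls[score])]
        return np.asarray(vals)

    seed_counter = config.seed
    for score in ("dls_baseline", "dls_contingent", "dls_disruption",
                  "dls_disruption_exploratory"):
        vals = subject_values(score)
        if len(vals) < 5:
            continue
        report.group_dls[score] = {
            "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)),
            "se": float(np.std(vals, ddof=1) / math.sqrt(len(vals))),
            "n": len(vals),
        }
        seed_counter += 1
        report.bf_results[score] = _bf_dict(
            _one_sample_test(vals, config, seed_counter))

    both = [
        (s.dls["dls_contingent_first_half"], s.dls["dls_contingent_second_half"])
        for s in included
        if not math.isnan(s.dls["dls_contingent_first_half"])
        and not math.isnan(s.dls["dls_contingent_second_half"])
    ]
    if len(both) >= 5:
        diffs = np.array([b - a for a, b in both])
        seed_counter += 1
        res = _one_sample_test(diffs, config, seed_counter, direction="greater")
        report.split_half = {
            "mean_first": float(np.mean([a for a, _ in both])),
            "mean_second": float(np.mean([b for _, b in both])),
            "n": len(both),
            **_bf_dict(res),
        }

    # post-hoc paired comparisons between phases (parametric default prior)
    for name, a_score, b_score in (
        ("baseline_vs_contingent", "dls_baseline", "dls_contingent"),
        ("contingent_vs_disruption", "dls_contingent", "dls_disruption"),
        ("baseline_vs_disruption", "dls_baseline", "dls_disruption"),
    ):
        pairs = [
            (s.dls[a_score], s.dls[b_score]) for s in included
            if not math.isnan(s.dls[a_score]) and not math.isnan(s.dls[b_score])
        ]
        if len(pairs) < 5:
            continue
        diffs = np.array([a - b for a, b in pairs])
        if np.std(diffs) == 0:
            continue
        res = bayes.jzs_bf_one_sample(diffs, direction="two_sided",
                                      prior_scale=config.prior_scale)
        report.phase_comparisons[name] = _bf_dict(res)

    # age correlations per phase
    for phase, score in (("baseline", "dls_baseline"),
                         ("contingent", "dls_contingent"),
                         ("disruption", "dls_disruption")):
        pairs = [(s.age_days, s.dls[score]) for s in included
                 if not math.isnan(s.dls[score])]
        if len(pairs) < 5:
            continue
        ages = np.array([p[0] for p in pairs], dtype=float)
        vals = np.array([p[1] for p in pairs])
        res = bayes.kendall_tau_bf(ages, vals,
                                   prior_width=config.kendall_prior_width,
                                   direction="greater")
        report.age_correlations[phase] = {"tau": res.extra["tau"], **_bf_dict(res)}

    # --- outputs -----------------------------------------------------------
    if out_path is not None:
        write_metrics_table(all_metrics, out_path / "trial_metrics.csv")
        subject_summary_frame(summaries).to_csv(
            out_path / "subject_summaries.csv", index=False, na_rep="NA")
        if config.data_source == "synthetic":
            write_gaze_table([rec for rec, _ in dataset], out_path / "gaze.csv")
        (out_path / "report.json").write_text(report.to_json(), encoding="utf-8")
        (out_path / "report.txt").write_text(report.to_text(), encoding="utf-8")
        report.table_paths = {
            "trial_metrics": str(out_path / "trial_metrics.csv"),
            "subject_summaries": str(out_path / "subject_summaries.csv"),
            "report_json": str(out_path / "report.json"),
            "report_text": str(out_path / "report.txt"),
        }
    logger.info("stage stats: %d scores tested", len(report.bf_results))
    return report
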