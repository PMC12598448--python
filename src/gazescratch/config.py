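"""Flat run configuration shared by every pipeline stage.

A :class:`RunConfig` holds every tunable of the paradigm simulation and the
analysis with its default value.  Configurations are loaded from a YAML
mapping of ``key: value`` pairs; unknown keys are rejected with a
nearest-match suggestion so that typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # --- screen & AOI geometry -------------------------------------------
    screen_w: int = 1920
    screen_h: int = 1080
    #: fraction of screen area covered by the two object-containing quadrants
    object_area_fraction: float = 0.5572
    #: side of the object boxes as a fraction of screen height
    object_box_frac: float = 0.15

    # --- trial phase schedule (ms) ---------------------------------------
    baseline_ms: float = 5000.0
    transition_ms: float = 3000.0
    contingent_cap_ms: float = 30000.0
    disruption_ms: float = 5000.0

    # --- gaze-contingent cover -------------------------------------------
    cover_square_px: int = 25
    stop_fraction: float = 0.20
    uncover_radius_cells: int = 0

    # --- sampling & fixation detection -----------------------------------
    sample_rate_hz: float = 120.0
    max_dispersion_px: float = 25.0
    min_fixation_ms: float = 200.0
    max_gap_samples: int = 2

    # --- preregistered exclusion rules -----------------------------------
    min_baseline_look_ms: float = 1000.0
    min_contingent_look_ms: float = 10000.0
    min_trials_per_condition: int = 2

    # --- exploratory disruption DLS --------------------------------------
    #: when True the visible-object fixation time is also removed from the
    #: denominator of the exploratory DLS (default keeps it, see docs)
    exploratory_denominator_excludes_visible: bool = False

    # --- Bayesian layer ---------------------------------------------------
    prior_scale: float = 0.707
    kendall_prior_width: float = 1.0
    bf_upper: float = 3.0
    bf_lower: float = 1.0 / 3.0
    n_min: int = 30
    mcmc_chains: int = 2
    mcmc_iter: int = 5000
    mcmc_burnin: int = 1000
    rhat_threshold: float = 1.1
    #: "rank" (latent-normal Wilcoxon analogue) or "jzs" (parametric t)
    bf_method: str = "rank"

    # --- stimulus set ------------------------------------------------------
    n_pairs: int = 16
    n_backgrounds: int = 16

    # --- synthetic cohort --------------------------------------------------
    n_subjects: int = 45
    trials_per_subject: int = 16
    age_min_days: int = 180
    age_max_days: int = 320
    p_obj_baseline: float = 0.64
    p_obj_contingent_start: float = 0.55
    p_obj_contingent_end: float = 0.65
    p_obj_disruption: float = 0.60
    age_slope: float = 0.0008
    fixation_median_ms: float = 300.0
    fixation_sigma: float = 0.5
    saccade_gap_ms: float = 50.0
    missing_rate: float = 0.10
    jitter_px: float = 5.0

    # --- orchestration ------------------------------------------------------
    seed: int = 0
    data_source: str = "synthetic"  # or "csv"
    data_dir: str = ""

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _coerce(key: str, value):
    """Check/convert a YAML value against the declared field type."""
    ftype = _FIELDS[key].type
    # dataclass field types are stored as strings under __future__ annotations
    tname = ftype if isinstance(ftype, str) else getattr(ftype, "__name__", str(ftype))
    if tname == "bool":
        if not isinstance(value, bool):
            raise ConfigError(f"config key {key!r} expects a boolean, got {value!r}")
        return value
    if tname == "int":
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"config key {key!r} expects an integer, got {value!r}")
        return value
    if tname == "float":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"config key {key!r} expects a number, got {value!r}")
        return float(value)
    if tname == "str":
        if not isinstance(value, str):
            raise ConfigError(f"config key {key!r} expects a string, got {value!r}")
        return value
    raise ConfigError(f"unsupported config field type for {key!r}")  # pragma: no cover


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file, applying ``overrides`` last.

    An empty or absent file yields all defaults.  Unknown keys raise
    :class:`~gazescratch.errors.ConfigError` naming the nearest valid key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a key/value mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)

    values = {}
    for key, value in data.items():
        if key not in _FIELDS:
            hint = difflib.get_close_matches(str(key), _FIELDS.keys(), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suggestion}")
        values[key] = _coerce(key, value)
    return RunConfig(**values)
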