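"""Shared fixtures: layouts, stimulus specs, and recording builders."""

from __future__ import annotations

import numpy as np
import pytest

from gazescratch.io import GazeRecording, GazeSample
from gazescratch.stimuli import build_aoi_layout, generate_stimulus_set

SCREEN_W, SCREEN_H = 1920, 1080
DT = 1000.0 / 120.0


@pytest.fixture(scope="session")
def layouts():
    return {c: build_aoi_layout(SCREEN_W, SCREEN_H, 0.5572, c)
            for c in ("drop", "rise")}


@pytest.fixture(scope="session")
def stimulus_set():
    return generate_stimulus_set(16, 16, rng_seed=123)


@pytest.fixture(scope="session")
def drop_stimulus(stimulus_set):
    return next(s for s in stimulus_set if s.condition == "drop")


def make_recording(points, dt_ms: float = DT, participant="p1", trial="t1",
                   age_days=260, t0: float = 0.0) -> GazeRecording:
    """Recording from (x, y) or (x, y, valid) tuples at a fixed sampling step."""
    samples = []
    for i, p in enumerate(points):
        if len(p) == 2:
            x, y, valid = p[0], p[1], True
        else:
            x, y, valid = p
        samples.append(GazeSample(t0 + i * dt_ms, float(x), float(y), bool(valid)))
    return GazeRecording(participant, trial, age_days, samples)


def hold_point(x, y, duration_ms, dt_ms: float = DT):
    """Sample tuples holding one point for (at least) a duration."""
    n = int(np.floor(duration_ms / dt_ms)) + 1
    return [(x, y)] * n


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
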