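"""Offline re-implementation of the gaze-contingent trial mechanics.

A trial runs through four phases: a 5-s baseline (image visible), a 3-s
transition (image being covered; gaze has no effect), a contingent phase in
which every valid on-screen gaze sample removes the cover cell it falls in,
and a 5-s disruption during which the cover freezes.  The contingent phase
ends at the first sample whose uncovering pushes the uncovered area to the
stop fraction (default 20% of the screen) or after a 30-s cap.

The cover is a grid of square cells (default 25 px); cells at the right and
bottom edges may be smaller, and the uncovered fraction is area-weighted
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Rect
from .io import GazeRecording
from .stimuli import StimulusSpec

__all__ = [
    "PhaseSchedule",
    "CoverState",
    "TrialRecord",
    "simulate_trial",
    "uncovered_fraction",
    "visible_object_region",
    "VisibleRegion",
]


@dataclass(frozen=True)
class PhaseSchedule:
    """Realized phase boundaries of one trial, in ms from trial onset."""

    baseline_ms: float = 5000.0
    transition_ms: float = 3000.0
    t_stop: float = 38000.0  #: absolute end of the contingent phase
    disruption_ms: float = 5000.0

    def __post_init__(self) -> None:
        if self.t_stop < self.contingent_start:
            raise ValueError("t_stop precedes the contingent phase start")

    @property
    def contingent_start(self) -> float:
        return self.baseline_ms + self.transition_ms

    @property
    def total_ms(self) -> float:
        return self.t_stop + self.disruption_ms

    def windows(self) -> dict[str, tuple[float, float]]:
        """Half-open phase windows keyed by phase name."""
        c0 = self.contingent_start
        return {
            "baseline": (0.0, self.baseline_ms),
            "transition": (self.baseline_ms, c0),
            "contingent": (c0, self.t_stop),
            "disruption": (self.t_stop, self.t_stop + self.disruption_ms),
        }

    def phase_of(self, t_ms: float) -> str | None:
        for name, (a, b) in self.windows().items():
            if a <= t_ms < b:
                return name
        return None


class CoverState:
    """Boolean cover grid over the screen (True = still covered)."""

    def __init__(self, screen_w: float, screen_h: float, square_px: float):
        if square_px <= 0:
            raise ValueError("square_px must be positive")
        self.screen_w = float(screen_w)
        self.screen_h = float(screen_h)
        self.square_px = float(square_px)
        self.n_cols = int(np.ceil(self.screen_w / self.square_px))
        self.n_rows = int(np.ceil(self.screen_h / self.square_px))
        self.grid = np.ones((self.n_rows, self.n_cols), dtype=bool)
        # edge cells are clipped by the screen border, hence area-weighted
        col_w = np.full(self.n_cols, self.square_px)
        col_w[-1] = self.screen_w - self.square_px * (self.n_cols - 1)
        row_h = np.full(self.n_rows, self.square_px)
        row_h[-1] = self.screen_h - self.square_px * (self.n_rows - 1)
        self.cell_areas = row_h[:, None] * col_w[None, :]
        self.total_area = self.screen_w * self.screen_h

    def copy(self) -> "CoverState":
        other = CoverState(self.screen_w, self.screen_h, self.square_px)
        other.grid = self.grid.copy()
        return other

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing an on-screen point, else None."""
        if not (0 <= x < self.screen_w and 0 <= y < self.screen_h):
            return None
        return (int(y // self.square_px), int(x // self.square_px))

    def cell_rect(self, row: int, col: int) -> Rect:
        s = self.square_px
        return Rect(
            col * s, row * s,
            min((col + 1) * s, self.screen_w), min((row + 1) * s, self.screen_h),
        )

    @property
    def uncovered_fraction(self) -> float:
        return float(self.cell_areas[~self.grid].sum() / self.total_area)


def uncovered_fraction(cover: CoverState) -> float:
    """Area-weighted fraction of the screen currently uncovered, in [0, 1]."""
    return cover.uncovered_fraction


@dataclass
class TrialRecord:
    """Simulator output for one trial."""

    stimulus: StimulusSpec
    schedule: PhaseSchedule
    cover_at_disruption: CoverState
    end_reason: str  #: "fraction_reached" | "timeout"
    uncover_events: list[tuple[float, tuple[int, int]]] = field(default_factory=list)

    @property
    def uncovered_fraction(self) -> float:
        return self.cover_at_disruption.uncovered_fraction


def simulate_trial(recording: GazeRecording, stimulus: StimulusSpec,
                   square_px: float = 25.0, stop_fraction: float = 0.20,
                   contingent_cap_ms: float = 30000.0,
                   baseline_ms: float = 5000.0, transition_ms: float = 3000.0,
                   disruption_ms: float = 5000.0,
                   screen_w: float = 1920.0, screen_h: float = 1080.0,
                   uncover_radius_cells: int = 0) -> TrialRecord:
    """Replay a gaze recording through the contingent cover mechanics.

    Samples are processed in time order.  During the contingent phase every
    valid on-screen sample clears the cell containing it (idempotently;
    ``uncover_radius_cells`` optionally clears a Chebyshev neighborhood).
    The phase ends at the timestamp of the first sample at which the
    uncovered fraction reaches ``stop_fraction``, else at the cap.  Off-screen
    samples are ignored for uncovering; an empty or all-invalid recording
    times out with fraction 0.
    """
    cover = CoverState(screen_w, screen_h, square_px)
    c0 = baseline_ms + transition_ms
    cap_t = c0 + contingent_cap_ms

    t, x, y, valid = recording.arrays() if len(recording) else (
        np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=bool))

    events: list[tuple[float, tuple[int, int]]] = []
    t_stop = cap_t
    end_reason = "timeout"

    in_phase = (t >= c0) & (t < cap_t) & valid
    on_screen = (x >= 0) & (x < screen_w) & (y >= 0) & (y < screen_h)
    idx = np.nonzero(in_phase & on_screen)[0]

    if uncover_radius_cells == 0 and len(idx):
        # vectorized fast path: first-touch cells and cumulative area
        rows = (y[idx] // square_px).astype(int)
        cols = (x[idx] // square_px).astype(int)
        flat = rows * cover.n_cols + cols
        first = np.zeros(len(flat), dtype=bool)
        seen: set[int] = set()
        for i, f in enumerate(flat):
            if f not in seen:
                seen.add(int(f))
                first[i] = True
        areas = np.where(first, cover.cell_areas[rows, cols], 0.0)
        cum = np.cumsum(areas) / cover.total_area
        reached = np.nonzero(cum >= stop_fraction)[0]
        stop_i = reached[0] if len(reached) else len(idx) - 1
        if len(reached):
            t_stop = float(t[idx[stop_i]])
            end_reason = "fraction_reached"
        take = idx[: stop_i + 1]
        for k in range(stop_i + 1):
            if first[k]:
                cell = (int(rows[k]), int(cols[k]))
                cover.grid[cell] = False
                events.append((float(t[take[k]]), cell))
    elif len(idx):
        # general path with neighborhood uncovering
        r = uncover_radius_cells
        for i in idx:
            cell = cover.cell_of(float(x[i]), float(y[i]))
            if cell is None:  # pragma: no cover - filtered above
                continue
            row, col = cell
            for rr in range(max(0, row - r), min(cover.n_rows, row + r + 1)):
                for cc in range(max(0, col - r), min(cover.n_cols, col + r + 1)):
                    if cover.grid[rr, cc]:
                        cover.grid[rr, cc] = False
                        events.append((float(t[i]), (rr, cc)))
            if cover.uncovered_fraction >= stop_fraction:
                t_stop = float(t[i])
                end_reason = "fraction_reached"
                break

    schedule = PhaseSchedule(baseline_ms, transition_ms, t_stop, disruption_ms)
    return TrialRecord(
        stimulus=stimulus,
        schedule=schedule,
        cover_at_disruption=cover,
        end_reason=end_reason,
        uncover_events=events,
    )


class VisibleRegion:
    """Uncovered parts of the object rectangles at disruption onset."""

    def __init__(self, rects: list[Rect], cover: CoverState,
                 object_rects: tuple[Rect, Rect]):
        self.rects = rects
        self._cover = cover
        self._object_rects = object_rects

    @property
    def area(self) -> float:
        return sum(r.area for r in self.rects)

    def contains(self, x: float, y: float) -> bool:
        """True when the point lies on an uncovered part of an object."""
        if not any(r.contains(x, y) for r in self._object_rects):
            return False
        cell = self._cover.cell_of(x, y)
        return cell is not None and not self._cover.grid[cell]


def visible_object_region(cover: CoverState, stimulus: StimulusSpec) -> VisibleRegion:
    """Intersection of the uncovered cells with the object rectangles.

    Empty for a fresh cover; equals the full object area once everything is
    uncovered.
    """
    pieces: list[Rect] = []
    rows, cols = np.nonzero(~cover.grid)
    for row, col in zip(rows, cols):
        cell_rect = cover.cell_rect(int(row), int(col))
        for obj in stimulus.object_rects:
            inter = cell_rect.intersect(obj)
            if inter is not None:
                pieces.append(inter)
    return VisibleRegion(pieces, cover, stimulus.object_rects)
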