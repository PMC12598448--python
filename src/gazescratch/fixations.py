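"""Dispersion-duration (I-DT style) fixation detection.

A fixation is a maximal run of samples whose valid members all stay within a
dispersion radius (default 25 px) of the window's running centroid, lasting
strictly longer than a duration threshold (default 200 ms).  Short runs of
invalid (lost) samples are tolerated inside a window; longer ones terminate
it.  Windows are grown greedily left-to-right and never overlap.

:func:`detect_fixations_oracle` re-implements the same definition by
exhaustive window checking with from-scratch recomputation at every step; it
exists purely as an independent cross-check for the incremental detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GazeSample

__all__ = ["Fixation", "detect_fixations", "detect_fixations_oracle",
           "fixations_frame"]


@dataclass(frozen=True)
class Fixation:
    """A detected fixation: time span, centroid of member samples, size."""

    onset_ms: float
    offset_ms: float
    centroid_x: float
    centroid_y: float
    n_samples: int

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def overlap_ms(self, window: tuple[float, float]) -> float:
        """Looking time this fixation contributes inside a half-open window."""
        a, b = window
        return max(0.0, min(self.offset_ms, b) - max(self.onset_ms, a))


def detect_fixations(samples: Sequence[GazeSample],
                     max_dispersion_px: float = 25.0,
                     min_duration_ms: float = 200.0,
                     max_gap_samples: int = 2) -> list[Fixation]:
    """Greedy left-to-right dispersion-duration detection.

    A window opens at a valid sample and grows sample by sample.  A valid
    candidate joins only if, after updating the centroid, *every* valid
    member lies within ``max_dispersion_px`` (Euclidean) of it; the first
    candidate that would break the radius closes the window, with no
    backtracking.  Invalid samples are tolerated in runs of at most
    ``max_gap_samples``; a longer run closes the window at its last valid
    member.  A closed window is emitted iff its duration (offset minus
    onset) strictly exceeds ``min_duration_ms``; the search then resumes
    after it, so emitted fixations are disjoint and ordered.
    """
    n = len(samples)
    t = np.array([s.t_ms for s in samples])
    x = np.array([s.x_px for s in samples])
    y = np.array([s.y_px for s in samples])
    valid = np.array([s.valid for s in samples], dtype=bool)

    r2 = max_dispersion_px**2
    # reusable member buffers; m counts current valid members
    bufx = np.empty(n)
    bufy = np.empty(n)

    out: list[Fixation] = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        # grow the window starting at valid sample i
        bufx[0] = x[i]
        bufy[0] = y[i]
        m = 1
        sx = float(x[i])
        sy = float(y[i])
        last_valid = i
        gap = 0
        j = i + 1
        while j < n:
            if not valid[j]:
                gap += 1
                if gap > max_gap_samples:
                    break
                j += 1
                continue
            # candidate centroid (left-fold sums, matching the oracle's sum())
            csx = sx + float(x[j])
            csy = sy + float(y[j])
            cx = csx / (m + 1)
            cy = csy / (m + 1)
            dx = bufx[:m] - cx
            dy = bufy[:m] - cy
            if (x[j] - cx) ** 2 + (y[j] - cy) ** 2 > r2 or np.max(dx * dx + dy * dy) > r2:
                break
            bufx[m] = x[j]
            bufy[m] = y[j]
            m += 1
            sx, sy = csx, csy
            last_valid = j
            gap = 0
            j += 1

        duration = t[last_valid] - t[i]
        if duration > min_duration_ms:
            out.append(
                Fixation(
                    onset_ms=float(t[i]),
                    offset_ms=float(t[last_valid]),
                    centroid_x=sx / m,
                    centroid_y=sy / m,
                    n_samples=m,
                )
            )
            i = last_valid + 1
        else:
            i += 1
    return out


def detect_fixations_oracle(samples: Sequence[GazeSample],
                            max_dispersion_px: float = 25.0,
                            min_duration_ms: float = 200.0,
                            max_gap_samples: int = 2) -> list[Fixation]:
    """Brute-force reference detector (pure Python, full recomputation).

    For every candidate start it re-derives the maximal coherent window by
    checking, at each prospective end, the dispersion predicate over all
    members with freshly recomputed means, then greedily selects
    non-overlapping qualifying windows left-to-right.  Deliberately O(n^3)
    and free of incremental state.
    """
    seq = list(samples)
    n = len(seq)

    def coherent_extension(start: int) -> tuple[list[int], int]:
        members = [start]
        last_valid = start
        gap = 0
        for j in range(start + 1, n):
            s = seq[j]
            if not s.valid:
                gap += 1
                if gap > max_gap_samples:
                    break
                continue
            cand = members + [j]
            cx = sum(seq[k].x_px for k in cand) / len(cand)
            cy = sum(seq[k].y_px for k in cand) / len(cand)
            ok = all(
                math.hypot(seq[k].x_px - cx, seq[k].y_px - cy) <= max_dispersion_px
                for k in cand
            )
            if not ok:
                break
            members = cand
            last_valid = j
            gap = 0
        return members, last_valid

    out: list[Fixation] = []
    i = 0
    while i < n:
        if not seq[i].valid:
            i += 1
            continue
        members, last_valid = coherent_extension(i)
        if seq[last_valid].t_ms - seq[i].t_ms > min_duration_ms:
            cx = sum(seq[k].x_px for k in members) / len(members)
            cy = sum(seq[k].y_px for k in members) / len(members)
            out.append(
                Fixation(seq[i].t_ms, seq[last_valid].t_ms, cx, cy, len(members))
            )
            i = last_valid + 1
        else:
            i += 1
    return out


def fixations_frame(fixations: Sequence[Fixation], trial_id: str = ""):
    """Fixation table (one row per fixation) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"trial_id": trial_id, "onset_ms": f.onset_ms, "offset_ms": f.offset_ms,
             "centroid_x": f.centroid_x, "centroid_y": f.centroid_y,
             "n_samples": f.n_samples}
            for f in fixations
        ],
        columns=["trial_id", "onset_ms", "offset_ms", "centroid_x", "centroid_y",
                 "n_samples"],
    )
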