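"""Counterbalanced stimulus set and AOI geometry.

The screen is tiled by four corner quadrants separated by one vertical and
one horizontal split line.  Two diagonally opposite quadrants contain the
objects: top-left/bottom-right in the *drop* condition, bottom-left/top-right
in *rise*.  The split lines sit symmetrically off-center so that the two
object quadrants jointly cover a configurable fraction of the screen
(default 55.72%); the drop and rise layouts are mirror images across the
vertical midline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Rect

__all__ = ["StimulusSpec", "AOILayout", "build_aoi_layout", "generate_stimulus_set"]

CONDITIONS = ("drop", "rise")

#: quadrant labels, keyed row-major from the top-left
QUADRANTS = ("TL", "TR", "BL", "BR")

_OBJECT_QUADRANTS = {"drop": ("TL", "BR"), "rise": ("BL", "TR")}


@dataclass(frozen=True)
class AOILayout:
    """Four corner quadrants exactly partitioning the screen.

    ``quadrants`` maps the labels TL/TR/BL/BR to half-open rectangles.  For a
    given condition, :meth:`object_aois` returns the two object-containing
    quadrants; their joint area over the screen area is
    :meth:`object_area_fraction`.
    """

    screen_w: float
    screen_h: float
    split_x: float
    split_y: float

    @property
    def quadrants(self) -> dict[str, Rect]:
        w, h, vx, hy = self.screen_w, self.screen_h, self.split_x, self.split_y
        return {
            "TL": Rect(0, 0, vx, hy),
            "TR": Rect(vx, 0, w, hy),
            "BL": Rect(0, hy, vx, h),
            "BR": Rect(vx, hy, w, h),
        }

    def object_aois(self, condition: str) -> tuple[Rect, Rect]:
        q = self.quadrants
        a, b = _OBJECT_QUADRANTS[condition]
        return (q[a], q[b])

    def nonobject_aois(self, condition: str) -> tuple[Rect, Rect]:
        q = self.quadrants
        keep = set(QUADRANTS) - set(_OBJECT_QUADRANTS[condition])
        a, b = sorted(keep)
        return (q[a], q[b])

    def object_area_fraction(self, condition: str) -> float:
        total = self.screen_w * self.screen_h
        return sum(r.area for r in self.object_aois(condition)) / total

    def quadrant_of(self, x: float, y: float) -> str | None:
        """Label of the quadrant containing (x, y), or None if off-screen."""
        for label, rect in self.quadrants.items():
            if rect.contains(x, y):
                return label
        return None


def build_aoi_layout(screen_w: float, screen_h: float,
                     object_area_fraction: float = 0.5572,
                     condition: str = "drop") -> AOILayout:
    """Construct the quadrant layout realizing a given object-area fraction.

    With split lines at ``(1/2 + a)w`` and ``(1/2 + b)h`` the two diagonal
    object quadrants cover the fraction ``1/2 + 2ab`` of the screen.  The
    offsets are taken equal in magnitude, ``|a| = |b| = sqrt(|f - 1/2| / 2)``,
    with signs chosen by condition and by whether f exceeds one half.  The
    rise layout is the mirror image of the drop layout across the vertical
    midline.
    """
    if not (0.0 < object_area_fraction < 1.0):
        raise ValueError(f"object_area_fraction must lie in (0,1), got {object_area_fraction}")
    if screen_w <= 0 or screen_h <= 0:
        raise ValueError("screen dimensions must be positive")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")

    s = object_area_fraction - 0.5
    alpha = math.sqrt(abs(s) / 2.0)
    a = alpha
    b = alpha if s >= 0 else -alpha
    # drop: objects in TL and BR; split lines pushed toward the bottom right
    split_x = (0.5 + a) * screen_w
    split_y = (0.5 + b) * screen_h
    if condition == "rise":
        split_x = screen_w - split_x
    return AOILayout(screen_w, screen_h, split_x, split_y)


@dataclass(frozen=True)
class StimulusSpec:
    """One trial image: an object pair on a background in one condition.

    ``object_rects`` are the two object bounding boxes, each lying fully
    inside one object quadrant of its condition's AOI layout.
    """

    pair_id: int
    background_id: int
    condition: str
    object_rects: tuple[Rect, Rect]
    set_id: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.object_rects[0].overlaps(self.object_rects[1]):
            raise ValueError("object rectangles overlap")


def _object_rects(layout: AOILayout, condition: str, box_frac: float) -> tuple[Rect, Rect]:
    """Square object boxes centered in each object quadrant."""
    side = box_frac * layout.screen_h
    rects = []
    for aoi in layout.object_aois(condition):
        cx, cy = aoi.center
        rect = Rect(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
        if not aoi.contains_rect(rect):
            raise ValueError(
                f"object box (side {side:.0f} px) does not fit inside its "
                f"{condition} quadrant; reduce object_box_frac"
            )
        rects.append(rect)
    return (rects[0], rects[1])


def generate_stimulus_set(n_pairs: int, n_backgrounds: int, rng_seed: int,
                          screen_w: float = 1920, screen_h: float = 1080,
                          object_area_fraction: float = 0.5572,
                          object_box_frac: float = 0.15) -> list[StimulusSpec]:
    """Generate the fully counterbalanced stimulus collection.

    Every object pair is assigned one background (a seeded random bijection,
    hence ``n_pairs == n_backgrounds``) and occurs once per condition with
    the same background, giving ``2 * n_pairs`` specs.  The collection is
    split into two presentation sets A and B of ``n_pairs`` images each with
    ``n_pairs / 2`` per condition; a pair shown in *drop* in set A appears in
    *rise* in set B and vice versa, and conditions alternate within a set's
    presentation order.  With an odd ``n_pairs`` the per-condition balance is
    impossible; the specs are still returned, with ``set_id=None`` and a
    warning.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_pairs != n_backgrounds:
        raise ValueError("n_pairs must equal n_backgrounds for a background bijection")

    rng = np.random.default_rng(rng_seed)
    backgrounds = rng.permutation(n_backgrounds) + 1

    balanced = n_pairs % 2 == 0
    if not balanced:
        warnings.warn(
            f"odd n_pairs={n_pairs}: cannot split into two condition-balanced sets; "
            "set_id left unassigned",
            stacklevel=2,
        )

    layouts = {c: build_aoi_layout(screen_w, screen_h, object_area_fraction, c)
               for c in CONDITIONS}
    rects = {c: _object_rects(layouts[c], c, object_box_frac) for c in CONDITIONS}

    specs: list[StimulusSpec] = []
    for i in range(n_pairs):
        pair_id = i + 1
        background_id = int(backgrounds[i])
        # alternating assignment: even pairs drop-in-A, odd pairs rise-in-A
        cond_a = CONDITIONS[i % 2]
        for condition in CONDITIONS:
            if balanced:
                set_id = "A" if condition == cond_a else "B"
            else:
                set_id = None
            specs.append(
                StimulusSpec(
                    pair_id=pair_id,
                    background_id=background_id,
                    condition=condition,
                    object_rects=rects[condition],
                    set_id=set_id,
                )
            )
    return specs


def presentation_order(specs: list[StimulusSpec], set_id: str) -> list[StimulusSpec]:
    """Specs of one set in presentation order (conditions alternating)."""
    chosen = [s for s in specs if s.set_id == set_id]
    if not chosen:
        raise ValueError(f"no specs in set {set_id!r} (odd n_pairs leaves sets unassigned)")
    return sorted(chosen, key=lambda s: s.pair_id)
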