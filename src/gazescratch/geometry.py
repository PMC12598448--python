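"""Axis-aligned rectangle primitives used for AOIs, object boxes and cover cells.

All rectangles are half-open, ``[x0, x1) x [y0, y1)``, in screen pixel
coordinates (origin top-left, y increasing downward).  Half-openness makes a
set of tiling rectangles an exact partition: every point belongs to exactly
one tile.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership test."""
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def intersect(self, other: "Rect") -> "Rect | None":
        """Intersection rectangle, or None when the interiors are disjoint."""
        x0 = max(self.x0, other.x0)
        y0 = max(self.y0, other.y0)
        x1 = min(self.x1, other.x1)
        y1 = min(self.y1, other.y1)
        if x1 <= x0 or y1 <= y0:
            return None
        return Rect(x0, y0, x1, y1)

    def overlaps(self, other: "Rect") -> bool:
        return self.intersect(other) is not None

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )
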