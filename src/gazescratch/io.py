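"""Reading and writing of on-disk artifacts.

All tabular artifacts are UTF-8 delimited text (comma by default) with a
header row.  Gaze recordings use one row per sample; samples lost by the
tracker are encoded as ``valid=False`` rows rather than dropped, so the
nominal sampling-rate bookkeeping survives blinks.  Cover masks are
exchanged either as plain-text 0/1 matrices or as grayscale PNG.

Coordinates are 0-based pixels with the origin at the top-left of the
screen and y increasing downward; times are milliseconds from trial onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "GazeSample",
    "GazeRecording",
    "read_gaze_table",
    "write_gaze_table",
    "write_metrics_table",
    "read_metrics_table",
    "read_mask",
    "write_mask",
]

#: sentinel used when a score is undefined (no on-screen looking)
NA_SENTINEL = "NA"

GAZE_COLUMNS = ["participant_id", "trial_id", "age_days", "t_ms", "x_px", "y_px", "valid"]


@dataclass(frozen=True)
class GazeSample:
    """One tracker sample: time (ms from trial start), screen position, validity.

    When ``valid`` is False the coordinates are carried along for debugging
    but ignored by every consumer.
    """

    t_ms: float
    x_px: float
    y_px: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.t_ms < 0:
            raise ValueError(f"negative sample time {self.t_ms}")


@dataclass
class GazeRecording:
    """Ordered gaze samples for one trial of one participant."""

    participant_id: str
    trial_id: str
    age_days: int
    samples: list[GazeSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise ValueError("age_days must be nonnegative")
        times = [s.t_ms for s in self.samples]
        for a, b in zip(times, times[1:]):
            if b <= a:
                raise IntegrityError(
                    f"trial {self.trial_id!r} of {self.participant_id!r}: "
                    f"samples not strictly increasing in t_ms ({a} then {b})"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Columns as numpy arrays ``(t, x, y, valid)``."""
        n = len(self.samples)
        t = np.empty(n)
        x = np.empty(n)
        y = np.empty(n)
        v = np.empty(n, dtype=bool)
        for i, s in enumerate(self.samples):
            t[i], x[i], y[i], v[i] = s.t_ms, s.x_px, s.y_px, s.valid
        return t, x, y, v


def _parse_valid(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "1", "yes"}:
        return True
    if text in {"false", "f", "0", "no"}:
        return False
    raise FormatError(f"unparseable validity flag {value!r}")


def read_gaze_table(path: str | Path, delimiter: str = ",") -> list[GazeRecording]:
    """Read a gaze-sample table into one :class:`GazeRecording` per trial.

    The file must carry the header-named columns
    ``participant_id, trial_id, age_days, t_ms, x_px, y_px, valid``.
    Sample order is *checked*, never silently repaired: non-monotone
    timestamps within a trial raise :class:`IntegrityError` naming the trial.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype={"participant_id": str, "trial_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file has no header row") from exc
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    recordings: list[GazeRecording] = []
    # preserve order of first appearance, do not re-sort
    for (pid, tid), group in df.groupby(["participant_id", "trial_id"], sort=False):
        samples = [
            GazeSample(
                t_ms=float(row.t_ms),
                x_px=float(row.x_px),
                y_px=float(row.y_px),
                valid=_parse_valid(row.valid),
            )
            for row in group.itertuples()
        ]
        recordings.append(
            GazeRecording(
                participant_id=str(pid),
                trial_id=str(tid),
                age_days=int(group["age_days"].iloc[0]),
                samples=samples,
            )
        )
    return recordings


def write_gaze_table(recordings: Iterable[GazeRecording], path: str | Path,
                     delimiter: str = ",") -> None:
    """Write recordings in the canonical gaze CSV layout (one row per sample)."""
    rows = []
    for rec in recordings:
        for s in rec.samples:
            rows.append(
                (rec.participant_id, rec.trial_id, rec.age_days,
                 s.t_ms, s.x_px, s.y_px, s.valid)
            )
    df = pd.DataFrame(rows, columns=GAZE_COLUMNS)
    df.to_csv(path, sep=delimiter, index=False)


def write_metrics_table(metrics: Sequence, path: str | Path, delimiter: str = ",") -> None:
    """Serialize trial metrics as one row per trial x phase.

    ``metrics`` is a sequence of :class:`gazescratch.metrics.TrialMetrics`.
    Undefined scores (no on-screen looking in a phase) are written as the
    explicit sentinel ``NA`` and round-trip back to ``nan``.
    """
    from .metrics import trial_metrics_frame  # local import to avoid a cycle

    df = trial_metrics_frame(metrics)
    df.to_csv(path, sep=delimiter, index=False, na_rep=NA_SENTINEL)


def read_metrics_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read back a metrics table written by :func:`write_metrics_table`."""
    path = Path(path)
    try:
        return pd.read_csv(
            path, sep=delimiter, na_values=[NA_SENTINEL], keep_default_na=False,
            dtype={"participant_id": str, "trial_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file has no header row") from exc


# ---------------------------------------------------------------------------
# cover masks


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean cover mask (True = still covered).

    ``.png`` paths get an 8-bit grayscale image (covered = 0/black,
    uncovered = 255/white); any other extension gets a plain-text 0/1 matrix
    (1 = covered), one row per line.
    """
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if path.suffix.lower() == ".png":
        from PIL import Image

        img = Image.fromarray(np.where(mask, 0, 255).astype(np.uint8), mode="L")
        img.save(path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for row in mask:
                fh.write("".join("1" if c else "0" for c in row) + "\n")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a cover mask written by :func:`write_mask` (PNG or 0/1 text)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return arr < 128
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if set(line) - {"0", "1"}:
            raise FormatError(f"{path}: mask lines must contain only 0/1")
        rows.append([c == "1" for c in line])
    if not rows:
        raise FormatError(f"{path}: empty mask file")
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: ragged mask rows")
    return np.asarray(rows, dtype=bool)
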