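"""Arena, individual and trajectory data model, plus kinematic derivations.

Coordinates are arena-frame centimetres with the origin at the bottom-left
corner, x increasing rightward and y upward.  Tracking exports are
time-stamped centroid positions; blank cells mark tracking dropouts.
Short dropouts are repaired by linear interpolation, long ones split the
track into independent segments that downstream analyses treat separately.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "Assay",
    "BodyShape",
    "EyeMorph",
    "IndividualRecord",
    "KinematicSeries",
    "Trajectory",
    "TrajectoryFormatError",
    "TrajectoryDataError",
    "read_trajectory_csv",
    "fill_gaps",
    "compute_kinematics",
    "path_length",
]

#: speed below which a fish is scored as resting (immobile), cm/s
RESTING_THRESHOLD_CM_S = 0.2

#: tracking gaps at most this long are linearly interpolated, seconds
DEFAULT_MAX_GAP_S = 0.5


class TrajectoryFormatError(ValueError):
    """Raised when a tracking export lacks the required layout."""


class TrajectoryDataError(ValueError):
    """Raised when a tracking export violates a data invariant."""


class EyeMorph(str, enum.Enum):
    EYELESS = "eyeless"
    MICRO_EYED = "micro_eyed"
    NORMAL_EYED = "normal_eyed"


class BodyShape(str, enum.Enum):
    FUSIFORM = "fusiform"
    COMPRESSIFORM = "compressiform"


class Assay(str, enum.Enum):
    """The three stimulation conditions and their testing durations."""

    NO_STIMULATION_10MIN = "no_stimulation_10min"
    LANDMARK_5MIN = "landmark_5min"
    VIBRATION_3MIN = "vibration_3min"

    @property
    def duration_s(self) -> float:
        return {"no_stimulation_10min": 600.0,
                "landmark_5min": 300.0,
                "vibration_3min": 180.0}[self.value]


@dataclass(frozen=True)
class ArenaConfig:
    """Rectangular assay arena (default 45 x 28 cm, shallow water)."""

    width_cm: float = 45.0
    height_cm: float = 28.0
    water_depth_cm: float = 12.5  # informational; 10-15 cm in the assays

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("arena dimensions must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_cm / 2.0, self.height_cm / 2.0)

    def contains(self, x: float, y: float, tol: float = 0.0) -> bool:
        return (-tol <= x <= self.width_cm + tol
                and -tol <= y <= self.height_cm + tol)


@dataclass(frozen=True)
class IndividualRecord:
    """One assayed fish: identity, species, morphology."""

    individual_id: str
    species: str
    eye_morph: EyeMorph
    standard_length_cm: float
    pectoral_fin_length_cm: float | None = None
    body_shape: BodyShape = BodyShape.COMPRESSIFORM
    clade: str | None = None  # A-D where known

    def __post_init__(self) -> None:
        if self.standard_length_cm <= 0:
            raise ValueError("standard_length_cm must be positive")
        if self.clade is not None and self.clade not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown clade {self.clade!r}")


@dataclass
class Trajectory:
    """A tracked centroid path for one trial of one individual.

    ``positions_cm`` holds NaN at samples that were lost by the tracker and
    have not been interpolated; ``gap_mask`` is True at every sample that was
    missing in the source (whether or not it has since been filled).
    """

    individual: IndividualRecord
    assay: Assay
    times_s: np.ndarray
    positions_cm: np.ndarray
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(len(self.times_s), dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        n = len(self.times_s)
        if self.positions_cm.shape != (n, 2):
            raise TrajectoryDataError(
                f"positions shape {self.positions_cm.shape} != ({n}, 2)")
        if len(self.gap_mask) != n:
            raise TrajectoryDataError("gap_mask length mismatch")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise TrajectoryDataError("times must be strictly increasing")
        bad = ~np.isfinite(self.positions_cm).all(axis=1) & ~self.gap_mask
        if bad.any():
            raise TrajectoryDataError(
                f"non-finite positions outside gaps at rows {np.where(bad)[0][:10]}")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def valid_mask(self) -> np.ndarray:
        """Samples with usable coordinates (original or interpolated)."""
        return np.isfinite(self.positions_cm).all(axis=1)

    @property
    def segments(self) -> list[slice]:
        """Maximal runs of contiguous valid samples, in time order."""
        return _runs(self.valid_mask)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if len(self) > 1 else 0.0


def _runs(mask: np.ndarray) -> list[slice]:
    """Slices covering each maximal run of True in ``mask``."""
    out: list[slice] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append(slice(i, j))
            i = j
        else:
            i += 1
    return out


def read_trajectory_csv(path, arena: ArenaConfig,
                        individual: IndividualRecord,
                        assay: Assay = Assay.NO_STIMULATION_10MIN,
                        sample_rate_hz: float = 25.0,
                        max_overshoot_cm: float = 1.0) -> Trajectory:
    """Read a tracking export (``frame,time_s,x_cm,y_cm``; blank cell = gap).

    Coordinates that overshoot the arena by at most ``max_overshoot_cm``
    (tracker jitter at the walls) are clipped to the boundary; larger
    excursions are a validation error listing the offending rows.  Gaps are
    flagged but not filled; use :func:`fill_gaps`.
    """
    df = pd.read_csv(path)
    required = ["frame", "time_s", "x_cm", "y_cm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise TrajectoryDataError(f"{path}: non-numeric time values")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise TrajectoryDataError(f"{path}: time column not strictly increasing")
    xy = df[["x_cm", "y_cm"]].to_numpy(dtype=float)
    gap = ~np.isfinite(xy).all(axis=1)
    xy[gap] = np.nan
    if gap.mean() > 0.5:
        raise TrajectoryDataError(
            f"{path}: {gap.mean():.0%} of samples are tracking gaps (>50%)")
    # wall-overshoot check
    lo = np.array([0.0, 0.0])
    hi = np.array([arena.width_cm, arena.height_cm])
    with np.errstate(invalid="ignore"):
        over = (xy < lo - max_overshoot_cm) | (xy > hi + max_overshoot_cm)
    bad_rows = np.where(over.any(axis=1) & ~gap)[0]
    if bad_rows.size:
        raise TrajectoryDataError(
            f"{path}: coordinates outside arena by more than "
            f"{max_overshoot_cm} cm at rows {bad_rows[:20].tolist()}")
    xy = np.clip(xy, lo, hi)
    return Trajectory(individual=individual, assay=assay, times_s=times,
                      positions_cm=xy, gap_mask=gap,
                      sample_rate_hz=sample_rate_hz)


def fill_gaps(t: Trajectory, max_gap_s: float = DEFAULT_MAX_GAP_S) -> Trajectory:
    """Linearly interpolate tracking gaps no longer than ``max_gap_s``.

    A gap's duration is the time between its flanking valid samples.  Longer
    gaps (and gaps at either end of the record) are left unfilled, which
    splits the trajectory into independent :attr:`Trajectory.segments`;
    analysed time downstream excludes those samples.  Idempotent.
    """
    if max_gap_s <= 0:
        raise ValueError("max_gap_s must be positive")
    if len(t) == 0:
        return t
    xy = t.positions_cm.copy()
    valid = np.isfinite(xy).all(axis=1)
    for run in _runs(~valid):
        i, j = run.start, run.stop  # gap samples are i..j-1
        if i == 0 or j == len(t):
            continue  # no flanking sample on one side
        t0, t1 = t.times_s[i - 1], t.times_s[j]
        if t1 - t0 > max_gap_s:
            continue
        frac = (t.times_s[i:j] - t0) / (t1 - t0)
        xy[i:j] = xy[i - 1] + frac[:, None] * (xy[j] - xy[i - 1])
    return replace(t, positions_cm=xy, gap_mask=t.gap_mask.copy())


@dataclass
class KinematicSeries:
    """Per-sample speed, heading and resting classification.

    ``speed_cm_s[i]`` is the speed over the interval ending at sample ``i``
    (``speed[0]`` copies ``speed[1]`` so every sample is classifiable); it is
    NaN across segment boundaries.  ``heading_rad`` is the direction of
    motion from a centred displacement window, NaN while resting, at segment
    edges, and wherever the window displacement is degenerate.
    """

    speed_cm_s: np.ndarray
    heading_rad: np.ndarray
    resting_mask: np.ndarray
    resting_threshold_cm_s: float = RESTING_THRESHOLD_CM_S

    def __len__(self) -> int:
        return len(self.speed_cm_s)


def compute_kinematics(t: Trajectory,
                       resting_threshold_cm_s: float = RESTING_THRESHOLD_CM_S,
                       heading_window: int = 5) -> KinematicSeries:
    """Derive speed, heading and the resting mask from a gap-filled track.

    Speed comes from consecutive displacements over dt; samples with speed
    below ``resting_threshold_cm_s`` are resting.  Heading is the angle of
    the displacement across a centred window of ``heading_window`` samples
    (half-window on each side), undefined while resting.
    """
    n = len(t)
    speed = np.full(n, np.nan)
    heading = np.full(n, np.nan)
    resting = np.zeros(n, dtype=bool)
    if n == 0:
        return KinematicSeries(speed, heading, resting, resting_threshold_cm_s)
    if n < heading_window:
        warnings.warn("trajectory shorter than heading window; "
                      "headings undefined", stacklevel=2)
    h = max(1, heading_window // 2)
    xy = t.positions_cm
    for seg in t.segments:
        i0, i1 = seg.start, seg.stop
        if i1 - i0 < 2:
            resting[i0:i1] = True  # single isolated sample: immobile
            continue
        d = np.linalg.norm(np.diff(xy[i0:i1], axis=0), axis=1)
        dt = np.diff(t.times_s[i0:i1])
        s = d / dt
        speed[i0 + 1:i1] = s
        speed[i0] = s[0]
        resting[i0:i1] = speed[i0:i1] < resting_threshold_cm_s
        for i in range(i0, i1):
            lo, hi_ = max(i0, i - h), min(i1 - 1, i + h)
            if hi_ <= lo or resting[i]:
                continue
            dx, dy = xy[hi_] - xy[lo]
            if dx * dx + dy * dy < 1e-24:
                continue
            heading[i] = np.arctan2(dy, dx)
    return KinematicSeries(speed, heading, resting, resting_threshold_cm_s)


def path_length(t: Trajectory) -> float:
    """Total swum distance (cm): per-segment sum of consecutive displacements."""
    total = 0.0
    for seg in t.segments:
        xy = t.positions_cm[seg]
        if len(xy) > 1:
            total += float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    return total


def resting_time_s(t: Trajectory, k: KinematicSeries) -> float:
    """Total time spent immobile, summed per interval over valid segments."""
    total = 0.0
    for seg in t.segments:
        i0, i1 = seg.start, seg.stop
        if i1 - i0 < 2:
            continue
        dt = np.diff(t.times_s[i0:i1])
        total += float(dt[k.resting_mask[i0 + 1:i1]].sum())
    return total
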