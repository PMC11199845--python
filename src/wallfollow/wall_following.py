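"""Near-wall belt geometry, wall-following event segmentation, WF indicators.

Wall-following (thigmotaxis) is scored inside the near-wall belt: the
rectangular annulus within 0.5 standard lengths (SL) of any arena wall.
A belt visit counts as a wall-following event only once the fish has
accumulated at least 2 SL of in-belt path during that visit; sub-threshold
visits contribute nothing to the distance/time/frequency indicators.

Six indicators summarise one trial:

==================  =========================================================
WF-Distance         total in-belt path over qualifying events, in SL
WF-Frequency        number of qualifying events
WF-Time             percent of testing time spent in qualifying events
WF-Resting Time     total immobile time over the whole assay, seconds
WF-Speed            event path / event mobile time, SL/s
WF-Max Speed        maximum instantaneous speed over the whole assay, SL/s
==================  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import (ArenaConfig, KinematicSeries, Trajectory, _runs,
                         resting_time_s)

__all__ = [
    "WallFollowingEvent",
    "WallFollowingMetrics",
    "distance_to_nearest_wall",
    "belt_membership",
    "segment_wf_events",
    "compute_wf_metrics",
]

#: belt half-width in standard lengths
BELT_SL = 0.5
#: minimum accumulated in-belt path for a visit to qualify, in SL
EVENT_MIN_SL = 2.0


def distance_to_nearest_wall(point, arena: ArenaConfig) -> float:
    """Distance (cm) from a point inside the arena to the closest wall."""
    x, y = float(point[0]), float(point[1])
    if not arena.contains(x, y):
        raise ValueError(f"point ({x}, {y}) outside arena")
    return min(x, arena.width_cm - x, y, arena.height_cm - y)


def _wall_distances(xy: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    return np.min(np.stack([xy[:, 0], arena.width_cm - xy[:, 0],
                            xy[:, 1], arena.height_cm - xy[:, 1]]), axis=0)


def belt_membership(point, arena: ArenaConfig, sl_cm: float,
                    belt_sl: float = BELT_SL) -> bool:
    """True iff the point lies within ``belt_sl`` x SL of a wall (inclusive)."""
    if sl_cm <= 0:
        raise ValueError("sl_cm must be positive")
    return distance_to_nearest_wall(point, arena) <= belt_sl * sl_cm


def belt_mask(t: Trajectory, arena: ArenaConfig, sl_cm: float,
              belt_sl: float = BELT_SL) -> np.ndarray:
    """Per-sample belt membership; False at unfilled gap samples."""
    xy = t.positions_cm
    out = np.zeros(len(t), dtype=bool)
    valid = t.valid_mask
    if valid.any():
        out[valid] = _wall_distances(xy[valid], arena) <= belt_sl * sl_cm
    return out


@dataclass(frozen=True)
class WallFollowingEvent:
    """One qualifying belt visit: sample span, in-belt path and duration."""

    start_index: int
    end_index: int  # inclusive index of the last in-belt sample
    in_belt_path_cm: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("event must span at least two samples")


@dataclass(frozen=True)
class WallFollowingMetrics:
    wf_distance_sl: float
    wf_frequency: int
    wf_time_pct: float
    wf_resting_time_s: float
    wf_speed_sl_s: float
    wf_max_speed_sl_s: float


def segment_wf_events(t: Trajectory, k: KinematicSeries, arena: ArenaConfig,
                      sl_cm: float, belt_sl: float = BELT_SL,
                      min_path_sl: float = EVENT_MIN_SL,
                      ) -> list[WallFollowingEvent]:
    """Segment qualifying wall-following events from a gap-filled track.

    A candidate bout is a maximal run of consecutive in-belt samples (within
    one valid segment); its in-belt path is the summed displacement between
    consecutive in-belt samples.  The bout qualifies iff that path reaches
    ``min_path_sl`` x SL.  Events are disjoint and time-ordered.
    """
    member = belt_mask(t, arena, sl_cm, belt_sl)
    xy = t.positions_cm
    events: list[WallFollowingEvent] = []
    for seg in t.segments:
        sub = member[seg]
        for run in _runs(sub):
            i = seg.start + run.start
            j = seg.start + run.stop - 1  # inclusive
            if j <= i:
                continue
            path = float(np.linalg.norm(
                np.diff(xy[i:j + 1], axis=0), axis=1).sum())
            if path >= min_path_sl * sl_cm:
                events.append(WallFollowingEvent(
                    start_index=i, end_index=j, in_belt_path_cm=path,
                    duration_s=float(t.times_s[j] - t.times_s[i])))
    return events


def count_belt_entries(t: Trajectory, arena: ArenaConfig, sl_cm: float,
                       belt_sl: float = BELT_SL) -> int:
    """Permissive frequency reading: every belt entry, qualifying or not."""
    member = belt_mask(t, arena, sl_cm, belt_sl)
    n = 0
    for seg in t.segments:
        n += len(_runs(member[seg]))
    return n


def compute_wf_metrics(t: Trajectory, k: KinematicSeries,
                       events: list[WallFollowingEvent], sl_cm: float,
                       testing_time_s: float,
                       count_all_entries: bool = False,
                       arena: ArenaConfig | None = None,
                       belt_sl: float = BELT_SL) -> WallFollowingMetrics:
    """Reduce events + kinematics to the six SL-normalised WF indicators.

    ``count_all_entries`` switches WF-Frequency to the permissive reading
    (every belt entry counts, not only qualifying events); it requires
    ``arena``.  WF-Speed divides event path by event *mobile* time: resting
    frames inside an event extend WF-Time but not the speed denominator.
    """
    if testing_time_s <= 0:
        raise ValueError("testing_time_s must be positive")
    path_cm = sum(e.in_belt_path_cm for e in events)
    dur_s = sum(e.duration_s for e in events)
    mobile_s = 0.0
    for e in events:
        dt = np.diff(t.times_s[e.start_index:e.end_index + 1])
        moving = ~k.resting_mask[e.start_index + 1:e.end_index + 1]
        mobile_s += float(dt[moving].sum())
    if count_all_entries:
        if arena is None:
            raise ValueError("count_all_entries requires the arena")
        freq = count_belt_entries(t, arena, sl_cm, belt_sl)
    else:
        freq = len(events)
    speeds = k.speed_cm_s
    max_speed = float(np.nanmax(speeds)) if np.isfinite(speeds).any() else 0.0
    return WallFollowingMetrics(
        wf_distance_sl=path_cm / sl_cm,
        wf_frequency=freq,
        wf_time_pct=100.0 * dur_s / testing_time_s,
        wf_resting_time_s=resting_time_s(t, k),
        wf_speed_sl_s=(path_cm / mobile_s / sl_cm) if mobile_s > 0 else 0.0,
        wf_max_speed_sl_s=max_speed / sl_cm,
    )
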