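"""Stimulation-range metrics and approach angle/distance quantification.

Two stimulated assays present either a novel landmark (opaque cylinder,
5 cm diameter) or a vibration source (aeration pump, 40-50 Hz) at the
arena centre.  A 10 x 16 cm rectangle around the stimulus is the
stimulation range; S-indicators summarise occupancy of and speed within
that range.  For the first three entries into the range ("approaches") the
approach angle (between the direction of motion and the bearing to the
stimulus centre) and the approach distance (closest gap between the fish's
body and the stimulus boundary, in SL) are recorded.

Only the centroid is tracked, so the fish body is modelled as a 1-D
segment of length SL centred on the tracked point and aligned with the
smoothed motion direction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .trajectory import ArenaConfig, KinematicSeries, Trajectory, _runs

__all__ = [
    "StimulusKind",
    "StimulusConfig",
    "StimulationMetrics",
    "ApproachEvent",
    "in_stimulation_range",
    "compute_stimulation_metrics",
    "approach_angle",
    "approach_distance",
    "detect_approaches",
]


class StimulusKind(str, enum.Enum):
    NONE = "none"
    LANDMARK = "landmark"
    VIBRATION = "vibration"


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus geometry: rectangular stimulation range around a source.

    The vibration pump's physical footprint is not observable from tracking,
    so it defaults to the landmark cylinder's radius unless configured.
    """

    kind: StimulusKind
    center_cm: tuple[float, float]
    zone_width_cm: float = 10.0    # y extent of the stimulation range
    zone_length_cm: float = 16.0   # x extent of the stimulation range
    cylinder_diameter_cm: float = 5.0
    vibration_hz: tuple[float, float] = (40.0, 50.0)  # informational
    footprint_radius_cm: float | None = None

    @classmethod
    def centered(cls, kind: StimulusKind, arena: ArenaConfig, **kw) -> "StimulusConfig":
        return cls(kind=kind, center_cm=arena.center, **kw)

    @property
    def source_radius_cm(self) -> float:
        if self.footprint_radius_cm is not None:
            return self.footprint_radius_cm
        return self.cylinder_diameter_cm / 2.0

    def validate_inside(self, arena: ArenaConfig) -> None:
        cx, cy = self.center_cm
        hx, hy = self.zone_length_cm / 2.0, self.zone_width_cm / 2.0
        if not (hx <= cx <= arena.width_cm - hx and hy <= cy <= arena.height_cm - hy):
            raise ValueError("stimulation range extends outside the arena")
        if self.source_radius_cm >= min(hx, hy):
            raise ValueError("stimulus source larger than the stimulation range")


@dataclass(frozen=True)
class StimulationMetrics:
    s_frequency: int
    s_time_pct: float
    s_speed_sl_s: float
    s_max_speed_sl_s: float


@dataclass(frozen=True)
class ApproachEvent:
    order: int                    # 1..3
    angle_deg: float              # [0, 180]
    distance_sl: float
    time_s: float
    heading_extrapolated: bool = False  # heading taken from nearest mobile sample


def in_stimulation_range(point, stimulus: StimulusConfig) -> bool:
    """Axis-aligned rectangle test with inclusive boundaries."""
    cx, cy = stimulus.center_cm
    return (abs(float(point[0]) - cx) <= stimulus.zone_length_cm / 2.0
            and abs(float(point[1]) - cy) <= stimulus.zone_width_cm / 2.0)


def zone_mask(t: Trajectory, stimulus: StimulusConfig) -> np.ndarray:
    """Per-sample stimulation-range membership; False at gap samples."""
    cx, cy = stimulus.center_cm
    xy = t.positions_cm
    with np.errstate(invalid="ignore"):
        inside = ((np.abs(xy[:, 0] - cx) <= stimulus.zone_length_cm / 2.0)
                  & (np.abs(xy[:, 1] - cy) <= stimulus.zone_width_cm / 2.0))
    return inside & t.valid_mask


def _zone_bouts(t: Trajectory, member: np.ndarray) -> list[tuple[int, int]]:
    bouts = []
    for seg in t.segments:
        for run in _runs(member[seg]):
            bouts.append((seg.start + run.start, seg.start + run.stop - 1))
    return bouts


def compute_stimulation_metrics(t: Trajectory, k: KinematicSeries,
                                stimulus: StimulusConfig, sl_cm: float,
                                testing_time_s: float) -> StimulationMetrics:
    """The four S-indicators for one stimulated trial.

    Zone time assigns each inter-sample interval to the membership of its
    endpoint, so time in and out of the range sum exactly to the analysed
    time.  Speeds are per-interval speeds at in-zone samples, SL-normalised;
    the average excludes resting intervals.
    """
    if stimulus.kind is StimulusKind.NONE:
        raise ValueError("stimulation metrics require a stimulated assay")
    if testing_time_s <= 0:
        raise ValueError("testing_time_s must be positive")
    member = zone_mask(t, stimulus)
    bouts = _zone_bouts(t, member)
    time_in = 0.0
    speed_sum = 0.0
    mobile_t = 0.0
    max_speed = 0.0
    for seg in t.segments:
        i0, i1 = seg.start, seg.stop
        if i1 - i0 < 2:
            continue
        dt = np.diff(t.times_s[i0:i1])
        m = member[i0 + 1:i1]
        time_in += float(dt[m].sum())
        sp = k.speed_cm_s[i0 + 1:i1]
        moving = ~k.resting_mask[i0 + 1:i1]
        sel = m & moving
        speed_sum += float((sp[sel] * dt[sel]).sum())
        mobile_t += float(dt[sel].sum())
        if m.any():
            max_speed = max(max_speed, float(sp[m].max()))
    return StimulationMetrics(
        s_frequency=len(bouts),
        s_time_pct=100.0 * time_in / testing_time_s,
        s_speed_sl_s=(speed_sum / mobile_t / sl_cm) if mobile_t > 0 else 0.0,
        s_max_speed_sl_s=max_speed / sl_cm,
    )


def approach_angle(heading_rad: float, position, stimulus: StimulusConfig) -> float:
    """Unsigned angle (degrees, [0, 180]) between the motion direction and
    the bearing from the fish to the stimulus centre."""
    if not math.isfinite(heading_rad):
        raise ValueError("heading undefined")
    cx, cy = stimulus.center_cm
    vx, vy = cx - float(position[0]), cy - float(position[1])
    norm = math.hypot(vx, vy)
    if norm == 0.0:
        return 0.0  # fish centred on the stimulus: bearing degenerate
    cosang = (math.cos(heading_rad) * vx + math.sin(heading_rad) * vy) / norm
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    s = 0.0 if denom == 0.0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(a + s * ab - p))


def approach_distance(position, heading_rad: float, sl_cm: float,
                      stimulus: StimulusConfig) -> float:
    """Shortest body-to-stimulus-boundary distance, in SL (clamped at 0).

    The body is the segment of length SL centred on the tracked centroid
    along ``heading_rad``; the stimulus boundary is the circle of
    :attr:`StimulusConfig.source_radius_cm` around the centre.
    """
    if not math.isfinite(heading_rad):
        raise ValueError("heading undefined")
    p = np.asarray(position, dtype=float)
    u = np.array([math.cos(heading_rad), math.sin(heading_rad)])
    a, b = p - 0.5 * sl_cm * u, p + 0.5 * sl_cm * u
    c = np.asarray(stimulus.center_cm, dtype=float)
    d = _point_segment_distance(c, a, b) - stimulus.source_radius_cm
    return max(0.0, d) / sl_cm


def detect_approaches(t: Trajectory, k: KinematicSeries,
                      stimulus: StimulusConfig, sl_cm: float,
                      max_approaches: int = 3,
                      measure_at: str = "closest") -> list[ApproachEvent]:
    """First ``max_approaches`` entries into the stimulation range.

    Each bout runs from range entry to exit.  Angle and distance are
    measured at the bout's frame of minimal body-to-stimulus distance
    (``measure_at="closest"``, default) or at the entry frame
    (``measure_at="entry"``).  If the heading is undefined at the chosen
    frame (fish resting), the nearest frame with a defined heading supplies
    the measurement and the event is flagged.
    """
    if stimulus.kind is StimulusKind.NONE:
        raise ValueError("approach detection requires a stimulated assay")
    if measure_at not in ("closest", "entry"):
        raise ValueError("measure_at must be 'closest' or 'entry'")
    member = zone_mask(t, stimulus)
    events: list[ApproachEvent] = []
    for i, j in _zone_bouts(t, member):
        if len(events) >= max_approaches:
            break
        frames = range(i, j + 1)
        if measure_at == "entry":
            best = i
        else:
            best, best_d = i, math.inf
            for f in frames:
                hf, flag = _nearest_defined_heading(k, f, i, j)
                if hf is None:
                    continue
                d = approach_distance(t.positions_cm[f], hf, sl_cm, stimulus)
                if d < best_d:
                    best, best_d = f, d
        hf, flag = _nearest_defined_heading(k, best, 0, len(t) - 1)
        if hf is None:
            continue  # no defined heading anywhere: skip bout
        events.append(ApproachEvent(
            order=len(events) + 1,
            angle_deg=approach_angle(hf, t.positions_cm[best], stimulus),
            distance_sl=approach_distance(t.positions_cm[best], hf, sl_cm,
                                          stimulus),
            time_s=float(t.times_s[best]),
            heading_extrapolated=flag))
    return events


def _nearest_defined_heading(k: KinematicSeries, f: int, lo: int, hi: int
                             ) -> tuple[float | None, bool]:
    """Heading at frame f, else from the nearest frame in [lo, hi] with one."""
    if math.isfinite(k.heading_rad[f]):
        return float(k.heading_rad[f]), False
    for off in range(1, hi - lo + 1):
        for g in (f - off, f + off):
            if lo <= g <= hi and math.isfinite(k.heading_rad[g]):
                return float(k.heading_rad[g]), True
    return None, False
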