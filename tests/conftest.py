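import numpy as np
import pytest

from wallfollow.trajectory import (ArenaConfig, Assay, EyeMorph,
                                   IndividualRecord, Trajectory)


@pytest.fixture
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture
def fish() -> IndividualRecord:
    return IndividualRecord(individual_id="f1", species="S_tianlinensis",
                            eye_morph=EyeMorph.EYELESS,
                            standard_length_cm=8.0)


def make_trajectory(times, xy, fish=None, assay=Assay.NO_STIMULATION_10MIN,
                    gap_mask=None, sample_rate_hz=25.0) -> Trajectory:
    if fish is None:
        fish = IndividualRecord(individual_id="f1", species="sp",
                                eye_morph=EyeMorph.EYELESS,
                                standard_length_cm=8.0)
    return Trajectory(individual=fish, assay=assay,
                      times_s=np.asarray(times, dtype=float),
                      positions_cm=np.asarray(xy, dtype=float),
                      gap_mask=gap_mask, sample_rate_hz=sample_rate_hz)


def perimeter_track(arena: ArenaConfig, inset_cm: float = 1.0,
                    speed_cm_s: float = 4.5, duration_s: float = 600.0,
                    step_cm: float = 0.5):
    """Counter-clockwise rectangle hugging the walls at ``inset_cm``.

    ``step_cm`` must divide both inset-rectangle side lengths so that the
    corners land exactly on samples and the summed chord lengths equal the
    true path length.
    """
    w = arena.width_cm - 2 * inset_cm
    h = arena.height_cm - 2 * inset_cm
    per = 2 * (w + h)
    assert abs(w / step_cm - round(w / step_cm)) < 1e-9
    assert abs(h / step_cm - round(h / step_cm)) < 1e-9
    n_steps = int(round(duration_s * speed_cm_s / step_cm))
    s = (np.arange(n_steps + 1) * step_cm) % per
    x = np.empty_like(s)
    y = np.empty_like(s)
    for i, si in enumerate(s):
        if si < w:
            x[i], y[i] = inset_cm + si, inset_cm
        elif si < w + h:
            x[i], y[i] = inset_cm + w, inset_cm + (si - w)
        elif si < 2 * w + h:
            x[i], y[i] = inset_cm + w - (si - w - h), inset_cm + h
        else:
            x[i], y[i] = inset_cm, inset_cm + h - (si - 2 * w - h)
    times = np.arange(n_steps + 1) * (step_cm / speed_cm_s)
    return times, np.column_stack([x, y])
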