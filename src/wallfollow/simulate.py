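"""Generative models for desk-scale study data.

Two generators stand in for the study's recordings:

* a boundary-attracted correlated random walk for centroid tracks in the
  rectangular assay arena (25 samples/s), with move/rest Markov switching,
  wrapped-normal turning noise, a steering torque that aligns the heading
  with the nearest-wall tangent inside a sensing range (wall-following
  drive), an optional bias toward a stimulus, and specular reflection at
  the walls; and

* a lambda-transformed Brownian-motion trait simulator on a chronogram for
  the phylogenetic-signal stage.

Morph presets calibrate the swim model so that the three eye morphs
reproduce the observed behavioural gradient (eyeless > micro-eyed >
normal-eyed in wall attraction and mean mobile speed; the reverse in
resting).  Calibration lives in the ``MORPH_PRESETS`` data table, not in
code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny
from .stimulus import StimulusConfig, StimulusKind
from .trajectory import ArenaConfig, Assay, IndividualRecord, Trajectory

__all__ = [
    "SwimSimConfig",
    "MorphPreset",
    "MORPH_PRESETS",
    "TraitSimConfig",
    "simulate_trajectory",
    "morph_preset",
    "simulate_bm_traits",
]


@dataclass(frozen=True)
class SwimSimConfig:
    """Parameters of the boundary-attracted correlated random walk.

    Speeds are in standard lengths per second; ``turn_kappa`` is the
    inverse angular diffusion (per-step turning sd = sqrt(dt / kappa)),
    ``wall_attraction`` the tangent-alignment steering gain (rad/s per unit
    misalignment) active within ``wall_sense_sl`` SL of a wall, and the
    rest rates drive a two-state move/rest Markov chain whose stationary
    resting fraction is rest_on / (rest_on + rest_off).
    """

    dt_s: float = 0.04  # 25 Hz
    duration_s: float = 600.0
    speed_mean_sl_s: float = 0.45
    speed_sd_sl_s: float = 0.20
    turn_kappa: float = 8.0
    wall_attraction: float = 0.0
    wall_sense_sl: float = 1.0
    stim_attraction: float = 0.0
    rest_on_rate_hz: float = 0.05
    rest_off_rate_hz: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("dt_s and duration_s must be positive")
        if min(self.rest_on_rate_hz, self.rest_off_rate_hz,
               self.wall_attraction, self.stim_attraction) < 0:
            raise ValueError("rates and gains must be non-negative")
        if self.turn_kappa <= 0:
            raise ValueError("turn_kappa must be positive")


@dataclass(frozen=True)
class MorphPreset:
    name: str
    config: SwimSimConfig
    target_speed_sl_s: float


# Calibration data: per-morph mobile speed (mean/sd, SL/s), wall-steering
# gain and rest switching.  Speed targets follow the observed morph means;
# wall attraction and resting are graded so eyeless presets hug walls most
# and rest least.
MORPH_PRESETS: dict[str, dict[str, float]] = {
    "eyeless": {"speed_mean_sl_s": 0.52, "speed_sd_sl_s": 0.20,
                "wall_attraction": 0.55, "rest_on_rate_hz": 0.02,
                "rest_off_rate_hz": 0.50, "target_speed_sl_s": 0.52},
    "micro_eyed": {"speed_mean_sl_s": 0.45, "speed_sd_sl_s": 0.21,
                   "wall_attraction": 0.45, "rest_on_rate_hz": 0.04,
                   "rest_off_rate_hz": 0.40, "target_speed_sl_s": 0.45},
    "normal_eyed": {"speed_mean_sl_s": 0.36, "speed_sd_sl_s": 0.20,
                    "wall_attraction": 0.30, "rest_on_rate_hz": 0.08,
                    "rest_off_rate_hz": 0.30, "target_speed_sl_s": 0.36},
}


def morph_preset(name: str, duration_s: float = 600.0, seed: int = 0) -> MorphPreset:
    """Calibrated simulator preset for one eye morph."""
    if name not in MORPH_PRESETS:
        raise KeyError(f"unknown morph preset {name!r}; "
                       f"choose from {sorted(MORPH_PRESETS)}")
    row = MORPH_PRESETS[name]
    cfg = SwimSimConfig(
        duration_s=duration_s, seed=seed,
        speed_mean_sl_s=row["speed_mean_sl_s"],
        speed_sd_sl_s=row["speed_sd_sl_s"],
        wall_attraction=row["wall_attraction"],
        rest_on_rate_hz=row["rest_on_rate_hz"],
        rest_off_rate_hz=row["rest_off_rate_hz"])
    return MorphPreset(name=name, config=cfg,
                       target_speed_sl_s=row["target_speed_sl_s"])


_ASSAY_BY_KIND = {StimulusKind.LANDMARK: Assay.LANDMARK_5MIN,
                  StimulusKind.VIBRATION: Assay.VIBRATION_3MIN}


def simulate_trajectory(cfg: SwimSimConfig, arena: ArenaConfig,
                        individual: IndividualRecord,
                        stimulus: StimulusConfig | None = None,
                        assay: Assay | None = None) -> Trajectory:
    """Simulate one centroid track; reproducible for a given seed.

    Heading update per step: wrapped-normal noise, plus a restoring torque
    ``wall_attraction * sin(target - heading) * dt`` toward a target that
    blends the nearest-wall tangent (sign matched to the current heading)
    with a component toward the wall, active inside the sensing range, plus
    an analogous ``stim_attraction`` torque toward the stimulus centre.
    Position integrates speed * dt along the heading with specular
    reflection at the walls; while resting the fish does not move.
    """
    rng = np.random.default_rng(cfg.seed)
    sl = individual.standard_length_cm
    n_steps = int(round(cfg.duration_s / cfg.dt_s))
    n = n_steps + 1
    dt = cfg.dt_s
    W, H = arena.width_cm, arena.height_cm

    # pre-drawn randomness (keeps the integration loop scalar and fast)
    mean, sd = cfg.speed_mean_sl_s, cfg.speed_sd_sl_s
    sig2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sig2 / 2.0
    speeds = np.exp(rng.normal(mu, math.sqrt(sig2), n_steps)) * sl  # cm/s
    noise = rng.normal(0.0, math.sqrt(dt / cfg.turn_kappa), n_steps)
    u_rest = rng.random(n_steps)
    p_to_rest = 1.0 - math.exp(-cfg.rest_on_rate_hz * dt)
    p_to_move = 1.0 - math.exp(-cfg.rest_off_rate_hz * dt)

    sense = cfg.wall_sense_sl * sl
    beta, gamma = cfg.wall_attraction, cfg.stim_attraction
    sx, sy = stimulus.center_cm if stimulus is not None else (0.0, 0.0)

    xy = np.empty((n, 2))
    x = rng.uniform(0.05 * W, 0.95 * W)
    y = rng.uniform(0.05 * H, 0.95 * H)
    theta = rng.uniform(-math.pi, math.pi)
    moving = True
    xy[0] = (x, y)
    for i in range(n_steps):
        if moving:
            if u_rest[i] < p_to_rest:
                moving = False
        else:
            if u_rest[i] < p_to_move:
                moving = True
        if not moving:
            xy[i + 1] = (x, y)
            continue
        # nearest wall and steering target
        if beta > 0.0:
            d = x
            wall = 0  # left
            if W - x < d:
                d, wall = W - x, 1  # right
            if y < d:
                d, wall = y, 2      # bottom
            if H - y < d:
                d, wall = H - y, 3  # top
            if d <= sense:
                if wall == 0:
                    tx, ty, nx_, ny_ = 0.0, 1.0, -1.0, 0.0
                elif wall == 1:
                    tx, ty, nx_, ny_ = 0.0, 1.0, 1.0, 0.0
                elif wall == 2:
                    tx, ty, nx_, ny_ = 1.0, 0.0, 0.0, -1.0
                else:
                    tx, ty, nx_, ny_ = 1.0, 0.0, 0.0, 1.0
                ct, st = math.cos(theta), math.sin(theta)
                if ct * tx + st * ty < 0.0:
                    tx, ty = -tx, -ty  # tangent sign matching the heading
                c = 0.8 * d / sense    # tilt toward the wall when far from it
                target = math.atan2(ty + c * ny_, tx + c * nx_)
                theta += beta * math.sin(target - theta) * dt
        if gamma > 0.0 and stimulus is not None:
            bearing = math.atan2(sy - y, sx - x)
            theta += gamma * math.sin(bearing - theta) * dt
        theta += noise[i]
        step = speeds[i] * dt
        x += step * math.cos(theta)
        y += step * math.sin(theta)
        # specular reflection (repeat in case of corner overshoot)
        while not (0.0 <= x <= W and 0.0 <= y <= H):
            if x < 0.0:
                x = -x
                theta = math.pi - theta
            elif x > W:
                x = 2.0 * W - x
                theta = math.pi - theta
            if y < 0.0:
                y = -y
                theta = -theta
            elif y > H:
                y = 2.0 * H - y
                theta = -theta
        xy[i + 1] = (x, y)

    times = np.arange(n) * dt
    if assay is None:
        if stimulus is not None and stimulus.kind in _ASSAY_BY_KIND:
            assay = _ASSAY_BY_KIND[stimulus.kind]
        else:
            assay = Assay.NO_STIMULATION_10MIN
    return Trajectory(individual=individual, assay=assay, times_s=times,
                      positions_cm=xy, sample_rate_hz=1.0 / dt)


@dataclass(frozen=True)
class TraitSimConfig:
    """Lambda-transformed Brownian-motion trait simulation on a chronogram."""

    tree: Phylogeny
    sigma2: float = 1.0
    lambda_true: float = 1.0
    root_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


def simulate_bm_traits(cfg: TraitSimConfig, n_traits: int = 1,
                       prefix: str = "trait") -> pd.DataFrame:
    """Draw species traits from N(root, sigma2 * C(lambda_true)).

    C is the Brownian covariance of the tree (shared root-to-MRCA path
    lengths) with off-diagonals scaled by ``lambda_true``.  Returns a
    species x trait table aligned to the tree's tip labels.
    """
    rng = np.random.default_rng(cfg.seed)
    C = cfg.tree.vcv().to_numpy().copy()
    d = np.diag(C).copy()
    C *= cfg.lambda_true
    np.fill_diagonal(C, d)
    V = cfg.sigma2 * C
    n = len(d)
    if cfg.sigma2 == 0.0:
        draws = np.full((n, n_traits), cfg.root_value)
    else:
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        draws = cfg.root_value + L @ rng.standard_normal((n, n_traits))
    cols = [f"{prefix}{i + 1}" if n_traits > 1 else prefix
            for i in range(n_traits)]
    return pd.DataFrame(draws, index=cfg.tree.tip_labels, columns=cols)
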