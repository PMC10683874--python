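"""Closed-loop BMI tasks: Jumper (navigation) and Jedi (object control).

Both tasks run the same discrete-time loop at the 100-ms control cadence:
the intention agent emits population activity conditioned on an intended
location, the decoder converts the trailing spike-count window into a
position, a causal moving average smooths the output (3 s for Jumper,
2 s for Jedi), and the avatar (Jumper) or controlled object (Jedi) is
updated from the smoothed stream.  Trial logic mirrors the tasks: Jumper
trials end on goal contact or a 62-s timeout; Jedi trials end after 3 min
or 0.5 mL of accrued reward, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArenaSpec, SpikeRaster, TICK_S, TrialLog
from .decoding import DecoderModel
from .population import PlaceFieldMap
from .synth import BASE_BIN_S, IntentionAgentConfig, intention_rates


@dataclass(frozen=True)
class JumperConfig:
    """BMI navigation task settings."""

    smoothing_s: float = 3.0
    timeout_s: float = 62.0
    goal_radius_cm: float = 10.0
    movement_rule: str = "teleport_to_smoothed"  # or rate_limited
    max_step_cm_per_tick: float = 5.0
    min_goal_dist_cm: float = 30.0
    n_trials: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.timeout_s <= 0:
            raise ValueError("timeout_s must be positive")
        if self.smoothing_s < TICK_S:
            raise ValueError("smoothing_s must be >= the output interval")
        if self.movement_rule not in ("teleport_to_smoothed", "rate_limited"):
            raise ValueError(f"unknown movement_rule {self.movement_rule!r}")


@dataclass(frozen=True)
class JediConfig:
    """BMI object-location control task settings."""

    smoothing_s: float = 2.0
    trial_limit_s: float = 180.0
    reward_cap_ml: float = 0.5
    reward_rate_ml_s: float = 0.01
    goal_radius_cm: float = 10.0
    min_goal_jump_cm: float = 40.0
    n_trials: int = 8
    # treadmill-motion emulation (the fixed animal occasionally shuffles)
    move_bout_rate_hz: float = 0.03
    move_bout_s: float = 2.0
    move_speed_cm_s: float = 10.0
    rotation_noise_deg_s: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.trial_limit_s <= 0 or self.reward_cap_ml <= 0:
            raise ValueError("trial_limit_s and reward_cap_ml must be positive")
        if self.reward_rate_ml_s <= 0:
            raise ValueError("reward_rate_ml_s must be positive")


def smooth_positions(decoded: np.ndarray, smoothing_s: float) -> np.ndarray:
    """Causal (trailing) moving average over min(elapsed, smoothing_s).

    The first output equals the first sample; sample k averages the most
    recent ``min(k+1, smoothing_s / 0.1)`` samples.
    """
    decoded = np.asarray(decoded, float)
    if len(decoded) == 0:
        return decoded.copy()
    w = max(round(smoothing_s / TICK_S), 1)
    csum = np.vstack([np.zeros((1, decoded.shape[1])), np.cumsum(decoded, axis=0)])
    k = np.arange(1, len(decoded) + 1)
    lo = np.maximum(k - w, 0)
    return (csum[k] - csum[lo]) / (k - lo)[:, None]


class _Loop:
    """Shared per-tick machinery for both closed-loop tasks."""

    def __init__(self, rpv_map: PlaceFieldMap, model: DecoderModel,
                 agent_cfg: IntentionAgentConfig, arena: ArenaSpec,
                 smoothing_s: float, seed: int, decode_fn=None):
        if model is not None and (
            len(model.unit_ids) != rpv_map.n_units
            or np.any(np.asarray(model.unit_ids) != np.asarray(rpv_map.unit_ids))
        ):
            raise ValueError("agent/model unit sets differ")
        self.rpv_map = rpv_map
        self.model = model
        self.agent_cfg = agent_cfg
        self.arena = arena
        self.rng = np.random.default_rng(seed)
        self.decode_fn = decode_fn
        self.sub = round(TICK_S / BASE_BIN_S)
        n_units = rpv_map.n_units
        self.window_bins = model.config.n_window_bins if model is not None else 15
        self.window = np.zeros((n_units, self.window_bins))
        self.smooth_w = max(round(smoothing_s / TICK_S), 1)
        self.smooth_buf: list[np.ndarray] = []
        self.base_counts: list[np.ndarray] = []
        self.decoded: list[np.ndarray] = []
        self.smoothed: list[np.ndarray] = []
        self.intended: list[np.ndarray] = []
        # random-walk policy state
        self.rw_pos = np.array([arena.side_cm / 2, arena.side_cm / 2])
        self.rw_heading = self.rng.uniform(0, 360)

    def intended_location(self, goal: np.ndarray, mover: np.ndarray) -> np.ndarray:
        policy = self.agent_cfg.policy
        if policy in ("toward_goal", "hold_goal"):
            return goal.copy()
        # reflected random walk, ~15 cm/s
        self.rw_heading += self.rng.normal(0, 40)
        step = 1.5
        d = step * np.array(
            [np.cos(np.radians(self.rw_heading)), np.sin(np.radians(self.rw_heading))]
        )
        self.rw_pos = np.clip(self.rw_pos + d, 1.0, self.arena.side_cm - 1.0)
        return self.rw_pos.copy()

    def tick(self, intended: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Emit spikes, decode, smooth; returns (decoded, smoothed)."""
        rates = intention_rates(self.rpv_map, intended, self.agent_cfg)
        counts10 = self.rng.poisson(
            np.tile(rates[:, None] * BASE_BIN_S, (1, self.sub))
        )
        self.base_counts.append(counts10)
        tick_counts = counts10.sum(axis=1)
        self.window = np.roll(self.window, -1, axis=1)
        self.window[:, -1] = tick_counts
        if self.decode_fn is not None:
            decoded = np.asarray(self.decode_fn(self.window, intended), float)
        else:
            decoded = self.model.estimator.predict(self.window[None])[0]
        decoded = np.clip(decoded, 0.0, self.arena.side_cm)
        self.smooth_buf.append(decoded)
        if len(self.smooth_buf) > self.smooth_w:
            self.smooth_buf.pop(0)
        smoothed = np.mean(self.smooth_buf, axis=0)
        self.decoded.append(decoded)
        self.smoothed.append(smoothed)
        self.intended.append(np.asarray(intended, float).copy())
        return decoded, smoothed

    def raster(self) -> SpikeRaster:
        counts = np.concatenate(self.base_counts, axis=1)
        return SpikeRaster(self.rpv_map.unit_ids, counts, bin_s=BASE_BIN_S)


def _place_goal(rng, arena, reference, min_dist, margin=None):
    # goal regions must lie fully inside the arena
    if margin is None:
        margin = arena.goal_radius_cm
    for _ in range(1000):
        g = rng.uniform(margin, arena.side_cm - margin, size=2)
        if np.linalg.norm(g - reference) >= min_dist:
            return g
    raise RuntimeError("could not place a goal at the required distance")


def run_jumper_session(
    rpv_map: PlaceFieldMap,
    model: DecoderModel,
    agent_cfg: IntentionAgentConfig,
    cfg: JumperConfig,
    arena: ArenaSpec,
    seed: int = 0,
    decode_fn=None,
) -> tuple[list[TrialLog], SpikeRaster, dict]:
    """Run the BMI navigation task.

    The avatar is updated from the 3-s-smoothed decoded stream (teleport
    by default, optionally rate-limited); a trial ends when the avatar
    enters the goal region or at the 62-s timeout, after which a new goal
    is placed uniformly at least ``min_goal_dist_cm`` away.
    """
    loop = _Loop(rpv_map, model, agent_cfg, arena, cfg.smoothing_s, seed,
                 decode_fn=decode_fn)
    rng = loop.rng
    avatar = np.array([arena.side_cm / 2, arena.side_cm / 2])
    avatars, goal_series = [], []
    trials: list[TrialLog] = []
    timeout_ticks = round(cfg.timeout_s / TICK_S)
    tick = 0
    for trial_id in range(cfg.n_trials):
        goal = _place_goal(rng, arena, avatar, cfg.min_goal_dist_cm)
        t_start = tick * TICK_S
        outcome = "timeout"
        for _ in range(timeout_ticks):
            intended = loop.intended_location(goal, avatar)
            _, smoothed = loop.tick(intended)
            if cfg.movement_rule == "teleport_to_smoothed":
                avatar = smoothed.copy()
            else:
                delta = smoothed - avatar
                dist = np.linalg.norm(delta)
                if dist > cfg.max_step_cm_per_tick:
                    delta *= cfg.max_step_cm_per_tick / dist
                avatar = avatar + delta
            avatars.append(avatar.copy())
            goal_series.append(goal.copy())
            tick += 1
            if np.linalg.norm(avatar - goal) <= cfg.goal_radius_cm:
                outcome = "reached"
                break
        trials.append(
            TrialLog(
                task="jumper",
                trial_id=trial_id,
                goal_xy=(float(goal[0]), float(goal[1])),
                t_start=t_start,
                t_end=tick * TICK_S,
                outcome=outcome,
                reward_ml=0.004 if outcome == "reached" else 0.0,
            )
        )
    streams = {
        "t": (np.arange(tick) + 1) * TICK_S,
        "decoded": np.array(loop.decoded),
        "smoothed": np.array(loop.smoothed),
        "avatar": np.array(avatars),
        "intended": np.array(loop.intended),
        "goal": np.array(goal_series),
    }
    return trials, loop.raster(), streams


def run_jedi_session(
    rpv_map: PlaceFieldMap,
    model: DecoderModel,
    agent_cfg: IntentionAgentConfig,
    cfg: JediConfig,
    arena: ArenaSpec,
    seed: int = 0,
    decode_fn=None,
) -> tuple[list[TrialLog], SpikeRaster, dict]:
    """Run the BMI object-control task.

    The animal is fixed at the arena center (free to rotate); the object
    tracks the 2-s-smoothed decoded stream.  Reward accrues at
    ``reward_rate_ml_s`` whenever the object touches the goal region; a
    trial ends at the reward cap or the 3-min limit, then a new goal
    appears at least ``min_goal_jump_cm`` away.
    """
    loop = _Loop(rpv_map, model, agent_cfg, arena, cfg.smoothing_s, seed,
                 decode_fn=decode_fn)
    rng = loop.rng
    center = np.array([arena.side_cm / 2, arena.side_cm / 2])
    goal = _place_goal(rng, arena, center, 0.0)
    trials: list[TrialLog] = []
    objects, goal_series, speeds, rotations = [], [], [], []
    heading = 0.0
    bout_left = 0
    limit_ticks = round(cfg.trial_limit_s / TICK_S)
    tick = 0
    for trial_id in range(cfg.n_trials):
        t_start = tick * TICK_S
        reward = 0.0
        outcome = "limit"
        for _ in range(limit_ticks):
            intended = loop.intended_location(goal, center)
            _, smoothed = loop.tick(intended)
            obj = smoothed
            objects.append(obj.copy())
            goal_series.append(goal.copy())
            # treadmill-motion emulation: mostly still, occasional bouts
            if bout_left == 0 and rng.random() < cfg.move_bout_rate_hz * TICK_S:
                bout_left = round(cfg.move_bout_s / TICK_S)
            speed = cfg.move_speed_cm_s if bout_left > 0 else 0.0
            bout_left = max(bout_left - 1, 0)
            speeds.append(speed)
            # heading relaxes toward the goal bearing, with noise
            bearing = np.degrees(np.arctan2(goal[1] - center[1], goal[0] - center[0]))
            err = (bearing - heading + 180) % 360 - 180
            dh = 0.2 * err + rng.normal(0, cfg.rotation_noise_deg_s * TICK_S)
            heading = (heading + dh) % 360
            rotations.append(dh / TICK_S)
            tick += 1
            if np.linalg.norm(obj - goal) <= cfg.goal_radius_cm:
                reward += cfg.reward_rate_ml_s * TICK_S
            if reward >= cfg.reward_cap_ml - 1e-12:
                outcome = "reward_cap"
                break
        trials.append(
            TrialLog(
                task="jedi",
                trial_id=trial_id,
                goal_xy=(float(goal[0]), float(goal[1])),
                t_start=t_start,
                t_end=tick * TICK_S,
                outcome=outcome,
                reward_ml=reward,
            )
        )
        goal = _place_goal(rng, arena, goal, cfg.min_goal_jump_cm)
    streams = {
        "t": (np.arange(tick) + 1) * TICK_S,
        "decoded": np.array(loop.decoded),
        "smoothed": np.array(loop.smoothed),
        "object": np.array(objects),
        "intended": np.array(loop.intended),
        "goal": np.array(goal_series),
        "speed": np.array(speeds),
        "rotation": np.array(rotations),
    }
    return trials, loop.raster(), streams
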