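"""Performance statistics and shuffle-based null distributions.

Two nulls establish the two claims of closed-loop control: shuffling
spike trains across unit identities destroys spatial specificity (decoded
trajectories no longer reach the goals quickly), and shuffling goal
locations while preserving the decoded trajectories destroys apparent
goal-directedness.  Empirical p-values use the add-one rule and are never
zero; a normal-approximation p (from the shuffle mean/SD) is reported
alongside, since extremely small tail probabilities are not resolvable
empirically at a few hundred shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import SpikeRaster, TICK_S, TrialLog
from .decoding import DecoderModel, decode_stream
from .closed_loop import JumperConfig, smooth_positions


@dataclass
class NullDistribution:
    """A shuffle null with observed statistic and both p-values."""

    statistic_name: str
    observed: float
    shuffled_values: np.ndarray
    tail: str  # 'lower': small observed is extreme; 'upper': large is
    seed: int
    p_empirical: float = 0.0
    p_normal: float = 0.0

    def __post_init__(self):
        self.shuffled_values = np.asarray(self.shuffled_values, float)
        n = len(self.shuffled_values)
        if self.tail == "lower":
            k = int(np.sum(self.shuffled_values <= self.observed))
        elif self.tail == "upper":
            k = int(np.sum(self.shuffled_values >= self.observed))
        else:
            raise ValueError("tail must be 'lower' or 'upper'")
        self.p_empirical = (1 + k) / (1 + n)
        mu, sd = self.shuffled_values.mean(), self.shuffled_values.std(ddof=1)
        if sd == 0:
            self.p_normal = 1.0 if (
                (self.tail == "lower" and self.observed >= mu)
                or (self.tail == "upper" and self.observed <= mu)
            ) else 0.0
        else:
            z = (self.observed - mu) / sd
            self.p_normal = float(
                sps.norm.cdf(z) if self.tail == "lower" else sps.norm.sf(z)
            )

    @property
    def n_shuffles(self) -> int:
        return len(self.shuffled_values)


def shuffle_unit_identities(
    raster: SpikeRaster, seed: int = 0, permutation: np.ndarray | None = None
) -> SpikeRaster:
    """Reassign whole spike trains to unit identities by a uniform random
    permutation; the per-bin population sum is invariant."""
    if raster.n_units < 2:
        raise ValueError("need >= 2 units to shuffle")
    if permutation is None:
        permutation = np.random.default_rng(seed).permutation(raster.n_units)
    return SpikeRaster(
        raster.unit_ids, raster.counts[permutation], raster.bin_s, raster.t0
    )


def replay_time_to_goals(
    positions: np.ndarray,
    goals: np.ndarray,
    goal_radius_cm: float,
    timeout_s: float,
) -> np.ndarray:
    """Offline replay of a position stream against a goal sequence.

    Starting at the stream head, find the first entry into goal 1's
    region; continue from there for goal 2, and so on.  Each goal is
    censored at ``timeout_s``; goals unreachable within the remaining
    stream are likewise scored as the timeout.  Returns per-goal
    durations (s).
    """
    positions = np.asarray(positions, float)
    timeout_ticks = round(timeout_s / TICK_S)
    durations = []
    ptr = 0
    n = len(positions)
    for goal in np.asarray(goals, float):
        end = min(ptr + timeout_ticks, n)
        if ptr >= n:
            durations.append(timeout_s)
            continue
        d = np.linalg.norm(positions[ptr:end] - goal, axis=1)
        hits = np.flatnonzero(d <= goal_radius_cm)
        if len(hits):
            durations.append((hits[0] + 1) * TICK_S)
            ptr += hits[0] + 1
        else:
            durations.append(timeout_s)
            ptr += timeout_ticks
    return np.array(durations)


def unit_shuffle_duration_null(
    raster: SpikeRaster,
    model: DecoderModel,
    goals: np.ndarray,
    jumper_cfg: JumperConfig,
    n_shuffles: int = 200,
    seed: int = 0,
    observed_mean_duration_s: float | None = None,
) -> NullDistribution:
    """Spatial-specificity null: decode unit-shuffled spikes, replay the
    Jumper kinematics offline against the original goal sequence, and
    compare the mean time-to-goal with the actual session.

    ``observed_mean_duration_s`` is the actual mean trial duration of the
    closed-loop session; when omitted it is recomputed by replaying the
    unshuffled decode through the same offline kinematics.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(goals) == 0:
        raise ValueError("empty goal list")
    rng = np.random.default_rng(seed)

    def mean_duration(r: SpikeRaster) -> float:
        _, decoded = decode_stream(model, r)
        smoothed = smooth_positions(decoded, jumper_cfg.smoothing_s)
        durs = replay_time_to_goals(
            smoothed, goals, jumper_cfg.goal_radius_cm, jumper_cfg.timeout_s
        )
        return float(durs.mean())

    observed = (
        observed_mean_duration_s
        if observed_mean_duration_s is not None
        else mean_duration(raster)
    )
    shuffled = np.array(
        [
            mean_duration(
                shuffle_unit_identities(raster, permutation=rng.permutation(raster.n_units))
            )
            for _ in range(n_shuffles)
        ]
    )
    return NullDistribution(
        "mean_trial_duration_s", observed, shuffled, tail="lower", seed=seed
    )


def shuffle_goals_null(
    paths: list[np.ndarray],
    goals: np.ndarray,
    goal_sampler,
    metric: str = "time_to_reach",
    n_shuffles: int = 200,
    goal_radius_cm: float = 10.0,
    seed: int = 0,
) -> NullDistribution:
    """Goal-directedness null: re-score the preserved per-trial decoded
    trajectories against freshly sampled goals.

    ``goal_sampler(rng, previous_goal)`` must respect the task's
    goal-placement constraints (otherwise the null is too easy).  Metrics:
    ``time_to_reach`` (first entry into the goal region, censored at the
    trial length) or ``mean_distance`` (time-average distance to goal).
    """
    if len(paths) == 0:
        raise ValueError("empty path list")
    if metric not in ("time_to_reach", "mean_distance"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    goals = np.asarray(goals, float)

    def score(goal_list) -> float:
        vals = []
        for path, goal in zip(paths, goal_list):
            d = np.linalg.norm(np.asarray(path) - np.asarray(goal), axis=1)
            if metric == "time_to_reach":
                hits = np.flatnonzero(d <= goal_radius_cm)
                vals.append(
                    (hits[0] + 1) * TICK_S if len(hits) else len(d) * TICK_S
                )
            else:
                vals.append(d.mean())
        return float(np.mean(vals))

    observed = score(goals)
    shuffled = []
    for _ in range(n_shuffles):
        prev = None
        draw = []
        for _ in paths:
            g = goal_sampler(rng, prev)
            draw.append(g)
            prev = g
        shuffled.append(score(draw))
    return NullDistribution(metric, observed, np.array(shuffled), tail="lower",
                            seed=seed)


def arena_uniform_goal_sampler(arena, min_dist_cm: float = 0.0,
                               margin: float | None = None):
    """Uniform goal sampler honoring a minimum jump from the previous goal.

    The margin (default: the arena's goal radius, matching task goal
    placement) keeps sampled goal regions fully inside the arena so the
    null draws from the same space as the true goals.
    """
    if margin is None:
        margin = arena.goal_radius_cm

    def sample(rng: np.random.Generator, prev):
        for _ in range(1000):
            g = rng.uniform(margin, arena.side_cm - margin, size=2)
            if prev is None or np.linalg.norm(g - np.asarray(prev)) >= min_dist_cm:
                return g
        raise RuntimeError("goal sampling failed")

    return sample


def angle_to_goal_histogram(
    path: np.ndarray,
    goals: np.ndarray,
    bin_deg: float = 15.0,
    min_step_cm: float = 0.5,
) -> dict:
    """Signed angles between instantaneous movement direction and the
    direction to the goal, for steps with displacement >= ``min_step_cm``.

    Angles are wrapped to (-180, 180]; the histogram is normalised to a
    probability distribution and the circular mean and resultant length
    are reported.
    """
    path = np.asarray(path, float)
    goals = np.asarray(goals, float)
    if goals.ndim == 1:
        goals = np.tile(goals, (len(path), 1))
    steps = np.diff(path, axis=0)
    disp = np.linalg.norm(steps, axis=1)
    keep = disp >= min_step_cm
    if not keep.any():
        import warnings

        warnings.warn("no steps above min_step_cm; empty histogram")
        return {
            "angles_deg": np.empty(0),
            "bin_edges_deg": np.arange(-180, 180 + bin_deg, bin_deg),
            "probability": np.zeros(int(round(360 / bin_deg))),
            "circular_mean_deg": np.nan,
            "resultant_length": np.nan,
            "mode_deg": np.nan,
        }
    move_bearing = np.degrees(np.arctan2(steps[keep, 1], steps[keep, 0]))
    to_goal = goals[:-1][keep] - path[:-1][keep]
    goal_bearing = np.degrees(np.arctan2(to_goal[:, 1], to_goal[:, 0]))
    ang = move_bearing - goal_bearing
    ang = -((-ang + 180.0) % 360.0 - 180.0)  # wrap to (-180, 180]
    edges = np.arange(-180, 180 + bin_deg, bin_deg)
    hist, _ = np.histogram(ang, bins=edges)
    prob = hist / hist.sum()
    rad = np.radians(ang)
    resultant = np.mean(np.exp(1j * rad))
    mode_bin = int(np.argmax(prob))
    return {
        "angles_deg": ang,
        "bin_edges_deg": edges,
        "probability": prob,
        "circular_mean_deg": float(np.degrees(np.angle(resultant))),
        "resultant_length": float(np.abs(resultant)),
        "mode_deg": float((edges[mode_bin] + edges[mode_bin + 1]) / 2),
    }


def mean_goal_distance(
    decoded: np.ndarray,
    goal: np.ndarray,
    rotation_deg_s: np.ndarray | None = None,
    exclude_above_deg_s: float = 12.0,
) -> dict:
    """Time-average distance of decoded locations to the goal, excluding
    samples where the body rotated faster than ``exclude_above_deg_s``."""
    decoded = np.asarray(decoded, float)
    goal = np.asarray(goal, float)
    if goal.ndim == 1:
        goal = np.tile(goal, (len(decoded), 1))
    keep = np.ones(len(decoded), bool)
    if rotation_deg_s is not None:
        keep = np.abs(np.asarray(rotation_deg_s, float)) <= exclude_above_deg_s
    if not keep.any():
        raise ValueError("all samples excluded by the rotation criterion")
    d = np.linalg.norm(decoded[keep] - goal[keep], axis=1)
    return {
        "mean_distance_cm": float(d.mean()),
        "retained_fraction": float(keep.mean()),
    }


def trial_duration_summary(trial_logs: list[TrialLog]) -> dict:
    """Per-task mean/median trial durations and reached fraction."""
    if not trial_logs:
        raise ValueError("no trials")
    out: dict[str, dict] = {}
    for task in sorted({t.task for t in trial_logs}):
        trs = [t for t in trial_logs if t.task == task]
        durs = np.array([t.duration_s for t in trs])
        reached = np.array([t.outcome in ("reached", "reward_cap") for t in trs])
        censored = np.array([t.outcome in ("timeout", "limit") for t in trs])
        out[task] = {
            "n_trials": len(trs),
            "mean_duration_s": float(durs.mean()),
            "median_duration_s": float(np.median(durs)),
            "reached_fraction": float(reached.mean()),
            "censored_fraction": float(censored.mean()),
        }
    return out
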