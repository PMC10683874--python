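"""Synthetic inputs for the closed-loop BMI pipeline.

Everything the analysis consumes can be generated here: a place-cell
ensemble with isotropic Gaussian tuning, goal-directed running sessions
(trajectory + inhomogeneous-Poisson spikes + LFP), the intention agent
that stands in for the animal during closed-loop control, and a
phenomenological theta-band LFP.

The intention agent emits population activity as a convex blend between
the reference population vector (rPV) of an intended location and the
unit's session-mean rate; its single ``fidelity`` knob sweeps the agent
from chance-level (0) to ideal rPV reproduction (1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ArenaSpec, LfpTrace, SpikeRaster, TICK_S, Trajectory, TrialLog

logger = logging.getLogger(__name__)

BASE_BIN_S = 0.01  # raster base bin (10 ms); decoders aggregate to 100 ms


class StallError(RuntimeError):
    """Raised when a simulated trial cannot reach its goal."""


@dataclass(frozen=True)
class PlaceCellEnsemble:
    """Population of units with isotropic 2-D Gaussian place fields.

    Unit ``i`` fires at ``baseline_i + peak_i * exp(-||xy - c_i||^2 / (2 s_i^2))``.
    """

    arena: ArenaSpec
    centers: np.ndarray  # (n_units, 2) cm
    sigmas: np.ndarray  # (n_units,) cm
    peak_rates: np.ndarray  # (n_units,) Hz
    baseline_rates: np.ndarray  # (n_units,) Hz
    seed: int = 0

    def __post_init__(self):
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be positive")
        if np.any(self.baseline_rates < 0) or np.any(
            self.peak_rates <= self.baseline_rates
        ):
            raise ValueError("need peak_rates > baseline_rates >= 0")
        if not np.all(self.arena.contains(self.centers)):
            raise ValueError("field centers must lie inside the arena")

    @property
    def n_units(self) -> int:
        return len(self.sigmas)

    @property
    def unit_ids(self) -> np.ndarray:
        return np.arange(self.n_units)


def make_ensemble(
    arena: ArenaSpec,
    n_units: int,
    sigma_range: tuple[float, float] = (8.0, 15.0),
    peak_range: tuple[float, float] = (10.0, 20.0),
    baseline_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> PlaceCellEnsemble:
    """Draw an ensemble with uniformly scattered field centers.

    Per-unit sigma/peak/baseline are drawn uniformly from the given ranges.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    for name, (lo, hi) in (
        ("sigma_range", sigma_range),
        ("peak_range", peak_range),
    ):
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid {name}: {(lo, hi)}")
    if baseline_range[0] < 0 or baseline_range[1] < baseline_range[0]:
        raise ValueError(f"invalid baseline_range: {baseline_range}")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, arena.side_cm, size=(n_units, 2))
    sigmas = rng.uniform(*sigma_range, size=n_units)
    peaks = rng.uniform(*peak_range, size=n_units)
    baselines = rng.uniform(*baseline_range, size=n_units)
    return PlaceCellEnsemble(arena, centers, sigmas, peaks, baselines, seed=seed)


def tuning_rate(ensemble: PlaceCellEnsemble, xy) -> np.ndarray:
    """Per-unit firing rate (Hz) at position(s) ``xy``.

    ``xy`` may be one position (2,) or a batch (n, 2); the result has a
    matching leading dimension.
    """
    xy = np.asarray(xy, float)
    single = xy.ndim == 1
    pts = xy[None, :] if single else xy
    if not np.all(ensemble.arena.contains(pts)):
        raise ValueError("position outside arena")
    d2 = ((pts[:, None, :] - ensemble.centers[None, :, :]) ** 2).sum(axis=2)
    rates = ensemble.baseline_rates + ensemble.peak_rates * np.exp(
        -d2 / (2 * ensemble.sigmas**2)
    )
    return rates[0] if single else rates


@dataclass(frozen=True)
class RunParams:
    """Kinematics of the simulated Running task."""

    speed_mean_cm_s: float = 15.0
    speed_sd_cm_s: float = 4.0
    heading_noise_deg: float = 20.0  # SD of heading perturbation per tick
    turn_gain: float = 0.5  # fraction of bearing error corrected per tick
    min_goal_dist_cm: float = 30.0
    dwell_s: float = 2.0  # immobile pause at each reached goal
    max_steps_per_trial: int = 5000


def _wrap_deg(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def poisson_spikes_from_rates(
    rates_tick: np.ndarray, rng: np.random.Generator, bin_s: float = BASE_BIN_S
) -> np.ndarray:
    """Inhomogeneous-Poisson counts at the base bin from per-tick rates.

    ``rates_tick`` is (n_units, n_ticks) in Hz, piecewise constant over each
    0.1-s tick; output is (n_units, n_ticks * ticks_per_bin) counts.
    """
    sub = round(TICK_S / bin_s)
    lam = np.repeat(rates_tick * bin_s, sub, axis=1)
    return rng.poisson(lam)


def simulate_running_session(
    arena: ArenaSpec,
    ensemble: PlaceCellEnsemble,
    n_trials: int,
    run_params: RunParams | None = None,
    seed: int = 0,
    with_lfp: bool = True,
) -> tuple[Trajectory, SpikeRaster, list[TrialLog], LfpTrace | None]:
    """Simulate the Running task: goal-directed travel to successive cues.

    Each trial places a goal uniformly at random at least
    ``min_goal_dist_cm`` from the current position; the agent turns toward
    it with noisy heading and Ornstein-Uhlenbeck speed until inside the
    goal region, then dwells immobile for ``dwell_s`` (reward pause).
    Spikes are inhomogeneous Poisson driven by the ensemble tuning at the
    current position.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    p = run_params or RunParams()
    rng = np.random.default_rng(seed)

    pos = np.array([arena.side_cm / 2, arena.side_cm / 2])
    heading = 0.0
    xs, heads, speeds, rots = [], [], [], []
    trials: list[TrialLog] = []
    dwell_ticks = round(p.dwell_s / TICK_S)
    margin = 1.0  # keep the agent off the exact wall

    tick = 0
    for trial_id in range(n_trials):
        # place a goal at least min_goal_dist from the current position,
        # with its goal region fully inside the arena
        gm = arena.goal_radius_cm
        for _ in range(1000):
            goal = rng.uniform(gm, arena.side_cm - gm, size=2)
            if np.linalg.norm(goal - pos) >= p.min_goal_dist_cm:
                break
        else:  # pragma: no cover - essentially impossible with defaults
            raise StallError("could not place a goal satisfying min distance")
        t_start = tick * TICK_S
        speed = max(p.speed_mean_cm_s, 0.0)
        steps = 0
        while np.linalg.norm(goal - pos) > arena.goal_radius_cm:
            steps += 1
            if steps > p.max_steps_per_trial:
                raise StallError(
                    f"trial {trial_id} exceeded {p.max_steps_per_trial} steps"
                )
            bearing = np.degrees(np.arctan2(goal[1] - pos[1], goal[0] - pos[0]))
            turn = p.turn_gain * _wrap_deg(bearing - heading)
            if p.heading_noise_deg > 0:
                turn += rng.normal(0, p.heading_noise_deg)
            new_heading = (heading + turn) % 360.0
            rot = _wrap_deg(new_heading - heading) / TICK_S
            heading = new_heading
            if p.speed_sd_cm_s > 0:
                speed += 0.3 * (p.speed_mean_cm_s - speed) + rng.normal(
                    0, p.speed_sd_cm_s
                )
                speed = max(speed, 0.0)
            if speed <= 0 and p.speed_sd_cm_s == 0:
                raise StallError("zero speed with no variability: unreachable goal")
            step = speed * TICK_S
            pos = pos + step * np.array(
                [np.cos(np.radians(heading)), np.sin(np.radians(heading))]
            )
            pos = np.clip(pos, margin, arena.side_cm - margin)
            xs.append(pos.copy())
            heads.append(heading)
            speeds.append(speed)
            rots.append(rot)
            tick += 1
        # reward dwell: immobile at the goal
        for _ in range(dwell_ticks):
            xs.append(pos.copy())
            heads.append(heading)
            speeds.append(0.0)
            rots.append(0.0)
            tick += 1
        trials.append(
            TrialLog(
                task="running",
                trial_id=trial_id,
                goal_xy=(float(goal[0]), float(goal[1])),
                t_start=t_start,
                t_end=tick * TICK_S,
                outcome="reached",
                reward_ml=0.004,
            )
        )

    xy = np.array(xs)
    n_ticks = len(xy)
    traj = Trajectory(
        t=np.arange(n_ticks) * TICK_S,
        xy=xy,
        heading_deg=np.array(heads) % 360.0,
        speed_cm_s=np.array(speeds),
        rotation_deg_s=np.array(rots),
    )
    rates = tuning_rate(ensemble, xy).T  # (units, ticks)
    counts = poisson_spikes_from_rates(rates, rng)
    raster = SpikeRaster(ensemble.unit_ids, counts, bin_s=BASE_BIN_S)
    lfp = simulate_lfp(traj.speed_cm_s, seed=int(rng.integers(2**31))) if with_lfp else None
    return traj, raster, trials, lfp


@dataclass(frozen=True)
class IntentionAgentConfig:
    """The simulated stand-in for the animal's volitional activity.

    Emission rate per unit is a convex blend
    ``fidelity * rate_gain * rPV_i(intended) + (1 - fidelity) * mean_rate_i
    + noise_floor_hz``; ``fidelity`` sweeps the agent from chance (0) to an
    ideal rPV reproduction (1).
    """

    fidelity: float = 1.0
    rate_gain: float = 1.0
    noise_floor_hz: float = 0.0
    policy: str = "toward_goal"  # toward_goal | hold_goal | random_walk
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.fidelity <= 1):
            raise ValueError("fidelity must be in [0, 1]")
        if self.rate_gain <= 0:
            raise ValueError("rate_gain must be positive")
        if self.noise_floor_hz < 0:
            raise ValueError("noise_floor_hz must be nonnegative")
        if self.policy not in ("toward_goal", "hold_goal", "random_walk"):
            raise ValueError(f"unknown policy {self.policy!r}")


def intention_rates(rpv_map, intended_xy, cfg: IntentionAgentConfig) -> np.ndarray:
    """Per-unit emission rate (Hz) for an intended location (no sampling)."""
    target = rpv_map.rate_at(intended_xy)
    mean_rates = rpv_map.session_mean_rates()
    return (
        cfg.fidelity * cfg.rate_gain * target
        + (1.0 - cfg.fidelity) * mean_rates
        + cfg.noise_floor_hz
    )


def intention_pv(
    rpv_map,
    intended_xy,
    cfg: IntentionAgentConfig,
    duration_s: float,
    seed: int = 0,
) -> SpikeRaster:
    """Emit a Poisson spike-raster segment for one intended location."""
    if not np.all(rpv_map.arena.contains(np.asarray(intended_xy, float))):
        raise ValueError("intended position outside arena")
    rng = np.random.default_rng(seed)
    rates = intention_rates(rpv_map, intended_xy, cfg)
    n_bins = round(duration_s / BASE_BIN_S)
    lam = np.tile(rates[:, None] * BASE_BIN_S, (1, n_bins))
    return SpikeRaster(rpv_map.unit_ids, rng.poisson(lam), bin_s=BASE_BIN_S)


@dataclass(frozen=True)
class LfpNoiseParams:
    """Background-noise settings for the synthetic LFP."""

    pink_amp: float = 0.5  # 1/f background amplitude (a.u.)
    theta_amp: float = 1.0
    still_duty: float = 0.6  # fraction of still time with theta present
    bout_s: float = 1.5  # mean bout length of intermittent still theta


def simulate_lfp(
    speed_trace: np.ndarray,
    theta_move_hz: float = 7.3,
    theta_still_hz: float = 6.3,
    band: tuple[float, float] = (5.0, 12.0),
    noise_params: LfpNoiseParams | None = None,
    seed: int = 0,
    fs: float = 1000.0,
    move_threshold_cm_s: float = 2.0,
) -> LfpTrace:
    """Phenomenological LFP: speed-dependent theta plus 1/f background.

    The instantaneous theta frequency is ``theta_move_hz`` whenever the
    0.1-s-grid speed exceeds the movement threshold and ``theta_still_hz``
    otherwise; during stillness theta is intermittent (random bouts).
    """
    if band[1] >= fs / 2:
        raise ValueError("band exceeds Nyquist frequency")
    np_ = noise_params or LfpNoiseParams()
    rng = np.random.default_rng(seed)
    speed = np.asarray(speed_trace, float)
    sub = round(fs * TICK_S)
    moving = np.repeat(speed > move_threshold_cm_s, sub)
    n = len(moving)
    freq = np.where(moving, theta_move_hz, theta_still_hz)
    phase = 2 * np.pi * np.cumsum(freq) / fs
    theta = np_.theta_amp * np.sin(phase)
    # intermittent theta during stillness: random on/off bouts
    if np_.still_duty < 1.0 and np.any(~moving):
        bout = max(round(np_.bout_s * fs), 1)
        gate_coarse = rng.random(n // bout + 1) < np_.still_duty
        gate = np.repeat(gate_coarse, bout)[:n]
        amp = np.where(moving, 1.0, gate.astype(float))
        theta = theta * amp
    if np_.pink_amp > 0:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1 / fs)
        scale = np.zeros_like(f)
        scale[1:] = 1.0 / np.sqrt(f[1:])
        pink = np.fft.irfft(spec * scale, n)
        pink *= np_.pink_amp / (pink.std() + 1e-12)
        theta = theta + pink
    return LfpTrace(fs=fs, values=theta)
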