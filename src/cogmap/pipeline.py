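"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` drives the three-phase experiment: simulate
the Running task, train the decoder on its spikes and trajectory, run the
closed-loop Jumper and Jedi tasks with the intention agent, then compute
the full analysis battery (shuffle nulls, angle histogram, PV-rPV
profile, PBE detection, LFP theta peaks, noise-robustness benchmark).
All randomness derives from one master seed via stable per-stage hashes,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import closed_loop, decoding, lfp as lfp_mod, population, stats, synth
from .core import ArenaSpec, derive_seed, trial_logs_to_frame

SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    """Everything needed for one full simulated experiment."""

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    n_units: int = 100
    n_running_trials: int = 120
    run_params: synth.RunParams = field(default_factory=synth.RunParams)
    decoder: decoding.DecoderConfig = field(default_factory=decoding.DecoderConfig)
    jumper: closed_loop.JumperConfig = field(default_factory=closed_loop.JumperConfig)
    jedi: closed_loop.JediConfig = field(default_factory=closed_loop.JediConfig)
    agent: synth.IntentionAgentConfig = field(
        default_factory=synth.IntentionAgentConfig
    )
    n_shuffles: int = 200
    pv_windows: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0)
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = {}
        nested = {
            "arena": ArenaSpec,
            "run_params": synth.RunParams,
            "decoder": decoding.DecoderConfig,
            "jumper": closed_loop.JumperConfig,
            "jedi": closed_loop.JediConfig,
            "agent": synth.IntentionAgentConfig,
        }
        for key, val in raw.items():
            if key in nested:
                if key == "decoder" and "augmentation" in val:
                    val = dict(val)
                    val["augmentation"] = decoding.AugmentationConfig(
                        **val["augmentation"]
                    )
                kwargs[key] = nested[key](**val)
            elif key == "pv_windows":
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_experiment(config: ExperimentConfig, out_dir=None, plots: bool = False) -> dict:
    """Execute phases 1-3 and the analyses; return (and optionally write)
    the machine-readable summary."""
    cfg = config
    arena = cfg.arena
    summary: dict = {"schema_version": SCHEMA_VERSION, "config": cfg.to_dict()}

    # phase 1: Running task
    ensemble = synth.make_ensemble(arena, cfg.n_units, seed=cfg.stage_seed("ensemble"))
    traj, raster, run_trials, run_lfp = synth.simulate_running_session(
        arena, ensemble, cfg.n_running_trials, cfg.run_params,
        seed=cfg.stage_seed("running"),
    )
    rpv = population.compute_rpv_map(raster, traj, arena)

    # phase 2: decoder training
    windows, _, targets = decoding.make_training_windows(raster, traj, cfg.decoder)
    model = decoding.train_decoder(
        windows, targets, cfg.decoder, arena,
        unit_ids=ensemble.unit_ids, seed=cfg.stage_seed("train"),
    )
    summary["decoder"] = {
        "validation_r2": model.validation_r2.tolist(),
        "median_error_cm": model.median_error_cm,
        "n_windows": int(len(windows)),
    }

    # phase 3: closed-loop tasks
    jp_trials, jp_raster, jp_streams = closed_loop.run_jumper_session(
        rpv, model, cfg.agent, cfg.jumper, arena, seed=cfg.stage_seed("jumper")
    )
    jedi_agent = dataclasses.replace(cfg.agent, policy="hold_goal")
    jd_trials, jd_raster, jd_streams = closed_loop.run_jedi_session(
        rpv, model, jedi_agent, cfg.jedi, arena, seed=cfg.stage_seed("jedi")
    )
    summary["trials"] = stats.trial_duration_summary(
        run_trials + jp_trials + jd_trials
    )

    # analyses
    goals = np.array([t.goal_xy for t in jp_trials])
    null_units = stats.unit_shuffle_duration_null(
        jp_raster, model, goals, cfg.jumper,
        n_shuffles=cfg.n_shuffles, seed=cfg.stage_seed("unit-shuffle"),
    )
    jd_paths, jd_goals = [], []
    for t in jd_trials:
        i0 = round(t.t_start / 0.1)
        i1 = round(t.t_end / 0.1)
        jd_paths.append(jd_streams["decoded"][i0:i1])
        jd_goals.append(t.goal_xy)
    null_goals = stats.shuffle_goals_null(
        jd_paths, np.array(jd_goals),
        stats.arena_uniform_goal_sampler(arena, cfg.jedi.min_goal_jump_cm),
        metric="mean_distance", n_shuffles=cfg.n_shuffles,
        goal_radius_cm=cfg.jedi.goal_radius_cm,
        seed=cfg.stage_seed("goal-shuffle"),
    )
    for name, null in (("unit_shuffle", null_units), ("goal_shuffle", null_goals)):
        summary[name] = {
            "observed": null.observed,
            "null_mean": float(null.shuffled_values.mean()),
            "p_empirical": null.p_empirical,
            "p_normal": null.p_normal,
            "n_shuffles": null.n_shuffles,
        }

    ang = stats.angle_to_goal_histogram(jp_streams["avatar"], jp_streams["goal"])
    summary["angle_to_goal"] = {
        "circular_mean_deg": ang["circular_mean_deg"],
        "resultant_length": ang["resultant_length"],
        "mode_deg": ang["mode_deg"],
    }

    dist = stats.mean_goal_distance(
        jd_streams["decoded"], jd_streams["goal"], jd_streams["rotation"]
    )
    summary["jedi_mean_goal_distance"] = dist

    pv = population.pv_rpv_correlation_profile(
        jd_raster, jd_streams["decoded"], rpv, windows=cfg.pv_windows,
        seed=cfg.stage_seed("pvcorr"),
    )
    summary["pv_rpv"] = _jsonable(pv)

    pbes = population.detect_pbes(jd_raster, jd_streams["speed"])
    summary["pbes"] = {"n_events": len(pbes)}

    robust = decoding.noise_robustness_curve(
        model, rpv, seed=cfg.stage_seed("robustness")
    )
    summary["noise_robustness"] = robust

    still = lfp_mod.segment_immobility(jd_streams["speed"])
    jd_lfp = synth.simulate_lfp(jd_streams["speed"], seed=cfg.stage_seed("jedi-lfp"))
    move = lfp_mod.movement_segments(traj.speed_cm_s)
    summary["theta"] = {}
    if move:
        summary["theta"]["move_peak_hz"] = lfp_mod.psd_theta_peak(
            run_lfp, move
        ).peak_hz
    if still:
        summary["theta"]["still_peak_hz"] = lfp_mod.psd_theta_peak(
            jd_lfp, still
        ).peak_hz
        summary["theta"]["n_still_segments"] = len(still)

    summary = _jsonable(summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, sort_keys=True)
        trial_logs_to_frame(run_trials + jp_trials + jd_trials).to_csv(
            out / "trials.csv", index=False
        )
        traj.to_csv(out / "running_trajectory.csv")
        if plots:
            _write_plots(out, jp_streams, jd_streams, ang, pv, robust)
    return summary


def _write_plots(out: Path, jp_streams, jd_streams, ang, pv, robust) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    axes[0, 0].plot(*jp_streams["avatar"].T, lw=0.5)
    axes[0, 0].set_title("Jumper BMI trajectories")
    centers = (ang["bin_edges_deg"][:-1] + ang["bin_edges_deg"][1:]) / 2
    axes[0, 1].bar(centers, ang["probability"], width=14)
    axes[0, 1].set_title("angle to goal (deg)")
    w = pv["windows"]
    axes[1, 0].errorbar(w, [m["mean"] for m in pv["matched"]], label="matched")
    axes[1, 0].errorbar(w, [m["mean"] for m in pv["random"]], label="random")
    axes[1, 0].set_title("PV-rPV correlation vs window (s)")
    axes[1, 0].legend()
    axes[1, 1].plot(robust["noise_levels"], robust["regressor_cm"], "-o",
                    label="regressor")
    axes[1, 1].plot(robust["noise_levels"], robust["bayesian_cm"], "-s",
                    label="Bayesian")
    axes[1, 1].set_title("probe decoding error vs noise")
    axes[1, 1].legend()
    fig.tight_layout()
    fig.savefig(out / "report.png", dpi=110)
    plt.close(fig)


def make_fixture(size: str = "tiny", seed: int = 0) -> dict:
    """Self-contained session bundles for tests and examples.

    tiny: 10 units, ~2 min of Running (fast unit tests); small: 80 units,
    ~40 min (integration scale).
    """
    if size == "tiny":
        n_units, n_trials = 10, 14
    elif size == "small":
        n_units, n_trials = 100, 430
    else:
        raise ValueError("size must be 'tiny' or 'small'")
    arena = ArenaSpec()
    ensemble = synth.make_ensemble(arena, n_units, seed=derive_seed(seed, "ensemble"))
    traj, raster, trials, lfp_trace = synth.simulate_running_session(
        arena, ensemble, n_trials, seed=derive_seed(seed, "running")
    )
    return {
        "arena": arena,
        "ensemble": ensemble,
        "trajectory": traj,
        "raster": raster,
        "trials": trials,
        "lfp": lfp_trace,
    }
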