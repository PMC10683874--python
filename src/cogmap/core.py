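"""Core containers for the closed-loop place-cell BMI pipeline.

All time series live on a uniform grid: spike rasters at a fine base bin
(10 ms by default) and behavioral/decoded streams at the 100-ms control
cadence of the interface.  Positions are in centimetres in a square arena
whose origin is the lower-left corner, x rightward, y upward.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

TICK_S = 0.1  # control/behavior sampling interval (s)


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from a master seed.

    seed = blake2s(f"{master_seed}:{stage}") truncated to 31 bits, so every
    pipeline stage gets an independent, reproducible generator.
    """
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class ArenaSpec:
    """Square virtual arena with a uniform spatial binning.

    Parameters
    ----------
    side_cm : float
        Side length of the square arena.
    spatial_bin_cm : float
        Width of the square spatial bins used for rate maps; must divide
        ``side_cm`` into an integer number (>= 4) of bins.
    goal_radius_cm : float
        Radius of the circular goal region around a goal cue.
    """

    side_cm: float = 100.0
    spatial_bin_cm: float = 5.0
    goal_radius_cm: float = 10.0

    def __post_init__(self):
        if self.side_cm <= 0 or self.spatial_bin_cm <= 0:
            raise ValueError("side_cm and spatial_bin_cm must be positive")
        n = self.side_cm / self.spatial_bin_cm
        if abs(n - round(n)) > 1e-9 or round(n) < 4:
            raise ValueError("side_cm / spatial_bin_cm must be an integer >= 4")
        if not (0 < self.goal_radius_cm < self.side_cm / 2):
            raise ValueError("goal_radius_cm must be in (0, side_cm / 2)")

    @property
    def n_bins_side(self) -> int:
        return round(self.side_cm / self.spatial_bin_cm)

    @property
    def n_bins(self) -> int:
        return self.n_bins_side**2

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        return np.all((xy >= 0) & (xy <= self.side_cm), axis=-1)

    def bin_index(self, xy: np.ndarray) -> np.ndarray:
        """Row-major flat bin index for positions; edge positions clip inward."""
        xy = np.asarray(xy, float)
        ij = np.clip(
            (xy / self.spatial_bin_cm).astype(int), 0, self.n_bins_side - 1
        )
        # row-major over (iy, ix) so index = iy * n + ix
        return ij[..., 1] * self.n_bins_side + ij[..., 0]

    def bin_centers(self) -> np.ndarray:
        """(n_bins, 2) array of bin-center coordinates, row-major (y outer)."""
        c = (np.arange(self.n_bins_side) + 0.5) * self.spatial_bin_cm
        gx, gy = np.meshgrid(c, c)  # gy varies along rows
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class Trajectory:
    """Behavioral streams on the 0.1-s grid.

    ``xy`` holds positions (cm), ``heading_deg`` the facing direction in
    [0, 360), ``speed_cm_s`` the treadmill speed and ``rotation_deg_s`` the
    body rotation rate.
    """

    t: np.ndarray
    xy: np.ndarray
    heading_deg: np.ndarray
    speed_cm_s: np.ndarray
    rotation_deg_s: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.xy = np.asarray(self.xy, float)
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if not np.allclose(steps, TICK_S, atol=1e-9):
                raise ValueError("trajectory must be on a uniform 0.1-s grid")
        for name in ("heading_deg", "speed_cm_s", "rotation_deg_s"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite positions")

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t_s": self.t,
                "x_cm": self.xy[:, 0],
                "y_cm": self.xy[:, 1],
                "heading_deg": self.heading_deg,
                "speed_cm_s": self.speed_cm_s,
                "rotation_deg_s": self.rotation_deg_s,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            t=df["t_s"].to_numpy(),
            xy=df[["x_cm", "y_cm"]].to_numpy(),
            heading_deg=df["heading_deg"].to_numpy(),
            speed_cm_s=df["speed_cm_s"].to_numpy(),
            rotation_deg_s=df["rotation_deg_s"].to_numpy(),
        )


@dataclass
class SpikeRaster:
    """Units x time-bins spike-count matrix at a fixed bin width."""

    unit_ids: np.ndarray
    counts: np.ndarray  # (n_units, n_bins), nonnegative integers
    bin_s: float = 0.01
    t0: float = 0.0

    def __post_init__(self):
        self.unit_ids = np.asarray(self.unit_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (units x bins)")
        if np.any(self.counts < 0):
            raise ValueError("negative spike counts")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_s

    def bin_times(self) -> np.ndarray:
        """Trailing-edge time of every bin."""
        return self.t0 + (np.arange(self.n_bins) + 1) * self.bin_s

    def rebin(self, bin_s: float) -> "SpikeRaster":
        """Sum counts into coarser bins; bin_s must be a multiple of the base.

        Conserves the total spike count per unit exactly.  A trailing
        partial bin, if any, is dropped (never present for the grid-aligned
        sessions this package generates).
        """
        factor = bin_s / self.bin_s
        if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
            raise ValueError("bin_s must be an integer multiple of raster.bin_s")
        factor = round(factor)
        if factor == 1:
            return replace(self, counts=self.counts.copy())
        n_full = self.n_bins // factor
        trimmed = self.counts[:, : n_full * factor]
        coarse = trimmed.reshape(self.n_units, n_full, factor).sum(axis=2)
        return SpikeRaster(self.unit_ids, coarse, bin_s=bin_s, t0=self.t0)

    def slice_time(self, t_start: float, t_end: float) -> "SpikeRaster":
        i0 = int(round((t_start - self.t0) / self.bin_s))
        i1 = int(round((t_end - self.t0) / self.bin_s))
        i0, i1 = max(i0, 0), min(i1, self.n_bins)
        return SpikeRaster(
            self.unit_ids,
            self.counts[:, i0:i1],
            bin_s=self.bin_s,
            t0=self.t0 + i0 * self.bin_s,
        )

    def mean_rates(self) -> np.ndarray:
        """Session-mean firing rate per unit (Hz)."""
        return self.counts.sum(axis=1) / self.duration_s


@dataclass
class LfpTrace:
    """Single-channel LFP signal."""

    fs: float
    values: np.ndarray
    zscored: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite LFP values")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs

    def zscore(self) -> "LfpTrace":
        v = self.values
        sd = v.std()
        if sd == 0:
            raise ValueError("cannot z-score a constant trace")
        return LfpTrace(self.fs, (v - v.mean()) / sd, zscored=True)


@dataclass
class TrialLog:
    """One trial of the Running, Jumper or Jedi task."""

    task: str  # running | jumper | jedi
    trial_id: int
    goal_xy: tuple[float, float]
    t_start: float
    t_end: float
    outcome: str  # reached | timeout | reward_cap | limit
    reward_ml: float = 0.0
    # per-0.1-s streams over the trial (may be None for lightweight logs)
    decoded: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    avatar: np.ndarray | None = None
    intended: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError("t_end < t_start")
        if self.reward_ml < 0:
            raise ValueError("negative reward")


def trial_logs_to_frame(trials: Sequence[TrialLog]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [tr.trial_id for tr in trials],
            "task": [tr.task for tr in trials],
            "goal_x_cm": [tr.goal_xy[0] for tr in trials],
            "goal_y_cm": [tr.goal_xy[1] for tr in trials],
            "t_start_s": [tr.t_start for tr in trials],
            "t_end_s": [tr.t_end for tr in trials],
            "outcome": [tr.outcome for tr in trials],
            "reward_ml": [tr.reward_ml for tr in trials],
        }
    )


def save_session_h5(
    path: str | Path,
    raster: SpikeRaster,
    lfp: LfpTrace | None = None,
    extra: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a raster (and optional LFP and streams) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=raster.counts, compression="gzip")
        ids = np.asarray(raster.unit_ids)
        if ids.dtype.kind in "UO":
            ids = ids.astype("S")
        f.create_dataset("unit_ids", data=ids)
        f.attrs["bin_s"] = raster.bin_s
        f.attrs["t0"] = raster.t0
        if lfp is not None:
            g = f.create_group("lfp")
            g.create_dataset("values", data=lfp.values, compression="gzip")
            g.attrs["fs"] = lfp.fs
            g.attrs["zscored"] = lfp.zscored
        for key, arr in (extra or {}).items():
            f.create_dataset(key, data=np.asarray(arr), compression="gzip")


def load_session_h5(path: str | Path) -> tuple[SpikeRaster, LfpTrace | None]:
    with h5py.File(path, "r") as f:
        ids = f["unit_ids"][()]
        if ids.dtype.kind == "S":
            ids = ids.astype(str)
        raster = SpikeRaster(
            unit_ids=ids,
            counts=f["counts"][()],
            bin_s=float(f.attrs["bin_s"]),
            t0=float(f.attrs.get("t0", 0.0)),
        )
        lfp = None
        if "lfp" in f:
            lfp = LfpTrace(
                fs=float(f["lfp"].attrs["fs"]),
                values=f["lfp/values"][()],
                zscored=bool(f["lfp"].attrs.get("zscored", False)),
            )
    return raster, lfp
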