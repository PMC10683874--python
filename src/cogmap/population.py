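"""Population-level analyses: rate maps, PV-rPV correlations, burst events.

The reference population vector (rPV) at a spatial bin is the mean firing
rate of every unit while the animal occupied that bin during the Running
task; the set of rPVs over all bins is the place-field map.  Downstream
analyses correlate instantaneous population vectors (PVs) with the rPV of
the concurrently decoded (or actual) location, detect population burst
events (PBEs) in the summed activity, and compare mean rates across tasks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import ArenaSpec, SpikeRaster, TICK_S, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class PlaceFieldMap:
    """Per-unit mean firing rate per spatial bin (the rPV map).

    ``rates`` is (n_units, n_bins) in Hz, spatially smoothed; the exact
    unsmoothed ratio is kept in ``rates_raw`` so the spike-count
    conservation identity (rate x occupancy summed over bins = total
    spikes) holds exactly.  Bins whose occupancy is below
    ``occupancy_min_s`` are masked out of all downstream statistics.
    """

    arena: ArenaSpec
    unit_ids: np.ndarray
    rates: np.ndarray  # (n_units, n_bins) Hz, smoothed
    rates_raw: np.ndarray  # unsmoothed ratio
    occupancy: np.ndarray  # (n_bins,) seconds
    occupancy_min_s: float
    smoothing_sigma_cm: float

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def valid_mask(self) -> np.ndarray:
        return self.occupancy >= self.occupancy_min_s

    def nearest_valid_bin(self, flat_idx: int) -> int:
        if self.valid_mask[flat_idx]:
            return flat_idx
        centers = self.arena.bin_centers()
        valid = np.flatnonzero(self.valid_mask)
        d = np.linalg.norm(centers[valid] - centers[flat_idx], axis=1)
        return int(valid[np.argmin(d)])

    def rate_at(self, xy) -> np.ndarray:
        """rPV (per-unit rates, Hz) at a position; masked bins fall back to
        the nearest valid bin with a logged warning."""
        idx = int(self.arena.bin_index(np.asarray(xy, float)))
        if not self.valid_mask[idx]:
            near = self.nearest_valid_bin(idx)
            warned = self.__dict__.setdefault("_warned_bins", set())
            if idx not in warned:  # warn once per masked bin
                logger.warning(
                    "position %s falls in an occupancy-masked bin %d; "
                    "substituting nearest valid bin %d",
                    np.asarray(xy).tolist(), idx, near,
                )
                warned.add(idx)
            idx = near
        return self.rates[:, idx].copy()

    def session_mean_rates(self) -> np.ndarray:
        """Occupancy-weighted mean rate per unit = total spikes / total time."""
        occ = self.occupancy
        return (self.rates_raw * occ).sum(axis=1) / occ.sum()


def _masked_smooth(field_2d: np.ndarray, mask_2d: np.ndarray, sigma_bins: float):
    """Normalized Gaussian smoothing restricted to unmasked bins."""
    v = np.where(mask_2d, field_2d, 0.0)
    w = mask_2d.astype(float)
    num = gaussian_filter(v, sigma_bins, mode="constant")
    den = gaussian_filter(w, sigma_bins, mode="constant")
    out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    return np.where(mask_2d, out, 0.0)


def compute_rpv_map(
    raster: SpikeRaster,
    trajectory: Trajectory,
    arena: ArenaSpec,
    occupancy_min_s: float = 0.5,
    smoothing_sigma_cm: float = 5.0,
) -> PlaceFieldMap:
    """Occupancy-normalised rate map over the session.

    Rates are spikes-in-bin / time-in-bin; Gaussian smoothing (sigma in cm)
    is applied to the ratio after masking, with mask-aware normalisation,
    so masked bins never leak into their neighbours.
    """
    n_ticks = min(len(trajectory), round(raster.duration_s / TICK_S))
    if n_ticks == 0:
        raise ValueError("empty session")
    counts_tick = raster.rebin(TICK_S).counts[:, :n_ticks]
    bins = arena.bin_index(trajectory.xy[:n_ticks])
    occ = np.bincount(bins, minlength=arena.n_bins) * TICK_S
    if occ.sum() == 0:
        raise ValueError("zero total occupancy")
    spikes = np.zeros((raster.n_units, arena.n_bins))
    for u in range(raster.n_units):
        spikes[u] = np.bincount(bins, weights=counts_tick[u], minlength=arena.n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(occ > 0, spikes / np.maximum(occ, 1e-12), 0.0)
    mask = occ >= occupancy_min_s
    n = arena.n_bins_side
    sigma_bins = smoothing_sigma_cm / arena.spatial_bin_cm
    smoothed = np.empty_like(raw)
    for u in range(raster.n_units):
        smoothed[u] = _masked_smooth(
            raw[u].reshape(n, n), mask.reshape(n, n), sigma_bins
        ).ravel()
    return PlaceFieldMap(
        arena=arena,
        unit_ids=np.asarray(raster.unit_ids),
        rates=smoothed,
        rates_raw=raw,
        occupancy=occ.astype(float),
        occupancy_min_s=occupancy_min_s,
        smoothing_sigma_cm=smoothing_sigma_cm,
    )


def population_vector(
    raster: SpikeRaster, t_end: float, window_s: float = 0.5
) -> np.ndarray:
    """Per-unit firing rate (Hz) in the window (t_end - window_s, t_end]."""
    t_start = t_end - window_s
    if t_start < raster.t0 - 1e-9:
        raise ValueError("window extends before session start")
    seg = raster.slice_time(t_start, t_end)
    return seg.counts.sum(axis=1) / window_s


def _pv_matrix(raster: SpikeRaster, t_ends: np.ndarray, window_s: float):
    """(n_times, n_units) PV matrix computed via a cumulative-count trick."""
    csum = np.concatenate(
        [np.zeros((raster.n_units, 1)), np.cumsum(raster.counts, axis=1)], axis=1
    )
    i1 = np.round((t_ends - raster.t0) / raster.bin_s).astype(int)
    i0 = i1 - round(window_s / raster.bin_s)
    if np.any(i0 < 0) or np.any(i1 > raster.n_bins):
        raise ValueError("PV window outside session")
    return (csum[:, i1] - csum[:, i0]).T / window_s


def pv_rpv_correlation_profile(
    raster: SpikeRaster,
    location_series: np.ndarray,
    rpv_map: PlaceFieldMap,
    windows: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0),
    near_goal_cm: float | None = None,
    goal_series: np.ndarray | None = None,
    n_random: int = 1000,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Mean PV-rPV Pearson correlation at matched vs random locations.

    For each integration window the PV ending at every 0.1-s sample is
    correlated (across units) with the rPV of the location at that sample,
    and with the rPV of a random unmasked bin; bootstrap CIs are over time
    points.  ``near_goal_cm`` keeps only samples whose location is within
    that distance of the concurrent goal.
    """
    rng = np.random.default_rng(seed)
    loc = np.asarray(location_series, float)
    n_ticks = len(loc)
    results = {"windows": list(windows), "matched": [], "random": []}
    valid_bins = np.flatnonzero(rpv_map.valid_mask)
    for window_s in windows:
        if window_s < 0.5 - 1e-9:
            raise ValueError("integration windows must be >= 0.5 s")
        first = int(np.ceil(window_s / TICK_S))
        idx = np.arange(first, n_ticks)
        if near_goal_cm is not None:
            if goal_series is None:
                raise ValueError("near_goal_cm filter requires goal_series")
            d = np.linalg.norm(loc - np.asarray(goal_series, float), axis=1)
            idx = idx[d[idx] <= near_goal_cm]
        t_ends = raster.t0 + idx * TICK_S
        pv = _pv_matrix(raster, t_ends, window_s)
        bins = rpv_map.arena.bin_index(loc[idx])
        bins = np.array([rpv_map.nearest_valid_bin(b) for b in bins])
        rpv_matched = rpv_map.rates[:, bins].T
        rand_bins = rng.choice(valid_bins, size=len(idx))
        rpv_random = rpv_map.rates[:, rand_bins].T

        def _corrs(a, b):
            # vectorised Pearson across units; zero-variance samples -> NaN
            am = a - a.mean(axis=1, keepdims=True)
            bm = b - b.mean(axis=1, keepdims=True)
            sa = np.sqrt((am**2).sum(axis=1))
            sb = np.sqrt((bm**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                c = (am * bm).sum(axis=1) / (sa * sb)
            c[(sa == 0) | (sb == 0)] = np.nan
            return c

        c_m = _corrs(pv, rpv_matched)
        c_r = _corrs(pv, rpv_random)
        if np.sum(np.isfinite(c_m)) < 3:
            raise ValueError("too few samples with unit variance for correlation")

        def _summ(c):
            c = c[np.isfinite(c)]
            boots = np.array(
                [c[rng.integers(0, len(c), len(c))].mean() for _ in range(n_boot)]
            )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            return {"mean": float(c.mean()), "ci": (float(lo), float(hi)),
                    "n": int(len(c))}

        results["matched"].append(_summ(c_m))
        results["random"].append(_summ(c_r))
    return results


@dataclass(frozen=True)
class PBEInterval:
    """One population burst event."""

    t_start: float
    t_end: float
    peak_z: float
    mean_speed_cm_s: float

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


def detect_pbes(
    raster: SpikeRaster,
    speed: np.ndarray,
    z_peak_min: float = 3.0,
    z_edge: float = 0.0,
    min_dur_s: float = 0.05,
    max_dur_s: float = 0.5,
    max_speed_cm_s: float = 5.0,
    smooth_sigma_s: float = 0.01,
) -> list[PBEInterval]:
    """Detect PBEs in the z-scored, smoothed summed-population activity.

    Candidate events peak at z >= ``z_peak_min`` and extend outward to
    where z falls to ``z_edge``; events must last 50-500 ms and coincide
    with low treadmill speed.  Returned intervals are disjoint and sorted.
    """
    summed = raster.counts.sum(axis=0).astype(float)
    if summed.std() == 0:
        warnings.warn("zero-variance summed activity; no PBEs detectable")
        return []
    sm = gaussian_filter1d(summed, smooth_sigma_s / raster.bin_s)
    z = (sm - sm.mean()) / sm.std()
    speed = np.asarray(speed, float)
    above_edge = z > z_edge
    # contiguous runs above the edge threshold
    d = np.diff(above_edge.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above_edge[0]:
        starts = np.r_[0, starts]
    if above_edge[-1]:
        ends = np.r_[ends, len(z)]
    events = []
    for s, e in zip(starts, ends):
        peak = z[s:e].max()
        if peak < z_peak_min:
            continue
        dur = (e - s) * raster.bin_s
        if not (min_dur_s <= dur <= max_dur_s):
            continue
        t0 = raster.t0 + s * raster.bin_s
        t1 = raster.t0 + e * raster.bin_s
        k0 = min(int(t0 / TICK_S), len(speed) - 1)
        k1 = min(int(np.ceil(t1 / TICK_S)), len(speed))
        mean_speed = float(speed[k0:max(k1, k0 + 1)].mean()) if len(speed) else 0.0
        if mean_speed > max_speed_cm_s:
            continue
        events.append(PBEInterval(t0, t1, float(peak), mean_speed))
    return events


def mask_pbes_and_redecode(
    raster: SpikeRaster,
    intervals: list[PBEInterval],
    model,
    rule: str = "mean",
):
    """Excise PBE activity and re-run the decoder post-hoc.

    Counts inside each interval are replaced by the unit's session-mean
    count per bin (``rule='mean'``) or zeroed (``rule='zero'``); the
    decoded series is recomputed and each output sample is flagged when
    its decoder window overlaps any event.

    Returns ``(t_ends, decoded_xy, overlaps_pbe)``.
    """
    from .decoding import decode_stream  # local import to avoid a cycle

    if rule not in ("mean", "zero"):
        raise ValueError("rule must be 'mean' or 'zero'")
    intervals = sorted(intervals, key=lambda iv: iv.t_start)
    merged: list[list[float]] = []
    for iv in intervals:
        if merged and iv.t_start < merged[-1][1]:
            warnings.warn("overlapping PBE intervals; merging")
            merged[-1][1] = max(merged[-1][1], iv.t_end)
        else:
            merged.append([iv.t_start, iv.t_end])
    counts = raster.counts.astype(float).copy()
    fill = (
        raster.counts.mean(axis=1, keepdims=True)
        if rule == "mean"
        else np.zeros((raster.n_units, 1))
    )
    for t0, t1 in merged:
        i0 = max(int(round((t0 - raster.t0) / raster.bin_s)), 0)
        i1 = min(int(round((t1 - raster.t0) / raster.bin_s)), raster.n_bins)
        counts[:, i0:i1] = fill
    masked = SpikeRaster(raster.unit_ids, counts, raster.bin_s, raster.t0)
    t_ends, decoded = decode_stream(model, masked)
    window_s = model.config.window_s
    flags = np.zeros(len(t_ends), bool)
    for t0, t1 in merged:
        flags |= (t_ends > t0) & (t_ends - window_s < t1)
    return t_ends, decoded, flags


def rate_correlation_across_tasks(
    raster_a: SpikeRaster, raster_b: SpikeRaster
) -> dict:
    """Per-unit mean rates in two tasks, their Pearson r and rate ratio."""
    if raster_a.n_units != raster_b.n_units or raster_a.n_units < 3:
        raise ValueError("need matching unit sets with >= 3 units")
    ra, rb = raster_a.mean_rates(), raster_b.mean_rates()
    r, p = sps.pearsonr(ra, rb)
    return {
        "rates_a": ra,
        "rates_b": rb,
        "pearson_r": float(r),
        "p_value": float(p),
        "mean_ratio_b_over_a": float(rb.sum() / ra.sum()),
    }
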