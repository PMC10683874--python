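import numpy as np
import pytest

from cogmap.core import ArenaSpec, SpikeRaster, Trajectory
from cogmap.population import (
    compute_rpv_map,
    detect_pbes,
    mask_pbes_and_redecode,
    population_vector,
    pv_rpv_correlation_profile,
    rate_correlation_across_tasks,
)

ARENA = ArenaSpec()


def stationary_session(n_units=4, n_ticks=100, rate=5.0, seed=0, xy=(12.0, 37.0)):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * 0.01, size=(n_units, n_ticks * 10))
    raster = SpikeRaster(np.arange(n_units), counts)
    traj = Trajectory(np.arange(n_ticks) * 0.1, np.tile(xy, (n_ticks, 1)),
                      np.zeros(n_ticks), np.zeros(n_ticks), np.zeros(n_ticks))
    return raster, traj


class TestRpvMap:
    def test_stationary_single_bin(self):
        raster, traj = stationary_session()
        m = compute_rpv_map(raster, traj, ARENA)
        idx = ARENA.bin_index(np.array([12.0, 37.0]))
        assert m.valid_mask.sum() == 1
        assert m.valid_mask[idx]
        dur = raster.duration_s
        expected = raster.counts.sum(axis=1) / dur
        assert np.allclose(m.rates_raw[:, idx], expected)

    def test_conservation_identity(self, medium):
        m = compute_rpv_map(medium["raster"], medium["trajectory"],
                            medium["arena"])
        per_unit = (m.rates_raw * m.occupancy).sum(axis=1)
        assert np.allclose(per_unit, medium["raster"].counts.sum(axis=1))

    def test_field_centers_recovered(self, medium):
        m = compute_rpv_map(medium["raster"], medium["trajectory"],
                            medium["arena"])
        ens = medium["ensemble"]
        arena = medium["arena"]
        centers = arena.bin_centers()
        strong = ens.peak_rates >= 5 * np.maximum(ens.baseline_rates, 0.1)
        # a field whose center was never visited cannot be recovered
        visited = m.valid_mask[arena.bin_index(ens.centers)]
        sel = np.flatnonzero(strong & visited)
        assert len(sel) >= 10
        hits = 0
        for u in sel:
            rates = np.where(m.valid_mask, m.rates[u], -np.inf)
            peak_xy = centers[np.argmax(rates)]
            hits += np.linalg.norm(peak_xy - ens.centers[u]) <= np.sqrt(2) * 5 + 2.5
        assert hits / len(sel) >= 0.8

    def test_zero_occupancy_rejected(self):
        raster, traj = stationary_session(n_ticks=100)
        empty = SpikeRaster(raster.unit_ids, raster.counts[:, :0])
        with pytest.raises(ValueError):
            compute_rpv_map(empty, traj, ARENA)


class TestPopulationVector:
    def test_counts_to_rates(self):
        counts = np.zeros((3, 100), int)
        counts[:, 60:70] = 0
        counts[0, 55] = 1
        counts[1, 59] = 1
        counts[2, 51] = 1
        raster = SpikeRaster(np.arange(3), counts)
        pv = population_vector(raster, t_end=0.6, window_s=0.5)
        assert np.allclose(pv, [2.0, 2.0, 2.0])  # 1 spike / 0.5 s

    def test_empty_window_zero(self):
        raster = SpikeRaster(np.arange(2), np.zeros((2, 100), int))
        assert np.allclose(population_vector(raster, 0.5), 0.0)

    def test_window_before_start_rejected(self):
        raster = SpikeRaster(np.arange(2), np.ones((2, 100), int))
        with pytest.raises(ValueError):
            population_vector(raster, t_end=0.3, window_s=0.5)

    def test_long_run_average_equals_mean_rates(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(0.05, (5, 20_000))
        raster = SpikeRaster(np.arange(5), counts)
        t_ends = np.arange(0.5, raster.duration_s + 1e-9, 0.5)
        pvs = np.array([population_vector(raster, t, 0.5) for t in t_ends])
        mean_rates = raster.mean_rates()
        se = np.sqrt(mean_rates / raster.duration_s)
        assert np.all(np.abs(pvs.mean(axis=0) - mean_rates) <= 3 * se + 1e-9)


class TestPvRpvCorrelation:
    def test_exact_rpv_column_correlates_perfectly(self, tiny_rpv):
        # construct a raster whose 0.5-s counts equal an rPV column scaled
        valid = np.flatnonzero(tiny_rpv.valid_mask)
        col = tiny_rpv.rates[:, valid[0]]
        # constant per-bin counts proportional to the rPV column: every
        # window's PV is then (nearly) a scalar multiple of that column
        per_bin = np.round(col * 10).astype(int)[:, None]
        # 100 ticks of location -> 1000 base (10-ms) raster bins
        raster = SpikeRaster(tiny_rpv.unit_ids, np.tile(per_bin, (1, 1000)))
        loc = np.tile(tiny_rpv.arena.bin_centers()[valid[0]], (100, 1))
        out = pv_rpv_correlation_profile(raster, loc, tiny_rpv,
                                         windows=(0.5,), n_boot=20, seed=0)
        assert out["matched"][0]["mean"] > 0.99

    def test_too_few_units_rejected(self, tiny_rpv):
        raster = SpikeRaster(tiny_rpv.unit_ids,
                             np.zeros((tiny_rpv.n_units, 100), int))
        loc = np.tile([50.0, 50.0], (100, 1))
        with pytest.raises(ValueError):
            pv_rpv_correlation_profile(raster, loc, tiny_rpv, windows=(0.5,),
                                       seed=0)

    def test_window_below_half_second_rejected(self, tiny_rpv):
        raster = SpikeRaster(tiny_rpv.unit_ids,
                             np.ones((tiny_rpv.n_units, 200), int))
        loc = np.tile([50.0, 50.0], (200, 1))
        with pytest.raises(ValueError):
            pv_rpv_correlation_profile(raster, loc, tiny_rpv, windows=(0.2,),
                                       seed=0)


class TestDetectPbes:
    def test_planted_bursts_recovered(self):
        rng = np.random.default_rng(0)
        n_units, dur_s = 60, 100.0
        base = rng.uniform(0.5, 3.0, n_units)
        nb = int(dur_s / 0.01)
        counts = rng.poisson(np.tile(base[:, None] * 0.01, (1, nb)))
        planted = np.arange(5.0, 95.0, 1.5)
        for t in planted:
            i0 = int(t / 0.01)
            counts[:, i0:i0 + 10] = rng.poisson(
                np.tile(base[:, None] * 0.1, (1, 10))
            )
        raster = SpikeRaster(np.arange(n_units), counts)
        events = detect_pbes(raster, np.zeros(int(dur_s / 0.1)))
        mids = np.array([(e.t_start + e.t_end) / 2 for e in events])
        recall = np.mean([np.any(np.abs(mids - (t + 0.05)) <= 0.1)
                          for t in planted])
        precision = np.mean([np.any(np.abs(planted + 0.05 - m) <= 0.1)
                             for m in mids])
        assert recall >= 0.9
        assert precision >= 0.9

    def test_intervals_disjoint_sorted_in_bounds(self, jedi_fid1):
        events = detect_pbes(jedi_fid1["raster"], jedi_fid1["streams"]["speed"])
        t_prev = 0.0
        for e in events:
            assert e.t_start >= t_prev
            assert e.t_end > e.t_start
            assert 0.05 - 1e-9 <= e.duration_s <= 0.5 + 1e-9
            t_prev = e.t_end
        assert all(e.t_end <= jedi_fid1["raster"].duration_s for e in events)

    def test_all_zero_raster_no_events(self):
        raster = SpikeRaster(np.arange(3), np.zeros((3, 5000), int))
        with pytest.warns(UserWarning):
            assert detect_pbes(raster, np.zeros(50)) == []

    def test_high_speed_events_excluded(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.02, (30, 10_000))
        counts[:, 5000:5010] = 5  # one huge burst at t = 50 s
        raster = SpikeRaster(np.arange(30), counts)
        fast = np.full(1000, 30.0)
        assert detect_pbes(raster, fast) == []


class TestMaskAndRedecode:
    def test_empty_interval_list_is_plain_decode(self, tiny_model, tiny):
        from cogmap.decoding import decode_stream

        t1, d1, flags = mask_pbes_and_redecode(tiny["raster"], [], tiny_model)
        t2, d2 = decode_stream(tiny_model, tiny["raster"])
        assert np.array_equal(d1, d2)
        assert not flags.any()

    def test_locality_outside_event_windows(self, tiny_model, tiny):
        from cogmap.decoding import decode_stream
        from cogmap.population import PBEInterval

        iv = [PBEInterval(20.0, 20.2, 5.0, 0.0)]
        t_m, d_m, flags = mask_pbes_and_redecode(tiny["raster"], iv, tiny_model)
        _, d0 = decode_stream(tiny_model, tiny["raster"])
        assert flags.any() and not flags.all()
        assert np.array_equal(d_m[~flags], d0[~flags])

    def test_overlapping_intervals_merged_with_warning(self, tiny_model, tiny):
        from cogmap.population import PBEInterval

        iv = [PBEInterval(10.0, 10.3, 4.0, 0.0), PBEInterval(10.2, 10.5, 4.0, 0.0)]
        with pytest.warns(UserWarning, match="overlapping"):
            mask_pbes_and_redecode(tiny["raster"], iv, tiny_model)


class TestRateCorrelation:
    def test_identical_rasters(self):
        rng = np.random.default_rng(0)
        r = SpikeRaster(np.arange(5), rng.poisson(1, (5, 1000)))
        out = rate_correlation_across_tasks(r, r)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["mean_ratio_b_over_a"] == pytest.approx(1.0)

    def test_subsampled_raster_same_rates(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(np.linspace(0.02, 0.3, 8)[:, None], (8, 40_000))
        a = SpikeRaster(np.arange(8), counts)
        b = SpikeRaster(np.arange(8), counts[:, ::2])  # half duration
        out = rate_correlation_across_tasks(a, b)
        assert out["pearson_r"] > 0.98
        assert out["mean_ratio_b_over_a"] == pytest.approx(1.0, abs=0.05)

    def test_thinned_raster_half_rate(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(np.linspace(0.05, 0.4, 8)[:, None], (8, 40_000))
        thinned = rng.binomial(counts, 0.5)
        a = SpikeRaster(np.arange(8), counts)
        b = SpikeRaster(np.arange(8), thinned)
        out = rate_correlation_across_tasks(a, b)
        assert out["mean_ratio_b_over_a"] == pytest.approx(0.5, abs=0.05)
        assert out["pearson_r"] > 0.95

    def test_too_few_units_rejected(self):
        r = SpikeRaster(np.arange(2), np.ones((2, 10), int))
        with pytest.raises(ValueError):
            rate_correlation_across_tasks(r, r)
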