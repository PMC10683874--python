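import numpy as np
import pytest

from cogmap.core import ArenaSpec, SpikeRaster
from cogmap.decoding import (
    AugmentationConfig,
    BayesianMAPDecoder,
    CountWindow,
    DecoderConfig,
    DecoderModel,
    augment_window,
    bayesian_map_decode,
    bin_counts,
    decode_stream,
    make_training_windows,
    r2_score,
    train_decoder,
)
from cogmap.population import PlaceFieldMap


def small_map(n_units, n_valid, seed, side=20.0):
    """A hand-built place-field map on a 4x4 grid with n_valid open bins."""
    arena = ArenaSpec(side_cm=side, spatial_bin_cm=side / 4, goal_radius_cm=side / 5)
    rng = np.random.default_rng(seed)
    rates = rng.uniform(0.5, 10.0, size=(n_units, 16))
    occ = np.zeros(16)
    occ[:n_valid] = 10.0
    return PlaceFieldMap(
        arena=arena, unit_ids=np.arange(n_units), rates=rates, rates_raw=rates,
        occupancy=occ, occupancy_min_s=0.5, smoothing_sigma_cm=0.0,
    )


class TestBinCounts:
    def test_identity_and_sum(self):
        r = SpikeRaster(np.arange(2), np.ones((2, 30), int), bin_s=0.01)
        assert np.array_equal(bin_counts(r, 0.01).counts, r.counts)
        assert np.all(bin_counts(r, 0.1).counts == 10)

    def test_totals_conserved(self):
        rng = np.random.default_rng(3)
        r = SpikeRaster(np.arange(4), rng.poisson(1, (4, 120)), bin_s=0.01)
        assert np.array_equal(
            bin_counts(r, 0.1).counts.sum(axis=1), r.counts.sum(axis=1)
        )


class TestTrainingWindows:
    def test_window_count_inclusive_endpoints(self, tiny):
        cfg = DecoderConfig(window_s=5.0)
        raster = tiny["raster"].slice_time(0, 10.0)
        traj = tiny["trajectory"]
        w, t_ends, tg = make_training_windows(raster, traj, cfg)
        # 10-s session, 5-s window: t_end = 5.0 ... 10.0 inclusive
        assert len(w) == 51
        assert t_ends[0] == pytest.approx(5.0)
        assert t_ends[-1] == pytest.approx(10.0)

    def test_window_shape_and_targets(self, tiny):
        cfg = DecoderConfig(window_s=1.5, bin_s=0.1)
        w, t_ends, tg = make_training_windows(
            tiny["raster"], tiny["trajectory"], cfg
        )
        assert w.shape[1:] == (tiny["raster"].n_units, 15)
        # target is the exact on-grid position at the window's trailing edge
        k = 10
        idx = round(t_ends[k] / 0.1) - 1
        assert np.allclose(tg[k], tiny["trajectory"].xy[idx])

    def test_short_session_warns_and_returns_empty(self, tiny):
        cfg = DecoderConfig(window_s=5.0)
        short = tiny["raster"].slice_time(0, 2.0)
        with pytest.warns(UserWarning):
            w, t_ends, tg = make_training_windows(
                short, tiny["trajectory"], cfg
            )
        assert len(w) == 0


class TestAugmentation:
    def test_all_zero_config_is_identity(self):
        win = CountWindow(np.arange(30).reshape(3, 10), t_end=1.0)
        out = augment_window(win, AugmentationConfig.none(), seed=0)
        assert np.array_equal(out.counts, win.counts)

    def test_dropout_fraction_matches_binomial(self):
        aug = AugmentationConfig(unit_dropout_p=0.3, count_noise_scale=0.0,
                                 time_jitter_bins=0)
        win = CountWindow(np.ones((20, 10)), t_end=1.0)
        n = 10_000
        dropped = 0
        for s in range(n // 100):
            out = augment_window(win, aug, seed=s)
            dropped += (out.counts.sum(axis=1) == 0).sum()
        total = (n // 100) * 20
        frac = dropped / total
        se = np.sqrt(0.3 * 0.7 / total)
        assert abs(frac - 0.3) <= 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(unit_dropout_p=1.0)
        with pytest.raises(ValueError):
            AugmentationConfig(count_noise_scale=-1)


class TestTrainDecoder:
    def test_determinism(self, tiny):
        cfg = DecoderConfig(max_iter=5)
        w, _, tg = make_training_windows(tiny["raster"], tiny["trajectory"], cfg)
        m1 = train_decoder(w, tg, cfg, tiny["arena"], seed=4)
        m2 = train_decoder(w, tg, cfg, tiny["arena"], seed=4)
        assert np.array_equal(m1.validation_r2, m2.validation_r2)
        assert np.array_equal(m1.estimator.predict(w[:5]),
                              m2.estimator.predict(w[:5]))

    def test_degenerate_targets_abort(self, tiny):
        cfg = DecoderConfig(max_iter=2)
        w, _, tg = make_training_windows(tiny["raster"], tiny["trajectory"], cfg)
        with pytest.raises(ValueError, match="degenerate"):
            train_decoder(w, np.tile([50.0, 50.0], (len(w), 1)), cfg,
                          tiny["arena"])

    def test_too_few_windows_rejected(self, tiny):
        cfg = DecoderConfig(max_iter=2)
        w, _, tg = make_training_windows(tiny["raster"], tiny["trajectory"], cfg)
        with pytest.raises(ValueError):
            train_decoder(w[:50], tg[:50], cfg, tiny["arena"])

    def test_no_spatial_information_gives_chance_r2(self, tiny_rpv, tiny):
        # fidelity-0 emissions carry no location signal: R^2 ~ 0
        from cogmap.synth import IntentionAgentConfig, intention_pv

        cfg = DecoderConfig(max_iter=10)
        agent = IntentionAgentConfig(fidelity=0.0)
        rng = np.random.default_rng(0)
        valid = np.flatnonzero(tiny_rpv.valid_mask)
        centers = tiny_rpv.arena.bin_centers()
        segs, targets_t = [], []
        seg_s = 2.0
        for k in range(40):
            xy = centers[rng.choice(valid)]
            segs.append(intention_pv(tiny_rpv, xy, agent, seg_s, seed=k).counts)
            targets_t.append(xy)
        counts = np.concatenate(segs, axis=1)
        raster = SpikeRaster(tiny_rpv.unit_ids, counts)
        from cogmap.core import Trajectory

        n_ticks = raster.n_bins // 10
        xy_t = np.repeat(np.array(targets_t), round(seg_s / 0.1), axis=0)[:n_ticks]
        traj = Trajectory(np.arange(n_ticks) * 0.1, xy_t, np.zeros(n_ticks),
                          np.zeros(n_ticks), np.zeros(n_ticks))
        w, _, tg = make_training_windows(raster, traj, cfg)
        model = train_decoder(w, tg, cfg, tiny_rpv.arena, seed=1)
        assert np.all(model.validation_r2 <= 0.05)


class TestDecodeStream:
    def test_matches_batch_prediction(self, tiny_model, tiny):
        t_ends, decoded = decode_stream(tiny_model, tiny["raster"])
        cfg = tiny_model.config
        w, te2, _ = make_training_windows(
            tiny["raster"], tiny["trajectory"], cfg
        )
        n = min(len(w), len(decoded))
        assert np.allclose(decoded[:n], tiny_model.estimator.predict(w[:n]))

    def test_unit_mismatch_hard_error(self, tiny_model, tiny):
        r = tiny["raster"]
        bad = SpikeRaster(r.unit_ids[:-1], r.counts[:-1], r.bin_s)
        with pytest.raises(ValueError, match="unit"):
            decode_stream(tiny_model, bad)

    def test_all_zero_raster_constant_inside_arena(self, tiny_model, tiny):
        r = tiny["raster"]
        zeros = SpikeRaster(r.unit_ids, np.zeros((r.n_units, 500), int))
        _, decoded = decode_stream(tiny_model, zeros)
        assert np.allclose(decoded, decoded[0])
        assert tiny["arena"].contains(decoded).all()

    def test_decoded_positions_inside_arena(self, tiny_model, tiny):
        _, decoded = decode_stream(tiny_model, tiny["raster"])
        assert tiny["arena"].contains(decoded).all()


class TestBayesianMAP:
    def test_two_bin_zero_count_posterior(self):
        # single unit, f = (1, 2) Hz, tau = 1 s, n = 0:
        # posterior ∝ (e^-1, e^-2) = (0.7311, 0.2689)
        m = small_map(1, 2, seed=0)
        m.rates[:] = 0.0
        m.rates[0, 0], m.rates[0, 1] = 1.0, 2.0
        post, xy = bayesian_map_decode(m, np.array([[0.0]]), window_s=1.0)
        assert post[0] == pytest.approx(0.73106, abs=1e-4)
        assert post[1] == pytest.approx(0.26894, abs=1e-4)
        assert np.allclose(xy, m.arena.bin_centers()[0])

    def test_posterior_normalised(self):
        rng = np.random.default_rng(2)
        for k in range(10):
            m = small_map(6, 16, seed=k)
            n = rng.poisson(2.0, size=6)
            post, _ = bayesian_map_decode(m, n[:, None], window_s=1.5)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_map_recovers_generating_bin(self):
        # windows drawn from one bin's rates: MAP lands there >= 95%
        m = small_map(8, 16, seed=5)
        m.rates *= 3  # make tau * sum(f) informative
        rng = np.random.default_rng(7)
        tau = 2.0
        hits = 0
        n_draws = 200
        dec = BayesianMAPDecoder().fit(m)
        for _ in range(n_draws):
            b = rng.integers(16)
            n = rng.poisson(m.rates[:, b] * tau)
            _, xy = dec.posterior(n, tau)
            hits += np.allclose(xy, m.arena.bin_centers()[b])
        assert hits / n_draws >= 0.95

    def test_all_masked_rejected(self):
        m = small_map(2, 0, seed=0)
        with pytest.raises(ValueError):
            BayesianMAPDecoder().fit(m)

    def test_nan_rates_rejected(self):
        m = small_map(2, 4, seed=0)
        m.rates[0, 0] = np.nan
        with pytest.raises(ValueError):
            BayesianMAPDecoder().fit(m)


class TestR2Score:
    def test_perfect_prediction(self):
        a = np.random.default_rng(0).uniform(0, 100, (20, 2))
        out = r2_score(a, a)
        assert out["r2_x"] == pytest.approx(1.0)
        assert out["median_error_cm"] == 0.0

    def test_constant_mean_prediction_is_zero(self):
        a = np.random.default_rng(1).uniform(0, 100, (50, 2))
        pred = np.tile(a.mean(axis=0), (50, 1))
        out = r2_score(pred, a)
        assert out["r2_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_table(self):
        actual = np.array([[0, 0], [1, 2], [2, 4], [3, 6], [4, 8]], float)
        pred = np.array([[0, 1], [1, 2], [2, 3], [3, 6], [4, 9]], float)
        ss_res_x = 0.0
        ss_res_y = 1 + 0 + 1 + 0 + 1
        ss_tot_x = ((actual[:, 0] - 2) ** 2).sum()
        ss_tot_y = ((actual[:, 1] - 4) ** 2).sum()
        out = r2_score(pred, actual)
        assert out["r2_x"] == pytest.approx(1 - ss_res_x / ss_tot_x)
        assert out["r2_y"] == pytest.approx(1 - ss_res_y / ss_tot_y)

    def test_zero_variance_rejected(self):
        a = np.zeros((5, 2))
        with pytest.raises(ValueError):
            r2_score(a, a)


def test_model_serialization_roundtrip(tmp_path, tiny_model, tiny):
    path = tmp_path / "model.pkl"
    tiny_model.save(path)
    back = DecoderModel.load(path)
    assert np.array_equal(back.unit_ids, tiny_model.unit_ids)
    w, _, _ = make_training_windows(
        tiny["raster"], tiny["trajectory"], tiny_model.config
    )
    assert np.array_equal(
        back.estimator.predict(w[:10]), tiny_model.estimator.predict(w[:10])
    )
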