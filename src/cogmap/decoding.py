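"""Position decoding from windowed spike counts.

Two decoders are provided behind a common surface:

* :class:`WindowedPlaceDecoder` — an sklearn-style regressor mapping a
  trailing window of binned spike counts (1.5 or 5 s of 100-ms bins) to
  the current 2-D position.  Training uses data augmentation (unit
  dropout, multiplicative rate jitter, small circular time shifts), which
  is what makes the decoder robust to corrupted inputs.
* :class:`BayesianMAPDecoder` — the classical memoryless Poisson decoder:
  ``P(x | n) ∝ P(x) · Π_i f_i(x)^{n_i} · exp(-τ Σ_i f_i(x))`` with
  ``f_i(x)`` from the place-field (rPV) map and ``τ`` the window length.

Module-level functions (``train_decoder``, ``decode_stream``,
``bayesian_map_decode`` ...) are thin wrappers over the estimators.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import r2_score as _sk_r2
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .core import ArenaSpec, SpikeRaster, TICK_S, Trajectory
from .population import PlaceFieldMap


@dataclass(frozen=True)
class AugmentationConfig:
    """Training-set corruption applied to spike-count windows.

    Order of application: unit dropout (whole rows zeroed with
    probability ``unit_dropout_p``), multiplicative jitter
    (``counts * max(0, 1 + eps)`` with ``eps ~ N(0, count_noise_scale)``
    per unit per window), then a circular time shift of up to
    ``time_jitter_bins`` bins.
    """

    unit_dropout_p: float = 0.4
    count_noise_scale: float = 0.2
    time_jitter_bins: int = 2
    n_augmented_copies: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.unit_dropout_p < 1):
            raise ValueError("unit_dropout_p must be in [0, 1)")
        if self.count_noise_scale < 0 or self.n_augmented_copies < 0:
            raise ValueError("negative augmentation parameter")

    @classmethod
    def none(cls) -> "AugmentationConfig":
        return cls(0.0, 0.0, 0, 0)


@dataclass(frozen=True)
class DecoderConfig:
    """Windowing and model settings for the position decoder."""

    window_s: float = 1.5
    bin_s: float = 0.1
    output_interval_s: float = 0.1
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    hidden_layer_sizes: tuple[int, ...] = (256, 256)
    max_iter: int = 60
    batch_size: int = 256
    learning_rate_init: float = 1e-3
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        ratio = self.window_s / self.bin_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("window_s must be an integer multiple of bin_s")
        if abs(self.output_interval_s - TICK_S) > 1e-12:
            raise ValueError("output cadence is fixed at 0.1 s")

    @property
    def n_window_bins(self) -> int:
        return round(self.window_s / self.bin_s)


@dataclass
class CountWindow:
    """One trailing window of spike counts (units x window bins)."""

    counts: np.ndarray
    t_end: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 2-D array")


def bin_counts(raster: SpikeRaster, bin_s: float) -> SpikeRaster:
    """Rebin a raster to a coarser bin width, conserving totals per unit."""
    return raster.rebin(bin_s)


def make_training_windows(
    raster: SpikeRaster, trajectory: Trajectory, config: DecoderConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding windows and current-location targets on the 0.1-s grid.

    Returns ``(windows, t_ends, targets)`` where windows is
    (n, units, window_bins); one window per 0.1-s step with
    ``t_end >= window_s`` and target = trajectory position at ``t_end``
    (the current location; no look-ahead).
    """
    coarse = raster.rebin(config.bin_s)
    w = config.n_window_bins
    n_ticks = min(coarse.n_bins, len(trajectory))
    if n_ticks < w:
        warnings.warn("session shorter than the decoder window; no windows")
        return (
            np.empty((0, raster.n_units, w)),
            np.empty(0),
            np.empty((0, 2)),
        )
    # window k ends at bin index w+k (exclusive): t_end = (w+k)*bin_s
    stops = np.arange(w, n_ticks + 1)
    windows = np.lib.stride_tricks.sliding_window_view(
        coarse.counts[:, :n_ticks], w, axis=1
    )  # (units, n_ticks-w+1, w)
    windows = np.ascontiguousarray(np.moveaxis(windows, 1, 0))
    t_ends = coarse.t0 + stops * config.bin_s
    # target index: position sample at t_end is trajectory sample stops-1
    targets = trajectory.xy[stops - 1]
    return windows, t_ends, targets


def augment_window(
    window: CountWindow, aug: AugmentationConfig, seed: int = 0
) -> CountWindow:
    """Apply the augmentation recipe to a single window (deterministic)."""
    rng = np.random.default_rng(seed)
    out = _augment_batch(window.counts[None].astype(float), aug, rng)[0]
    return CountWindow(out, window.t_end)


def _augment_batch(
    batch: np.ndarray, aug: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised augmentation of a (n, units, bins) batch."""
    out = batch.astype(float, copy=True)
    n, u, b = out.shape
    if aug.unit_dropout_p > 0:
        keep = rng.random((n, u)) >= aug.unit_dropout_p
        out *= keep[:, :, None]
    if aug.count_noise_scale > 0:
        eps = rng.normal(0, aug.count_noise_scale, size=(n, u))
        out *= np.maximum(0.0, 1.0 + eps)[:, :, None]
    if aug.time_jitter_bins > 0:
        shifts = rng.integers(-aug.time_jitter_bins, aug.time_jitter_bins + 1, n)
        for k in np.flatnonzero(shifts):
            out[k] = np.roll(out[k], shifts[k], axis=1)
    return out


class WindowedPlaceDecoder(BaseEstimator, RegressorMixin):
    """Sliding-window spike-count -> 2-D position regressor (MLP).

    Fits a multilayer perceptron on flattened (units x window-bins) count
    windows with augmentation-expanded training data and a contiguous
    train/validation block split (random splits would leak temporally
    correlated windows across the boundary).

    Parameters follow :class:`DecoderConfig`; after :meth:`fit` the
    estimator exposes ``validation_r2_`` (per coordinate),
    ``median_error_cm_`` and the fitted ``net_``.
    """

    def __init__(self, config: DecoderConfig | None = None,
                 arena: ArenaSpec | None = None):
        self.config = config
        self.arena = arena

    def _flatten(self, windows: np.ndarray) -> np.ndarray:
        w = np.asarray(windows, np.float32)
        if w.ndim == 3:
            w = w.reshape(len(w), -1)
        return w

    def fit(self, X, y, unit_ids=None):
        """Fit on windows (n, units, bins) or flattened, targets (n, 2)."""
        cfg = self.config or DecoderConfig()
        self.config = cfg
        y = np.asarray(y, float)
        if len(X) < 100:
            raise ValueError("need at least 100 training windows")
        if np.allclose(y.var(axis=0), 0):
            raise ValueError("degenerate targets: all positions identical")
        X3 = np.asarray(X)
        if X3.ndim == 2:
            X3 = X3.reshape(len(X3), -1, cfg.n_window_bins)
        self.unit_ids_ = (
            np.asarray(unit_ids) if unit_ids is not None else np.arange(X3.shape[1])
        )
        n = len(X3)
        n_train = int(round(cfg.train_fraction * n))
        rng = np.random.default_rng(cfg.seed)
        Xtr, ytr = X3[:n_train], y[:n_train]
        Xva, yva = X3[n_train:], y[n_train:]
        parts_X = [self._flatten(Xtr)]
        parts_y = [ytr]
        for _ in range(cfg.augmentation.n_augmented_copies):
            parts_X.append(self._flatten(_augment_batch(Xtr, cfg.augmentation, rng)))
            parts_y.append(ytr)
        Xfit = np.concatenate(parts_X)
        yfit = np.concatenate(parts_y)
        self.net_ = make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=cfg.hidden_layer_sizes,
                max_iter=cfg.max_iter,
                batch_size=cfg.batch_size,
                learning_rate_init=cfg.learning_rate_init,
                random_state=cfg.seed,
                tol=0.0,
                n_iter_no_change=cfg.max_iter,
            ),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings expected
            self.net_.fit(Xfit, np.asarray(yfit, np.float32))
        if len(Xva):
            pred = self.predict(Xva)
            self.validation_r2_ = np.array(
                [_sk_r2(yva[:, k], pred[:, k]) for k in range(2)]
            )
            self.median_error_cm_ = float(
                np.median(np.linalg.norm(pred - yva, axis=1))
            )
            self._val_X = self._flatten(Xva)
            self._val_pred = pred
        else:
            self.validation_r2_ = np.array([np.nan, np.nan])
            self.median_error_cm_ = np.nan
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        out = self.net_.predict(self._flatten(np.asarray(X)))
        if self.arena is not None:
            out = np.clip(out, 0.0, self.arena.side_cm)
        return out


class BayesianMAPDecoder(BaseEstimator):
    """Memoryless Poisson MAP decoder over the place-field map.

    ``fit`` takes the rPV map (and optional prior over spatial bins);
    ``predict`` maps count windows to the centers of the maximum a
    posteriori bins.  Ties break to the lowest row-major bin index.
    """

    def __init__(self, rate_floor_hz: float = 0.01):
        self.rate_floor_hz = rate_floor_hz

    def fit(self, rpv_map: PlaceFieldMap, prior: np.ndarray | None = None):
        self.rpv_map_ = rpv_map
        mask = rpv_map.valid_mask
        if not mask.any():
            raise ValueError("all spatial bins are occupancy-masked")
        if prior is None:
            prior = mask / mask.sum()
        prior = np.asarray(prior, float)
        if abs(prior[mask].sum() - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1 over unmasked bins")
        self.prior_ = prior
        rates = np.maximum(rpv_map.rates, self.rate_floor_hz)
        if np.any(~np.isfinite(rates)):
            raise ValueError("NaN in rate map")
        self.log_rates_ = np.log(rates)  # (units, bins)
        self.sum_rates_ = rates.sum(axis=0)
        return self

    def posterior(self, counts_window: np.ndarray, window_s: float):
        """Posterior over unmasked bins and the MAP position."""
        check_is_fitted(self, "log_rates_")
        n_i = np.asarray(counts_window, float)
        if n_i.ndim == 2:
            n_i = n_i.sum(axis=1)
        mask = self.rpv_map_.valid_mask
        logpost = np.full(len(mask), -np.inf)
        with np.errstate(divide="ignore"):
            logprior = np.where(mask, np.log(np.maximum(self.prior_, 1e-300)), -np.inf)
        ll = n_i @ self.log_rates_ - window_s * self.sum_rates_
        logpost[mask] = logprior[mask] + ll[mask]
        post = np.exp(logpost - logsumexp(logpost[mask]))
        post[~mask] = 0.0
        idx = int(np.argmax(np.where(mask, logpost, -np.inf)))
        return post, self.rpv_map_.arena.bin_centers()[idx]

    def predict(self, X, window_s: float | None = None):
        """MAP positions for (n, units, bins) windows (bins at 0.1 s) or
        (n, units) total counts with an explicit ``window_s``."""
        X = np.asarray(X, float)
        if X.ndim == 3:
            tau = window_s if window_s is not None else X.shape[2] * TICK_S
            totals = X.sum(axis=2)
        else:
            if window_s is None:
                raise ValueError("window_s required for pre-summed counts")
            tau, totals = window_s, X
        return np.array([self.posterior(t, tau)[1] for t in totals])


@dataclass
class DecoderModel:
    """A trained decoder bundled with its config and unit identities."""

    config: DecoderConfig
    estimator: WindowedPlaceDecoder
    unit_ids: np.ndarray
    arena: ArenaSpec
    validation_r2: np.ndarray
    median_error_cm: float

    def save(self, path) -> None:
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @classmethod
    def load(cls, path) -> "DecoderModel":
        with open(path, "rb") as f:
            model = pickle.load(f)
        if not isinstance(model, cls):
            raise TypeError("file does not contain a DecoderModel")
        return model


def train_decoder(
    windows: np.ndarray,
    targets: np.ndarray,
    config: DecoderConfig,
    arena: ArenaSpec,
    unit_ids: np.ndarray | None = None,
    seed: int | None = None,
) -> DecoderModel:
    """Train the windowed regressor; see :class:`WindowedPlaceDecoder`."""
    if seed is not None:
        config = DecoderConfig(**{**asdict(config), "seed": seed,
                                  "augmentation": config.augmentation})
    est = WindowedPlaceDecoder(config=config, arena=arena).fit(
        windows, targets, unit_ids=unit_ids
    )
    return DecoderModel(
        config=config,
        estimator=est,
        unit_ids=est.unit_ids_,
        arena=arena,
        validation_r2=est.validation_r2_,
        median_error_cm=est.median_error_cm_,
    )


def _check_units(model: DecoderModel, raster: SpikeRaster) -> None:
    if len(model.unit_ids) != raster.n_units or np.any(
        np.asarray(model.unit_ids) != np.asarray(raster.unit_ids)
    ):
        raise ValueError("raster unit set does not match the trained model")


def decode_stream(
    model: DecoderModel, raster: SpikeRaster
) -> tuple[np.ndarray, np.ndarray]:
    """Decode a whole session: one position per 0.1-s step once a full
    window of history exists.  Returns ``(t_ends, positions)``."""
    _check_units(model, raster)
    cfg = model.config
    coarse = raster.rebin(cfg.bin_s)
    w = cfg.n_window_bins
    if coarse.n_bins < w:
        return np.empty(0), np.empty((0, 2))
    windows = np.lib.stride_tricks.sliding_window_view(coarse.counts, w, axis=1)
    windows = np.ascontiguousarray(np.moveaxis(windows, 1, 0))
    t_ends = coarse.t0 + np.arange(w, coarse.n_bins + 1) * cfg.bin_s
    return t_ends, model.estimator.predict(windows)


def bayesian_map_decode(
    rpv_map: PlaceFieldMap,
    window: CountWindow | np.ndarray,
    window_s: float | None = None,
    prior: np.ndarray | None = None,
    rate_floor_hz: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior over spatial bins and MAP position for one window."""
    counts = window.counts if isinstance(window, CountWindow) else np.asarray(window)
    if window_s is None:
        if counts.ndim != 2:
            raise ValueError("window_s required for pre-summed counts")
        window_s = counts.shape[1] * TICK_S
    dec = BayesianMAPDecoder(rate_floor_hz=rate_floor_hz).fit(rpv_map, prior)
    return dec.posterior(counts, window_s)


def r2_score(predicted: np.ndarray, actual: np.ndarray) -> dict:
    """Per-coordinate R^2, their mean, and the median Euclidean error (cm)."""
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    if len(predicted) != len(actual) or len(actual) < 2:
        raise ValueError("need equal-length series with >= 2 samples")
    if np.any(actual.var(axis=0) == 0):
        raise ValueError("actual positions have zero variance")
    per = np.array([_sk_r2(actual[:, k], predicted[:, k]) for k in range(2)])
    return {
        "r2_x": float(per[0]),
        "r2_y": float(per[1]),
        "r2_mean": float(per.mean()),
        "median_error_cm": float(
            np.median(np.linalg.norm(predicted - actual, axis=1))
        ),
    }


def rpv_probe_windows(
    rpv_map: PlaceFieldMap,
    config: DecoderConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probe windows whose expected counts equal rPV(bin) * bin_s in every
    window bin, one probe per unmasked spatial bin.

    Counts are Poisson draws around that expectation (spike counts, like
    the decoder's training inputs); pass ``rng=None`` for the raw
    expectations instead.  Returns
    ``(windows (n_bins_valid, units, window_bins), bin_centers)``.
    """
    valid = np.flatnonzero(rpv_map.valid_mask)
    rates = rpv_map.rates[:, valid]  # (units, n_valid)
    w = config.n_window_bins
    lam = np.repeat(
        (rates.T * config.bin_s)[:, :, None], w, axis=2
    )  # (n_valid, units, w)
    windows = lam if rng is None else rng.poisson(lam).astype(float)
    return windows, rpv_map.arena.bin_centers()[valid]


def corrupt_probes(
    windows: np.ndarray, level: float, rng: np.random.Generator
) -> np.ndarray:
    """Probe corruption at a scalar noise level: unit dropout with
    probability ``level`` plus multiplicative jitter with SD ``level``."""
    aug = AugmentationConfig(
        unit_dropout_p=min(level, 0.99),
        count_noise_scale=level,
        time_jitter_bins=0,
        n_augmented_copies=0,
    )
    return _augment_batch(windows, aug, rng)


def noise_robustness_curve(
    model: DecoderModel,
    rpv_map: PlaceFieldMap,
    noise_levels=(0.0, 0.25, 0.5, 0.75, 0.9),
    n_repeats: int = 3,
    seed: int = 0,
) -> dict:
    """Mean decoding error (cm) of the trained regressor vs the Bayesian
    MAP decoder on rPV probe inputs under increasing corruption."""
    rng = np.random.default_rng(seed)
    bayes = BayesianMAPDecoder().fit(rpv_map)
    out = {"noise_levels": list(noise_levels), "regressor_cm": [], "bayesian_cm": []}
    for level in noise_levels:
        errs_r, errs_b = [], []
        for _ in range(n_repeats):
            probes, centers = rpv_probe_windows(rpv_map, model.config, rng)
            x = probes if level == 0 else corrupt_probes(probes, level, rng)
            pr = model.estimator.predict(x)
            pb = bayes.predict(x, window_s=model.config.window_s)
            errs_r.append(np.linalg.norm(pr - centers, axis=1).mean())
            errs_b.append(np.linalg.norm(pb - centers, axis=1).mean())
        out["regressor_cm"].append(float(np.mean(errs_r)))
        out["bayesian_cm"].append(float(np.mean(errs_b)))
    return out
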