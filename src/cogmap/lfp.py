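"""LFP spectral analysis: immobility segmentation, wavelet spectrograms
and Welch theta-peak estimation.

The hippocampal LFP shows a prominent theta rhythm (~5-12 Hz) whose peak
frequency is speed-dependent; the analyses here recover the peak
separately for movement and long immobility segments (>= 8 s with
treadmill speed <= 1 cm/s), pooling segments in a gap-aware Welch
estimate so no window ever spans a discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as spsig

from .core import LfpTrace, TICK_S


@dataclass
class SpectralResult:
    """Frequencies, power (PSD or time x frequency) and the band peak."""

    freqs: np.ndarray
    power: np.ndarray
    band: tuple[float, float]
    peak_hz: float
    peak_prominent: bool = True
    method: str = ""


def segment_immobility(
    speed: np.ndarray, min_dur_s: float = 8.0, max_speed_cm_s: float = 1.0
) -> list[tuple[float, float]]:
    """Maximal runs of treadmill speed <= ``max_speed_cm_s`` lasting at
    least ``min_dur_s``; returned as sorted, disjoint (t_start, t_end)."""
    speed = np.asarray(speed, float)
    still = speed <= max_speed_cm_s
    if len(still) == 0:
        return []
    d = np.diff(still.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if still[0]:
        starts = np.r_[0, starts]
    if still[-1]:
        ends = np.r_[ends, len(still)]
    out = []
    for s, e in zip(starts, ends):
        if (e - s) * TICK_S >= min_dur_s:
            out.append((s * TICK_S, e * TICK_S))
    return out


def movement_segments(
    speed: np.ndarray, min_dur_s: float = 4.0, min_speed_cm_s: float = 2.0
) -> list[tuple[float, float]]:
    """Runs of sustained movement (speed > threshold), for pooling the
    movement-state PSD."""
    inverted = -np.asarray(speed, float)
    return segment_immobility(inverted, min_dur_s, -min_speed_cm_s)


def wavelet_spectrogram(
    lfp: LfpTrace,
    freqs: np.ndarray | None = None,
    wavelet_width: float = 7.0,
    band: tuple[float, float] = (2.0, 50.0),
) -> SpectralResult:
    """Continuous Morlet-wavelet power over a log-spaced frequency grid."""
    if freqs is None:
        freqs = np.geomspace(band[0], band[1], 40)
    freqs = np.asarray(freqs, float)
    if freqs.max() >= lfp.fs / 2:
        raise ValueError("requested frequencies exceed Nyquist")
    wavelet = f"cmor{wavelet_width / (2 * np.pi):.4f}-1.0"
    # pywt: frequency = center_freq * fs / scale
    cf = pywt.central_frequency(wavelet)
    scales = cf * lfp.fs / freqs
    coeffs, _ = pywt.cwt(lfp.values, scales, wavelet, sampling_period=1 / lfp.fs)
    # normalize by scale so a pure tone's power peaks at its own frequency
    power = np.abs(coeffs) ** 2 / scales[:, None]  # (freqs, time)
    mean_p = power.mean(axis=1)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    peak = float(freqs[keep][np.argmax(mean_p[keep])])
    return SpectralResult(
        freqs=freqs, power=power, band=band, peak_hz=peak, method="morlet-cwt"
    )


def psd_theta_peak(
    lfp: LfpTrace,
    intervals: list[tuple[float, float]] | None = None,
    band: tuple[float, float] = (5.0, 12.0),
    zscore_first: bool = True,
    welch_window_s: float = 4.0,
) -> SpectralResult:
    """Gap-aware Welch PSD over the given segments and its theta peak.

    Each segment is Welch-analysed separately (4-s Hann windows, 50%
    overlap -> 0.25-Hz resolution) and segment periodograms are averaged
    weighted by their window counts, so no window spans a gap between
    segments.
    """
    trace = lfp.zscore() if (zscore_first and not lfp.zscored) else lfp
    if intervals is None:
        intervals = [(0.0, trace.duration_s)]
    nperseg = round(welch_window_s * trace.fs)
    total = sum(t1 - t0 for t0, t1 in intervals)
    if total < welch_window_s * 2:
        raise ValueError("segments too short for the Welch window")
    acc = None
    wsum = 0.0
    freqs = None
    for t0, t1 in intervals:
        i0, i1 = round(t0 * trace.fs), round(t1 * trace.fs)
        seg = trace.values[i0:i1]
        if len(seg) < nperseg:
            continue
        f, p = spsig.welch(
            seg, fs=trace.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
        )
        n_windows = 1 + (len(seg) - nperseg) // (nperseg // 2)
        freqs = f
        acc = p * n_windows if acc is None else acc + p * n_windows
        wsum += n_windows
    if acc is None:
        raise ValueError("no segment long enough for one Welch window")
    psd = acc / wsum
    keep = (freqs >= band[0]) & (freqs <= band[1])
    band_p = psd[keep]
    peak = float(freqs[keep][np.argmax(band_p)])
    # prominence: the band peak should clearly exceed the band median
    prominent = bool(band_p.max() > 2.0 * np.median(band_p))
    return SpectralResult(
        freqs=freqs,
        power=psd,
        band=band,
        peak_hz=peak,
        peak_prominent=prominent,
        method="welch",
    )
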