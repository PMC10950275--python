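"""Shared low-level signal helpers (filters, rolling statistics).

Internal module: everything here operates on plain 1-D float arrays.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal


def bandpass_sos(low_hz: float, high_hz: float, fs: float, order: int = 2) -> np.ndarray:
    """Cascaded high-pass + low-pass Butterworth sections.

    Designed as two separate filters because corner ratios like
    0.07 Hz / 10 kHz make a joint band-pass design ill-conditioned.
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    hp = signal.butter(order, low_hz, btype="highpass", fs=fs, output="sos")
    lp = signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    return np.vstack([hp, lp])


def zero_phase(sos: np.ndarray, x: np.ndarray, padlen: int | None = None) -> np.ndarray:
    """Apply a SOS filter forward and backward (no phase distortion).

    ``padlen`` should cover several time constants of the slowest corner;
    scipy's default (a few dozen samples) leaves seconds-long edge
    transients for sub-Hz corners at 10 kHz.
    """
    if padlen is not None:
        padlen = min(padlen, x.shape[-1] - 1)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def white_noise_gain(sos: np.ndarray, fs: float, n_freqs: int = 65536) -> float:
    """sd ratio out/in for white noise through ``zero_phase(sos, ...)``.

    Forward-backward filtering has amplitude response |H|^2, so the output
    variance of unit white noise is the mean of |H|^4 over frequency.
    """
    _, h = signal.sosfreqz(sos, worN=n_freqs, fs=fs)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int = 2) -> np.ndarray:
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def rolling_median(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centred rolling median of ``x``, evaluated on a coarse grid and
    linearly interpolated back to full resolution.

    The coarse grid keeps the cost independent of the sampling rate; the
    grid step is window_s/40, ample for baselines that vary over seconds.
    """
    n = x.size
    if n == 0:
        return x.copy()
    stride = max(1, int(round(window_s * fs / 200.0)))
    dec = x[::stride]
    win = max(3, int(round(window_s * fs / stride)))
    if win % 2 == 0:
        win += 1
    if dec.size < win:
        return np.full(n, float(np.median(x)))
    half = win // 2
    padded = np.pad(dec, half, mode="edge")
    med = np.median(sliding_window_view(padded, win), axis=-1)
    grid = np.arange(dec.size) * stride
    return np.interp(np.arange(n), grid, med)


def contiguous_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs in a boolean mask."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def merge_regions(regions: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by fewer than ``max_gap`` samples."""
    if not regions:
        return []
    merged = [regions[0]]
    for start, stop in regions[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged
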