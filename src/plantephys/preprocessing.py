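"""Baseline subtraction, normalisation, sign inversion and peak alignment.

The analysis convention for building comparable response epochs across
recordings and species is: subtract the pre-stimulus baseline, invert the
sign when the extremum is a negative minimum (a normalisation step only —
recorded polarity depends on electrode placement and is not interpreted),
normalise to unit peak amplitude, and align epochs on their extremum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _scipy_signal

from .recordings_io import EventLog, Recording

DEFAULT_BASELINE_WINDOW_S = 30.0
DEFAULT_PRE_S = 10.0
DEFAULT_POST_S = 60.0


@dataclass
class Epoch:
    """A fixed-length signal segment around a peak or stimulus.

    ``t0_offset_s`` is the time of sample 0 relative to the alignment
    anchor; after :func:`peak_align` the anchor (extremum) sits at index
    ``round(pre_s * sampling_rate)``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0_offset_s: float = 0.0
    normalized: bool = False
    inverted: bool = False
    padded: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Epoch samples must be 1-D")

    def times(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.samples.size) / self.sampling_rate


def baseline_subtract(
    rec: Recording, events: EventLog, window_s: float = DEFAULT_BASELINE_WINDOW_S
) -> Recording:
    """Subtract the pre-stimulus median from every sample (per channel).

    The baseline is the median of [stimulus_on - window_s, stimulus_on); a
    median is robust to pre-stimulus artifacts.  If the stimulus comes
    earlier than ``window_s`` into the recording the window shrinks to the
    available data (with a warning).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    ons = events.stimulus_on_times()
    if not ons:
        raise ValueError("baseline_subtract needs at least one stimulus_on marker")
    on = ons[0]
    fs = rec.sampling_rate
    stop = int(round(on * fs))
    start = int(round((on - window_s) * fs))
    if start < 0:
        warnings.warn(
            f"pre-stimulus window shrunk from {window_s:.1f} s to {on:.1f} s of available data",
            stacklevel=2,
        )
        start = 0
    if stop <= start:
        raise ValueError("no pre-stimulus data before the first stimulus_on marker")
    baselines = np.median(rec.samples[:, start:stop], axis=1, keepdims=True)
    return replace(rec, samples=rec.samples - baselines)


def sign_invert_if_negative(epoch: Epoch) -> Epoch:
    """Multiply by -1 when the extremum is a negative minimum.

    Strict comparison: an exact |min| == |max| tie is left unchanged, and
    the operation is idempotent (a second application is a no-op).
    """
    if epoch.samples.size == 0:
        raise ValueError("empty epoch")
    if -epoch.samples.min() > epoch.samples.max():
        return replace(epoch, samples=-epoch.samples, inverted=True)
    return replace(epoch)


def normalize_amplitude(epoch: Epoch) -> Epoch:
    """Divide by the extremum magnitude so max |value| is exactly 1."""
    extremum = float(np.max(np.abs(epoch.samples)))
    if extremum == 0.0:
        raise ValueError("cannot normalize an all-zero epoch")
    return replace(epoch, samples=epoch.samples / extremum, normalized=True)


def peak_align(
    epochs: list[Epoch], pre_s: float = DEFAULT_PRE_S, post_s: float = DEFAULT_POST_S
) -> list[Epoch]:
    """Re-window each epoch to [-pre_s, +post_s] around its extremum.

    All outputs share one length; windows that would run past the epoch
    bounds are zero-padded and flagged.  The extremum is the global
    |value| maximum (first sample on ties).
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValueError("pre_s and post_s must be positive")
    out = []
    for epoch in epochs:
        fs = epoch.sampling_rate
        pre_n = int(round(pre_s * fs))
        post_n = int(round(post_s * fs))
        peak = int(np.argmax(np.abs(epoch.samples)))
        start = peak - pre_n
        stop = peak + post_n + 1
        pad_left = max(0, -start)
        pad_right = max(0, stop - epoch.samples.size)
        window = epoch.samples[max(0, start):min(epoch.samples.size, stop)]
        if pad_left or pad_right:
            window = np.pad(window, (pad_left, pad_right))
        out.append(
            replace(
                epoch,
                samples=window,
                t0_offset_s=-pre_n / fs,
                padded=bool(pad_left or pad_right) or epoch.padded,
            )
        )
    return out


def extract_epoch(
    rec: Recording,
    center_time_s: float,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    channel: int = 0,
) -> Epoch:
    """Cut a [-pre_s, +post_s] window around a time point (zero-padded)."""
    fs = rec.sampling_rate
    x = rec.channel(channel)
    center = int(round(center_time_s * fs))
    start = center - int(round(pre_s * fs))
    stop = center + int(round(post_s * fs)) + 1
    pad_left = max(0, -start)
    pad_right = max(0, stop - x.size)
    window = x[max(0, start):min(x.size, stop)]
    if pad_left or pad_right:
        window = np.pad(window, (pad_left, pad_right))
    return Epoch(
        samples=window,
        sampling_rate=fs,
        t0_offset_s=-pre_s,
        padded=bool(pad_left or pad_right),
    )


def decimate_recording(rec: Recording, target_rate_hz: float = 100.0) -> Recording:
    """Anti-aliased decimation (e.g. 10 kHz → 100 Hz) for faster detection.

    Factors > 10 are applied in stages of ≤ 10 as scipy recommends.  The
    seconds-scale responses this pipeline targets are unaffected; spike
    widths down to ~50 ms survive a 100 Hz rate.
    """
    factor = rec.sampling_rate / target_rate_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"sampling rate {rec.sampling_rate} is not an integer multiple of {target_rate_hz}")
    factor = int(round(factor))
    samples = rec.samples
    while factor > 1:
        step = 10 if factor % 10 == 0 and factor >= 10 else factor
        samples = _scipy_signal.decimate(samples, step, axis=1, zero_phase=True)
        factor //= step
    return replace(rec, samples=samples, sampling_rate=target_rate_hz)


def epoch_to_csv(epoch: Epoch, path) -> None:
    """Export an epoch as (time_s, value) CSV for plotting."""
    import pandas as pd

    pd.DataFrame({"time_s": epoch.times(), "value": epoch.samples}).to_csv(path, index=False)
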