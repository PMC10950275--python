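"""Trace-level artifact rejection.

Whole traces are accepted or rejected (never repaired) by three filters:

1. **fast_spike** — any excursion narrower than 500 ms at half prominence;
   these are touching artifacts of the recording wire, far faster than the
   seconds-scale electrical responses of plants.
2. **clipping** — a sustained run of samples at the recording full scale
   (amplifier/ADC saturation).
3. **elevated_baseline** — an excursion riding on a baseline already at
   ≥ 75 % of the trace extremum, which corrupts peak normalisation.

Excursions are defined against a rolling-median baseline, thresholded in
robust-sigma units (scaled MAD) estimated on the pre-stimulus window so
genuine responses do not inflate the noise estimate.  The elevated-baseline
reference is the rolling median over the window immediately *preceding*
each excursion: a genuine slow response raises the rolling median at its
own peak, so evaluating the baseline there would misfire on every clean
responsive trace (the rule's baseline reference is interpretation-
dependent; this choice is recorded in the report metadata).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import signal as _scipy_signal

from . import _signal
from .recordings_io import EventLog, Recording

FAST_SPIKE = "fast_spike"
CLIPPING = "clipping"
ELEVATED_BASELINE = "elevated_baseline"

#: scaled-MAD factor making the threshold Gaussian-sigma equivalent
_MAD_TO_SIGMA = 1.4826

BASELINE_INTERPRETATION = (
    "elevated_baseline compares the rolling-median baseline over the window "
    "preceding each excursion against baseline_fraction x the trace extremum"
)


@dataclass(frozen=True)
class ArtifactConfig:
    fast_spike_max_width_s: float = 0.5
    spike_threshold_mads: float = 5.0
    clip_margin: float = 0.01
    clip_min_run_s: float = 0.05
    baseline_fraction: float = 0.75
    baseline_window_s: float = 5.0
    #: rolling-median window for the spike-detection residual; much longer
    #: than any response so an excursion cannot pollute its own baseline
    spike_baseline_window_s: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "fast_spike_max_width_s",
            "spike_threshold_mads",
            "clip_margin",
            "clip_min_run_s",
            "baseline_window_s",
            "spike_baseline_window_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.baseline_fraction <= 1:
            raise ValueError("baseline_fraction must be in (0, 1]")


class Spike(NamedTuple):
    peak_time_s: float
    width_s: float
    amplitude: float


@dataclass
class ArtifactReport:
    accepted: bool
    reasons: list[str] = field(default_factory=list)
    details: dict[str, list[float]] = field(default_factory=dict)
    notes: str = BASELINE_INTERPRETATION

    def __post_init__(self) -> None:
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted must be True exactly when reasons is empty")


def _robust_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    return _MAD_TO_SIGMA * float(np.median(np.abs(x - med)))


def _sustained_crossing(seg: np.ndarray, half: float, min_run: int) -> Optional[float]:
    """Fractional index of the first crossing below ``half`` that stays
    below for ``min_run`` samples (robust to brief noise dips)."""
    below = seg < half
    if below.size < min_run:
        return None
    counts = np.convolve(below.astype(np.int32), np.ones(min_run, dtype=np.int32), "valid")
    hits = np.flatnonzero(counts == min_run)
    if hits.size == 0:
        return None
    i = int(hits[0])
    if i == 0:
        return 0.0
    return i - 1 + (seg[i - 1] - half) / (seg[i - 1] - seg[i])


def _half_prominence_width(
    r: np.ndarray, start: int, stop: int, fs: float, search_s: float = 10.0
) -> tuple[int, float, float]:
    """(peak index, width_s at half prominence, prominence) of one excursion.

    The width is measured on the rectified residual, walking out from the
    peak to the first *sustained* half-prominence crossing on each side
    (the signal must stay below half prominence for 100 ms); a monotone
    noise-free excursion gives the exact interpolated crossing, while a
    momentary noise dip inside a wide excursion cannot truncate its width.
    """
    seg = r[start:stop]
    local_peak = int(np.argmax(np.abs(seg)))
    peak = start + local_peak
    sign = 1.0 if r[peak] >= 0 else -1.0
    s = sign * r
    half = s[peak] / 2.0
    min_run = max(1, int(round(0.1 * fs)))
    max_n = max(min_run + 1, int(round(search_s * fs)))

    right_seg = s[peak:peak + max_n]
    right = _sustained_crossing(right_seg, half, min_run)
    right = (max_n - 1.0) if right is None else right

    left_seg = s[max(0, peak - max_n + 1):peak + 1][::-1]
    left = _sustained_crossing(left_seg, half, min_run)
    left = (left_seg.size - 1.0) if left is None else left

    return peak, (left + right) / fs, float(s[peak])


def detect_spikes(
    rec: Recording,
    cfg: ArtifactConfig = ArtifactConfig(),
    events: Optional[EventLog] = None,
    channel: int = 0,
    smooth_hz: float = 4.0,
) -> list[Spike]:
    """Prominent excursions of signal - rolling-median baseline.

    Candidate peaks are found on a gently low-passed residual with a
    *prominence* threshold of ``spike_threshold_mads`` robust sigmas:
    prominence (height above the saddle to neighbouring structure) rejects
    noise tips riding on the shoulder of a genuine slow response, and the
    smoothing removes above-band residual noise that would otherwise
    multiply the threshold-crossing chances.  Width at half prominence and
    amplitude are then measured on the raw residual, so clean synthetic
    excursions report their exact analytic widths.

    Returns every prominent excursion regardless of width (the fast/slow
    distinction is applied by :func:`reject_trace`).  With ``events``
    given, noise is estimated on the pre-stimulus residual only.
    """
    x = rec.channel(channel)
    fs = rec.sampling_rate
    base = _signal.rolling_median(x, fs, cfg.spike_baseline_window_s)
    r1 = x - base
    # second-stage short median absorbs everything slower than the fast-spike
    # scale (response bumps, high-pass undershoots, their tracking errors);
    # excursions narrower than fast_spike_max_width_s occupy < 50 % of the
    # window and pass through exactly
    fast_window = 2.0 * cfg.fast_spike_max_width_s
    r2 = r1 - _signal.rolling_median(r1, fs, fast_window)

    def _noise_seg(arr: np.ndarray) -> np.ndarray:
        if events is not None:
            ons = events.stimulus_on_times()
            if ons:
                stop = int(round(ons[0] * fs))
                if stop >= int(1.0 * fs):
                    return arr[:stop]
        return arr

    def _candidates(residual: np.ndarray) -> list[Spike]:
        rs = _signal.lowpass(residual, fs, smooth_hz) if smooth_hz < fs / 4 else residual
        sigma = _robust_sigma(_noise_seg(rs))
        if sigma == 0.0:
            sigma = float(np.finfo(np.float64).tiny)
        threshold = cfg.spike_threshold_mads * sigma
        # the excursion must also clear the threshold in *unsmoothed* robust
        # sigmas, so the detector is not over-sensitive on broadband inputs
        sigma_raw = _robust_sigma(_noise_seg(residual))
        min_amplitude = cfg.spike_threshold_mads * (
            sigma_raw or float(np.finfo(np.float64).tiny)
        )
        refine = max(1, int(round(0.5 * fs / smooth_hz)))
        # the rolling baseline is one-sided within the first/last second,
        # and pre-stimulus/response windows are interior anyway
        guard = int(round(1.0 * fs))
        found: dict[int, Spike] = {}
        for sign in (1.0, -1.0):
            peaks, _ = _scipy_signal.find_peaks(
                sign * rs, height=threshold, prominence=threshold
            )
            peaks = peaks[(peaks >= guard) & (peaks < rs.size - guard)]
            raw = sign * residual
            for p in peaks:
                lo = max(0, p - refine)
                hi = min(raw.size, p + refine + 1)
                peak = lo + int(np.argmax(raw[lo:hi]))
                if peak in found or raw[peak] < min_amplitude:
                    continue
                _, width_s, prom = _half_prominence_width(raw, peak, peak + 1, fs)
                found[peak] = Spike(peak_time_s=peak / fs, width_s=width_s, amplitude=prom)
        return sorted(found.values(), key=lambda sp: sp.peak_time_s)

    # candidate peaks and widths from the full residual (so prominence and
    # width keep their plain meaning for response-scale excursions) ...
    candidates = _candidates(r1)

    # ... but a *narrow* candidate must also stand out in the short-median
    # residual, where slow structure and its tracking error are absent: a
    # real sub-half-second transient passes r2 unchanged, while a noise tip
    # that only crossed threshold by riding on a slow baseline-tracking
    # offset does not.
    r2s = _signal.lowpass(r2, fs, smooth_hz) if smooth_hz < fs / 4 else r2
    sigma2 = _robust_sigma(_noise_seg(r2s))
    thr2 = cfg.spike_threshold_mads * (sigma2 or float(np.finfo(np.float64).tiny))
    halo = max(1, int(round(0.025 * fs)))
    spikes = []
    for sp in candidates:
        if sp.width_s < cfg.fast_spike_max_width_s:
            peak = int(round(sp.peak_time_s * fs))
            lo, hi = max(0, peak - halo), min(r2s.size, peak + halo + 1)
            if float(np.max(np.abs(r2s[lo:hi]))) < thr2:
                continue
        spikes.append(sp)
    return spikes


def _clipping_times(x: np.ndarray, fs: float, cfg: ArtifactConfig) -> list[float]:
    mask = np.abs(x) >= 1.0 - cfg.clip_margin
    min_run = max(1, int(round(cfg.clip_min_run_s * fs)))
    return [
        start / fs
        for start, stop in _signal.contiguous_regions(mask)
        if stop - start >= min_run
    ]


def reject_trace(
    rec: Recording,
    events: Optional[EventLog] = None,
    cfg: ArtifactConfig = ArtifactConfig(),
    channel: int = 0,
) -> ArtifactReport:
    """Apply the three rejection filters to one trace."""
    x = rec.channel(channel)
    fs = rec.sampling_rate
    spikes = detect_spikes(rec, cfg, events=events, channel=channel)

    reasons: list[str] = []
    details: dict[str, list[float]] = {}

    fast = [s.peak_time_s for s in spikes if s.width_s < cfg.fast_spike_max_width_s]
    if fast:
        reasons.append(FAST_SPIKE)
        details[FAST_SPIKE] = fast

    clips = _clipping_times(x, fs, cfg)
    if clips:
        reasons.append(CLIPPING)
        details[CLIPPING] = clips

    extremum = float(np.max(np.abs(x))) if x.size else 0.0
    if extremum > 0 and spikes:
        elevated = []
        win = int(round(cfg.baseline_window_s * fs))
        for s in spikes:
            # baseline over the window just before the excursion (see module docstring)
            onset = int(round((s.peak_time_s - s.width_s) * fs))
            start = max(0, onset - win)
            if onset <= start:
                continue
            pre_baseline = float(np.median(x[start:onset]))
            if abs(pre_baseline) > cfg.baseline_fraction * extremum:
                elevated.append(s.peak_time_s)
        if elevated:
            reasons.append(ELEVATED_BASELINE)
            details[ELEVATED_BASELINE] = elevated

    return ArtifactReport(accepted=not reasons, reasons=reasons, details=details)


def batch_report_frame(reports: list[tuple[str, ArtifactReport]]) -> pd.DataFrame:
    """Tabular batch report: id, accepted, reasons, first event time per reason."""
    rows = []
    for rec_id, rep in reports:
        rows.append(
            {
                "recording_id": rec_id,
                "accepted": rep.accepted,
                "reasons": ";".join(rep.reasons),
                **{
                    f"first_{reason}_s": round(times[0], 4)
                    for reason, times in rep.details.items()
                    if times
                },
            }
        )
    return pd.DataFrame(rows)


def write_batch_report(path: str | Path, reports: list[tuple[str, ArtifactReport]]) -> None:
    batch_report_frame(reports).to_csv(Path(path), index=False)
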