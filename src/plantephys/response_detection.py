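"""Stimulus-locked response classification and species response libraries.

A trace counts as responsive when, inside the post-stimulus response
window, it deviates more than 75 % outside the signal range observed
before the stimulus: with pre-stimulus range (lo, hi) and R = hi - lo, a
crossing is any sample strictly above hi + 0.75 R or strictly below
lo - 0.75 R.  The criterion is two-sided, so classification is invariant
to the recorded sign.  Onset latency is the first crossing time relative
to stimulus onset.

Species libraries average normalised, peak-aligned epochs across
recordings; an entry is only produced once at least ``min_peaks`` epochs
survive artifact rejection and classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import preprocessing
from .preprocessing import Epoch
from .recordings_io import EventLog, Recording


@dataclass(frozen=True)
class DetectionConfig:
    deviation_fraction: float = 0.75
    pre_window_s: float = 30.0
    response_window_s: float = 60.0
    #: floor on the pre-stimulus range so a perfectly flat baseline cannot
    #: be trivially "responsive" to quantization noise (full-scale units)
    min_prestim_range: float = 1e-4

    def __post_init__(self) -> None:
        if self.deviation_fraction <= 0:
            raise ValueError("deviation_fraction must be positive")
        if self.pre_window_s <= 0 or self.response_window_s <= 0:
            raise ValueError("windows must be positive")
        if self.min_prestim_range < 0:
            raise ValueError("min_prestim_range must be >= 0")


@dataclass(frozen=True)
class PrestimRange:
    lo: float
    hi: float
    degenerate: bool = False

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class DetectionResult:
    responsive: bool
    onset_latency_s: Optional[float] = None
    peak_time_s: Optional[float] = None
    peak_amplitude: Optional[float] = None
    prestim_range: Optional[PrestimRange] = None
    epoch: Optional[Epoch] = None
    degenerate_baseline: bool = False
    species: str = ""

    def __post_init__(self) -> None:
        if self.responsive != (self.onset_latency_s is not None):
            raise ValueError("onset_latency_s must be present exactly when responsive")
        if self.onset_latency_s is not None and self.onset_latency_s < 0:
            raise ValueError("onset_latency_s must be >= 0")


@dataclass(frozen=True)
class LibraryConfig:
    min_peaks: int = 10

    def __post_init__(self) -> None:
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")


@dataclass
class SpeciesLibraryEntry:
    species: str
    n_epochs: int
    mean_trace: np.ndarray
    sd_trace: np.ndarray
    responsive_fraction: float
    sampling_rate: float
    t0_offset_s: float

    def __post_init__(self) -> None:
        if len(self.mean_trace) != len(self.sd_trace):
            raise ValueError("mean_trace and sd_trace must have equal length")
        if not 0 <= self.responsive_fraction <= 1:
            raise ValueError("responsive_fraction must be in [0, 1]")


class InsufficientPeaksError(ValueError):
    """Fewer peak-aligned epochs than the library requires."""

    def __init__(self, species: str, n_found: int, required: int):
        self.species, self.n_found, self.required = species, n_found, required
        super().__init__(
            f"species {species!r}: {n_found} epochs after artifact rejection, "
            f"library requires at least {required}"
        )


@dataclass(frozen=True)
class CohortSummary:
    n_species: int
    n_responsive: int

    @property
    def pct_responsive_exact(self) -> float:
        return 100.0 * self.n_responsive / self.n_species

    @property
    def pct_responsive(self) -> int:
        return int(round(self.pct_responsive_exact))


# --------------------------------------------------------------------------


def prestimulus_range(
    rec: Recording,
    events: EventLog,
    cfg: DetectionConfig = DetectionConfig(),
    channel: int = 0,
    trial: int = 0,
) -> PrestimRange:
    """Min/max of the signal over [stimulus_on - pre_window_s, stimulus_on).

    A narrower-than-``min_prestim_range`` window is widened symmetrically
    and flagged degenerate.
    """
    ons = events.stimulus_on_times()
    if not ons:
        raise ValueError("no stimulus_on marker")
    on = ons[trial]
    fs = rec.sampling_rate
    stop = int(round(on * fs))
    start = max(0, int(round((on - cfg.pre_window_s) * fs)))
    if stop <= start:
        raise ValueError(f"stimulus_on at {on} s leaves no pre-stimulus data")
    window = rec.channel(channel)[start:stop]
    lo, hi = float(window.min()), float(window.max())
    if hi - lo < cfg.min_prestim_range:
        pad = (cfg.min_prestim_range - (hi - lo)) / 2.0
        return PrestimRange(lo=lo - pad, hi=hi + pad, degenerate=True)
    return PrestimRange(lo=lo, hi=hi)


def classify_response(
    rec: Recording,
    events: EventLog,
    cfg: DetectionConfig = DetectionConfig(),
    channel: int = 0,
    trial: int = 0,
    build_epoch: bool = True,
) -> DetectionResult:
    """Classify one stimulus trial with the 75 %-of-prestimulus-range rule.

    Works on the baseline-subtracted raw trace (before normalisation).
    ``trial`` selects which stimulus_on marker anchors the analysis.  The
    returned epoch (responsive traces only) is sign-normalised, unit-peak
    and peak-aligned.
    """
    rec = preprocessing.baseline_subtract(rec, events, window_s=cfg.pre_window_s)
    pr = prestimulus_range(rec, events, cfg, channel=channel, trial=trial)
    on = events.stimulus_on_times()[trial]
    fs = rec.sampling_rate
    x = rec.channel(channel)
    start = int(round(on * fs)) + 1  # window is open at stimulus_on
    stop = min(x.size, int(round((on + cfg.response_window_s) * fs)) + 1)
    window = x[start:stop]
    if window.size == 0:
        raise ValueError("no post-stimulus data inside the response window")

    margin = cfg.deviation_fraction * pr.width
    crossings = (window > pr.hi + margin) | (window < pr.lo - margin)
    responsive = bool(crossings.any())

    if not responsive:
        return DetectionResult(
            responsive=False,
            prestim_range=pr,
            degenerate_baseline=pr.degenerate,
            species=rec.species,
        )

    onset_idx = int(np.argmax(crossings))
    onset_latency = (start + onset_idx) / fs - on
    peak_idx = start + int(np.argmax(np.abs(window)))
    peak_time = peak_idx / fs
    peak_amplitude = float(x[peak_idx])

    epoch = None
    if build_epoch:
        raw = preprocessing.extract_epoch(rec, peak_time, channel=channel)
        epoch = preprocessing.normalize_amplitude(preprocessing.sign_invert_if_negative(raw))
        epoch = preprocessing.peak_align([epoch])[0]

    return DetectionResult(
        responsive=True,
        onset_latency_s=onset_latency,
        peak_time_s=peak_time,
        peak_amplitude=peak_amplitude,
        prestim_range=pr,
        epoch=epoch,
        degenerate_baseline=pr.degenerate,
        species=rec.species,
    )


def classify_all_trials(
    rec: Recording,
    events: EventLog,
    cfg: DetectionConfig = DetectionConfig(),
    channel: int = 0,
) -> list[DetectionResult]:
    """One DetectionResult per stimulus_on marker; a recording counts as
    responsive when any trial is."""
    return [
        classify_response(rec, events, cfg, channel=channel, trial=i)
        for i in range(len(events.stimulus_on_times()))
    ]


def build_species_library(
    results: list[DetectionResult],
    lib_cfg: LibraryConfig = LibraryConfig(),
) -> SpeciesLibraryEntry:
    """Pointwise mean ± sd over the responsive, normalised, aligned epochs.

    Raises :class:`InsufficientPeaksError` (an explicit outcome, never a
    silent omission) when fewer than ``min_peaks`` epochs are available.
    """
    if not results:
        raise ValueError("no detection results")
    species = {r.species for r in results}
    if len(species) > 1:
        raise ValueError(f"results span several species: {sorted(species)}")
    species_name = species.pop()
    epochs = [r.epoch for r in results if r.responsive and r.epoch is not None]
    if len(epochs) < lib_cfg.min_peaks:
        raise InsufficientPeaksError(species_name, len(epochs), lib_cfg.min_peaks)
    lengths = {e.samples.size for e in epochs}
    if len(lengths) > 1:
        raise ValueError(f"epochs have differing lengths: {sorted(lengths)}")
    stack = np.vstack([e.samples for e in epochs])
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    return SpeciesLibraryEntry(
        species=species_name,
        n_epochs=len(epochs),
        mean_trace=stack.mean(axis=0),
        sd_trace=sd,
        responsive_fraction=len(epochs) / len(results),
        sampling_rate=epochs[0].sampling_rate,
        t0_offset_s=epochs[0].t0_offset_s,
    )


def summarize_cohort(per_species: list[tuple[str, bool]]) -> CohortSummary:
    """Percent of species with at least one responsive accepted recording.

    Input rows are (species, any responsive recording?); duplicate species
    rows are OR-combined.
    """
    if not per_species:
        raise ValueError("empty cohort")
    by_species: dict[str, bool] = {}
    for name, flag in per_species:
        by_species[name] = by_species.get(name, False) or bool(flag)
    return CohortSummary(
        n_species=len(by_species),
        n_responsive=sum(by_species.values()),
    )


# --------------------------------------------------------------------------
# exports


def detection_frame(rows: list[tuple[str, bool, Optional[DetectionResult]]]) -> pd.DataFrame:
    """Tabular per-recording detection report.

    Rows are (recording id, accepted, result-or-None-if-rejected).
    """
    out = []
    for rec_id, accepted, res in rows:
        row: dict = {"recording_id": rec_id, "accepted": accepted}
        if res is not None:
            row.update(
                species=res.species,
                responsive=res.responsive,
                onset_latency_s=None if res.onset_latency_s is None else round(res.onset_latency_s, 4),
                peak_time_s=None if res.peak_time_s is None else round(res.peak_time_s, 4),
                prestim_lo=None if res.prestim_range is None else round(res.prestim_range.lo, 6),
                prestim_hi=None if res.prestim_range is None else round(res.prestim_range.hi, 6),
                flags="degenerate_baseline" if res.degenerate_baseline else "",
            )
        out.append(row)
    return pd.DataFrame(out)


def write_library_csv(path: str | Path, entry: SpeciesLibraryEntry) -> None:
    """Per-species (time_s, mean, sd) export of a library entry."""
    times = entry.t0_offset_s + np.arange(len(entry.mean_trace)) / entry.sampling_rate
    pd.DataFrame(
        {"time_s": times, "mean": entry.mean_trace, "sd": entry.sd_trace}
    ).to_csv(Path(path), index=False, float_format="%.6f")
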