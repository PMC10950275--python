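"""Seeded synthetic plant electrophysiology recordings.

Generates recordings with the statistical structure the analysis pipeline
assumes, so that every downstream stage (artifact rejection, stimulus-locked
detection, response libraries, conduction velocity) is testable without the
original raw data.

Waveforms are phenomenological, not biophysical:

* **Wound potentials** — monophasic seconds-scale deflections modelled as a
  double exponential (fast rise, slow decay), appearing 3–6 s after stimulus
  onset.
* **Action potentials** — the faster transient impulses of venus flytrap and
  sensitive mimosa, parameterised by total duration (fast 1–3 s, slow
  5–15 s) with a short latency after the tactile stimulus.

The amplifier model reproduces the AC recording chain: causal Butterworth
band-pass (0.07–8.8 Hz single-channel, 0.2–130 Hz two-channel) at 10 kHz.
Noise is white + slow sinusoidal drift + mains hum, all passed through the
amplifier.  Two-channel generation delays the waveform on channel 2 by an
integer number of samples matching separation / velocity, with independent
noise per channel.  All randomness flows from one explicit integer seed per
call; identical (preset, seed) gives bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import signal as _scipy_signal

from . import _signal
from .recordings_io import (
    Event,
    EventKind,
    EventLog,
    Recording,
    write_events,
    write_wav,
)

DEFAULT_DURATION_S = 120.0
DEFAULT_STIMULUS_ON_S = 30.0

#: real noise samples synthesized beyond each end and trimmed after the
#: amplifier filter, so sub-Hz corner transients never touch the recording
_EDGE_PAD_S = 25.0


# --------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class WoundPotentialModel:
    """Slow monophasic deflection following tissue damage.

    ``amplitude`` is the recorded-trace peak in full-scale units.  The onset
    latency is drawn uniformly from ``latency_range_s`` unless ``latency_s``
    pins it.  ``polarity`` ±1, or None to draw each sign with probability
    one half (the recorded sign is electrode-placement dependent).
    """

    amplitude: float = 0.5
    latency_s: Optional[float] = None
    latency_range_s: tuple[float, float] = (3.0, 6.0)
    rise_tau_s: float = 0.4
    decay_tau_s: float = 8.0
    polarity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if self.latency_s is not None and self.latency_s <= 0:
            raise ValueError("latency_s must be positive")
        if self.latency_range_s[0] <= 0 or self.latency_range_s[1] < self.latency_range_s[0]:
            raise ValueError("latency_range_s must be an increasing positive pair")
        if self.polarity not in (None, 1, -1):
            raise ValueError("polarity must be +1, -1 or None")


@dataclass(frozen=True)
class ActionPotentialModel:
    """Transient impulse (flytrap / mimosa style), set by total duration."""

    duration_s: float = 2.0
    amplitude: float = 0.5
    latency_s: Optional[float] = None
    latency_range_s: tuple[float, float] = (0.5, 1.5)
    polarity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.polarity not in (None, 1, -1):
            raise ValueError("polarity must be +1, -1 or None")


Waveform = Union[WoundPotentialModel, ActionPotentialModel]


@dataclass(frozen=True)
class AmplifierModel:
    """AC amplifier: gain plus causal Butterworth band limits.

    Filtering is causal (like the analog hardware), so a response can
    never bleed backwards past its own onset — essential for the
    stimulus-locked latency semantics downstream.
    """

    gain: float = 72.0
    band_low_hz: float = 0.07
    band_high_hz: float = 8.8
    sampling_rate_hz: float = 10_000.0
    order: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz < self.sampling_rate_hz / 2:
            raise ValueError("require 0 < band_low < band_high < Nyquist")

    def sos(self) -> np.ndarray:
        return _signal.bandpass_sos(
            self.band_low_hz, self.band_high_hz, self.sampling_rate_hz, self.order
        )

    def apply(self, x: np.ndarray) -> np.ndarray:
        return _scipy_signal.sosfilt(self.sos(), x)

    def white_noise_gain(self) -> float:
        """sd ratio out/in for white noise (mean |H|^2 over frequency)."""
        _, h = _scipy_signal.sosfreqz(self.sos(), worN=65536, fs=self.sampling_rate_hz)
        return float(np.sqrt(np.mean(np.abs(h) ** 2)))


SINGLE_CHANNEL_AMPLIFIER = AmplifierModel(gain=72.0, band_low_hz=0.07, band_high_hz=8.8)
TWO_CHANNEL_AMPLIFIER = AmplifierModel(gain=55.0, band_low_hz=0.2, band_high_hz=130.0)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument/environment noise.

    ``white_sd`` is the *post-amplifier* (in-band) white-noise sd; the raw
    broadband noise is rescaled by the filter's measured white-noise gain.
    Drift and hum amplitudes are pre-amplifier and get band-limited like any
    other input.
    """

    white_sd: float = 0.02
    drift_amplitude: float = 0.01
    drift_period_s: float = 50.0
    hum_amplitude: float = 0.005
    hum_freq_hz: float = 50.0

    def __post_init__(self) -> None:
        for name in ("white_sd", "drift_amplitude", "hum_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_period_s <= 0 or self.hum_freq_hz <= 0:
            raise ValueError("drift_period_s and hum_freq_hz must be positive")


@dataclass(frozen=True)
class PropagationSpec:
    """Two-electrode geometry and the true propagation speed."""

    separation_mm: float
    true_velocity_mm_s: float

    def __post_init__(self) -> None:
        if self.separation_mm <= 0 or self.true_velocity_mm_s <= 0:
            raise ValueError("separation_mm and true_velocity_mm_s must be positive")

    @property
    def delta_t_s(self) -> float:
        return self.separation_mm / self.true_velocity_mm_s


@dataclass(frozen=True)
class SpeciesPreset:
    name: str
    responsive: bool
    waveform: Optional[Waveform] = None
    stimulus: str = "flame"
    stimulus_duration_s: float = 3.0
    amplifier: AmplifierModel = SINGLE_CHANNEL_AMPLIFIER
    noise: NoiseModel = NoiseModel()
    velocity_list_mm_s: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.responsive != (self.waveform is not None):
            raise ValueError("responsive presets need a waveform; non-responsive must not have one")
        if not 0 < self.stimulus_duration_s:
            raise ValueError("stimulus_duration_s must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually embedded, for parameter-recovery tests."""

    species: str
    responsive: bool
    latency_s: Optional[float] = None
    peak_time_s: Optional[float] = None
    polarity: Optional[int] = None
    delta_t_s: Optional[float] = None
    separation_mm: Optional[float] = None
    true_velocity_mm_s: Optional[float] = None


# --------------------------------------------------------------------------
# preset registry
#
# One preset per species studied; the responsive/non-responsive split (9 / 7)
# mirrors the study cohort.  The sundew two-channel velocities are the fixed
# arithmetic series 2.2, 2.4, ..., 4.2 mm/s (mean exactly 3.2 mm/s); tomato
# and mimosa two-channel presets carry the single observed speeds 9 and
# 8 mm/s.

_TWO_CHANNEL_NOISE = NoiseModel(white_sd=0.002, drift_amplitude=0.005, hum_amplitude=0.002)

RESPONSIVE_SPECIES = (
    "argentinian_dollar",
    "basil",
    "mint",
    "rosemary",
    "ruda",
    "mimosa",
    "sundew",
    "tomato",
    "venus_flytrap",
)
NONRESPONSIVE_SPECIES = (
    "araucaria",
    "fern",
    "ivy",
    "lemon_balm",
    "oregano",
    "papyrus",
    "radiators",
)

SUNDEW_VELOCITY_SERIES_MM_S = tuple(round(2.2 + 0.2 * i, 1) for i in range(11))


def _wound(**kw) -> WoundPotentialModel:
    return WoundPotentialModel(**kw)


def _make_presets() -> dict[str, SpeciesPreset]:
    presets: dict[str, SpeciesPreset] = {}
    for name in RESPONSIVE_SPECIES:
        if name == "venus_flytrap":
            wf: Waveform = ActionPotentialModel(duration_s=2.0)
            stim = "tactile"
        elif name == "mimosa":
            wf = ActionPotentialModel(duration_s=2.5)
            stim = "tactile"
        else:
            wf = _wound()
            stim = "flame"
        presets[name] = SpeciesPreset(name=name, responsive=True, waveform=wf, stimulus=stim)
    for name in NONRESPONSIVE_SPECIES:
        presets[name] = SpeciesPreset(name=name, responsive=False, waveform=None)
    presets["mimosa_slow"] = SpeciesPreset(
        name="mimosa_slow",
        responsive=True,
        waveform=ActionPotentialModel(duration_s=8.0),
        stimulus="tactile",
    )
    presets["sundew_two_channel"] = SpeciesPreset(
        name="sundew_two_channel",
        responsive=True,
        waveform=_wound(polarity=1),
        stimulus="flame",
        amplifier=TWO_CHANNEL_AMPLIFIER,
        noise=_TWO_CHANNEL_NOISE,
        velocity_list_mm_s=SUNDEW_VELOCITY_SERIES_MM_S,
    )
    presets["tomato_two_channel"] = SpeciesPreset(
        name="tomato_two_channel",
        responsive=True,
        waveform=_wound(polarity=1),
        stimulus="flame",
        amplifier=TWO_CHANNEL_AMPLIFIER,
        noise=_TWO_CHANNEL_NOISE,
        velocity_list_mm_s=(9.0,),
    )
    presets["mimosa_two_channel"] = SpeciesPreset(
        name="mimosa_two_channel",
        responsive=True,
        waveform=ActionPotentialModel(duration_s=2.0, polarity=1),
        stimulus="tactile",
        amplifier=TWO_CHANNEL_AMPLIFIER,
        noise=_TWO_CHANNEL_NOISE,
        velocity_list_mm_s=(8.0,),
    )
    return presets


PRESETS = _make_presets()


def get_preset(name: str) -> SpeciesPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None


# --------------------------------------------------------------------------
# waveform synthesis


def _double_exp(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak double exponential, zero for t < 0."""
    if rise_tau >= decay_tau:
        rise_tau = 0.999 * decay_tau  # keep the log-ratio peak formula defined
    w = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_tau) - np.exp(-np.maximum(t, 0) / rise_tau), 0.0)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    return w / peak


def _waveform_taus(model: Waveform) -> tuple[float, float]:
    if isinstance(model, WoundPotentialModel):
        return model.rise_tau_s, model.decay_tau_s
    # action potential: taus derived from total duration
    return model.duration_s / 8.0, model.duration_s / 3.0


def _draw_latency(model: Waveform, rng: np.random.Generator) -> float:
    if model.latency_s is not None:
        return float(model.latency_s)
    lo, hi = model.latency_range_s
    return float(rng.uniform(lo, hi))


def _draw_polarity(model: Waveform, rng: np.random.Generator) -> int:
    if model.polarity is not None:
        return int(model.polarity)
    return 1 if rng.random() < 0.5 else -1


def _raw_noise(
    noise: NoiseModel, amp: AmplifierModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    fs = amp.sampling_rate_hz
    t = np.arange(n) / fs
    out = np.zeros(n)
    if noise.white_sd > 0:
        out += rng.normal(0.0, noise.white_sd / amp.white_noise_gain(), n)
    if noise.drift_amplitude > 0:
        out += noise.drift_amplitude * np.sin(
            2 * np.pi * t / noise.drift_period_s + rng.uniform(0, 2 * np.pi)
        )
    if noise.hum_amplitude > 0:
        out += noise.hum_amplitude * np.sin(
            2 * np.pi * noise.hum_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    return out


def _events_for(stimulus_on_s: float, stimulus_duration_s: float) -> EventLog:
    return EventLog(
        events=[
            Event(stimulus_on_s, EventKind.STIMULUS_ON),
            Event(stimulus_on_s + stimulus_duration_s, EventKind.STIMULUS_OFF),
        ]
    )


# --------------------------------------------------------------------------
# generators


def _filtered_noise(
    noise: NoiseModel, amp: AmplifierModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited noise with real (not mirrored) edge padding trimmed off."""
    pad = int(round(_EDGE_PAD_S * amp.sampling_rate_hz))
    raw = _raw_noise(noise, amp, n + 2 * pad, rng)
    return amp.apply(raw)[pad:pad + n]


def _filtered_wave(
    model: Waveform,
    amp: AmplifierModel,
    n: int,
    onset_s: float,
    polarity: int,
) -> np.ndarray:
    """Amplifier-filtered waveform whose *post-filter* peak magnitude equals
    ``model.amplitude`` — so preset amplitudes are recorded-trace peaks and
    amplitude / white_sd is the trace SNR by construction."""
    fs = amp.sampling_rate_hz
    pad = int(round(_EDGE_PAD_S * fs))
    t = (np.arange(n + 2 * pad) - pad) / fs
    rise, decay = _waveform_taus(model)
    unit = _double_exp(t - onset_s, rise, decay)
    fw = amp.apply(unit)[pad:pad + n]
    peak = float(np.max(np.abs(fw)))
    if peak == 0.0:
        raise ValueError("waveform lies entirely outside the recording")
    return model.amplitude * polarity / peak * fw


def generate_recording(
    preset: SpeciesPreset,
    seed: int,
    duration_s: float = DEFAULT_DURATION_S,
    stimulus_on_s: float = DEFAULT_STIMULUS_ON_S,
) -> tuple[Recording, EventLog, GroundTruth]:
    """One single-channel recording: filtered (waveform + noise).

    Ground truth records the latency/polarity actually drawn and the peak
    time of the noise-free filtered waveform.
    """
    rng = np.random.default_rng(seed)
    amp = preset.amplifier
    fs = amp.sampling_rate_hz
    n = int(round(duration_s * fs))
    events = _events_for(stimulus_on_s, preset.stimulus_duration_s)

    if preset.responsive:
        assert preset.waveform is not None
        latency = _draw_latency(preset.waveform, rng)
        polarity = _draw_polarity(preset.waveform, rng)
        fw = _filtered_wave(preset.waveform, amp, n, stimulus_on_s + latency, polarity)
        peak_idx = int(np.argmax(np.abs(fw)))
        truth = GroundTruth(
            species=preset.name,
            responsive=True,
            latency_s=latency,
            peak_time_s=peak_idx / fs,
            polarity=polarity,
        )
        signal = fw + _filtered_noise(preset.noise, amp, n, rng)
    else:
        truth = GroundTruth(species=preset.name, responsive=False)
        signal = _filtered_noise(preset.noise, amp, n, rng)

    rec = Recording(
        samples=signal[None, :],
        sampling_rate=fs,
        species=preset.name,
        plant_id=f"{preset.name}-s{seed}",
        source="synthetic",
    )
    return rec, events, truth


def generate_two_channel(
    preset: SpeciesPreset,
    prop: PropagationSpec,
    seed: int,
    duration_s: float = DEFAULT_DURATION_S,
    stimulus_on_s: float = DEFAULT_STIMULUS_ON_S,
) -> tuple[Recording, EventLog, GroundTruth]:
    """Two-channel recording with the waveform delayed on channel 2.

    The delay is quantised to an integer number of samples, so on noiseless
    presets the channel-2 peak index minus the channel-1 peak index equals
    ``round(delta_t * fs)`` exactly.  Noise is independent per channel.
    """
    if not preset.responsive:
        raise ValueError("two-channel generation needs a responsive preset (a propagating event)")
    assert preset.waveform is not None
    rng = np.random.default_rng(seed)
    amp = preset.amplifier
    fs = amp.sampling_rate_hz
    n = int(round(duration_s * fs))

    delta_t = prop.delta_t_s
    n_delay = int(round(delta_t * fs))
    latency = _draw_latency(preset.waveform, rng)
    polarity = _draw_polarity(preset.waveform, rng)
    if stimulus_on_s + latency + delta_t >= duration_s - 1.0:
        raise ValueError(
            f"delayed event at {stimulus_on_s + latency + delta_t:.1f} s does not fit "
            f"in a {duration_s:.1f} s recording"
        )
    fw = _filtered_wave(preset.waveform, amp, n, stimulus_on_s + latency, polarity)
    shifted = np.zeros_like(fw)
    if n_delay < n:
        shifted[n_delay:] = fw[: n - n_delay]
    ch1 = fw + _filtered_noise(preset.noise, amp, n, rng)
    ch2 = shifted + _filtered_noise(preset.noise, amp, n, rng)

    peak_idx = int(np.argmax(np.abs(fw)))
    truth = GroundTruth(
        species=preset.name,
        responsive=True,
        latency_s=latency,
        peak_time_s=peak_idx / fs,
        polarity=polarity,
        delta_t_s=delta_t,
        separation_mm=prop.separation_mm,
        true_velocity_mm_s=prop.true_velocity_mm_s,
    )
    rec = Recording(
        samples=np.vstack([ch1, ch2]),
        sampling_rate=fs,
        species=preset.name,
        plant_id=f"{preset.name}-s{seed}",
        source="synthetic",
    )
    return rec, _events_for(stimulus_on_s, preset.stimulus_duration_s), truth


def generate_cohort(
    n_responsive: int,
    n_nonresponsive: int,
    seed: int,
    duration_s: float = DEFAULT_DURATION_S,
    stimulus_on_s: float = DEFAULT_STIMULUS_ON_S,
) -> list[tuple[Recording, EventLog, GroundTruth]]:
    """One recording per synthetic species: responsive presets first, then
    noise-only presets.  Child seeds derive deterministically from ``seed``.
    """
    if n_responsive < 0 or n_nonresponsive < 0:
        raise ValueError("counts must be >= 0")
    if n_responsive + n_nonresponsive == 0:
        raise ValueError("cohort must contain at least one recording")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_responsive):
        base = RESPONSIVE_SPECIES[i % len(RESPONSIVE_SPECIES)]
        preset = get_preset(base)
        if i >= len(RESPONSIVE_SPECIES):
            preset = replace(preset, name=f"{base}_{i // len(RESPONSIVE_SPECIES) + 1}")
        out.append(
            generate_recording(preset, int(rng.integers(0, 2**31)), duration_s, stimulus_on_s)
        )
    for i in range(n_nonresponsive):
        base = NONRESPONSIVE_SPECIES[i % len(NONRESPONSIVE_SPECIES)]
        preset = get_preset(base)
        if i >= len(NONRESPONSIVE_SPECIES):
            preset = replace(preset, name=f"{base}_{i // len(NONRESPONSIVE_SPECIES) + 1}")
        out.append(
            generate_recording(preset, int(rng.integers(0, 2**31)), duration_s, stimulus_on_s)
        )
    return out


# --------------------------------------------------------------------------
# artifact injection

ARTIFACT_KINDS = ("fast_spike", "clipping", "baseline_jump")


def inject_artifact(rec: Recording, kind: str, seed: int) -> Recording:
    """Return a copy of ``rec`` with one artifact added to channel 1.

    fast_spike
        Gaussian transient, half-prominence width drawn in [50, 300] ms,
        amplitude 10× the trace sd (capped so the trace stays inside full
        scale), random sign, placed mid-recording.
    clipping
        300 ms of samples pinned at ±1 full scale.
    baseline_jump
        Sustained step of 5× the pre-injection extremum starting in the
        first fifth of the recording — an elevated plateau under any
        later activity.  (The step exceeds 75 % of the resulting trace
        peak; it can legitimately co-trigger the clipping rule when it
        leaves full scale.)
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; expected one of {ARTIFACT_KINDS}")
    rng = np.random.default_rng(seed)
    fs = rec.sampling_rate
    samples = rec.samples.copy()
    x = samples[0]
    n = x.size
    t = np.arange(n) / fs
    dur = n / fs

    if kind == "fast_spike":
        width = rng.uniform(0.05, 0.3)  # half-prominence width, s
        center = rng.uniform(0.3, 0.8) * dur
        sign = 1.0 if rng.random() < 0.5 else -1.0
        amp = min(10.0 * float(np.std(x)), 0.95 - float(np.max(np.abs(x))))
        sigma = width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        x += sign * amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    elif kind == "clipping":
        start = rng.uniform(0.3, 0.8) * dur
        sign = 1.0 if rng.random() < 0.5 else -1.0
        i0 = int(start * fs)
        i1 = min(n, i0 + int(0.3 * fs))
        x[i0:i1] = sign * 1.0
    else:  # baseline_jump
        t0 = rng.uniform(0.1, 0.2) * dur
        step = 5.0 * float(np.max(np.abs(x)))
        x[int(t0 * fs):] += step

    return Recording(
        samples=samples,
        sampling_rate=fs,
        species=rec.species,
        plant_id=rec.plant_id,
        source=rec.source,
    )


# --------------------------------------------------------------------------
# on-disk fixtures


def write_ground_truth(path: str | Path, truths: list[tuple[str, GroundTruth]]) -> None:
    """Ground-truth sidecar CSV: (recording id, GroundTruth) rows."""
    rows = []
    for rec_id, gt in truths:
        rows.append(
            {
                "recording_id": rec_id,
                "species": gt.species,
                "responsive": gt.responsive,
                "latency_s": "" if gt.latency_s is None else f"{gt.latency_s:.6f}",
                "peak_time_s": "" if gt.peak_time_s is None else f"{gt.peak_time_s:.6f}",
                "polarity": "" if gt.polarity is None else gt.polarity,
                "delta_t_s": "" if gt.delta_t_s is None else f"{gt.delta_t_s:.6f}",
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def write_fixture(
    out_dir: str | Path,
    rec_id: str,
    rec: Recording,
    events: EventLog,
) -> tuple[Path, Path]:
    """Write one recording as WAV + event txt; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wav_path = out_dir / f"{rec_id}.wav"
    evt_path = out_dir / f"{rec_id}-events.txt"
    write_wav(wav_path, rec)
    write_events(evt_path, events)
    return wav_path, evt_path
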