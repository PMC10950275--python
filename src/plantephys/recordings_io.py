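"""Readers and writers for plant electrophysiology recordings.

Recordings arrive as PCM WAV files (the acquisition software writes the
amplified, AC-coupled signal at 10 kHz) together with a plain-text event log
of manually keyed stimulus markers: ``1`` when the stimulus (flame or tactile
probe) is applied, ``2`` when it is removed.  Amplitudes are kept in
ADC-normalised arbitrary units throughout — the AC amplifiers do not permit
absolute millivolt calibration — with integer full scale mapped to ±1.

Also hosts the species catalog (per-species recording counts and whether an
electrical response was ever observed) and its summary statistics.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


class FormatError(ValueError):
    """A file exists but is not in the expected format."""


class EventValidationError(ValueError):
    """An event log violates ordering/pairing constraints."""


# --------------------------------------------------------------------------
# domain types


@dataclass
class Recording:
    """A 1- or 2-channel sampled voltage trace in arbitrary units.

    ``samples`` has shape (n_channels, n_samples); full scale is ±1.
    """

    samples: np.ndarray
    sampling_rate: float
    species: str = ""
    plant_id: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, samples) array")
        if self.samples.shape[0] not in (1, 2):
            raise ValueError(f"channel_count must be 1 or 2, got {self.samples.shape[0]}")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, index: int = 0) -> np.ndarray:
        return self.samples[index]


class EventKind(enum.Enum):
    STIMULUS_ON = "stimulus_on"
    STIMULUS_OFF = "stimulus_off"


@dataclass(frozen=True)
class Event:
    time_s: float
    kind: EventKind


@dataclass
class EventLog:
    """Time-sorted stimulus on/off markers, validated for pairing."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time_s)
        balance = 0
        for ev in self.events:
            if ev.time_s < 0:
                raise EventValidationError(f"negative event time {ev.time_s}")
            balance += 1 if ev.kind is EventKind.STIMULUS_ON else -1
            if balance < 0:
                raise EventValidationError(
                    f"stimulus_off at {ev.time_s} s has no preceding stimulus_on"
                )

    def __len__(self) -> int:
        return len(self.events)

    def stimulus_on_times(self) -> list[float]:
        return [e.time_s for e in self.events if e.kind is EventKind.STIMULUS_ON]

    def stimulus_off_times(self) -> list[float]:
        return [e.time_s for e in self.events if e.kind is EventKind.STIMULUS_OFF]


@dataclass(frozen=True)
class CatalogEntry:
    common_name: str
    latin_name: str
    electrical_response: bool
    n_recordings: int
    n_plants: int

    def __post_init__(self) -> None:
        if self.n_recordings < 1 or self.n_plants < 1:
            raise ValueError("n_recordings and n_plants must be >= 1")


@dataclass(frozen=True)
class CatalogSummary:
    n_species: int
    n_recordings_total: int
    n_plants_total: int
    n_responsive: int
    pct_responsive_exact: float

    @property
    def pct_responsive(self) -> int:
        """Nearest-integer percent of species with an observed response."""
        return int(round(self.pct_responsive_exact))


# --------------------------------------------------------------------------
# WAV I/O

_INT_FULL_SCALE = {
    np.dtype(np.int16): 2**15,
    np.dtype(np.int32): 2**31,
}


def read_wav(path: str | Path, species: str = "", plant_id: str = "") -> Recording:
    """Read a PCM WAV file into a :class:`Recording`.

    Integer samples are mapped to floats in [-1, 1] against the type's full
    scale (24-bit data arrives left-justified in int32 and maps the same
    way); float WAVs are taken as already normalised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise FormatError(f"{path}: not a PCM WAV file ({exc})") from exc
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] > 2:
        raise FormatError(f"{path}: {data.shape[1]} channels; this pipeline handles 1 or 2")
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _INT_FULL_SCALE:
        samples = data.astype(np.float64) / _INT_FULL_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported sample dtype {data.dtype}")
    return Recording(
        samples=samples.T,
        sampling_rate=float(rate),
        species=species,
        plant_id=plant_id,
        source=str(path),
    )


def write_wav(path: str | Path, rec: Recording) -> None:
    """Write a recording as 16-bit PCM.

    Scaling by 2^15 with saturation at +full-scale-minus-one keeps the
    write→read round-trip error within one 16-bit quantization step.
    """
    scaled = np.round(rec.samples * 2**15)
    data = np.clip(scaled, -(2**15), 2**15 - 1).astype(np.int16)
    wavfile.write(str(Path(path)), int(round(rec.sampling_rate)), data.T.copy())


# --------------------------------------------------------------------------
# event logs

_MARKER_MAP = {"1": EventKind.STIMULUS_ON, "2": EventKind.STIMULUS_OFF}


def _parse_event_line(line: str, dialect: str) -> tuple[str, str]:
    if dialect == "marker_time":
        marker, _, time_part = line.partition(",")
        return marker.strip(), time_part.strip()
    if dialect == "time_marker":
        time_part, _, marker = line.partition("\t")
        return marker.strip(), time_part.strip()
    raise ValueError(f"unknown event-file dialect {dialect!r}")


def read_events(path: str | Path, dialect: str = "marker_time") -> EventLog:
    """Parse a stimulus-marker text file.

    Default dialect is ``marker,time_s`` records with ``#`` comments; the
    ``time_marker`` dialect accepts ``time_s<TAB>marker`` lines instead.
    Markers ``1``/``2`` map to stimulus on/off.  Output is time-sorted.
    """
    path = Path(path)
    events: list[Event] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        marker, time_part = _parse_event_line(line, dialect)
        if marker not in _MARKER_MAP:
            raise FormatError(f"{path}:{lineno}: unknown marker {marker!r}")
        try:
            time_s = float(time_part)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable time {time_part!r}") from exc
        events.append(Event(time_s=time_s, kind=_MARKER_MAP[marker]))
    return EventLog(events=events)


def write_events(path: str | Path, log: EventLog, dialect: str = "marker_time") -> None:
    lines = ["# marker,time_s"] if dialect == "marker_time" else []
    rev = {EventKind.STIMULUS_ON: "1", EventKind.STIMULUS_OFF: "2"}
    for ev in log.events:
        if dialect == "marker_time":
            lines.append(f"{rev[ev.kind]}, {ev.time_s:.4f}")
        else:
            lines.append(f"{ev.time_s:.4f}\t{rev[ev.kind]}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# species catalog

_CATALOG_COLUMNS = ["common_name", "latin_name", "electrical_response", "n_recordings", "n_plants"]


def default_catalog_path() -> Path:
    """Path of the packaged species-catalog fixture."""
    return Path(resources.files("plantephys").joinpath("data/species_catalog.csv"))


def load_catalog(path: str | Path | None = None) -> list[CatalogEntry]:
    """Load a species catalog CSV (one row per species studied)."""
    path = default_catalog_path() if path is None else Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing catalog columns {missing}")
    entries = []
    for _, row in df.iterrows():
        resp_raw = str(row["electrical_response"]).strip().lower()
        if resp_raw not in ("yes", "no"):
            raise FormatError(f"{path}: electrical_response must be Yes/No, got {resp_raw!r}")
        for col in ("n_recordings", "n_plants"):
            if float(row[col]) != int(row[col]):
                raise FormatError(f"{path}: non-integer count in column {col}: {row[col]!r}")
        entries.append(
            CatalogEntry(
                common_name=str(row["common_name"]),
                latin_name=str(row["latin_name"]),
                electrical_response=resp_raw == "yes",
                n_recordings=int(row["n_recordings"]),
                n_plants=int(row["n_plants"]),
            )
        )
    return entries


def catalog_summary(entries: list[CatalogEntry]) -> CatalogSummary:
    """Column totals and the fraction of species with an observed response."""
    if not entries:
        raise ValueError("catalog_summary requires a non-empty catalog")
    n_responsive = sum(e.electrical_response for e in entries)
    return CatalogSummary(
        n_species=len(entries),
        n_recordings_total=sum(e.n_recordings for e in entries),
        n_plants_total=sum(e.n_plants for e in entries),
        n_responsive=n_responsive,
        pct_responsive_exact=100.0 * n_responsive / len(entries),
    )


def gain_divide(rec: Recording, gain: float) -> Recording:
    """Divide amplitudes by an amplifier gain (72 single-channel, 55
    two-channel).  Informational only: AC coupling makes true millivolt
    values unrecoverable, so downstream analysis stays in arbitrary units.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    return replace(rec, samples=rec.samples / gain)
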