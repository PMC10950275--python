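"""Shared fixtures: fast (downsampled) presets so unit tests stay quick.

Full study conditions (10 kHz, 120 s) are exercised in the acceptance
tests; unit tests use 1 kHz variants of the same presets, which leaves
every band edge (0.07-8.8 Hz and 0.2-130 Hz) untouched.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plantephys.synthetic_data import (
    AmplifierModel,
    SpeciesPreset,
    get_preset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FAST_FS = 1000.0


def fast_preset(name: str, **amp_overrides) -> SpeciesPreset:
    """A registry preset re-rated to 1 kHz for quick unit tests."""
    preset = get_preset(name)
    amp = dataclasses.replace(
        preset.amplifier, sampling_rate_hz=FAST_FS, **amp_overrides
    )
    return dataclasses.replace(preset, amplifier=amp)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def basil_fast():
    return fast_preset("basil")


@pytest.fixture
def fern_fast():
    return fast_preset("fern")


@pytest.fixture
def sundew_fast():
    return fast_preset("sundew_two_channel")
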