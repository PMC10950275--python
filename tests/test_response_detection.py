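"""The 75 %-of-prestimulus-range criterion, latency, and species libraries."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from plantephys.preprocessing import Epoch
from plantephys.recordings_io import Event, EventKind, EventLog, Recording
from plantephys.response_detection import (
    DetectionConfig,
    DetectionResult,
    InsufficientPeaksError,
    LibraryConfig,
    build_species_library,
    classify_all_trials,
    classify_response,
    prestimulus_range,
    summarize_cohort,
)
from plantephys.synthetic_data import generate_recording
from tests.conftest import fast_preset

FS = 100.0
CFG = DetectionConfig(pre_window_s=10.0, response_window_s=20.0)


def _rec(x):
    return Recording(samples=np.asarray(x, dtype=float), sampling_rate=FS)


def _events(on=30.0):
    return EventLog(
        events=[Event(on, EventKind.STIMULUS_ON), Event(on + 3, EventKind.STIMULUS_OFF)]
    )


def _trace_with_prerange_and_pulse(pulse_height, lo=-1.0, hi=1.0, n=6000, on=30.0):
    """Noise-free trace: a pre-stimulus square alternation spanning [lo, hi]
    (median 0, so baseline subtraction leaves it untouched), then a
    rectangular post-stimulus pulse of the requested height."""
    x = np.zeros(n)
    pre = slice(int((on - 10) * FS), int(on * FS))
    seg = x[pre]
    seg[0::2] = hi
    seg[1::2] = lo
    x[int((on + 5) * FS): int((on + 7) * FS)] = pulse_height
    return _rec(x)


class TestPrestimulusRange:
    def test_matches_brute_force_min_max(self, rng):
        x = rng.normal(size=6000)
        pr = prestimulus_range(_rec(x), _events(), CFG)
        window = x[int(20 * FS): int(30 * FS)]
        assert pr.lo == window.min()
        assert pr.hi == window.max()
        assert not pr.degenerate

    def test_constant_prestimulus_flags_degenerate_and_widens(self):
        pr = prestimulus_range(_rec(np.zeros(6000)), _events(), CFG)
        assert pr.degenerate
        assert pr.width == pytest.approx(CFG.min_prestim_range)

    def test_stimulus_at_time_zero_errors(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            prestimulus_range(_rec(np.zeros(600)), _events(on=0.0), CFG)


class TestClassifyArithmetic:
    def test_above_threshold_is_responsive(self):
        # pre-range (-1, 1), R = 2: threshold hi + 0.75 R = 2.5
        rec = _trace_with_prerange_and_pulse(2.6)
        assert classify_response(rec, _events(), CFG).responsive

    def test_below_threshold_is_not(self):
        rec = _trace_with_prerange_and_pulse(2.4)
        assert not classify_response(rec, _events(), CFG).responsive

    def test_exact_threshold_is_strict(self):
        lo, hi = -1.0, 1.0
        exact = hi + 0.75 * (hi - lo)
        at = classify_response(_trace_with_prerange_and_pulse(exact), _events(), CFG)
        above = classify_response(
            _trace_with_prerange_and_pulse(exact + 1e-9), _events(), CFG
        )
        assert not at.responsive
        assert above.responsive

    def test_negative_excursions_count_too(self):
        rec = _trace_with_prerange_and_pulse(-2.6)
        res = classify_response(rec, _events(), CFG)
        assert res.responsive
        assert res.peak_amplitude < 0

    def test_sign_symmetry(self):
        rec, events, _ = generate_recording(fast_preset("basil"), 17)
        flipped = Recording(samples=-rec.samples, sampling_rate=rec.sampling_rate)
        a = classify_response(rec, events)
        b = classify_response(flipped, events)
        assert a.responsive == b.responsive
        assert a.onset_latency_s == pytest.approx(b.onset_latency_s)

    def test_amplitude_monotonicity(self, rng):
        """Scaling the embedded pulse up never flips responsive -> not."""
        noise = rng.normal(0.0, 0.02, 6000)
        flags = []
        for height in (0.1, 0.5, 1.0, 2.0, 4.0):
            rec = _trace_with_prerange_and_pulse(height, lo=-0.1, hi=0.1)
            rec = Recording(samples=rec.samples + noise, sampling_rate=FS)
            flags.append(classify_response(rec, _events(), CFG).responsive)
        assert flags == sorted(flags)

    def test_onset_is_first_crossing_time(self):
        rec = _trace_with_prerange_and_pulse(2.6)
        res = classify_response(rec, _events(), CFG)
        assert res.onset_latency_s == pytest.approx(5.0, abs=2.0 / FS)

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError):
            DetectionResult(responsive=True, onset_latency_s=None)
        with pytest.raises(ValueError):
            DetectionResult(responsive=False, onset_latency_s=1.0)


class TestLatencyRecovery:
    def test_pinned_latency_recovered_within_half_second(self):
        preset = fast_preset("basil")
        preset = dataclasses.replace(
            preset, waveform=dataclasses.replace(preset.waveform, latency_s=4.0)
        )
        for seed in (1, 2, 3):
            rec, events, gt = generate_recording(preset, seed)
            res = classify_response(rec, events)
            assert res.responsive
            assert res.onset_latency_s == pytest.approx(4.0, abs=0.5)

    def test_epoch_is_normalized_and_aligned(self):
        rec, events, _ = generate_recording(fast_preset("basil"), 23)
        res = classify_response(rec, events)
        assert res.responsive
        assert float(np.max(np.abs(res.epoch.samples))) == 1.0
        anchor = int(round(10.0 * rec.sampling_rate))
        assert res.epoch.samples[anchor] == 1.0


class TestMultipleTrials:
    def test_one_result_per_stimulus_on(self):
        rec, events, _ = generate_recording(fast_preset("basil"), 23)
        double = EventLog(
            events=events.events
            + [Event(100.0, EventKind.STIMULUS_ON), Event(103.0, EventKind.STIMULUS_OFF)]
        )
        results = classify_all_trials(rec, double)
        assert len(results) == 2
        assert results[0].responsive
        assert not results[1].responsive  # nothing embedded at the second trial


class TestSpeciesLibrary:
    @staticmethod
    def _result(samples, species="basil"):
        epoch = Epoch(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=FS,
            normalized=True,
        )
        return DetectionResult(
            responsive=True,
            onset_latency_s=4.0,
            peak_time_s=35.0,
            peak_amplitude=1.0,
            epoch=epoch,
            species=species,
        )

    def test_pointwise_mean_matches_brute_force(self, rng):
        mats = rng.normal(size=(12, 50))
        entry = build_species_library([self._result(row) for row in mats])
        assert entry.n_epochs == 12
        oracle_mean = [sum(mats[:, j]) / 12 for j in range(50)]
        assert np.allclose(entry.mean_trace, oracle_mean)
        oracle_sd = [
            (sum((mats[i, j] - oracle_mean[j]) ** 2 for i in range(12)) / 11) ** 0.5
            for j in range(50)
        ]
        assert np.allclose(entry.sd_trace, oracle_sd)

    def test_insufficient_peaks_is_explicit(self):
        results = [self._result(np.ones(10)) for _ in range(3)]
        with pytest.raises(InsufficientPeaksError) as err:
            build_species_library(results, LibraryConfig(min_peaks=10))
        assert err.value.n_found == 3
        assert err.value.required == 10

    def test_identical_epochs_have_zero_sd(self):
        results = [self._result(np.arange(20.0)) for _ in range(11)]
        entry = build_species_library(results)
        assert np.all(entry.sd_trace == 0.0)

    def test_mixed_species_rejected(self):
        results = [self._result(np.ones(5)), self._result(np.ones(5), species="mint")]
        with pytest.raises(ValueError, match="several species"):
            build_species_library(results, LibraryConfig(min_peaks=1))


class TestCohortSummary:
    def test_nine_of_sixteen(self):
        rows = [(f"sp{i}", i < 9) for i in range(16)]
        s = summarize_cohort(rows)
        assert s.n_responsive == 9
        assert s.pct_responsive == 56
        assert s.pct_responsive_exact == pytest.approx(56.25)

    def test_all_and_none(self):
        assert summarize_cohort([("a", True), ("b", True)]).pct_responsive == 100
        assert summarize_cohort([("a", False)]).pct_responsive == 0

    def test_duplicate_species_rows_are_or_combined(self):
        s = summarize_cohort([("a", False), ("a", True), ("b", False)])
        assert s.n_species == 2
        assert s.n_responsive == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
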