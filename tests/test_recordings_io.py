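"""Recording/event/catalog I/O: formats, round trips, and summaries."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.io import wavfile

from plantephys.recordings_io import (
    CatalogEntry,
    EventKind,
    EventLog,
    EventValidationError,
    FormatError,
    Recording,
    catalog_summary,
    default_catalog_path,
    gain_divide,
    load_catalog,
    read_events,
    read_wav,
    write_events,
    write_wav,
)

LSB16 = 2.0**-15


class TestWav:
    def test_16bit_mono_header_arithmetic(self, tmp_path):
        path = tmp_path / "a.wav"
        wavfile.write(str(path), 10_000, np.zeros(100_000, dtype=np.int16))
        rec = read_wav(path)
        assert rec.n_channels == 1
        assert rec.sampling_rate == 10_000.0
        assert rec.duration_s == pytest.approx(10.0)
        assert np.all(np.abs(rec.samples) <= 1.0)

    def test_all_zero_wav_has_zero_range(self, tmp_path):
        path = tmp_path / "z.wav"
        wavfile.write(str(path), 10_000, np.zeros(1000, dtype=np.int16))
        rec = read_wav(path)
        assert float(np.ptp(rec.samples)) == 0.0

    @pytest.mark.parametrize("n_channels", [1, 2])
    def test_round_trip_within_one_quantization_step(self, tmp_path, rng, n_channels):
        samples = rng.uniform(-1.0, 1.0, size=(n_channels, 5000))
        rec = Recording(samples=samples, sampling_rate=10_000.0)
        path = tmp_path / "rt.wav"
        write_wav(path, rec)
        back = read_wav(path)
        assert back.n_channels == rec.n_channels
        assert back.n_samples == rec.n_samples
        assert back.sampling_rate == rec.sampling_rate
        assert np.max(np.abs(back.samples - rec.samples)) <= LSB16

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_wav(tmp_path / "nope.wav")

    def test_non_wav_content_names_the_problem(self, tmp_path):
        path = tmp_path / "bad.wav"
        path.write_bytes(b"not a riff file at all")
        with pytest.raises(FormatError, match="PCM WAV"):
            read_wav(path)

    def test_more_than_two_channels_rejected(self, tmp_path):
        path = tmp_path / "quad.wav"
        wavfile.write(str(path), 8000, np.zeros((100, 4), dtype=np.int16))
        with pytest.raises(FormatError, match="channels"):
            read_wav(path)


class TestRecordingInvariants:
    def test_channel_count_limited(self):
        with pytest.raises(ValueError, match="channel_count"):
            Recording(samples=np.zeros((3, 10)), sampling_rate=100.0)

    def test_positive_sampling_rate(self):
        with pytest.raises(ValueError, match="sampling_rate"):
            Recording(samples=np.zeros(10), sampling_rate=0.0)

    def test_gain_divide_is_informational_scaling(self):
        rec = Recording(samples=np.full(10, 0.72), sampling_rate=100.0)
        assert gain_divide(rec, 72.0).samples == pytest.approx(0.01)


class TestEvents:
    def test_parse_marker_time_lines(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("# header\n1, 30.00\n2, 33.50\n")
        log = read_events(path)
        assert [(e.time_s, e.kind) for e in log.events] == [
            (30.0, EventKind.STIMULUS_ON),
            (33.5, EventKind.STIMULUS_OFF),
        ]

    def test_empty_file_gives_empty_log(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("")
        assert len(read_events(path)) == 0

    def test_unordered_lines_are_sorted(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("2, 33.5\n1, 30.0\n")
        log = read_events(path)
        assert [e.time_s for e in log.events] == [30.0, 33.5]

    def test_time_marker_dialect(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("30.0\t1\n33.5\t2\n")
        log = read_events(path, dialect="time_marker")
        assert log.stimulus_on_times() == [30.0]
        assert log.stimulus_off_times() == [33.5]

    def test_unparseable_line_reports_line_number(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("1, 30.0\n1, not-a-number\n")
        with pytest.raises(FormatError, match=":2:"):
            read_events(path)

    def test_unknown_marker_rejected(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("7, 30.0\n")
        with pytest.raises(FormatError, match="marker"):
            read_events(path)

    def test_off_without_on_is_invalid(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("2, 10.0\n")
        with pytest.raises(EventValidationError):
            read_events(path)

    def test_round_trip(self, tmp_path):
        src = tmp_path / "src.txt"
        src.write_text("1, 30.0\n2, 33.5\n")
        log = read_events(src)
        out = tmp_path / "out.txt"
        write_events(out, log)
        back = read_events(out)
        assert [(e.time_s, e.kind) for e in back.events] == [
            (e.time_s, e.kind) for e in log.events
        ]

    @given(
        times=st.lists(
            st.floats(min_value=0, max_value=1000, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_on_only_logs_always_sorted_and_valid(self, times):
        from plantephys.recordings_io import Event

        log = EventLog(events=[Event(t, EventKind.STIMULUS_ON) for t in times])
        out = [e.time_s for e in log.events]
        assert out == sorted(out)


class TestCatalog:
    def test_packaged_fixture_has_16_species(self):
        assert len(load_catalog()) == 16

    def test_basil_row(self):
        basil = [e for e in load_catalog() if e.common_name == "Basil"][0]
        assert basil.latin_name == "Ocimum basilicum"
        assert basil.electrical_response is True
        assert basil.n_recordings == 42
        assert basil.n_plants == 6

    def test_header_only_csv_is_empty(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("common_name,latin_name,electrical_response,n_recordings,n_plants\n")
        assert load_catalog(path) == []

    def test_missing_column(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("common_name,latin_name\nA,B\n")
        with pytest.raises(FormatError, match="missing"):
            load_catalog(path)

    def test_non_integer_count(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "common_name,latin_name,electrical_response,n_recordings,n_plants\nA,B,Yes,1.5,2\n"
        )
        with pytest.raises(FormatError, match="non-integer"):
            load_catalog(path)

    def test_fixture_summary_matches_study_totals(self):
        summary = catalog_summary(load_catalog())
        assert summary.n_recordings_total == 398
        assert summary.n_plants_total == 89
        assert summary.n_responsive == 9
        assert summary.pct_responsive == 56

    def test_single_entry_summary(self):
        s = catalog_summary([CatalogEntry("A", "a", True, 7, 2)])
        assert (s.n_recordings_total, s.n_plants_total, s.pct_responsive) == (7, 2, 100)

    def test_half_responsive(self):
        s = catalog_summary(
            [CatalogEntry("A", "a", True, 1, 1), CatalogEntry("B", "b", False, 1, 1)]
        )
        assert s.pct_responsive == 50

    def test_empty_catalog_errors(self):
        with pytest.raises(ValueError):
            catalog_summary([])

    @given(
        rows=st.lists(
            st.tuples(
                st.booleans(),
                st.integers(min_value=1, max_value=99),
                st.integers(min_value=1, max_value=99),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_totals_equal_column_sums(self, rows):
        entries = [
            CatalogEntry(f"sp{i}", f"lat{i}", resp, nr, np_)
            for i, (resp, nr, np_) in enumerate(rows)
        ]
        s = catalog_summary(entries)
        assert s.n_recordings_total == sum(r[1] for r in rows)
        assert s.n_plants_total == sum(r[2] for r in rows)
        assert s.pct_responsive_exact == pytest.approx(
            100.0 * sum(r[0] for r in rows) / len(rows)
        )

    def test_fixture_file_is_packaged(self):
        assert default_catalog_path().exists()
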