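import numpy as np
import pandas as pd
import pytest

import ehgpredict as ep
from ehgpredict.preprocess import (FWH, WBW, FormatError, aggregate_median,
                                   artifact_free_segments, read_cohort,
                                   read_record, segment_windows, write_cohort,
                                   zero_phase_bandpass)


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        fs = 20.0
        t = np.arange(4800) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        y = zero_phase_bandpass(x, fs, WBW)
        # compare amplitude away from the edges
        core = slice(500, -500)
        assert np.max(np.abs(y[core])) == pytest.approx(1.0, rel=0.01)

    def test_out_of_band_attenuated(self):
        fs = 20.0
        t = np.arange(200000) / fs
        x = np.sin(2 * np.pi * 0.01 * t)
        y = zero_phase_bandpass(x, fs, WBW)
        core = slice(20000, -20000)
        assert np.max(np.abs(y[core])) < 0.1  # > 90% attenuation

    def test_zero_phase_impulse_symmetric(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        y = zero_phase_bandpass(x, 20.0, WBW)
        # symmetric up to the short-pad IIR transient
        assert np.allclose(y[:1000], y[1001:][::-1], atol=1e-5)

    def test_linearity(self, rng):
        x = rng.standard_normal(3000)
        a = 3.7
        assert np.allclose(zero_phase_bandpass(a * x, 20.0, FWH),
                           a * zero_phase_bandpass(x, 20.0, FWH),
                           rtol=1e-9, atol=1e-9)

    def test_invalid_band_edges(self):
        with pytest.raises(ValueError):
            zero_phase_bandpass(np.zeros(100), 20.0,
                                ep.BandSpec("bad", 0.1, 15.0))


def _record_with_intervals(intervals, duration_s=1800.0, fs=20.0):
    n = int(duration_s * fs)
    return ep.EHGRecord(record_id="r", signals=np.zeros((n, 3)), fs=fs,
                        artifact_intervals={"S1": intervals})


class TestArtifactSegments:
    def test_no_annotations_full_signal(self):
        rec = _record_with_intervals([])
        segs = artifact_free_segments(rec, "S1")
        assert len(segs) == 1 and segs[0].size == rec.n_samples

    def test_one_interval_splits_in_two(self):
        rec = _record_with_intervals([(100.0, 200.0)])
        segs = artifact_free_segments(rec, "S1")
        assert [s.size for s in segs] == [100 * 20, 1600 * 20]

    def test_total_coverage_gives_empty(self):
        rec = _record_with_intervals([(0.0, 1800.0)])
        assert artifact_free_segments(rec, "S1") == []

    def test_overlapping_intervals_merged(self):
        rec = _record_with_intervals([(100.0, 200.0), (150.0, 300.0)])
        segs = artifact_free_segments(rec, "S1")
        assert [s.size for s in segs] == [100 * 20, 1500 * 20]


class TestWindowing:
    @pytest.mark.parametrize("seg_lens,expected", [
        ([1800.0], 29),     # floor((1800-120)/60)+1
        ([119.0], 0),
        ([300.0, 300.0], 8),
    ])
    def test_window_counts(self, seg_lens, expected):
        fs = 20.0
        segs = [np.zeros(int(s * fs)) for s in seg_lens]
        ws = segment_windows(segs, fs, win_s=120.0, overlap=0.5)
        assert len(ws) == expected

    def test_windows_do_not_span_segments(self, rng):
        fs = 20.0
        segs = [rng.standard_normal(int(150 * fs)),
                rng.standard_normal(int(150 * fs))]
        ws = segment_windows(segs, fs, win_s=120.0, overlap=0.5)
        # each window must be a contiguous slice of exactly one segment
        for w in ws.windows:
            found = any(
                any(np.array_equal(w, seg[i:i + w.size])
                    for i in range(0, seg.size - w.size + 1, 1200))
                for seg in segs)
            assert found


class TestAggregateMedian:
    @pytest.mark.parametrize("values,expected", [
        ([1.0, 2.0, 9.0], 2.0),
        ([1.0, np.nan, 3.0], 2.0),
    ])
    def test_median(self, values, expected):
        assert aggregate_median(values) == expected

    def test_empty_gives_missing(self):
        assert np.isnan(aggregate_median([]))
        assert np.isnan(aggregate_median([np.nan, np.nan]))


class TestCohortIO:
    def test_roundtrip_identity(self, tmp_path):
        params = ep.SynthCohortParams(n_term=2, n_preterm=1, duration_s=30.0,
                                      seed=5)
        records = ep.gen_cohort(params)
        write_cohort(records, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back) == 3
        for orig, rec in zip(records, back):
            assert rec.record_id == orig.record_id
            assert rec.label == orig.label
            assert rec.fs == orig.fs
            np.testing.assert_array_equal(rec.signals, orig.signals)
            for f in ("age", "parity", "weight", "gestation_week"):
                assert rec.obstetric[f] == pytest.approx(orig.obstetric[f])
            assert rec.artifact_intervals == orig.artifact_intervals

    def test_two_channel_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"t": [0, 0.05], "S1": [0, 1], "S2": [0, 1]}).to_csv(
            path, index=False)
        with pytest.raises(FormatError):
            read_record(path, "csv", manifest={"fs": 20.0})

    def test_nonuniform_sampling_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"t": [0.0, 0.05, 0.2], "S1": [0, 1, 2],
                      "S2": [0, 1, 2], "S3": [0, 1, 2]}).to_csv(
            path, index=False)
        with pytest.raises(FormatError):
            read_record(path, "csv", manifest={"fs": 20.0})
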