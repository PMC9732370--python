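import numpy as np
import pytest

from tfdenoise import preprocess as pp


@pytest.fixture
def csv_file(tmp_path):
    def _write(text, name="rec.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p
    return _write


class TestCsvIO:
    def test_reads_matrix_shape(self, csv_file):
        p = csv_file("0,1\n0,1\n0,1\n0,1\n")
        rec = pp.load_csv(p, fs=250)
        assert rec.data.shape == (4, 2)
        assert rec.fs == 250

    def test_header_row_gives_channel_names(self, csv_file):
        p = csv_file("Cz,Pz\n1,2\n3,4\n")
        rec = pp.load_csv(p, fs=250, has_header=True)
        assert rec.channel_names == ["Cz", "Pz"]
        assert rec.data.shape == (2, 2)

    def test_non_numeric_cell_names_row(self, csv_file):
        p = csv_file("1,2\n3,oops\n5,6\n")
        with pytest.raises(pp.ParseError, match="row 1"):
            pp.load_csv(p, fs=250)

    def test_ragged_rows_error(self, csv_file):
        p = csv_file("1,2\n3\n5,6\n")
        with pytest.raises(pp.ParseError):
            pp.load_csv(p, fs=250)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            pp.load_csv(tmp_path / "nope.csv", fs=250)

    def test_round_trip_bit_exact(self, tmp_path, rng):
        rec = pp.Recording(rng.normal(size=(40, 3)), fs=250)
        pp.save_csv(rec, tmp_path / "r.csv")
        back = pp.load_csv(tmp_path / "r.csv", fs=250)
        assert np.array_equal(back.data, rec.data)


class TestRecordingInvariants:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            pp.Recording(np.array([[1.0], [np.nan]]), fs=250)

    def test_rejects_out_of_range_events(self):
        with pytest.raises(ValueError, match="event"):
            pp.Recording(np.zeros((10, 1)), fs=250, events=[10])

    def test_rejects_nonpositive_fs(self):
        with pytest.raises(ValueError, match="rate"):
            pp.Recording(np.zeros((10, 1)), fs=0)


class TestBandpass:
    FS = 250.0

    def _amp(self, y):
        n = y.size
        central = y[n // 4: 3 * n // 4]
        return np.abs(central).max()

    def test_dc_removed(self):
        y = pp.bandpass(np.full(1000, 5.0), self.FS, 2, 30)
        n = y.size
        assert np.abs(y[n // 4: 3 * n // 4]).max() < 1e-6 * 5

    def test_passband_tone_preserved(self):
        t = np.arange(1000) / self.FS
        y = pp.bandpass(np.sin(2 * np.pi * 10 * t), self.FS, 2, 30)
        assert abs(self._amp(y) - 1.0) < 0.05

    def test_stopband_tone_suppressed(self):
        t = np.arange(1000) / self.FS
        y = pp.bandpass(np.sin(2 * np.pi * 60 * t), self.FS, 2, 30)
        assert self._amp(y) < 0.05

    def test_idempotent_in_passband(self):
        t = np.arange(2000) / self.FS
        x = np.sin(2 * np.pi * 10 * t)
        once = pp.bandpass(x, self.FS, 2, 30)
        twice = pp.bandpass(once, self.FS, 2, 30)
        assert abs(self._amp(twice) - self._amp(once)) < 0.01 * self._amp(once)

    @pytest.mark.parametrize("low,high", [(0, 30), (30, 2), (2, 200)])
    def test_invalid_band_edges(self, low, high):
        with pytest.raises(ValueError):
            pp.bandpass(np.zeros(1000), self.FS, low, high)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="short"):
            pp.bandpass(np.zeros(20), self.FS, 2, 30)


class TestDownsample:
    def test_length_arithmetic(self):
        y = pp.downsample(np.zeros(1000), 1000, 250)
        assert y.size == 250

    def test_tone_survives_decimation(self):
        t_in = np.arange(1000) / 1000.0
        y = pp.downsample(np.sin(2 * np.pi * 5 * t_in), 1000, 250)
        t_out = np.arange(250) / 250.0
        ideal = np.sin(2 * np.pi * 5 * t_out)
        assert np.corrcoef(y, ideal)[0, 1] > 0.99

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            pp.downsample(np.zeros(1000), 1000, 300)


class TestCommonAverageReference:
    def test_two_channel_example(self):
        rec = pp.Recording(np.array([[1.0, 3.0]]), fs=250)
        out = pp.common_average_reference(rec)
        assert np.allclose(out.data, [[-1.0, 1.0]])

    def test_per_sample_mean_zero(self, rng):
        rec = pp.Recording(rng.normal(size=(100, 5)), fs=250)
        out = pp.common_average_reference(rec)
        assert np.abs(out.data.sum(axis=1)).max() < 1e-12

    def test_identical_channels_zero_out(self):
        col = np.linspace(0, 1, 50)
        rec = pp.Recording(np.column_stack([col, col, col]), fs=250)
        out = pp.common_average_reference(rec)
        assert np.abs(out.data).max() < 1e-15

    def test_single_channel_rejected(self):
        rec = pp.Recording(np.zeros((10, 1)), fs=250)
        with pytest.raises(ValueError, match="CAR"):
            pp.common_average_reference(rec)


class TestExtractEpochs:
    def test_window_arithmetic(self):
        rec = pp.Recording(np.arange(500.0)[:, None], fs=250, events=[0])
        ep = pp.extract_epochs(rec, 0, 1.0)
        assert ep.trials.shape == (1, 250)

    def test_56_events_give_56_trials(self, rng):
        n = 250 * 60
        events = list(range(0, 56 * 260, 260))
        rec = pp.Recording(rng.normal(size=(n, 1)), fs=250, events=events)
        ep = pp.extract_epochs(rec, 0, 1.0)
        assert ep.n_trials == 56

    def test_overrunning_event_listed(self):
        rec = pp.Recording(np.zeros((100, 1)), fs=250, events=[0, 90])
        with pytest.raises(ValueError, match="90"):
            pp.extract_epochs(rec, 0, 1.0)

    def test_half_open_window_reads_no_sentinels(self):
        # plant sentinels immediately outside each epoch window
        data = np.full(500, 1e9)
        data[100:350] = np.arange(250.0)
        rec = pp.Recording(data[:, None], fs=250, events=[100])
        ep = pp.extract_epochs(rec, 0, 1.0)
        assert np.array_equal(ep.trials[0], np.arange(250.0))

    def test_full_preprocessing_chain(self):
        """1000 Hz multichannel recording -> 250 Hz band-limited epochs."""
        rng = np.random.default_rng(0)
        fs_in = 1000.0
        n = int(fs_in * 10)
        t = np.arange(n) / fs_in
        sig = np.sin(2 * np.pi * 10 * t)  # in-band component
        data = np.column_stack([sig + 0.1 * rng.normal(size=n)
                                for _ in range(3)])
        events = [1000, 4000, 7000]
        rec = pp.Recording(data, fs=fs_in, events=events)
        ep = pp.preprocess_recording(rec, channel=0)
        assert ep.fs == 250.0
        assert ep.trials.shape == (3, 250)
        # the common in-band sinusoid is removed by CAR up to channel noise,
        # and the output is band-limited: no content above 30 Hz
        from scipy.signal import periodogram
        f, p = periodogram(ep.trials[1], fs=250.0)
        assert p[f > 40].sum() < 0.05 * p.sum()

    def test_channel_by_name(self):
        rec = pp.Recording(np.column_stack([np.zeros(250), np.ones(250)]),
                           fs=250, events=[0], channel_names=["Cz", "Pz"])
        ep = pp.extract_epochs(rec, "Pz", 1.0)
        assert np.all(ep.trials == 1.0)
        with pytest.raises(KeyError):
            pp.extract_epochs(rec, "Oz", 1.0)
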