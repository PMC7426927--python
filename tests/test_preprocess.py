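import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import filtfilt

from slowmod import Level, bandpass_downsample, build_neighbor_graph, design_filter_bank
from slowmod.preprocess import (
    BandFilterer,
    BandSpec,
    compute_artifact_mask,
    define_levels,
    detect_bridged_channels,
    fir_kernel,
    laplacian_transform,
    select_epochs,
    zero_phase_bandpass,
)
from slowmod.containers import LevelSchedule


class TestFilterBankDesign:
    def test_default_tiling_has_23_bands(self):
        bank = design_filter_bank(4, 50, 2, 1)
        assert len(bank.high_bands) == 23
        assert (bank.high_bands[0].low_hz, bank.high_bands[0].high_hz) == (4, 6)
        assert (bank.high_bands[-1].low_hz, bank.high_bands[-1].high_hz) == (48, 50)
        assert (bank.slow_band.low_hz, bank.slow_band.high_hz) == (0.1, 4)

    def test_small_tiling(self):
        bank = design_filter_bank(4, 8, 2, 1)
        assert [(b.low_hz, b.high_hz) for b in bank.high_bands] == [(4, 6), (6, 8)]

    def test_nondividing_width_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            design_filter_bank(4, 7, 2, 1)

    def test_tiling_covers_range_exactly(self):
        bank = design_filter_bank()
        edges = [bank.high_bands[0].low_hz] + [b.high_hz for b in bank.high_bands]
        assert edges == list(np.arange(4.0, 52.0, 2.0))


class TestZeroPhaseFilter:
    fs = 200.0
    band = BandSpec(8, 16, 1)

    def _measure(self, f_hz, n_s=60):
        t = np.arange(int(n_s * self.fs)) / self.fs
        x = np.cos(2 * np.pi * f_hz * t)
        y = zero_phase_bandpass(x, self.fs, self.band)
        interior = slice(int(5 * self.fs), int((n_s - 5) * self.fs))
        # complex demodulation for amplitude and phase
        z = np.exp(-2j * np.pi * f_hz * t[interior])
        c = 2 * np.mean(y[interior] * z)
        return abs(c), np.angle(c)

    def test_passband_amplitude_and_phase(self):
        amp, ph = self._measure(10.0)
        assert abs(amp - 1.0) < 0.01
        assert abs(np.degrees(ph)) < 1.0

    def test_stopband_attenuation(self):
        amp, _ = self._measure(25.0)
        assert amp < 0.01  # > 40 dB

    def test_matches_forward_backward_filtfilt(self, rng):
        # independent realization: direct filtfilt with the same kernel
        x = rng.standard_normal(4000)
        h = fir_kernel(self.band, self.fs)
        ours = zero_phase_bandpass(x, self.fs, self.band)
        ref = filtfilt(h, 1.0, x, padtype=None)
        interior = slice(len(h), len(x) - len(h))
        np.testing.assert_allclose(ours[interior], ref[interior], atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            zero_phase_bandpass(np.zeros(10000), 100.0, BandSpec(40, 49.8, 1))


class TestBandpassDownsample:
    def test_decimation_sample_count(self, make_rec, rng):
        fs_in, fs_out = 5000.0, 200.0
        t = np.arange(int(5 * fs_in)) / fs_in
        rec = make_rec(np.cos(2 * np.pi * 10 * t)[None, :], fs=fs_in)
        out = bandpass_downsample(rec, BandSpec(8, 16, 1), fs_out)
        assert abs(out.n_samples - rec.n_samples * fs_out / fs_in) <= 1
        assert out.sample_rate_hz == fs_out

    def test_nyquist_violation_rejected(self, make_rec):
        rec = make_rec(np.zeros((1, 10000)), fs=1000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_downsample(rec, BandSpec(40, 60, 1), 100.0)

    def test_noninteger_ratio_rejected(self, make_rec):
        rec = make_rec(np.zeros((1, 10000)), fs=300.0)
        with pytest.raises(ValueError, match="integer"):
            bandpass_downsample(rec, BandSpec(8, 16, 1), 200.0)

    def test_recording_shorter_than_filter_span_rejected(self, make_rec):
        rec = make_rec(np.zeros((1, 200)), fs=200.0)
        with pytest.raises(ValueError, match="shorter"):
            bandpass_downsample(rec, BandSpec(8, 16, 1), 200.0)


class TestNeighborGraph:
    def test_square_corners_edges_along_sides_only(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        graph = build_neighbor_graph(pos)
        # oracle: brute-force distance enumeration under the adopted rule
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        expect = d <= 1.25 * d.min(axis=1)[:, None]
        expect |= expect.T
        for i in range(4):
            assert graph[i] == set(np.flatnonzero(expect[i]))
        assert graph[0] == {1, 2}  # diagonal (sqrt 2) excluded

    def test_two_channels_single_mutual_edge(self):
        graph = build_neighbor_graph(np.array([[0, 0, 0], [0, 0, 1.0]]))
        assert graph == {0: {1}, 1: {0}}

    def test_grid_interior_has_four_neighbors(self):
        xx, yy = np.meshgrid(np.arange(8.0), np.arange(8.0))
        pos = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(64)])
        graph = build_neighbor_graph(pos)
        interior = [i for i, p in enumerate(pos) if 0 < p[0] < 7 and 0 < p[1] < 7]
        assert all(len(graph[i]) == 4 for i in interior)

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_neighbor_graph(np.zeros((3, 3)))


class TestLaplacian:
    def test_identical_channels_give_zero(self):
        data = np.ones((4, 10)) * 7.3
        graph = {0: {1, 2}, 1: {0, 3}, 2: {0, 3}, 3: {1, 2}}
        np.testing.assert_allclose(laplacian_transform(data, graph), 0.0)

    def test_channel_with_zero_neighbors_keeps_value(self):
        data = np.zeros((4, 5))
        data[0] = 2.5
        data[3] = 99.0  # not a neighbor of 0
        graph = {0: {1, 2}, 1: {0}, 2: {0}, 3: {1}}
        out = laplacian_transform(data, graph)
        np.testing.assert_allclose(out[0], 2.5)

    def test_two_channel_antisymmetry(self):
        data = np.array([[3.0], [1.0]])
        out = laplacian_transform(data, {0: {1}, 1: {0}})
        np.testing.assert_allclose(out, [[2.0], [-2.0]])

    def test_isolated_channel_rejected(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            laplacian_transform(np.zeros((2, 5)), {0: {1}, 1: set()})

    def test_commutes_with_filtering(self, rng):
        # both operations are linear, so the order cannot matter
        data = rng.standard_normal((4, 8000))
        graph = {0: {1}, 1: {0, 2}, 2: {1, 3}, 3: {2}}
        band = BandSpec(8, 16, 1)
        filt = BandFilterer(8000, 200.0)
        a = laplacian_transform(filt.filter(data, band), graph)
        b = filt.filter(laplacian_transform(data, graph), band)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestDefineLevels:
    @staticmethod
    def _schedule(doses, loc, bs_labels=()):
        levels = [
            Level(f"L{i}", 100.0 * i, 100.0 * (i + 1), d, burst_suppression=f"L{i}" in bs_labels)
            for i, d in enumerate(doses)
        ]
        return LevelSchedule(levels, loc_time_s=loc)

    def test_burst_suppression_caps_high_dose(self):
        sched = self._schedule([0, 1, 2, 3, 4, 5], loc=250.0, bs_labels={"L5"})
        assert define_levels(sched) == {
            "Baseline": "L0", "Sedation": "L1", "UncLow": "L3", "UncHigh": "L4",
        }

    def test_loc_in_first_drug_level_means_no_sedation(self):
        sched = self._schedule([0, 1, 2, 3], loc=150.0)
        m = define_levels(sched)
        assert m["Sedation"] is None
        assert m["Baseline"] == "L0"
        assert m["UncLow"] == "L2"

    def test_without_burst_suppression_highest_dose_wins(self):
        sched = self._schedule([0, 1, 2, 3, 4, 5], loc=250.0)
        assert define_levels(sched)["UncHigh"] == "L5"

    def test_missing_loc_rejected(self):
        with pytest.raises(ValueError, match="LOC"):
            define_levels(self._schedule([0, 1, 2], loc=None))

    def test_missing_predrug_period_rejected(self):
        with pytest.raises(ValueError, match="pre-drug"):
            define_levels(self._schedule([1, 2, 3], loc=150.0))


class TestSelectEpochs:
    def test_clean_level_earliest_first_disjoint(self, make_rec, rng):
        fs = 200.0
        rec = make_rec(
            rng.standard_normal((1, int(720 * fs))),
            levels=[Level("lvl", 0, 720, 1.0)],
        )
        es = select_epochs(rec, "lvl", n=10, duration_s=30)
        assert es.count == 10
        assert es.windows[0] == (0.0, 30.0)
        starts = [w[0] for w in es.windows]
        assert starts == sorted(starts)
        for (s0, e0), (s1, _) in zip(es.windows, es.windows[1:]):
            assert s1 >= e0

    def test_mask_shifts_first_epoch(self, make_rec, rng):
        fs = 200.0
        n = int(720 * fs)
        mask = np.zeros((1, n), dtype=bool)
        mask[0, : int(120 * fs)] = True
        rec = make_rec(rng.standard_normal((1, n)), levels=[Level("lvl", 0, 720, 1.0)], mask=mask)
        es = select_epochs(rec, "lvl", n=10, duration_s=30)
        assert es.windows[0][0] == pytest.approx(120.0)

    def test_insufficient_data_reports_achievable(self, make_rec, rng):
        fs = 200.0
        rec = make_rec(rng.standard_normal((1, int(240 * fs))), levels=[Level("lvl", 0, 240, 1.0)])
        with pytest.raises(ValueError, match="only 8"):
            select_epochs(rec, "lvl", n=10, duration_s=30)


def test_artifact_mask_flags_spikes_and_flats(make_rec, rng):
    fs = 200.0
    data = rng.standard_normal((2, int(10 * fs))) * 20
    data[0, 400:410] = 800.0  # amplitude artifact
    data[1, 600:800] = 3.14  # one flat second
    rec = make_rec(data)
    mask = compute_artifact_mask(rec)
    assert mask[0, 400:410].all()
    assert mask[1, 600:800].all()
    assert not mask[0, :300].any()


def test_bridged_channels_detected(rng):
    data = rng.standard_normal((4, 5000))
    data[2] = data[0] * 1.001 + 1e-4  # near-duplicate of channel 0
    assert detect_bridged_channels(data) == [2]
    assert detect_bridged_channels(rng.standard_normal((3, 5000))) == []


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=4.0, max_value=30.0), st.integers(min_value=1, max_value=10))
def test_band_tiling_property(low, n):
    width = 2.0
    bank = design_filter_bank(low, low + n * width, width, 1.0)
    assert len(bank.high_bands) == n
    for a, b in zip(bank.high_bands, bank.high_bands[1:]):
        assert a.high_hz == pytest.approx(b.low_hz)


def test_read_eeg_fif_roundtrip(tmp_path, rng):
    mne = pytest.importorskip("mne")
    from slowmod import read_eeg

    info = mne.create_info(["Fz", "Cz", "Oz"], sfreq=200.0, ch_types="eeg")
    raw = mne.io.RawArray(rng.standard_normal((3, 1000)) * 1e-6, info, verbose="error")
    path = tmp_path / "test_raw.fif"
    raw.save(path, verbose="error")
    rec = read_eeg(path)
    assert rec.n_channels == 3
    assert rec.sample_rate_hz == 200.0
    np.testing.assert_allclose(rec.data, raw.get_data() * 1e6, atol=1e-9)
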