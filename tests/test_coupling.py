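import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slowmod import (
    cfc_correlation,
    instantaneous_amplitude,
    instantaneous_phase,
    mean_vector,
    stacked_correlation,
)
from slowmod.coupling import compute_modulogram, modulogram_from_envelopes
from slowmod.preprocess import BandSpec, design_filter_bank
from slowmod.synthetic import generate_modulated_component

FS = 200.0
T30 = np.arange(int(30 * FS)) / FS  # 30 s epoch


def _slow(freq=1.0, amp=1.0):
    return amp * np.cos(2 * np.pi * freq * T30)


class TestInstantaneousAmplitude:
    def test_constant_amplitude_sinusoid(self):
        env = instantaneous_amplitude(3.0 * np.cos(2 * np.pi * 10 * T30))
        interior = env[200:-200]
        assert np.max(np.abs(interior - 3.0)) / 3.0 < 0.01

    def test_am_identity(self):
        # envelope of (1 + 0.5 cos(2 pi t)) cos(2 pi 10 t) is 1 + 0.5 cos(2 pi t)
        target = 1 + 0.5 * np.cos(2 * np.pi * 1.0 * T30)
        env = instantaneous_amplitude(target * np.cos(2 * np.pi * 10 * T30))
        interior = slice(400, len(T30) - 400)
        rmse = np.sqrt(np.mean((env[interior] - target[interior]) ** 2))
        assert rmse / np.mean(target) < 0.02

    def test_zero_input_zero_envelope(self):
        np.testing.assert_array_equal(instantaneous_amplitude(np.zeros(100)), 0.0)


class TestCorrelationIdentities:
    def test_positive_linear_relation_gives_plus_one(self):
        V = _slow()
        rec = cfc_correlation(V, 5.0 + 2.0 * V)
        assert abs(rec.r - 1.0) < 1e-9

    def test_negative_linear_relation_gives_minus_one(self):
        V = _slow()
        rec = cfc_correlation(V, 5.0 - 2.0 * V)
        assert abs(rec.r + 1.0) < 1e-9

    def test_orthogonal_sinusoid_gives_zero(self):
        V = np.cos(2 * np.pi * 1.0 * T30)
        env = 2.0 + np.sin(2 * np.pi * 1.0 * T30)
        assert abs(cfc_correlation(V, env).r) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        V = _slow()
        env = 3.0 + V + 0.3 * rng.standard_normal(len(V))
        r0 = cfc_correlation(V, env).r
        assert abs(cfc_correlation(7.7 * V, env).r - r0) < 1e-12
        assert abs(cfc_correlation(V, 0.01 * env).r - r0) < 1e-12

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(6)
        V = _slow()
        env = 3.0 + V + 0.5 * rng.standard_normal(len(V))
        fluct = env - env.mean()
        assert cfc_correlation(V, env.mean() - fluct).r == -cfc_correlation(V, env).r

    def test_zero_variance_flagged_not_zero(self):
        rec = cfc_correlation(_slow(), np.full(len(T30), 4.2))
        assert not rec.defined
        assert np.isnan(rec.r)
        rec2 = cfc_correlation(np.zeros(100), np.arange(100.0))
        assert not rec2.defined

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cfc_correlation(np.zeros(10), np.zeros(11))

    def test_noisy_regression_matches_analytic_expectation(self):
        # env = c + k*V + noise: E[r] ~ k*sd_V / sqrt(k^2 sd_V^2 + sigma^2),
        # checked against a brute-force Monte-Carlo oracle
        rng = np.random.default_rng(7)
        V = _slow()
        k, sigma = 0.8, 0.7
        sd_v = V.std()
        expect = k * sd_v / np.hypot(k * sd_v, sigma)
        rs = np.array(
            [
                cfc_correlation(V, 2.0 + k * V + sigma * rng.standard_normal(len(V))).r
                for _ in range(200)
            ]
        )
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean() - expect) < 2 * se + 1e-3


class TestStackedCorrelation:
    def test_duplication_invariance(self):
        rng = np.random.default_rng(8)
        V = _slow()
        env = 2.0 + 0.5 * V + 0.2 * rng.standard_normal(len(V))
        one = stacked_correlation([(V, env)]).r
        two = stacked_correlation([(V, env), (V, env)]).r
        assert two == pytest.approx(one, abs=1e-12)

    def test_sign_flipped_twin_cancels(self):
        rng = np.random.default_rng(9)
        V = _slow()
        env = 2.0 + 0.5 * V + 0.2 * rng.standard_normal(len(V))
        flipped = 2 * env.mean() - env  # equal norm, opposite fluctuation
        assert stacked_correlation([(V, env), (V, flipped)]).r == pytest.approx(0.0, abs=1e-12)

    def test_equals_concatenation_not_mean_of_rs(self):
        # heteroscedastic pairs: brute-force oracle for both quantities
        rng = np.random.default_rng(10)
        V = _slow()
        pairs = []
        for scale, k in [(0.1, 0.9), (1.0, 0.1), (5.0, -0.5)]:
            env = 10.0 + scale * (k * V + 0.4 * rng.standard_normal(len(V)))
            pairs.append((V, env))
        stacked = stacked_correlation(pairs).r
        # oracle 1: direct evaluation on the concatenated, per-epoch-centered vectors
        Vc = np.concatenate([p[0] for p in pairs])
        Ac = np.concatenate([p[1] - p[1].mean() for p in pairs])
        direct = (Vc @ Ac) / np.sqrt((Vc @ Vc) * (Ac @ Ac))
        assert stacked == pytest.approx(direct, abs=1e-12)
        # oracle 2: the mean of per-pair correlations is a different estimator
        mean_r = np.mean([cfc_correlation(*p).r for p in pairs])
        assert abs(stacked - mean_r) > 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            stacked_correlation([])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.floats(min_value=1e-3, max_value=1e3),
    st.floats(min_value=1e-3, max_value=1e3),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_scale_invariance_property(a, b, seed):
    rng = np.random.default_rng(seed)
    V = _slow()
    env = 3.0 + 0.4 * V + 0.3 * rng.standard_normal(len(V))
    r0 = cfc_correlation(V, env).r
    assert cfc_correlation(a * V, b * env).r == pytest.approx(r0, abs=1e-9)


class TestMeanVector:
    phi = 2 * np.pi * 1.0 * T30  # whole cycles at 200 Hz over 30 s

    def test_constant_amplitude_cancels(self):
        mv = mean_vector(np.full(len(self.phi), 2.0), np.angle(np.exp(1j * self.phi)))
        assert mv.magnitude < 1e-6 * 2.0

    def test_peak_locked_amplitude(self):
        # A = 1 + cos(phi): mean(A e^{i phi}) = 0.5 e^{i 0}
        mv = mean_vector(1 + np.cos(self.phi), np.angle(np.exp(1j * self.phi)))
        assert abs(mv.value - 0.5) < 1e-3
        assert abs(mv.preferred_phase) < 1e-3

    def test_trough_locked_amplitude(self):
        mv = mean_vector(1 - np.cos(self.phi), np.angle(np.exp(1j * self.phi)))
        assert abs(mv.value + 0.5) < 1e-3  # 0.5 e^{i pi}
        assert abs(abs(mv.preferred_phase) - np.pi) < 1e-3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mean_vector(np.zeros(5), np.zeros(6))

    def test_phase_concentration_on_synthetic_coupling(self):
        # peakmax/troughmax components concentrate the preferred phase at 0/pi
        for depth, target in [(0.8, 0.0), (-0.8, np.pi)]:
            hits = 0
            for seed in range(10):
                slow = _slow(amp=50.0)
                comp = generate_modulated_component(
                    slow, (8, 16), depth, 2.0, seed, FS
                )
                env = instantaneous_amplitude(comp)
                phase = instantaneous_phase(slow)
                mv = mean_vector(env[200:-200], phase[200:-200])
                d = np.angle(np.exp(1j * (mv.preferred_phase - target)))
                hits += abs(d) < np.pi / 8
            assert hits >= 9


class TestNullCalibration:
    def test_uncoupled_component_centered_at_zero(self):
        # depth = 0 over independent seeds: mean r within 2 standard errors of 0
        slow = _slow(amp=50.0)
        rs = []
        for seed in range(100):
            comp = generate_modulated_component(slow, (8, 16), 0.0, 2.0, seed, FS)
            env = instantaneous_amplitude(comp)
            rs.append(cfc_correlation(slow, env).r)
        rs = np.array(rs)
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean()) < 2 * se

    def test_null_quantile_small_over_300s(self):
        # Monte-Carlo null oracle: the 95% quantile of |r| over 300 s of
        # uncoupled data stays well below the 0.1 "near-zero" reading
        rng = np.random.default_rng(11)
        n = int(300 * FS)
        t = np.arange(n) / FS
        slow = np.cos(2 * np.pi * 1.0 * t)
        rs = []
        for seed in range(40):
            comp = generate_modulated_component(slow, (8, 16), 0.0, 2.0, seed, FS)
            env = instantaneous_amplitude(comp)
            rs.append(abs(cfc_correlation(slow, env).r))
        assert np.quantile(rs, 0.95) < 0.1


class TestModulogram:
    def test_single_window_single_location_equals_cfc(self):
        rng = np.random.default_rng(12)
        V = _slow()
        env = 2.0 + 0.5 * V + 0.1 * rng.standard_normal(len(V))
        m = modulogram_from_envelopes(
            V[None, :], {BandSpec(8, 16, 1): env[None, :]}, FS, window_s=30.0
        )
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(cfc_correlation(V, env).r, abs=1e-12)

    def test_masked_window_flagged_missing(self):
        rng = np.random.default_rng(13)
        n = int(90 * FS)
        V = np.cos(2 * np.pi * np.arange(n) / FS)
        env = 2.0 + 0.5 * V + 0.1 * rng.standard_normal(n)
        bad = np.zeros(n, dtype=bool)
        bad[int(40 * FS)] = True  # single bad sample in window 2
        m = modulogram_from_envelopes(
            V[None, :], {BandSpec(8, 16, 1): env[None, :]}, FS, window_s=30.0, bad=bad
        )
        assert np.isnan(m.values[0, 1])
        assert np.isfinite(m.values[0, [0, 2]]).all()

    def test_stacking_across_locations_matches_pairs(self):
        rng = np.random.default_rng(14)
        V = np.stack([_slow(), _slow(freq=1.3)])
        env = 2.0 + 0.5 * V + 0.2 * rng.standard_normal(V.shape)
        m = modulogram_from_envelopes(V, {BandSpec(8, 16, 1): env}, FS, window_s=30.0)
        expect = stacked_correlation([(V[0], env[0]), (V[1], env[1])]).r
        assert m.values[0, 0] == pytest.approx(expect, abs=1e-7)

    def test_session_modulogram_recovers_planned_sign(self, make_rec):
        # posterior-style broadband peakmax: all-band positive column
        from slowmod.synthetic import broadband_entries

        rng = np.random.default_rng(15)
        fs = FS
        n = int(60 * fs)
        t = np.arange(n) / fs
        slow = 50.0 * np.cos(2 * np.pi * 1.0 * t)
        data = slow.copy()
        for k, e in enumerate(broadband_entries(0.8)):
            data = data + generate_modulated_component(slow, e.band, e.depth, 2.0, 100 + k, fs)
        rec = make_rec(data[None, :] + 0.5 * rng.standard_normal(n))
        bank = design_filter_bank()
        m = compute_modulogram(rec, bank, ["CH00"], window_s=30.0)
        assert m.values.shape == (23, 2)
        assert (m.values > 0).all()
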