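"""Band scheme, coherence estimation, IAAFT surrogates and layer building."""

import numpy as np
import pytest
from scipy import signal

from muxbrain.connectivity import (
    RoiTimeSeriesSet,
    band_coherence,
    build_layers,
    iaaft_surrogate,
    make_band_scheme,
    surrogate_null,
)


class TestBandScheme:
    def test_study_decomposition_gives_twelve_bands(self):
        scheme = make_band_scheme(0.01, 0.25, 0.02)
        assert scheme.n_bands == 12
        assert scheme.band_edges[0] == (0.01, 0.03)
        assert scheme.band_edges[-1][0] == pytest.approx(0.23)
        assert scheme.band_edges[-1][1] == pytest.approx(0.25)

    def test_two_band_split(self):
        assert make_band_scheme(0.01, 0.05, 0.02).n_bands == 2

    def test_non_divisible_range_rejected(self):
        # 0.24 / 0.05 = 4.8: no silent truncation
        with pytest.raises(ValueError):
            make_band_scheme(0.01, 0.25, 0.05)

    @pytest.mark.parametrize("args", [(0.05, 0.01, 0.02), (0.01, 0.05, -0.02)])
    def test_bad_edges_rejected(self, args):
        with pytest.raises(ValueError):
            make_band_scheme(*args)


class TestBandCoherence:
    scheme = make_band_scheme(0.01, 0.25, 0.02)

    def test_identical_channels_have_unit_coherence(self, rng):
        x = rng.standard_normal(512)
        ts = RoiTimeSeriesSet(np.vstack([x, x]), tr_seconds=2.0)
        w = band_coherence(ts, self.scheme).w
        assert np.allclose(w[:, 0, 1], 1.0)

    def test_time_shift_leaves_coherence_near_one(self, rng):
        # coherence is invariant under linear time shifts (small vs window)
        x = rng.standard_normal(2048)
        ts = RoiTimeSeriesSet(np.vstack([x[:-3], x[3:]]), tr_seconds=2.0)
        w = band_coherence(ts, self.scheme).w
        assert (w[:, 0, 1] >= 0.95).all()

    def test_independent_noise_has_low_band_coherence(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ts = RoiTimeSeriesSet(rng.standard_normal((2, 4096)), tr_seconds=2.0)
            w = band_coherence(ts, self.scheme).w
            assert (w[:, 0, 1] < 0.2).all()

    def test_symmetry_bounds_and_zero_diagonal(self, rng):
        ts = RoiTimeSeriesSet(rng.standard_normal((5, 256)), tr_seconds=2.0)
        w = band_coherence(ts, self.scheme).w
        assert np.allclose(w, np.swapaxes(w, 1, 2))
        assert (w >= 0).all() and (w <= 1).all()
        assert np.allclose(w[:, np.eye(5, dtype=bool)], 0)

    def test_band_above_nyquist_rejected(self, rng):
        ts = RoiTimeSeriesSet(rng.standard_normal((2, 256)), tr_seconds=4.0)
        with pytest.raises(ValueError, match="Nyquist"):
            band_coherence(ts, self.scheme)

    def test_band_without_bins_rejected(self, rng):
        ts = RoiTimeSeriesSet(rng.standard_normal((2, 256)), tr_seconds=0.01)
        narrow = make_band_scheme(0.01, 0.03, 0.005)
        with pytest.raises(ValueError, match="no spectral bins"):
            band_coherence(ts, narrow)


class TestIaaft:
    def test_amplitude_multiset_preserved_exactly(self, rng):
        x = rng.gamma(2.0, size=257)
        s = iaaft_surrogate(x, max_iter=50, seed=0)
        assert np.array_equal(np.sort(s), np.sort(x))

    def test_spectrum_deviation_small_on_white_noise(self, rng):
        x = rng.standard_normal(1024)
        s = iaaft_surrogate(x, max_iter=100, seed=1)
        amp_x = np.abs(np.fft.rfft(x))[1:]
        amp_s = np.abs(np.fft.rfft(s))[1:]
        assert np.mean(np.abs(amp_s - amp_x) / amp_x.mean()) < 0.05

    def test_ar1_autocorrelation_preserved(self, rng):
        # spectrum preservation implies autocovariance preservation
        n, phi = 2048, 0.9
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.standard_normal()
        s = iaaft_surrogate(x, max_iter=200, seed=2)

        def acf1(v):
            v = v - v.mean()
            return float(np.dot(v[:-1], v[1:]) / np.dot(v, v))

        assert abs(acf1(s) - acf1(x)) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            iaaft_surrogate(np.ones(64), seed=0)

    def test_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            iaaft_surrogate(rng.standard_normal(4), seed=0)


class TestBuildLayers:
    def test_matches_unvectorized_scipy_oracle(self):
        """z-scores agree with a per-pair loop using scipy.signal.coherence."""
        rng = np.random.default_rng(7)
        n_ch, n_t, n_sur = 4, 96, 20
        values = rng.standard_normal((n_ch, n_t))
        tr = 2.0
        scheme = make_band_scheme(0.01, 0.25, 0.12)  # 2 bands
        ts = RoiTimeSeriesSet(values.copy(), tr)
        layers, null = build_layers(ts, scheme, n_surrogates=n_sur, seed=33)

        nperseg = min(n_t, 64)

        def msc_bands(a, b):
            f, c = signal.coherence(
                a, b, fs=1.0 / tr, window="hann", nperseg=nperseg,
                noverlap=nperseg // 2, detrend="constant",
            )
            out = []
            for k, (lo, hi) in enumerate(scheme.band_edges):
                mask = (f >= lo - 1e-12) & (f < hi - 1e-12)
                if k == scheme.n_bands - 1:
                    mask |= np.isclose(f, hi, atol=1e-12)
                out.append(c[mask].mean())
            return np.array(out)

        # same surrogate stream as build_layers: one generator, channel-major
        sur_rng = np.random.default_rng(33)
        draws = np.empty((n_sur, 2, n_ch, n_ch))
        for r in range(n_sur):
            sur = np.vstack(
                [iaaft_surrogate(values[c], max_iter=100, rng=sur_rng)
                 for c in range(n_ch)]
            )
            for i in range(n_ch):
                for j in range(i + 1, n_ch):
                    draws[r, :, i, j] = draws[r, :, j, i] = msc_bands(sur[i], sur[j])
        w = np.empty((2, n_ch, n_ch))
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                w[:, i, j] = w[:, j, i] = msc_bands(values[i], values[j])
        mu = draws.mean(axis=0)
        sigma = draws.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_expected = np.abs(w - mu) / sigma
        z_expected = np.where(z_expected >= 3.0, z_expected, 0.0)
        for k, layer in enumerate(layers):
            for i in range(n_ch):
                for j in range(i + 1, n_ch):
                    assert layer.z[i, j] == pytest.approx(z_expected[k, i, j], abs=1e-9)

    def test_threshold_monotonicity(self, rng):
        ts = RoiTimeSeriesSet(rng.standard_normal((6, 128)), tr_seconds=2.0)
        scheme = make_band_scheme(0.01, 0.25, 0.06)
        low, _ = build_layers(ts, scheme, n_surrogates=20, z_threshold=2.0, seed=5)
        high, _ = build_layers(ts, scheme, n_surrogates=20, z_threshold=3.0, seed=5)
        for la, lb in zip(low, high):
            edges_high = set(map(tuple, np.argwhere(lb.z > 0)))
            edges_low = set(map(tuple, np.argwhere(la.z > 0)))
            assert edges_high <= edges_low

    def test_retained_weights_meet_threshold(self, rng):
        ts = RoiTimeSeriesSet(rng.standard_normal((5, 128)), tr_seconds=2.0)
        scheme = make_band_scheme(0.01, 0.25, 0.08)
        layers, _ = build_layers(ts, scheme, n_surrogates=20, seed=6)
        for layer in layers:
            vals = layer.z[layer.z > 0]
            assert (vals >= 3.0).all()
            assert np.allclose(layer.z, layer.z.T)

    def test_surrogate_count_floor(self, rng):
        ts = RoiTimeSeriesSet(rng.standard_normal((3, 128)), tr_seconds=2.0)
        with pytest.raises(ValueError):
            build_layers(ts, make_band_scheme(0.01, 0.25, 0.12), n_surrogates=5, seed=1)

    def test_null_moment_shapes_and_diagnostics(self, rng):
        ts = RoiTimeSeriesSet(rng.standard_normal((4, 128)), tr_seconds=2.0)
        scheme = make_band_scheme(0.01, 0.25, 0.12)
        null = surrogate_null(ts, scheme, n_surrogates=20, seed=3)
        assert null.mu.shape == (2, 4, 4)
        off = ~np.eye(4, dtype=bool)
        assert (null.sigma[:, off] > 0).all()
        assert null.skew.shape == null.mu.shape
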