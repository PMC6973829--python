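"""Wavelet band-energy feature path: kernels, transform, band averaging,
Ward sensor clustering, spatial/segment averaging, dimensions, PSD baseline,
and agreement with an independent band-pass + Hilbert oracle."""

import numpy as np
import pytest
from scipy import signal

from megstates import GenConfig, generate_block, generate_layout
from megstates.epochs import Epoch
from megstates.features import (ALL_BANDS, BAND_TABLE, SENSOR_BANDS,
                                WaveletSpec, band_energy, extract_features,
                                feature_matrix, morlet_kernel, psd_features,
                                segment_average, spatial_average,
                                ward_cluster_sensors, wavelet_transform)
from megstates.synth import SensorLayout


@pytest.fixture(scope="module")
def spec():
    return WaveletSpec(fs=1000.0)


def make_epoch(data, T=None, fs=1000.0, label="transition"):
    data = np.atleast_2d(data)
    T = data.shape[-1] / fs * 1000.0 if T is None else T
    return Epoch(data=data, label=label, T=T, offset=-T, condition="NCC",
                 subject_id="S01", fs=fs)


class TestKernel:
    def test_peak_value_is_A(self, spec):
        for f in (1.0, 10.0, 80.0):
            k = morlet_kernel(f, spec)
            mid = len(k) // 2
            assert k[mid] == pytest.approx(spec.amplitude(f))
            assert abs(k[mid]) == max(np.abs(k))

    def test_gaussian_envelope_at_one_sd(self, spec):
        f = 10.0
        k = morlet_kernel(f, spec)
        mid = len(k) // 2
        i = int(round(spec.sd(f) * spec.fs))
        t_i = i / spec.fs                      # nearest discrete sample to t = s
        expected = spec.amplitude(f) * np.exp(-t_i ** 2 / (2 * spec.sd(f) ** 2))
        assert abs(k[mid + i]) == pytest.approx(expected, rel=1e-9)
        # magnitude symmetric about t = 0
        np.testing.assert_allclose(np.abs(k), np.abs(k[::-1]), rtol=1e-12)

    def test_fft_peak_at_kernel_frequency(self, spec):
        """DFT of the kernel peaks within one bin of f (10 s grid)."""
        n = 10_000
        for f in (4.0, 10.0, 40.0):
            k = morlet_kernel(f, spec)
            buf = np.zeros(n, dtype=complex)
            buf[:len(k)] = k
            freqs = np.fft.fftfreq(n, d=1 / spec.fs)
            peak = freqs[np.argmax(np.abs(np.fft.fft(buf)))]
            assert abs(peak - f) <= spec.fs / n + 1e-9

    def test_nonpositive_frequency_rejected(self, spec):
        with pytest.raises(ValueError):
            morlet_kernel(0.0, spec)


class TestTransform:
    def test_pure_cosine_peaks_at_nearest_grid_frequency(self, spec):
        t = np.arange(4000) / spec.fs
        x = np.cos(2 * np.pi * 10.0 * t)
        Y = wavelet_transform(x, spec)
        power = np.abs(Y[:, 1500:2500]) ** 2
        best = np.argmax(power.mean(axis=-1))
        grid = np.asarray(spec.frequencies)
        assert best == np.argmin(np.abs(grid - 10.0))

    def test_zero_signal_zero_coefficients(self, spec):
        Y = wavelet_transform(np.zeros(3000), spec)
        assert np.all(Y == 0)

    def test_linearity(self, spec):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        Y1 = wavelet_transform(x, spec, frequencies=[10.0, 40.0])
        Y3 = wavelet_transform(3.0 * x, spec, frequencies=[10.0, 40.0])
        np.testing.assert_allclose(Y3, 3.0 * Y1, rtol=1e-10)


class TestBandEnergy:
    def test_single_bin_average(self, spec):
        """A single nonzero alpha bin of magnitude m gives Z = m^2 / N_alpha."""
        n_f = len(spec.frequencies)
        Y = np.zeros((n_f, 100), dtype=complex)
        bins = spec.band_bins("alpha")
        Y[bins[0]] = 2.0
        Z = band_energy(Y, spec)
        i_alpha = ALL_BANDS.index("alpha")
        np.testing.assert_allclose(Z[i_alpha], 4.0 / len(bins))
        other = [i for i in range(6) if i != i_alpha]
        assert np.all(Z[other] == 0)

    def test_amplitude_doubling_quadruples_energy(self, spec):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        Z1 = band_energy(wavelet_transform(x, spec), spec)
        Z2 = band_energy(wavelet_transform(2 * x, spec), spec)
        np.testing.assert_allclose(Z2, 4 * Z1, rtol=1e-10)

    def test_every_band_has_bins(self, spec):
        counts = spec.band_counts()
        assert all(v >= 2 for v in counts.values())
        assert sum(counts.values()) == len(spec.frequencies)

    def test_sparse_grid_raises_naming_band(self):
        poor = WaveletSpec(fs=1000.0, n_freqs=4)
        x = np.random.default_rng(0).standard_normal(1500)
        with pytest.raises(ValueError, match="no frequency bins"):
            band_energy(wavelet_transform(x, poor), poor)


class TestWardClustering:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        pts = np.r_[rng.normal(0, 0.1, (8, 3)) + [10, 0, 0],
                    rng.normal(0, 0.1, (8, 3)) - [10, 0, 0]]
        lay = SensorLayout(tuple(f"s{i}" for i in range(16)), pts,
                           ("right",) * 8 + ("left",) * 8,
                           np.zeros(16, dtype=bool))
        a = ward_cluster_sensors(lay, 2)
        assert len(set(a[:8])) == 1 and len(set(a[8:])) == 1
        assert a[0] != a[8]

    def test_singleton_clusters(self, small_layout):
        n_keep = int(small_layout.retained.sum())
        a = ward_cluster_sensors(small_layout, n_keep)
        vals = a[small_layout.retained]
        assert sorted(vals) == list(range(1, n_keep + 1))

    def test_four_gaussian_blobs_recovered(self):
        rng = np.random.default_rng(2)
        centers = np.array([[5, 5, 0], [-5, 5, 0], [5, -5, 0], [-5, -5, 0]], float)
        pts = np.concatenate([c + rng.normal(0, 0.3, (5, 3)) for c in centers])
        lay = SensorLayout(tuple(f"s{i}" for i in range(20)), pts,
                           ("left",) * 20, np.zeros(20, dtype=bool))
        a = ward_cluster_sensors(lay, 4)
        for blob in range(4):
            assert len(set(a[blob * 5:(blob + 1) * 5])) == 1
        assert len(set(a)) == 4

    def test_excluded_sensors_unassigned(self, small_layout):
        a = ward_cluster_sensors(small_layout, 10)
        assert np.all(a[small_layout.motor_excluded] == 0)
        assert np.all(a[small_layout.retained] >= 1)
        assert a.max() == 10

    def test_too_many_clusters_rejected(self, small_layout):
        with pytest.raises(ValueError):
            ward_cluster_sensors(small_layout, 1000)


class TestSpatialAverage:
    def _layout(self):
        pts = np.array([[-3, 0, 1], [-2, 1, 1], [3, 0, 1], [2, 1, 1]], float)
        return SensorLayout(("a", "b", "c", "d"), pts,
                            ("left", "left", "right", "right"),
                            np.zeros(4, dtype=bool))

    def test_hemispheric_and_global_arithmetic(self):
        lay = self._layout()
        Z = np.array([[[1.0], [3.0], [5.0], [7.0]]])   # (band=1, ch=4, t=1)
        assert spatial_average(Z, lay, "left-hemi")[0, 0, 0] == 2.0
        assert spatial_average(Z, lay, "right-hemi")[0, 0, 0] == 6.0
        assert spatial_average(Z, lay, "global")[0, 0, 0] == 4.0

    def test_identical_channels_any_scope(self, small_layout):
        Z = np.ones((2, small_layout.n_sensors, 10)) * 3.5
        cl = ward_cluster_sensors(small_layout, 10)
        for scope in ("global", "left-hemi", "right-hemi"):
            out = spatial_average(Z, small_layout, scope)
            np.testing.assert_allclose(out, 3.5)
        np.testing.assert_allclose(
            spatial_average(Z, small_layout, "local-10", cl), 3.5)

    def test_motor_exclusion_matches_manual_mean(self):
        lay = self._layout()
        lay = SensorLayout(lay.sensor_id, lay.positions, lay.hemisphere,
                           np.array([True, False, False, False]))
        Z = np.array([[[1.0], [3.0], [5.0], [7.0]]])
        assert spatial_average(Z, lay, "global")[0, 0, 0] == np.mean([3, 5, 7])

    def test_empty_hemisphere_rejected(self):
        lay = SensorLayout(("a",), np.array([[1.0, 0, 1]]), ("right",),
                           np.zeros(1, dtype=bool))
        with pytest.raises(ValueError, match="left"):
            spatial_average(np.ones((1, 1, 5)), lay, "left-hemi")


class TestSegmentAverage:
    def test_constant_signal(self):
        assert np.all(segment_average(np.full((2, 1, 1200), 7.0), 4) == 7.0)

    def test_step_function_plateaus(self):
        z = np.r_[np.ones(600), 5 * np.ones(600)][None, None]
        np.testing.assert_allclose(segment_average(z, 2)[0, 0], [1.0, 5.0])

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            segment_average(np.ones((1, 1, 1000)), 3)


class TestFeatureDimensions:
    @pytest.mark.parametrize("scope, bands, T, L, dim", [
        ("local-10", SENSOR_BANDS, 1200, 4, 160),
        ("global", SENSOR_BANDS, 1200, 4, 16),
        ("left-hemi", SENSOR_BANDS, 1200, 4, 16),
        ("right-hemi", SENSOR_BANDS, 1200, 4, 16),
        ("global", SENSOR_BANDS, 1800, 6, 24),
        ("global", SENSOR_BANDS, 600, 2, 8),
    ])
    def test_sensor_dimension_closed_forms(self, small_layout, scope, bands, T, L, dim):
        rng = np.random.default_rng(0)
        e = make_epoch(rng.standard_normal((small_layout.n_sensors, T)), T=T)
        fv = extract_features(e, small_layout, scope, bands, L)
        assert len(fv) == dim
        assert len(fv.index) == dim

    def test_source_dimension_closed_form(self):
        rng = np.random.default_rng(0)
        e = make_epoch(rng.standard_normal((89, 1200)))
        fv = extract_features(e, scope="source-89", bands=ALL_BANDS, L=4)
        assert len(fv) == 89 * 6 * 4

    def test_index_ordering_band_major(self, small_layout):
        rng = np.random.default_rng(0)
        e = make_epoch(rng.standard_normal((small_layout.n_sensors, 1200)))
        fv = extract_features(e, small_layout, "local-10", SENSOR_BANDS, 4)
        bands = [ix[0] for ix in fv.index]
        assert bands == sorted(bands, key=list(SENSOR_BANDS).index)
        # within one band: element-major, then segment
        first = fv.index[:8]
        assert [ix[2] for ix in first] == [0, 1, 2, 3, 0, 1, 2, 3]
        assert first[0][1] == first[3][1] != first[4][1]

    def test_scale_equivariance(self, small_layout):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((small_layout.n_sensors, 1200))
        f1 = extract_features(make_epoch(x), small_layout, "global")
        f2 = extract_features(make_epoch(2.5 * x), small_layout, "global")
        np.testing.assert_allclose(f2.values, 2.5 ** 2 * f1.values, rtol=1e-10)

    def test_channel_permutation_invariance(self, small_layout):
        """Averaging is order-free: permuting channels within a hemisphere
        (and permuting the layout the same way) leaves features unchanged."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal((small_layout.n_sensors, 1200))
        perm = rng.permutation(small_layout.n_sensors)
        lay_p = SensorLayout(tuple(np.array(small_layout.sensor_id)[perm]),
                             small_layout.positions[perm],
                             tuple(np.array(small_layout.hemisphere)[perm]),
                             small_layout.motor_excluded[perm])
        f1 = extract_features(make_epoch(x), small_layout, "global")
        f2 = extract_features(make_epoch(x[perm]), lay_p, "global")
        np.testing.assert_allclose(f2.values, f1.values, rtol=1e-10)


class TestWaveletVsBandpassOracle:
    """Independent oracle: zero-phase band-pass + Hilbert envelope power.

    Both paths are compared on scale-free quantities (the pipeline is
    scale-invariant): the power ratio across an amplitude step, and the
    normalized temporal profile of a modulated narrowband signal.
    """

    def test_amplitude_step_ratio_agrees(self, spec):
        n = 8000
        t = np.arange(n) / 1000.0
        x = np.cos(2 * np.pi * 10.0 * t)
        x[n // 2:] *= 2.0          # power steps x4
        margin, mid = 1000, n // 2
        # wavelet path
        Z = band_energy(wavelet_transform(x, spec), spec)[ALL_BANDS.index("alpha")]
        r_wav = Z[mid + margin:-margin].mean() / Z[margin:mid - margin].mean()
        # oracle path
        env2 = np.abs(signal.hilbert(x)) ** 2
        r_orc = env2[mid + margin:-margin].mean() / env2[margin:mid - margin].mean()
        assert r_wav == pytest.approx(r_orc, rel=0.10)

    def test_normalized_profiles_agree(self, spec):
        t = np.arange(8000) / 1000.0
        am = 1.0 + 0.6 * np.sin(2 * np.pi * 0.4 * t)
        x = am * np.cos(2 * np.pi * 10.0 * t)
        Z = band_energy(wavelet_transform(x, spec), spec)[ALL_BANDS.index("alpha")]
        env = np.abs(signal.hilbert(x))
        # the wavelet smooths the analytic signal before squaring: apply the
        # kernel's own Gaussian time resolution to the oracle envelope
        sd = spec.sd(10.0)
        k = signal.windows.gaussian(int(8 * sd * 1000) | 1, sd * 1000)
        env_s = signal.fftconvolve(env, k / k.sum(), mode="same") ** 2
        sl = slice(1500, 6500)
        zn = Z[sl] / Z[sl].mean()
        en = env_s[sl] / env_s[sl].mean()
        assert np.max(np.abs(zn - en)) < 0.10


class TestPSDFeatures:
    def test_sinusoid_dominates_alpha(self, small_layout):
        t = np.arange(1200) / 1000.0
        x = np.tile(np.cos(2 * np.pi * 10 * t), (small_layout.n_sensors, 1))
        fv = psd_features(make_epoch(x), small_layout)
        df = {b: np.mean([v for v, ix in zip(fv.values, fv.index) if ix[0] == b])
              for b in SENSOR_BANDS}
        assert df["alpha"] > 10 * max(v for b, v in df.items() if b != "alpha")

    def test_dimension_10x4(self, small_layout):
        rng = np.random.default_rng(0)
        fv = psd_features(make_epoch(rng.standard_normal(
            (small_layout.n_sensors, 1200))), small_layout)
        assert len(fv) == 40

    def test_white_noise_epochs_indistinguishable(self, small_layout):
        """Feature distributions from disjoint white-noise epochs match."""
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(6)
        a = [psd_features(make_epoch(rng.standard_normal((24, 1200))),
                          small_layout).values.sum() for _ in range(40)]
        b = [psd_features(make_epoch(rng.standard_normal((24, 1200))),
                          small_layout).values.sum() for _ in range(40)]
        assert mannwhitneyu(a, b).pvalue > 0.01

    def test_oversized_welch_window_rejected(self, small_layout):
        e = make_epoch(np.zeros((small_layout.n_sensors, 300)))
        with pytest.raises(ValueError, match="exceeds"):
            psd_features(e, small_layout, nperseg_ms=500)


class TestFeatureMatrix:
    def test_labels_and_shapes(self, small_layout, small_gen):
        from megstates import extract_epochs
        blk = generate_block(small_layout, "NCC", small_gen)
        es = extract_epochs(blk, 1200)
        X, y, index, meta = feature_matrix(es, small_layout, "global")
        assert X.shape == (len(es), 16)
        assert set(y) == {0, 1} and y.sum() * 2 == len(y)


class TestFeatureExport:
    def test_tsv_roundtrip_with_sidecar(self, small_layout, tmp_path):
        import json
        import pandas as pd
        from megstates.features import features_to_tsv
        rng = np.random.default_rng(0)
        e = make_epoch(rng.standard_normal((small_layout.n_sensors, 1200)))
        fv = extract_features(e, small_layout, "global")
        path = tmp_path / "features.tsv"
        features_to_tsv(fv.values[None, :], fv.index, path,
                        spec=WaveletSpec(fs=1000.0), layout=small_layout)
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back.to_numpy()[0], fv.values)
        assert back.columns[0] == "alpha|all|0"
        sidecar = json.loads((tmp_path / "features.tsv.json").read_text())
        assert "layout_sha256" in sidecar and "bands" in sidecar
        assert sidecar["wavelet"]["n_cycles"] == 7.0
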