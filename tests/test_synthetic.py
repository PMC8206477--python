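"""Generator contracts: source maps, time courses, subjects, cohorts."""

import numpy as np
import pytest

from brainnets.io_core import DimensionError, InputError, NumericError
from brainnets.synthetic import (
    DEFAULT_T, EffectSpec, SourceSpec, generate_cohort, make_coupling,
    make_source_maps, make_time_courses, signal_sd, synthesize_subject,
)

GRID = (16, 18, 16)


class TestSourceMaps:
    def test_disjoint_networks_nearly_uncorrelated(self):
        spec = SourceSpec(K=2, grid_shape=GRID)
        maps = make_source_maps(spec, seed=0)
        r = np.corrcoef(maps)[0, 1]
        assert abs(r) < 0.3

    def test_deterministic_given_seed(self):
        spec = SourceSpec(K=4, grid_shape=GRID)
        np.testing.assert_array_equal(make_source_maps(spec, seed=3),
                                      make_source_maps(spec, seed=3))
        assert not np.array_equal(make_source_maps(spec, seed=3),
                                  make_source_maps(spec, seed=4))

    def test_eight_networks_on_mid_grid_all_nonempty(self):
        spec = SourceSpec(K=8, grid_shape=(24, 28, 24))
        maps = make_source_maps(spec, seed=1)
        assert maps.shape == (8, 24 * 28 * 24)
        # every network has suprathreshold voxels and values in [0, 1]
        assert ((maps > 0.5).sum(axis=1) > 0).all()
        assert maps.min() >= 0.0 and maps.max() <= 1.0


class TestTimeCourses:
    def test_zero_mean_unit_variance(self):
        tcs = make_time_courses(200, 2.0, np.eye(4), seed=0)
        np.testing.assert_allclose(tcs.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tcs.std(axis=0), 1.0, atol=1e-9)

    def test_identity_coupling_uncorrelated(self):
        tcs = make_time_courses(10000, 2.0, np.eye(3), seed=1)
        r = np.corrcoef(tcs.T)
        off = r[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_target_coupling_reached(self):
        C = make_coupling(3, {(0, 1): 0.6})
        tcs = make_time_courses(10000, 2.0, C, seed=2)
        r = np.corrcoef(tcs.T)
        assert 0.55 <= r[0, 1] <= 0.65

    def test_band_limited_power(self):
        from scipy.signal import welch
        tcs = make_time_courses(2048, 2.0, np.eye(2), seed=3)
        f, p = welch(tcs[:, 0], fs=0.5, nperseg=512)
        band = (f >= 0.01) & (f <= 0.1)
        assert p[band].sum() / p[f > 0].sum() > 0.8

    def test_non_psd_coupling_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        with pytest.raises(NumericError):
            make_time_courses(100, 2.0, C, seed=0)


class TestSynthesizeSubject:
    def _pieces(self, K=3, T=64, seed=0):
        spec = SourceSpec(K=K, grid_shape=GRID)
        maps = make_source_maps(spec, seed=seed)
        tcs = make_time_courses(T, 2.0, np.eye(K), seed=seed + 1)
        return maps, tcs

    def test_noiseless_equals_bilinear_signal(self):
        maps, tcs = self._pieces()
        eff = EffectSpec(K=3, noise_sigma=0.0)
        series, truth = synthesize_subject(maps, tcs, eff, "control", GRID,
                                           seed=0)
        expected = maps.T @ tcs.T
        np.testing.assert_allclose(
            series.data.reshape(-1, tcs.shape[0]), expected, atol=1e-12)

    def test_noiseless_cohort_is_rank_k(self):
        maps, tcs = self._pieces(K=3)
        eff = EffectSpec(K=3, noise_sigma=0.0)
        series, _ = synthesize_subject(maps, tcs, eff, "control", GRID, seed=0)
        s = np.linalg.svd(series.data.reshape(-1, tcs.shape[0]),
                          compute_uv=False)
        assert s[2] > 1e-8
        assert s[3] < 1e-10 * s[0]

    def test_amplitude_effect_recovered_by_regression(self):
        maps, tcs = self._pieces(T=400, seed=2)
        eff = EffectSpec(K=3, amplitude_delta=[1.0, 1.5, 1.0],
                         noise_sigma=0.05)
        case, _ = synthesize_subject(maps, tcs, eff, "case", GRID, seed=3)
        ctrl, _ = synthesize_subject(maps, tcs, eff, "control", GRID, seed=4)
        design = tcs - tcs.mean(axis=0)
        for data, expected in ((case, 1.5), (ctrl, 1.0)):
            Y = data.data.reshape(-1, 400).T
            beta, *_ = np.linalg.lstsq(design, Y - Y.mean(axis=0), rcond=None)
            fitted = beta[1] @ maps[1] / (maps[1] @ maps[1])
            assert fitted == pytest.approx(expected, abs=0.05)

    def test_white_noise_when_ar1_zero(self):
        maps, tcs = self._pieces(K=3, T=64)
        eff = EffectSpec(K=3, noise_sigma=1.0, ar1_coefficient=0.0)
        series, truth = synthesize_subject(maps * 0.0, tcs, eff, "control",
                                           GRID, seed=5)
        x = series.data.reshape(-1, 64)
        # pool lag-1 autocorrelation across many voxels
        a, b = x[:, :-1].ravel(), x[:, 1:].ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 0.05

    def test_ar1_autocorrelation_matches_coefficient(self):
        maps, tcs = self._pieces(K=3, T=200)
        eff = EffectSpec(K=3, noise_sigma=1.0, ar1_coefficient=0.6)
        series, _ = synthesize_subject(maps * 0.0, tcs, eff, "control",
                                       GRID, seed=6)
        x = series.data.reshape(-1, 200)
        r = np.corrcoef(x[:, :-1].ravel(), x[:, 1:].ravel())[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)
        assert x.std() == pytest.approx(1.0, abs=0.05)

    def test_unknown_group_rejected(self):
        maps, tcs = self._pieces()
        with pytest.raises(InputError):
            synthesize_subject(maps, tcs, EffectSpec(K=3), "patient", GRID,
                               seed=0)


class TestGenerateCohort:
    def test_counts_files_and_default_length(self, tmp_path):
        spec = SourceSpec(K=2, grid_shape=(10, 12, 10))
        eff = EffectSpec(K=2, noise_sigma=0.1)
        table, truth, series = generate_cohort(5, 5, spec, eff, seed=1,
                                               out_dir=tmp_path)
        assert len(list(tmp_path.glob("sub-*.nii.gz"))) == 10
        assert (table.frame["group"] == "case").sum() == 5
        assert (table.frame["group"] == "control").sum() == 5
        # 6-minute scan at TR = 2 s
        assert DEFAULT_T == 180
        assert series[0].n_timepoints == 180

    def test_ground_truth_archive_byte_identical_across_runs(self, tmp_path):
        spec = SourceSpec(K=2, grid_shape=(10, 12, 10))
        eff = EffectSpec(K=2, noise_sigma=0.1)
        for d in ("a", "b"):
            generate_cohort(2, 2, spec, eff, seed=9, out_dir=tmp_path / d, T=64)
        for name in ("maps_control.npy", "maps_case.npy", "tcs.npy",
                     "amplitudes_case.npy", "meta.yaml"):
            fa = (tmp_path / "a" / "ground_truth" / name).read_bytes()
            fb = (tmp_path / "b" / "ground_truth" / name).read_bytes()
            assert fa == fb, name

    def test_group_coupling_difference_matches_spec(self):
        K = 4
        eff = EffectSpec(K=K, noise_sigma=0.0,
                         coupling_case=make_coupling(K, {(0, 1): 0.5}),
                         coupling_control=make_coupling(K, {}))
        spec = SourceSpec(K=K, grid_shape=(10, 12, 10))
        _, truth, _ = generate_cohort(8, 8, spec, eff, seed=3,
                                      out_dir=".", write_files=False, T=120)
        rs = {g: [] for g in ("case", "control")}
        for i, g in enumerate(truth.groups):
            rs[g].append(np.corrcoef(truth.tcs[i].T)[0, 1])
        diff = np.mean(rs["case"]) - np.mean(rs["control"])
        assert diff == pytest.approx(0.5, abs=0.05)

    def test_group_size_validation(self, tmp_path):
        spec = SourceSpec(K=2, grid_shape=(10, 12, 10))
        with pytest.raises(InputError):
            generate_cohort(0, 5, spec, EffectSpec(K=2), seed=0,
                            out_dir=tmp_path)

    def test_k_mismatch_rejected(self, tmp_path):
        with pytest.raises(DimensionError):
            generate_cohort(1, 1, SourceSpec(K=3, grid_shape=(10, 12, 10)),
                            EffectSpec(K=2), seed=0, out_dir=tmp_path)


def test_signal_sd_matches_empirical_noiseless_sd():
    spec = SourceSpec(K=3, grid_shape=GRID)
    maps = make_source_maps(spec, seed=0)
    tcs = make_time_courses(5000, 2.0, np.eye(3), seed=1)
    series, _ = synthesize_subject(maps, tcs, EffectSpec(K=3, noise_sigma=0.0),
                                   "control", GRID, seed=0)
    empirical = series.data.std()
    assert signal_sd(maps) == pytest.approx(empirical, rel=0.05)
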