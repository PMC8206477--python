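"""Dual regression: exact recovery, normalization, stacking, properties."""

import numpy as np
import pytest

from brainnets.dual_regression import (
    assemble_subject_stack, dual_regress_subject, normalize_timecourses,
    stage1_spatial_regression, stage2_temporal_regression, SubjectTimeCourses,
)
from brainnets.io_core import (
    BrainMask, CollinearityError, DegenerateInputError, InputError,
    compute_mask,
)
from brainnets.synthetic import (
    EffectSpec, SourceSpec, generate_cohort, make_source_maps, signal_sd,
)

GRID = (16, 18, 16)


def _templates(truth, mask):
    return truth.maps_control[:, mask.mask.ravel()]


class TestStage1:
    def test_noiseless_time_courses_exact(self, noiseless_cohort):
        _, truth, series = noiseless_cohort
        mask = compute_mask(series)
        templates = _templates(truth, mask)
        for i, s in enumerate(series):
            stc = stage1_spatial_regression(templates, s, mask)
            true_tcs = truth.true_tcs(i) * truth.true_amplitudes(i)
            np.testing.assert_allclose(stc.tcs, true_tcs, atol=1e-8)

    def test_orthonormal_templates_closed_form(self):
        rng = np.random.default_rng(0)
        V, K, T = 400, 3, 30
        Q, _ = np.linalg.qr(rng.standard_normal((V, K)))
        Q -= Q.mean(axis=0)  # demeaned columns stay the regression design
        Q, _ = np.linalg.qr(Q)
        data = rng.standard_normal((V, T))
        from brainnets.io_core import VolumeSeries
        series = VolumeSeries(data=data.reshape(8, 10, 5, T),
                              voxel_size_mm=(4, 4, 4), tr_seconds=2.0,
                              affine=np.eye(4))
        mask = BrainMask(np.ones((8, 10, 5), dtype=bool))
        stc = stage1_spatial_regression(Q.T, series, mask)
        expected = Q.T @ (data - data.mean(axis=0))
        np.testing.assert_allclose(stc.tcs, expected.T, atol=1e-10)

    def test_duplicate_template_collinearity_error(self, noiseless_cohort):
        _, truth, series = noiseless_cohort
        mask = compute_mask(series)
        templates = _templates(truth, mask)
        dup = np.vstack([templates, templates[0]])
        with pytest.raises(CollinearityError) as exc:
            stage1_spatial_regression(dup, series[0], mask)
        assert len(exc.value.components) == 2


class TestNormalize:
    def test_scaling_and_round_trip(self):
        rng = np.random.default_rng(1)
        tcs = rng.standard_normal((50, 3)) * np.array([3.0, 1.0, 0.2])
        stc = SubjectTimeCourses(tcs=tcs)
        out = normalize_timecourses(stc)
        np.testing.assert_allclose(out.tcs.std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.tcs * out.scale_factors, tcs,
                                   atol=1e-12)
        again = normalize_timecourses(out)
        np.testing.assert_allclose(again.tcs, out.tcs, atol=1e-12)

    def test_zero_variance_column_rejected(self):
        tcs = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(DegenerateInputError):
            normalize_timecourses(SubjectTimeCourses(tcs=tcs))


class TestStage2:
    def test_noiseless_maps_exact_fixed_point(self, noiseless_cohort):
        _, truth, series = noiseless_cohort
        mask = compute_mask(series)
        templates = _templates(truth, mask)
        for i, s in enumerate(series):
            _, maps = dual_regress_subject(templates, s, mask, des_norm=True)
            true_maps = truth.true_maps(i)[:, mask.mask.ravel()]
            for k in range(truth.K):
                # per-component scale matching, then exact agreement
                scale = (maps[k] @ true_maps[k]) / (true_maps[k] @ true_maps[k])
                np.testing.assert_allclose(maps[k], scale * true_maps[k],
                                           atol=1e-6)

    def test_recovery_above_bound_at_snr_one(self):
        spec = SourceSpec(K=3, grid_shape=GRID)
        maps0 = make_source_maps(spec, seed=21)
        eff = EffectSpec(K=3, noise_sigma=signal_sd(maps0))
        _, truth, series = generate_cohort(2, 2, spec, eff, seed=21,
                                           out_dir=".", write_files=False,
                                           T=180)
        mask = compute_mask(series)
        templates = _templates(truth, mask)
        rs = []
        for i, s in enumerate(series):
            _, maps = dual_regress_subject(templates, s, mask)
            tm = truth.true_maps(i)[:, mask.mask.ravel()]
            rs += [abs(np.corrcoef(maps[k], tm[k])[0, 1]) for k in range(3)]
        assert np.mean(rs) > 0.95

    def test_recovery_degrades_monotonically_with_noise(self):
        spec = SourceSpec(K=3, grid_shape=GRID)
        mean_rs = []
        for sigma in (0.05, 0.4, 1.2):
            eff = EffectSpec(K=3, noise_sigma=sigma)
            _, truth, series = generate_cohort(1, 1, spec, eff, seed=33,
                                               out_dir=".", write_files=False,
                                               T=100)
            mask = compute_mask(series)
            templates = _templates(truth, mask)
            rs = []
            for i, s in enumerate(series):
                _, maps = dual_regress_subject(templates, s, mask)
                tm = truth.true_maps(i)[:, mask.mask.ravel()]
                rs += [abs(np.corrcoef(maps[k], tm[k])[0, 1]) for k in range(3)]
            mean_rs.append(np.mean(rs))
        assert mean_rs[0] > mean_rs[1] > mean_rs[2]

    def test_amplitude_effect_encoded_in_map_magnitude(self):
        spec = SourceSpec(K=3, grid_shape=GRID)
        eff = EffectSpec(K=3, amplitude_delta=[1.0, 1.5, 1.0],
                         noise_sigma=0.02)
        _, truth, series = generate_cohort(6, 6, spec, eff, seed=8,
                                           out_dir=".", write_files=False,
                                           T=150)
        mask = compute_mask(series)
        templates = _templates(truth, mask)
        mags = {"case": [], "control": []}
        for i, s in enumerate(series):
            _, maps = dual_regress_subject(templates, s, mask, des_norm=True)
            mags[truth.groups[i]].append(np.linalg.norm(maps[1]))
        ratio = np.mean(mags["case"]) / np.mean(mags["control"])
        assert ratio == pytest.approx(1.5, abs=0.1)

    def test_insufficient_timepoints_rejected(self, noiseless_cohort):
        _, truth, series = noiseless_cohort
        mask = compute_mask(series)
        stc = SubjectTimeCourses(tcs=np.random.default_rng(0).standard_normal((3, 3)))
        with pytest.raises(InputError):
            stage2_temporal_regression(stc, series[0], mask)

    def test_template_permutation_equivariance(self, noiseless_cohort):
        _, truth, series = noiseless_cohort
        mask = compute_mask(series)
        templates = _templates(truth, mask)
        perm = [2, 0, 1]
        _, maps_a = dual_regress_subject(templates, series[0], mask)
        _, maps_b = dual_regress_subject(templates[perm], series[0], mask)
        np.testing.assert_allclose(maps_b, maps_a[perm], atol=1e-8)


class TestAssembleStack:
    def test_shape_and_crop_round_trip(self, noiseless_cohort):
        _, truth, series = noiseless_cohort
        mask = compute_mask(series)
        templates = _templates(truth, mask)
        _, maps = dual_regress_subject(templates, series[0], mask)
        pad = (20, 20, 20)
        stack = assemble_subject_stack(maps, [0, 1, 2], mask, pad,
                                       channel_names=["a", "b", "c"])
        assert stack.maps.shape == (3, 20, 20, 20)
        from brainnets.io_core import crop_to_shape
        for k in range(3):
            vol = crop_to_shape(stack.maps[k], mask.mask.shape)
            np.testing.assert_allclose(vol[mask.mask], maps[k], atol=1e-12)

    def test_single_channel_stack(self, noiseless_cohort):
        _, truth, series = noiseless_cohort
        mask = compute_mask(series)
        maps = np.random.default_rng(0).standard_normal((3, mask.n_voxels))
        stack = assemble_subject_stack(maps, [1], mask, mask.mask.shape)
        assert stack.maps.shape == (1, *mask.mask.shape)

    def test_bad_index_rejected(self, noiseless_cohort):
        _, _, series = noiseless_cohort
        mask = compute_mask(series)
        maps = np.zeros((3, mask.n_voxels))
        with pytest.raises(InputError):
            assemble_subject_stack(maps, [3], mask, mask.mask.shape)
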