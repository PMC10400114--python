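"""Confound computations: hand-worked FD examples, a Monte-Carlo sphere
oracle for the affine RMS displacement, DVARS/global-signal checks, DCT
filter properties, CompCor planted-component recovery, expansion and
outlier-flag rules."""

import numpy as np
import pytest

from funcnet.confounds import (
    ConfoundTable,
    MotionTrace,
    TissueMask,
    VolumeSeries,
    _rigid_affine,
    acompcor,
    annotate_outliers,
    dct_highpass,
    dvars_standardized,
    expand_confounds,
    fd_power,
    fd_jenkinson,
    global_signals,
    retain_components,
    tcompcor,
)


def motion_from(params):
    return MotionTrace(params=np.asarray(params, dtype=float), tr=2.0)


class TestFdPower:
    def test_zero_motion(self):
        fd = fd_power(motion_from(np.zeros((5, 6))))
        assert np.array_equal(fd, np.zeros(5))

    def test_translation_hand_example(self):
        p = np.zeros((2, 6))
        p[1, :3] = (0.1, 0.2, -0.1)
        assert fd_power(motion_from(p))[1] == pytest.approx(0.4)

    def test_rotation_hand_example(self):
        p = np.zeros((2, 6))
        p[1, 3:] = 0.01
        assert fd_power(motion_from(p), rotation_radius=50.0)[1] == pytest.approx(1.5)

    def test_sign_invariance(self, rng):
        steps = rng.normal(0, 0.05, size=(6, 6))
        p = np.cumsum(steps, axis=0)
        assert np.allclose(fd_power(motion_from(p)), fd_power(motion_from(-p)))

    def test_positive_for_any_change(self):
        p = np.zeros((3, 6))
        p[2, 4] = 1e-4
        fd = fd_power(motion_from(p))
        assert fd[1] == 0.0 and fd[2] > 0.0

    def test_rejects_nonfinite(self):
        p = np.zeros((2, 6))
        p[1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            motion_from(p)


class TestFdJenkinson:
    def test_identity_motion(self):
        assert np.array_equal(fd_jenkinson(motion_from(np.zeros((4, 6)))), np.zeros(4))

    def test_pure_translation_equals_magnitude(self):
        p = np.zeros((2, 6))
        p[1, 1] = 0.3
        assert fd_jenkinson(motion_from(p))[1] == pytest.approx(0.3, abs=1e-12)

    def test_monte_carlo_ball_oracle(self, rng):
        """RMS displacement over points sampled uniformly in the sphere."""
        p = rng.normal(0, 0.02, size=(3, 6))
        p[:, 3:] *= 0.01
        fd = fd_jenkinson(motion_from(p), sphere_radius=80.0)
        pts = rng.uniform(-80, 80, size=(3_000_000, 3))
        pts = pts[(pts**2).sum(axis=1) <= 80.0**2]
        for t in (1, 2):
            T = _rigid_affine(p[t]) @ np.linalg.inv(_rigid_affine(p[t - 1]))
            moved = pts @ T[:3, :3].T + T[:3, 3]
            rms = np.sqrt(((moved - pts) ** 2).sum(axis=1).mean())
            assert fd[t] == pytest.approx(rms, abs=1e-3)


class TestDvars:
    def _vols(self, data):
        return VolumeSeries(data=np.asarray(data, dtype=float), voxel_size=2.0, tr=2.0)

    def test_constant_series_zeros_with_warning(self):
        vols = self._vols(np.ones((2, 2, 1, 4)))
        mask = TissueMask(np.ones((2, 2, 1)), "whole-brain")
        with pytest.warns(UserWarning, match="degenerate"):
            assert np.array_equal(dvars_standardized(vols, mask), np.zeros(4))

    def test_two_voxel_hand_example(self):
        a = 0.7
        data = np.zeros((2, 1, 1, 2))
        data[0, 0, 0] = (0.0, a)
        data[1, 0, 0] = (0.0, -a)
        vols = self._vols(data)
        mask = TissueMask(np.ones((2, 1, 1)), "whole-brain")
        raw_like = dvars_standardized(vols, mask)  # single nonzero frame: scaled by itself
        # recover raw from the standardization: median of frame 1..T-1 is a
        assert raw_like[0] == 0.0 and raw_like[1] == pytest.approx(1.0)

    def test_median_of_standardized_is_one(self, random_volume):
        vols, mask = random_volume
        dv = dvars_standardized(vols, mask)
        assert np.median(dv[1:]) == pytest.approx(1.0)

    def test_invariant_to_constant_offset(self, random_volume):
        vols, mask = random_volume
        shifted = VolumeSeries(data=vols.data + 123.0, voxel_size=3.0, tr=2.0)
        assert np.allclose(dvars_standardized(vols, mask), dvars_standardized(shifted, mask))

    def test_empty_mask_errors(self, random_volume):
        vols, _ = random_volume
        empty = TissueMask(np.zeros((6, 6, 5)), "CSF")
        with pytest.raises(ValueError, match="no voxels"):
            dvars_standardized(vols, empty)


class TestGlobalSignals:
    def test_uniform_volume(self):
        vols = VolumeSeries(data=np.full((3, 3, 2, 5), 7.0), voxel_size=2.0, tr=2.0)
        masks = [TissueMask(np.ones((3, 3, 2)), "CSF"), TissueMask(np.ones((3, 3, 2)), "WM")]
        sig = global_signals(vols, masks)
        assert np.allclose(sig["CSF"], 7.0) and np.allclose(sig["WM"], 7.0)

    def test_disjoint_constant_regions(self):
        data = np.zeros((4, 2, 1, 3))
        data[:2] = 5.0
        data[2:] = 9.0
        vols = VolumeSeries(data=data, voxel_size=2.0, tr=2.0)
        m1 = np.zeros((4, 2, 1))
        m1[:2] = 1.0
        m2 = np.zeros((4, 2, 1))
        m2[2:] = 1.0
        sig = global_signals(vols, [TissueMask(m1, "CSF"), TissueMask(m2, "WM")])
        assert np.allclose(sig["CSF"], 5.0) and np.allclose(sig["WM"], 9.0)

    def test_exhaustive_mean_oracle(self, random_volume):
        vols, mask = random_volume
        sig = global_signals(vols, [mask])["whole-brain"]
        expected = np.array(
            [vols.data[..., t].mean() for t in range(vols.n_frames)]
        )
        assert np.allclose(sig, expected)

    def test_empty_after_binarization_names_tissue(self, random_volume):
        vols, _ = random_volume
        weak = TissueMask(np.full((6, 6, 5), 0.2), "WM")
        with pytest.raises(ValueError, match="WM"):
            global_signals(vols, [weak])


class TestDctHighpass:
    def test_constant_removed(self):
        out = dct_highpass(np.full(100, 3.0), cutoff_period=128.0, tr=2.3)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_linear_drift_removed(self):
        t = np.arange(261) * 2.3  # ~600 s
        drift = 0.05 * t
        out = dct_highpass(drift, cutoff_period=128.0, tr=2.3)
        assert out.var() < 0.01 * drift.var()

    def test_fast_sinusoid_preserved(self):
        t = np.arange(261) * 2.3
        sig = np.sin(2 * np.pi * t / 20.0)
        out = dct_highpass(sig, cutoff_period=128.0, tr=2.3)
        assert np.corrcoef(sig, out)[0, 1] > 0.99

    def test_idempotent(self, rng):
        x = rng.normal(size=(120, 3))
        once = dct_highpass(x, 128.0, 2.3)
        twice = dct_highpass(once, 128.0, 2.3)
        assert np.max(np.abs(once - twice)) < 1e-10

    def test_output_orthogonal_to_removed_basis(self, rng):
        from funcnet.confounds import _dct_drop_basis

        x = rng.normal(size=(100, 2))
        out = dct_highpass(x, 128.0, 2.3)
        basis = _dct_drop_basis(100, 2.3, 128.0)
        basis /= np.linalg.norm(basis, axis=0)
        assert np.max(np.abs(basis.T @ out)) < 1e-8


def _planted_volume(rng, shape=(8, 8, 4), frames=80, n_planted=None, region=None):
    """Weak-noise volume with a strong shared sinusoid in selected voxels."""
    n_vox = int(np.prod(shape))
    data = rng.normal(0, 0.1, size=(n_vox, frames))
    t = np.arange(frames)
    sinus = np.sin(2 * np.pi * t / 11.0)
    if region is None:
        n_planted = n_planted or int(np.ceil(0.02 * n_vox))
        region = np.arange(n_planted)
    data[region] += 3.0 * sinus
    vols = VolumeSeries(
        data=data.reshape(*shape, frames), voxel_size=3.0, tr=2.0
    )
    return vols, sinus, region


class TestTcompcor:
    def test_planted_component_recovered(self, rng):
        vols, sinus, _ = _planted_volume(rng)
        mask = TissueMask(np.ones(vols.spatial_shape), "whole-brain")
        res = tcompcor(vols, mask, top_fraction=0.02)
        r = np.corrcoef(res.components[:, 0], sinus)[0, 1]
        assert abs(r) > 0.95

    def test_full_fraction_equals_full_pca(self, random_volume):
        vols, mask = random_volume
        full = tcompcor(vols, mask, top_fraction=1.0)
        from funcnet.confounds import _mask_voxels, _principal_components

        direct = _principal_components(_mask_voxels(vols, mask.binarize(0.5)))
        assert np.allclose(full.components, direct.components)

    def test_components_orthogonal(self, random_volume):
        vols, mask = random_volume
        res = tcompcor(vols, mask, top_fraction=0.5)
        gram = res.components.T @ res.components
        assert np.max(np.abs(gram - np.eye(gram.shape[0]))) < 1e-8

    def test_all_constant_errors(self):
        vols = VolumeSeries(data=np.ones((3, 3, 2, 6)), voxel_size=2.0, tr=2.0)
        mask = TissueMask(np.ones((3, 3, 2)), "whole-brain")
        with pytest.raises(ValueError, match="constant"):
            tcompcor(vols, mask)


class TestAcompcor:
    def test_threshold_keeps_only_high_probability(self):
        probs = np.full((4, 4, 2), 0.5)
        probs[0, 0, 0] = 0.995
        mask = TissueMask(probs, "CSF")
        assert mask.binarize(0.99).sum() == 1

    def test_planted_csf_component(self, rng):
        region = np.arange(10)
        vols, sinus, _ = _planted_volume(rng, region=region)
        probs = np.zeros(vols.spatial_shape).reshape(-1)
        probs[region] = 1.0
        res = acompcor(vols, [TissueMask(probs.reshape(vols.spatial_shape), "CSF")])
        r = np.corrcoef(res["CSF"].components[:, 0], sinus)[0, 1]
        assert abs(r) > 0.95

    def test_identical_masks_identical_subspaces(self, random_volume):
        vols, _ = random_volume
        probs = np.ones(vols.spatial_shape)
        res = acompcor(
            vols, [TissueMask(probs, "CSF"), TissueMask(probs.copy(), "WM")]
        )
        assert np.allclose(res["CSF"].components, res["WM"].components)

    def test_empty_mask_names_tissue(self, random_volume):
        vols, _ = random_volume
        with pytest.raises(ValueError, match="CSF"):
            acompcor(vols, [TissueMask(np.full(vols.spatial_shape, 0.5), "CSF")])


class TestRetainComponents:
    @pytest.mark.parametrize(
        "shares,target,expected",
        [
            ((0.6, 0.3, 0.1), 0.5, 1),
            ((0.25, 0.25, 0.25, 0.25), 0.5, 2),
            ((0.5, 0.3, 0.2), 1.0, 3),
        ],
    )
    def test_cases(self, shares, target, expected):
        s = np.sqrt(np.asarray(shares))
        assert retain_components(s, target) == expected

    def test_monotone_in_target(self, rng):
        s = np.sort(rng.uniform(0.1, 2.0, size=8))[::-1]
        ks = [retain_components(s, t) for t in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            retain_components(np.array([]))


class TestExpandConfounds:
    def _table(self, cols):
        import pandas as pd

        return ConfoundTable(frame=pd.DataFrame(cols))

    def test_constant_column_zero_derivative(self):
        t = expand_confounds(self._table({"a": [2.0, 2.0, 2.0]}), ["a"])
        assert np.array_equal(t.frame["a_derivative1"], [0, 0, 0])

    def test_quadratic_definition(self):
        t = expand_confounds(self._table({"a": [1.0, 2.0]}), ["a"])
        assert np.array_equal(t.frame["a_power2"], [1.0, 4.0])

    def test_nine_columns_give_36_lineage(self, rng):
        cols = {f"c{i}": rng.normal(size=10) for i in range(9)}
        t = expand_confounds(self._table(cols), list(cols))
        assert len(t.frame.columns) == 36
        assert len(t.lineage) == 36

    def test_collision_errors(self):
        t = self._table({"a": [1.0, 2.0], "a_power2": [1.0, 4.0]})
        with pytest.raises(ValueError, match="already exists"):
            expand_confounds(t, ["a"])


class TestAnnotateOutliers:
    def test_paper_threshold_example(self):
        flags = annotate_outliers(
            np.array([0.2, 0.6, 0.3]), np.array([1.0, 1.0, 2.0]), 0.5, 1.5
        )
        assert np.array_equal(flags, [False, True, True])

    def test_all_below_no_flags(self):
        flags = annotate_outliers(np.array([0.1, 0.2]), np.array([0.5, 1.0]))
        assert not flags.any()

    def test_exact_threshold_not_flagged(self):
        assert not annotate_outliers(np.array([0.5]), np.array([1.5])).any()

    def test_flag_count_monotone_in_thresholds(self, rng):
        fd = rng.uniform(0, 1, 50)
        dv = rng.uniform(0, 3, 50)
        counts = [
            annotate_outliers(fd, dv, fd_thr, 1.5).sum()
            for fd_thr in (0.8, 0.5, 0.3, 0.1)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
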