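"""Unit and property tests for the GFC core: masking, Fisher transform,
fast-path vs brute-force equivalence, and the minimal preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfcmap import (
    VolumeSeries,
    build_gray_mask,
    compute_gfc,
    drop_constant_voxels,
    fisher_z,
    preprocess_minimal,
    GlobalConnectivity,
)
from conftest import full_mask, pairwise_gfc_oracle, random_volume


class TestGrayMask:
    def test_all_pass_when_every_probability_exceeds_threshold(self):
        mask = build_gray_mask(np.full((3, 3, 3), 0.5), 0.2)
        assert len(mask) == 27

    def test_boundary_is_strict_inequality(self):
        with pytest.raises(ValueError, match="0.2"):
            build_gray_mask(np.full((3, 3, 3), 0.2), 0.2)

    def test_size_matches_direct_scan_on_random_map(self):
        rng = np.random.default_rng(42)
        prob = rng.random((6, 5, 4))
        mask = build_gray_mask(prob, 0.2)
        # brute-force voxel scan oracle
        count = sum(
            1
            for x in range(6)
            for y in range(5)
            for z in range(4)
            if prob[x, y, z] > 0.2
        )
        assert len(mask) == count

    def test_ordering_is_row_major(self):
        prob = np.zeros((2, 2, 2))
        prob[1, 0, 1] = 0.9
        prob[0, 1, 0] = 0.9
        mask = build_gray_mask(prob, 0.2)
        assert mask.member_voxels.tolist() == [[0, 1, 0], [1, 0, 1]]

    def test_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            build_gray_mask(np.full((2, 2, 2), 1.5), 0.2)


class TestFisherZ:
    def test_fixed_point_and_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_function(self):
        assert fisher_z(-0.5) == pytest.approx(-fisher_z(0.5), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_z(1.0 + 1e-6)

    def test_clamped_at_one(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))

    @given(st.floats(-0.999, 0.998))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing(self, r):
        assert fisher_z(r + 1e-3) > fisher_z(r)


class TestComputeGfc:
    @pytest.mark.parametrize("z_order", ["z_of_mean_r", "mean_of_z"])
    @pytest.mark.parametrize(
        "shape,n_frames,seed", [((4, 4, 4), 50, 0), ((3, 5, 2), 20, 1), ((6, 6, 6), 60, 2)]
    )
    def test_fast_path_equals_pairwise_oracle(self, z_order, shape, n_frames, seed):
        vs = random_volume(shape, n_frames, seed)
        mask = full_mask(shape)
        got = compute_gfc(vs, mask, z_order=z_order, block_size=37).values
        want = pairwise_gfc_oracle(vs, mask, z_order)
        assert np.max(np.abs(got - want)) < 1e-10

    def test_identical_series_hit_the_clamp(self):
        series = np.sin(np.arange(30))
        data = np.broadcast_to(series, (3, 1, 1, 30)).copy()
        vs = VolumeSeries(data=data, affine=np.eye(4), tr=2.0)
        gfc = compute_gfc(vs, full_mask((3, 1, 1)))
        assert np.allclose(gfc.values, np.arctanh(1 - 1e-7))
        assert np.all(np.isfinite(gfc.values))

    def test_orthogonal_pair_gives_zero(self):
        t = np.arange(32)
        data = np.stack([np.cos(2 * np.pi * t / 32), np.sin(2 * np.pi * t / 32)])
        vs = VolumeSeries(data=data.reshape(2, 1, 1, 32), affine=np.eye(4), tr=2.0)
        gfc = compute_gfc(vs, full_mask((2, 1, 1)))
        assert np.allclose(gfc.values, 0.0, atol=1e-12)

    def test_constant_voxel_is_an_error_listing_position(self):
        vs = random_volume((3, 3, 3), 40, 3)
        vs.data[1, 1, 1, :] = 5.0
        with pytest.raises(ValueError, match="zero temporal variance"):
            compute_gfc(vs, full_mask((3, 3, 3)))

    def test_fewer_than_two_voxels_is_an_error(self):
        vs = random_volume((2, 2, 2), 30, 4)
        prob = np.zeros((2, 2, 2))
        prob[0, 0, 0] = 0.9
        with pytest.raises(ValueError, match="at least 2"):
            compute_gfc(vs, build_gray_mask(prob, 0.2))

    def test_affine_rescaling_of_one_voxel_leaves_map_unchanged(self):
        vs = random_volume((4, 4, 4), 50, 5)
        mask = full_mask((4, 4, 4))
        base = compute_gfc(vs, mask).values
        vs.data[2, 1, 3, :] = 7.5 * vs.data[2, 1, 3, :] - 3.0
        assert np.allclose(compute_gfc(vs, mask).values, base, atol=1e-9)

    def test_sign_flip_of_one_voxel_matches_oracle(self):
        vs = random_volume((3, 3, 3), 40, 6)
        mask = full_mask((3, 3, 3))
        vs.data[0, 0, 0, :] *= -1
        got = compute_gfc(vs, mask).values
        want = pairwise_gfc_oracle(vs, mask, "z_of_mean_r")
        assert np.max(np.abs(got - want)) < 1e-10

    def test_z_order_conventions_agree_for_weak_correlations(self):
        # large T, independent voxels -> all |r| small
        vs = random_volume((3, 3, 3), 800, 7)
        mask = full_mask((3, 3, 3))
        a = compute_gfc(vs, mask, z_order="z_of_mean_r").values
        b = compute_gfc(vs, mask, z_order="mean_of_z").values
        assert np.max(np.abs(a - b)) <= 0.01


class TestDropConstantVoxels:
    def test_identity_when_nothing_is_constant(self):
        vs = random_volume((3, 3, 3), 30, 8)
        mask = full_mask((3, 3, 3))
        assert drop_constant_voxels(vs, mask) is mask

    def test_single_constant_voxel_removed(self):
        vs = random_volume((3, 3, 3), 30, 9)
        vs.data[2, 2, 2, :] = 0.0
        out = drop_constant_voxels(vs, full_mask((3, 3, 3)))
        assert len(out) == 26
        assert [2, 2, 2] not in out.member_voxels.tolist()

    def test_random_constant_set_removed_exactly(self):
        rng = np.random.default_rng(10)
        vs = random_volume((4, 4, 4), 30, 10)
        flat = rng.choice(64, size=9, replace=False)
        coords = np.stack(np.unravel_index(flat, (4, 4, 4))).T
        for c in coords:
            vs.data[tuple(c)] = 1.23
        out = drop_constant_voxels(vs, full_mask((4, 4, 4)))
        removed = {tuple(v) for v in full_mask((4, 4, 4)).member_voxels} - {
            tuple(v) for v in out.member_voxels
        }
        assert removed == {tuple(c) for c in coords}

    def test_all_constant_is_an_error(self):
        vs = VolumeSeries(
            data=np.ones((2, 2, 2, 10)), affine=np.eye(4), tr=2.0
        )
        with pytest.raises(ValueError, match="empty"):
            drop_constant_voxels(vs, full_mask((2, 2, 2)))


class TestPreprocessMinimal:
    def test_detrend_annihilates_affine_trend(self):
        t = np.arange(40, dtype=float)
        data = np.broadcast_to(3.0 + 0.5 * t, (2, 2, 2, 40)).copy()
        vs = VolumeSeries(data=data, affine=np.eye(4), tr=2.0)
        out = preprocess_minimal(vs, detrend=True)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_in_band_sinusoid_passes_through(self):
        t = np.arange(150) * 2.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        data = np.broadcast_to(sig, (2, 2, 2, 150)).copy()
        vs = VolumeSeries(data=data, affine=np.eye(4), tr=2.0)
        out = preprocess_minimal(vs, bandpass=(0.01, 0.08))
        assert np.max(np.abs(out.data - data)) < 1e-8

    def test_out_of_band_sinusoid_is_rejected(self):
        t = np.arange(150) * 2.0
        sig = np.sin(2 * np.pi * 0.2 * t)
        data = np.broadcast_to(sig, (2, 2, 2, 150)).copy()
        vs = VolumeSeries(data=data, affine=np.eye(4), tr=2.0)
        out = preprocess_minimal(vs, bandpass=(0.01, 0.08))
        assert np.max(np.abs(out.data)) < 1e-8 * np.max(np.abs(data))

    def test_bandpass_above_nyquist_is_an_error(self):
        vs = random_volume((2, 2, 2), 50, 11)  # TR 2 s -> Nyquist 0.25 Hz
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_minimal(vs, bandpass=(0.01, 0.3))

    def test_motion_regression_removes_motion_shaped_signal(self):
        rng = np.random.default_rng(12)
        motion = rng.normal(size=(60, 6))
        weights = rng.normal(size=6)
        series = motion @ weights
        data = np.broadcast_to(series, (2, 2, 2, 60)).copy()
        vs = VolumeSeries(data=data, affine=np.eye(4), tr=2.0)
        out = preprocess_minimal(vs, motion=motion, regress_motion=True)
        assert np.max(np.abs(out.data)) < 1e-9

    def test_frame_count_unchanged(self):
        vs = random_volume((2, 2, 2), 51, 13)
        out = preprocess_minimal(vs, detrend=True, bandpass=(0.01, 0.08))
        assert out.n_frames == 51


class TestGlobalConnectivityEstimator:
    def test_transform_stacks_per_subject_maps(self):
        mask = full_mask((3, 3, 3))
        vols = [random_volume((3, 3, 3), 30, s) for s in (1, 2, 3)]
        est = GlobalConnectivity(mask=mask)
        Y = est.fit_transform(vols)
        assert Y.shape == (3, 27)
        assert np.allclose(Y[1], compute_gfc(vols[1], mask).values)

    def test_sklearn_param_protocol(self):
        est = GlobalConnectivity(mask=None, z_order="z_of_mean_r")
        est.set_params(z_order="mean_of_z")
        assert est.get_params()["z_order"] == "mean_of_z"
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
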