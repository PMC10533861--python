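"""Vessel thresholding, isovoxel resampling, curvature keypoints, patches."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import aneucad as ac
from aneucad.extraction import VesselMask, extract_patch
from tests.test_phantom import brute_force_membership


# ---------------------------------------------------------------- vessels
def test_otsu_mask_recovers_exact_geometry(noiseless_phantom):
    _, volume, lesions, geometry = noiseless_phantom
    mask = ac.extract_vessels(volume, "otsu")
    member = volume.intensities == 1000.0  # two-valued by construction
    assert np.array_equal(mask.mask, member)


def test_constant_volume_gives_empty_mask():
    volume = ac.VoxelVolume(np.full((8, 8, 8), 5.0), (1, 1, 1))
    mask = ac.extract_vessels(volume)
    assert not mask.mask.any()
    assert mask.threshold is None


def test_noisy_mask_dice_at_least_090():
    """Noise at 10% of contrast: Otsu mask overlaps true geometry at Dice >= 0.90."""
    config = ac.PhantomConfig(noise_sd=90.0, seed=11)
    volume, lesions, geometry = ac.generate_phantom(config, full_output=True)
    mask = ac.extract_vessels(volume, "otsu")
    truth = brute_force_membership(volume, geometry, lesions)
    inter = (mask.mask & truth).sum()
    dice = 2 * inter / (mask.mask.sum() + truth.sum())
    assert dice >= 0.90


@given(q1=st.floats(50, 99), q2=st.floats(50, 99))
@settings(max_examples=25, deadline=None)
def test_percentile_mask_monotone_in_q(q1, q2):
    rng = np.random.default_rng(0)
    volume = ac.VoxelVolume(rng.normal(size=(12, 12, 12)), (1, 1, 1))
    lo, hi = sorted([q1, q2])
    m_lo = ac.extract_vessels(volume, "percentile", q=lo).mask
    m_hi = ac.extract_vessels(volume, "percentile", q=hi).mask
    assert not (m_hi & ~m_lo).any()  # raising q never adds voxels


# ------------------------------------------------------------- resampling
def test_resample_identity_on_isotropic_volume():
    volume = ac.VoxelVolume(np.random.default_rng(1).normal(size=(10, 10, 10)), (1, 1, 1))
    out = ac.resample_isovoxel(volume, 1.0)
    assert out is volume  # bit-identical, no copy


def test_resample_preserves_constants():
    volume = ac.VoxelVolume(np.full((8, 8, 4), 3.5), (1.0, 1.0, 2.0))
    out = ac.resample_isovoxel(volume, 1.0)
    assert out.shape == (8, 8, 8)
    assert np.allclose(out.intensities, 3.5)


def test_resample_exact_on_affine_intensity():
    """Trilinear interpolation reproduces a linear ramp exactly (interior)."""
    shape, spacing = (8, 8, 8), np.array([1.0, 1.0, 2.0])
    volume = ac.VoxelVolume(np.zeros(shape), spacing)
    world_z = volume.voxel_centers()[..., 2]
    a, b = 0.7, 2.0
    volume.intensities = a * world_z + b
    out = ac.resample_isovoxel(volume, 1.0)
    expected = a * out.voxel_centers()[..., 2] + b
    # interior only: the edge half-voxel extrapolates with 'nearest'
    assert np.allclose(out.intensities[:, :, 2:-2], expected[:, :, 2:-2], atol=1e-6)


def test_resample_preserves_world_extent():
    volume = ac.VoxelVolume(np.zeros((20, 20, 10)), (0.5, 0.5, 1.2))
    out = ac.resample_isovoxel(volume)  # default: min spacing
    assert np.allclose(out.spacing, 0.5)
    in_extent = np.asarray(volume.shape) * volume.spacing
    out_extent = np.asarray(out.shape) * out.spacing
    assert np.all(np.abs(in_extent - out_extent) <= out.spacing)


def test_resample_rejects_bad_spacing():
    volume = ac.VoxelVolume(np.zeros((4, 4, 4)), (1, 1, 1))
    with pytest.raises(ValueError):
        ac.resample_isovoxel(volume, -1.0)


# -------------------------------------------------------------- keypoints
def full_mask(volume):
    return VesselMask(np.ones(volume.shape, dtype=bool), volume.shape)


def brute_force_keypoints(volume, mask, smoothing_scale_mm, cutoff):
    """Independent dense eigen-analysis with explicit per-voxel loops."""
    sigma = smoothing_scale_mm / volume.spacing
    sm = ndimage.gaussian_filter(volume.intensities, sigma)
    span = sm.max() - sm.min()
    if span > 0:
        sm = (sm - sm.min()) / span
    grads = np.gradient(sm, *volume.spacing)
    hess = np.empty(sm.shape + (3, 3))
    for i in range(3):
        second = np.gradient(grads[i], *volume.spacing)
        for j in range(3):
            hess[..., i, j] = second[j]
    hess = 0.5 * (hess + np.swapaxes(hess, -1, -2))
    shape = volume.shape
    hits = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask.mask[x, y, z]:
                    continue
                eigs = np.linalg.eigvalsh(hess[x, y, z])
                if not np.all(eigs < 0):
                    continue
                blob = -eigs[2]
                if blob <= cutoff:
                    continue
                neighborhood = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            nx, ny, nz = x + dx, y + dy, z + dz
                            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                                e = np.linalg.eigvalsh(hess[nx, ny, nz])
                                neighborhood.append(-e[2] if np.all(e < 0) else 0.0)
                            else:
                                neighborhood.append(0.0)
                if blob >= max(neighborhood):
                    hits.append((x, y, z))
    return sorted(hits)


def test_constant_volume_has_no_keypoints():
    volume = ac.VoxelVolume(np.full((16, 16, 16), 2.0), (1, 1, 1))
    kps = ac.detect_keypoints(volume, full_mask(volume))
    assert kps == []


def test_single_gaussian_blob_gives_one_central_keypoint():
    shape = (24, 24, 24)
    volume = ac.VoxelVolume(np.zeros(shape), (1, 1, 1))
    center = np.array([12.5, 12.5, 12.5])  # a voxel center: unique maximum
    d2 = ((volume.voxel_centers() - center) ** 2).sum(axis=-1)
    volume.intensities = np.exp(-d2 / (2 * 3.0**2))
    kps = ac.detect_keypoints(volume, full_mask(volume), smoothing_scale_mm=1.0)
    assert len(kps) == 1
    assert np.linalg.norm(np.array(kps[0].voxel_index) - (center - 0.5)) <= 1.0


def test_keypoints_match_brute_force_oracle():
    """Dense per-voxel eigen-analysis on small grids reproduces the detector."""
    for seed in (0, 1):
        config = ac.PhantomConfig(
            grid_shape=(32, 32, 32), voxel_spacing=(1, 1, 1), noise_sd=30.0,
            n_vessels=2, n_aneurysms=1, aneurysm_radius_range=(3.0, 4.0),
            vessel_radius_range=(1.5, 2.0), seed=seed,
        )
        volume, _ = ac.generate_phantom(config)
        mask = ac.extract_vessels(volume)
        kps = ac.detect_keypoints(volume, mask, 1.0, 1e-4)
        got = sorted(kp.voxel_index for kp in kps)
        expected = brute_force_keypoints(volume, mask, 1.0, 1e-4)
        assert got == expected


def test_keypoints_lie_inside_mask_and_monotone_in_cutoff(noiseless_phantom):
    _, volume, _, _ = noiseless_phantom
    iso = ac.resample_isovoxel(volume)
    mask = ac.extract_vessels(iso)
    kp_low = ac.detect_keypoints(iso, mask, 1.0, 1e-5)
    kp_high = ac.detect_keypoints(iso, mask, 1.0, 1e-2)
    assert all(mask.mask[kp.voxel_index] for kp in kp_low)
    assert len(kp_high) <= len(kp_low)
    low_set = {kp.voxel_index for kp in kp_low}
    assert all(kp.voxel_index in low_set for kp in kp_high)


def test_bulge_attracts_keypoints(noiseless_phantom):
    """At least one keypoint within the bulge radius of the bulge center."""
    _, volume, lesions, _ = noiseless_phantom
    iso = ac.resample_isovoxel(volume)
    mask = ac.extract_vessels(iso)
    kps = ac.detect_keypoints(iso, mask)
    les = lesions[0]
    dists = [np.linalg.norm(kp.position - les.center) for kp in kps]
    assert min(dists) <= les.radius


def test_anisotropic_volume_rejected_by_detector():
    volume = ac.VoxelVolume(np.zeros((8, 8, 8)), (1, 1, 2))
    with pytest.raises(ValueError):
        ac.detect_keypoints(volume, VesselMask(np.ones((8, 8, 8), bool), (8, 8, 8)))


# ---------------------------------------------------------------- patches
def test_patch_has_contract_shape(noiseless_phantom):
    _, volume, _, _ = noiseless_phantom
    iso = ac.resample_isovoxel(volume)
    kp = ac.KeyPoint(iso.voxel_to_world(np.array([10, 10, 10])), (10, 10, 10), 0.1)
    patch = extract_patch(iso, kp)
    assert patch.values.shape == (5, 24, 24)
    assert 0.0 <= patch.values.min() and patch.values.max() <= 1.0


def test_constant_volume_patch_is_all_zeros():
    volume = ac.VoxelVolume(np.full((30, 30, 30), 7.0), (1, 1, 1))
    kp = ac.KeyPoint(np.zeros(3), (15, 15, 15), 0.0)
    patch = extract_patch(volume, kp)
    assert np.all(patch.values == 0.0)


def test_corner_patch_zero_fill_matches_index_arithmetic():
    rng = np.random.default_rng(4)
    volume = ac.VoxelVolume(rng.uniform(1, 2, size=(30, 30, 30)), (1, 1, 1))
    kp = ac.KeyPoint(np.zeros(3), (0, 0, 0), 0.0)
    patch = extract_patch(volume, kp, normalize=False)
    for s in range(5):
        z = s - 2
        for r in range(24):
            x = r - 12
            for c in range(24):
                y = c - 12
                expected = (
                    volume.intensities[x, y, z]
                    if (0 <= x < 30 and 0 <= y < 30 and 0 <= z < 30)
                    else 0.0
                )
                assert patch.values[s, r, c] == expected
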