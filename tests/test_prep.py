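"""Voxel selection, autocorrelation pre-filter, half-map noise floors."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import voxfit as vf
from voxfit.maps import DensityMap, HalfMapPair, VoxelSet
from voxfit.prep import (
    EmptySelectionError,
    correlation_prefilter,
    noise_floor,
    select_voxels,
)
from voxfit.structure import ResidueId, StructureModel


def _point_model(xyz):
    return StructureModel(
        elements=np.array(["C"], dtype=object),
        names=np.array(["CA"], dtype=object),
        coords=np.array([xyz], dtype=float),
        residue_ordinal=np.array([0]),
        residues=[ResidueId("A", 1, "", "ALA")],
        het=np.array([False]),
    )


def _uniform_map(shape=(21, 21, 21), value=1.0, voxel=1.0):
    return DensityMap(np.full(shape, value), [voxel] * 3, [0.0, 0.0, 0.0])


def test_selection_count_matches_sphere_in_grid():
    dmap = _uniform_map()
    model = _point_model([10.0, 10.0, 10.0])
    vox = select_voxels(dmap, model, cutoff=3.5)
    # oracle: direct geometric count of grid centers within the sphere
    idx = np.stack(np.meshgrid(*[np.arange(21)] * 3, indexing="ij"), axis=-1)
    dist = np.linalg.norm(idx - np.array([10, 10, 10]), axis=-1)
    assert len(vox) == int(np.count_nonzero(dist <= 3.5))


def test_selection_sorted_descending():
    rng = np.random.default_rng(0)
    dmap = DensityMap(np.abs(rng.standard_normal((15, 15, 15))), [1] * 3, [0] * 3)
    vox = select_voxels(dmap, _point_model([7.0, 7.0, 7.0]))
    assert np.all(np.diff(vox.densities) <= 0)


def test_model_outside_map_raises():
    with pytest.raises(EmptySelectionError):
        select_voxels(_uniform_map(), _point_model([100.0, 100.0, 100.0]))


def test_all_negative_map_raises():
    dmap = _uniform_map(value=-1.0)
    with pytest.raises(EmptySelectionError):
        select_voxels(dmap, _point_model([10.0, 10.0, 10.0]))


def _white_noise_fixture(seed=0, n=24):
    rng = np.random.default_rng(seed)
    dens = rng.standard_normal((n, n, n)) + 5.0  # positive i.i.d. densities
    dmap = DensityMap(dens, [1.0] * 3, [0.0] * 3)
    model = _point_model([n / 2.0] * 3)
    return dmap, model


def test_prefilter_threshold_one_is_noop():
    dmap, model = _white_noise_fixture()
    vox = select_voxels(dmap, model)
    out = correlation_prefilter(dmap, vox, threshold=1.0)
    assert len(out) == len(vox)
    np.testing.assert_array_equal(out.densities, vox.densities)


def test_prefilter_white_noise_removes_little():
    """i.i.d. voxels have ≈0 lag correlation: < 5% removed at threshold 0.8."""
    dmap, model = _white_noise_fixture(seed=1)
    vox = select_voxels(dmap, model)
    out = correlation_prefilter(dmap, vox, threshold=0.8)
    assert 1.0 - len(out) / len(vox) < 0.05


def test_prefilter_smoothing_removes_more():
    """Induced spatial correlation strictly increases removal."""
    dmap, model = _white_noise_fixture(seed=1)
    vox = select_voxels(dmap, model)
    kept_raw = len(correlation_prefilter(dmap, vox, threshold=0.8))
    smooth = DensityMap(
        gaussian_filter(dmap.densities, sigma=2.0), dmap.voxel_size, dmap.origin
    )
    vox_s = select_voxels(smooth, model)
    kept_smooth = len(correlation_prefilter(smooth, vox_s, threshold=0.8))
    removed_raw = len(vox) - kept_raw
    removed_smooth = len(vox_s) - kept_smooth
    assert removed_smooth > removed_raw


def test_prefilter_monotone_in_threshold_and_keeps_max():
    dmap, model = _white_noise_fixture(seed=2)
    smooth = DensityMap(
        gaussian_filter(dmap.densities, sigma=1.5), dmap.voxel_size, dmap.origin
    )
    vox = select_voxels(smooth, model)
    kept = [
        len(correlation_prefilter(smooth, vox, threshold=thr))
        for thr in (0.5, 0.7, 0.9, 1.0)
    ]
    assert kept == sorted(kept)  # removal monotone non-increasing in threshold
    out = correlation_prefilter(smooth, vox, threshold=0.5)
    assert out.densities[0] == vox.densities[0]  # the densest voxel survives
    # output is a subset, in descending order
    assert np.all(np.diff(out.densities) <= 0)
    assert set(map(tuple, out.centers)) <= set(map(tuple, vox.centers))


def test_prefilter_determinism():
    dmap, model = _white_noise_fixture(seed=3)
    vox = select_voxels(dmap, model)
    a = correlation_prefilter(dmap, vox, threshold=0.8)
    b = correlation_prefilter(dmap, vox, threshold=0.8)
    np.testing.assert_array_equal(a.centers, b.centers)


def test_prefilter_minibox_too_small():
    dmap = _uniform_map(voxel=3.0)
    vox = VoxelSet(np.array([[9.0, 9.0, 9.0]]), np.array([1.0]))
    with pytest.raises(ValueError, match="minibox"):
        correlation_prefilter(dmap, vox, threshold=0.8, minibox_side=4.0)


# --- noise floors ----------------------------------------------------------

def test_identical_half_maps_give_epsilon_floor():
    dmap = _uniform_map()
    halves = HalfMapPair(dmap, _uniform_map())
    vox = VoxelSet(np.array([[10.0, 10.0, 10.0]]), np.array([1.0]))
    out = noise_floor(halves, vox)
    assert out.noise_floors[0] == pytest.approx(1e-6 * 1.0)


def test_half_map_difference_definition():
    a = _uniform_map()
    b_d = np.full((21, 21, 21), 1.0)
    b_d[10, 10, 10] += 2 * 0.3  # +2δ at one voxel → σ_min = δ there
    b = DensityMap(b_d, [1.0] * 3, [0.0] * 3)
    vox = VoxelSet(np.array([[10.0, 10.0, 10.0], [5.0, 5.0, 5.0]]), np.ones(2))
    out = noise_floor(HalfMapPair(a, b), vox)
    assert out.noise_floors[0] == pytest.approx(0.3)


def test_half_map_noise_median_monte_carlo():
    """Half maps = truth ± N(0, 2s²): the median floor matches the median of
    |N(0, 4s²)|/2 ≈ 0.954 s (Monte-Carlo oracle)."""
    rng = np.random.default_rng(4)
    s = 0.1
    n = 47  # 47³ ≈ 1e5 voxels
    truth = np.full((n, n, n), 1.0)
    a = DensityMap(truth + np.sqrt(2) * s * rng.standard_normal(truth.shape),
                   [1.0] * 3, [0.0] * 3)
    b = DensityMap(truth + np.sqrt(2) * s * rng.standard_normal(truth.shape),
                   [1.0] * 3, [0.0] * 3)
    idx = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1)
    vox = VoxelSet(idx.reshape(-1, 3).astype(float), np.ones(n**3))
    out = noise_floor(HalfMapPair(a, b), vox)
    # a−b ~ N(0, 4s²), so |a−b|/2 ~ |N(0, s²)| with median s·Φ⁻¹(0.75) ≈ 0.6745·s
    expected = s * 0.674490
    assert np.median(out.noise_floors) == pytest.approx(expected, rel=0.15)


def test_voxel_outside_halfmap_raises():
    dmap = _uniform_map()
    vox = VoxelSet(np.array([[50.0, 0.0, 0.0]]), np.array([1.0]))
    with pytest.raises(ValueError, match="outside"):
        noise_floor(HalfMapPair(dmap, _uniform_map()), vox)
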