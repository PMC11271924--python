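"""Marginalized likelihood kernel, B-factor prior, hybrid energy, scale scan."""

import numpy as np
import pytest
from scipy.integrate import quad

import voxfit as vf
from voxfit.energy import (
    RefineConfig,
    bfactor_prior_energy,
    contact_pairs,
    hybrid_energy,
    log_marginal_kernel,
    marginal_kernel_derivative,
    marginal_voxel_energy,
    optimize_scale,
)
from voxfit.forward import MapPredictor
from voxfit.maps import VoxelSet
from voxfit.refine import ZeroPrior
from voxfit.synth import elastic_network_prior


def _quadrature_marginal(x, sigma_min):
    """Independent oracle: ∫_{σmin}^∞ N(x; 0, σ²) σ⁻¹ dσ."""
    val, _ = quad(
        lambda s: np.exp(-x**2 / (2 * s**2)) / (s * np.sqrt(2 * np.pi)) / s,
        sigma_min, np.inf, limit=400,
    )
    return val


def test_marginal_likelihood_matches_quadrature():
    """exp(−E) equals the numerical marginalization for 50 random tuples."""
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(50):
        d = rng.uniform(0.0, 3.0)
        f = rng.uniform(0.0, 3.0)
        alpha = rng.uniform(0.5, 1.5)
        sigma = rng.uniform(0.005, 0.5)
        e = marginal_voxel_energy(d, f, alpha, sigma)
        oracle = _quadrature_marginal(d - alpha * f, sigma)
        worst = max(worst, abs(np.exp(-e) - oracle) / oracle)
    assert worst < 1e-8


def test_kernel_limit_at_zero_mismatch():
    sigma = 0.3
    e = marginal_voxel_energy(1.0, 1.0, 1.0, sigma)
    assert e == pytest.approx(-np.log(1.0 / (sigma * np.sqrt(2 * np.pi))), rel=1e-12)


def test_kernel_even_and_series_continuity():
    sigma = 0.2
    for delta in (1e-9, 1e-6, 1e-3, 0.1, 3.0):
        ep = marginal_voxel_energy(1.0 + delta, 1.0, 1.0, sigma)
        em = marginal_voxel_energy(1.0 - delta, 1.0, 1.0, sigma)
        assert ep == pytest.approx(em, rel=1e-12)
    # continuity across the series/direct switch at |x| = 1e−4 σ
    xs = np.array([0.9e-4, 1.1e-4]) * sigma
    es = -log_marginal_kernel(xs, sigma)
    assert abs(es[1] - es[0]) < 1e-9


def test_kernel_monotone_in_mismatch():
    sigma = 0.1
    x = np.linspace(0.0, 5.0, 200)
    e = -log_marginal_kernel(x, sigma)
    assert np.all(np.diff(e) >= 0)


def test_kernel_derivative_matches_finite_difference():
    sigma = 0.25
    for x in (1e-6, 1e-3, 0.05, 0.4, 2.0):
        h = 1e-7
        fd = (-log_marginal_kernel(np.array([x + h]), sigma)
              + log_marginal_kernel(np.array([x - h]), sigma))[0] / (2 * h)
        an = marginal_kernel_derivative(np.array([x]), sigma)[0]
        assert an == pytest.approx(fd, rel=1e-5, abs=1e-8)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x=st.floats(min_value=-50.0, max_value=50.0,
                    allow_nan=False, allow_infinity=False),
        sigma=st.floats(min_value=1e-4, max_value=100.0),
    )
    def test_kernel_even_positive_bounded(x, sigma):
        """Property: the marginal kernel is even, and its likelihood never
        exceeds the x=0 limit 1/(σ√2π)."""
        lk = log_marginal_kernel(np.array([x]), sigma)[0]
        lk_neg = log_marginal_kernel(np.array([-x]), sigma)[0]
        assert lk == pytest.approx(lk_neg, rel=1e-12, abs=1e-12)
        assert lk <= -np.log(sigma * np.sqrt(2 * np.pi)) + 1e-12
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_sigma_must_be_positive():
    with pytest.raises(ValueError):
        marginal_voxel_energy(1.0, 0.0, 1.0, 0.0)


# --- B-factor prior --------------------------------------------------------

def test_bfactor_prior_matches_quadrature():
    rng = np.random.default_rng(8)
    pairs = np.array([[0, 1]])
    for _ in range(10):
        b = rng.uniform(0.0, 80.0, size=2)
        sbf = rng.uniform(2.0, 20.0)
        e, per = bfactor_prior_energy(b, pairs, sbf)
        oracle = _quadrature_marginal(b[0] - b[1], sbf)
        assert np.exp(-e) == pytest.approx(oracle, rel=1e-8)


def test_bfactor_prior_equal_bfactors_limit():
    e, per = bfactor_prior_energy(np.array([30.0, 30.0]), np.array([[0, 1]]), 10.0)
    assert e == pytest.approx(-np.log(1.0 / (10.0 * np.sqrt(2 * np.pi))))


def test_bfactor_prior_log_growth():
    """Doubling |Δb| from 2σ to 4σ costs ≈ log 2 (heavy tail tolerates outliers)."""
    sbf = 10.0
    e2, _ = bfactor_prior_energy(np.array([0.0, 2 * sbf]), np.array([[0, 1]]), sbf)
    e4, _ = bfactor_prior_energy(np.array([0.0, 4 * sbf]), np.array([[0, 1]]), sbf)
    assert 0.0 < e4 - e2 < 2 * np.log(2.0)


def test_bfactor_prior_shift_invariant_and_empty():
    pairs = np.array([[0, 1], [1, 2]])
    b = np.array([10.0, 40.0, 25.0])
    e1, _ = bfactor_prior_energy(b, pairs, 10.0)
    e2, _ = bfactor_prior_energy(b + 500.0, pairs, 10.0)
    assert e1 == pytest.approx(e2, rel=1e-12)
    e0, per0 = bfactor_prior_energy(b, np.zeros((0, 2), dtype=int), 10.0)
    assert e0 == 0.0 and len(per0) == 0


def test_contact_pairs_symmetric_dedup(helix20):
    pairs = contact_pairs(helix20, 5.0)
    assert np.all(pairs[:, 0] < pairs[:, 1])
    assert len(np.unique(pairs, axis=0)) == len(pairs)
    # helix neighbors in sequence are always in contact
    seq_neighbors = {(i, i + 1) for i in range(19)}
    assert seq_neighbors <= set(map(tuple, pairs))


# --- hybrid energy ---------------------------------------------------------

def test_hybrid_breakdown_sums_exactly(table, helix3, helix3_noisy_voxels):
    vox = helix3_noisy_voxels["voxels"]
    bf = helix3_noisy_voxels["bfactors"]
    pred = MapPredictor(vox, helix3, table)
    cfg = RefineConfig(seed=0)
    brk = hybrid_energy(pred, bf, ZeroPrior(), cfg)
    assert brk.total == brk.e_prior + brk.e_cryoem + brk.e_bf
    assert brk.e_cryoem == pytest.approx(brk.per_voxel.sum())
    assert brk.e_bf == pytest.approx(brk.per_pair.sum())


def test_hybrid_forces_match_finite_differences(table, helix3, helix3_noisy_voxels):
    vox = helix3_noisy_voxels["voxels"]
    bf = helix3_noisy_voxels["bfactors"]
    pred = MapPredictor(vox, helix3, table)
    cfg = RefineConfig(seed=0)
    prior = elastic_network_prior(helix3, k=5.0, cutoff=6.0)
    brk = hybrid_energy(pred, bf, prior, cfg)
    h = 1e-4
    rng = np.random.default_rng(3)
    for _ in range(8):
        i = rng.integers(helix3.n_atoms)
        ax = rng.integers(3)
        c = helix3.coords.copy()
        c[i, ax] += h
        pred.move(c)
        ep = hybrid_energy(pred, bf, prior, cfg, with_forces=False).total
        c[i, ax] -= 2 * h
        pred.move(c)
        em = hybrid_energy(pred, bf, prior, cfg, with_forces=False).total
        assert -(ep - em) / (2 * h) == pytest.approx(brk.forces[i, ax], abs=1e-4)


def test_perfect_fit_is_stationary(table, helix3):
    """With f ≡ d/α the cryo-EM term sits at N_V times the kernel limit and
    exerts no forces."""
    bf = np.full(3, 25.0)
    full, _, _ = vf.simulate_map([helix3], [1.0], bf, noise_sd=0.0,
                                 alpha_true=0.8, seed=2)
    vox0 = vf.select_voxels(full, helix3)
    sigma = 0.05
    vox = VoxelSet(vox0.centers, vox0.densities, np.full(len(vox0), sigma))
    pred = MapPredictor(vox, helix3, table)
    cfg = RefineConfig(scale=0.8, seed=0)
    brk = hybrid_energy(pred, bf, ZeroPrior(), cfg)
    limit = -np.log(1.0 / (sigma * np.sqrt(2 * np.pi)))
    assert brk.e_cryoem == pytest.approx(len(vox) * limit, rel=1e-9)
    np.testing.assert_allclose(brk.forces, 0.0, atol=1e-7)


def test_rigid_translation_invariance(table, helix3, helix3_noisy_voxels):
    vox = helix3_noisy_voxels["voxels"]
    bf = helix3_noisy_voxels["bfactors"]
    cfg = RefineConfig(seed=0)
    pred = MapPredictor(vox, helix3, table)
    e0 = hybrid_energy(pred, bf, ZeroPrior(), cfg, with_forces=False).e_cryoem
    shift = np.array([2.0, -1.0, 0.5])
    vox2 = VoxelSet(vox.centers + shift, vox.densities, vox.noise_floors)
    pred2 = MapPredictor(vox2, helix3.with_coords(helix3.coords + shift), table)
    e1 = hybrid_energy(pred2, bf, ZeroPrior(), cfg, with_forces=False).e_cryoem
    assert e0 == pytest.approx(e1, rel=1e-12)


# --- scale factor ----------------------------------------------------------

def test_optimize_scale_singleton_grid(table, helix3, helix3_noisy_voxels):
    cfg = RefineConfig(seed=1)
    alpha = optimize_scale(
        [(helix3, helix3_noisy_voxels["bfactors"])],
        helix3_noisy_voxels["voxels"], table, cfg, scan=(1.0, 1.0, 0.0),
    )
    assert alpha == 1.0


def test_optimize_scale_recovers_generating_alpha(table):
    m = vf.make_toy_structure("helix", 10, seed=1)
    bf = np.full(10, 30.0)
    truth, _, _ = vf.simulate_map([m], [1.0], bf, noise_sd=0.0, alpha_true=1.0, seed=2)
    peak = truth.densities.max()
    full, halves, _ = vf.simulate_map([m], [1.0], bf, noise_sd=0.01 * peak,
                                      alpha_true=0.8, seed=2)
    vox = vf.noise_floor(halves, vf.select_voxels(full, m))
    alpha = optimize_scale([(m, bf)], vox, table, RefineConfig(seed=3), n_sweeps=3)
    assert alpha == pytest.approx(0.80)


def test_optimize_scale_covariant_under_map_rescaling(table):
    """Doubling densities and noise floors doubles the recovered α."""
    m = vf.make_toy_structure("helix", 8, seed=1)
    bf = np.full(8, 30.0)
    truth, _, _ = vf.simulate_map([m], [1.0], bf, noise_sd=0.0, alpha_true=1.0, seed=2)
    peak = truth.densities.max()
    full, halves, _ = vf.simulate_map([m], [1.0], bf, noise_sd=0.01 * peak,
                                      alpha_true=0.5, seed=2)
    vox = vf.noise_floor(halves, vf.select_voxels(full, m))
    cfg = RefineConfig(seed=3)
    a1 = optimize_scale([(m, bf)], vox, table, cfg, scan=(0.3, 1.3, 0.05), n_sweeps=3)
    vox2 = VoxelSet(vox.centers, 2.0 * vox.densities, 2.0 * vox.noise_floors)
    a2 = optimize_scale([(m, bf)], vox2, table, cfg, scan=(0.3, 1.3, 0.05), n_sweeps=3)
    assert a2 == pytest.approx(2.0 * a1, abs=0.051)


def test_optimize_scale_empty_grid_raises(table, helix3, helix3_noisy_voxels):
    with pytest.raises(ValueError):
        optimize_scale([(helix3, helix3_noisy_voxels["bfactors"])],
                       helix3_noisy_voxels["voxels"], table,
                       RefineConfig(seed=0), scan=(1.0, 0.5, 0.05))


def test_config_validation():
    with pytest.raises(ValueError):
        RefineConfig(scale=0.0)
    with pytest.raises(ValueError):
        RefineConfig(bf_mc_stride=0)
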