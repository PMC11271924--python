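"""Metainference energetics, replica symmetry, ensemble statistics."""

import numpy as np
import pytest

import voxfit as vf
from voxfit.energy import RefineConfig, hybrid_energy
from voxfit.ensemble import (
    EnsembleTrajectory,
    _replica_predictors,
    ensemble_statistics,
    metainference_energy,
    run_metainference,
)
from voxfit.forward import MapPredictor
from voxfit.refine import ZeroPrior
from voxfit.synth import elastic_network_prior


@pytest.fixture(scope="module")
def two_replica_setup(table):
    m = vf.make_toy_structure("helix", 3, seed=1)
    bf = np.full(3, 25.0)
    truth, _, _ = vf.simulate_map([m], [1.0], bf, noise_sd=0.0, seed=2)
    peak = truth.densities.max()
    full, halves, _ = vf.simulate_map([m], [1.0], bf, noise_sd=0.1 * peak, seed=2)
    vox = vf.noise_floor(halves, vf.select_voxels(full, m))
    rng = np.random.default_rng(4)
    m2 = m.with_coords(m.coords + 0.3 * rng.standard_normal(m.coords.shape))
    return m, m2, vox


def test_identical_replicas_reduce_to_single_structure(table, two_replica_setup):
    """With all replicas identical, f̄ = f and the data term is N_R × the
    single-structure marginalized energy."""
    m, _, vox = two_replica_setup
    cfg = RefineConfig(seed=0)
    n_rep = 4
    preds = _replica_predictors([m] * n_rep, vox, table, "atomistic", 10.0)
    e_meta, _ = metainference_energy(preds, 25.0, cfg)
    single = MapPredictor(vox, m, table)
    brk = hybrid_energy(single, np.full(3, 25.0), ZeroPrior(), cfg,
                        pairs=np.zeros((0, 2), dtype=int), with_forces=False)
    assert e_meta == pytest.approx(n_rep * brk.e_cryoem, rel=1e-12)


def test_replica_permutation_invariance(table, two_replica_setup):
    m, m2, vox = two_replica_setup
    cfg = RefineConfig(seed=0)
    e1, f1 = metainference_energy(
        _replica_predictors([m, m2], vox, table, "atomistic", 10.0), 25.0, cfg)
    e2, f2 = metainference_energy(
        _replica_predictors([m2, m], vox, table, "atomistic", 10.0), 25.0, cfg)
    assert e1 == pytest.approx(e2, rel=1e-12)
    np.testing.assert_allclose(f1[0], f2[1])
    np.testing.assert_allclose(f1[1], f2[0])


def test_metainference_forces_match_finite_differences(table, two_replica_setup):
    m, m2, vox = two_replica_setup
    cfg = RefineConfig(seed=0)
    prior = elastic_network_prior(m, k=5.0, cutoff=6.0)
    models = [m, m2]
    preds = _replica_predictors(models, vox, table, "atomistic", 10.0)
    e0, forces = metainference_energy(preds, 25.0, cfg, priors=[prior, prior])
    h = 1e-4
    rng = np.random.default_rng(1)
    for _ in range(6):
        r = rng.integers(2)
        i = rng.integers(m.n_atoms)
        ax = rng.integers(3)

        def energy_at(delta):
            shifted = []
            for rr, mm in enumerate(models):
                c = mm.coords.copy()
                if rr == r:
                    c[i, ax] += delta
                shifted.append(mm.with_coords(c))
            p = _replica_predictors(shifted, vox, table, "atomistic", 10.0)
            e, _ = metainference_energy(p, 25.0, cfg, priors=[prior, prior])
            return e

        fd = -(energy_at(h) - energy_at(-h)) / (2 * h)
        assert fd == pytest.approx(forces[r][i, ax], abs=1e-4)


def test_energy_multiplier_switch(table, two_replica_setup):
    m, m2, vox = two_replica_setup
    cfg = RefineConfig(seed=0)
    preds = _replica_predictors([m, m2], vox, table, "atomistic", 10.0)
    e_n, _ = metainference_energy(preds, 25.0, cfg)
    e_1, _ = metainference_energy(preds, 25.0, cfg, energy_multiplier=1.0)
    assert e_n == pytest.approx(2.0 * e_1, rel=1e-12)


def test_zero_data_weight_decouples_replicas(table, two_replica_setup):
    """With the data term switched off the replica forces are exactly the
    independent prior forces."""
    m, m2, vox = two_replica_setup
    cfg = RefineConfig(seed=0)
    prior = elastic_network_prior(m, k=5.0, cutoff=6.0)
    preds = _replica_predictors([m, m2], vox, table, "atomistic", 10.0)
    _, forces = metainference_energy(preds, 25.0, cfg, priors=[prior, prior],
                                     energy_multiplier=0.0)
    np.testing.assert_allclose(forces[0], prior.forces(m.coords), atol=1e-12)
    np.testing.assert_allclose(forces[1], prior.forces(m2.coords), atol=1e-12)


def test_mismatched_topologies_raise(table, two_replica_setup):
    m, _, vox = two_replica_setup
    other = vf.make_toy_structure("helix", 4, seed=1)
    with pytest.raises(ValueError, match="topology"):
        _replica_predictors([m, other], vox, table, "atomistic", 10.0)


def test_run_metainference_deterministic(table, two_replica_setup):
    m, m2, vox = two_replica_setup
    cfg = RefineConfig(seed=5, neighbor_stride=10)
    prior = elastic_network_prior(m, k=5.0, cutoff=6.0)
    e1 = run_metainference([m, m2], vox, prior, table, cfg, n_steps=30,
                           b_const=25.0, record_stride=10)
    e2 = run_metainference([m, m2], vox, prior, table, cfg, n_steps=30,
                           b_const=25.0, record_stride=10)
    np.testing.assert_array_equal(e1.coords, e2.coords)


def test_single_frame_statistics_degenerate(table, two_replica_setup):
    m, m2, vox = two_replica_setup
    coords = np.stack([np.stack([m.coords, m.coords])])  # 1 frame, 2 replicas
    ens = EnsembleTrajectory(model=m, coords=coords[:, :1], b_const=25.0,
                             record_stride=1)
    stats = ensemble_statistics(ens, vox, table,
                                state_defs={"all": lambda fr: True,
                                            "none": lambda fr: False})
    np.testing.assert_allclose(stats["msf"], 0.0)
    assert stats["populations"]["all"]["fraction"] == 1.0
    assert stats["populations"]["none"]["fraction"] == 0.0
    # average map of identical frames equals the single-frame prediction
    single = MapPredictor(vox, m, table).predict(np.full(3, 25.0))
    np.testing.assert_allclose(stats["average_map"], single, rtol=1e-12)


def test_single_frame_ensemble_cc_equals_single_structure(table):
    """Regression link: ensemble CC_mask of a one-frame ensemble equals the
    single-structure CC_mask."""
    from voxfit.metrics import build_mask, cc_mask, cc_mask_model, mask_voxelset
    from voxfit.forward import predict_map

    m = vf.make_toy_structure("helix", 6, seed=3)
    bf = np.full(6, 30.0)
    truth, _, _ = vf.simulate_map([m], [1.0], bf, noise_sd=0.0, seed=4)
    peak = truth.densities.max()
    full, _, _ = vf.simulate_map([m], [1.0], bf, noise_sd=0.03 * peak, seed=4)
    mask = build_mask(m, full)
    vox = mask_voxelset(full, mask)
    ens = EnsembleTrajectory(model=m, coords=m.coords[None, None], b_const=30.0,
                             record_stride=1)
    stats = ensemble_statistics(ens, vox, table)
    cc_ens = cc_mask(full, stats["average_map"], mask)
    pred = predict_map(m, bf, vox, table).values
    cc_single = cc_mask(full, pred, mask)
    assert cc_ens == pytest.approx(cc_single, rel=1e-12)
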