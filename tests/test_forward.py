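"""Forward model: mass conservation, cutoff adequacy, gradients, CG parity."""

import numpy as np
import pytest
from scipy.integrate import quad

import voxfit as vf
from voxfit.cgfit import map_to_beads
from voxfit.forward import MapPredictor, atom_density, map_gradient, predict_map
from voxfit.maps import VoxelSet
from voxfit.scattering import load_bead_table


@pytest.mark.parametrize("b", [0.0, 10.0, 40.0])
def test_density_integrates_to_total_weight(table, b):
    """∫ρ d³r = Σ_k A_k for every B-factor: blurring conserves mass."""
    for el in table.types:
        integral, _ = quad(
            lambda r: 4.0 * np.pi * r**2 * atom_density(table, el, b, r),
            0.0, 60.0, limit=300,
        )
        assert integral == pytest.approx(table.total_weight(el), rel=1e-3)


def test_density_monotone_in_r_and_b(table):
    r = np.linspace(0.0, 6.0, 200)
    prof = atom_density(table, "C", 0.0, r)
    assert np.all(np.diff(prof) < 0)
    assert atom_density(table, "C", 40.0, 0.0) < atom_density(table, "C", 0.0, 0.0)
    # far tail rises with b (mass pushed outward)
    assert atom_density(table, "C", 40.0, 4.0) > atom_density(table, "C", 0.0, 4.0)
    assert atom_density(table, "C", 0.0, 1e3) == pytest.approx(0.0, abs=1e-30)


def test_unknown_type_raises(table):
    with pytest.raises(KeyError):
        atom_density(table, "Xx", 0.0, 1.0)


def test_single_carbon_at_voxel_center(table, helix3):
    """A one-atom model contributes exactly atom_density(C, b, 0) at its own
    position."""
    from voxfit.structure import ResidueId, StructureModel

    model = StructureModel(
        elements=np.array(["C"], dtype=object),
        names=np.array(["CA"], dtype=object),
        coords=np.array([[1.0, 2.0, 3.0]]),
        residue_ordinal=np.array([0]),
        residues=[ResidueId("A", 1, "", "ALA")],
        het=np.array([False]),
    )
    vox = VoxelSet(np.array([[1.0, 2.0, 3.0]]), np.array([0.0]))
    pred = predict_map(model, np.array([12.0]), vox, table)
    assert pred.values[0] == pytest.approx(atom_density(table, "C", 12.0, 0.0))


def test_neighbor_list_matches_brute_force(table, helix20):
    """10 Å cutoff prediction equals the all-pairs sum to < 1e−6 relative on
    voxels near the model."""
    bf = np.linspace(10.0, 60.0, 20)
    full, _, _ = vf.simulate_map([helix20], [1.0], bf, seed=3)
    vox = vf.select_voxels(full, helix20, cutoff=3.5)
    fast = predict_map(helix20, bf, vox, table).values
    # brute force: no neighbor list
    from voxfit.forward import contributing_atoms

    idx, keys = contributing_atoms(helix20, "atomistic", table)
    brute = np.zeros(len(vox))
    for i, key in zip(idx, keys):
        r = np.linalg.norm(vox.centers - helix20.coords[i], axis=1)
        brute += atom_density(table, key, bf[helix20.residue_ordinal[i]], r)
    assert np.max(np.abs(fast - brute) / np.maximum(brute, 1e-300)) < 1e-6


def test_empty_model_predicts_zero(table):
    from voxfit.structure import ResidueId, StructureModel

    model = StructureModel(
        elements=np.array(["H"], dtype=object),  # hydrogens are excluded
        names=np.array(["H"], dtype=object),
        coords=np.array([[0.0, 0.0, 0.0]]),
        residue_ordinal=np.array([0]),
        residues=[ResidueId("A", 1, "", "ALA")],
        het=np.array([False]),
    )
    vox = VoxelSet(np.zeros((4, 3)), np.zeros(4))
    pred = predict_map(model, np.array([0.0]), vox, table)
    assert np.all(pred.values == 0.0)


def test_carboxylate_oxygens_excluded(table):
    from voxfit.structure import ResidueId, StructureModel

    model = StructureModel(
        elements=np.array(["O", "O"], dtype=object),
        names=np.array(["OE1", "O"], dtype=object),
        coords=np.zeros((2, 3)),
        residue_ordinal=np.array([0, 0]),
        residues=[ResidueId("A", 1, "", "GLU")],
        het=np.array([False, False]),
    )
    vox = VoxelSet(np.zeros((1, 3)), np.zeros(1))
    pred = predict_map(model, np.array([0.0]), vox, table)
    # only the backbone O contributes
    assert pred.values[0] == pytest.approx(atom_density(table, "O", 0.0, 0.0))


def test_map_gradient_matches_finite_differences(table, helix3):
    bf = np.full(3, 25.0)
    full, _, _ = vf.simulate_map([helix3], [1.0], bf, seed=2)
    vox = vf.select_voxels(full, helix3)
    pred = MapPredictor(vox, helix3, table)
    atom_i, vox_i, grads = pred.pair_gradients(bf)
    # aggregate: d(sum_i f_i)/dX_j, compare with finite differences
    total_grad = np.zeros((helix3.n_atoms, 3))
    np.add.at(total_grad, atom_i, grads)
    h = 1e-4
    for j in (0, 7, 14):
        for ax in range(3):
            c = helix3.coords.copy()
            c[j, ax] += h
            fp = predict_map(helix3.with_coords(c), bf, vox, table).values.sum()
            c[j, ax] -= 2 * h
            fm = predict_map(helix3.with_coords(c), bf, vox, table).values.sum()
            assert (fp - fm) / (2 * h) == pytest.approx(
                total_grad[j, ax], abs=1e-5
            )


def test_gradient_zero_at_voxel_center(table):
    from voxfit.structure import ResidueId, StructureModel

    model = StructureModel(
        elements=np.array(["C"], dtype=object),
        names=np.array(["CA"], dtype=object),
        coords=np.array([[0.5, 0.5, 0.5]]),
        residue_ordinal=np.array([0]),
        residues=[ResidueId("A", 1, "", "ALA")],
        het=np.array([False]),
    )
    vox = VoxelSet(np.array([[0.5, 0.5, 0.5]]), np.zeros(1))
    _, _, grads = map_gradient(model, np.array([0.0]), vox, table)
    np.testing.assert_allclose(grads, 0.0)


def test_translation_invariance(table, helix3):
    bf = np.full(3, 25.0)
    full, _, _ = vf.simulate_map([helix3], [1.0], bf, seed=2)
    vox = vf.select_voxels(full, helix3)
    f0 = predict_map(helix3, bf, vox, table).values
    shift = np.array([3.3, -1.2, 0.7])
    vox2 = VoxelSet(vox.centers + shift, vox.densities)
    f1 = predict_map(helix3.with_coords(helix3.coords + shift), bf, vox2, table).values
    np.testing.assert_allclose(f0, f1, rtol=1e-12)


def test_cg_mode_matches_atomistic_within_fit_residual(table, helix20):
    """The single-Gaussian bead map reproduces the atomistic map of the
    grouped atoms with per-voxel MSE no worse than the combined per-bead
    grid-fit residuals (each map voxel sees at most ~2 beads' error fields,
    so residuals can add coherently up to a factor 2)."""
    from voxfit.cgfit import fit_bead_parameters, occurrences_from_model

    bead_table = load_bead_table()
    beads = map_to_beads(helix20)
    blur = 40.0  # representative refined B-factor; CG maps are always blurred
    bf = np.full(20, blur)
    full, _, _ = vf.simulate_map([helix20], [1.0], bf, seed=5)
    vox = vf.select_voxels(full, helix20)
    f_at = predict_map(helix20, bf, vox, table).values
    f_cg = predict_map(beads, bf, vox, bead_table, mode="cg").values
    mse = float(np.mean((f_at - f_cg) ** 2))
    occ = occurrences_from_model(helix20)
    residual_sum = sum(
        fit_bead_parameters(v, table, bfactor=blur)[2] for v in occ.values()
    )
    assert mse <= 2.0 * residual_sum + 1e-9
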