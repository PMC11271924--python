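"""Gaussian forward model: predicted cryo-EM density at voxel centers.

Each contributing atom (or coarse-grained bead) of type *t* with per-residue
B-factor *b* (Å²) adds, at distance *r* (Å) from a voxel center,

    ρ_t(r; b) = Σ_k A_k (4π / C_k)^{3/2} exp(−4π² r² / C_k),   C_k = B_k + b/4,

the real-space Fourier pair of the Gaussian scattering-factor fit
f(s) = Σ_k A_k exp(−B_k s²). The prefactor makes the density of one atom
integrate to Σ_k A_k for every b, so B-factor blurring conserves mass.

Atomistic predictions sum over non-hydrogen atoms, excluding the carboxylate
oxygens of Glu/Asp (beam-damaged groups); coarse-grained predictions sum over
beads keyed by bead type. Sums are restricted to a neighbor list with a 10 Å
atom–voxel cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .maps import VoxelSet
from .scattering import ScatteringTable
from .structure import StructureModel

__all__ = [
    "PredictedMap",
    "MapPredictor",
    "atom_density",
    "predict_map",
    "map_gradient",
    "contributing_atoms",
    "NEIGHBOR_CUTOFF",
]

NEIGHBOR_CUTOFF = 10.0  # Å, atom-to-voxel-center neighbor-list cutoff

_FOUR_PI = 4.0 * np.pi
_FOUR_PI2 = 4.0 * np.pi**2

# carboxylate oxygens excluded from the atomistic forward model; protonated
# variants are treated identically (the exclusion reflects beam damage to the
# chemical group, not its protonation state)
_EXCLUDED_SIDE_CHAIN_O = {
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("GLH", "OE1"), ("GLH", "OE2"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("ASH", "OD1"), ("ASH", "OD2"),
}


@dataclass
class PredictedMap:
    """Forward-model densities f_i on a :class:`~voxfit.maps.VoxelSet`."""

    values: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if len(self.values) != self.n_voxels:
            raise ValueError("predicted values length != voxel count")
        if np.any(self.values < 0):
            raise ValueError("predicted densities must be non-negative")


def atom_density(
    table: ScatteringTable, type_key: str, b: float, r: np.ndarray | float
) -> np.ndarray | float:
    """Density contribution of one atom/bead of ``type_key`` at distance ``r`` Å.

    ``b`` is the residue B-factor in Å². Strictly decreasing in ``r``;
    at r=0 strictly decreasing in ``b``.
    """
    if b < 0:
        raise ValueError("B-factor must be non-negative")
    a_k, b_k = table[type_key]
    r = np.asarray(r, dtype=np.float64)
    c_k = b_k + b / 4.0
    vals = a_k * (_FOUR_PI / c_k) ** 1.5 * np.exp(
        -_FOUR_PI2 * r[..., None] ** 2 / c_k
    )
    out = vals.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def contributing_atoms(
    model: StructureModel, mode: str, table: ScatteringTable
) -> tuple[np.ndarray, list[str]]:
    """Atom indices that contribute to the forward model, with their table keys.

    ``mode="atomistic"``: keys are element symbols; hydrogens and Glu/Asp
    carboxylate oxygens are excluded. ``mode="cg"``: every entry contributes
    and its *atom name* is the bead-type key.
    """
    if mode not in ("atomistic", "cg"):
        raise ValueError(f"unknown forward-model mode {mode!r}")
    if mode == "cg":
        keys = [str(n) for n in model.names]
        for i, k in enumerate(keys):
            if k not in table:
                raise KeyError(f"bead {i} has no scattering entry for type {k!r}")
        return np.arange(model.n_atoms, dtype=np.intp), keys
    idx: list[int] = []
    keys = []
    for i in range(model.n_atoms):
        el = str(model.elements[i]).upper()
        if el in ("H", "D"):
            continue
        rid = model.residues[model.residue_ordinal[i]]
        if (rid.name, str(model.names[i])) in _EXCLUDED_SIDE_CHAIN_O:
            continue
        el_key = el.capitalize()
        if el_key not in table:
            raise KeyError(
                f"atom {i} ({model.names[i]} in {rid}): no scattering entry "
                f"for element {el_key!r}"
            )
        idx.append(i)
        keys.append(el_key)
    return np.asarray(idx, dtype=np.intp), keys


class MapPredictor:
    """Caches the atom–voxel neighbor list for repeated forward evaluations.

    Built once per (voxel set, topology); ``rebuild(coords)`` refreshes the
    neighbor list after coordinate moves. Evaluations take per-residue
    B-factors (Å²) and are vectorized over the cached pair list.
    """

    def __init__(
        self,
        voxels: VoxelSet,
        model: StructureModel,
        table: ScatteringTable,
        mode: str = "atomistic",
        cutoff: float = NEIGHBOR_CUTOFF,
    ) -> None:
        self.voxels = voxels
        self.model = model
        self.table = table
        self.mode = mode
        self.cutoff = float(cutoff)
        self.atom_idx, keys = contributing_atoms(model, mode, table)
        # per contributing atom: row in the stacked (A, B) matrices
        uniq = sorted(set(keys))
        key_row = {k: i for i, k in enumerate(uniq)}
        self._amat = np.stack([table[k][0] for k in uniq]) if uniq else np.zeros((0, 1))
        self._bmat = np.stack([table[k][1] for k in uniq]) if uniq else np.zeros((0, 1))
        self.type_row = np.array([key_row[k] for k in keys], dtype=np.intp)
        self.res_of_contrib = model.residue_ordinal[self.atom_idx]
        self._tree_vox = cKDTree(voxels.centers) if len(voxels) else None
        self.rebuild(model.coords)

    # -- neighbor list ------------------------------------------------------

    def rebuild(self, coords: np.ndarray) -> None:
        """Recompute the atom–voxel pair list for the given coordinates."""
        self.coords = np.asarray(coords, dtype=np.float64)
        pa: list[np.ndarray] = []
        pv: list[np.ndarray] = []
        if self._tree_vox is None or len(self.atom_idx) == 0:
            self.pair_atom = np.zeros(0, dtype=np.intp)
            self.pair_vox = np.zeros(0, dtype=np.intp)
        else:
            lists = self._tree_vox.query_ball_point(
                self.coords[self.atom_idx], self.cutoff
            )
            for a, vs in enumerate(lists):
                if vs:
                    pa.append(np.full(len(vs), a, dtype=np.intp))
                    pv.append(np.asarray(vs, dtype=np.intp))
            self.pair_atom = np.concatenate(pa) if pa else np.zeros(0, dtype=np.intp)
            self.pair_vox = np.concatenate(pv) if pv else np.zeros(0, dtype=np.intp)
        self._update_pair_geometry()
        # pair indices grouped by residue, for incremental B-factor moves
        self._res_pairs: dict[int, np.ndarray] = {}
        res_of_pair = self.res_of_contrib[self.pair_atom]
        order = np.argsort(res_of_pair, kind="stable")
        bounds = np.searchsorted(
            res_of_pair[order], np.arange(self.model.n_residues + 1)
        )
        for r in range(self.model.n_residues):
            sel = order[bounds[r] : bounds[r + 1]]
            if sel.size:
                self._res_pairs[r] = sel
        self._res_uniq: dict[int, np.ndarray] = {}

    def residue_voxels(self, residue: int) -> np.ndarray:
        """Unique voxel indices touched by one residue's atoms (cached)."""
        u = self._res_uniq.get(residue)
        if u is None:
            sel = self._res_pairs.get(residue)
            u = (
                np.unique(self.pair_vox[sel])
                if sel is not None
                else np.zeros(0, dtype=np.intp)
            )
            self._res_uniq[residue] = u
        return u

    def _update_pair_geometry(self) -> None:
        disp = (
            self.coords[self.atom_idx[self.pair_atom]]
            - self.voxels.centers[self.pair_vox]
        )
        self.pair_disp = disp
        self.pair_r2 = np.einsum("ij,ij->i", disp, disp)

    def move(self, coords: np.ndarray) -> None:
        """Update coordinates without rebuilding the neighbor list."""
        self.coords = np.asarray(coords, dtype=np.float64)
        self._update_pair_geometry()

    # -- evaluation ---------------------------------------------------------

    def _pair_c(self, b_res: np.ndarray, pair_sel: np.ndarray | slice = slice(None)):
        rows = self.type_row[self.pair_atom[pair_sel]]
        b = b_res[self.res_of_contrib[self.pair_atom[pair_sel]]]
        return self._amat[rows], self._bmat[rows] + b[:, None] / 4.0

    def pair_values(self, b_res: np.ndarray, pair_sel=slice(None)) -> np.ndarray:
        a, c = self._pair_c(b_res, pair_sel)
        g = a * (_FOUR_PI / c) ** 1.5 * np.exp(
            -_FOUR_PI2 * self.pair_r2[pair_sel, None] / c
        )
        return g.sum(axis=1)

    def eval_pairs(self, b_res: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One pass over all pairs: (values, radial gradient coefficients).

        ``coef`` is −2 g'(r²) per pair, so ∂f/∂X_j of a pair is
        ``−coef · (X_j − V_i)``; sharing the Gaussian evaluation between the
        density and its gradient halves the cost of an energy+force step.
        """
        a, c = self._pair_c(b_res)
        g = a * (_FOUR_PI / c) ** 1.5 * np.exp(-_FOUR_PI2 * self.pair_r2[:, None] / c)
        vals = g.sum(axis=1)
        coef = (g * (2.0 * _FOUR_PI2 / c)).sum(axis=1)
        return vals, coef

    def values_to_map(self, vals: np.ndarray) -> np.ndarray:
        return np.bincount(self.pair_vox, weights=vals, minlength=len(self.voxels))

    def predict(self, b_res: np.ndarray) -> np.ndarray:
        """f_i for all voxels given per-residue B-factors."""
        vals = self.pair_values(b_res)
        return np.bincount(self.pair_vox, weights=vals, minlength=len(self.voxels))

    def force_from_coef(self, coef: np.ndarray, w_vox: np.ndarray) -> np.ndarray:
        """Σ_i w_i ∂f_i/∂X_j from cached pair coefficients (see eval_pairs)."""
        vec = (-coef * w_vox[self.pair_vox])[:, None] * self.pair_disp
        idx = self.atom_idx[self.pair_atom]
        grad = np.zeros((self.model.n_atoms, 3))
        n = self.model.n_atoms
        for ax in range(3):
            grad[:, ax] = np.bincount(idx, weights=vec[:, ax], minlength=n)
        return grad

    def residue_contribution(
        self, residue: int, b_res: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(voxel indices, summed contribution) of one residue's atoms.

        Voxel indices may repeat across the residue's pair list; callers
        accumulate with ``np.add.at`` or ``bincount``.
        """
        sel = self._res_pairs.get(residue)
        if sel is None:
            return np.zeros(0, dtype=np.intp), np.zeros(0)
        return self.pair_vox[sel], self.pair_values(b_res, sel)

    def force_accumulate(self, w_vox: np.ndarray, b_res: np.ndarray) -> np.ndarray:
        """Σ_i w_i ∂f_i/∂X_j for all atoms, shape (n_atoms, 3).

        ``w_vox`` is a per-voxel weight (e.g. ∂E/∂f_i); the return value is
        the corresponding energy gradient with respect to coordinates.
        """
        _, coef = self.eval_pairs(b_res)
        return self.force_from_coef(coef, w_vox)

    def pair_gradients(self, b_res: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse ∂f_i/∂X_j: (atom index, voxel index, (P,3) gradients)."""
        a, c = self._pair_c(b_res)
        g = a * (_FOUR_PI / c) ** 1.5 * np.exp(-_FOUR_PI2 * self.pair_r2[:, None] / c)
        coef = (g * (2.0 * _FOUR_PI2 / c)).sum(axis=1)
        grads = -coef[:, None] * self.pair_disp
        return self.atom_idx[self.pair_atom], self.pair_vox.copy(), grads


def predict_map(
    model: StructureModel,
    bfactors: np.ndarray,
    voxels: VoxelSet,
    table: ScatteringTable,
    mode: str = "atomistic",
    cutoff: float = NEIGHBOR_CUTOFF,
) -> PredictedMap:
    """Predict densities f_i(X, b) at the voxel centers (one-shot API)."""
    bfactors = np.asarray(bfactors, dtype=np.float64).reshape(-1)
    if len(bfactors) != model.n_residues:
        raise ValueError("one B-factor per residue required")
    pred = MapPredictor(voxels, model, table, mode=mode, cutoff=cutoff)
    return PredictedMap(values=pred.predict(bfactors), n_voxels=len(voxels))


def map_gradient(
    model: StructureModel,
    bfactors: np.ndarray,
    voxels: VoxelSet,
    table: ScatteringTable,
    mode: str = "atomistic",
    cutoff: float = NEIGHBOR_CUTOFF,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse analytic gradient ∂f_i/∂X_j over the neighbor pair list.

    Returns ``(atom_index, voxel_index, grad)`` parallel arrays with ``grad``
    of shape (n_pairs, 3) in map-units/Å.
    """
    bfactors = np.asarray(bfactors, dtype=np.float64).reshape(-1)
    pred = MapPredictor(voxels, model, table, mode=mode, cutoff=cutoff)
    return pred.pair_gradients(bfactors)
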