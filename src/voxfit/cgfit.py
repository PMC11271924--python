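"""Coarse-grained bead parameterization: single-Gaussian fits by grid scan.

A coarse-grained bead replaces a group of heavy atoms; its scattering
profile is a single Gaussian (A, B) fitted so that the bead's predicted
density matches the atomistic forward model of the underlying atom group on
a cube of 19³ = 6859 evenly spaced voxels (side 6 Å) centered on the bead.
The fit scans A from 0 to 8.0 in steps of 0.1 and B from 0 to 40 Å² in
steps of 0.5 Å², averaging the mean-squared-error surface over all
occurrences of the bead type and taking the argmin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import atom_density
from .scattering import ScatteringTable
from .structure import StructureModel

__all__ = [
    "BeadOccurrence",
    "fit_bead_parameters",
    "delta_cc_binned",
    "occurrences_from_model",
    "ALA_BEAD_MAPPING",
    "map_to_beads",
    "A_GRID",
    "B_GRID",
]

A_GRID = (0.0, 8.0, 0.1)     # dimensionless amplitude scan
B_GRID = (0.0, 40.0, 0.5)    # Å² width scan
BOX_SIDE = 6.0               # Å
N_PER_AXIS = 19              # 19³ = 6859 voxels

_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

# minimal polyalanine bead mapping: (residue, bead name) -> (atom names, type key)
ALA_BEAD_MAPPING = {
    ("ALA", "BB"): (("N", "CA", "C", "O"), "BB"),
    ("ALA", "SC1"): (("CB",), "SC1"),
}


@dataclass
class BeadOccurrence:
    """One instance of a bead type: its atom group and the bead center."""

    atom_keys: list[str]      # scattering-table keys of the constituent atoms
    atom_coords: np.ndarray   # (n, 3) Å
    center: np.ndarray        # (3,) Å, bead position

    def __post_init__(self) -> None:
        self.atom_coords = np.asarray(self.atom_coords, dtype=np.float64).reshape(-1, 3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)


def _cube_offsets(box_side: float = BOX_SIDE, n: int = N_PER_AXIS) -> np.ndarray:
    axis = np.linspace(-box_side / 2.0, box_side / 2.0, n)
    return np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)


def fit_bead_parameters(
    occurrences: list[BeadOccurrence],
    table: ScatteringTable,
    a_grid: tuple[float, float, float] = A_GRID,
    b_grid: tuple[float, float, float] = B_GRID,
    box_side: float = BOX_SIDE,
    n_per_axis: int = N_PER_AXIS,
    bfactor: float = 0.0,
) -> tuple[float, float, float]:
    """Grid-scan fit of one bead type; returns (A, B, min mean MSE).

    The MSE surface is quadratic in A for fixed B, so the A scan is
    evaluated in closed form from the cross-moments of the bead profile and
    the atomistic target; ties are broken toward smaller B, then smaller A.
    A = 0 (zero density) is permitted; B = 0 is singular and can win only
    with A = 0 (unless a blur ``bfactor`` is applied).

    ``bfactor`` (Å²) applies the same residue B-factor blur to the atomistic
    target and the bead profile (both forward models add b/4 to their
    Gaussian widths); 0 fits the raw scattering profiles.
    """
    if not occurrences:
        raise ValueError("no occurrences to fit")
    offs = _cube_offsets(box_side, n_per_axis)
    r_bead = np.linalg.norm(offs, axis=1)  # bead sits at the cube center
    a_vals = np.round(np.arange(round(a_grid[0] / a_grid[2]), round(a_grid[1] / a_grid[2]) + 1) * a_grid[2], 10)
    b_vals = np.round(np.arange(round(b_grid[0] / b_grid[2]), round(b_grid[1] / b_grid[2]) + 1) * b_grid[2], 10)
    # accumulate cross-moments over occurrences
    dot_sum = np.zeros(len(b_vals))
    const_sum = 0.0
    m2 = np.zeros(len(b_vals))
    profiles = np.zeros((len(b_vals), len(offs)))
    four_pi = 4.0 * np.pi
    four_pi2 = 4.0 * np.pi**2
    for bi, b in enumerate(b_vals):
        c = b + bfactor / 4.0
        if c > 0:
            profiles[bi] = (four_pi / c) ** 1.5 * np.exp(-four_pi2 * r_bead**2 / c)
    m2 = np.mean(profiles**2, axis=1)
    for occ in occurrences:
        vox = occ.center + offs
        f_at = np.zeros(len(offs))
        for key, xyz in zip(occ.atom_keys, occ.atom_coords):
            r = np.linalg.norm(vox - xyz, axis=1)
            f_at += atom_density(table, key, bfactor, r)
        dot_sum += np.mean(profiles * f_at[None, :], axis=1)
        const_sum += float(np.mean(f_at**2))
    n_occ = len(occurrences)
    dot = dot_sum / n_occ
    const = const_sum / n_occ
    # mse[b, a] = a² m2_b − 2 a dot_b + const
    mse = (
        a_vals[None, :] ** 2 * m2[:, None]
        - 2.0 * a_vals[None, :] * dot[:, None]
        + const
    )
    if bfactor == 0.0:
        zero_b = np.where(b_vals == 0.0)[0]
        zero_a = np.where(a_vals == 0.0)[0]
        mse[zero_b, :] = np.inf
        for bi in zero_b:
            mse[bi, zero_a] = const  # zero-density bead is well defined
    # row-major argmin: smallest B wins ties, then smallest A
    flat = int(np.argmin(np.round(mse, 12)))
    bi, ai = divmod(flat, len(a_vals))
    return float(a_vals[ai]), float(b_vals[bi]), float(mse[bi, ai])


def occurrences_from_model(
    model: StructureModel,
    mapping: dict = ALA_BEAD_MAPPING,
) -> dict[str, list[BeadOccurrence]]:
    """Collect bead occurrences per type key from a structure.

    Beads with missing atoms are skipped. The bead center is the
    mass-weighted centroid of the group.
    """
    out: dict[str, list[BeadOccurrence]] = {}
    for r, rid in enumerate(model.residues):
        atom_idx = model.residue_atoms(r)
        names = {str(model.names[i]): i for i in atom_idx}
        for (resname, _bead), (atoms, key) in mapping.items():
            if resname != rid.name:
                continue
            if not all(a in names for a in atoms):
                continue  # skip beads with missing atoms
            idx = [names[a] for a in atoms]
            keys = [str(model.elements[i]).capitalize() for i in idx]
            coords = model.coords[idx]
            masses = np.array([_MASS.get(k, 12.0) for k in keys])
            center = (coords * masses[:, None]).sum(axis=0) / masses.sum()
            out.setdefault(key, []).append(
                BeadOccurrence(atom_keys=keys, atom_coords=coords, center=center)
            )
    return out


def map_to_beads(model: StructureModel, mapping: dict = ALA_BEAD_MAPPING) -> StructureModel:
    """Coarse-grain a structure: one pseudo-atom per mapped bead.

    The returned model's atom *names* are the bead type keys (the convention
    the forward model's ``cg`` mode uses for scattering lookups).
    """
    coords: list[np.ndarray] = []
    names: list[str] = []
    ordinals: list[int] = []
    for r, rid in enumerate(model.residues):
        atom_idx = model.residue_atoms(r)
        byname = {str(model.names[i]): i for i in atom_idx}
        for (resname, _bead), (atoms, key) in mapping.items():
            if resname != rid.name or not all(a in byname for a in atoms):
                continue
            idx = [byname[a] for a in atoms]
            masses = np.array(
                [_MASS.get(str(model.elements[i]).capitalize(), 12.0) for i in idx]
            )
            c = (model.coords[idx] * masses[:, None]).sum(axis=0) / masses.sum()
            coords.append(c)
            names.append(key)
            ordinals.append(r)
    if not coords:
        raise ValueError("no beads could be mapped")
    return StructureModel(
        elements=np.asarray(["X"] * len(names), dtype=object),
        names=np.asarray(names, dtype=object),
        coords=np.asarray(coords),
        residue_ordinal=np.asarray(ordinals, dtype=np.intp),
        residues=model.residues,
        het=np.zeros(len(names), dtype=bool),
    )


def delta_cc_binned(
    records: pd.DataFrame | list[tuple[float, float, float]],
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Bin (resolution, CC_atomistic, CC_cg) records and average ΔCC per bin.

    ΔCC = CC_atomistic − CC_cg; the table carries per-bin mean, standard
    deviation (0 for singleton bins) and count. Empty bins are omitted.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            records, columns=["resolution", "cc_atomistic", "cc_cg"]
        )
    if len(records) == 0:
        raise ValueError("no records")
    df = records.copy()
    df["delta_cc"] = df["cc_atomistic"] - df["cc_cg"]
    df["bin"] = np.floor(df["resolution"] / bin_width) * bin_width
    grouped = df.groupby("bin")["delta_cc"]
    out = pd.DataFrame(
        {
            "bin": grouped.mean().index,
            "mean_delta_cc": grouped.mean().values,
            "sd_delta_cc": grouped.std(ddof=1).fillna(0.0).values,
            "n_structures": grouped.count().values,
        }
    ).reset_index(drop=True)
    return out
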