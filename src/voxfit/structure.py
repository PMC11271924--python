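"""Atomic models: reading, residue bookkeeping, writing with B-factors.

A :class:`StructureModel` is a flat array view of the non-water content of a
PDB/mmCIF file: per-atom element, name, coordinates and a per-atom ordinal
into the residue list. B-factors in this package are per-residue (Å²) and are
broadcast to atoms through that ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "ResidueId",
    "StructureModel",
    "EmptyModelError",
    "read_structure",
    "write_model_with_bfactors",
]


class EmptyModelError(ValueError):
    """Raised when a structure file contains no atoms."""


@dataclass(frozen=True)
class ResidueId:
    """Identifies one residue: chain, sequence number, insertion code, name."""

    chain: str
    seqid: int
    icode: str
    name: str

    def __str__(self) -> str:  # e.g. "A:42A:LYS"
        return f"{self.chain}:{self.seqid}{self.icode.strip()}:{self.name}"


@dataclass
class StructureModel:
    """Atomic coordinates X_j grouped into residues.

    Attributes
    ----------
    elements : array of element symbols per atom (e.g. ``"C"``).
    names : array of atom names per atom (e.g. ``"CA"``, ``"OE1"``).
    coords : (N, 3) float array, Å.
    residue_ordinal : per-atom index into ``residues``.
    residues : list of :class:`ResidueId` in file order.
    het : per-atom heteroatom flag.
    """

    elements: np.ndarray
    names: np.ndarray
    coords: np.ndarray
    residue_ordinal: np.ndarray
    residues: list[ResidueId]
    het: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.residue_ordinal = np.asarray(self.residue_ordinal, dtype=np.intp)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.n_atoms and self.residue_ordinal.max() >= len(self.residues):
            raise ValueError("residue ordinal out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_atoms(self, ordinal: int) -> np.ndarray:
        """Atom indices belonging to residue ``ordinal``."""
        return np.nonzero(self.residue_ordinal == ordinal)[0]

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """A copy sharing metadata but with new coordinates."""
        return StructureModel(
            elements=self.elements,
            names=self.names,
            coords=np.array(coords, dtype=np.float64),
            residue_ordinal=self.residue_ordinal,
            residues=self.residues,
            het=self.het,
        )

    def same_topology(self, other: "StructureModel") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.elements, other.elements)
            and np.array_equal(self.names, other.names)
            and np.array_equal(self.residue_ordinal, other.residue_ordinal)
        )


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken toward altloc 'A' (then alphabetical)
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def read_structure(path: str) -> StructureModel:
    """Read a PDB or mmCIF model.

    Alternate locations are resolved to the highest-occupancy conformer (ties
    to altloc 'A'); insertion codes are preserved in the residue identifiers;
    waters are kept (they carry density through their oxygen).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    elements: list[str] = []
    names: list[str] = []
    coords: list[list[float]] = []
    ordinals: list[int] = []
    het: list[bool] = []
    residues: list[ResidueId] = []
    if len(st) == 0:
        raise EmptyModelError(f"{path!r}: no models in file")
    model = st[0]
    for chain in model:
        for res in chain:
            rid = ResidueId(
                chain=chain.name,
                seqid=res.seqid.num,
                icode=res.seqid.icode.strip(),
                name=res.name,
            )
            ordinal = len(residues)
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                groups.setdefault(atom.name, []).append(atom)
            placed = False
            for name, group in groups.items():
                atom = _pick_altloc(group)
                elements.append(atom.element.name)
                names.append(name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                ordinals.append(ordinal)
                het.append(res.het_flag == "H")
                placed = True
            if placed:
                residues.append(rid)
    if not coords:
        raise EmptyModelError(f"{path!r}: structure contains no atoms")
    return StructureModel(
        elements=np.asarray(elements, dtype=object),
        names=np.asarray(names, dtype=object),
        coords=np.asarray(coords, dtype=np.float64),
        residue_ordinal=np.asarray(ordinals, dtype=np.intp),
        residues=residues,
        het=np.asarray(het, dtype=bool),
    )


def write_model_with_bfactors(
    model: StructureModel, bfactors: np.ndarray, path: str
) -> None:
    """Write a PDB whose B column carries each residue's B-factor (Å²).

    ``bfactors`` has one entry per residue in ``model.residues`` order; a NaN
    entry is treated as missing and rejected.
    """
    bfactors = np.asarray(bfactors, dtype=np.float64).reshape(-1)
    if len(bfactors) != model.n_residues:
        raise ValueError(
            f"expected {model.n_residues} B-factors, got {len(bfactors)}"
        )
    bad = np.nonzero(~np.isfinite(bfactors))[0]
    if bad.size:
        raise ValueError(f"residue {model.residues[bad[0]]} has no B-factor")
    # gemmi add_chain/add_residue copy their argument: assemble residues fully
    # (grouped by ordinal), then chains, then the model.
    per_res_atoms: dict[int, list[int]] = {}
    for i in range(model.n_atoms):
        per_res_atoms.setdefault(int(model.residue_ordinal[i]), []).append(i)
    chain_residues: dict[str, list[gemmi.Residue]] = {}
    chain_order: list[str] = []
    for ordinal in sorted(per_res_atoms):
        rid = model.residues[ordinal]
        res = gemmi.Residue()
        res.name = rid.name
        res.seqid = gemmi.SeqId(rid.seqid, rid.icode if rid.icode else " ")
        for i in per_res_atoms[ordinal]:
            atom = gemmi.Atom()
            atom.name = str(model.names[i])
            atom.element = gemmi.Element(str(model.elements[i]))
            atom.pos = gemmi.Position(*model.coords[i])
            atom.occ = 1.0
            atom.b_iso = float(bfactors[ordinal])
            res.add_atom(atom)
            res.het_flag = "H" if model.het[i] else "A"
        if rid.chain not in chain_residues:
            chain_residues[rid.chain] = []
            chain_order.append(rid.chain)
        chain_residues[rid.chain].append(res)
    st = gemmi.Structure()
    st.name = "voxfit"
    gm = gemmi.Model("1")
    for cname in chain_order:
        chain = gemmi.Chain(cname)
        for res in chain_residues[cname]:
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
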