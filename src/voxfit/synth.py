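"""Synthetic fixtures: toy structures, ground-truth maps, elastic-network prior.

Everything downstream (pre-filtering, refinement, ensembles, metrics) is
exercised against data produced here, so each generator records its exact
parameters and is reproducible from (parameters, seed) alone. The maps
emulate a reconstruction with two half maps: the full map carries i.i.d.
Gaussian voxel noise of variance s², each half map carries independent noise
of variance 2s², so averaging the halves reproduces the full map's noise
level in expectation and the half-map difference has an analytic
distribution for noise-floor tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .forward import predict_map
from .maps import DensityMap, HalfMapPair, VoxelSet
from .scattering import ScatteringTable, load_atomistic_table
from .structure import ResidueId, StructureModel

__all__ = [
    "make_toy_structure",
    "simulate_map",
    "GroundTruth",
    "ElasticNetworkPrior",
    "elastic_network_prior",
]

_HELIX_RADIUS = 2.3   # Å, CA distance from the helix axis
_HELIX_RISE = 1.5     # Å per residue
_HELIX_TWIST = np.deg2rad(100.0)


def _helix_ca(n: int) -> np.ndarray:
    i = np.arange(-1, n + 1)  # one extra on each side for bond directions
    return np.stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TWIST * i),
            _HELIX_RADIUS * np.sin(_HELIX_TWIST * i),
            _HELIX_RISE * i,
        ],
        axis=1,
    )


def _strand_ca(n: int) -> np.ndarray:
    i = np.arange(-1, n + 1)
    dx = np.sqrt(3.8**2 - 1.0**2)
    return np.stack([dx * i, 0.5 * (-1.0) ** i, np.zeros_like(i, dtype=float)], axis=1)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _backbone(ca_ext: np.ndarray, n: int) -> tuple[np.ndarray, list[str], list[int]]:
    """Place N, CA, C, O, CB per residue from an extended CA trace."""
    coords: list[np.ndarray] = []
    names: list[str] = []
    ordinals: list[int] = []
    for r in range(n):
        ca = ca_ext[r + 1]
        prev_dir = _unit(ca_ext[r] - ca)
        next_dir = _unit(ca_ext[r + 2] - ca)
        radial = ca - np.array([0.0, 0.0, ca[2]])
        nr = np.linalg.norm(radial)
        radial = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
        n_at = ca + 1.46 * prev_dir
        c_at = ca + 1.52 * next_dir
        o_at = c_at + 1.23 * _unit(radial + np.array([0.0, 0.0, 0.35]))
        cb_at = ca + 1.53 * _unit(radial - np.array([0.0, 0.0, 0.45]))
        for name, pos in (("N", n_at), ("CA", ca), ("C", c_at), ("O", o_at), ("CB", cb_at)):
            names.append(name)
            coords.append(pos)
            ordinals.append(r)
    return np.asarray(coords), names, ordinals


def _assemble(coords: np.ndarray, names: list[str], ordinals: list[int], n: int) -> StructureModel:
    elements = [n[0] for n in names]  # N->N, CA->C, C->C, O->O, CB->C
    residues = [ResidueId(chain="A", seqid=r + 1, icode="", name="ALA") for r in range(n)]
    return StructureModel(
        elements=np.asarray(elements, dtype=object),
        names=np.asarray(names, dtype=object),
        coords=coords,
        residue_ordinal=np.asarray(ordinals, dtype=np.intp),
        residues=residues,
        het=np.zeros(len(names), dtype=bool),
    )


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def make_toy_structure(
    kind: str,
    n_residues: int,
    seed: int = 0,
    hinge_angle_deg: float = 30.0,
    jitter: float = 0.02,
):
    """Build an ideal-geometry polyalanine toy (backbone + CB).

    ``kind`` is ``"helix"``, ``"strand"`` or ``"two_state"``; the latter
    returns a *pair* of models differing by a rigid hinge rotation (default
    30°) of the C-terminal half about an axis through the midpoint CA. A
    small seeded Gaussian jitter (σ = ``jitter`` Å) is applied identically
    to the rigid bodies of both states, so equal seeds give identical
    fixtures and the two states differ only by the hinge.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if kind not in ("helix", "strand", "two_state"):
        raise ValueError(f"unknown toy kind {kind!r}")
    rng = np.random.default_rng(seed)
    ca_ext = _strand_ca(n_residues) if kind == "strand" else _helix_ca(n_residues)
    coords, names, ordinals = _backbone(ca_ext, n_residues)
    coords = coords + jitter * rng.standard_normal(coords.shape)
    model = _assemble(coords, names, ordinals, n_residues)
    if kind != "two_state":
        return model
    mid = n_residues // 2
    pivot = coords[np.asarray(ordinals) == mid][1]  # CA of the hinge residue
    rot = _rotation(np.array([1.0, 0.0, 0.0]), np.deg2rad(hinge_angle_deg))
    moving = np.asarray(ordinals) >= mid
    coords_b = coords.copy()
    coords_b[moving] = (coords[moving] - pivot) @ rot.T + pivot
    return model, model.with_coords(coords_b)


@dataclass
class GroundTruth:
    """Everything needed to regenerate / score a synthetic map."""

    kind: str
    weights: list[float]
    bfactors: list[float]
    alpha_true: float
    noise_sd: float
    seed: int
    voxel_size: float
    model_coords: list[list[list[float]]]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def simulate_map(
    models: list[StructureModel],
    weights: list[float],
    bfactors: np.ndarray,
    voxel_size: float = 1.0,
    padding: float = 5.0,
    noise_sd: float = 0.0,
    alpha_true: float = 1.0,
    seed: int = 0,
    table: ScatteringTable | None = None,
    mode: str = "atomistic",
    kind: str = "synthetic",
) -> tuple[DensityMap, HalfMapPair, GroundTruth]:
    """Ground-truth map plus half maps from one or more weighted models.

    The noiseless truth is d = α_true · Σ_m w_m f_m evaluated on the full
    grid; the full map adds N(0, noise_sd²) per voxel, each half map adds
    independent N(0, 2·noise_sd²). ``noise_sd`` is in map units (the truth
    grid's units); pass e.g. 2% of the truth's peak for a "2% noise" map.
    """
    if not models:
        raise ValueError("need at least one model")
    weights_arr = np.asarray(weights, dtype=np.float64)
    if len(weights_arr) != len(models) or not np.isclose(weights_arr.sum(), 1.0):
        raise ValueError("weights must match models and sum to 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if table is None:
        table = load_atomistic_table()
    allc = np.vstack([m.coords for m in models])
    origin = allc.min(axis=0) - padding
    extent = allc.max(axis=0) + padding - origin
    shape = np.ceil(extent / voxel_size).astype(int) + 1
    nx, ny, nz = shape
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    centers = origin + idx * voxel_size
    grid_voxels = VoxelSet(centers=centers, densities=np.zeros(len(centers)))
    truth = np.zeros(len(centers))
    for w, m in zip(weights_arr, models):
        truth += w * predict_map(m, bfactors, grid_voxels, table, mode=mode).values
    truth *= alpha_true
    rng = np.random.default_rng(seed)
    full = truth + noise_sd * rng.standard_normal(truth.shape)
    half_a = truth + np.sqrt(2.0) * noise_sd * rng.standard_normal(truth.shape)
    half_b = truth + np.sqrt(2.0) * noise_sd * rng.standard_normal(truth.shape)

    def as_map(vals: np.ndarray) -> DensityMap:
        return DensityMap(
            densities=vals.reshape(nx, ny, nz),
            voxel_size=np.full(3, voxel_size),
            origin=origin,
        )

    record = GroundTruth(
        kind=kind,
        weights=[float(w) for w in weights_arr],
        bfactors=[float(b) for b in np.asarray(bfactors).ravel()],
        alpha_true=float(alpha_true),
        noise_sd=float(noise_sd),
        seed=int(seed),
        voxel_size=float(voxel_size),
        model_coords=[m.coords.tolist() for m in models],
    )
    return as_map(full), HalfMapPair(as_map(half_a), as_map(half_b)), record


class ElasticNetworkPrior:
    """Harmonic springs between reference-close atom pairs (toy E_FF stand-in).

    E = Σ_pairs ½ k (d − d_ref)²; zero energy and forces at the reference.
    """

    def __init__(self, reference: np.ndarray, pairs: np.ndarray, k: float) -> None:
        self.pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        if len(self.pairs) == 0:
            raise ValueError("elastic network has no springs")
        self.k = float(k)
        ref = np.asarray(reference, dtype=np.float64)
        self.d_ref = np.linalg.norm(
            ref[self.pairs[:, 0]] - ref[self.pairs[:, 1]], axis=1
        )

    def _dists(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        disp = coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]]
        return disp, np.linalg.norm(disp, axis=1)

    def energy(self, coords: np.ndarray) -> float:
        _, d = self._dists(np.asarray(coords, dtype=np.float64))
        return float(0.5 * self.k * np.sum((d - self.d_ref) ** 2))

    def forces(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.float64)
        disp, d = self._dists(coords)
        coef = self.k * (d - self.d_ref) / np.maximum(d, 1e-12)
        grad_pair = coef[:, None] * disp  # ∂E/∂X_a for atom a of the pair
        out = np.zeros_like(coords)
        np.add.at(out, self.pairs[:, 0], -grad_pair)
        np.add.at(out, self.pairs[:, 1], grad_pair)
        return out


def elastic_network_prior(
    reference: StructureModel,
    k: float = 10.0,
    cutoff: float = 8.0,
    residue_groups: list[set[int]] | None = None,
) -> ElasticNetworkPrior:
    """Build an elastic network on all atom pairs within ``cutoff`` Å.

    ``residue_groups`` optionally restricts springs to pairs whose residues
    fall in the same group (e.g. the two rigid bodies of a hinge fixture);
    atoms outside every group get no springs.
    """
    if k <= 0 or cutoff <= 0:
        raise ValueError("spring constant and cutoff must be positive")
    pairs = cKDTree(reference.coords).query_pairs(cutoff, output_type="ndarray")
    if residue_groups is not None:
        ro = reference.residue_ordinal
        group_of = {}
        for gi, grp in enumerate(residue_groups):
            for r in grp:
                group_of[r] = gi
        keep = []
        for a, b in pairs:
            ga = group_of.get(int(ro[a]))
            gb = group_of.get(int(ro[b]))
            if ga is not None and ga == gb:
                keep.append((a, b))
        pairs = np.asarray(keep, dtype=np.intp).reshape(-1, 2)
    if len(pairs) == 0:
        raise ValueError("no atom pairs within the elastic-network cutoff")
    return ElasticNetworkPrior(reference.coords, pairs, k)
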