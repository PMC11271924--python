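"""Map–model agreement: global CC_mask and per-residue local CC / noise.

CC_mask is the Pearson correlation between experimental and model-predicted
densities over the voxels near the model (the mask). No isotropic B-factor
is fitted before the correlation. For ensembles the predicted map is the
frame average but the mask is built from the single-structure model alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .forward import NEIGHBOR_CUTOFF, predict_map
from .maps import DensityMap, HalfMapPair, VoxelSet
from .scattering import ScatteringTable
from .structure import StructureModel

__all__ = [
    "build_mask",
    "mask_voxelset",
    "cc_mask",
    "cc_mask_model",
    "local_cc_and_noise",
    "MASK_RADIUS",
    "UndefinedCorrelationError",
]

MASK_RADIUS = 3.5  # Å, uniform per-atom masking radius


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested over constant values."""


def build_mask(
    model: StructureModel, dmap: DensityMap, radius: float = MASK_RADIUS
) -> np.ndarray:
    """Grid indices (N, 3) of voxels whose center is within ``radius`` of any
    non-hydrogen atom."""
    if radius <= 0:
        raise ValueError("mask radius must be positive")
    heavy = np.array([str(e).upper() not in ("H", "D") for e in model.elements])
    coords = model.coords[heavy]
    shape = np.asarray(dmap.grid_shape)
    lo = np.maximum(
        np.floor((coords.min(axis=0) - radius - dmap.origin) / dmap.voxel_size), 0
    ).astype(int)
    hi = np.minimum(
        np.ceil((coords.max(axis=0) + radius - dmap.origin) / dmap.voxel_size),
        shape - 1,
    ).astype(int)
    if np.any(hi < lo):
        raise ValueError("empty mask: model outside the map box")
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = dmap.origin + idx * dmap.voxel_size
    dist, _ = cKDTree(coords).query(centers, k=1)
    idx = idx[dist <= radius]
    if len(idx) == 0:
        raise ValueError("empty mask: no voxel centers within the radius")
    return idx


def mask_voxelset(dmap: DensityMap, mask: np.ndarray) -> VoxelSet:
    """The masked voxels as a VoxelSet (negative densities clipped to 0 for
    the container invariant; the raw values are used for correlations)."""
    centers = dmap.origin + mask * dmap.voxel_size
    dens = dmap.densities[mask[:, 0], mask[:, 1], mask[:, 2]]
    return VoxelSet(centers=centers, densities=np.maximum(dens, 0.0))


def cc_mask(
    exp_map: DensityMap, predicted: np.ndarray, mask: np.ndarray
) -> float:
    """Pearson correlation between experimental and predicted densities on the mask."""
    if len(mask) == 0:
        raise ValueError("empty mask")
    predicted = np.asarray(predicted, dtype=np.float64).reshape(-1)
    if len(predicted) != len(mask):
        raise ValueError("predicted values do not cover the mask")
    exp_vals = exp_map.densities[mask[:, 0], mask[:, 1], mask[:, 2]]
    if np.ptp(exp_vals) == 0 or np.ptp(predicted) == 0:
        raise UndefinedCorrelationError("constant densities over the mask")
    return float(np.corrcoef(exp_vals, predicted)[0, 1])


def cc_mask_model(
    exp_map: DensityMap,
    model: StructureModel,
    bfactors: np.ndarray,
    table: ScatteringTable,
    radius: float = MASK_RADIUS,
    mode: str = "atomistic",
) -> float:
    """CC_mask of a single model: builds the mask, predicts, correlates."""
    mask = build_mask(model, exp_map, radius)
    voxels = mask_voxelset(exp_map, mask)
    pred = predict_map(model, bfactors, voxels, table, mode=mode)
    return cc_mask(exp_map, pred.values, mask)


def local_cc_and_noise(
    model: StructureModel,
    exp_map: DensityMap,
    predicted: np.ndarray,
    mask: np.ndarray,
    halfmaps: HalfMapPair | None = None,
    min_voxels: int = 5,
) -> pd.DataFrame:
    """Per-residue local CC and median noise floor via nearest-atom Voronoi.

    Each masked voxel is assigned to the residue of its nearest model atom
    (a partition of the mask); per residue the local CC is the Pearson
    correlation over its voxels and the local error the median half-map
    noise floor. Residues with fewer than ``min_voxels`` voxels are flagged
    ``low_coverage`` and get NaN local CC.
    """
    centers = exp_map.origin + mask * exp_map.voxel_size
    exp_vals = exp_map.densities[mask[:, 0], mask[:, 1], mask[:, 2]]
    predicted = np.asarray(predicted, dtype=np.float64).reshape(-1)
    _, nearest = cKDTree(model.coords).query(centers, k=1)
    res_of_vox = model.residue_ordinal[nearest]
    if halfmaps is not None:
        da = halfmaps.half_a.value_at(centers)
        db = halfmaps.half_b.value_at(centers)
        scale = float(
            np.max(0.5 * np.abs(halfmaps.half_a.densities + halfmaps.half_b.densities))
        )
        eps = 1e-6 * scale if scale > 0 else 1e-12
        floors = np.maximum(0.5 * np.abs(da - db), eps)
    else:
        floors = np.full(len(mask), np.nan)
    rows = []
    for r, rid in enumerate(model.residues):
        sel = res_of_vox == r
        n = int(np.count_nonzero(sel))
        if n >= 2 and np.ptp(exp_vals[sel]) > 0 and np.ptp(predicted[sel]) > 0:
            local = float(np.corrcoef(exp_vals[sel], predicted[sel])[0, 1])
        else:
            local = np.nan
        rows.append(
            {
                "chain": rid.chain,
                "seqid": rid.seqid,
                "residue": str(rid),
                "local_cc": local if n >= min_voxels else np.nan,
                "median_noise": float(np.median(floors[sel])) if n else np.nan,
                "n_voxels": n,
                "low_coverage": n < min_voxels,
            }
        )
    return pd.DataFrame(rows)
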