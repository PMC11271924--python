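"""Voxel selection, autocorrelation pre-filtering, and half-map noise floors.

Neighboring voxels of a reconstructed map carry correlated information;
treating all of them as independent data points overcounts the data and
drives overfitting. The pre-filter walks the selected voxels in descending
density order and, around each keeper, measures the map's spatial
autocorrelation within a small cubic minibox; candidate voxels whose lag from
the keeper is autocorrelated above a threshold are dropped from the pool.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .maps import DensityMap, HalfMapPair, VoxelSet
from .structure import StructureModel

__all__ = [
    "EmptySelectionError",
    "select_voxels",
    "correlation_prefilter",
    "noise_floor",
    "SELECTION_CUTOFF",
    "CORRELATION_THRESHOLD",
    "MINIBOX_SIDE",
]

SELECTION_CUTOFF = 3.5   # Å, voxel-center-to-atom selection distance
CORRELATION_THRESHOLD = 0.8  # default Pearson threshold of the pre-filter
MINIBOX_SIDE = 4.0       # Å, side of the autocorrelation minibox
_MIN_PAIRS = 8           # lags with fewer valid pairs are treated as uncorrelated


class EmptySelectionError(ValueError):
    """Raised when voxel selection produces no voxels."""


def select_voxels(
    dmap: DensityMap,
    model: StructureModel,
    cutoff: float = SELECTION_CUTOFF,
) -> VoxelSet:
    """Voxels within ``cutoff`` of any non-hydrogen atom, negatives dropped.

    The returned set is sorted in descending density; noise floors are unset
    and must be filled by :func:`noise_floor`.
    """
    heavy = np.array([str(e).upper() not in ("H", "D") for e in model.elements])
    coords = model.coords[heavy]
    if len(coords) == 0:
        raise EmptySelectionError("model has no heavy atoms")
    # candidate grid indices: bounding box of the model padded by the cutoff
    shape = np.asarray(dmap.grid_shape)
    lo = np.maximum(
        np.floor((coords.min(axis=0) - cutoff - dmap.origin) / dmap.voxel_size), 0
    ).astype(int)
    hi = np.minimum(
        np.ceil((coords.max(axis=0) + cutoff - dmap.origin) / dmap.voxel_size),
        shape - 1,
    ).astype(int)
    if np.any(hi < lo):
        raise EmptySelectionError("model lies entirely outside the map box")
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = dmap.origin + idx * dmap.voxel_size
    dist, _ = cKDTree(coords).query(centers, k=1)
    near = dist <= cutoff
    idx = idx[near]
    centers = centers[near]
    dens = dmap.densities[idx[:, 0], idx[:, 1], idx[:, 2]]
    keep = dens >= 0
    # exact zeros are kept: only negative values are discarded
    idx, centers, dens = idx[keep], centers[keep], dens[keep]
    if len(dens) == 0:
        raise EmptySelectionError(
            "no non-negative voxels within the selection cutoff of the model"
        )
    order = np.argsort(-dens, kind="stable")
    return VoxelSet(centers=centers[order], densities=dens[order])


def _lag_offsets(half_extent: np.ndarray) -> np.ndarray:
    axes = [np.arange(-h, h + 1) for h in half_extent]
    offs = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return offs


def correlation_prefilter(
    dmap: DensityMap,
    voxels: VoxelSet,
    threshold: float = CORRELATION_THRESHOLD,
    minibox_side: float = MINIBOX_SIDE,
) -> VoxelSet:
    """Remove spatially correlated voxels (descending-density greedy sweep).

    For the current keeper, the lag-ℓ autocorrelation is the Pearson
    correlation of the map densities over starting voxels in the minibox
    against their ℓ-lagged values; every pool voxel inside the minibox whose
    lag has autocorrelation above ``threshold`` is removed (the keeper never
    is). ``threshold=1.0`` is a no-op.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    half = np.floor((minibox_side / 2.0) / dmap.voxel_size).astype(int)
    if np.any(half < 1):
        raise ValueError(
            "minibox smaller than one voxel on some axis; increase minibox_side"
        )
    if threshold >= 1.0:
        return VoxelSet(
            voxels.centers.copy(), voxels.densities.copy(),
            None if voxels.noise_floors is None else voxels.noise_floors.copy(),
        )
    n = len(voxels)
    grid_idx = np.rint((voxels.centers - dmap.origin) / dmap.voxel_size).astype(int)
    slot_of = {tuple(gi): i for i, gi in enumerate(grid_idx)}
    alive = np.ones(n, dtype=bool)

    offs = _lag_offsets(half)            # minibox starting-voxel offsets
    center_slot = np.nonzero(np.all(offs == 0, axis=1))[0][0]
    lags = np.delete(offs, center_slot, axis=0)   # ℓ ≠ 0
    # local subcube reach: start offsets + lags span [−2h, 2h]
    reach = 2 * half
    sub_axes = [np.arange(-r, r + 1) for r in reach]
    shape = np.asarray(dmap.grid_shape)
    # map (offset + reach) -> index into the gathered subcube
    off_local = offs + reach             # start voxels, local indices
    pair_local = offs[None, :, :] + lags[:, None, :] + reach  # (L, S, 3)

    for i in range(n):
        if not alive[i]:
            continue
        c = grid_idx[i]
        # gather the padded subcube around the keeper, NaN outside the map
        lo = c - reach
        hi = c + reach
        sub = np.full(2 * reach + 1, np.nan)
        src_lo = np.maximum(lo, 0)
        src_hi = np.minimum(hi, shape - 1)
        if np.all(src_hi >= src_lo):
            dst_lo = src_lo - lo
            dst_hi = src_hi - lo
            sub[
                dst_lo[0] : dst_hi[0] + 1,
                dst_lo[1] : dst_hi[1] + 1,
                dst_lo[2] : dst_hi[2] + 1,
            ] = dmap.densities[
                src_lo[0] : src_hi[0] + 1,
                src_lo[1] : src_hi[1] + 1,
                src_lo[2] : src_hi[2] + 1,
            ]
        x = sub[off_local[:, 0], off_local[:, 1], off_local[:, 2]]      # (S,)
        y = sub[pair_local[..., 0], pair_local[..., 1], pair_local[..., 2]]  # (L, S)
        valid = np.isfinite(x)[None, :] & np.isfinite(y)
        nv = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            xm = np.where(valid, x[None, :], 0.0)
            ym = np.where(valid, y, 0.0)
            sx = xm.sum(axis=1)
            sy = ym.sum(axis=1)
            sxx = (xm * xm).sum(axis=1)
            syy = (ym * ym).sum(axis=1)
            sxy = (xm * ym).sum(axis=1)
            cov = sxy - sx * sy / np.maximum(nv, 1)
            vx = sxx - sx * sx / np.maximum(nv, 1)
            vy = syy - sy * sy / np.maximum(nv, 1)
            corr = cov / np.sqrt(vx * vy)
        corr[~np.isfinite(corr)] = 0.0
        corr[nv < _MIN_PAIRS] = 0.0
        for lag in lags[corr > threshold]:
            slot = slot_of.get(tuple(c + lag))
            if slot is not None and slot != i:
                alive[slot] = False
    return voxels.subset(np.nonzero(alive)[0])


def noise_floor(halfmaps: HalfMapPair, voxels: VoxelSet) -> VoxelSet:
    """Fill σ_i^min = |d_i^A − d_i^B| / 2 from the half-map pair.

    The floor is clamped from below at ε = 1e−6 × the maximum density of the
    averaged half maps (a strictly positive numerical floor), so identical
    half maps yield ε everywhere.
    """
    a, b = halfmaps.half_a, halfmaps.half_b
    covered = a.covers(voxels.centers) & b.covers(voxels.centers)
    if not np.all(covered):
        raise ValueError(
            f"{np.count_nonzero(~covered)} voxel centers fall outside the half-map grid"
        )
    da = a.value_at(voxels.centers)
    db = b.value_at(voxels.centers)
    sigma = 0.5 * np.abs(da - db)
    scale = float(np.max(0.5 * np.abs(a.densities + b.densities)))
    eps = 1e-6 * scale if scale > 0 else 1e-12
    return VoxelSet(
        centers=voxels.centers.copy(),
        densities=voxels.densities.copy(),
        noise_floors=np.maximum(sigma, eps),
    )
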