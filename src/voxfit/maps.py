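"""Density maps, half maps and voxel lists.

Internal conventions used throughout the package:

* lengths in Å, B-factors in Å²;
* a :class:`DensityMap` stores densities indexed ``[ix, iy, iz]`` with the x
  axis first, regardless of the axis permutation (MAPC/MAPR/MAPS) of the file
  it was read from;
* ``origin`` is the physical position (Å) of the *center* of voxel
  ``(0, 0, 0)``; index ↔ coordinate mapping is 0-based,
  ``coord = origin + index * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "HalfMapPair",
    "VoxelSet",
    "MapFormatError",
    "VoxelFileError",
    "read_density_map",
    "write_density_map",
    "read_voxel_file",
    "write_voxel_file",
]


class MapFormatError(ValueError):
    """Raised for unreadable or internally inconsistent map files."""


class VoxelFileError(ValueError):
    """Raised for malformed voxel-list files."""


@dataclass
class DensityMap:
    """A 3D grid of densities with origin/spacing metadata.

    Parameters
    ----------
    densities
        Array of shape ``grid_shape`` indexed ``[ix, iy, iz]``.
    voxel_size
        Å per axis, shape ``(3,)``; all entries > 0.
    origin
        Position (Å) of the center of voxel ``(0, 0, 0)``.
    """

    densities: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=np.float64)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.densities.ndim != 3:
            raise MapFormatError("densities must be a 3D array")
        if not np.all(self.voxel_size > 0):
            raise MapFormatError("voxel_size must be positive on all axes")
        if not np.all(np.isfinite(self.densities)):
            raise MapFormatError("densities must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.densities.shape  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates (Å) of all voxel centers, shape (N, 3)."""
        nx, ny, nz = self.grid_shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return self.origin + idx * self.voxel_size

    def index_of(self, coords: np.ndarray) -> np.ndarray:
        """Nearest grid index of physical coordinates; no bounds check."""
        coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
        return np.rint((coords - self.origin) / self.voxel_size).astype(np.intp)

    def value_at(self, coords: np.ndarray) -> np.ndarray:
        """Density at the voxel containing each coordinate.

        Raises
        ------
        IndexError
            If any coordinate falls outside the grid.
        """
        idx = self.index_of(coords)
        shape = np.asarray(self.grid_shape)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise IndexError("coordinate outside the map grid")
        return self.densities[idx[:, 0], idx[:, 1], idx[:, 2]]

    def covers(self, coords: np.ndarray) -> np.ndarray:
        idx = self.index_of(coords)
        shape = np.asarray(self.grid_shape)
        return np.all((idx >= 0) & (idx < shape), axis=1)


@dataclass
class HalfMapPair:
    """Two independent reconstructions of the same map."""

    half_a: DensityMap
    half_b: DensityMap

    def __post_init__(self) -> None:
        a, b = self.half_a, self.half_b
        if a.grid_shape != b.grid_shape:
            raise MapFormatError("half maps differ in grid shape")
        if not (np.allclose(a.voxel_size, b.voxel_size) and np.allclose(a.origin, b.origin)):
            raise MapFormatError("half maps differ in voxel size or origin")


@dataclass
class VoxelSet:
    """The filtered list of independent data points.

    ``centers`` are voxel centers V_i (Å), ``densities`` the observed d_i and
    ``noise_floors`` the per-voxel lower bounds σ_i^min on the noise level
    (same units as density). ``noise_floors`` may be ``None`` until filled by
    :func:`voxfit.prep.noise_floor`.
    """

    centers: np.ndarray
    densities: np.ndarray
    noise_floors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        self.densities = np.asarray(self.densities, dtype=np.float64).reshape(-1)
        if len(self.densities) != len(self.centers):
            raise ValueError("centers and densities length mismatch")
        if np.any(self.densities < 0):
            raise ValueError("voxel densities must be non-negative")
        if self.noise_floors is not None:
            self.noise_floors = np.asarray(self.noise_floors, dtype=np.float64).reshape(-1)
            if len(self.noise_floors) != len(self.centers):
                raise ValueError("noise_floors length mismatch")
            if np.any(self.noise_floors <= 0):
                raise ValueError("noise floors must be strictly positive")

    def __len__(self) -> int:
        return len(self.densities)

    @property
    def n_voxels(self) -> int:
        return len(self.densities)

    def subset(self, index: np.ndarray) -> "VoxelSet":
        nf = None if self.noise_floors is None else self.noise_floors[index]
        return VoxelSet(self.centers[index], self.densities[index], nf)


# ---------------------------------------------------------------------------
# MRC / CCP4 map IO (via gemmi)
# ---------------------------------------------------------------------------

def read_density_map(path: str) -> DensityMap:
    """Read an MRC/CCP4 volume.

    Axis order is normalized to x-fastest-index internally whatever the file's
    MAPC/MAPR/MAPS permutation; the origin is taken from the ORIGIN header
    words when set, otherwise from NXSTART/NYSTART/NZSTART.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path!r}: {exc}") from exc
    # origin before setup(): ORIGIN words 50-52, else nstart
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=np.float64)
    nstart = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=np.float64)
    axis_order = [m.header_i32(w) for w in (17, 18, 19)]  # MAPC/MAPR/MAPS
    # normalize axis order so array index (u,v,w) -> (x,y,z)
    m.setup(float("nan"))
    grid = m.grid
    data = np.array(grid, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise MapFormatError(f"map {path!r}: non-finite densities (header/data mismatch?)")
    spacing = np.array(grid.spacing, dtype=np.float64)
    if np.allclose(origin, 0.0) and np.any(nstart != 0):
        # nstart counts grid columns/rows/sections in file axis order; permute to x,y,z
        perm = np.argsort(axis_order)  # file axis -> crystal axis
        origin = nstart[perm] * spacing
    return DensityMap(densities=data, voxel_size=spacing, origin=origin)


def write_density_map(dmap: DensityMap, path: str) -> None:
    """Write a mode-2 (float32) MRC/CCP4 map in canonical x,y,z axis order."""
    grid = gemmi.FloatGrid(*dmap.grid_shape)
    np.asarray(grid)[...] = dmap.densities.astype(np.float32)
    nx, ny, nz = dmap.grid_shape
    sx, sy, sz = dmap.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Voxel-list exchange file
# ---------------------------------------------------------------------------

_VOXEL_HEADER = "# voxfit voxel list: x y z density noise_floor (A, map units)"


def write_voxel_file(voxels: VoxelSet, path: str) -> None:
    """Write the plain-text voxel list: one ``x y z density noise_floor`` line per voxel.

    Values are written with ``repr`` round-trip precision so that
    ``read_voxel_file(write_voxel_file(v)) == v`` exactly. Voxels without
    noise floors are written with noise_floor ``nan``.
    """
    nf = voxels.noise_floors
    with open(path, "w") as fh:
        fh.write(_VOXEL_HEADER + "\n")
        for i in range(len(voxels)):
            x, y, z = (float(v) for v in voxels.centers[i])
            s = float("nan") if nf is None else float(nf[i])
            fh.write(f"{x!r} {y!r} {z!r} {float(voxels.densities[i])!r} {s!r}\n")


def read_voxel_file(path: str) -> VoxelSet:
    centers: list[list[float]] = []
    dens: list[float] = []
    floors: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise VoxelFileError(f"line {lineno}: expected 5 fields, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise VoxelFileError(f"line {lineno}: {exc}") from exc
            if vals[3] < 0:
                raise VoxelFileError(f"line {lineno}: negative density {vals[3]}")
            centers.append(vals[:3])
            dens.append(vals[3])
            floors.append(vals[4])
    floor_arr = np.asarray(floors, dtype=np.float64)
    has_floors = len(floor_arr) > 0 and not np.any(np.isnan(floor_arr))
    return VoxelSet(
        centers=np.asarray(centers, dtype=np.float64).reshape(-1, 3),
        densities=np.asarray(dens, dtype=np.float64),
        noise_floors=floor_arr if has_floors else None,
    )
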