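"""Gaussian electron-scattering parameter tables.

Atomistic types carry the standard 5-Gaussian fit of the electron scattering
factor, f(s) = Σ_k A_k exp(−B_k s²) with s = sinθ/λ and B_k in Å²; the
real-space density kernel used by the forward model is the Fourier pair of
that fit. Coarse-grained bead types carry a single (A, B) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["ScatteringTable", "load_atomistic_table", "load_bead_table"]


@dataclass
class ScatteringTable:
    """Maps an atom or bead type key to its Gaussian (A_k, B_k) pairs.

    ``entries[key] = (A, B)`` with 1-D arrays of equal length: 5 for
    atomistic element types, 1 for coarse-grained bead types.
    """

    entries: dict[str, tuple[np.ndarray, np.ndarray]]
    n_gaussians: int

    def __post_init__(self) -> None:
        for key, (a, b) in self.entries.items():
            a = np.asarray(a, dtype=np.float64)
            b = np.asarray(b, dtype=np.float64)
            if len(a) != self.n_gaussians or len(b) != self.n_gaussians:
                raise ValueError(f"{key}: expected {self.n_gaussians} Gaussian pairs")
            if np.any(a <= 0) or np.any(b <= 0):
                raise ValueError(f"{key}: A_k and B_k must be positive")
            self.entries[key] = (a, b)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"no scattering parameters for type {key!r}") from None

    @property
    def types(self) -> list[str]:
        return list(self.entries)

    def total_weight(self, key: str) -> float:
        """Σ_k A_k — the integral of the type's real-space density kernel."""
        return float(self[key][0].sum())


def _parse_table(text: str, n_gaussians: int) -> ScatteringTable:
    entries: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("type\t"):
            continue
        parts = line.split("\t")
        key = parts[0]
        vals = np.array([float(p) for p in parts[1:]], dtype=np.float64)
        if len(vals) != 2 * n_gaussians:
            raise ValueError(f"{key}: expected {2 * n_gaussians} columns")
        entries[key] = (vals[:n_gaussians], vals[n_gaussians:])
    return ScatteringTable(entries=entries, n_gaussians=n_gaussians)


def load_table(path: str, n_gaussians: int) -> ScatteringTable:
    """Load a scattering table from a TSV file (type, A_1..A_n, B_1..B_n)."""
    with open(path) as fh:
        return _parse_table(fh.read(), n_gaussians)


def load_atomistic_table() -> ScatteringTable:
    """The shipped 5-Gaussian element table (neutral atoms, B_k in Å²)."""
    text = resources.files("voxfit.data").joinpath("atomistic_scattering.tsv").read_text()
    return _parse_table(text, 5)


def load_bead_table() -> ScatteringTable:
    """The shipped single-Gaussian bead table.

    This table is synthetic: it is regenerated by this package's own grid-scan
    fit (:func:`voxfit.cgfit.fit_bead_parameters`) on ideal-geometry fixture
    structures, not taken from any deposited parameter set.
    """
    text = (
        resources.files("voxfit.data")
        .joinpath("bead_scattering_synthetic.tsv")
        .read_text()
    )
    return _parse_table(text, 1)
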