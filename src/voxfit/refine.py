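"""Single-structure refinement: Gibbs sampling of coordinates and B-factors.

Coordinates are sampled with overdamped Langevin dynamics on the hybrid
energy (a desk-scale, prior-agnostic stand-in for molecular dynamics);
per-residue B-factors are sampled with Metropolis Monte Carlo every
``bf_mc_stride`` coordinate steps. The final model is produced by a downhill
phase: gradient descent on coordinates with greedy (downhill-only) B-factor
moves, guaranteed non-increasing in energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import (
    HybridEnergyBreakdown,
    RefineConfig,
    bfactor_prior_energy,
    contact_pairs,
    hybrid_energy,
    log_marginal_kernel,
)
from .forward import MapPredictor
from .maps import VoxelSet
from .scattering import ScatteringTable
from .structure import StructureModel

__all__ = [
    "ZeroPrior",
    "RefineState",
    "init_bfactors",
    "mc_bfactor_sweep",
    "gibbs_refine",
    "downhill_minimize",
]

# empirical resolution → mean B-factor relation, nm² as a function of res in nm
_BF_QUAD = 6.95408
_BF_CONST = 0.01 * 2.45697


class ZeroPrior:
    """A structural prior that contributes nothing (data-only refinement)."""

    def energy(self, coords: np.ndarray) -> float:
        return 0.0

    def forces(self, coords: np.ndarray) -> np.ndarray:
        return np.zeros_like(np.asarray(coords, dtype=np.float64))


@dataclass
class RefineState:
    """One recorded state of a refinement trajectory."""

    step: int
    coords: np.ndarray
    bfactors: np.ndarray
    e_prior: float
    e_cryoem: float
    e_bf: float

    @property
    def total_energy(self) -> float:
        return self.e_prior + self.e_cryoem + self.e_bf


def init_bfactors(model: StructureModel, resolution_nm: float) -> np.ndarray:
    """Initial per-residue B-factors (Å²) from the map resolution (nm).

    Uses the empirical mean-B-factor/resolution relation
    b(nm²) = 6.95408 res² − 0.01·2.45697, floored at zero, applied uniformly
    to every residue.
    """
    if resolution_nm <= 0:
        raise ValueError("resolution must be positive")
    b_nm2 = max(_BF_QUAD * resolution_nm**2 - _BF_CONST, 0.0)
    return np.full(model.n_residues, 100.0 * b_nm2)  # 1 nm² = 100 Å²


def _sweep(
    predictor: MapPredictor,
    bfactors: np.ndarray,
    pairs: np.ndarray,
    config: RefineConfig,
    rng: np.random.Generator,
    max_move: float,
    greedy: bool,
) -> tuple[np.ndarray, float, float]:
    """One MC pass over all residues; returns (bfactors, acceptance, energy).

    ``energy`` is E_cryoEM + E_bf at the final state (the prior does not
    depend on B-factors). Proposals are uniform in ±max_move and reflected
    at zero; ``greedy`` restricts acceptance to downhill moves.
    """
    voxels = predictor.voxels
    d = voxels.densities
    sig = voxels.noise_floors
    alpha = config.scale
    bf = np.array(bfactors, dtype=np.float64)
    f = predictor.predict(bf)
    e_vox = -log_marginal_kernel(d - alpha * f, sig)
    # adjacency of the B-factor prior graph
    adj: dict[int, np.ndarray] = {}
    if len(pairs):
        for r in np.unique(pairs):
            mask = (pairs[:, 0] == r) | (pairs[:, 1] == r)
            others = pairs[mask].ravel()
            adj[int(r)] = others[others != r]
    accepted = 0
    n_res = predictor.model.n_residues
    for r in range(n_res):
        proposal = bf[r] + rng.uniform(-max_move, max_move)
        if proposal < 0:
            proposal = -proposal  # reflect at zero
        vox_idx, old_vals = predictor.residue_contribution(r, bf)
        bf_new = bf.copy()
        bf_new[r] = proposal
        _, new_vals = predictor.residue_contribution(r, bf_new)
        uniq = predictor.residue_voxels(r)
        if uniq.size:
            delta = np.zeros(len(voxels))
            np.add.at(delta, vox_idx, new_vals - old_vals)
            f_new_u = f[uniq] + delta[uniq]
            e_new_u = -log_marginal_kernel(d[uniq] - alpha * f_new_u, sig[uniq])
            d_cryo = float(e_new_u.sum() - e_vox[uniq].sum())
        else:
            f_new_u = e_new_u = np.zeros(0)
            d_cryo = 0.0
        neigh = adj.get(r)
        if neigh is not None and neigh.size:
            e_bf_old = -log_marginal_kernel(bf[r] - bf[neigh], config.sigma_bf_min)
            e_bf_new = -log_marginal_kernel(proposal - bf[neigh], config.sigma_bf_min)
            d_bf = float(e_bf_new.sum() - e_bf_old.sum())
        else:
            d_bf = 0.0
        d_total = d_cryo + d_bf
        if greedy:
            accept = d_total <= 0.0
        else:
            accept = d_total <= 0.0 or rng.random() < np.exp(
                -d_total / config.temperature
            )
        if accept:
            accepted += 1
            bf[r] = proposal
            if uniq.size:
                f[uniq] = f_new_u
                e_vox[uniq] = e_new_u
    e_bf_total, _ = bfactor_prior_energy(bf, pairs, config.sigma_bf_min)
    energy = float(e_vox.sum()) + e_bf_total
    return bf, accepted / max(n_res, 1), energy


def mc_bfactor_sweep(
    predictor: MapPredictor,
    bfactors: np.ndarray,
    pairs: np.ndarray,
    config: RefineConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """One Metropolis sweep over residue B-factors at fixed coordinates.

    Returns (new B-factors, acceptance rate, E_cryoEM + E_bf after the
    sweep). Maximum move ±``config.bf_mc_max_move`` (Å²), reflected at zero.
    """
    return _sweep(
        predictor, bfactors, pairs, config, rng,
        max_move=config.bf_mc_max_move, greedy=False,
    )


def _langevin_step(
    coords: np.ndarray,
    forces: np.ndarray,
    config: RefineConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    drift = config.step_size * forces
    norm = np.linalg.norm(drift, axis=1, keepdims=True)
    cap = config.max_displacement
    drift = np.where(norm > cap, drift * (cap / np.maximum(norm, 1e-300)), drift)
    noise = rng.standard_normal(coords.shape) * np.sqrt(
        2.0 * config.step_size * config.temperature
    )
    return coords + drift + noise


def gibbs_refine(
    model: StructureModel,
    voxels: VoxelSet,
    prior,
    table: ScatteringTable,
    config: RefineConfig,
    n_steps: int,
    bfactors: np.ndarray | None = None,
    resolution_nm: float | None = None,
    record_stride: int = 50,
    mode: str = "atomistic",
) -> list[RefineState]:
    """Gibbs refinement: Langevin coordinate updates + periodic B-factor MC.

    The neighbor list (and the contact-pair graph of the B-factor prior) is
    refreshed every ``config.neighbor_stride`` coordinate steps; a B-factor
    Metropolis sweep runs every ``config.bf_mc_stride`` steps; states are
    recorded every ``record_stride`` steps (and at the last step).
    Deterministic given ``config.seed``.
    """
    if bfactors is None:
        if resolution_nm is None:
            raise ValueError("provide bfactors or resolution_nm")
        bfactors = init_bfactors(model, resolution_nm)
    bf = np.array(bfactors, dtype=np.float64)
    coords = np.array(model.coords, dtype=np.float64)
    predictor = MapPredictor(voxels, model, table, mode=mode, cutoff=config.neighbor_cutoff)
    pairs = contact_pairs(model.with_coords(coords), config.contact_cutoff)
    rng = config.rng(salt=101)
    trajectory: list[RefineState] = []

    def record(step: int) -> None:
        brk = hybrid_energy(predictor, bf, prior, config, pairs=pairs, with_forces=False)
        trajectory.append(
            RefineState(
                step=step,
                coords=coords.copy(),
                bfactors=bf.copy(),
                e_prior=brk.e_prior,
                e_cryoem=brk.e_cryoem,
                e_bf=brk.e_bf,
            )
        )

    for step in range(1, n_steps + 1):
        brk = hybrid_energy(predictor, bf, prior, config, pairs=pairs)
        if not np.isfinite(brk.total):
            raise RuntimeError(
                f"energy diverged at step {step}: prior={brk.e_prior} "
                f"cryoem={brk.e_cryoem} bf={brk.e_bf}"
            )
        coords = _langevin_step(coords, brk.forces, config, rng)
        if step % config.neighbor_stride == 0:
            predictor.rebuild(coords)
            pairs = contact_pairs(model.with_coords(coords), config.contact_cutoff)
        else:
            predictor.move(coords)
        if step % config.bf_mc_stride == 0:
            bf, _acc, _e = mc_bfactor_sweep(predictor, bf, pairs, config, rng)
        if step % record_stride == 0 or step == n_steps:
            record(step)
    return trajectory


def downhill_minimize(
    model: StructureModel,
    bfactors: np.ndarray,
    voxels: VoxelSet,
    prior,
    table: ScatteringTable,
    config: RefineConfig,
    max_iter: int = 500,
    tol: float = 1e-8,
    bf_stride: int = 100,
    bf_max_move: float = 10.0,
    mode: str = "atomistic",
) -> tuple[StructureModel, np.ndarray, list[float]]:
    """Downhill phase: gradient-based coordinate descent + greedy B-factor moves.

    Coordinates are minimized with L-BFGS in chunks of ``bf_stride``
    iterations; between chunks the neighbor list and contact pairs are
    refreshed and the B-factors are swept with maximum move ``bf_max_move``
    (Å², i.e. 0.1 nm²), accepting only downhill moves. The recorded energy
    sequence is non-increasing. Stops after ``max_iter`` coordinate
    iterations or when improvement falls below ``tol``.
    """
    from scipy.optimize import minimize

    coords = np.array(model.coords, dtype=np.float64)
    bf = np.array(bfactors, dtype=np.float64)
    predictor = MapPredictor(voxels, model, table, mode=mode, cutoff=config.neighbor_cutoff)
    rng = config.rng(salt=202)
    shape = coords.shape

    def refresh(c: np.ndarray) -> np.ndarray:
        predictor.rebuild(c)
        return contact_pairs(model.with_coords(c), config.contact_cutoff)

    pairs = refresh(coords)
    energy = hybrid_energy(predictor, bf, prior, config, pairs=pairs, with_forces=False).total
    trace = [energy]
    done = 0
    while done < max_iter:
        chunk = min(bf_stride, max_iter - done)

        def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
            predictor.move(x.reshape(shape))
            brk = hybrid_energy(predictor, bf, prior, config, pairs=pairs)
            return brk.total, -brk.forces.ravel()

        res = minimize(
            fun, coords.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": chunk, "ftol": tol, "gtol": 1e-10},
        )
        done += max(res.nit, 1)
        if res.fun <= energy:  # guard: keep the sequence non-increasing
            coords = res.x.reshape(shape)
            energy = float(res.fun)
        pairs = refresh(coords)
        trace.append(energy)
        # greedy (downhill-only) B-factor sweep at the protocol max move
        bf, _acc, _e = _sweep(
            predictor, bf, pairs, config, rng, max_move=bf_max_move, greedy=True
        )
        e_after = hybrid_energy(
            predictor, bf, prior, config, pairs=pairs, with_forces=False
        ).total
        energy = min(energy, e_after)
        trace.append(energy)
        if len(trace) > 4 and trace[-5] - trace[-1] < tol * max(1.0, abs(trace[-1])):
            break
    return model.with_coords(coords), bf, trace
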