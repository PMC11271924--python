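"""Metainference ensemble refinement: replica-averaged map restraints.

N_R copies of the system are evolved together; the forward prediction
entering the likelihood is the replica average f̄_i, so the ensemble — not
any single copy — is required to match the map. B-factors are held constant
(at the minimum residue B-factor of the single-structure refinement) so map
fuzziness is explained by conformational heterogeneity plus noise rather
than per-copy blurring. Each marginalized voxel restraint is counted once
per replica (an ``energy_multiplier`` of N_R, configurable to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .energy import RefineConfig, log_marginal_kernel, marginal_kernel_derivative
from .forward import MapPredictor
from .maps import VoxelSet
from .scattering import ScatteringTable
from .structure import StructureModel

__all__ = [
    "EnsembleTrajectory",
    "metainference_energy",
    "run_metainference",
    "ensemble_statistics",
]


@dataclass
class EnsembleTrajectory:
    """Recorded metainference frames.

    ``coords`` has shape (n_frames, n_replicas, n_atoms, 3); all replicas
    share the topology of ``model``; ``b_const`` is the constant per-residue
    B-factor (Å²) used for every prediction.
    """

    model: StructureModel
    coords: np.ndarray
    b_const: float
    record_stride: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 4:
            raise ValueError("coords must be (frames, replicas, atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_replicas(self) -> int:
        return self.coords.shape[1]

    def concatenated(self) -> np.ndarray:
        """All frames of all replicas as one (F·R, n_atoms, 3) ensemble."""
        f, r, n, _ = self.coords.shape
        return self.coords.reshape(f * r, n, 3)

    def bfactor_array(self) -> np.ndarray:
        return np.full(self.model.n_residues, self.b_const)


def _replica_predictors(
    models: list[StructureModel],
    voxels: VoxelSet,
    table: ScatteringTable,
    mode: str,
    cutoff: float,
) -> list[MapPredictor]:
    first = models[0]
    for m in models[1:]:
        if not m.same_topology(first):
            raise ValueError("replicas must share topology")
    return [MapPredictor(voxels, m, table, mode=mode, cutoff=cutoff) for m in models]


def metainference_energy(
    predictors: list[MapPredictor],
    b_const: float,
    config: RefineConfig,
    priors: list | None = None,
    energy_multiplier: float | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Replica-averaged hybrid energy and per-replica forces (k_B T units).

    E = Σ_r E_prior(X_r) + M · Σ_i E_marg(d_i − α f̄_i; σ_i^min) with
    f̄_i the replica mean prediction and M = N_R by default. Forces on
    replica r include the 1/N_R chain-rule factor through f̄_i.
    """
    n_rep = len(predictors)
    if n_rep < 1:
        raise ValueError("need at least one replica")
    voxels = predictors[0].voxels
    if voxels.noise_floors is None:
        raise ValueError("voxels must carry noise floors")
    mult = float(n_rep) if energy_multiplier is None else float(energy_multiplier)
    bf = np.full(predictors[0].model.n_residues, float(b_const))
    evals = [p.eval_pairs(bf) for p in predictors]
    f_bar = np.mean([p.values_to_map(v) for p, (v, _) in zip(predictors, evals)], axis=0)
    x = voxels.densities - config.scale * f_bar
    e_data = mult * float(-log_marginal_kernel(x, voxels.noise_floors).sum())
    total = e_data
    # ∂E/∂f̄_i, then 1/N_R into each replica
    dE_dx = marginal_kernel_derivative(x, voxels.noise_floors)
    w = mult * (-config.scale) * dE_dx / n_rep
    forces = []
    for r, p in enumerate(predictors):
        grad = p.force_from_coef(evals[r][1], w)
        f_r = -grad
        if priors is not None:
            prior = priors[r] if isinstance(priors, (list, tuple)) else priors
            total += float(prior.energy(p.coords))
            f_r = f_r + np.asarray(prior.forces(p.coords))
        forces.append(f_r)
    return total, forces


def run_metainference(
    starting_models: list[StructureModel],
    voxels: VoxelSet,
    prior,
    table: ScatteringTable,
    config: RefineConfig,
    n_steps: int,
    b_const: float,
    record_stride: int = 50,
    mode: str = "atomistic",
    energy_multiplier: float | None = None,
) -> EnsembleTrajectory:
    """Multi-replica Langevin sampling against the metainference energy.

    All replica predictions for a step are combined into f̄ before any
    replica advances (barrier semantics); B-factors stay at ``b_const``.
    Deterministic given ``config.seed``.
    """
    if len(starting_models) < 2:
        raise ValueError("metainference needs at least two replicas")
    predictors = _replica_predictors(
        starting_models, voxels, table, mode, config.neighbor_cutoff
    )
    n_rep = len(predictors)
    coords = [np.array(m.coords, dtype=np.float64) for m in starting_models]
    rng = config.rng(salt=303)
    frames: list[np.ndarray] = []
    priors = [prior] * n_rep
    for step in range(1, n_steps + 1):
        total, forces = metainference_energy(
            predictors, b_const, config, priors=priors,
            energy_multiplier=energy_multiplier,
        )
        if not np.isfinite(total):
            raise RuntimeError(f"metainference energy diverged at step {step}")
        for r in range(n_rep):
            drift = config.step_size * forces[r]
            norm = np.linalg.norm(drift, axis=1, keepdims=True)
            cap = config.max_displacement
            drift = np.where(
                norm > cap, drift * (cap / np.maximum(norm, 1e-300)), drift
            )
            noise = rng.standard_normal(coords[r].shape) * np.sqrt(
                2.0 * config.step_size * config.temperature
            )
            coords[r] = coords[r] + drift + noise
        if step % config.neighbor_stride == 0:
            for r in range(n_rep):
                predictors[r].rebuild(coords[r])
        else:
            for r in range(n_rep):
                predictors[r].move(coords[r])
        if step % record_stride == 0 or step == n_steps:
            frames.append(np.stack(coords))
    return EnsembleTrajectory(
        model=starting_models[0],
        coords=np.stack(frames),
        b_const=float(b_const),
        record_stride=record_stride,
    )


def ensemble_statistics(
    ensemble: EnsembleTrajectory,
    voxels: VoxelSet,
    table: ScatteringTable,
    state_defs: dict | None = None,
    mode: str = "atomistic",
) -> dict:
    """Average predicted map, per-residue MSF/RMSF and state populations.

    * average map: mean of the forward prediction at ``b_const`` over all
      concatenated frames, on ``voxels``;
    * MSF: per-residue mean squared deviation of the residue's atom centroid
      from its ensemble mean, with no superposition (frames share the map
      frame);
    * populations: for each classifier in ``state_defs`` (callable
      frame-coords → bool), the fraction of frames matched, with a Wilson
      95% interval.
    """
    frames = ensemble.concatenated()
    if len(frames) == 0:
        raise ValueError("empty ensemble")
    model = ensemble.model
    bf = ensemble.bfactor_array()
    predictor = MapPredictor(voxels, model, table, mode=mode)
    avg = np.zeros(len(voxels))
    for fr in frames:
        predictor.rebuild(fr)
        avg += predictor.predict(bf)
    avg /= len(frames)
    # per-residue centroids, (F, n_res, 3)
    n_res = model.n_residues
    cent = np.zeros((len(frames), n_res, 3))
    counts = np.bincount(model.residue_ordinal, minlength=n_res).astype(float)
    for i, fr in enumerate(frames):
        sums = np.zeros((n_res, 3))
        np.add.at(sums, model.residue_ordinal, fr)
        cent[i] = sums / counts[:, None]
    mean_cent = cent.mean(axis=0)
    msf = np.mean(np.sum((cent - mean_cent) ** 2, axis=2), axis=0)
    populations = {}
    if state_defs:
        n = len(frames)
        for name, classifier in state_defs.items():
            hits = sum(bool(classifier(fr)) for fr in frames)
            lo, hi = proportion_confint(hits, n, alpha=0.05, method="wilson")
            populations[name] = {
                "fraction": hits / n,
                "wilson_low": float(lo),
                "wilson_high": float(hi),
                "n_frames": n,
            }
    return {"average_map": avg, "msf": msf, "rmsf": np.sqrt(msf), "populations": populations}
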