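# Methods

This note documents the models implemented in `voxfit`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Posterior and hybrid energy

A model is a structure X with one B-factor per residue, b (Å²). Given the
densities d_i of N_V pre-filtered voxels, the posterior is

    p(X, b | D) ∝ ∏_i p(d_i | X, b) · p(b) · p(X),

and refinement samples or minimizes the hybrid energy E = −kT log p =
E_prior + E_cryoEM + E_bf. All energies in the package are expressed in
units of k_B T; the `temperature` configuration parameter only rescales
Monte-Carlo acceptance and Langevin noise.

### Forward model

The density an atom of type t contributes at distance r from a voxel center
is the Fourier pair of the 5-Gaussian electron scattering-factor fit
f(s) = Σ_k A_k exp(−B_k s²) (International Tables vol. C, 4.3.2.2), blurred
by the residue B-factor:

    ρ_t(r; b) = Σ_k A_k (4π / C_k)^{3/2} exp(−4π² r² / C_k),  C_k = B_k + b/4.

The (4π/C)^{3/2} prefactor makes ∫ρ d³r = Σ_k A_k for every b — blurring
conserves mass — and the test suite pins this by quadrature. Predictions sum
over non-hydrogen atoms, excluding the carboxylate oxygens of Glu/Asp (and
their protonated variants: the exclusion models beam damage to the chemical
group, not its protonation state), within a 10 Å atom-to-voxel-center
neighbor list. The coarse-grained mode is the same machinery with a
single-Gaussian (A, B) per bead type, keyed by the pseudo-atom name.

### Noise model and marginalization

Per-voxel noise is Gaussian with unknown width σ_i, bounded below by
σ_i^min = |d_i^A − d_i^B| / 2 from the half maps and given a Jeffreys prior
above the bound. Marginalizing σ_i analytically yields

    p(d_i | X, b) = erf(x / (√2 σ_i^min)) / (2x),   x = d_i − α f_i,

an even kernel with removable singularity at x = 0 (limit 1/(σ√2π));
for |x| < 1e−4 σ both the kernel and its derivative switch to their Taylor
expansions. The kernel's energy grows only logarithmically in |x|, so
high-noise voxels are automatically down-weighted rather than dominating the
fit. The identical kernel, with lower bound σ_bf^min = 10 Å² (0.1 nm²),
restrains B-factor differences of residue pairs with any interatomic
distance under 5 Å; each unordered pair is counted once. Because the kernel
is positive everywhere, the log never sees a non-positive argument.

The half-map difference estimator is one of several plausible readings of
"voxel-by-voxel variation"; it is unbiased for the magnitude of the full-map
error when half-map errors are independent, and it is exposed (with ε =
1e−6 × the peak of the averaged halves as a strictly positive floor) as the
single place noise floors are computed.

### Voxel pre-filtering

Correlated neighboring voxels would overcount the data. Selection keeps
voxels within 3.5 Å of any heavy atom, discards negative densities, and
sorts descending. The greedy sweep then visits survivors in density order;
around each keeper a cubic minibox of side 4 Å defines both the starting
voxels of the autocorrelation estimate and the candidate lags (all nonzero
integer displacement vectors with components within the minibox half-side).
The lag-ℓ autocorrelation is the Pearson correlation of minibox densities
against their ℓ-shifted values (lags with fewer than 8 valid in-map pairs
are treated as uncorrelated — small-sample Pearson is unstable); candidates
whose lag exceeds the threshold (default 0.8) are removed, never the keeper
itself. Threshold 1.0 is an exact no-op. On an i.i.d. white-noise map the
sweep removes (sampling error aside) nothing; smoothing the same map
strictly increases removal — both are acceptance checks.

### Scale factor

The global scale α between predicted and observed maps is scanned on a grid
(default 0.5–1.5, step 0.05). For each α the B-factors of each sample state
are re-optimized by Metropolis MC (move ≤ 5 Å²) and the lowest hybrid energy
seen per sample is recorded; the α minimizing the summed lowest energies
wins. On fixtures generated with d = α_true·f + noise the scan returns
α_true exactly on-grid.

## Sampling

### Gibbs refinement

Coordinates are updated with overdamped Langevin dynamics (Euler–Maruyama:
drift `step_size`·F clamped at `max_displacement` per step, noise
√(2·step_size·T)), a desk-scale, prior-agnostic stand-in for molecular
dynamics. Every `bf_mc_stride` steps (default 500) a Metropolis sweep
proposes per-residue B-factor moves uniform in ±5 Å², reflected at zero (the
boundary rule is this package's choice); the sweep maintains the predicted
map incrementally per residue, so a sweep costs O(residue neighborhood)
rather than O(N_V). The neighbor list and the contact-pair graph refresh
every `neighbor_stride` steps (default 50). Everything is driven by one
seed; equal seeds give bit-identical trajectories.

### Downhill phase

The final model minimizes the hybrid energy: L-BFGS on coordinates in chunks
of 100 iterations, interleaved with greedy (downhill-only) B-factor sweeps
with moves ≤ 10 Å² (0.1 nm²), neighbor structures refreshed between chunks.
The recorded energy sequence is non-increasing by construction; an
already-minimal state is a fixed point up to the line-search tolerance.

### B-factor initialization

B-factors start from the empirical resolution relation b(nm²) =
6.95408·res² − 0.01·2.45697 (res in nm), floored at zero and applied
uniformly; internally everything is Å² (1 nm² = 100 Å²).

### Metainference ensembles

N_R replicas evolve against a likelihood evaluated at the replica-averaged
prediction f̄_i, with constant per-residue B-factor b_min (the blurring a
single structure would need is instead carried by the spread of replicas).
Each replica's σ_i is marginalized exactly as in the single-structure case,
so each replica feels the (marginal) restraint once and the data term
carries an N_R multiplier; whether the reference treatment scales by N_R or
by 1 is not determined by the published description, so the multiplier is a
configuration switch with N_R as default. All replica predictions of a step
are combined before any replica moves. With one replica and B-factor
sampling re-enabled the machinery reduces exactly to single-structure
refinement (a regression test).

## Synthetic fixtures

The generator builds ideal-geometry polyalanine backbones (N, CA, C, O, CB;
helix, strand, or a two-state pair differing by a rigid 30° hinge at the
midpoint residue), with a small seeded jitter so fixtures differ across
seeds but are identical for equal seeds. Maps are d = α_true · Σ_m w_m f_m
on a padded grid plus i.i.d. Gaussian voxel noise; each half map carries
independent noise of twice the variance, so averaging halves matches the
full map's noise in expectation and |ΔAB|/2 has an analytic distribution
for testing the floor estimator. The elastic-network prior (springs between
all reference atom pairs within a cutoff; optionally restricted to residue
groups, e.g. the two rigid bodies of the hinge) stands in for a molecular
force field: it preserves topology and local geometry but has none of a
force field's chemistry, so passing recovery tests demonstrates the
inference machinery, not chemical realism. Fixtures also lack CTF effects,
anisotropic noise, and solvent contributions.

## Benchmark studies and their problem sizes

The studies in `voxfit.benchmarks` fix the conditions; only the seed varies.

* **B-factor recovery** — 20-residue helix, true B-factors 15–80 Å²
  (shuffled), 2% voxel noise; 600 MC sweeps at the true coordinates; scored
  by Pearson r (> 0.9) of the lowest-energy set against truth.
* **Scale recovery** — α_true = 0.8, 1% noise, 10 residues; exact on-grid
  recovery expected.
* **Coordinate recovery** — a 10-residue helix misplaced by ≈1 Å (rigid
  rotation + translation + 0.15 Å jitter — the realistic "initial model
  that already fits the density" scenario; independent per-atom 1 Å
  displacements would wreck stereochemistry, which no starting model has).
  The map is noiseless with a uniform likelihood width of 2% of peak (a
  noiseless half-map pair would give ε floors, making the landscape
  needle-sharp and scoring only numerics, not inference). The
  elastic-network prior is built on the *perturbed* start — being
  rigid-motion invariant it does not bias toward the start, but it forbids
  the atom-identity swaps that make the data-only landscape degenerate.
  Short Gibbs, downhill, then a second downhill round with the network
  rebuilt on the refined model (removing the residual bias of the start's
  jittered spring lengths); final RMSD < 0.2 Å.
* **Two-state populations** — 16-residue hinge fixture mixed 50/50 or
  70/30, 2% noise, hinge-free elastic network, N_R = 10, b_const = 30 Å².
  Spontaneous hinge crossings under plain Langevin are too rare to
  re-equilibrate the discrete replica split within desk-scale runs (the
  collective arm coordinate diffuses ∝ 1/√N_atoms), so the study first
  optimizes the discrete assignment exhaustively — the metainference energy
  of every (k at A, N_R−k at B) split — and then samples 1200 Langevin
  steps from the minimum. Recovery is falsifiable at both stages: it fails
  if the replica-averaged likelihood does not rank the true mixture lowest,
  or if sampling drifts off it. Populations are counted over the second
  half of the run by nearest-state assignment of the hinge arm. The
  ensemble-averaged map's CC_mask (mask built from the single state A only)
  must meet or beat the single-state CC_mask.
* **Noise vs heterogeneity** — single-state 12-residue fixture at 2% and
  6% noise, floors from matching half maps, N_R = 6, 800 steps. Tripling
  pure noise must not manufacture heterogeneity: the median per-residue MSF
  may grow only marginally (well under 0.3 Å², i.e. ≲10% of the ≈3 Å²
  signal a genuine 50/50 two-state hinge produces), because the enlarged
  noise floors soften the restraint instead of moving atoms.
* **Coarse-grained fit** — the grid scan (A 0–8 step 0.1; B 0–40 Å² step
  0.5; 19³ = 6859 voxels in a 6 Å cube centered on the bead) recovers an
  on-grid single-Gaussian target exactly. Fitting raw (b = 0) profiles
  chases the sharp core of the scattering factor and does not preserve the
  integral; under a representative blur of 40 Å² — coarse-grained maps are
  always B-factor-smoothed in use — the carbon fit conserves integrated
  density within 10%. The shipped bead table is fitted at that blur from
  the package's own polyalanine fixtures and is synthetic: it covers the
  backbone (BB) and side-chain (SC1) beads the fixtures use, not any
  published parameter set. Backbone groups have total weight ≈9.7 > the A
  grid's cap of 8, so their fit saturates the grid corner; this is a
  property of the printed scan range, kept as-is.

Problem sizes (residue counts, step counts, replica counts) were chosen so
the full suite and the reproduction script each complete in minutes on a
single CPU while leaving clear margins on every recovery threshold.

## Numerical choices

* Series switch at |x| = 1e−4 σ for the marginal kernel and its derivative.
* Neighbor-list cutoff 10 Å by default; the Gaussian kernels decay with
  length ≈1.2 Å, so ensemble studies use 6 Å (error < 1e−6 relative) for
  speed. Cutoff adequacy is tested against the all-pairs sum.
* Langevin step 1e−4 Å²/kT with a 0.02 Å/step drift clamp by default; the
  ensemble studies use 2e−3 and 0.08 Å (the hinge arm must travel ≈3.6 Å).
* B-factor proposals reflect at zero; contact pairs refresh with the
  neighbor list; grid-scan ties break toward smaller B then smaller A.
* CC_mask uses a uniform 3.5 Å masking radius (per-element radii are not
  reproduced here; the radius is configurable) and no isotropic B-factor
  fitting before correlation.
* Voxel-list files store full `repr` precision, so IO round-trips are exact.

## Known limitations

* The elastic-network prior cannot assess stereochemical quality; clash or
  rotamer metrics are out of scope.
* The altloc policy (highest occupancy, ties to 'A') discards minor input
  conformers; alternates are meant to be modeled by ensembles instead.
* Ion scattering uses neutral-atom factors.
* The pre-filter assumes an approximately stationary local autocorrelation;
  strongly anisotropic local resolution violates this quietly.
* Population recovery was validated on a two-basin fixture; many-state or
  continuous heterogeneity has no discrete assignment stage to lean on.
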