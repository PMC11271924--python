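# voxfit

Bayesian single-structure and ensemble refinement against cryo-EM density
maps, with explicit treatment of data correlation and noise.

Refining an atomic model against a cryo-EM map means balancing two sources
of information — the experimental density and prior physico-chemical
knowledge — without overfitting noise or discarding genuine heterogeneity.
`voxfit` implements a Bayesian framework for this problem:

* a **Gaussian forward model**: the density atom *j* contributes at voxel
  center *V_i* is ρ(r) = Σ_k A_k (4π/(B_k + b/4))^{3/2} exp(−4π² r²/(B_k + b/4)),
  the Fourier pair of the 5-Gaussian electron scattering-factor fit, blurred
  by a per-residue B-factor *b* (Å²) that is *inferred*, not fixed;
* a **marginalized noise model**: per-voxel noise widths σ_i carry a
  Jeffreys prior bounded below by the half-map difference
  σ_i^min = |d_i^A − d_i^B|/2 and are integrated out analytically, giving the
  heavy-tailed likelihood p(d_i|X,b) = erf(x/(√2 σ_i^min))/(2x) with
  x = d_i − α f_i(X,b) — outlier voxels down-weight themselves;
* **voxel pre-filtering**: a greedy sweep in descending density removes
  voxels whose spatial autocorrelation with an already-kept neighbor exceeds
  a threshold (default Pearson 0.8), so the likelihood counts only
  approximately independent data points;
* **Gibbs refinement**: Langevin dynamics on coordinates against the hybrid
  energy E = E_prior + E_cryoEM + E_bf (with a pluggable structural prior),
  interleaved with Metropolis Monte-Carlo sweeps of the residue B-factors,
  followed by a strictly downhill minimization;
* **metainference ensembles**: N_R replicas restrained through their
  *average* predicted map at constant B-factor, turning fuzzy density into
  populations of distinct conformations instead of inflated B-factors;
* **validation metrics**: global CC_mask (for models and ensembles) and
  per-residue local CC / noise via nearest-atom Voronoi assignment.

Everything is exercised end-to-end on synthetic fixtures with known ground
truth (toy polyalanine structures, simulated maps and half maps, a
two-state hinge mixture), generated by the package itself — no downloads.

## Worked example

Recover the populations of a conformational mixture
(`examples/ensemble_two_state.py`): the map averages two hinge conformations
of a 16-residue helix with weights 70/30 plus 2% voxel noise; ten
metainference replicas must divide themselves between the states so that
their mean prediction matches the map.

```text
true major population:      70%
energy-optimal assignment:  70% of replicas at A
recovered from trajectory:  70.0% (95% CI 64–75%)
CC_mask single structure:   0.945
CC_mask ensemble average:   0.978
```

The replica-averaged likelihood ranks the true 7:3 split lowest among all
eleven possible assignments, sampling holds it there, and the
ensemble-averaged map fits the data better than the best single conformer —
the signature that the fuzzy density was heterogeneity, not noise.

The other examples each run in seconds to minutes and print what they
compute: `forward_model.py` (mass conservation under B-factor blurring),
`prefilter_and_noise.py` (voxel selection, decorrelation, noise floors),
`single_structure_refinement.py` (scale-factor recovery and sub-0.2 Å
coordinate recovery from a ~1 Å misplacement), `cg_bead_fit.py`
(single-Gaussian coarse-grained bead parameterization by grid scan).

A thin CLI wraps the same library calls:

```sh
voxfit synth --kind helix --n 20 --noise 0.02 --seed 1 --out fixture/
voxfit prefilter --map fixture/map.mrc --halfmap1 fixture/half_a.mrc \
    --halfmap2 fixture/half_b.mrc --model fixture/model.pdb --out voxels.txt
voxfit refine --model fixture/model.pdb --voxels voxels.txt --out refined.pdb
voxfit pipeline --config config.yaml --out run/      # full protocol, resumable
```

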