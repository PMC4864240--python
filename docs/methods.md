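# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each analysis stage, and what the synthetic-data
generators do and do not emulate.

## Competitive fluorescence binding

### Saturation titration

A 2 μM CSP solution titrated with the fluorescent probe 1-NPN over
2–30 μM follows the one-site model *I* = *B*max·*c*/(*K* + *c*), with
*c* the probe concentration (μM), *B*max the saturating intensity (AU)
and *K* the probe dissociation constant *K*₁-NPN (μM).  Two estimators
are provided:

* **nonlinear** — least squares on the hyperbola
  (`scipy.optimize.curve_fit`, initialized at *B*max = max intensity,
  *K* = median concentration, both bounded positive);
* **scatchard** — linear regression of bound/free (*I*/*c*) on bound
  (*I*); the slope is −1/*K* and the intercept *B*max/*K*.

On noiseless one-site data both are exact and agree; under multiplicative
noise the nonlinear fit is preferred (Scatchard division by *c* reweights
errors) and is the pipeline default.  Degenerate inputs — constant
intensity, non-negative Scatchard slope, non-convergence, non-positive
estimates — raise `FitError` rather than returning a number.

The titration uses total probe concentration as the abscissa; depletion
of free probe by the 2 μM protein is not modeled (see Limitations).

### Competition curves and Ki

Displacement data are percentages of the zero-competitor fluorescence.
The generating/fitting model is the one-site competition form

    percent(L) = 100 · (P + K) / (P + K · (1 + L/Ki)),

with *P* the probe concentration and *K* = *K*₁-NPN.  Its
half-displacement point is exactly *L*₅₀ = *Ki*·(1 + *P*/*K*), which is
why the classic occupancy correction

    Ki = IC50 / (1 + P / K)

inverts it without approximation.

IC₅₀ is estimated by fitting a logistic in log₁₀ concentration,
`bottom + (top − bottom)/(1 + (L/IC50)^hill)`:

* **top is fixed at 100**: the normalization *defines* the zero-competitor
  plateau as 100%, and the assay's lowest measured competitor
  concentration (2 μM) can already displace appreciably, so estimating
  the plateau from the lowest-concentration readings would bias IC₅₀
  downward whenever IC₅₀ is within an order of magnitude of that
  concentration.  Fixing top at its definitional value makes noiseless
  recovery exact and roughly halves the estimator's spread on short
  (5–8 point) curves; `top=None` restores a free plateau in [80, 120]
  for data whose normalization is suspect.
* bottom is bounded in [0, 50] (a competitive binder displaces fully at
  infinite concentration; values above 50 would put the midpoint outside
  the data's meaning), Hill slope bounded [0.2, 5], initialized at 1
  (one-site competition has hill = 1).
* the log-IC₅₀ start value comes from interpolating the curve's midpoint
  crossing.

When the sigmoid fit fails but the data bracket 50%, IC₅₀ falls back to
log-linear interpolation between the bracketing points (a reading at
exactly 50% takes the lower concentration; a bracket starting at 0 μM
interpolates linearly since log 0 is undefined).

**Reporting rules.**  Fitted IC₅₀ > 100 μM (configurable), or data that
never reach 50%, give status `undetermined` — rendered "u.d." in the
affinity table, with no Ki computed.  Curves with no net displacement
(last reading ≥ first) are `failed`.  Ki is only reported for
`determined` fits.

**Free vs total probe.**  The occupancy correction formally uses the
*free* 1-NPN concentration, which is never directly observed.  The
package uses the total concentration (2 μM), the only value available
from the protocol; back-calculation shows this shifts Ki by roughly
1–3% relative to constants derived from free-probe estimates.  The
acceptance script's outputs carry exactly this residual.

## Ensemble-docking consensus

Inputs are poses — predicted binding free energy ΔG (kcal/mol) plus
ligand heavy-atom coordinates (Å) — across an ensemble of receptor
models sharing one reference frame.

* **RMSD without superposition.**  Poses are compared by plain
  heavy-atom RMSD; superposing would erase exactly the binding-site
  placement differences the clustering is meant to detect.  Atom count
  and order must match across the ensemble.
* **Leader clustering.**  Poses are visited by ascending energy (ties
  broken by model id then pose index); each unassigned pose seeds a
  cluster and absorbs every unassigned pose within the cutoff (default
  2.0 Å, the common docking-pose clustering convention; configurable).
  The procedure is deterministic, assigns every pose exactly once, and
  guarantees that members lie within the cutoff of their representative
  and representatives lie pairwise farther apart than the cutoff.
* **Cluster population is counted in distinct models**, because the
  free/bound bookkeeping is per receptor model; counting raw poses is
  available as a switch (`by_models=False`).  Ties between equally
  populated clusters break by lower mean member energy, then lower
  representative energy, making the selection order-invariant.
* **Energy aggregation** takes the best (lowest) energy per represented
  model, then the mean and sample standard deviation over those
  per-model values — models contributing many near-duplicate poses do
  not dominate.  A single-model cluster has sd 0.
* **Kd = exp(ΔG/RT)** with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and
  T = 300 K (configurable); computed in mol/L, reported in μM.
* **Occupancy weighting**: weighted Kd = Kd · *free*/*bound* with
  *bound* = models represented in the consensus cluster and *free* the
  rest.  When *free* = 0 the literal weight would give an unphysical
  zero, so the weight is taken as 1 and the result flagged
  `degenerate`.  The weighting is the literal free/bound reading; a
  (free+bound)/bound normalization would differ by a factor
  *n*/*bound*.

Predicted Kd values from real docking depend on the modeling and docking
engines that produced the pose tables; this package aggregates such
tables but does not reproduce engine output.

## Relative expression (2^−ΔΔCt)

Replicate Ct values are averaged per sample × gene before differencing
(the standard comparative-Ct convention; per-replicate pairing is not
implemented).  ΔCt = mean Ct(target) − mean Ct(reference);
ΔΔCt subtracts the calibrator's ΔCt, making the calibrator's fold
exactly 1 by construction; fold = 2^−ΔΔCt.

Uncertainty: sd(ΔCt) = √(sd²target + sd²reference) from replicate
scatter; the fold range is reported as [2^−(ΔΔCt+sd), 2^−(ΔΔCt−sd)]
and a delta-method sd (fold·ln2·sd) accompanies it.  The calibrator is
treated as a fixed reference point, and technical and biological
replicates are treated as exchangeable — the data carry no structure to
distinguish them.  Downstream significance grouping (ANOVA letters) is
out of scope; the summary table (per-group mean, sd, n) is the hand-off
point.

## Synthetic data generators

Each generator is a bit-exact function of its config, seed included,
and is inverted by its analysis stage exactly at zero noise — that
round trip is the backbone of the test suite.

* **Saturation**: 15 points (default) on [2, 30] μM, multiplicative
  Gaussian noise (`I·(1+ε)`) matching the relative character of
  fluorescence instrument error; default 0.
* **Competition**: 8 log-spaced points on [2, 50] μM (the bench
  protocol's competitor range; widen `conc_max` to bracket weak
  binders), same multiplicative noise, percentages clipped to [0, 120].
* **Pose ensembles**: ⌈occupancy·*n*⌉ randomly chosen models get a pose
  jittered at most cutoff/2 (RMSD) around one reference geometry with
  energies Normal(mean, sd); the rest get decoys rigidly translated
  3.5–6.5× the cutoff away (≥ 3× after their own jitter) with energies
  offset +2 kcal/mol.  Decoy separation makes planted-cluster recovery
  well-defined at small *n*; real docking decoys can sit arbitrarily
  close to the true mode.
* **Ct tables**: the housekeeping reference sits at its baseline (it is
  the assay's invariant control); the target gene sits
  ΔCt(calibrator) − log₂(fold) cycles relative to it with additive
  Gaussian cycle noise (default 0.2 cycles when enabled, a typical
  qPCR replicate scatter).

What passing tests show — and do not.  The generators realize exactly
the models the estimators assume, so round-trip tests validate the
estimators' correctness and noise robustness, not their robustness to
model violations in real data: inner-filter effects and quenching in
fluorescence, multi-site binding, probe depletion, docking decoys near
the true mode, primer-efficiency differences in qPCR are all outside
the generated data and outside the estimators' assumptions alike.

## Problem sizes and tolerances

Noise-robustness checks use 100-seed medians (binding: 2% relative
noise; expression: 0.2 cycles, triplicates) and 200-seed ensembles of
100 models for planted-cluster recovery — sizes at which the medians
are stable to re-seeding.  Exact identities (energy↔Kd round trip,
weighting arithmetic) are asserted to 1e-12 relative; fitted quantities
to tolerances reflecting their estimator spread (noiseless fits 1e-4
or better; noisy medians 5–10%).

## Known limitations

* No spectral processing: inputs are per-concentration intensities, not
  350–500 nm emission scans.
* No quencher/inner-filter corrections; one-site models only.
* The IC₅₀ → Ki conversion uses total probe concentration (above).
* Pose tables must share a receptor frame; the package does not parse
  PDB/PDBQT or run modeling/docking engines.
* qPCR analysis assumes perfect (2-fold per cycle) amplification
  efficiency for both genes.
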