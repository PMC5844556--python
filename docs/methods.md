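# Methods

`cbscaffold` places assembled contigs on a densely labeled optical DNA map
(a competitive-binding barcode) without overlap, and reports calibrated
significance for every placement. This note records the models, the
defaults and the design choices, in the order the pipeline runs them.

## 1. Competitive-binding barcode theory

A stretched DNA molecule stained with a mixture of YOYO-1 (fluorescent
intercalator) and netropsin (non-fluorescent, strongly AT-specific
minor-groove binder) emits light where YOYO wins the competition, i.e. in
GC-rich regions. We model the stain equilibrium as a grand-canonical
two-species lattice gas: a bound ligand of species *s* occupies
`footprint_s` consecutive basepairs and carries statistical weight
`K_s(site) · c_free_s`; ligands exclude each other and there is no
cooperativity. YOYO has a single sequence-independent constant
(`K_yoyo = 26 /uM`); netropsin's constant is looked up per 4-mer, with a
4-mer and its reverse complement sharing a constant (a minor-groove binder
cannot distinguish strands). Both footprints default to 4 bp, matching the
4-mer parameterization of the constants.

Per-basepair YOYO coverage probabilities are exact equilibrium marginals
of this model, computed by the standard forward/backward partition-function
recursion (transfer matrix) in log space. Linear molecules use free ends
(no protruding ligand); circular molecules are solved exactly by
conditioning on the bond between the last and first basepair (one linear
solve per possible boundary-crossing ligand). The recursion is
cross-checked in the tests against exhaustive enumeration of all ligand
configurations on small lattices (agreement to 1e-10).

**Free concentrations.** Experiments fix total concentrations; the model
needs free ones. We solve the two-ligand mass balance
`c_total = c_free + c_dna · n_bound(c_free) / L` by a damped fixed-point
iteration on the relative residuals (tolerance 1e-9, max 200 iterations,
bounded least-squares fallback), which converges in ~10 iterations at
assay-typical occupancies.

**Defaults.** The bundled netropsin table is synthetic: AT-content graded
from 0.1 to ~100 /uM with a 1.5x bonus when both central positions are
A/T and deterministic lognormal scatter per symmetric 4-mer class. It has
realistic magnitudes and produces strong AT/GC contrast, but it is a
stand-in — replace it with a measured table for real data. Total
concentrations default to `c_dna = 0.2 uM(bp)`, `c_yoyo = 0.02 uM` (one
dye per ten basepairs) and `c_netropsin = 6 uM` (large netropsin excess),
within the ranges typical of competitive-binding mapping assays.

**Optics.** The coverage profile is convolved with a Gaussian point
spread function of `sigma = 1000 bp` (the experimental resolution is
about 1 kbp); circular profiles wrap, linear profiles renormalize the
kernel mass at the molecule ends. The smoothed profile is then linearly
interpolated at pixel centers (block averaging is available as an option)
at `bp_per_px = 500`. The pixel scale is an instrument property and is
configurable; 500 bp/px keeps a 220 kbp plasmid at ~440 px.

## 2. Match scores

A contig barcode of *m* pixels is slid along the circular reference
barcode (`x_max` pixels): for every start pixel and both orientations, a
Pearson correlation with the wrap-around window of equal length is
computed, giving `2·x_max` scores per contig. Scores are computed at
integer pixel offsets only; local stretching and sub-pixel alignment are
out of scope. Zero-variance windows or contigs score 0 (with a warning)
so the score table stays total; such positions can never produce a bid.
Ties in the best match break to the smallest start pixel, forward before
flipped, so every downstream result is deterministic.

## 3. p-values from a random-barcode null

The best score of a contig is a maximum over ~2·x_max correlated
comparisons, so its null distribution must be estimated. For each
distinct contig length (in pixels) we generate `R = 1000` random barcodes
matched to the contig's lag-1 autocorrelation — stationary AR(1) Gaussian
processes by default; Gaussian-filtered white noise is available behind
the same interface — match them against the same reference, and fit the
family

    F(c) = G(c; nu_eff) ^ n_eff

by maximum likelihood, where `G` is the null CDF of a single Pearson
coefficient from `nu_eff` effective samples (`(1+c)/2 ~ Beta(a, a)` with
`a = (nu_eff - 2)/2`) and `n_eff` is an effective number of independent
comparisons. Both parameters are *effective* because pixels are
correlated; the fit recovers them from the simulated maxima. A Gumbel
baseline is fitted alongside and the log-likelihoods recorded; on our
simulations the beta-power family fits better, and unlike the Gumbel it
respects the hard support boundary at c = 1. p-values are the closed-form
upper tail `p = 1 - F(c)`; below 1e-12 the log-p is computed directly in
log space so the Fisher transform `-2 ln p` never underflows. Fits are
cached per (length_px, autocorrelation rounded to 2 decimals); the null
RNG substream is derived deterministically from the master seed and the
cache key, so a cache entry does not depend on which contig triggered it.

Calibration is tested two ways: fresh random barcodes from the generator
reach `P(p < alpha) ≈ alpha` at alpha = 0.01 and 0.05, and — the stricter
check — theory barcodes of *unrelated random sequences* pass the 0.01
threshold at a rate statistically compatible with 1%.

**Length threshold.** Barcodes shorter than a few PSF widths carry almost
no spatial information and their null fit degrades, so contigs shorter
than `l_thresh = 12·sigma ≈ 12 kbp` are excluded before step 3.

## 4. Placement as an interval-bidding auction

Significant positions (`p < p_thresh = 0.01`, strict) become bids with
score `b = -2 ln p` (natural log; a Fisher-method-style transform that is
positive by construction). Non-significant positions produce no bid. The
winner determination problem — maximize the summed score with each pixel
sold at most once and each contig winning at most one interval — is
solved *exactly* by a dynamic program over bid end pixels whose state is
a bitmask over the currently relevant bidders. Pixels with no ending bid
cost nothing, and a bidder's bit is projected out of all states as soon
as its last bid has passed, so the mask width tracks local bid density
(cost `A·B²·2^C` with C the maximal concurrent relevant-bidder count,
reported per instance). If C exceeds a configurable guard (default 25)
the solver raises an explicit error rather than degrade to a heuristic.
Circularity is handled by conditioning on the cut between pixel `x_max`
and pixel 1: since any two wrap-around intervals overlap at pixel 1, it
suffices to solve one linear instance with no crossing bid plus one per
crossing bid. Equal-score optima break ties to the lexicographically
smallest (bidder, x_end, orientation) set. The solver is cross-validated
against an independent branch-and-bound enumeration on hundreds of random
instances.

## 5. Synthetic data and what it does (not) emulate

The generators reproduce the published simulation protocols at desk
scale. Random genomes are i.i.d. with adjustable GC content. Cut plans
draw inter-cut distances from an exponential truncated (censored) at the
genome length — a draw past the end produces no further cut, so a mean
near the genome length often leaves a single full-length contig — with a
uniform random origin on circular genomes, randomized per-contig
orientation, and an exact truth table; the default mean fragment length
is 24.5 kbp, the mean contig size observed in real mixed-sample Illumina
assemblies. Pseudo-experimental reference barcodes are the theory barcode
plus additive stationary correlated Gaussian noise, z-normalized:
`noise_sd = 0.3` (in normalized-barcode units) and lag-1 autocorrelation
0.9, chosen because the microscope PSF (sigma ≈ 2 px) smooths optical
noise to roughly its own width.

This emulates the *amplitude and smoothness* of consensus-barcode noise
but not its real structure: stretch-factor variability, bleaching
gradients, molecule-to-molecule alignment error and systematic
theory/experiment mismatch are all absent. Passing the calibration
simulations therefore shows the statistical machinery is self-consistent
under a plausible noise model, not that the chosen constants reproduce
any particular instrument.

## 6. Simulation study sizes

The bundled studies (shared by the tests and `scripts/acceptance.py`) use:

* p-value calibration — one 138 kbp circular genome, 250 contigs each of
  20/30/40 kbp, independent placement (no auction), ~750 placements;
* pure-sample scaffolding — one 220 kbp circular genome, mean contig
  sizes 10/24.5/40/80 kbp, 30 cut-plan replicates each, full pipeline;
* foreign rejection — a 2 Mbp unrelated genome cut at means 10–45 kbp
  (5 means x 6 replicates) and attempted on the 220 kbp stand-in
  reference (steps 1–3 only).

These sizes keep each study in the minutes range on one CPU while leaving
binomial errors small enough to resolve the 1%-scale rates being checked.

## 7. Numerical choices and degenerate inputs

* Partition-function recursions run in log space; probabilities are exact
  marginals, clipped only against 1e-12-scale roundoff.
* Pearson scores clip to [-1, 1]; zero-variance windows score 0.
* The null MLE starts from a 5x5 coarse grid and refines by Nelder-Mead
  in log-parameter space with bounds nu_eff > 3, n_eff >= 1.
* Sequences containing ambiguity codes are rejected at construction;
  resolve them upstream (the policy hook is deliberate: silently
  resampling N's would perturb the barcode).
* Linear sequences shorter than one ligand footprint, empty barcodes and
  contigs longer than the reference raise immediately with stage-tagged
  messages.
* All randomness flows from one master seed through SHA-256-derived
  substreams, so every report is bit-reproducible.

## Known limitations

* The binding model ignores cooperativity, YOYO sequence preference
  beyond competition, and partial intercalation at molecule ends.
* The AR(1) null matches only the lag-1 autocorrelation of a contig
  barcode; heavier long-range structure (e.g. repeats) would make the
  p-values anti-conservative. The mid-distribution of foreign-contig
  p-values is visibly non-uniform; only the decision tail near
  p_thresh is calibrated, which is what placement uses.
* Integer-pixel matching bounds placement accuracy at +-1 px before the
  5 px correctness tolerance even in the noise-free limit.
* The auction guard refuses pathologically entangled instances instead
  of solving them approximately; such instances did not occur in any
  simulation performed here.
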