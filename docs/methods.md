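# Methods

This note documents the models implemented in `sifted`, the parameter
choices and their rationale, the scope of the synthetic data used for
validation, and known limitations. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate conventions

A TALE protein is a sequence of repeat variable diresidues (RVDs). The
canonical code is NI→A, HD→C, NN→G, NG→T. The N-terminal region (NTR)
contacts a 5′ T, treated as site position 0; repeat *k* contacts position
*k*. The final, truncated half-repeat counts 0.5 toward the nominal repeat
number but contacts a full base, so a protein with *n* repeat elements has
`nominal_length = n − 0.5` and targets a site of `n + 1` bases.

An **energy matrix** (EM) is an `(L, 4)` table of ΔΔG values in RT units,
base order A, C, G, T. A site's total energy is the sum of its per-position
entries. EMs are *anchored*: the canonical-code base of each column is the
zero reference, so `relative Kd = exp(ΔΔG)` is relative to the canonical
site. Because only within-column differences are physical, per-column shifts
are a gauge freedom; `normalize_em` re-anchors and the Boltzmann PWM
(`p ∝ exp(−ΔΔG)` per column) is shift-invariant. Both invariances are
asserted in the acceptance suite.

## PBM quantification

Raw input is a table of per-spot background-subtracted intensities (BSI) in
two channels (Alexa = protein, Cy3 = dsDNA), replicate spots per probe, and
a foreground/background role per probe.

- **Pseudocount.** Each channel is shifted so its minimum is +1, preserving
  ordering and gaps while making all values positive.
- **Cy3 correction.** Observed Cy3 medians are regressed (ordinary least
  squares, minimum-norm solution) on the probe's 64 trinucleotide counts.
  The design is rank-deficient by construction (counts sum to
  `len(seq) − 2`), but fitted values are unique. The per-probe factor
  `f = expected / observed` multiplies the Alexa replicates, correcting for
  per-spot dsDNA abundance; probes with `f > 2`, `f < 0.5` or negative
  adjusted intensities are removed (strict inequalities; the boundary
  behaviour is pinned by tests). At least 64 Cy3-bearing probes are required
  for identifiability.
- **Replicate aggregation.** Median with a 3-robust-SD filter, where
  `robust_sd = 1.4826 × MAD`. When MAD is zero, the default (`"strict"`)
  keeps only replicates equal to the median: the plain-SD fallback is
  provably vacuous at this scale (for n replicates, max |z| = (n−1)/√n < 3
  for n ≤ 9), so it would silently keep contaminated replicates. A `"sd"`
  mode provides the fallback behaviour when wanted.
- **Z-scores.** Foreground medians are centred and scaled by the median and
  robust SD of the background probe medians (≥ 20 background probes
  required). Z-scores are therefore invariant to positive affine intensity
  transforms, which the downstream occupancy model's `a`, `b` parameters
  absorb anyway.

## Occupancy model and ΔΔG inference

Site occupancy follows a Fermi/logistic function of site energy:
`occ = 1 / (1 + exp(E − μ))`, with chemical potential `μ = ln([TF]/Kd_opt)`.
The measured z-score is modelled as `z = a + (b − a)·occ + ε`,
`ε ~ Normal(0, σ)` — `a` the unbound level, `b` the saturated level.

Priors: each ΔΔG has a shifted-exponential prior with mean 10 RT and floor
−2 RT (weakly informative, disfavouring unphysically favourable mismatches;
optionally floored at 0 via `truncate_at_zero`); `μ`, `a`, `b` are uniform;
`σ` is half-Cauchy(5). Initial point: ΔΔG = 3 RT, `μ = −1`,
`a = min z`, `b = max z`.

Two inference paths share the same log posterior:

- **MAP + Laplace** (`method="map"`): L-BFGS-B with the analytic gradient;
  credible intervals from the inverse Hessian (finite differences of the
  gradient). The posterior is multimodal — a degenerate "saturated" mode
  with `μ` at its bound and flat predictions can trap the optimiser, and a
  too-small initial σ makes the first line search overshoot into it — so the
  optimiser multi-starts over `μ0 ∈ {−3, −1, 1, 3, 6}` crossed with initial
  σ at 5% and 25% of the z-range, keeping the best optimum.
- **MCMC** (`method="mcmc"`): affine-invariant ensemble sampling (emcee),
  run as 4 independent ensembles initialised around the MAP point so that
  split Gelman–Rubin R̂ can be computed per parameter across ensembles.
  Convergence is flagged at R̂ < 1.05. The affine-invariant sampler replaces
  a per-parameter random-walk Metropolis sampler because it is the
  established, dependency-supported choice for correlated posteriors; the
  inferential target is identical.

Fitting requires every site position to be covered by at least one variant
probe (a missing position is reported by index), and the scaling-only helper
`fit_scaling` (Levenberg–Marquardt on `μ, a, b` with the EM fixed) requires
≥ 4 distinct site energies. With zero simulated noise the full
simulate → quantify → `fit_scaling` path returns the generating
`(μ, a, b)` to ≈ 1e−13 and R² = 1, because the simulated background block is
rescaled to exact median 0 / robust SD 1.

## Context model (SIFTED)

Each non-anchored (element, base) slot of each training protein is one
regression row; the response is the measured/true ΔΔG. Features (195 total):

- 15 type indicators `rvd[T:B]` (NTR plus the four RVDs, three non-anchored
  bases each, with A/C/G for the NTR);
- 48 positional terms `pos/lnpos/len/lnlen[T:B]` — linear and log position
  and protein length, repeats only;
- 60 N-neighbour indicators `nnb[T:B|N]` (neighbour ∈ 4 RVDs + NTR) and 72
  C-neighbour indicators `cnb[T:B|C]` (neighbour ∈ 4 RVDs + CTR; the NTR
  row only has the four repeat C-neighbours).

Rows are weighted `1 / (#proteins of the same nominal length)` so
over-represented lengths do not dominate. Features are standardised;
constant columns are dropped.

The fit is an Elastic Net with `l1_ratio = 0.95` over a 100-point λ path
spanning 4 decades below `λ_max = max|Xᵀ(w ⊙ (y − ȳ_w))| / (n·l1_ratio)`
(the smallest λ with all-zero coefficients, verified exactly against
scikit-learn). Model selection is nested: outer leave-one-protein-out,
inner protein-grouped 5-fold CV pooled across outer folds, bootstrap
(B = 1000) standard errors, and the one-SE rule; a single λ is shared by
every outer refit and by the final full-panel model. The path solver uses
warm starts at tolerance 1e−4 (scikit-learn's default; timed at ~2× faster
than 1e−6 with an identical selected λ and held-out correlation), while
final refits use 1e−6.

`predict_em` assembles a new protein's rows, applies the model and anchors
the result; the PWM follows by the Boltzmann transform. Planted-effect
recovery is evaluated by *prediction contrasts* (predict a focal column with
and without a neighbour, or at 5′ vs 3′ positions, and compare mean
non-anchored ΔΔG) rather than by reading individual coefficients: the
one-SE penalty deliberately zeroes weak collinear coefficients while the
prediction-level effect survives. Weak position/length slopes are evaluated
on a refit at the minimum-MSE λ, the standard estimator for support
recovery.

## Off-target pipeline

- **Enumeration**: bounded breadth-first search over site positions, pruning
  a prefix when its energy plus the sum of remaining column minima exceeds
  `ln(Kd threshold)`; an `eps = 1e−12` guard keeps boundary sites whose
  floating-point sum strays above the exact threshold. Verified equal to
  exhaustive 4^L enumeration for 50 random matrices at thresholds 1, 2, 10.
- **Genome scan**: rolling fixed-width window with hash-set lookup over both
  strands (exact multi-pattern matching; all enumerated sites share one
  length). Minus-strand hits report the forward footprint in 0-based
  half-open coordinates. Verified equal to a naive one-pattern-at-a-time
  sliding window on a 50 kb genome.
- **Summary score**: `Σ 1/rel_Kd` over off-target hits — each term is the
  relative occupancy contribution of one genomic site, so the score grows
  with both the number and strength of off-targets. The intended locus is
  excluded by coordinate identity (sequence-identical loci elsewhere still
  count); candidate designs are every T-initiated window of the target
  region on both strands, ranked ascending.
- **TALEN pair score**: per monomer `(S_opt/S_site)^0.6` with
  `S = Σ −ln p_j(base_j)`; partials lie in (0, 1] and the optimal pair
  totals exactly 2. The 0.6 exponent flattens the penalty so that single
  mismatches in long sites are not annihilating.
- **Evaluation utilities**: ROC (tie-grouped thresholds, trapezoidal AUC,
  verified against scikit-learn), log-Pearson and Spearman correlations for
  relative-Kd comparisons.

## Synthetic data: scope and defaults

The simulator generates data with exactly the statistical structure the
models assume plus controlled violations (outlier spikes, per-spot dsDNA
variation, Cy3 measurement noise). It is the study's evidence base — its
defaults are the study conditions and are not tuned to test outcomes.

- Panels draw repeat counts uniformly in the configured range; an Eulerian
  circuit over the complete 4-node RVD digraph is threaded through the first
  proteins so all 16 ordered adjacent RVD pairs occur (neighbour effects are
  observable).
- Planted truth coefficients (`default_truth`): baselines of ~2–4 RT against
  non-canonical bases (HD strongly rejects G; NN only weakly rejects A),
  negative position and length slopes (stronger for NN/NG), six neighbour
  adjustments (e.g. NN loses specificity at the C-terminal end, gains next
  to NI), per-entry Gaussian scatter 0.25 RT, floor 0.3 RT.
- PBM defaults: `μ = 3` (strong TALE, ~20× the optimal-site Kd), z-range
  `a = 0` to `b = 30`, replicate noise 1 z-unit, 8 replicates, 1% outlier
  spikes at 10 robust SDs, 60 background probes, 5% lognormal per-spot
  dsDNA variation shared by both channels, 2% relative Cy3 noise.
- Probe sets are the dinucleotide-substitution design: the canonical site,
  all single substitutions, and all adjacent double substitutions —
  `12n − 8` unique sites for an `n`-base site — embedded in fixed random
  flanks to 60-mers.
- Genomes are i.i.d. at a chosen GC content with sites planted at known
  coordinates/strands (overlaps rejected).

## Numerical choices

- All randomness flows through `numpy.random.SeedSequence` spawning; derived
  integer seeds are reduced modulo 2³¹.
- Energy sums in the enumerator use a 1e−12 boundary guard (see above).
- TSV round trips parse with `float_precision="round_trip"` so saved models
  reload bit-exactly.
- The Cy3 OLS uses `numpy.linalg.lstsq` (min-norm) rather than a
  pseudo-inverse of the normal equations, for rank-deficient stability.
- Split-R̂ follows the split-chain Gelman–Rubin formula; each of the 4
  emcee ensembles is split in half.

## Limitations

- **Credible-interval calibration under realistic noise.** The likelihood is
  iid Gaussian in z with a single σ. The simulated (and real) quantification
  pipeline leaves probe-level noise that this model cannot represent: the
  Cy3 trinucleotide regression has ~56 effective degrees of freedom for
  ~170 probes, so a fraction of each probe's dsDNA factor leaks into its
  fitted "expected" value and survives the correction, and the residual is
  heteroscedastic in intensity. σ absorbs the magnitude but not the
  per-experiment correlated component, so whole energy matrices can be
  displaced by ~0.05–0.15 RT and 95% credible intervals undercover —
  pooled coverage across simulated panels straddles 90% (below it for most
  realisations of the MAP-Laplace path). Point recovery is unaffected
  (median RMSE ≈ 0.09 RT vs the 0.3 RT target). The strict coverage
  acceptance test is left in place and may fail; fixing it would require a
  heteroscedastic or heavier-tailed likelihood, which is outside the
  implemented model.
- **Affine z-scale absorption.** Background-referenced z-scores carry an
  experiment-specific scale (background robust SD estimated from 60
  probes); the occupancy model's `a`, `b` absorb any affine transform, so
  ΔΔG is identified but `a`, `b`, `σ` are only meaningful per experiment.
- **One-SE sparsity vs weak effects.** At the one-SE λ, weak collinear
  coefficients (e.g. the mildest position slopes) are shrunk exactly to
  zero; effect signs should be read from prediction contrasts or from the
  min-MSE fit, as the acceptance suite does.
- **Exact-match scanning.** The genome scan finds exact occurrences of
  enumerated sites; near-misses below the enumeration threshold are invisible
  by construction, so the threshold choice bounds the scan's sensitivity.
- **Synthetic validation only.** All quantitative results in this repository
  are computed on simulated data; no claims are made about performance on
  experimental arrays.
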