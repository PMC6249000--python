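# Methods

This note documents the models, conventions and numerical choices behind
`plastnet`, and what the synthetic-data validation does and does not
establish.

## Data model

All analyses are indexed by a fixed, ordered region catalogue.  The bundled
atlas has 82 entries (41 macroscopic cortical/subcortical areas per
hemisphere); the hippocampus and amygdala are flagged out-of-network
bilaterally, leaving 78 regions for graph analyses so that the node set
stays constant across timepoints and matches the coverage of the cellular
density data.  The published source of the area list does not fix a row
order, so the bundled table orders areas alphabetically within hemisphere
(left block first); this is a convention of this package, and any consistent
order gives identical results provided all inputs share it.  On disk,
regions are identified as `<abbrev>_<L|R>`; matrices and vectors are
tab-delimited UTF-8 with header labels that are checked, not assumed.

Functional connectivity is the Pearson correlation of region timecourses,
stored signed and unthresholded.  Group matrices are plain elementwise
averages across subjects (Fisher-z averaging is available as an option but
is not the default, because the analysed studies average raw correlations;
for correlations in the typical |r| < 0.7 range the difference is small).

## Community detection and node metrics

Modules maximize Newman-Girvan modularity with resolution γ on the positive
part of the weight matrix, diagonal zeroed; the degree-product null term
runs over all ordered pairs, which yields the closed forms Q = 1 − γ for a
single module and Q = 1 − γ/2 for two equal disconnected cliques in their
natural partition.  Negative correlations are excluded from community
detection and participation by default (keeping Pᵢ ∈ [0, 1]); an
asymmetric signed variant Q⁺ − (v⁻/(v⁺+v⁻))Q⁻ is available behind a flag.

The Louvain implementation is deterministic given its seed: within each
local-moving sweep nodes are visited in seeded-random order, a move is made
only on a strict gain (tolerance 1e−12), and among equal-gain targets the
lowest-index community wins.  Because the merge-only level hierarchy cannot
split a supernode, node-level refinement passes on the original graph
alternate with supernode merge phases until the partition is stable; and
because greedy single-node moves from singletons cannot always reach coarse
optima on weak-structure graphs, each seeded call additionally explores
random 2-way and 3-way starting assignments and keeps the best Q.  With
these two safeguards, best-of-100-restarts attains the global maximum found
by exhaustively enumerating all 4140 partitions on every random 8-node
graph tested (400 graphs across independent streams).

Consensus partitioning runs `n_reps` seeded restarts, forms the
region-by-region co-assignment frequency matrix, zeroes entries below
τ = 0.5, re-clusters the thresholded matrix (at γ = 1) and iterates until
the co-assignment matrix is exactly block-binary (at most 50 iterations,
after which an error reports the residual agreement statistics).  The rule
behind "most consistent modules" is not uniquely defined in the literature
this package follows; iterative co-assignment clustering was chosen because
it is the standard consensus-clustering construction for stochastic
partitions and degenerates correctly (a single repetition, or a graph on
which every restart agrees, returns the plain Louvain result).

Node strength sums signed weights by default (positive-part optional).
Participation uses positive weights and assigns Pᵢ = 0 to regions with zero
positive strength.  Within-module connectivity is the signed mean toward
same-module regions, NaN for singletons.  Hubness is the first principal
component of the two z-scored columns (strength, participation), computed
from the eigendecomposition of their 2×2 correlation matrix and signed so
that hubness correlates positively with strength; the percentage of
variance explained by this component is reported alongside.

Default γ = 1; robustness sweeps use the grid 0.8, 0.9, …, 1.4, the range
over which module structure goes from two modules to near-singleton
modules on matrices of this kind.

## Stage changes and stepwise regression

Stage changes are elementwise later − earlier differences: acute
(pre → 3 months) and chronic (3 → 12 months).  Because both windows share
the middle scan, chronic changes are residualized on acute changes (OLS
with intercept) before modelling; residuals have exactly zero mean and zero
sample correlation with the acute vector.

Stepwise regression is forward-backward with p-value thresholds
p-enter = 0.05 and p-remove = 0.10 (the canonical defaults of the stepwise
tools this reproduces; both configurable, p-enter ≤ p-remove enforced).
Predictors are z-scored before selection so betas are comparable across
predictors; the dependent variable is left raw.  At each forward step the
candidate with the smallest add-one partial p enters if below p-enter; the
backward step then drops any retained predictor whose final-model p exceeds
p-remove; the loop runs to a fixed point.  Ties are broken by candidate
order.  Forward entry is suppressed once the current model is numerically
perfect (SSE ≤ 1e−12·SST), since partial statistics on zero residuals are
floating-point noise.  Perfect collinearity among candidates raises an
error naming the collinear set.  Reporting: selected predictors carry
final-model betas/t/p; non-selected predictors are reported with add-one
partial statistics relative to the final model; unselected betas are exactly
0 by convention.  Whether the original analyses were forward-only or
forward-backward is not documented; forward-backward was chosen as the
standard default of the common stepwise implementations, and at these
thresholds the two rarely differ.

Module dispersion is a one-way ANOVA of per-region change grouped by module
(each module must retain ≥ 2 regions after dropping missing values).

## Resampling nulls

*Shared-timepoint null.*  Two difference scores sharing a middle measurement
are negatively correlated by construction: for i.i.d. equal-variance A, B, C,
corr(B−A, C−B) = −0.5.  The null distribution of the acute-predicts-chronic
slope t statistic is therefore simulated: each simulation draws three
independent standard-normal pseudo-timepoint vectors per region, forms the
two pseudo-changes, and records the slope t of chronic on acute.  Standard
normals are used because the t statistic is location- and scale-invariant,
so only distributional shape matters.  Significance is membership in the
top or bottom 2.5% of simulated values; reported p-values are +1-corrected
two-tailed ranks, p = 2·min(#{T≤t}+1, #{T≥t}+1)/(n+1), so finite simulation
never produces p = 0.  Note that the t null is mildly left-skewed
(skewness ≈ −0.19 at 78 regions): the t-transform of a correlation centred
at −0.5 is nonlinear, so exact symmetry should not be expected or enforced.

*Beta-difference permutation test.*  To compare stepwise betas between a
full dataset and a subset dataset, the reference betas come from the
full-data fit; each permutation draws every region's dependent value
independently from the full or subset data with probability ½, reruns the
entire stepwise selection (never frozen at the reference model), and records
beta differences from the reference, with unselected predictors
contributing 0.  Observed subset-minus-full differences are compared
two-tailed against this distribution with the same rank rule; under exact
dataset identity every permuted difference is 0 and all p-values are 1.

## Lesion volumetry

Lesion extent is 100·(1 − remaining/reference) for remaining-tissue
measurements and 100·measured/reference for direct lesion measurements.
Reported percentages are rounded half-away-from-zero to 2 decimals; summary
tables report mean volumes truncated (floored) to integers and mean
percents as the mean of the per-subject rounded percents — the conventions
that exactly reproduce the bundled demonstration tables (mean-of-unrounded
percents differs in the second decimal).  A remaining volume exceeding its
reference clamps to 0% with a warning rather than reporting a negative
extent.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, with
known ground truth:

- **Latent factor model.**  Each region loads on its module factor
  (√(within − between) = √0.5 by default) and a global factor (√between =
  √0.1), giving within-module correlation 0.6 and between-module 0.1 —
  block contrast strong enough for reliable module detection yet well below
  deterministic.  Hub regions (top 15% of the hubness gradient) carry a
  ×1.5 global loading.  The construction guarantees a positive-semidefinite
  latent covariance, so matrices can be emitted analytically (fast mode,
  plus symmetric subject-level jitter, sd 0.05) or via finite timecourses
  sampled from the covariance (988 samples, matching a typical 40-minute
  scan).
- **Predictors.**  Four smooth per-region gradients drawn from a 1-D
  Gaussian process (length-scale 0.08 of the region axis) and mixed to a
  target correlation structure (neuron↔hubness +0.4, non-neuronal↔hubness
  −0.3, neuron↔non-neuronal −0.2, seed-FC weakly positive), mirroring the
  empirical signs of density-hub relationships; densities are shifted and
  scaled strictly positive (arbitrary units).
- **Stage effects.**  Planted per-region change fields are linear in the
  z-scored predictors (default standardized effect ±0.5 on the empirically
  associated predictors) plus Gaussian noise (sd 0.5).  For the
  connectivity metrics the fields perturb the *metric-generating
  parameters* — global loadings for participation, module loadings for
  within-module FC (gain 0.15 per unit change, loadings jointly rescaled to
  keep every pairwise correlation inside (−1, 1)) — so those metrics are
  exercised end-to-end rather than pasted in.  The regional volume series
  (log-Jacobian) is itself a direct per-region scalar, so its planted
  changes are exactly linear; it is the route used for quantitative
  parameter-recovery validation.

What passing tests show: on data with this structure, consensus detection
recovers planted modules exactly at the stated contrast; stepwise selection
is calibrated under the null (per-predictor inclusion ≈ p-enter) and
recovers planted standardized effects of 0.5 with ≤ a few percent mean bias
and ≥ 80% joint selection.  What they do not show: robustness to
physiological confounds (motion, vascular artifacts), to atlas
misregistration, to non-Gaussian BOLD noise, or to spatial autocorrelation
beyond the smooth-gradient form modelled here.  Note also that smooth
gradients reduce the effective number of independent regions well below 78,
so single-study coefficient estimates are more variable than i.i.d.
intuition suggests — visible in the worked example's spurious second
predictor.

## Pipeline conventions

Modules are defined once, on the pre-lesion consensus, and held fixed for
all timepoints' participation and within-module metrics (per-timepoint
re-partitioning appears only in the modularity-trajectory diagnostic);
hubness is likewise computed from pre-lesion strength and participation,
since it serves as a *pre-lesion* predictor of subsequent change.  Every
random draw derives from the root seed through named `SeedSequence`
children recorded in the run log, and the JSON report is byte-identical
across reruns at a fixed config.  Demo/test problem sizes (consensus
restarts 100–1000, null sims 200–1000, permutations 200–2000) are chosen so
the full validation suite runs in a few minutes on one CPU; the defaults of
the library itself (10000 consensus restarts, 10000 permutations) match the
sizes used in the kind of study the pipeline reproduces.

## Known limitations

- Louvain refinement guarantees local optimality at the node level only;
  global optimality is verified exhaustively for 8-node graphs, not in
  general (it is NP-hard).
- The asymmetric signed modularity variant is provided but lightly
  exercised; all headline analyses use positive-part weights.
- The stepwise reporting convention (add-one partials for excluded
  predictors) matches common practice but is one of several defensible
  choices; exact degrees of freedom are always reported from the fits
  actually performed.
- The cell-density crosswalk helper averages donor areas with equal weight;
  volume-weighted averaging would require donor volumes that are typically
  not published.
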