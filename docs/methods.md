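# Methods notes

This note records the models, conventions and numerical choices behind
`comland`, the reasoning where a design was genuinely open, and what the
synthetic validation does and does not establish.

## Data model and filters

Tables are samples × ASVs integer read counts; all statistics except
rarefaction run on the filtered, unrarefied counts or on their row-wise
relative abundances.  The quality cascade drops ASVs with fewer than 100
reads summed across samples and then samples with fewer than 10,000 reads;
"fewer than" is strict, so totals equal to the bound survive.  By default
the ASV filter is applied jointly across the start and final tables
(configurable), because the two tables must share their ASV columns for
every downstream comparison.  Rarefaction (without replacement, exact
multivariate hypergeometric) exists for visual summaries only and is never
used by the statistical stages.

## Dissimilarity, ordination, ANOSIM

Jensen–Shannon divergence is computed in base 2 so it is bounded by 1; zeros
need no pseudocounts because of the 0·log 0 = 0 convention.  Clustering and
ordination consume the *square root* of the divergence, which is a metric —
the standard enterotyping choice, and a requirement for classical scaling to
be well behaved.  Both the base and the square-root step are configurable.

PCoA is classical metric scaling: double-centre −d²/2, eigendecompose, keep
axes with positive eigenvalues scaled by √eigenvalue.  Negative eigenvalues
are dropped (no Cailliez correction); the discarded fraction of total
inertia is recorded on the result object.

ANOSIM uses average ranks for ties and Clarke's denominator n(n−1)/4, which
maps complete separation to R = 1 and random grouping to R ≈ 0.  P-values
use the add-one permutation estimator, so the smallest attainable p is
1/(n_perm+1); permutations are seeded and reproducible.

## Community typing

PAM consumes the distance matrix directly: deterministic greedy BUILD
seeding, then full steepest-descent SWAP to a local optimum, ties broken by
lowest medoid position then lowest candidate index.  When the medoid subset
lattice is tiny (C(n,k) ≤ 2048) the optimum is found by exhaustive
enumeration instead — steepest descent can stall in local optima on a few
percent of tiny instances, and at that size enumeration is free.  Random
restarts are available but off by default, so results are seed-independent.

The Calinski–Harabasz index needs a Euclidean embedding, so it is evaluated
in the PCoA coordinates (all positive axes) of the same distance matrix the
clustering used.  The k-scan records the full CH curve, its global argmax
and all interior local maxima, and allows pinning k: CH can legitimately
prefer a coarser partition when between-class gaps are unequal, and an
analysis may prefer a particular local maximum; the evidence is always
reported alongside.  The scan bound defaults to min(25, n−1) in the library
and 10 in the pipeline configuration.

## Rigid-body superposition

The Kabsch fit centres both matrices on their column means, takes the SVD of
the cross-covariance XcᵀYc = USVᵀ and applies the proper rotation UDVᵀ with
D correcting a reflection.  RMSD is ‖Xc·R − Yc‖_F/√n, the root mean squared
row-wise Euclidean deviation.  When the number of ASVs is large the rotation
is never materialised: thin QR/SVD factors represent its action on the data
span, where the reflection correction lives in the null space of the
cross-covariance and cannot affect the fit (the two routes are asserted
equal in the tests; the dense route is used up to p = 512).

The null RMSD interval refits after permuting *all cells* of the starting
matrix (50 randomisations, 2.5/97.5 percentiles).  Holdout comparison
computes thin-SVD sample scores (U·S) of the transformed start matrix and of
each held-out replicate, each centred on its own column means (uncentred
scores available by flag), aligns the arbitrary component signs so the
paired correlation is non-negative (R² is unaffected; the slope sign
follows the convention), and reports Pearson R², the two-sided t-test
p-value, slope and intercept for components 1 and 2.  Components are paired
by rank — first with first, second with second — so a high R² requires the
two clouds' principal axes to correspond, not merely their geometries.

## Landscape geometry

A class centroid resamples every member once as a multinomial draw of
10,000 reads from its relative abundances, takes the per-ASV *median of the
resampled counts* across members (not the median of relative abundances)
and renormalises; an optional `n_resamples` averages several rounds.  The
border distance of a query community to a class is the minimum sqrt-JSD to
the class's members, excluding the query itself whenever it belongs to the
reference set — otherwise every member's border distance would be trivially
zero.  No inequality between centroid and border distances is assumed; both
are reported.  Class-to-class summaries average sqrt-JSD over all cross
pairs, excluding identical-sample pairs.

## Propensities, groups, tipping points

Presence means count ≥ 1 (threshold configurable) on the filtered,
unrarefied counts.  The propensity of ASV i for trajectory type T is the
natural-log ratio log[P(present|T)/P(present)], evaluated independently for
the start table (one community per trajectory) and the final table (four
replicate communities per trajectory, all labelled with the trajectory's
type).  A type in which the ASV never occurs gives −∞, carried explicitly
and never significant; no pseudocounts are added.  Bootstrap CIs resample
communities with replacement, labels travelling with rows; replicates in
which a type stratum vanishes are redrawn and counted, and replicates in
which an ASV vanishes entirely contribute NaN cells that the percentile
step ignores.

Point estimates obey the law of total probability,
Σ_T P(T)·exp(prop_T) = 1, for every ASV with finite propensities — the
tests assert this to 1e-9.  An important consequence: *no ASV can have
strictly positive propensity for every trajectory type*, in the full table
or in any bootstrap replicate; at most two of three types can be positive at
once, so a strictly-positive 95% CI in all six cells is unattainable for
any taxon.  A "cosmopolitan" taxon — present in essentially every community
of every type — instead has its propensities pinned at exactly zero, with
CIs collapsing onto [0, 0].  The group assignment therefore detects
cosmopolitans as taxa whose CIs are non-negative with finite propensities in
all six cells (the ubiquity signature); a strict ci_low > 0 rule remains
available (`cosmopolitan_rule="strict"`) and everywhere else
`significant_positive` means the whole CI above zero.  Group priority is
cosmopolitan, then S&F1/S&F2 (significantly positive for C1/C2 at both time
points), then a signature label built from the significant cells (all 2⁶
signatures are emitted for downstream tallies).

The tipping-point rule predicts C1 when the S&F1 sum exceeds its threshold
while the cosmopolitan sum does not, C2 in the reverse case, and
"unpredictable" (D) when both or neither exceed — balanced abundances of
the two groups are exactly the unpredictable regime.  The default
thresholds, 0.125 and 0.2, are treated as fixed constants of the analysis;
a grid-search utility that fits them to observed types exists as a clearly
separate extension (`optimise=True`) and always includes the fixed
thresholds among its candidates.

## The synthetic generator

`simulate()` draws a hierarchical Dirichlet–multinomial model with three
ASV blocks: an S&F1 block, a cosmopolitan block, and a background block
split into an abundant core shared by all classes plus flat class-specific
tails.  Each parent community draws its (S&F1, cosmopolitan) block masses
from one of three archetypes — S&F1-heavy, cosmopolitan-heavy, balanced —
with lognormal spread; start classes are defined by the background tails,
and archetypes are allocated proportionally *within* every class, so the
planted tipping variable is orthogonal to class membership by design.  This
orthogonality is deliberate: if replicate fates correlated with start
classes, every class-specific background ASV would genuinely acquire the
S&F1 statistical signature and planted-group recovery would be ill-posed
for any correct implementation.  Class-linked fates can still be configured
through `transition_probs` and the archetype fields.

Replicate fates follow p(class 1) ∝ T[class]·σ((s − c)/τ), where s and c
are the parent's planted block masses, τ (`tipping_noise`, default 0.04) is
the logistic temperature (0 gives a hard threshold, ∞ disables tipping so
the transition matrix acts alone), and T defaults to flat rows.  Final
compositions blend the final-class base with the parent's own profile
(`parent_carryover = 0.4`), which is what makes replicate sets cluster by
parent, final compositions predictable from starting ones, and the leading
SVD axes of start and final clouds correspond.  Defaults anchored to the
experimental design are 275 parents × 4 replicates at 15,000 reads with 5
start and 2 final classes; block masses are chosen so that class-1-bound
communities carry S&F1 sums near 0.4 and class-2-bound communities carry
cosmopolitan sums near 0.28, on the far sides of the fixed thresholds.

What the generator does **not** emulate: mechanistic population dynamics
(no Lotka–Volterra or resource models — fates are drawn, not integrated),
sequencing error, chimeras or taxonomy, uneven sequencing depth, batch or
plate effects, and any coupling between background classes and fates.
Passing the end-to-end tests therefore shows that the pipeline recovers the
statistical structure it targets when that structure is present at
realistic effect sizes and sample sizes — not that real communities satisfy
the model.

## Orchestration, seeds, problem sizes

`run_all` executes filters → typing (start and final, final classes
relabelled 1, 2, … by decreasing size) → ANOSIM (class sharpness, parent
grouping, replicate grouping) → superposition against a chosen fit
replicate → landscape distances on a chosen replicate → bootstrap
propensities → group assignment → tipping-point classification, and emits a
JSON-serialisable summary plus every intermediate table.  One global seed
fans out to fixed per-stage child seeds via `numpy.random.SeedSequence`, so
reruns are byte-identical and stages are individually reproducible.

Validation sizes are chosen to exercise the estimators well inside a
laptop-scale budget: the standard fixture uses 150 parents (600 final
communities) and 200 ASVs; bootstrap calibration runs 100 simulations of
200 communities at 200 bootstrap tables; class-number recovery scans 20
seeds per planted k.  The acceptance script runs the fixture at the full
study settings (1000 permutations, 1000 bootstrap tables, 50
randomisations).

## Known limitations

* CH-based selection can prefer a coarser k than planted when between-class
  gaps are unequal; the package surfaces the whole CH curve and local
  maxima rather than silently trusting the argmax.
* A rigid motion cannot represent the contraction of a scattered start
  cloud onto tight attractors; holdout R² on simulated data is therefore a
  function of the parent-carryover level, and component-rank pairing makes
  R² sensitive to axis ordering in borderline cases.
* Bootstrap CIs are percentile intervals; with 200–1000 replicates the
  one-sided significance rate runs slightly above its 2.5% nominal level
  (the calibration test allows ≤ 6%).
* The cosmopolitan rule detects exact-ubiquity signatures; taxa present in,
  say, 90% of communities of every type are not detectable as cosmopolitan
  by any CI-positivity rule, for the total-probability reason above.
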