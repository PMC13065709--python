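# Methods

## Problem and model

The pipeline contrasts two within-subject conditions (fear vs. neutral)
on per-participant weighted functional-connectivity matrices drawn from
several datasets. Analysis proceeds in four stages — adjacency
preparation and graph metrics, a proportional-threshold sweep,
mass-univariate mixed-model contrasts, and permutation-tested SVM
classification — each exposed as an independent module and orchestrated
end to end.

## Adjacency preparation and thresholding

Raw matrices may contain negative weights (anticorrelations). They are
preserved by absolute value before thresholding, so only magnitude ranks
matter downstream. Proportional thresholding at cost `c` keeps the
`ceil(c · N(N−1)/2)` largest upper-triangle entries of `|W|` — counted
against all *possible* edges, not just nonzero ones — with weights
preserved (no binarization). Ties at the cutoff are broken by `(i, j)`
lexicographic order, making the operation deterministic; at `c = 1` it
reduces to the absolute value. The default cost grid is 1%–50% in 1%
steps (50 thresholds); the range is standard for weighted
brain-network analyses and the 1% step is a configurable default.

## Graph measures

Path-based measures travel on edge lengths `L_ij = 1/A_ij` — the usual
weighted-network convention in brain-connectivity tooling, where strong
connections are short. Conventions for degenerate inputs are: PC = 0 and
BC = 0 for isolated nodes, and disconnected pairs contribute 0 to global
efficiency. Betweenness counts each unordered pair once and is left
unnormalized (an ordered-pair variant is exactly twice these values).
Betweenness is computed through igraph's C implementation of Brandes'
algorithm; correctness against the definition is established by an
exhaustive simple-path enumeration oracle in the tests.

Modularity uses the partition found by Newman spectral community
detection, not the a-priori networks: recursive bisection by the sign of
the leading eigenvector of the (generalized) modularity matrix,
fine-tuned after each split by Kernighan–Lin-style single-node flips.
The eigenvector sign is fixed deterministically (largest-magnitude entry
positive; zero entries join the positive group) so results are
bit-reproducible. After recursion, a greedy refinement pass (single-node
moves, community merges, and singleton split-offs) polishes the
partition; on graphs of ≤ 20 nodes an additional deterministic "kick"
search (forcing each node — and, at ≤ 10 nodes, each node pair — into
every alternative community and re-refining) is affordable and reliably
reaches the global modularity optimum, as verified against exhaustive
set-partition enumeration in the tests. All improvement thresholds use a
round-off-aware tolerance (~1e−10 scaled) with iteration caps, because
incremental gain updates can drift below double precision and cycle.

The participation coefficient uses the fixed a-priori partition of 412
nodes into 8 networks (400 cortical parcels in 7 networks, plus 12
subcortical regions — thalamus, caudate, putamen, pallidum, hippocampus,
amygdala per hemisphere — treated as one extra network). Both the
cortical listing and the subcortical set are configurable; the default
table is generated programmatically from the per-network parcel counts
of the 400-parcel/7-network atlas.

## Threshold sweep

Each record is thresholded at every cost; PC, BC, E and Q are computed
per cost and collapsed to arithmetic means per participant × condition.
Q is computed on the thresholded graph (consistent with "metrics at each
threshold") and averaged across costs exactly like E, since the
downstream contrast needs one value per subject per condition. A sweep
of one 412-node record across all 50 costs takes ~35 s on one CPU
(betweenness and the spectral detection dominate); cohorts parallelize
over records with identical results for any worker count.

## Mass-univariate contrasts

Per node, `value ~ condition + age` is fit by REML with a random
intercept for dataset and a participant-within-dataset variance
component, i.e. the nested structure `(1 | dataset/participant)`. The
reported contrast is fear − neutral adjusted for age, so negative
estimates mean *lower in fear*. With as few as 4 dataset levels the
dataset variance is frequently estimated at the boundary; a singular or
non-convergent nested fit falls back to a participant-only random
intercept with a logged warning. A covariate with zero variance (all
ages equal) is dropped as collinear with the intercept, which also gives
the closed-form limit: with equal ages and no dataset variance the
contrast equals the simple paired mean difference. p-values use a t
reference with df = n_participants − 1, the paired-design convention
(the fitting backend offers no Satterthwaite approximation); df is
recorded in the output. FDR correction is Benjamini–Hochberg across the
nodes of one metric, with NaN p-values propagated without affecting the
ranks of the rest.

## SVM classification

Feature rows are participant × condition; folds are assigned at the
participant level so a participant's two rows can never straddle
train/test, and are stratified so each fold holds nearly equal numbers
of participants per dataset (round-robin dealing from a seeded shuffle;
per-dataset fold counts differ by at most 1). Features are standardized
with train-fold statistics only. The inner CV (default 3 folds) selects
the cost parameter `c` from {1, …, 10} by accuracy, ties going to the
smallest `c`; the winning `c` is refit on the full training set. Outer
test predictions are pooled within a run before computing accuracy and
macro dice; primal weight vectors are averaged over outer folds, then
over runs. The true statistic repeats the whole nested CV with freshly
drawn folds (default 1,000 repetitions) and averages; the null
distribution repeats it with condition labels swapped within participant
(the exchangeable unit of a paired design) with probability ½. The
permutation p-value is `count(null ≥ true mean)/n` by default (an
add-one variant is available). Feature z-scores standardize the mean
weights across features; |z| > 1.96 flags a feature (two-sided, signed z
reported). A run whose pooled predictions collapse to one class is
counted; when every run collapses, the degenerate report flags the
result and states the analytically forced values on balanced data —
accuracy 50% and macro dice (2/3 + 0)/2 = 1/3.

## Synthetic cohorts

The generator works at the connectivity-matrix level (no BOLD
simulation): neutral-condition weights are `mu_within` inside a network
and `mu_between` across networks, plus a per-dataset offset, a
per-subject offset, and i.i.d. symmetric Gaussian edge noise; a fraction
`neg_fraction` of between-network edges is sign-flipped per subject to
emulate anticorrelations. The fear condition adds `effect_delta` to
every edge with both endpoints in the affected network, which raises
within-network strength and therefore *lowers* the participation
coefficient of affected nodes — the planted, recoverable signature.
Ages are normal (mean 22.06, SD 4.79) truncated at 18, matching an
adult-student recruitment profile. Default dataset sizes are
(18, 29, 34, 28); weights live on an unconstrained real scale (a
unit-clipping option exists) since only ranks survive thresholding.
Defaults for the block means (0.5 within / 0.2 between) and noise scales
(0.05–0.1) sit in the range typical of correlation-based connectivity.
Everything derives from one seed and is byte-reproducible.

What the generator does *not* emulate: spatial autocorrelation between
neighboring parcels, heavy-tailed or subject-specific network topology,
motion artifacts, and non-additive condition effects. Passing recovery
tests therefore demonstrates that the pipeline detects the planted
additive effect under nested random variation — not that it would have
the same power on real data.

## Scaled-down test conditions

Recovery and calibration checks run at desk scale, as the package's own
choice of test sizes: parameter recovery uses 4 datasets × 10
participants and a 64-node table (7 cortical networks × 8 + 8
subcortical) with a strong planted effect (`effect_delta = 0.3` against
edge noise 0.05) and a 10-cost grid (5%–50% in 5% steps); permutation
calibration uses 16 participants, 3 noise features, a single-value
c-grid, 200-draw nulls and 100 repeated experiments. The acceptance
script uses the same conditions with seeds derived from its `--seed`.

## Known limitations

- The dataset-level variance is weakly identified with 4 datasets; the
  documented fallback makes the per-node contrast robust but the
  dataset variance estimate itself should not be interpreted.
- Degrees of freedom are a convention (n_participants − 1), not a
  Satterthwaite approximation; t-values are unaffected.
- The spectral detection guarantees the global modularity optimum only
  where the kick search is active (≤ 20 nodes); at full scale it is a
  high-quality deterministic heuristic, like all modularity maximizers.
- No signed-network modularity, alternative community algorithms, or
  nonlinear kernels; the pipeline mirrors one analysis design.
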