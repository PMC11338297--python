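# Methods

This note documents the models, parameter choices, and numerical decisions
behind `sortalign`, in the order the pipeline runs them.

## Stimulus synthesis

Two family-resemblance categories are each seeded by a 39-vertex closed
prototype normalized to a unit bounding box. Contours are periodic cubic
splines through the vertices (the standard closed-curve interpolant);
`interpolate_contour` returns `n_vertices x points_per_segment + 1` points
with the last repeating the first, exact at the knots. Exemplars perturb
every fifth vertex (0-based indices 0, 5, 10, …; the phase is a documented
convention and trivially changeable) with i.i.d. Gaussian noise in x and y
and re-interpolate. Distortion SDs are 0.25 / 0.55 / 0.75 (low/medium/high,
contour mode, 6 + 6 + 6 exemplars per category) and 0.35 (point-stimulus
mode, 10 per category, no contour), all in unit-bounding-box units, so
noise scale is relative to shape size.

The original prototypes were hand-drawn and are not reproducible; the
package ships two synthetic stand-ins as versioned JSON fixtures — a pair
of fixed-seed smooth radial-noise blobs for the contour mode, and a
39-point circle and square outline for the point mode.

The free-sort set is 20 items: per category, 3 pre-exposed exemplars, 6
unseen exemplars, and the prototype (contour mode); in point mode, where
only 10 exemplars exist per category, the set is the 9 pre-exposed
exemplars plus the prototype. The xAB pre-exposure list crosses 9 exemplars
per category (never the prototypes) into 81 cross-category pairs per block;
3 blocks give 243 trials. The sample alternates deterministically between
the A and the B member of a pair (the design does not pin this down), and
the correct side is counterbalanced to within one trial per block.

## Synthetic sorters

The canvas defaults to 1024 × 768 px (both key statistics are invariant to
canvas scale, so this is cosmetic). Strategies:

- `random_uniform`: i.i.d. uniform positions — the null model.
- `grid`: an evenly spaced lattice filling the canvas, assignment
  seed-shuffled — perfectly alignable with no cluster structure.
- `categorical`: two cluster centers `center_separation` px apart on the
  horizontal midline; each item sits at its category's center plus
  isotropic Gaussian noise (`within_sd`).
- `mixed_clusters`: cluster memberships deliberately interleave the two
  categories — alignable but low-categoricality by construction.

Gaussian scatter is folded back into the canvas by reflection at the
borders, which preserves within-cluster spread better than truncation.
Per-participant seeds are derived by hashing (master seed, condition,
index), giving reproducibility with independence.

The default three-condition cohort gives every condition the `categorical`
strategy at separation 400 px, with within-cluster SD 150 px for Baseline
and No-Labels and 85 px for With-Labels — a larger separation-to-spread
ratio standing in for the label-induced categoricality boost. A lognormal
jitter (σ = 0.35) multiplies each sorter's `within_sd` so categoricality
varies across individuals within a condition, which is what makes
covariate-based mediation estimable at all. These synthetic cohorts emulate
the structure of real sorts (two noisy category clusters of varying
tightness), not their idiosyncrasies: real participants form subclusters,
leave items at edges, and vary in strategy, so passing tests here validates
the pipeline's statistics, not any claim about human behavior.

A separate table-level generator (`simulate_mediated_table`) draws
categoricality per participant from a condition-shifted normal
(shift 0.25, SD 0.5, near the human scale) and sets alignment to
0.6 × categoricality plus N(0, 0.08) noise. Because condition enters
alignment only through categoricality, the covariate-adjusted condition
coefficient is exactly zero in expectation — the clean benchmark for
complete-mediation recovery. (Driving mediation through full sort
simulation instead would make measured categoricality a noisy proxy for the
latent manipulation, and the benchmark would then measure attenuation from
measurement error rather than the mediation logic.)

## Metrics

Pairwise distance vectors use a canonical pair order (lexicographically
sorted item ids, `itertools.combinations` order), so vectors from different
participants are comparable positionally. Spearman rho is computed as
average-ranks-then-Pearson; for cohorts, rank vectors are centered and
L2-normalized once per sorter so the full dyadic rho matrix is a single
matrix product (this is what makes the 3000-sorter null study take seconds
rather than hours). Fisher z uses `atanh` after clipping rho to
±(1 − 10⁻⁶): identical sorts get a large but finite z (≈ 7.25) and remain
comparable. Rho of a zero-variance distance vector is an error, not NaN.
The categoricality log is natural; only sign and ordering matter.

Ties in distances are handled by average ranks. Note a numerical subtlety:
exact ties are knife-edge under floating-point similarity transforms — a
rotation perturbs distances at the 10⁻¹⁵ level and can split a tie, moving
rho discretely. The invariance of alignment under rigid motion and uniform
scaling is exact for tie-free configurations (the generic case).

Data-quality rules: trials with RT < 150 ms or more than 2 SDs above the
participant's mean (mean/SD computed before exclusion, upper tail only —
the floor handles the lower tail) are dropped; participants are excluded
for incomplete sorts, match-to-sample accuracy below 80%, or fewer than
7/9 catch trials, each with a reason code.

## Cluster counts

`pam` is the classic deterministic BUILD + SWAP k-medoids on Euclidean
pixel distances (no standardization; both axes share units). BUILD starts
from the most central item and greedily adds the largest-gain medoid; SWAP
applies the best strictly improving exchange until none exists, ties broken
by lowest index. `estimate_k` scans k = 2…10 (one-cluster sorts are not
observed in this task) and keeps the k with maximal average silhouette
width, ties toward smaller k; singleton-cluster silhouettes are 0 by
convention.

Single-swap descent is a heuristic: on unstructured point sets it can stop
in a local optimum that no single medoid exchange escapes (the reference R
implementation of the same algorithm behaves identically, up to basin).
On separated clustered configurations — what sorts look like — it attains
the exhaustive-search optimum, and the test suite asserts exact equality
with brute-force enumeration there, plus the one-sided bound everywhere.

## Inference

All models are fixed-effects fits on per-participant aggregates, which
sidesteps dyad non-independence: each participant's outcome is their mean
alignment to the rest of their condition. Condition predictors are
centered (slopes unchanged, intercept = grand mean). OLS for continuous
outcomes, Poisson (log link) for cluster counts, logistic for the
2-cluster indicator; perfect separation is flagged as a degenerate fit
rather than fitted.

Mediation by covariate entry reports both the adjusted model's R² and, as
`variance_accounted`, the covariate's squared partial correlation
t²/(t² + df). Verdicts: *complete* if the adjusted condition term is
non-significant at α = .05, *partial* if it remains significant but shrinks
while the covariate itself is significant, *none* otherwise (the covariate
requirement stops chance shrinkage with an irrelevant covariate from being
read as partial mediation).

## Null simulations

The random-placement study simulates N uniform sorters (default 3000, 20
items), computes the full within-cohort alignment matrix, and reports the
maximum per-sorter mean alignment and the Pearson correlation between
min-bridged categoricality (fixed 10/10 A/B labeling — random placement is
label-exchangeable) and mean alignment. "Maximum alignment" is taken over
sorters' means, matching the per-participant aggregation used everywhere
else; the dyad-level maximum is also reported but is a far larger
order statistic over ~4.5 million correlated dyads.

One caveat worth knowing: the correlation reported by the null study is a
noisy estimate even at 3000 sorters. All sorters share the cohort's mean
rank pattern, so cohort-level fluctuations move everyone's alignment and
categoricality together; the effective sample size is a few hundred, and
the estimate scatters around zero with an SD near 0.05 across seeds. The
sign and approximate magnitude (≈ 0) are stable; the second decimal is not.

The grid demonstration constructs two identically assigned lattice sorts:
alignment is exactly 1 while a checkerboard A/B labeling yields near-zero
categoricality and every candidate k has low silhouette — perfect alignment
without categorical structure is possible in principle, which is precisely
why the observed tight coupling of alignment and categoricality in human
sorts is informative.

## Problem sizes

Defaults throughout are the study-scale values: 20 items, ~40 sorters per
condition, 3000 sorters in the null study. Tests exercise smaller cohorts
(3–20 sorters) for speed where the property under test does not depend on
cohort size, and full scale where it does (the null study, mediation
recovery at 200/condition × 100 replicates, monotonicity at 500
sorters/level).

## Known limitations

- The synthetic prototypes are stand-ins; geometric properties of the
  original hand-drawn shapes (e.g. nameability) are out of reach.
- Mixed-effects / multiple-membership dyadic models are out of scope; the
  aggregation approach is the implemented path.
- Sorter strategies beyond the four listed (e.g. serial chaining, edge
  anchoring) are not modeled.
- The point-stimulus free-sort composition (9 seen + prototype) is an
  inference from the set sizes, as the 3+6+1 recipe cannot apply there.
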