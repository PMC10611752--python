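# Methods

## Model and assumptions

`trajalign` assumes a cohort of individuals undergoing the *same* underlying
progression process at individual-specific, possibly nonlinear rates.
Formally, sample `n` of individual `i`, collected at within-individual
scaled time `u ∈ [0, 1]`, is assumed to measure the process state at latent
time `w_i(u)`, where `w_i` is an unknown strictly increasing warp.  The goal
is a per-sample estimate of that latent position — disease pseudotime —
without ever comparing absolute times across individuals.

Consequences of the assumptions:

* **Time is ordinal within an individual and meaningless across them.**
  Only the ordering and relative spacing of one individual's samples enter
  the model; all within-individual times are min–max scaled to [0, 1].
  Any affine transform of an individual's clock leaves the fit unchanged;
  any strictly increasing transform preserves sample order and endpoint
  anchoring.
* **A shared backbone exists.** Some features (the conserved-dynamics seed)
  must change monotonically with progression in most individuals.  Seed
  detection is deliberately restricted to increasing or decreasing
  features; processes whose markers rise and fall would need a predefined
  seed or an extended detector.
* **One-dimensional dynamics.** The consensus is a single curve; branching
  or cyclic processes are out of scope.
* **Every training individual spans the modeled range.** Progressive
  averaging aligns whole trajectories; an individual observed only in a
  late window is represented only there, and non-progressing individuals
  should be excluded from training (they can still be projected — that is
  how the progressor/non-progressor contrast is produced).

## Procedure

1. **Validation.** Individuals need ≥ 3 samples; features with NaN or zero
   variance are excluded from seed candidacy; duplicate sample ids and
   non-finite times are hard errors.  Duplicate within-individual times are
   an error by default (ordering is the model's only use of time; silent
   tie-breaking hides data problems) and can be resolved by stable-order
   epsilon jitter on request.
2. **Seed selection.** Raw (unstandardized — Pearson and Spearman are
   location/scale free) per-individual profiles are linearly interpolated
   onto `G` uniform scaled-time points.  Features pass the monotone filter
   when a fraction ≥ `consistency_min` of individuals show the majority
   trend sign with |Spearman| ≥ `rho_min`; survivors are ranked by the mean
   pairwise-Pearson conservation score and the top `K` kept.  Sign ties
   break to +1 and score ties break lexicographically, for determinism.
3. **Alignment.** Each individual's seed profile is z-scored with training
   means/sds (population sd) and interpolated onto `G` grid points, giving a
   `G × S` point sequence.  Pairwise alignment is classic dynamic time
   warping — steps {(1,0), (0,1), (1,1)}, no gap penalty, Euclidean point
   cost by default (`1 − Pearson` optional) — with backtrace ties preferring
   the diagonal, then the step reducing the first index.  Consensus building
   is progressive: align running consensus to the next individual, average
   matched points with contribution weights, resample to `consensus_length`.
   The merge order matters, so an ensemble of `n_members` consensus curves is
   built from independent random permutations (optionally random subsets) of
   the individuals.
4. **Projection.** A sample is standardized into seed space and assigned,
   per member, the normalized index of its nearest consensus point (ties to
   the smallest index); pseudotime is the mean across members (median
   optional) and the member standard deviation is reported as dispersion.
   Nearest-point assignment was chosen over continuous arc-length projection
   for determinism and simplicity; positions are normalized per member
   before averaging so members of different lengths are commensurable.
5. **Downstream statistics.** Feature association: Pearson `r` plus an
   F-test of a polynomial regression (default degree 2 — saturating
   dynamics without overfitting 3-point series) against the intercept-only
   model, BH-corrected across features; constant features are reported with
   `r = 0, p = 1` and a flag rather than NaN.  Dual-axis classification
   labels each feature by which axes reach a q cutoff, optionally swept over
   `10⁻⁵ … 10⁻¹`.  Enrichment: two-sample KS on member vs background
   correlation coefficients, scored `−log10 p`; a `signed` mode tests each
   direction one-sidedly.  Transition point: over thresholds in [0.1, 0.9]
   (step 0.01), the absolute Welch-t of pre vs post groups (each ≥ 5
   samples) is maximized, with an optional permutation p-value
   (`(1 + #{null ≥ obs})/(1 + B)`).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `G` | 10 | grid points per individual; comparable to the densest cohorts this model targets (10–15 points) without inventing resolution |
| `K` | 50 | seed size; cohort-specific in practice (a transcriptome cohort may use 100, a 10-feature imaging panel uses all 10 predefined) |
| `rho_min` | 0.3 | minimum \|Spearman\| for an individual to count as trending |
| `consistency_min` | 0.7 | fraction of individuals that must share the majority trend |
| `consensus_length` | 50 | consensus resolution; bounds memory/time, ≥ any individual grid |
| `n_members` | 50 | ensemble size; order randomization is the only stochasticity |
| `cost_metric` | euclidean | point cost; `pearson` (1 − r) offered for shape-dominated data |
| `rng_seed` | 0 | single source of randomness, recorded in the model archive |

All tables are written with 17 significant digits so round-trips are exact
for float64 (the reader parses with round-trip precision).

## The synthetic cohorts

The generator emulates the structural features the method must cope with:
irregular per-individual sampling (5–10 points over a log-normal
individual-specific span), strictly monotone individual warps (Beta CDF
with shapes `exp(N(0, 0.75))`), a minority of shared-dynamics features
(logistic templates of latent time: amplitude U(1, 3), random sign,
midpoint U(0.25, 0.75), steepness U(5, 15); individual intercepts
N(0, 0.5²)) among i.i.d. Gaussian noise features, measurement noise sd 0.5,
and optionally non-progressing individuals whose latent state is frozen at
a random constant.

It does **not** emulate: count noise or library-size effects of raw
sequencing data (inputs are assumed normalized upstream), batch effects,
missing values, correlated noise between features, features with
non-monotone dynamics, or cohort-level confounders.  Passing tests
therefore demonstrate correct behavior of the algorithmic machinery under
the stated generative assumptions — monotone shared dynamics distorted by
monotone warps — not robustness to every artifact of real omics data.

## Numerical choices

* Linear interpolation everywhere (profiles, consensus resampling):
  deterministic, monotone-preserving, and stable for 3–15-point series
  where splines are not; consensus endpoints are preserved exactly on
  resampling.
* DP backtrace tie-breaking and argmin tie-breaking are fixed (diagonal
  first; smallest index), making fits and predictions bit-reproducible for
  a given seed.
* Standardization uses the population standard deviation; zero-variance
  seed features are rejected with the feature named.
* Association p-values are floored at the smallest positive float to keep
  `−log10` finite; F-statistics from numerically perfect fits map to that
  floor.
* The threshold scan runs on prefix sums after sorting by pseudotime,
  making permutation calibration cheap (O(B·(N + T))).

## Design choices where the design was open

* The exact conservation statistic, alignment recurrence and ensemble
  construction are this package's own: mean pairwise Pearson for
  conservation, unpenalized DTW for alignment, and order-randomized
  progressive averaging for the ensemble.  They satisfy the published
  contract of the approach (trajectory alignment on a conserved seed,
  prediction from a set of consensus trajectories) but no bit-compatibility
  with any other implementation is claimed.
* Interpolation is on scaled time rather than sample rank; with irregular
  sampling, scaled time preserves relative spacing information that rank
  discards.
* Ensemble members are combined by mean (median optional); dispersion is
  reported rather than folded into the estimate.
* Patient-specific progression *rates* are not an operation; the recipe —
  refit with one individual held out, project, regress position on
  chronological time — can be assembled from `subset_individuals`, `fit`
  and `predict` (the leave-one-out test does exactly this).

## Known limitations

* Nearest-point projection quantizes pseudotime to `1/(L−1)` steps; two
  samples closer than the local consensus spacing can tie or invert.
* Individuals whose warp compresses most samples into a tiny latent
  interval have genuinely unrecoverable internal ordering once noise
  exceeds the latent signal spacing; cohort-level recovery is the
  meaningful guarantee (the leave-one-out check asserts the median over
  held-out individuals).
* Progressive averaging can underweight individuals merged early when
  subsampling is enabled; weights mitigate but do not remove order effects
  — hence the ensemble.
* The transition-point scan assumes a single mean shift; gradual or
  multiple changes yield a best single split, not a segmentation.

## Problem sizes used by the test suite

Unit tests run on compact cohorts (4–8 individuals, 12–42 features); the
end-to-end checks use the generator defaults (10 individuals, 200 features,
ensembles of 5–20 members) and the acceptance script mirrors those sizes —
the full suite and the acceptance script each complete in well under a
minute on a single CPU.
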