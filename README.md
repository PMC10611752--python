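# trajalign

**Disease pseudotime from short longitudinal omics profiles, by multiple
trajectory alignment.**

Longitudinal disease cohorts are hard to compare across patients: each
individual is sampled at different times, a different number of times, and
progresses at their own rate, so chronological time is a poor coordinate for
disease state. `trajalign` infers a shared *disease pseudotime* — a scalar in
[0, 1] placing every sample on a common progression axis — from a
feature × sample matrix (bulk transcriptomes, proteomes, imaging-derived
features, …) with as few as three time points per individual.

It is aimed at computational biologists analyzing short, irregular
time-series cohorts (challenge studies, recurrent-tumor series, periodic
clinical imaging) who need a progression coordinate that is comparable
across patients.

## Method

Given profiles `x_i(t)` for individuals `i` at within-individual times `t`:

1. **Conserved-dynamics seed.** Select a small feature set `S` whose dynamics
   are monotone within individuals and similar across them.  For feature
   `g`, each individual's profile is interpolated onto `G` uniform positions
   of min–max-scaled time; the conservation score is the mean Pearson
   correlation over all individual pairs, and a Spearman-based
   monotone-consistency filter keeps only features trending the same way in
   ≥ 70 % of individuals (defaults `K = 50`, `ρ_min = 0.3`).  The seed can
   instead be predefined by the user.
2. **Multiple trajectory alignment.** Each individual becomes a sequence of
   `G` standardized seed vectors.  Sequences are merged progressively:
   dynamic time warping (steps →, ↓, ↘; Euclidean point cost
   `d(i,j) = ‖a_i − b_j‖`; cumulative cost
   `D(i,j) = d(i,j) + min(D(i−1,j), D(i−1,j−1), D(i,j−1))`) aligns the
   running consensus to the next individual, points are averaged weighted by
   how many profiles they summarize, and the consensus is resampled to a
   fixed length `L` (default 50).  Because the result depends on merge
   order, the model keeps an ensemble of `B` consensus trajectories from
   random orders (default 50).
3. **Pseudotime.** A sample is standardized into seed space and placed at
   its nearest point on each consensus member; its pseudotime is the mean
   normalized position `(argmin_j ‖x − c_j‖)/(L−1)` across members, with the
   member standard deviation reported as dispersion.  Prediction never uses
   the time column, so new or cross-sectional samples project the same way.

Downstream, the package associates features with pseudotime (Pearson `r`
plus a polynomial-regression F-test, BH-corrected), classifies features by
pseudotime-vs-chronological-time association, scores gene-set enrichment
with a two-sample KS test on correlation coefficients (`−log10 p`), and
locates transition points (sharp shifts of a scalar such as tumor purity)
along pseudotime with a Welch-t threshold scan and permutation calibration.

A built-in generator simulates cohorts with known latent progression,
individual-specific monotone warps, planted seed features and optional
non-progressing individuals, and is used by the test suite throughout.

## Worked example

```python
import trajalign as ta

cohort = ta.simulate_cohort(rng_seed=1)          # 10 individuals, 200 features
model  = ta.fit(cohort.dataset, K=50, n_members=20, rng_seed=1)
est    = ta.predict(model, cohort.dataset)
print(ta.evaluate_recovery(cohort, est)["spearman_global"])
# 0.981  -- pooled Spearman between pseudotime and the true latent time

print(ta.estimates_frame(est).head(4))
#  sample_id  pseudotime  dispersion
#   ind00_s0    0.028571    0.051386
#   ind00_s1    0.134694    0.114431
#   ind00_s2    0.100000    0.110449
#   ind00_s3    0.127551    0.113238

pt    = [e.pseudotime for e in est]
assoc = ta.associate_features(cohort.dataset.values, pt,
                              cohort.dataset.feature_names)
print((assoc.q_value < 0.01).sum())
# 49  -- of the 50 planted dynamic features reach q < 0.01

corrs = assoc.set_index("feature")["pearson_r"]
print(ta.pathway_enrichment(corrs, {"planted": cohort.planted_seed}))
#   pathway  n_members  ks_statistic   p_value    score
#   planted         50          0.56  2.54e-11  10.60
```

The pseudotime column orders ind00's samples along the shared axis even
though its chronological sampling grid is unique to it; dispersion is the
spread of positions across ensemble members (an uncertainty proxy).

The same pipeline runs from the shell:

```
trajalign simulate --rng 1 --out-prefix cohort
trajalign seed    --matrix cohort_matrix.tsv --meta cohort_meta.tsv --k 50 --out seed.tsv
trajalign fit     --matrix cohort_matrix.tsv --meta cohort_meta.tsv --k 50 --rng 1 --out model.json
trajalign predict --model model.json --matrix cohort_matrix.tsv --out pt.tsv
trajalign associate --matrix cohort_matrix.tsv --pseudotime pt.tsv \
    --time-from cohort_meta.tsv --out assoc.tsv
trajalign enrich  --assoc assoc.tsv --gmt sets.gmt --out enrich.tsv
trajalign changepoint --values purity.tsv --pseudotime pt.tsv \
    --permutations 199 --out spip.txt
```

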