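# Methods

This note records the statistical procedures immunomet implements, the
modeling assumptions behind them, the defaults and why they were chosen,
and what the synthetic cohort does and does not emulate.

## Problem setting

Bulk expression profiles of pre-treatment breast tumor biopsies carry
transcriptional footprints of tumor-infiltrating immune cells. Three
immune metagenes — B/P (B cells / plasma cells), T/NK (T and
natural-killer cells) and M/D (monocytes / dendritic cells) — together
with a proliferation metagene P summarize those footprints as per-tumor
scores. The analysis asks whether the immune scores predict pathologic
response to neoadjuvant chemotherapy, on their own and after accounting
for proliferation and intrinsic molecular subtype.

## Preprocessing

Pooled multi-dataset cohorts are consolidated in a fixed order, each
stage a pure transformation with a machine-readable report:

1. **Profile deduplication.** The same tumor deposited in several GEO
   series, or hybridization repeats, show near-perfect pairwise Pearson
   correlation. Any sample correlated above 0.99 with an earlier-ordered
   sample is dropped; the earlier one is kept (stable, documented).
   Technical replicates on these array platforms exceed 0.99, so the
   threshold separates replicates from merely similar tumors.
2. **Outlier-array screening.** Arrays with failed hybridizations show
   globally depressed signal. A sample is removed when its median
   intensity lies more than 3 normal-consistent MADs *and* at least 0.5
   log2 units below the cohort median of per-sample medians. The
   absolute floor stops tightly homogeneous cohorts from flagging
   samples on a noise-scale MAD; the rule as a whole is a declared
   surrogate for an unstated original criterion, not a reconstruction.
3. **Common-probe restriction.** Matrices from different platforms are
   intersected on their shared probe panel (order follows the first
   matrix).
4. **Quantile normalization.** Every sample is mapped onto the
   mean-of-sorted reference distribution; ties receive the reference
   value interpolated at their average rank, making the map
   deterministic and idempotent. This is a stand-in for probe-level RMA,
   which requires CEL files and is out of scope — the package accepts
   already-normalized matrices.
5. **Batch adjustment.** Parametric empirical-Bayes location/scale
   correction (the standard ComBat recipe with an intercept-only
   design): per-probe standardization against the size-weighted grand
   mean and pooled variance, per-batch location/scale estimates shrunk
   toward normal / inverse-gamma priors fit across probes, then
   back-transformation. Batches need at least two samples; a single
   batch is the identity. The implementation follows the Bioconductor
   `sva::ComBat` reference and is tested against it directly (agreement
   to 1e-4 on a shared fixture).

## Metagene scoring

Scores use a two-stage mean: probe sets mapping to the same gene symbol
are averaged first, then gene-level values are averaged across the
metagene's member genes, per sample, on the log2 scale. Three probe sets
shared between the T/NK and M/D definitions are excluded by default so
the immune compartments stay disjoint. Signature probes missing from a
matrix are skipped and logged when at least half the metagene's probes
are present; below that the scoring fails loudly, because pipelines on a
common probe panel should have near-full coverage.

Modeling uses the raw (uncentered) score; one odds-ratio unit is one
log2-intensity unit of that score, recorded in the run manifest.
Mean-centering exists only for cross-dataset distribution comparison.
Proliferation tertiles (low / intermediate / high) cut at the empirical
33rd/66th percentiles taken at the lower adjacent order statistic, with
scores equal to a threshold falling in the lower group — the identical
partition to linearly interpolated thresholds under the ≤ rule, but
exactly invariant under monotone transforms of the scores. Tertiles are
computed on the full scored cohort; response analyses then use each
stratum's annotated subset, so stratum sizes need not be equal.

## Subtype assignment

Intrinsic subtype is the nearest centroid by Spearman correlation over
the shared panel genes, requiring at least 50% panel coverage. The six
centroids (Basal, LumA, LumB, HER2-E, Normal-like, Claudin-low) are data
supplied as a TSV, not code. Handling claudin-low as a sixth centroid in
the same pass is a deliberate single-stage simplification of the
published two-stage claudin-low predictor; ties are broken by centroid
column order with a logged warning.

## Response coding and models

Response is binary: RCB 0 or 1, or pCR = yes when RCB is unassigned,
codes 1; any other case with outcome data codes 0; no outcome data is
missing. RCB wins over a contradictory pCR flag, being the
finer-grained measure. Entries recorded as `uncertain` (discordant
across source datasets) are censored. All models are complete-case on
their own variables, so each table uses the maximal annotated subset for
its covariates and the reported n varies by table.

Logistic models are maximum-likelihood fits (Newton; score tolerance
1e-8, 100 iterations) with Wald 95% CIs exponentiated to the OR scale
and likelihood-ratio p-values, matching how such tables are footnoted.
Categorical covariates expand to indicators against a declared
reference: Normal-like for subtype, positive for ER (ORs read
negative-versus-positive). Perfect separation is flagged as
non-converged (|log-odds| > 15 or optimizer failure) rather than
raised, with the log-likelihood evaluated in a numerically stable form
so downstream LRTs stay finite; a rank-deficient design is an error
naming the collinear columns.

The association analyses are: simple models per metagene and for
subtype; immune models adjusted for P and subtype (LRT on the immune
term); per-stratum simple models across P tertiles and across subtypes
(strata with fewer than 10 annotated cases are reported but not
modeled, which is why very small subtypes drop out); and two
forward-stepwise selections with a stay criterion (entry and stay at
p = 0.05, LRT-based, lexicographic tie-break) over ER, P, the three
immune metagenes and subtype coded either as one categorical term or as
six separate binary indicators. LRT-based stepwise at 0.05/0.05 is a
choice: the original software's stepwise defaults (score/Wald tests)
are unknowable from a published table and can flip selections that sit
near p = 0.05. Treatment-by-response independence is a Pearson
chi-square on a 4×2 table after collapsing the eight regimen labels
into anthracycline-only, anthracycline+taxane, taxane-only and
unspecified — a documented grouping, since an 8-level table cannot be
the published 4×2 one.

## Synthetic cohort

The simulator generates the statistical structure the analysis assumes,
so every stage runs offline:

* **Latent factors.** (B/P, T/NK, M/D, P) come from a Gaussian copula.
  Spearman targets are converted to Pearson via 2·sin(πρ/6). The
  M/D–T/NK entry is 0.80 (the observed value in real cohorts); the
  remaining immune–immune entries default to 0.6 and immune–P to 0.0 —
  free parameters labeled as assumptions, since only the 0.80 is
  pinned by observation.
* **Subtypes.** Drawn at frequencies Basal .30, LumA .31, LumB .19,
  HER2-E .11, Claudin-low .07, Normal-like .02. Proliferation is
  shifted per subtype (+0.9 Basal, +0.6 HER2-E, +0.5 LumB, −0.6 LumA,
  −0.3 Normal-like), making Basal/HER2-E/LumB the proliferative
  classes. ER positivity is subtype-dependent (10% in Basal, 95% in
  LumA), so ER is negatively associated with Basal as in real cohorts.
* **Response.** Bernoulli with logit = intercept + Σ effect·latent +
  subtype term. Effects default to the log of per-unit odds ratios
  1.60 (B/P), 1.59 (T/NK), 1.69 (M/D) and 2.54 (P); subtype terms
  default to log univariate-scale ORs vs Normal-like (1.33 Basal, 1.12
  CL, 1.08 HER2-E, 0.18 LumA, 0.55 LumB). The intercept is calibrated
  by root-finding on a fixed 1e5-draw Monte-Carlo estimate of the
  marginal response rate (target 0.27; closed-form logit(0.27) when all
  effects are zero). RCB/pCR annotations are generated consistently
  with the drawn response (RCB 0/1 for responders, 2/3 otherwise; pCR
  yes exactly for RCB 0), with ~7% of RCB values blanked and a pCR flag
  backfilled for 60% of those, leaving ~3% of samples with no outcome.
* **Expression.** Each metagene is a miniature signature of 16 genes ×
  2 probes: gene value = latent + N(0, 0.4), probe row = gene value +
  N(0, 0.3). A 40-gene subtype marker panel has per-subtype means (the
  generative centroids, N(0,1)) plus N(0, 0.5) sample noise. 3000
  background probes are N(0,1). Everything sits on a baseline of 7 log2
  units with additive per-batch shifts (0, +0.4, −0.4 across three
  batches). Sixteen genes per metagene keeps measurement-error
  attenuation comparable to the real 19–54-gene signatures, and the
  3000 background probes keep signature probes a small fraction of the
  array (~4%, vs ~1% on real platforms) — important because quantile
  normalization of a matrix dominated by signature probes would strip
  the latent factors' shared component, an artifact impossible at real
  array scale.

**Attenuation.** Effects act on the noise-free latent scale, so fitted
coefficients on observed scores are attenuated: the score adds noise of
variance (0.4² + 0.3²/2)/16 ≈ 0.013 to the latent. Consequently the
observed M/D–T/NK Spearman is expected near 0.78 rather than 0.80, and
parameter-recovery tests compare CIs against pseudo-true coefficients
computed by a large-n (150,000-sample) oracle fit on score-level draws
rather than against the latent-scale generative values. The score-level
fast path used by that oracle adds noise of exactly the analytic
variance, so it matches the probe-level path by construction (verified
by test).

**What the simulator does not emulate:** full-transcriptome covariance,
probe-level chemistry (sequence effects, saturation), platform
differences, non-additive batch effects, treatment-effect
heterogeneity, and any coupling between treatment regimen and response
(treatment is drawn independently, matching the null chi-square
finding). Tests passing on this cohort show the pipeline's statistics
behave correctly under the assumed structure; they do not certify
performance on real arrays.

## Problem sizes and numerical choices

Default cohort size is 680 samples (the response-annotated panel scale);
replicate-based checks use 200 replicates at that size, and Monte-Carlo
calibration uses 1e5 draws. Convergence tolerances: 1e-8 for the
logistic score, 1e-4 relative change for the empirical-Bayes shrinkage
iteration, 1e-6 for intercept root-finding. Degenerate inputs are
handled explicitly: all-equal scores put every sample in the low
tertile with a warning; constant score vectors make Spearman entries
undefined (NaN) with a warning; a stratum below 10 annotated cases is
reported but not modeled; LRTs between non-converged fits report NaN
rather than a sham p-value.

## Known limitations

* The outlier-array rule and the 0.99 deduplication threshold are
  declared surrogates for the original cohort's unstated criteria.
* Claudin-low assignment by a sixth centroid underestimates the
  published predictor's sophistication.
* Stepwise selection near the entry/stay boundary depends on the test
  statistic used; see above.
* Wald CIs on pseudo-true projections under mild model
  misspecification (measurement noise in scores) are asymptotically
  slightly conservative or liberal depending on the direction; at the
  cohort scale used here their empirical coverage stays within
  0.90–0.98 (tested), but exact nominal coverage is not claimed.
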