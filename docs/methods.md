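# Methods

This note documents the models, estimators, defaults and limitations of
`neurotau`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Timescale estimation

The sample ACF uses the biased normalization
r_k = Σ_{t≤T−k} (x_t−x̄)(x_{t+k}−x̄) / Σ_t (x_t−x̄)², with a single global
mean. This guarantees |r_k| ≤ 1 and is the common neuroimaging convention;
the unbiased per-lag variant can exceed 1 at long lags and destabilizes the
positive-sum estimator. Default `max_lag = min(50, T/2)` covers BOLD
timescales at typical TRs while bounding cost. Zero-variance voxels are
flagged missing (NaN), never silently 0, so they cannot bias group
statistics. Degeneracy is detected relative to the signal amplitude, so the
estimators are exactly invariant to affine rescaling of the signal.

**Positive-sum definition.** τ = TR · Σ r_k over the *initial* run of
strictly positive lags, excluding lag 0. Excluding lag 0 makes white noise
map to τ = 0, the interpretable zero point (including it adds a constant TR
to every voxel and cannot change contrasts or correlations). Stopping at the
first non-positive lag, rather than summing all positive lags anywhere,
discards later positive excursions of the sample ACF, which are noise.

**Half-FWHM definition.** The ACF of a stationary process is symmetric, so
half its full width at half maximum is the lag k* where r decays through
0.5. We locate k* by linear interpolation in the first bracketing interval
[k, k+1] with r_k ≥ 0.5 > r_{k+1}. If the ACF never drops below 0.5 within
`max_lag`, the estimate is right-censored at TR · max_lag and flagged.

*Resolution limit.* Linear interpolation is exact when the crossing falls on
an integer lag and accurate when it falls beyond lag 1, but for processes
whose crossing lies inside the first sampling interval (AR(1) with φ < 0.5)
the convexity of the ACF biases the interpolated crossing upward, and the
bias does not vanish with T. Closed-form recovery checks therefore evaluate
the half-FWHM estimator at φ ≥ 0.5, where the population crossing is at
lag ≥ 1; below that the quantity is under the temporal resolution of the
sampling grid. The positive-sum estimator has no such limit and is checked
over φ ∈ [0.2, 0.8].

## ALFF

Voxel signals are linearly detrended (no taper) and transformed with an
rFFT; amplitudes are scaled so that the sum of squared amplitudes over all
bins equals the mean square of the detrended signal (a_k = √2 |X_k| / T at
interior bins), a Parseval identity the tests verify. ALFF is the mean
amplitude over the band 0.01–0.08 Hz by default — the convention of the
resting-state toolboxes this index originates from; band and normalization
(`mean_divide` across gray-matter voxels for ALFF, `zscore` for FCD) are
arguments.

## FCD

The correlation threshold is the minimal r whose two-sided single-connection
p-value survives Bonferroni correction, obtained by inverting the exact
t-transform t = r√((T−2)/(1−r²)), df = T−2. The family defaults to
`per_seed` (n_voxels − 1 tests), matching the convention of FCD mapping;
`all_pairs` is available for sensitivity analysis. Only positive
correlations count as connections (standard FCD convention). Local FCD is
the size minus one of the contiguous cluster (face adjacency by default;
18/26-connectivity available) of suprathreshold voxels grown from the seed;
long-range = global − local, an identity the tests assert on raw counts.
Correlations are computed in seed chunks against all voxels so memory stays
bounded; output is bit-identical to the naive all-pairs matrix, which serves
as the test oracle.

## Dominance analysis

General dominance is computed by exhaustive enumeration of all 2^p − 1
subset models (p ≤ 12) with subset R² memoized by predictor bitmask and
computed from moment matrices; the empty model contributes R² = 0. The
values sum exactly to the full-model R² (asserted to 1e−10 against a
brute-force design-matrix implementation). Inputs to the landscape
decomposition are the across-subject mean maps, z-scored; note that *raw*
FCD means are exactly collinear (global = local + long-range), so the
pipeline averages per-subject z-scored FCD maps, whose subject-specific
scalings break the collinearity — this is also what the z-scoring convention
of the FCD literature produces. Voxels missing in any map are dropped
listwise with a logged count.

## Group statistics

The group contrast is an OLS GLM with intercept, group indicator (patients
= 1), and covariates age, sex (0/1), mean framewise displacement, SNR0 and
education, continuous covariates mean-centered. With no covariates the GLM
t equals the pooled-variance two-sample t exactly (tested to 1e−10).
Voxels missing in more than 20% of subjects are flagged; less-missing voxels
are refit on available subjects.

Cluster-level inference replaces parametric random-field correction with a
max-cluster-size permutation test: suprathreshold clusters (two-tailed
forming threshold, default p < 0.001; face adjacency; positive and negative
tails labelled separately) are compared against the permutation null of the
maximum cluster size. Permutations follow the Freedman–Lane scheme — the
nuisance-only model is fit, its residuals row-permuted, the nuisance fit
added back, the full model refit — so covariates are respected under the
null. Corrected p uses the add-one estimator (1 + #{perm ≥ obs})/(n_perm+1);
the rejection rule p ≤ α is exact-level. Because cluster size is integer,
the test is conservative on spatially unstructured data where clusters are
single voxels; its empirical level is checked on spatially smooth null maps,
the regime cluster inference exists for.

Stage stratification bins patients by illness duration: stage 1 0 ≤ d ≤ 12
months, stage 2 12 < d ≤ 24, stage 3 d > 24, with early-onset flags d < 3
and d < 6. Each stage is contrasted against the full control group.

`map_correlation` tests a whole-map Pearson r by permuting one map's voxel
values. This exchangeability null ignores spatial autocorrelation (as does
the corresponding step of the published workflows it mirrors); a
variogram/spin-preserving null is out of scope and flagged as a limitation.

## Spatial (annotation) association

Maps are aggregated to atlas parcels by the mean over non-missing in-mask
voxels; parcels with fewer than 5 contributing voxels are flagged missing.
The association between the target (t-map) profile and each annotation
profile is a partial Spearman correlation: both rank vectors (average ranks
for ties) are residualized on the ranked gray-matter confound profile and
the residuals correlated. Significance comes from random permutation of the
target's parcel assignment, recomputing the partial correlation each time,
two-sided; family-wise error across the annotation family uses the
single-step max-|ρ| distribution from the same permutations, which is exact
under permutation and yields p_fwe ≥ p_perm by construction. Parcel
exchangeability again ignores residual spatial autocorrelation between
parcels; a spin-test hook is future work. Atlas robustness reruns the
analysis under alternative parcellations and reports sign agreement.

## Transcriptomic association and enrichment

Gene profiles are correlated (Pearson) with the parcel-aggregated
unthresholded t-map, restricted to left-hemisphere parcels by default
because donor coverage of expression atlases is left-dominant. Genes with
constant expression or fewer than 10 shared parcels are excluded and do not
count toward the Bonferroni family, whose size is the number of genes
actually tested (logged). A gene is listed positive (negative) if
r > +0.2 (r < −0.2) and Bonferroni-corrected p < 0.05; Bonferroni is the
conservative, assumption-free reading of "FWE corrected" for this family.

Enrichment of a list against a GMT collection is the one-sided
hypergeometric tail P[X ≥ k] for a term with K members in the universe
(N genes; list size n; overlap k), with BH-FDR across tested terms. The
universe is the expression matrix's gene set intersected with the GMT gene
space — explicit and reproducible. Term databases are user inputs, never
bundled. `shared_terms` intersects the significant terms of two enrichment
results (sorted by the larger q), supporting multi-list meta-analysis
against externally supplied gene lists.

## Synthetic cohort

The generator produces the statistical structure the analysis assumes and
nothing more (no hemodynamics, motion, or scanner physics):

* **Signals.** Voxel-wise AR(1), x_t = φ(v) x_{t−1} + ε_t, burn-in 200
  samples. φ follows a smooth spatial gradient (default 0.2 → 0.7 along the
  z-axis with a mild transverse modulation to avoid ties), giving the
  closed-form timescale ground truth τ = TR·φ/(1−φ). Innovations are
  spatially smoothed (periodic Gaussian, σ = 0.6 voxels, variance
  renormalized): this induces realistic spatial correlation — without it
  local FCD is identically zero — while leaving each voxel's marginal AR(1)
  law, and hence all timescale ground truth, exactly unchanged.
* **Patients.** φ is reduced by `delta_phi` (default 0.25) inside planted
  effect blocks (default one 100-voxel block in the long-timescale zone),
  scaled by stage multipliers 1.0 / 0.4 / 0.0, emulating an alteration that
  fades with illness duration; stage-3 patients are statistically identical
  to controls by construction. Covariates are drawn independently of group
  so the GLM adjustment is benign; illness durations are drawn within each
  stage's interval.
* **Cohort size.** Defaults: 10×10×10 grid (1000 voxels), 20 HC, 20/10/10
  patients per stage, T = 300, TR = 2 s — sized so the full pipeline runs in
  seconds on one CPU while leaving the stage-1 contrast well powered
  (the planted effect is ≈ 1.3–1.9 s of τ against a within-group spread far
  smaller after averaging).
* **Parcellation.** Deterministic near-equal blocks (default 5×5×5 = 125
  parcels of 8 voxels); hemisphere tags from the parcel centroid (left /
  midline / right); an `offset` parameter shifts block boundaries to provide
  alternative atlases for robustness checks.
* **Annotations.** For each requested ρ, the profile is built on
  rank-standardized, confound-residualized vectors: y = ρ·u + √(1−ρ²)·e plus
  a gray-matter loading (0.3), where u is the standardized rank-residual of
  the true parcel difference profile given gm — so the planted value is a
  partial Spearman by construction, up to the final ranking of y and the
  ties of the sparse difference profile, which attenuate the measured ρ
  somewhat; detection (not unbiased estimation) is the design goal. Defaults
  plant seven nonzero maps (5HT2a, D1, D2, DAT, FDOPA, NAT, SERT at
  ρ 0.5–0.7) and three nulls (GABAa, 5HT1a, 5HT1b).
* **Expression.** Planted genes (default 60 of 1500) get profiles
  sign·(r·d + √(1−r²)·ε) with r = 0.9 against the standardized true
  difference profile d, alternating sign so both the positive and negative
  lists are exercised; null genes mix a smooth spatial gradient (weight 0.3)
  with noise. The GMT collection contains a PLANTED term (planted genes +
  50% decoys) and 19 random decoy terms.
* **Reproducibility.** One config seed expands into per-subject and
  per-component substreams via `numpy` seed sequences; regeneration is
  bit-identical and independent of call order.

What passing tests on this generator do *not* show: robustness to
hemodynamic convolution, physiological noise spectra, motion artifacts,
registration error, or the heavy-tailed spatial autocorrelation of real
BOLD; those belong to preprocessing, which is explicitly out of scope.

## Numerical choices

* ACF via FFT with zero padding; equals the double-loop definition to
  1e−14.
* Correlation threshold infeasibility: corrected alpha so small that the
  required r is within 1e−9 of 1 raises an error rather than returning an
  unusable threshold.
* Partial Spearman residuals indistinguishable from rounding noise
  (‖resid‖ ≤ 1e−8 of the rank scale) raise a degenerate-confound error
  instead of returning a 0/0 artifact.
* Permutation p-values always use the add-one estimator, so p ∈ (0, 1].
* TR is taken from configuration, not the NIfTI header; a >1 ms mismatch
  with the header logs a warning.
* All stochastic operations take an explicit seed and log it.

## Known limitations

* Permutation nulls (voxel / parcel exchangeability) ignore spatial
  autocorrelation for the map-correlation and annotation tests; cluster
  inference handles it correctly by permuting subjects.
* The half-FWHM estimator is resolution-limited below a crossing of one
  sampling interval (see above) and right-censored profiles carry only a
  lower bound.
* Cluster-size inference is conservative on spatially unstructured data
  (integer statistic with heavy ties).
* Dominance is reported as general dominance only (no conditional/complete
  dominance, no bootstrap intervals).
* The pipeline assumes preprocessed, co-registered inputs on a shared grid.
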