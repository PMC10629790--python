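# Methods

## The inference problem

Given a voxel-wise group-difference t-map and donor-level expression samples
located in the same world space, the pipeline asks which genes' expression
topography aligns with the anatomy of the group difference. The statistical
difficulty throughout is spatial autocorrelation: both brain maps and
expression are smooth in space, so naive correlation p-values are badly
anti-conservative. Three devices address it at different stages: Moran
eigenvector covariates in the voxel-level association, sphere-rotation
(spin) nulls at ROI level, and random-gene-list bootstraps for gene-set
composites.

## Group-difference t-maps

Per masked voxel, ordinary least squares of subject intensities on a shared
design (intercept, group indicator, covariates; categorical covariates
one-hot with the first level dropped; a categorical contrast becomes a
single indicator of the level coded positive, so the map's direction
convention is explicit). t = c'β̂ / √(σ̂²·c'(XᵀX)⁻¹c) with σ̂² = RSS/(n−p).
Voxels with zero residual variance are NaN and flagged, never silently
zeroed. Variance is pooled across groups (the standard single-σ² GLM).
No smoothing happens here; smoothness is a property of the inputs.

## Voxel-level association

Samples take the t-value of their nearest voxel (rounding half to even);
samples outside the analysis mask are dropped and counted. For each probe:

* rank-transform expression and t-values (average ranks on ties);
* residualize **both** rank vectors on [1, E] where E holds Moran eigenvector
  maps built from the donor's sample coordinates — symmetric residualization
  keeps the statistic invariant to which variable is called x;
* the Pearson correlation of the residuals is the adjusted rho;
  t = rho·√((n−2−k)/(1−rho²)) with k = number of eigenvectors, and z is the
  signed normal quantile of its two-tailed p, capped at |z| = 8.21 (the
  double-precision limit of Φ⁻¹ near 1).

MEMs are the eigenvectors of H W H, W = 1/dᵢⱼ with zero diagonal and H the
centering matrix. Eigenvalue order is spatial scale order: the leading
vectors are the broadest smooth patterns.

**Retention rule.** The default keeps the broadest half of the spectrum
(k = ⌊n/2⌋). The more familiar rule — keep vectors whose Moran's I exceeds
its null expectation, i.e. the positive-eigenvalue block — is available as
`rule="positive-moran"`, and an explicit `k` can be given. The aggressive
default is deliberate: a Gaussian-random-field confound spreads its energy
well past the positive-eigenvalue block of the inverse-distance operator, so
retaining only that block leaves enough structured residual to inflate
false-positive rates noticeably (we measured ~9–11% at nominal 5% under the
generator's conditions, versus ~5–7% with the half-spectrum rule, and ~20%
unadjusted). The cost is absorbed signal; the df term n−2−k keeps the test
honest about it, and the planted-signal analyses below show the power that
survives. Calibration holds because residualizing the *map* side against a
near-complete smooth basis leaves a map residual close to exchangeable, and
exchangeability of one side is enough for a correlation null.

**Donor combination.** Per probe, donor z-scores are combined with
Z = Σwᵢzᵢ/√(Σwᵢ²); weights default to donor sample counts (√n and equal
weights are options). With equal weights this is exactly the unweighted
Stouffer statistic. Probe T is the same weighted mean of donor t-statistics.

**Gene level.** Gene T is the unweighted mean of its probes' T. The gene
Z is the mean of probe Z's treated as perfectly correlated (the mean of
perfectly correlated unit normals is a unit normal), and gene p is its
two-tailed transform. This is conservative: probes of one gene measure the
same transcript with correlated error, and assuming correlation 1 never
understates the variance of the mean. Probes disagreeing in sign are
retained in all statistics. Top-fraction lists take ⌈frac·N⌉ genes from each
end of the T ranking; ties break alphabetically from opposite ends so
equal-T lists stay disjoint and deterministic.

## ROI arm

The ROI pipeline is intentionally separate from the voxel arm (they consume
probes differently): background filter (probe kept if above background in
strictly more than 50% of samples), max-intensity probe per gene
(lexicographic probe-id tie-break), sample→parcel assignment (containing
parcel, else nearest labelled voxel centre within 2 mm, else unassigned),
per-donor ROI means, per-gene scaled robust sigmoid across ROIs
(median/IQR with the 1.35 normal-consistency factor, then min–max to [0,1]),
then the across-donor mean where an ROI missing in one donor takes the mean
of the donors that have it.

## Spatial nulls

Spin test: Haar-uniform rotations (QR of a Gaussian matrix with sign
correction, det +1) applied to unit-sphere parcel centroids; each parcel
receives the value of the parcel whose original centroid is nearest to its
rotated centroid. The default greedy reassignment can duplicate source
parcels (standard for volumetric spins); an optimal one-to-one assignment
preserving the value multiset is available. p_spin = (1+#{|rho_null| ≥
|rho_obs|})/(1+n_perm), two-tailed, never zero. Rotations are applied to the
single hemisphere's centroids without mirrored-pair averaging, matching a
left-hemisphere-only analysis.

PC1 composites: genes centred across ROIs, SVD, scores = first right
singular direction scaled by its singular value, sign fixed by nonnegative
mean loading (inference is on |rho|, so the sign convention only affects
reporting). The random-gene-list bootstrap redraws lists of the target-list
size (distinct genes, target excluded), recomputes PC1 and its Spearman
correlation with the target map, and uses the same empirical two-tailed p.

## Cell-type enrichment

Specificity s[g,c] = mean expression of g in c over its sum across types;
all-zero genes are dropped and listed. The EWCE statistic for a target list
is its summed specificity per type; nulls redraw lists respecting the
target's joint transcript-length × GC decile-bin composition (10×10 bins by
default; 1 bin = unmatched). p is upper-tail empirical with +1 smoothing,
BH-adjusted across the cell types of one run; the effect size reported is
standard deviations from the null mean. Fine matching degrades gracefully:
with very small gene universes the bins collapse toward the target itself,
so enrichment analyses should use universes comfortably larger than
n_bins². DEG overlap uses the inclusive upper-tail hypergeometric
P(X ≥ k); the default universe is the intersection of association-table
genes and reference genes. BH is the standard step-up procedure
(statsmodels' fdr_bh).

## Summary-statistics tests

Pooled-variance (Student) two-sample t from printed mean/SD/n, and the
uncorrected Pearson chi-square on 2×2 counts. Pooled rather than Welch, and
no Yates correction: these are the variants that reproduce demographic-table
p-values computed from summary data at printed precision, and they match a
raw-data pooled t-test exactly on moment-matched samples (tested).

## Synthetic data: what it emulates and what it does not

All generators hang off one `SeedSequence` fanned into fixed-order
substreams (cohort covariates, cohort noise, expression layout, expression
noise, parcellation, cell-type reference), so every stage is
bit-reproducible and adding a consumer does not shift earlier streams.

* **Cohort images**: baseline + group·effect_map + covariate contributions +
  Gaussian-smoothed white noise rescaled to unit variance (FWHM sets the
  autocorrelation scale; default 2 mm voxels, 12 mm FWHM — chosen, like all
  generator defaults, for testability of the statistical properties rather
  than anatomical realism, since effect sizes and autocorrelation scales of
  real maps are study-specific). Site is a four-level categorical; age and
  TIV effects apply per SD of the covariate.
* **Donor expression** (default 2 donors × 200 samples × 200 genes): per
  gene, base level + coupling_beta·(sign)·standardized map t at the sample
  + spatially smooth noise (unit-variance smoothed field, default FWHM
  12 mm) + i.i.d. measurement noise of equal amplitude. The i.i.d. component
  matters: microarray data has substantial measurement noise, and a
  generator with purely smooth variation would make *any* finite spatial
  basis mis-calibrated by construction. Planted fractions default to 10%
  positive, 10% negative with coupling_beta = 2.0 (a strong planted signal,
  so recovery analyses measure the ranking machinery rather than borderline
  power). Bad probes are appended per filter class; low-expression probes
  are built to sit below the background level in well over half of samples;
  samples carry cortical/hemisphere labels (bottom-slab non-cortical,
  left/right split).
* **Parcellation**: Voronoi labels grown from random seed voxels (cells on a
  lattice are contiguous); ROI centroids are re-centred world coordinates
  projected to the unit sphere.
* **Cell-type reference**: markers have expression `marker_fold` in their
  type and 1 elsewhere, so marker specificity is fold/(fold+C−1) exactly
  (4/7 at fold 4 with 4 types); DEG lists are fixed-size samples of each
  type's markers. Marker sets can be pinned to chosen genes so end-to-end
  runs can plant cell-type signatures inside map-coupled gene sets.

Passing tests on these data show the statistics do what they claim under
known ground truth with realistic nuisance structure (smoothness, probe
pathologies, donor imbalance). They do not show robustness to what the
generator omits: anatomical geometry, non-Gaussian expression distributions,
donor-specific batch effects, scanner-site interactions, or registration
error.

## Numerical choices

* Nearest-voxel rounding is round-half-to-even; ties are measure-zero with
  jittered sample coordinates.
* Duplicate sample coordinates make 1/d weights infinite and are rejected
  rather than silently jittered.
* z-scores are capped at ±8.21; the cap is the Φ⁻¹ double-precision limit.
* Combined p-values are floored at the smallest positive double, keeping
  them in (0, 1].
* Empirical p-values use (1+k)/(1+n) and are never zero.
* EWCE without-replacement draws use chunked random-key argpartition with a
  ~2·10⁷-element working-set bound, so 100k permutations fit in memory.

## Problem sizes

The shipped tests and the acceptance script run the association analyses at
2 donors × 200 samples × 200 genes on a 20³ grid (20+20 subjects), spin
calibration at 60 ROIs × 500 rotations × 200 map pairs, Moran preservation
on a 250-ROI parcellation, and the EWCE oracle at 20 000 permutations —
sizes at which every Monte-Carlo criterion is stable across seeds while the
whole suite stays interactive.

## Known limitations

* The MEM basis costs an O(n³) eigendecomposition per donor; thousands of
  samples per donor would want a sparse/truncated variant.
* Gene-level p under the perfect-correlation assumption is conservative for
  genes whose probes are only weakly correlated.
* The spin test assumes parcel centroids lie meaningfully on a sphere;
  volumetric parcellations with strongly non-spherical geometry weaken the
  null's autocorrelation preservation.
* ORA treats annotation terms independently (no ontology-graph propagation),
  and BH is applied globally across tested terms by default.
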