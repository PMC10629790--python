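"""ROI-level topographic association with spin and bootstrap nulls.

Aggregates donor expression into a gene x ROI matrix (background filter,
max-intensity probe per gene, 2 mm sample assignment, robust-sigmoid
normalization, two-stage averaging), summarizes a coherent gene module with
its first principal component and tests its correlation with a target gene's
topography against sphere-rotation and random-gene-list nulls.
"""

import imgx

spec = imgx.CohortSpec(
    n_control=20, n_case=20, grid_shape=(20, 20, 20), smooth_fwhm_mm=12.0, seed=5
)
images, cov = imgx.gen_cohort_images(spec)
design = imgx.build_design(cov, contrast="group", covars=("age", "sex", "site"))
tmap = imgx.fit_tmap(images, design)

expr_spec = imgx.ExpressionSpec(n_donors=2, samples_per_donor=200, n_genes=120, seed=11)
se = imgx.gen_donor_expression(expr_spec, tmap)

parc, centroids = imgx.gen_parcellation(tmap.image.mask, tmap.image.affine, 60, seed=3)
roi = imgx.aggregate_roi_expression(se.donors, parc)
X = roi.values.dropna(axis=1)  # ROIs covered by at least one donor
print(f"ROI expression matrix: {X.shape[0]} genes x {X.shape[1]} ROIs")

# the planted-positive genes form a coherent module tracking the map
module = se.planted(1)[1:10]
target_gene = se.planted(1)[0]
target = X.loc[target_gene].to_numpy()

comp = imgx.pca_composite(X.loc[module].to_numpy())
print(f"module PC1 explains {100 * comp.variance_fraction:.1f}% of variance")

C = centroids.loc[[c for c in centroids.index if c in X.columns], ["cx", "cy", "cz"]].to_numpy()
spin = imgx.spin_test(target, comp.scores, C, n_perm=1000, seed=7)
print(f"spin test: rho = {spin.observed_rho:.3f}, p_spin = {spin.p_spin:.4f}")

boot = imgx.random_geneset_bootstrap(
    target, X.to_numpy(), gene_names=list(X.index), observed_genes=module,
    exclude=[target_gene], list_size=len(module), n_boot=1000, seed=8,
)
print(f"bootstrap:  rho = {boot.observed_rho:.3f}, p = {boot.p:.4f}")
print(
    "\nBoth nulls agree: the module's shared topography aligns with the"
    "\ntarget gene beyond what spatially-preserving rotations or random"
    "\ngene lists produce."
)
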