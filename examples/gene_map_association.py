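"""Spatially-adjusted gene-map association with planted coupled genes.

Simulates a group t-map and two expression donors in which 10% of genes are
positively and 10% negatively coupled to the map, runs probe filtering, the
MEM-adjusted per-donor Spearman stage, weighted-Z donor combination and
probe-to-gene averaging, and shows that the planted genes dominate the
signed ranking.
"""

import imgx

spec = imgx.CohortSpec(
    n_control=20, n_case=20, grid_shape=(20, 20, 20), smooth_fwhm_mm=12.0, seed=5
)
images, cov = imgx.gen_cohort_images(spec)
design = imgx.build_design(cov, contrast="group", covars=("age", "sex", "site"))
tmap = imgx.fit_tmap(images, design, direction="case > control")

expr_spec = imgx.ExpressionSpec(
    n_donors=2, samples_per_donor=200, n_genes=200,
    pos_gene_frac=0.1, neg_gene_frac=0.1, coupling_beta=2.0, seed=11,
)
se = imgx.gen_donor_expression(expr_spec, tmap)

run = imgx.run_association(se.donors, tmap, hemisphere=None, cortical=None)
print("probe filter exclusions:", run.filter_counts)
print(f"{run.n_probes_kept} probes kept, {len(run.genes.table)} genes scored\n")
print("strongest positive associations:")
print(run.genes.table.sort_values("T", ascending=False).head(5).round(3))

auc = imgx.ranking_auc(run.genes.table["T"], se.planted(1), se.planted(-1))
pos, neg = imgx.top_fraction_lists(run.genes, frac=0.1)
hit = len(set(pos) & set(se.planted(1)))
print(f"\nplanted-positive vs planted-negative ranking AUC = {auc:.3f}")
print(f"{hit}/{len(pos)} of the top-decile positive list are planted-positive genes")
print(
    "\nAn AUC near 1 means the combined T statistic orders planted-positive"
    "\nabove planted-negative genes almost perfectly despite the shared"
    "\nspatial autocorrelation the MEM covariates absorb."
)
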