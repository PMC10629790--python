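"""Cell-type enrichment of map-associated gene lists.

Builds a marker-structured single-cell reference whose astrocyte and
endothelial markers are planted inside the positively map-coupled gene set
(neuronal and microglial markers inside the negative set), runs the
association stage, and tests the top-decile gene lists with the EWCE
specificity bootstrap and hypergeometric DEG overlap.
"""

import imgx

spec = imgx.CohortSpec(
    n_control=20, n_case=20, grid_shape=(20, 20, 20), smooth_fwhm_mm=12.0, seed=5
)
images, cov = imgx.gen_cohort_images(spec)
design = imgx.build_design(cov, contrast="group", covars=("age", "sex", "site"))
tmap = imgx.fit_tmap(images, design)

expr_spec = imgx.ExpressionSpec(n_donors=2, samples_per_donor=200, n_genes=200, seed=11)
se = imgx.gen_donor_expression(expr_spec, tmap)
pos, neg = se.planted(1), se.planted(-1)

marker_sets = {
    "astrocyte": pos[:10], "endothelial": pos[10:20],
    "neuron": neg[:10], "microglia": neg[10:20],
}
ct_spec = imgx.CellTypeSpec(n_celltypes=4, marker_fold=4.0, deg_size=5, seed=2)
mean_expr, annot, deg_lists = imgx.gen_celltype_reference(
    ct_spec, se.genes, marker_sets=marker_sets
)
S = imgx.compute_specificity(mean_expr, annot["length_bp"], annot["gc"])

run = imgx.run_association(se.donors, tmap, hemisphere=None, cortical=None)
top_pos, top_neg = imgx.top_fraction_lists(run.genes, frac=0.1)

print("EWCE on the positively associated top decile:")
res = imgx.ewce_test(top_pos, S, n_perm=20_000, seed=3)
print(res.table[["sd_from_mean", "p", "p_adj"]].round(4))

print("\nDEG-overlap dissociation (hypergeometric p):")
universe = list(run.genes.table.index)
for ctname in marker_sets:
    p_pos = imgx.hypergeom_overlap(top_pos, deg_lists[ctname], universe).p
    p_neg = imgx.hypergeom_overlap(top_neg, deg_lists[ctname], universe).p
    print(f"  {ctname:12s}  pos-list p = {p_pos:.2e}   neg-list p = {p_neg:.2e}")
print(
    "\nAstrocyte/endothelial signatures enrich only the positive list and"
    "\nneuronal/microglial signatures only the negative list — the planted"
    "\ndissociation the pipeline is built to detect."
)
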