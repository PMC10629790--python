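import numpy as np
import pytest

import imgx
from imgx.simulate import (
    BACKGROUND_LEVEL,
    CellTypeSpec,
    CohortSpec,
    ExpressionSpec,
    gen_celltype_reference,
    gen_cohort_images,
    gen_donor_expression,
    gen_parcellation,
)
from imgx.spatial import grid_rook_weights, morans_i_permutation_p


class TestCohortImages:
    def test_same_seed_bit_identical(self):
        spec = CohortSpec(n_control=3, n_case=3, grid_shape=(8, 8, 8), seed=1)
        im1, cov1 = gen_cohort_images(spec)
        im2, cov2 = gen_cohort_images(spec)
        for a, b in zip(im1, im2):
            np.testing.assert_array_equal(a.data, b.data)
        assert cov1.equals(cov2)

    def test_zero_effect_limit_groups_match(self):
        """With effect_map = 0 and vanishing noise, group means coincide."""
        spec = CohortSpec(
            n_control=4, n_case=4, grid_shape=(6, 6, 6), noise_sd=1e-12, seed=2
        )
        images, cov = gen_cohort_images(spec)
        data = np.stack([im.data for im in images])
        case = data[(cov["group"] == "case").to_numpy()]
        ctrl = data[(cov["group"] == "control").to_numpy()]
        np.testing.assert_allclose(case.mean(axis=0), ctrl.mean(axis=0), atol=1e-9)

    def test_planted_blob_mean_difference(self):
        """Case minus control mean inside the blob recovers delta within 3 SE."""
        delta = 2.0
        shape = (8, 8, 8)
        effect = np.zeros(shape)
        effect[2:5, 2:5, 2:5] = delta
        n = 60
        spec = CohortSpec(
            n_control=n, n_case=n, grid_shape=shape, effect_map=effect,
            noise_sd=1.0, smooth_fwhm_mm=0.0, seed=3,
        )
        images, cov = gen_cohort_images(spec)
        data = np.stack([im.data for im in images])
        case = data[(cov["group"] == "case").to_numpy()]
        ctrl = data[(cov["group"] == "control").to_numpy()]
        blob_diff = (case.mean(axis=0) - ctrl.mean(axis=0))[effect > 0].mean()
        se = np.sqrt(2 / n) / np.sqrt((effect > 0).sum())
        assert abs(blob_diff - delta) <= 3 * se

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_control=3, n_case=3, grid_shape=(2, 8, 8))

    def test_smooth_fields_positively_autocorrelated(self):
        """Moran's I of a generated image is significantly positive."""
        spec = CohortSpec(
            n_control=2, n_case=2, grid_shape=(10, 10, 10),
            voxel_size_mm=2.0, smooth_fwhm_mm=6.0, seed=4,
        )
        images, _ = gen_cohort_images(spec)
        W = grid_rook_weights(np.ones((10, 10, 10), bool))
        vals = images[0].data.ravel()
        _, p = morans_i_permutation_p(vals, W, n_perm=199, seed=0)
        assert p < 0.01


class TestDonorExpression:
    def test_same_seed_bit_identical(self, small_tmap):
        spec = ExpressionSpec(n_donors=2, samples_per_donor=30, n_genes=10, seed=5)
        s1 = gen_donor_expression(spec, small_tmap)
        s2 = gen_donor_expression(spec, small_tmap)
        for a, b in zip(s1.donors, s2.donors):
            np.testing.assert_array_equal(a.expression, b.expression)
            assert a.samples.equals(b.samples)

    def test_requested_bad_probe_counts_present(self, small_tmap):
        bad = {"multi_gene": 3, "intergenic": 2, "unmapped": 4, "low_expression": 5}
        spec = ExpressionSpec(
            n_donors=1, samples_per_donor=40, n_genes=12, n_bad_probes=bad, seed=6
        )
        donor = gen_donor_expression(spec, small_tmap).donors[0]
        cls = donor.probes["probe_class"].value_counts()
        for k, v in bad.items():
            assert cls[k] == v

    def test_low_expression_probes_below_background_majority(self, small_tmap):
        spec = ExpressionSpec(
            n_donors=1, samples_per_donor=100, n_genes=10,
            n_bad_probes={"low_expression": 6}, seed=7,
        )
        donor = gen_donor_expression(spec, small_tmap).donors[0]
        low = (donor.probes["probe_class"] == "low_expression").to_numpy()
        frac_above = donor.above_background[low].mean(axis=1)
        assert np.all(frac_above < 0.5)
        clean = (donor.probes["probe_class"] == "clean").to_numpy()
        assert np.all(donor.above_background[clean].mean(axis=1) > 0.5)

    def test_noiseless_strong_coupling_gives_extreme_rho(self, small_tmap):
        """With no spatial or iid noise, planted-positive genes have rho ~ +1."""
        from scipy.stats import spearmanr

        spec = ExpressionSpec(
            n_donors=1, samples_per_donor=50, n_genes=10,
            pos_gene_frac=0.2, neg_gene_frac=0.2, coupling_beta=5.0,
            noise_sd=1e-9, iid_noise_sd=1e-9, n_bad_probes={}, seed=8,
        )
        se = gen_donor_expression(spec, small_tmap)
        donor = se.donors[0]
        tvals, kept, _ = imgx.match_samples_to_map(small_tmap, donor.samples)
        for gene in se.planted(1):
            rows = donor.probes.index[donor.probes["gene_symbol"] == gene]
            rho = spearmanr(donor.expression[rows[0], kept], tvals[kept]).statistic
            assert rho > 0.99

    def test_null_genes_not_rho_inflated_at_zero(self, small_tmap):
        """With coupling 0 the distribution of |rho| is noise-like, not 0-inflated."""
        from scipy.stats import spearmanr

        spec = ExpressionSpec(
            n_donors=1, samples_per_donor=100, n_genes=40,
            coupling_beta=0.0, n_bad_probes={}, seed=9,
        )
        se = gen_donor_expression(spec, small_tmap)
        donor = se.donors[0]
        tvals, kept, _ = imgx.match_samples_to_map(small_tmap, donor.samples)
        rhos = [
            spearmanr(donor.expression[i, kept], tvals[kept]).statistic
            for i in range(donor.n_probes)
        ]
        med = np.median(np.abs(rhos))
        assert 0.02 < med < 0.4

    def test_too_few_samples_rejected(self, small_tmap):
        with pytest.raises(ValueError):
            ExpressionSpec(samples_per_donor=5)

    def test_fraction_invariant_enforced(self):
        with pytest.raises(ValueError):
            ExpressionSpec(pos_gene_frac=0.6, neg_gene_frac=0.6)


class TestParcellation:
    def test_unit_centroids_nonempty_rois_deterministic(self, small_tmap):
        img = small_tmap.image
        p1, c1 = gen_parcellation(img.mask, img.affine, 20, seed=1)
        p2, c2 = gen_parcellation(img.mask, img.affine, 20, seed=1)
        np.testing.assert_array_equal(p1.data, p2.data)
        norms = np.linalg.norm(c1[["cx", "cy", "cz"]].to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        labels = np.rint(p1.data).astype(int)
        for roi in range(1, 21):
            assert (labels == roi).sum() > 0

    def test_too_many_rois_rejected(self):
        mask = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError):
            gen_parcellation(mask, np.eye(4), 100, seed=0)

    def test_too_few_rois_rejected(self):
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError):
            gen_parcellation(mask, np.eye(4), 5, seed=0)


class TestCellTypeReference:
    def test_marker_specificity_formula(self):
        spec = CellTypeSpec(n_celltypes=4, markers_per_celltype=5, marker_fold=4.0, seed=2)
        genes = [f"G{i}" for i in range(40)]
        me, annot, degs = gen_celltype_reference(spec, genes)
        S = imgx.compute_specificity(me)
        for ct in me.columns:
            markers = me.index[me[ct] == 4.0]
            np.testing.assert_allclose(S.values.loc[markers, ct], 4 / 7, atol=1e-12)

    def test_flat_reference_when_fold_near_one(self):
        spec = CellTypeSpec(n_celltypes=4, markers_per_celltype=5, marker_fold=1.0 + 1e-9, seed=3)
        me, _, _ = gen_celltype_reference(spec, [f"G{i}" for i in range(30)])
        S = imgx.compute_specificity(me)
        np.testing.assert_allclose(S.values.to_numpy(), 0.25, atol=1e-9)

    def test_deg_lists_subsets_of_markers(self):
        spec = CellTypeSpec(n_celltypes=3, markers_per_celltype=6, deg_size=4, seed=4)
        genes = [f"G{i}" for i in range(40)]
        me, _, degs = gen_celltype_reference(spec, genes)
        for ct, deg in degs.items():
            markers = set(me.index[me[ct] == spec.marker_fold])
            assert set(deg) <= markers and len(deg) == 4

    def test_marker_demand_exceeding_genes_rejected(self):
        spec = CellTypeSpec(n_celltypes=4, markers_per_celltype=10, seed=5)
        with pytest.raises(ValueError):
            gen_celltype_reference(spec, [f"G{i}" for i in range(20)])

    def test_overlapping_pinned_markers_rejected(self):
        spec = CellTypeSpec(n_celltypes=2, markers_per_celltype=2, deg_size=2, seed=6)
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError, match="disjoint"):
            gen_celltype_reference(spec, genes, marker_sets={"x": ["a", "b"], "y": ["b", "c"]})

    def test_marker_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            CellTypeSpec(marker_fold=1.0)
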