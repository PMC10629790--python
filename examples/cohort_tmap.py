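"""Simulate an imaging cohort and fit a mass-univariate group t-map.

Builds a two-group cohort with a planted cluster of grey-matter change,
fits the voxel-wise GLM with age/sex/site covariates and reports how the
planted region stands out, plus the correlation between two modality maps.
"""

import numpy as np

import imgx

shape = (16, 16, 16)
effect = np.zeros(shape)
effect[5:11, 5:11, 5:11] = 1.5  # planted group difference (case > control)

spec = imgx.CohortSpec(
    n_control=20, n_case=20, grid_shape=shape, voxel_size_mm=2.0,
    smooth_fwhm_mm=8.0, effect_map=effect, noise_sd=1.0, seed=42,
)
images, covariates = imgx.gen_cohort_images(spec)
design = imgx.build_design(covariates, contrast="group", covars=("age", "sex", "site"))
tmap = imgx.fit_tmap(images, design, direction="case > control")

inside = tmap.image.data[effect > 0].mean()
outside = tmap.image.data[effect == 0].mean()
print(f"df = {tmap.df}; mean t inside planted blob = {inside:.2f}, outside = {outside:.2f}")

# a second "modality": same effect, independent noise
spec2 = imgx.CohortSpec(
    n_control=20, n_case=20, grid_shape=shape, voxel_size_mm=2.0,
    smooth_fwhm_mm=8.0, effect_map=effect, noise_sd=1.0, seed=43,
)
images2, cov2 = imgx.gen_cohort_images(spec2)
design2 = imgx.build_design(cov2, contrast="group", covars=("age", "sex", "site"))
tmap2 = imgx.fit_tmap(images2, design2, direction="case > control")

r, p = imgx.correlate_tmaps(tmap, tmap2)
print(f"cross-modality t-map correlation: r = {r:.2f} (p = {p:.1e})")
print(
    "\nThe planted cluster elevates t inside the blob; two maps of the same"
    "\nunderlying pathology correlate positively across voxels."
)
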