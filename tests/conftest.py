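import numpy as np
import pytest

import imgx


@pytest.fixture(scope="session")
def small_tmap():
    """Group-difference t-map from a small synthetic cohort (no planted effect)."""
    spec = imgx.CohortSpec(
        n_control=12, n_case=12, grid_shape=(16, 16, 16), smooth_fwhm_mm=12.0, seed=5
    )
    images, cov = imgx.gen_cohort_images(spec)
    design = imgx.build_design(cov, contrast="group", covars=("age", "sex", "site"))
    return imgx.fit_tmap(images, design, direction="case > control")


@pytest.fixture(scope="session")
def small_expression(small_tmap):
    """Two-donor expression with planted coupled gene sets on the small map."""
    spec = imgx.ExpressionSpec(
        n_donors=2, samples_per_donor=120, n_genes=60, seed=11
    )
    return imgx.gen_donor_expression(spec, small_tmap)


@pytest.fixture(scope="session")
def parcellation(small_tmap):
    img = small_tmap.image
    return imgx.gen_parcellation(img.mask, img.affine, 40, seed=3)
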