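import numpy as np
import pytest

import colonyscreen as cs


@pytest.fixture(scope="session")
def small_layout() -> cs.PlateLayout:
    """An 8x12 mini-plate at the standard 500 um pitch."""
    return cs.PlateLayout(8, 12, pitch_um=500.0)


@pytest.fixture(scope="session")
def noiseless_optics() -> cs.OpticsModel:
    """No PSF, no background, no noise: ideal photometry."""
    return cs.OpticsModel(
        psf_sigma_px=0.0, background_level=0.0, read_noise_sd=0.0, shot_noise=False
    )


@pytest.fixture(scope="session")
def rendered_small_plate(small_layout, noiseless_optics):
    """A fully occupied noise-free mini-plate with one red spike colony."""
    gt = cs.sample_ground_truth(
        small_layout,
        viability=1.0,
        doublet_rate=0.0,
        variant_mix={"x5_FLuc": 0.9, "x5_FLuc_red": 0.1},
        seed=7,
    )
    rendered = cs.render_plate(gt, optics=noiseless_optics, seed=7)
    return gt, rendered


@pytest.fixture(scope="session")
def quantified_small_plate(small_layout, rendered_small_plate):
    gt, rendered = rendered_small_plate
    records, unoccupied, transform, qc = cs.quantify_plate(
        rendered.images, small_layout, pixel_um=rendered.optics.pixel_um
    )
    return gt, rendered, records, unoccupied, transform, qc
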