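import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rendered_cell():
    """A noise-free polarized synthetic cell: image, mask, ground truth, params."""
    from stomapolar import synth

    params = synth.SynthCellParams(
        crescent_amplitude=90.0, baseline_intensity=10.0,
        crescent_width_sigma=0.3, crescent_center=np.pi / 2,
        noise_sd=0.0, ellipse_axes=(30.0, 22.0), seed=3,
    )
    image, mask, truth = synth.render_cell_image(params)
    return image, mask, truth, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
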