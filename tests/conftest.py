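import numpy as np
import pytest

from octavd import NoiseParams, PipelineConfig, VesselParams, generate_vessel_mask, render_octa


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def truth_mask():
    """Ground-truth 304x304 vascular mask at the default 25% fraction."""
    return generate_vessel_mask(VesselParams(), seed=0)


@pytest.fixture(scope="session")
def noise_free_image(truth_mask):
    """Degenerate render: no speckle, no stripes, no blur."""
    return render_octa(
        truth_mask,
        NoiseParams(speckle_shape=np.inf, stripe_amplitude=0.0, blur_sigma=0.0),
        seed=100,
    )


@pytest.fixture(scope="session")
def noisy_image(truth_mask):
    """Render under the default speckle/stripe/blur degradations."""
    return render_octa(truth_mask, NoiseParams(), seed=100)


@pytest.fixture()
def fast_config():
    """Pipeline config scaled for small (>=128 px) test frames."""
    cfg = PipelineConfig()
    cfg.segment.threshold_window = 31
    return cfg
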