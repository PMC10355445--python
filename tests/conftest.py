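import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import origamiqc as oq

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def separated_scene_spec(seed: int, staple_target: float = 0.3,
                         side: int = 256) -> oq.SceneSpec:
    """Scene with component mean separation >= 3x the largest sigma,
    and enough staples for roughly the requested staple pixel fraction."""
    blob_px = 5  # pixels per staple blob
    n_staples = int(-(side * side) / blob_px * np.log(1 - staple_target))
    return oq.SceneSpec(width_px=side, height_px=side,
                        mica_mu=0.0, staple_mu=1.0, origami_mu=3.0,
                        mica_sigma=0.15, staple_sigma=0.25, origami_sigma=0.4,
                        noise_sigma=0.05, n_staples=n_staples,
                        n_monomers=4, n_dimers=1, seed=seed)


@pytest.fixture(scope="session")
def separated_scene():
    """One well-separated scene with ground truth, shared across tests."""
    spec = separated_scene_spec(seed=42)
    return spec, *oq.generate_afm_scene(spec)
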