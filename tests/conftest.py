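import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from y90dosim import phantom as ph

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom: activity, attenuation map, masks, ground truth."""
    spec = ph.PhantomSpec()
    activity, mu, masks, truth = ph.build_phantom(spec)
    return spec, activity, mu, masks, truth


def _project_all(activity, mu, spec, noise=False):
    return {
        (v, w): ph.project_planar(activity, mu, v, w, spec, noise=noise)
        for v in ("anterior", "posterior")
        for w in ("peak", "downscatter")
    }


@pytest.fixture(scope="session")
def attenuated_planar(default_phantom):
    """Noise-free planar image set with the default attenuation map."""
    spec, activity, mu, masks, _ = default_phantom
    return _project_all(activity, mu, spec), ph.planar_rois(masks)


@pytest.fixture(scope="session")
def scatter_only_planar(default_phantom):
    """Noise-free planar image set with attenuation switched off (mu = 0),
    isolating the scatter/DEW model."""
    spec, activity, mu, masks, _ = default_phantom
    return _project_all(activity, np.zeros_like(mu), spec), ph.planar_rois(masks)
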