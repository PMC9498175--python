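import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import grainscan as g
from grainscan import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def irri6_config():
    return g.load_preset("irri6")


@pytest.fixture(scope="session")
def profile_12_5():
    return g.CalibrationProfile(ppm=12.5, source="manual")


@pytest.fixture(scope="session")
def plain_scene():
    """A 10-kernel plain scene at the default scale, with its manifest."""
    spec = syn.build_scene_spec(n_kernels=10, seed=42)
    image, manifest = syn.render_scene(spec)
    return spec, image, manifest


@pytest.fixture(scope="session")
def mixed_scene():
    """A 40-kernel scene with all paint classes represented."""
    spec = syn.build_scene_spec(
        n_kernels=40,
        seed=7,
        class_fractions={
            "yellow": 0.15,
            "chalky_patch": 0.15,
            "damaged_patch": 0.1,
            "paddy_texture": 0.1,
        },
    )
    image, manifest = syn.render_scene(spec)
    return spec, image, manifest


def match_by_centroid(manifest, kernels):
    """Pair each manifest kernel with the nearest detected contour."""
    pairs = []
    for m in manifest:
        mx, my = m["centroid_px"]
        best = min(kernels, key=lambda k: (k.centroid[0] - mx) ** 2 + (k.centroid[1] - my) ** 2)
        pairs.append((m, best))
    return pairs
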