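import numpy as np
import pandas as pd
import pytest

from morphdiv.tps import LandmarkConfiguration


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_configuration(rng, k_fixed=4, curve_sizes=(3, 2), specimen_id="s1",
                         species="sp1", family="FamA", view="dorsal",
                         scale_applied=True):
    """A random but structurally valid landmark configuration."""
    total = k_fixed + sum(curve_sizes)
    pts = rng.normal(size=(total, 2)) * 5.0 + rng.normal(size=2) * 10.0
    curves = []
    start = k_fixed
    for n in curve_sizes:
        curves.append((start, start + n))
        start += n
    return LandmarkConfiguration(
        specimen_id=specimen_id, species=species, family=family, view=view,
        points=pts, fixed_count=k_fixed, curves=curves,
        scale_applied=scale_applied,
    )


def table_for(configs):
    return pd.DataFrame(
        [{"specimen_id": c.specimen_id, "species": c.species,
          "family": c.family, "view": c.view} for c in configs]
    )


@pytest.fixture
def random_configuration_factory():
    return random_configuration


def similarity_transform(rng, points):
    """Apply a random rotation, translation and positive scale."""
    theta = rng.uniform(-np.pi, np.pi)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    scale = rng.uniform(0.2, 5.0)
    t = rng.uniform(-50.0, 50.0, size=2)
    return scale * points @ R.T + t
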