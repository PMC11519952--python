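import numpy as np
import pytest

from thyroscan import phantom


GLAND_X = phantom.AnatomyConfig().width_mm / 2 + 6.0
GLAND_Z = phantom.AnatomyConfig().length_mm / 2


def centered_probe(**kwargs) -> phantom.VirtualProbe:
    defaults = dict(lateral_mm=GLAND_X, elevation_mm=GLAND_Z)
    defaults.update(kwargs)
    return phantom.VirtualProbe(**defaults)


def render_nodule(spec: phantom.NoduleSpecification, seed: int) -> phantom.USFrame:
    tissue = phantom.single_nodule_phantom(spec, seed=seed)
    probe = centered_probe(elevation_mm=spec.center_mm[0])
    return phantom.render_frame(tissue, probe, seed=seed + 1)


@pytest.fixture(scope="session")
def plain_tissue() -> phantom.TissueMap:
    return phantom.single_nodule_phantom(None, seed=1)


@pytest.fixture(scope="session")
def nodule_tissue() -> phantom.TissueMap:
    return phantom.single_nodule_phantom(phantom.default_nodule(), seed=1)


@pytest.fixture(scope="session")
def nodule_frame(nodule_tissue) -> phantom.USFrame:
    return phantom.render_frame(nodule_tissue, centered_probe(), seed=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
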