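import numpy as np
import pytest

from fedsim import (
    LabelMap,
    RegionMask,
    SitePhantomSpec,
    TinySegNet,
    generate_site,
    make_federation,
)


@pytest.fixture(scope="session")
def small_client():
    """One 20-case site of 32x32 phantoms."""
    return generate_site(SitePhantomSpec(site_id="fix-a", n_cases=20, seed=7))


@pytest.fixture(scope="session")
def tiny_model():
    return TinySegNet(width=4)


@pytest.fixture(scope="session")
def homog_federation():
    """Four statistically identical 12-case sites."""
    specs = tuple(
        SitePhantomSpec(site_id=f"h{i}", n_cases=12, seed=300 + i) for i in range(4)
    )
    return make_federation(specs, size_law="fixed", rng_seed=11)


def make_mask(values, region="ET", spacing=None):
    values = np.asarray(values, dtype=bool)
    if spacing is None:
        spacing = (1.0,) * values.ndim
    return RegionMask(region=region, mask=values, spacing=spacing)


def labelmap(values, spacing=None):
    return LabelMap(values=np.asarray(values, dtype=np.int16), spacing=spacing)
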