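import numpy as np
import pytest

from mpiquant.phantom import (
    IronSource,
    PhantomConfig,
    default_fiducials,
    default_graft_center,
    fiducial_sources,
    render_scan,
)


@pytest.fixture(scope="session")
def fiducials():
    return default_fiducials()


@pytest.fixture(scope="session")
def noise_free_scan(fiducials):
    """Noise-free scan: three standard fiducials + one 2.0 ug graft."""
    cfg = PhantomConfig(
        noise_additive_sd=0.0,
        noise_multiplicative_cv=0.0,
        sources=fiducial_sources(fiducials)
        + [IronSource(center=default_graft_center(), iron_ug=2.0, kind="graft")],
    )
    return render_scan(cfg)
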