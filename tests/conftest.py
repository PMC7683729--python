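import numpy as np
import pytest

from deerscape import deer, synthdata


@pytest.fixture(scope="session")
def hinge_26():
    """Synthetic two-domain structure with a 2.6 nm inter-site distance."""
    spec = synthdata.HingeSpec(theta=synthdata.hinge_angle_for_distance(2.6))
    return spec, synthdata.make_two_domain_structure(spec)


@pytest.fixture(scope="session")
def r_grid():
    return deer.default_r_grid()


@pytest.fixture(scope="session")
def coarse_r_grid():
    """Coarser grid for inversion property tests (keeps NNLS cheap)."""
    return deer.default_r_grid(step=0.04)


@pytest.fixture(scope="session")
def two_gauss_dataset(r_grid):
    """The two-peak study-like truth: 3.2/4.4 nm, s.d. 0.15 nm, snr 50."""
    truth = synthdata.DeerGroundTruth(seed=11)
    trace, p = synthdata.make_deer_dataset(truth)
    return truth, trace, p
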