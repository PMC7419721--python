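import math

import pytest

from stereosim import CohortSpec, PsychometricParams, SimulatedObserver, sample_cohort


@pytest.fixture(scope="session")
def reference_observer() -> SimulatedObserver:
    """Balanced observer with a 40-arcsec threshold, unit-octave spread and no
    lapse — the worked-example observer used throughout."""
    return SimulatedObserver(
        stereo=PsychometricParams(alpha=math.log2(40.0), beta=1.0, lapse=0.0),
        kappa=0.35,
        cr_true=1.0,
    )


@pytest.fixture(scope="session")
def normal_cohort():
    return sample_cohort(CohortSpec.normal(n=25, seed=42))


@pytest.fixture(scope="session")
def amblyopic_cohort():
    return sample_cohort(CohortSpec.amblyopic(n=25, seed=42))
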