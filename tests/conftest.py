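import numpy as np
import pytest

from proctrace import EmissionParams, KineticParams


@pytest.fixture
def em_clean() -> EmissionParams:
    """Noiseless photophysics: no background, bleedthrough or bleaching."""
    return EmissionParams(
        noise_sd=0.0, alpha=0.0,
        background_donor=0.0, background_acceptor=0.0,
        bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)


@pytest.fixture
def em_quiet() -> EmissionParams:
    """Realistic backgrounds/bleedthrough but no noise or bleaching."""
    return EmissionParams(
        noise_sd=0.0, bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)


@pytest.fixture
def kin_wt() -> KineticParams:
    from proctrace import get_preset
    return get_preset("wt").kinetics.evolve(p_capture=1.0)
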