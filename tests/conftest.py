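import numpy as np
import pytest

from idpprof.synth import SynthesisRecipe, synth_saxs


@pytest.fixture(scope="session")
def lab_s_grid():
    """The s-range of a typical laboratory IDP measurement, 1/Å."""
    return np.linspace(0.010, 0.213, 200)


@pytest.fixture(scope="session")
def sphere50_curve(lab_s_grid):
    """Noiseless solid-sphere curve, R = 50 Å (Rg = sqrt(3/5)*50)."""
    curve, truth = synth_saxs(
        SynthesisRecipe("sphere", {"radius": 50.0}, s_grid=lab_s_grid)
    )
    return curve, truth


@pytest.fixture(scope="session")
def debye52_curve():
    """Noiseless Gaussian-chain curve, Rg = 52.2 Å, on a low-angle-rich grid."""
    s = np.linspace(0.002, 0.213, 400)
    curve, truth = synth_saxs(
        SynthesisRecipe("debye_chain", {"rg": 52.2}, s_grid=s)
    )
    return curve, truth
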