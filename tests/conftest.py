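import pytest
from hypothesis import settings

from synercomb import HillCurve, MuSyCSurface
from synercomb.synthgen import (
    RTGLO_DOSES_COL,
    RTGLO_DOSES_ROW,
    SynthConfig,
    generate_matrix,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kill_curve():
    """Monotherapy kill curve on the inhibition scale (full efficacy)."""
    return HillCurve(E0=0.0, Emax=100.0, C=65.7, h=1.5)


@pytest.fixture(scope="session")
def plateau_curve():
    """Kill curve with a 20% resistant plateau."""
    return HillCurve(E0=0.0, Emax=80.0, C=1.0, h=1.0)


@pytest.fixture(scope="session")
def truth_surface():
    """Synergistic MuSyC ground truth used for recovery experiments."""
    return MuSyCSurface(
        E0=1.0, E1=0.4, E2=0.3, E3=0.05, h1=1.0, h2=1.0, C1=260.0, C2=0.8,
        alpha12=3.0, alpha21=3.0, gamma12=1.0, gamma21=1.0,
    )


@pytest.fixture(scope="session")
def rtglo_truth_matrix(truth_surface):
    """Noise-free checkerboard from the truth surface on the 7x7 grid."""
    cfg = SynthConfig(
        seed=0, surface=truth_surface,
        doses_row=RTGLO_DOSES_ROW, doses_col=RTGLO_DOSES_COL,
        noise_sd=0.0, timepoints=(72.0,), n_replicates=1,
    )
    return generate_matrix(cfg)[0]


@pytest.fixture(scope="session")
def bliss_null_matrix():
    """Noise-free Bliss-consistent checkerboard from the default
    near-complete-kill monotherapy curves."""
    cfg = SynthConfig(
        seed=0, null_model="bliss", noise_sd=0.0,
        timepoints=(72.0,), n_replicates=1,
    )
    return generate_matrix(cfg)[0]


@pytest.fixture(scope="session")
def bliss_headroom_matrix():
    """Bliss-consistent checkerboard with moderate-efficacy curves, so adding
    a constant to combination cells stays below 100% inhibition."""
    cfg = SynthConfig(
        seed=0, null_model="bliss", noise_sd=0.0,
        null_curve_row=HillCurve(E0=0.0, Emax=60.0, C=50.0, h=1.2),
        null_curve_col=HillCurve(E0=0.0, Emax=50.0, C=1.0, h=1.0),
        timepoints=(72.0,), n_replicates=1,
    )
    return generate_matrix(cfg)[0]
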