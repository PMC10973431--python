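import numpy as np
import pytest

from cvrkit.physio import CapnoTrace, compute_etco2
from cvrkit.synthetic import PhantomSpec, make_bold, make_capno


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Small noiseless phantom shared by fast unit tests."""
    return PhantomSpec(shape=(6, 6, 6), n_frames=120, tsnr=np.inf, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    bold, decomp, truth = make_bold(small_spec)
    return bold, decomp, truth


@pytest.fixture(scope="session")
def small_etco2(small_spec):
    return compute_etco2(make_capno(small_spec))


def sinusoid_trace(
    plateau: float = 40.0,
    dip: float = 2.0,
    freq: float = 0.25,
    duration: float = 60.0,
    fs: float = 10.0,
) -> CapnoTrace:
    """Breathing-like trace oscillating between a dip and a plateau."""
    t = np.arange(0, duration, 1 / fs)
    w = 0.5 * (1 - np.cos(2 * np.pi * freq * t))
    return CapnoTrace(samples=dip + (plateau - dip) * w, sampling_frequency=fs)
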