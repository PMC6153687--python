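import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hpdfinder import DetectionParams, Spectrum

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def flat_spectrum() -> Spectrum:
    """Exact 0.05 m/z spacing over [100, 120]: density 20 in every 1 m/z
    window, so the reference sigma is exactly zero everywhere."""
    mz = 100.025 + 0.05 * np.arange(int(20 / 0.05))
    return Spectrum(mz=mz, intensity=np.full(mz.size, 1e3), mz_range=(100.0, 120.0))


def random_poisson_spectrum(rng: np.random.Generator, n_max: int = 500,
                            lo: float = 100.0, hi: float = 200.0) -> Spectrum:
    n = rng.integers(0, n_max + 1)
    mz = np.sort(rng.uniform(lo, hi, size=n))
    return Spectrum(mz=mz, intensity=rng.lognormal(7, 1, size=n), mz_range=(lo, hi))


def naive_density(spectrum: Spectrum, centers: np.ndarray, width: float) -> np.ndarray:
    """Brute-force per-center recount, the oracle for the profile."""
    out = np.empty(centers.size, dtype=int)
    for i, c in enumerate(centers):
        out[i] = int(np.sum((spectrum.mz >= c - width / 2) & (spectrum.mz < c + width / 2)))
    return out
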