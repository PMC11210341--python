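import logging

import numpy as np
import pytest
from hypothesis import settings

from forcekinetics import BellParameters, ForceCurve

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# pipeline stages log expected warnings (degenerate gates etc.) on small fixtures
logging.getLogger("forcekinetics").setLevel(logging.ERROR)


@pytest.fixture
def canonical_bell() -> BellParameters:
    """Single-bond truth of the canonical nanobody / HER2-positive-cell
    condition: koff = 0.23 1/s, xbeta = 1.23 nm (12.3 A)."""
    return BellParameters(koff=0.23, xbeta=1.23)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_retract_curve(
    planted,
    n: int = 2000,
    z_range: float = 3000.0,
    noise_sd: float = 0.0,
    ramp_samples: int = 120,
    kc: float = 10.0,
    velocity: float = 3000.0,
    seed: int = 0,
    curve_id: str = "planted",
) -> ForceCurve:
    """Hand-built retract-only curve with triangular rupture ramps.

    ``planted`` is a list of (force_pN, position_nm) pairs; each produces a
    linear tensile ramp over ``ramp_samples`` samples ending in an
    instantaneous drop to baseline at the given position.
    """
    gen = np.random.default_rng(seed)
    z = np.linspace(0.0, z_range, n)
    force = np.zeros(n)
    for f_pk, pos in planted:
        i = int(np.searchsorted(z, pos))
        i = min(max(i, 1), n - 1)
        j = max(i - ramp_samples, 0)
        force[j:i + 1] = np.linspace(0.0, f_pk, i + 1 - j)
    if noise_sd > 0:
        force = force + gen.normal(0.0, noise_sd, size=n)
    segment = np.array(["retract"] * n, dtype=object)
    dz = z_range / (n - 1)
    return ForceCurve(z=z, force=force, segment=segment, kc=kc, velocity=velocity,
                      sampling_rate=velocity / dz, curve_id=curve_id)
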