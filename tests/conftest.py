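import numpy as np
import pytest

from catchbond import (
    BEParams,
    FRCParams,
    HandleModel,
    NoiseModel,
    ThermalContext,
    generate_constant_speed_curve,
    single_state_model,
)
from catchbond.pipeline import FingerprintCriteria


@pytest.fixture(scope="session")
def thermal() -> ThermalContext:
    return ThermalContext()


@pytest.fixture(scope="session")
def frc() -> FRCParams:
    return FRCParams()


@pytest.fixture(scope="session")
def strong_bond():
    """Single-state bond stable enough to survive full fingerprint unfolding."""
    return single_state_model(BEParams(k0=1e-4, delta_x=0.3))


@pytest.fixture(scope="session")
def weak_bond():
    """Single-state bond rupturing at ~30-45 pN, before any fingerprint
    unfolding (below the 50 pN window) but above the 10 pN noise floor."""
    return single_state_model(BEParams(k0=0.3, delta_x=0.7))


@pytest.fixture(scope="session")
def synthetic_criteria():
    """Fingerprint criteria matched to the generator's default geometry.

    The generator's folded construct starts at 158 nm contour (reaching
    ~190 nm after the 32 nm fingerprint); criterion-1 classification of its
    pre-fingerprint ruptures therefore targets 158 nm.
    """
    return FingerprintCriteria(criterion1_contour=158.0)


def make_clean_curve(model, seed=0, handle=None, **kwargs):
    """Zero-noise synthetic curve + truth, for exact round-trip checks."""
    return generate_constant_speed_curve(
        model,
        handle=handle or HandleModel(),
        noise=NoiseModel(force_noise_sd=0.0),
        seed=seed,
        **kwargs,
    )
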