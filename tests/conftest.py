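import numpy as np
import pytest

from epomfit import (
    DepthValueCurve,
    Quantity,
    SyntheticBeam,
    SyntheticTruth,
    correct_scan,
    default_reference_grid,
    make_chamber_scan,
    make_reference_pdd,
)


@pytest.fixture(scope="session")
def beam12() -> SyntheticBeam:
    """A typical mid-energy beam (nominal 12 MeV, R50 = 4.93 cm)."""
    return SyntheticBeam.nominal("12")


@pytest.fixture(scope="session")
def ref12(beam12) -> DepthValueCurve:
    return make_reference_pdd(beam12, default_reference_grid(beam12))


def make_pair(beam, dz_true, noise_sigma=0.0, seed=0):
    """Reference dose curve plus corrected chamber ionization curve."""
    ref = make_reference_pdd(beam, default_reference_grid(beam))
    truth = SyntheticTruth(dz_true=dz_true, noise_sigma=noise_sigma, seed=seed)
    det, _ = correct_scan(make_chamber_scan(ref, truth, beam))
    return ref, det


def falloff_curve() -> DepthValueCurve:
    """A hand-entered monotone distal-falloff segment (dose)."""
    depths = np.array([3.0, 3.2, 3.4, 3.6, 3.8, 4.0, 4.2, 4.4])
    values = np.array([95.0, 88.0, 76.0, 60.0, 42.0, 26.0, 14.0, 7.0])
    return DepthValueCurve(depths, values, Quantity.DOSE)
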