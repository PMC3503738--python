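import numpy as np
import pytest

from calfpkpd.pk_model import ClearanceParams, DoseRegimen, MicroParams
from calfpkpd.synthetic_data import STUDY_SCHEDULE_H


@pytest.fixture
def dose():
    """The study dose: 0.5 mg/kg IV bolus, stored as 500 µg/kg."""
    return DoseRegimen(dose_per_kg=500.0)


@pytest.fixture
def published_clearance():
    """Published mean clearance-family parameter set (mL/kg, mL/h/kg)."""
    return ClearanceParams(vc=94.88, cl=6.64, cld2=225.18, v2=99.07)


@pytest.fixture
def published_micro():
    """Published mean micro-rate constants (means are per-parameter, so
    this set is not algebraically consistent with the clearance set)."""
    return MicroParams(vc=94.88, k10=0.075, k12=2.70, k21=2.20)


@pytest.fixture
def schedule():
    """Blood-sampling schedule in hours."""
    return np.asarray(STUDY_SCHEDULE_H)


def random_identifiable_micro(rng):
    """A micro parameter set whose phases the study schedule can resolve:
    fast distribution (alpha half-life minutes) and slow elimination
    (beta half-life tens of hours), well separated."""
    while True:
        p = MicroParams(
            vc=rng.uniform(50, 200),
            k10=rng.uniform(0.03, 0.2),
            k12=rng.uniform(0.5, 5.0),
            k21=rng.uniform(0.5, 5.0),
        )
        s = p.k10 + p.k12 + p.k21
        prod = p.k10 * p.k21
        alpha = 0.5 * (s + np.sqrt(s * s - 4 * prod))
        beta = prod / alpha
        if alpha / beta > 10:
            return p
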