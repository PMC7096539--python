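"""Shared fixtures.

The expensive objects (averaged curves, the onset/offset class table)
are computed once per session and reused by unit and acceptance tests.
"""

import numpy as np
import pytest

from epileptor import ParameterSet, SystemId
from epileptor.averaging import AveragedCurve
from epileptor.continuation import classify_sle


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def sub1_curve_m0(params):
    """Averaged <x1>(z) of the uncoupled fast subsystem at m = 0."""
    return AveragedCurve.compute(SystemId.SUB1, params)


@pytest.fixture(scope="session")
def sub1_curve_m2(params):
    """Averaged <x1>(z) of the uncoupled fast subsystem at m = 2."""
    return AveragedCurve.compute(SystemId.SUB1, params.with_(m=2.0))


@pytest.fixture(scope="session")
def full_curve_m0(params):
    """Averaged <x1>(z) of the full model's fast equations at m = 0."""
    return AveragedCurve.compute(SystemId.FULL, params)


SLE_CONFIGS = {
    (0.5, 0.45): "fold/homoclinic",
    (0.0, 0.45): "fold/circle",
    (0.0, 0.0): "fold/homoclinic",
    (-0.5, 0.0): "fold/Hopf",
    (-1.0, 0.0): "fold/fold",
    (-8.0, 0.0): "fold/fold",
}


@pytest.fixture(scope="session")
def sle_table(params):
    """Onset/offset classification at the published (m, Iext2) settings."""
    out = {}
    for (m, iext2) in SLE_CONFIGS:
        out[(m, iext2)] = classify_sle(params.with_(m=m, Iext2=iext2))
    return out
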