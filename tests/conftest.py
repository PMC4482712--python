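"""Shared fixtures.

Simulator-backed fixtures are session-scoped because each involves ODE
integration; the big design fixtures (200 design + 20 test runs and a
50-point restitution design) back the end-to-end statistical checks and
are only built when a test requests them.
"""

import numpy as np
import pytest

from cardioemu.biomarkers import fit_restitution, restitution_protocol
from cardioemu.design import generate_dataset
from cardioemu.emulator import GaussianProcessEmulator
from cardioemu.lr1991 import APTrace, CellState, Conductances, run_s1_protocol
from cardioemu.sensitivity import InputDistribution


@pytest.fixture(scope="session")
def nominal_trace():
    return run_s1_protocol(Conductances())


@pytest.fixture(scope="session")
def nominal_restitution(nominal_trace):
    curve = restitution_protocol(Conductances(), s1_trace=nominal_trace)
    return curve, fit_restitution(curve)


@pytest.fixture(scope="session")
def ap_design():
    """40-point design, S1 outputs only (fast)."""
    return generate_dataset(40, seed=101, include_restitution=False)


@pytest.fixture(scope="session")
def full_design():
    """Small design with the restitution outputs included."""
    return generate_dataset(14, seed=102, include_restitution=True)


@pytest.fixture(scope="session")
def design200():
    """Full-size Latin-hypercube design (S1 outputs)."""
    return generate_dataset(200, seed=211, include_restitution=False)


@pytest.fixture(scope="session")
def test20():
    return generate_dataset(20, seed=212, include_restitution=False)


@pytest.fixture(scope="session")
def combined220(design200, test20):
    return design200.combined_with(test20)


@pytest.fixture(scope="session")
def restitution50():
    """Reduced-size design with the S1-S2 restitution protocol per point."""
    return generate_dataset(50, seed=213, include_restitution=True)


@pytest.fixture(scope="session")
def apd90_emulator(design200):
    return GaussianProcessEmulator(
        n_restarts=10, random_state=0, output_name="apd90"
    ).fit(design200.x, design200.output("apd90"))


@pytest.fixture(scope="session")
def apd90_emulator_combined(combined220):
    return GaussianProcessEmulator(
        n_restarts=10, random_state=0, output_name="apd90"
    ).fit(combined220.x, combined220.output("apd90"))


@pytest.fixture(scope="session")
def study_distribution():
    return InputDistribution()


@pytest.fixture(scope="session")
def toy_surface():
    """A smooth 6-input test function with a known emulator fit."""
    rng = np.random.default_rng(7)

    def f(X):
        X = np.atleast_2d(X)
        return 2.0 + 3.0 * X[:, 0] + np.sin(3.0 * X[:, 1]) + X[:, 2] * X[:, 3]

    X = rng.random((70, 6))
    em = GaussianProcessEmulator(n_restarts=5, random_state=1).fit(X, f(X))
    return f, X, em


def make_trapezoid_trace(resting=-85.0, peak=15.0, width=300.0, rise=1.0,
                         fall=5.0, onset=50.0, total=500.0, dt=0.1):
    """Synthetic AP-like pulse with known geometry for biomarker tests."""
    t = np.arange(0.0, total + dt / 2, dt)
    v = np.full_like(t, resting)
    up = (t >= onset) & (t < onset + rise)
    v[up] = resting + (peak - resting) * (t[up] - onset) / rise
    top = (t >= onset + rise) & (t < onset + rise + width)
    v[top] = peak
    down = (t >= onset + rise + width) & (t < onset + rise + width + fall)
    v[down] = peak - (peak - resting) * (t[down] - (onset + rise + width)) / fall
    state = CellState(v=float(v[-1]), m=0.0, h=1.0, j=1.0, d=0.0, f=1.0,
                      x=0.0, ca_i=1e-4)
    return APTrace(times=t, voltages=v, stimulus_onset=onset, final_state=state)


@pytest.fixture
def trapezoid_trace():
    return make_trapezoid_trace()
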