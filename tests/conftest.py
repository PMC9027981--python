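import numpy as np
import pytest
from hypothesis import settings

from acidocest.bloch import PoolModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from acidocest.synthetic import build_phantom, simulate_acquisition

WATER_FREQ_MHZ = 127.731


def steady_state_oracle(pools, offset_hz, b1_ut, water_frequency_mhz):
    """Closed-form steady state of the linearized exchange system.

    Independent re-derivation used as the oracle for the propagator: the
    drift matrix is assembled pool-by-pool from the rotating-frame equations
    and the fixed point solved directly, with no code shared with the
    package's integrator.
    """
    n = len(pools)
    gamma = 42.577  # Hz/uT
    w1 = 2 * np.pi * gamma * b1_ut
    A = np.zeros((3 * n, 3 * n))
    c = np.zeros(3 * n)
    for i, p in enumerate(pools):
        dw = 2 * np.pi * (p.chemical_shift_ppm * water_frequency_mhz - offset_hz)
        blk = np.array([
            [-1.0 / p.t2, dw, 0.0],
            [-dw, -1.0 / p.t2, w1],
            [0.0, -w1, -1.0 / p.t1],
        ])
        A[3 * i:3 * i + 3, 3 * i:3 * i + 3] += blk
        c[3 * i + 2] = p.proton_fraction / p.t1
    for i, p in enumerate(pools):
        if i == 0:
            continue
        ks, kw = p.exchange_rate, p.proton_fraction * p.exchange_rate
        for comp in range(3):
            A[comp, comp] -= kw
            A[comp, 3 * i + comp] += ks
            A[3 * i + comp, 3 * i + comp] -= ks
            A[3 * i + comp, comp] += kw
    m = np.linalg.solve(A, -c)
    return m[2]


def random_two_pool(rng):
    """A random but physically sensible water + solute pool pair."""
    water = PoolModel("water", 0.0, rng.uniform(0.5, 3.0), rng.uniform(0.02, 0.5))
    solute = PoolModel(
        "solute", rng.uniform(2.0, 6.0), rng.uniform(0.2, 2.0),
        rng.uniform(0.0005, 0.02), rng.uniform(0.0005, 0.02),
        rng.uniform(10.0, 1000.0),
    )
    return [water, solute]


@pytest.fixture(scope="session")
def small_phantom():
    return build_phantom(matrix_size=(24, 24, 4),
                         ph_by_tissue={1: 6.8, 2: 7.0, 3: 7.2},
                         b0_amplitude_hz=30.0, seed=11)


@pytest.fixture(scope="session")
def noisefree_acquisition(small_phantom):
    return simulate_acquisition(small_phantom, agent="iohexol",
                                noise_sigma=0.0, seed=11)
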