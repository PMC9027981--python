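"""Bloch-McConnell simulation of continuous-wave CEST saturation.

The chemical-exchange system is linear in the magnetization vector once the
saturation field is treated as a constant-amplitude (continuous-wave) field
in the rotating frame.  For pools :math:`i = 1..N` (pool 0 is water, the
others are solute pools exchanging with water only) the state is

.. math:: M = (M_{x,0}, M_{y,0}, M_{z,0}, \\ldots, M_{x,N-1}, M_{y,N-1}, M_{z,N-1})

and evolves as :math:`dM/dt = A M + b`, where ``A`` collects relaxation,
off-resonance precession, RF nutation and exchange, and ``b`` holds the
thermal-equilibrium recovery terms.  The saturated water signal is the
longitudinal water component after the saturation period, normalized by its
thermal-equilibrium value.

Shaped saturation pulses are represented by their power-equivalent
continuous-wave amplitude (the B1 value "as calculated by power average"),
which is the standard desk-scale surrogate for trains of frequency-selective
pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

#: Proton gyromagnetic ratio over 2*pi, in MHz/T (equivalently Hz/uT).
GAMMA_HZ_PER_UT = 42.577

__all__ = [
    "GAMMA_HZ_PER_UT",
    "PoolModel",
    "bm_matrix",
    "simulate_zspectrum",
    "batch_steady_state_signal",
]


@dataclass(frozen=True)
class PoolModel:
    """One exchanging proton pool.

    Parameters
    ----------
    name
        Label for reports ("water", "amide_4.3ppm", ...).
    chemical_shift_ppm
        Resonance offset from water, in ppm (water = 0).
    t1, t2
        Longitudinal / transverse relaxation times in seconds.
    proton_fraction
        Equilibrium pool size relative to water (water pool = 1).
    exchange_rate
        Solute-to-water exchange rate in 1/s (0 for the water pool).
    """

    name: str
    chemical_shift_ppm: float
    t1: float
    t2: float
    proton_fraction: float = 1.0
    exchange_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(
                f"pool {self.name!r}: relaxation times must be positive "
                f"(t1={self.t1}, t2={self.t2})"
            )
        if not 0 <= self.proton_fraction <= 1:
            raise ValueError(
                f"pool {self.name!r}: proton_fraction must lie in [0, 1]"
            )
        if self.exchange_rate < 0:
            raise ValueError(f"pool {self.name!r}: exchange_rate must be >= 0")


def _check_pools(pools: list[PoolModel]) -> None:
    if not pools:
        raise ValueError("at least a water pool is required")
    if pools[0].proton_fraction != 1.0:
        raise ValueError("pools[0] is the water pool and must have proton_fraction 1")


def bm_matrix(
    pools: list[PoolModel],
    offset_hz: float,
    b1_ut: float,
    water_frequency_mhz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the Bloch-McConnell drift matrix ``A`` and constant term ``b``.

    ``offset_hz`` is the saturation frequency relative to water (signed,
    positive = downfield/agent side).  Solute pools exchange with water only;
    the water-to-solute rate follows from detailed balance,
    ``k_ws = proton_fraction * k_sw``.
    """
    _check_pools(pools)
    n = len(pools)
    dim = 3 * n
    A = np.zeros((dim, dim))
    b = np.zeros(dim)
    w1 = 2.0 * np.pi * GAMMA_HZ_PER_UT * b1_ut  # rad/s, B1 along x

    for i, p in enumerate(pools):
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        # offset of this pool's resonance from the RF carrier, rad/s
        omega = 2.0 * np.pi * (p.chemical_shift_ppm * water_frequency_mhz - offset_hz)
        A[x, x] -= 1.0 / p.t2
        A[y, y] -= 1.0 / p.t2
        A[z, z] -= 1.0 / p.t1
        A[x, y] += omega
        A[y, x] -= omega
        A[y, z] += w1
        A[z, y] -= w1
        b[z] = p.proton_fraction / p.t1

    wx, wy, wz = 0, 1, 2
    for i, p in enumerate(pools[1:], start=1):
        k_sw = p.exchange_rate
        k_ws = p.proton_fraction * k_sw
        for c in range(3):
            s = 3 * i + c
            w = c
            A[w, w] -= k_ws
            A[w, s] += k_sw
            A[s, s] -= k_sw
            A[s, w] += k_ws
    return A, b


def simulate_zspectrum(
    pools: list[PoolModel],
    offset_hz: float,
    b1_ut: float,
    water_frequency_mhz: float,
    t_sat: float | None = None,
) -> float:
    """Normalized water signal after continuous-wave saturation.

    Propagates the Bloch-McConnell system from thermal equilibrium over the
    saturation period via the exact matrix exponential of the affine system
    (state augmented with a constant 1).  ``t_sat=None`` uses a period long
    enough (50x the longest T1) that the result is the steady state to well
    below 1e-9 relative.

    Returns a value in [0, 1]: saturated water Mz over its equilibrium value.
    """
    _check_pools(pools)
    if b1_ut == 0.0:
        return 1.0
    if t_sat is None:
        t_sat = 50.0 * max(p.t1 for p in pools)
    elif t_sat < 0:
        raise ValueError("t_sat must be non-negative")

    A, b = bm_matrix(pools, offset_hz, b1_ut, water_frequency_mhz)
    dim = A.shape[0]
    # augmented homogeneous system: d/dt [M; 1] = [[A, b], [0, 0]] [M; 1]
    aug = np.zeros((dim + 1, dim + 1))
    aug[:dim, :dim] = A
    aug[:dim, dim] = b
    m0 = np.zeros(dim + 1)
    m0[2::3][: len(pools)] = [p.proton_fraction for p in pools]
    m0[dim] = 1.0
    m = expm(aug * t_sat) @ m0
    return float(np.clip(m[2], 0.0, 1.0))


def batch_steady_state_signal(
    pools: list[PoolModel],
    offsets_hz: np.ndarray,
    b1_ut: float,
    water_frequency_mhz: float,
    exchange_rates: np.ndarray | None = None,
    proton_fraction_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Steady-state saturated water signal for many offsets at once.

    Vectorized closed-form steady state ``M = solve(A, -b)`` of the same
    linear system that :func:`simulate_zspectrum` propagates; used by the
    acquisition simulator where one system per voxel per spectral channel is
    required.  ``exchange_rates`` (same shape as ``offsets_hz``) overrides the
    solute exchange rate per case (applied to every solute pool, as all amide
    pools of one agent share the pH-driven rate); ``proton_fraction_scale``
    scales all solute pool sizes per case (agent concentration).

    Agreement with :func:`simulate_zspectrum` is part of the test suite.
    """
    _check_pools(pools)
    offsets_hz = np.asarray(offsets_hz, dtype=float)
    flat = offsets_hz.reshape(-1)
    m = flat.size
    n = len(pools)
    dim = 3 * n

    if b1_ut == 0.0:
        return np.ones_like(offsets_hz, dtype=float)

    rates = None
    if exchange_rates is not None:
        rates = np.asarray(exchange_rates, dtype=float).reshape(-1)
        if rates.size != m:
            raise ValueError("exchange_rates must match offsets_hz in shape")
    scale = None
    if proton_fraction_scale is not None:
        scale = np.asarray(proton_fraction_scale, dtype=float).reshape(-1)
        if scale.size != m:
            raise ValueError("proton_fraction_scale must match offsets_hz in shape")

    A = np.zeros((m, dim, dim))
    b = np.zeros((m, dim))
    w1 = 2.0 * np.pi * GAMMA_HZ_PER_UT * b1_ut

    for i, p in enumerate(pools):
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        omega = 2.0 * np.pi * (p.chemical_shift_ppm * water_frequency_mhz - flat)
        frac = np.full(m, p.proton_fraction)
        if i > 0 and scale is not None:
            frac = frac * scale
        A[:, x, x] -= 1.0 / p.t2
        A[:, y, y] -= 1.0 / p.t2
        A[:, z, z] -= 1.0 / p.t1
        A[:, x, y] += omega
        A[:, y, x] -= omega
        A[:, y, z] += w1
        A[:, z, y] -= w1
        b[:, z] = frac / p.t1

    for i, p in enumerate(pools[1:], start=1):
        k_sw = np.full(m, p.exchange_rate)
        if rates is not None:
            if p.exchange_rate <= 0:
                raise ValueError(
                    "per-case exchange_rates require positive nominal rates"
                )
            k_sw = rates
        frac = np.full(m, p.proton_fraction)
        if scale is not None:
            frac = frac * scale
        k_ws = frac * k_sw
        for c in range(3):
            s, w = 3 * i + c, c
            A[:, w, w] -= k_ws
            A[:, w, s] += k_sw
            A[:, s, s] -= k_sw
            A[:, s, w] += k_ws

    sol = np.linalg.solve(A, -b[..., None])[..., 0]
    return np.clip(sol[:, 2], 0.0, 1.0).reshape(offsets_hz.shape)
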