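"""Off-resonance (delta-B0) mapping from a dual-echo acquisition.

With two echoes at ``te1`` and ``te2`` the phase accrued by a voxel
off-resonant by ``delta_f`` differs by ``2*pi*delta_f*(te2-te1)``, so

.. math:: \\Delta f = \\mathrm{arg}(S_1^* S_2) / (2\\pi\\,\\Delta TE)

Any phase common to both echoes (coil phase, B1 phase) cancels in the
conjugate product.  The map is unambiguous only within the aliasing band
``|delta_f| < 1/(2*dTE)`` (about +/-230.6 Hz at dTE = 2.168 ms); no phase
unwrapping is attempted, which comfortably covers the field inhomogeneity
this pipeline corrects (|delta_f| <= 120 Hz by default downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DualEchoPair", "DeltaB0Map", "compute_delta_b0"]


@dataclass
class DualEchoPair:
    """Complex volumes at two echo times (ms)."""

    echo1: np.ndarray
    echo2: np.ndarray
    te1_ms: float
    te2_ms: float

    def __post_init__(self) -> None:
        if self.echo1.shape != self.echo2.shape:
            raise ValueError("echo volumes must share a shape")
        if not self.te2_ms > self.te1_ms > 0:
            raise ValueError("echo times must satisfy te2 > te1 > 0")

    @property
    def delta_te_s(self) -> float:
        return (self.te2_ms - self.te1_ms) * 1e-3


@dataclass
class DeltaB0Map:
    """Per-voxel off-resonance in Hz and the magnitude-validity mask."""

    delta_f_hz: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.delta_f_hz.shape != self.valid.shape:
            raise ValueError("delta_f_hz and valid must share a shape")
        if not np.all(np.isfinite(self.delta_f_hz)):
            raise ValueError("delta_f_hz must be finite")

    @property
    def aliasing_bound_hz(self) -> float:
        return float(np.abs(self.delta_f_hz).max())


def compute_delta_b0(pair: DualEchoPair, magnitude_floor: float = 0.05) -> DeltaB0Map:
    """Phase-difference field map from a dual-echo pair.

    Voxels whose first-echo magnitude falls below ``magnitude_floor`` times
    the volume maximum carry no reliable phase; they are masked invalid and
    set to 0 Hz (downstream QC excludes them explicitly rather than
    propagating NaN).
    """
    if not 0 <= magnitude_floor < 1:
        raise ValueError("magnitude_floor must be a fraction in [0, 1)")
    dte = pair.delta_te_s
    phase_diff = np.angle(np.conj(pair.echo1) * pair.echo2)
    delta_f = phase_diff / (2.0 * np.pi * dte)
    mag = np.abs(pair.echo1)
    valid = mag >= magnitude_floor * mag.max()
    delta_f = np.where(valid, delta_f, 0.0)
    return DeltaB0Map(delta_f_hz=delta_f, valid=valid)
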