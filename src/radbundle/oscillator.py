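"""Damped-oscillator signal model of a silicon-nanotweezer (SNT) resonator.

A DNA bundle trapped between the tweezer tips adds a stiffness ``K_DNA`` and a
viscosity ``eta_DNA`` in parallel to the bare device (stiffness ``K_T``,
viscosity ``eta_T``).  The loaded resonance frequency ``F`` and quality factor
``Q`` then encode the bundle mechanics through the standard damped-oscillator
relations

    K_DNA   = K_T * (F**2 - F_T**2) / F_T**2
    eta_DNA = (K_T + K_DNA) / (2*pi*Q*F) - eta_T

where ``F_T`` and ``Q_T`` are the calibrated reference response of the bare
device (including immersion and meniscus effects).  This module implements
these extraction relations and their exact inverses (the forward model used by
the synthetic-data generator).

All quantities are SI; frequency is in Hz throughout (the ``2*pi*Q*F``
denominator uses the frequency in Hz, not rad/s).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DeviceParams",
    "BundleMechanics",
    "ResonanceReading",
    "extract_stiffness",
    "extract_viscosity",
    "forward_frequency",
    "forward_quality",
    "mechanics_from_trace",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class DeviceParams:
    """Bare-resonator mechanics.

    Parameters
    ----------
    K_T : float
        Stiffness of the mobile arm, N/m.
    eta_T : float
        Total viscosity (friction + fluid damping), N·s/m.
    F_T : float
        Reference resonance frequency of the bare device in its operating
        medium, Hz.
    Q_T : float, optional
        Reference quality factor.  If omitted it is derived from the other
        three parameters so that the device is self-consistent:
        ``Q_T = K_T / (2*pi*F_T*eta_T)``.
    """

    K_T: float = 25.0
    eta_T: float = 1.0e-5
    F_T: float = 1000.0
    Q_T: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (self.K_T > 0):
            raise ValueError(f"K_T must be positive, got {self.K_T}")
        if not (self.F_T > 0):
            raise ValueError(f"F_T must be positive, got {self.F_T}")
        if self.eta_T < 0:
            raise ValueError(f"eta_T must be nonnegative, got {self.eta_T}")
        if self.Q_T == 0.0:
            if self.eta_T == 0:
                raise ValueError("Q_T cannot be derived with eta_T = 0")
            object.__setattr__(
                self, "Q_T", self.K_T / (_TWO_PI * self.F_T * self.eta_T)
            )
        elif self.Q_T < 0:
            raise ValueError(f"Q_T must be positive, got {self.Q_T}")


@dataclass(frozen=True)
class BundleMechanics:
    """Extracted bundle stiffness (N/m) and viscosity (N·s/m).

    ``k_dna`` may be negative on noisy data when the loaded frequency dips
    below the reference; such values are flagged, never clamped, so that
    averages of repeated extractions stay unbiased.
    """

    k_dna: float
    eta_dna: float

    @property
    def physical(self) -> bool:
        return self.k_dna >= 0


@dataclass(frozen=True)
class ResonanceReading:
    """One timestamped (frequency, quality-factor) sample of the PLL output."""

    t: float
    F: float
    Q: float

    def __post_init__(self) -> None:
        if not (self.F > 0):
            raise ValueError(f"F must be positive, got {self.F}")
        if not (self.Q > 0):
            raise ValueError(f"Q must be positive, got {self.Q}")


def _as_float(x):
    arr = np.asarray(x, dtype=float)
    return arr if arr.ndim else float(arr)


def extract_stiffness(F, device: DeviceParams):
    """Bundle stiffness from the loaded resonance frequency.

    ``K_DNA = K_T * (F**2 - F_T**2) / F_T**2``.  Accepts a scalar or an array
    of frequencies in Hz.  Negative results (F below the bare reference) are
    returned as-is with a warning.
    """
    F = _as_float(F)
    if np.any(np.asarray(F) <= 0):
        raise ValueError("resonance frequency must be positive")
    k = device.K_T * (F**2 - device.F_T**2) / device.F_T**2
    if np.any(np.asarray(k) < 0):
        warnings.warn(
            "extracted stiffness is negative (frequency below bare reference); "
            "returned unclamped",
            stacklevel=2,
        )
    return k


def extract_viscosity(F, Q, device: DeviceParams, k_dna):
    """Bundle viscosity from the loaded response and extracted stiffness.

    ``eta_DNA = (K_T + K_DNA) / (2*pi*Q*F) - eta_T`` with F in Hz.
    """
    F = _as_float(F)
    Q = _as_float(Q)
    if np.any(np.asarray(F) <= 0) or np.any(np.asarray(Q) <= 0):
        raise ValueError("F and Q must be positive")
    return (device.K_T + np.asarray(k_dna, dtype=float) * 1.0) / (
        _TWO_PI * Q * F
    ) - device.eta_T


def forward_frequency(k_dna, device: DeviceParams):
    """Loaded resonance frequency for a given bundle stiffness.

    Exact inverse of :func:`extract_stiffness`:
    ``F = F_T * sqrt(1 + K_DNA/K_T)``.
    """
    k = _as_float(k_dna)
    if np.any(np.asarray(k) < -device.K_T):
        raise ValueError("k_dna < -K_T has no real resonance frequency")
    return device.F_T * np.sqrt(1.0 + k / device.K_T)


def forward_quality(k_dna, eta_dna, device: DeviceParams):
    """Loaded quality factor for given bundle stiffness and viscosity.

    Exact inverse of :func:`extract_viscosity`:
    ``Q = (K_T + K_DNA) / (2*pi*F*(eta_T + eta_DNA))`` with ``F`` from
    :func:`forward_frequency`.
    """
    eta_total = device.eta_T + _as_float(eta_dna)
    if np.any(np.asarray(eta_total) <= 0):
        raise ValueError("total viscosity must be positive")
    F = forward_frequency(k_dna, device)
    return (device.K_T + _as_float(k_dna)) / (_TWO_PI * F * eta_total)


def mechanics_from_trace(trace, device: DeviceParams):
    """Extract stiffness and viscosity series from a (t, F, Q) trace.

    Parameters
    ----------
    trace : pandas.DataFrame
        Columns ``t``, ``F``, ``Q``.
    device : DeviceParams

    Returns
    -------
    pandas.DataFrame
        Columns ``t``, ``k_dna``, ``eta_dna``.
    """
    import pandas as pd

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = extract_stiffness(trace["F"].to_numpy(), device)
    eta = extract_viscosity(trace["F"].to_numpy(), trace["Q"].to_numpy(), device, k)
    if np.any(k < 0):
        warnings.warn(
            f"{int(np.sum(k < 0))} samples extracted with negative stiffness "
            "(noise below reference); returned unclamped",
            stacklevel=2,
        )
    return pd.DataFrame({"t": trace["t"].to_numpy(), "k_dna": k, "eta_dna": eta})
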