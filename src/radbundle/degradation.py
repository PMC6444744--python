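"""Exponential stiffness degradation of a fiber bundle with strand breaks.

For a bundle of M parallel fibers (Young's modulus E, cross-section A,
clamped length l) carrying N randomly placed breaks, the effective axial
stiffness decays exponentially in the breaks-per-fiber ratio,

    k_eff(N) = M * (E*A/l) * exp(-phi(alpha) * N / M),

valid at low break density (N/M up to order 1).  ``phi`` is a universal decay
value set by the dimensionless inter-fiber coupling ``alpha``; it is stored
here as a scalar at the operating point and can be estimated empirically with
:mod:`radbundle.network`.  Composing with the break kinetics N(t) gives the
time course

    k_eff(t) = M * (E*A/l) * exp(-phi * tanh(b*sqrt(beta)*t) / (M*sqrt(beta)))

whose initial slope is ``dk_eff/dt(0) = -(E*A/l) * phi * b`` — the relation
the two-step parameter inference exploits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .kinetics import KineticsParams, breaks_closed_form

__all__ = [
    "BundleGeometry",
    "DegradationParams",
    "molecule_stiffness",
    "effective_stiffness_from_breaks",
    "effective_stiffness_vs_time",
    "initial_slope",
    "equivalent_broken_molecules",
    "estimate_M",
    "MoleculeCount",
]

#: Rounded ~3.2 nm^2 cross-section (pi * (1 nm)^2) used in all
#: reference-value checks.  The unrounded default is pi*R**2.
REFERENCE_AREA = 3.2e-18


@dataclass(frozen=True)
class BundleGeometry:
    """Geometry and elasticity of the trapped bundle.

    ``A`` defaults to ``pi*R**2`` but is an explicit input, never silently
    recomputed: reference-value checks use the rounded 3.2e-18 m^2.
    """

    M: float = 1800.0
    E: float = 350.0e6
    R: float = 1.0e-9
    l: float = 15.0e-6
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.A == 0.0:
            object.__setattr__(self, "A", math.pi * self.R**2)
        for name in ("M", "E", "R", "l", "A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def reference(cls) -> "BundleGeometry":
        """The operating-point bundle: M=1800, E=350 MPa, A=3.2 nm^2, l=15 um."""
        return cls(M=1800.0, E=350.0e6, R=1.0e-9, l=15.0e-6, A=REFERENCE_AREA)


@dataclass(frozen=True)
class DegradationParams:
    """Decay value ``phi`` (dimensionless) at the operating coupling ``alpha``.

    ``alpha`` and the underlying coupling coefficient ``k_int`` are optional
    bookkeeping; only ``phi`` enters the stiffness law.
    """

    phi: float = 0.7
    alpha: float | None = None
    k_int: float | None = None

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError(f"phi must be nonnegative, got {self.phi}")


class MoleculeCount(NamedTuple):
    count: int
    ratio: float


def molecule_stiffness(geom: BundleGeometry) -> float:
    """Axial stiffness of one clamped molecule, E*A/l (N/m)."""
    return geom.E * geom.A / geom.l


def effective_stiffness_from_breaks(
    geom: BundleGeometry, deg: DegradationParams, N
):
    """Bundle stiffness at break count N: ``M*(E*A/l)*exp(-phi*N/M)``.

    Warns (soft) outside the low-break-density validity domain N/M > 1.
    """
    N_arr = np.asarray(N, dtype=float)
    if np.any(N_arr < 0):
        raise ValueError("break count must be nonnegative")
    if np.any(N_arr / geom.M > 1):
        warnings.warn(
            "N/M > 1: outside the low-break-density validity domain of the "
            "exponential stiffness law",
            stacklevel=2,
        )
    out = geom.M * molecule_stiffness(geom) * np.exp(-deg.phi * N_arr / geom.M)
    return out if out.ndim else float(out)


def effective_stiffness_vs_time(
    geom: BundleGeometry, deg: DegradationParams, kin: KineticsParams, t
):
    """Bundle stiffness versus cumulative beam-on time.

    Exact composition of the exponential stiffness law with the closed-form
    break kinetics; monotone nonincreasing in t with finite limit
    ``k0 * exp(-phi/(M*sqrt(beta)))`` when beta > 0.
    """
    return effective_stiffness_from_breaks(geom, deg, breaks_closed_form(kin, t))


def initial_slope(
    geom: BundleGeometry, deg: DegradationParams, kin: KineticsParams
) -> float:
    """Initial stiffness decay rate, ``-(E*A/l)*phi*b`` (N/m/s).

    Independent of beta and M: at t=0 the kinetics are pure creation and the
    exponential is at its unit-slope point.
    """
    return -molecule_stiffness(geom) * deg.phi * kin.b


def equivalent_broken_molecules(delta_k, geom: BundleGeometry):
    """Stiffness loss expressed as an equivalent count of severed molecules.

    Scales the stiffness change by the single-molecule stiffness E*A/l — the
    order-of-magnitude damage readout attached to a measured stiffness drop.
    """
    dk = np.asarray(delta_k, dtype=float)
    if np.any(dk < 0):
        raise ValueError("stiffness loss must be nonnegative")
    out = dk / molecule_stiffness(geom)
    return out if out.ndim else float(out)


def estimate_M(k0: float, geom: BundleGeometry) -> MoleculeCount:
    """Initial molecule count from the intact-bundle stiffness.

    Ratio of the initial bundle stiffness to the single-molecule stiffness,
    rounded to the nearest integer; the raw ratio is reported alongside.
    """
    if k0 < 0:
        raise ValueError("k0 must be nonnegative")
    if k0 == 0:
        warnings.warn("k0 = 0: degenerate input, zero molecules inferred",
                      stacklevel=2)
        return MoleculeCount(0, 0.0)
    ratio = k0 / molecule_stiffness(geom)
    return MoleculeCount(int(round(ratio)), ratio)
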