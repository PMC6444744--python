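"""Synthetic resonance traces with the structure of the irradiation runs.

Generates (t, F, Q) traces emulating a nanotweezer with a trapped DNA bundle
under a fractionated X-ray protocol: the bundle stiffness follows the
exponential-degradation / second-order-kinetics law on cumulative beam-on
time, stays frozen during the recovery gaps, and is pushed through the
forward oscillator model with small Gaussian PLL noise on the frequency
shift and on the quality factor.  The reference protocol is four 210 s
sessions of 30 Gy separated by 180 s recovery gaps (120 Gy total).

Traces are written as plain CSV with header ``t,F,Q`` preceded by ``#``
provenance comment lines recording the seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degradation import BundleGeometry, DegradationParams, effective_stiffness_vs_time
from .kinetics import KineticsParams
from .oscillator import DeviceParams, forward_frequency, forward_quality

__all__ = [
    "Session",
    "IrradiationSchedule",
    "NoiseModel",
    "make_schedule",
    "simulate_trace",
    "write_trace",
    "read_trace",
    "TraceFormatError",
]


@dataclass(frozen=True)
class Session:
    """One irradiation session: beam-on window [start, start+duration), dose in Gy."""

    start: float
    duration: float
    dose: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("session duration must be positive")
        if self.start < 0 or self.dose < 0:
            raise ValueError("session start and dose must be nonnegative")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class IrradiationSchedule:
    """Time-ordered, non-overlapping irradiation sessions."""

    sessions: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        sess = tuple(self.sessions)
        object.__setattr__(self, "sessions", sess)
        for a, b in zip(sess, sess[1:]):
            if b.start < a.end:
                raise ValueError("sessions must be time-ordered and non-overlapping")

    @property
    def total_dose(self) -> float:
        return sum(s.dose for s in self.sessions)

    @property
    def beam_on_time(self) -> float:
        """Cumulative beam-on duration (the kinetics time axis)."""
        return sum(s.duration for s in self.sessions)

    @property
    def end_time(self) -> float:
        return self.sessions[-1].end if self.sessions else 0.0

    def cumulative_beam_on(self, t):
        """Map wall-clock time to cumulative beam-on time (frozen in gaps)."""
        t_arr = np.asarray(t, dtype=float)
        tau = np.zeros_like(t_arr, dtype=float)
        for s in self.sessions:
            tau += np.clip(t_arr - s.start, 0.0, s.duration)
        return tau if tau.ndim else float(tau)

    def in_session(self, t):
        """Boolean mask: beam on at wall-clock time t."""
        t_arr = np.asarray(t, dtype=float)
        mask = np.zeros(t_arr.shape, dtype=bool)
        for s in self.sessions:
            mask |= (t_arr >= s.start) & (t_arr < s.end)
        return mask if mask.ndim else bool(mask)

    def delivered_dose(self, t):
        """Dose delivered up to wall-clock time t (linear within sessions)."""
        t_arr = np.asarray(t, dtype=float)
        dose = np.zeros_like(t_arr, dtype=float)
        for s in self.sessions:
            dose += s.dose * np.clip(t_arr - s.start, 0.0, s.duration) / s.duration
        return dose if dose.ndim else float(dose)


def make_schedule(
    n_sessions: int, session_s: float, gap_s: float, dose_gy: float,
    start_s: float = 0.0,
) -> IrradiationSchedule:
    """Regular fractionated schedule: n sessions of ``session_s`` seconds and
    ``dose_gy`` gray each, separated by ``gap_s`` recovery gaps."""
    if n_sessions < 0:
        raise ValueError("n_sessions must be nonnegative")
    sessions = []
    t = start_s
    for _ in range(n_sessions):
        sessions.append(Session(start=t, duration=session_s, dose=dose_gy))
        t += session_s + gap_s
    return IrradiationSchedule(tuple(sessions))


@dataclass(frozen=True)
class NoiseModel:
    """PLL measurement noise.

    ``sd_rel_freq``: Gaussian sd on the DNA-induced frequency shift, relative
    to the instantaneous shift (default 0.0019, i.e. ~0.005 Hz sd — roughly
    0.02 Hz peak-to-peak — on a 2.7 Hz initial shift).  ``sd_rel_q``: relative
    Gaussian sd on Q.  ``drift_hz_per_30gy``: slow linear frequency drift per
    30 Gy delivered, for emulating charge-accumulation at large apertures
    (default 0: with a 5 mm aperture the drift sits inside the PLL noise).
    """

    sd_rel_freq: float = 0.0019
    sd_rel_q: float = 0.0019
    drift_hz_per_30gy: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sd_rel_freq", "sd_rel_q", "drift_hz_per_30gy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def simulate_trace(
    device: DeviceParams,
    geom: BundleGeometry,
    kin: KineticsParams,
    deg: DegradationParams,
    schedule: IrradiationSchedule,
    sample_hz: float = 1.0,
    noise: NoiseModel | None = None,
    seed=None,
    eta_dna: float = 0.0,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Simulate a (t, F, Q) resonance trace under an irradiation schedule.

    The bundle stiffness follows the degradation law on cumulative beam-on
    time and is frozen outside sessions; the viscosity contribution is held
    constant (only stiffness degradation is modelled).  Passing ``noise=None``
    uses package-default noise; use ``NoiseModel(0, 0, 0)`` for a noiseless
    trace.  Deterministic under ``seed``.
    """
    if sample_hz <= 0:
        raise ValueError("sample_hz must be positive")
    if noise is None:
        noise = NoiseModel()
    if t_end is None:
        t_end = schedule.end_time if schedule.sessions else 60.0
    n = int(np.floor(t_end * sample_hz)) + 1
    t = np.arange(n) / sample_hz

    tau = schedule.cumulative_beam_on(t)
    k_eff = effective_stiffness_vs_time(geom, deg, kin, tau)
    F_clean = forward_frequency(k_eff, device)
    Q_clean = forward_quality(k_eff, eta_dna, device)

    rng = np.random.default_rng(seed)
    shift = F_clean - device.F_T
    F = device.F_T + shift * (1.0 + noise.sd_rel_freq * rng.standard_normal(n))
    if noise.drift_hz_per_30gy > 0:
        F = F + noise.drift_hz_per_30gy * schedule.delivered_dose(t) / 30.0
    Q = Q_clean * (1.0 + noise.sd_rel_q * rng.standard_normal(n))
    return pd.DataFrame({"t": t, "F": F, "Q": Q})


class TraceFormatError(ValueError):
    """Malformed trace file (bad header or unparsable row)."""


def write_trace(trace: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a trace as CSV (header ``t,F,Q``) with ``#`` provenance comments.

    Full float precision (repr round-trip) and C-locale decimal points.
    """
    with open(path, "w", newline="") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        fh.write("t,F,Q\n")
        for t, F, Q in zip(trace["t"], trace["F"], trace["Q"]):
            fh.write(f"{float(t)!r},{float(F)!r},{float(Q)!r}\n")


def read_trace(path) -> pd.DataFrame:
    """Read a trace CSV written by :func:`write_trace`.

    Raises :class:`TraceFormatError` naming the offending line on schema or
    parse errors.  ``read_trace(write_trace(x)) == x`` to full precision.
    """
    rows = []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header != ["t", "F", "Q"]:
                    raise TraceFormatError(
                        f"{path}: line {lineno}: expected header 't,F,Q', "
                        f"got {','.join(header)!r}"
                    )
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise TraceFormatError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                rows.append(tuple(float(p) for p in parts))
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from None
    if header is None:
        raise TraceFormatError(f"{path}: empty file, no header")
    return pd.DataFrame(rows, columns=["t", "F", "Q"])
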