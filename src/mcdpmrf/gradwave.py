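"""Diffusion-preparation gradient waveforms and their physics.

A preparation waveform is stored as one shared amplitude shape on a uniform
raster (the hardware dwell time), together with the centers of the refocusing
pulses inside the preparation and a unit diffusion-encoding direction.  The
same shape is played out simultaneously on the three Cartesian axes, which
triples the b-value relative to a single-axis waveform.

All phase bookkeeping uses the *effective* gradient: the sign of the played
gradient toggles after every refocusing pulse, because a 180deg pulse negates
the accumulated transverse phase.  Concomitant (Maxwell) terms are different:
their phase is invariant to gradient polarity (it scales with g^2) but is
still refocused by the 180deg pulses, so the concomitant bookkeeping toggles
only the *segment* sign, never the polarity of g.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import GAMMA

__all__ = [
    "GradientWaveform",
    "HardwareLimits",
    "MomentVector",
    "ValidationReport",
    "effective_gradient",
    "moment",
    "bvalue",
    "concomitant_residual",
    "validate",
    "scale_to_b",
    "flow_phase",
    "write_waveform",
    "read_waveform",
]

_DEFAULT_DIRECTION = np.ones(3) / np.sqrt(3.0)


class InvalidTimingError(ValueError):
    """A refocusing pulse or RF window lies outside the waveform duration."""


@dataclass(frozen=True)
class HardwareLimits:
    """Per-axis gradient hardware and safety limits.

    Defaults correspond to a clinical 3T system with 62 mT/m amplitude and a
    slew rate administratively capped at 70 T/m/s for peripheral-nerve-
    stimulation safety.
    """

    g_max: float = 62.0  # mT/m
    s_max: float = 70.0  # T/m/s
    dwell: float = 6.4e-6  # s
    node_spacing: float = 25.6e-6  # s, optimizer node interval

    def __post_init__(self) -> None:
        if min(self.g_max, self.s_max, self.dwell, self.node_spacing) <= 0:
            raise ValueError("hardware limits must be strictly positive")
        ratio = self.node_spacing / self.dwell
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("node_spacing must be an integer multiple of dwell")


@dataclass(frozen=True)
class MomentVector:
    m0: float  # s * mT/m
    m1: float  # s^2 * mT/m
    m2: float | None = None  # s^3 * mT/m


@dataclass
class GradientWaveform:
    """One shared gradient shape applied along three axes.

    Parameters
    ----------
    samples:
        Shared shape amplitudes in mT/m on the ``dt`` raster.  Sample ``i``
        is the amplitude at time ``i * dt``.
    dt:
        Raster interval in seconds (hardware dwell time).
    refocus_times:
        Ordered centers of the refocusing pulses, in seconds, strictly
        inside ``(0, duration)``.
    rf_windows:
        Intervals (start, stop) in seconds during which the gradient must be
        zero (RF pulses plus eddy-current gaps).
    direction:
        Unit 3-vector of the diffusion-encoding direction.  The per-axis
        amplitude is ``samples * sqrt(3) * direction[a]``, so the default
        direction plays the full shape on every axis.
    """

    samples: np.ndarray
    dt: float = 6.4e-6
    refocus_times: tuple[float, ...] = ()
    rf_windows: tuple[tuple[float, float], ...] = ()
    direction: np.ndarray = field(default_factory=lambda: _DEFAULT_DIRECTION.copy())

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if not np.isclose(nrm, 1.0, atol=1e-6):
            raise ValueError("direction must have unit norm")
        self.refocus_times = tuple(sorted(self.refocus_times))
        for t in self.refocus_times:
            if not 0.0 < t < self.duration:
                raise InvalidTimingError(
                    f"refocusing time {t} s outside (0, {self.duration}) s"
                )

    @property
    def duration(self) -> float:
        """Total preparation time in seconds (samples span [0, T])."""
        return (self.samples.size - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    @property
    def axis_scales(self) -> np.ndarray:
        """Per-axis multiplier of the shared shape (sqrt(3) * direction)."""
        return np.sqrt(3.0) * self.direction

    def scaled(self, factor: float) -> "GradientWaveform":
        return replace(self, samples=self.samples * factor)


def _segment_signs(times: np.ndarray, refocus_times: tuple[float, ...]) -> np.ndarray:
    """(-1)^(number of refocusing pulses before t), per raster sample."""
    counts = np.searchsorted(np.asarray(refocus_times), times, side="left")
    return np.where(counts % 2 == 0, 1.0, -1.0)


def effective_gradient(w: GradientWaveform) -> np.ndarray:
    """Signed shared-shape amplitude: sign toggles after each refocusing pulse."""
    return w.samples * _segment_signs(w.times, w.refocus_times)


def moment(w: GradientWaveform, order: int) -> float:
    """n-th time moment of the effective gradient at t = T (shared shape).

    ``Mn = integral of t^n * g_eff(t) dt`` over the full preparation,
    evaluated with the trapezoidal rule on the raster.  Units are
    ``s^(n+1) * mT/m``.
    """
    if order not in (0, 1, 2):
        raise ValueError("moment order must be 0, 1, or 2")
    g = effective_gradient(w)
    return float(np.trapezoid(w.times**order * g, dx=w.dt))


def moments(w: GradientWaveform) -> MomentVector:
    return MomentVector(moment(w, 0), moment(w, 1), moment(w, 2))


def bvalue(w: GradientWaveform) -> float:
    """Diffusion weighting b in s/mm^2, summed over the three axes.

    ``b = gamma^2 * sum_a integral F_a(t)^2 dt`` with ``F_a`` the running
    integral of the effective gradient on axis ``a``.  For the default
    direction the three axes carry equal shapes and b is three times the
    single-axis value.
    """
    g_si = effective_gradient(w) * 1e-3  # T/m
    # Running integral on the raster (trapezoid), F(0) = 0.
    f = np.concatenate(
        ([0.0], np.cumsum(0.5 * (g_si[1:] + g_si[:-1]) * w.dt))
    )
    b_shape = GAMMA**2 * np.trapezoid(f**2, dx=w.dt)  # s/m^2, single axis
    b_total = b_shape * float(np.sum(w.axis_scales**2))
    return float(b_total * 1e-6)  # s/mm^2


def concomitant_residual(w: GradientWaveform) -> float:
    """Signed integral of g^2 with sign toggling at refocusing pulses.

    Concomitant (Maxwell) phase grows with g(t)^2 regardless of gradient
    polarity but is refocused by 180deg pulses; for the shared-shape design
    the lowest-order residual reduces to the signed integral of the squared
    shape.  Units: s * (mT/m)^2.
    """
    s = _segment_signs(w.times, w.refocus_times)
    return float(np.trapezoid(s * w.samples**2, dx=w.dt))


@dataclass(frozen=True)
class ValidationReport:
    max_amplitude: float  # mT/m, worst axis
    max_slew: float  # T/m/s, worst axis
    amplitude_ok: bool
    slew_ok: bool
    rf_windows_ok: bool
    m0: float
    m1: float
    m0_ok: bool
    m1_ok: bool
    maxwell_residual: float

    @property
    def passed(self) -> bool:
        return (
            self.amplitude_ok
            and self.slew_ok
            and self.rf_windows_ok
            and self.m0_ok
            and self.m1_ok
        )


def validate(
    w: GradientWaveform,
    limits: HardwareLimits | None = None,
    moment_tol: float = 1e-6,
) -> ValidationReport:
    """Check hardware limits, RF-window compliance and moment nulls.

    Moment nulls use a relative tolerance ``moment_tol * max|g| * T^(n+1)``.
    The report never raises; callers decide what a failure means.
    """
    limits = limits or HardwareLimits()
    axis_amp = np.max(np.abs(w.samples)) * np.max(np.abs(w.axis_scales))
    slew_shape = np.max(np.abs(np.diff(w.samples))) / w.dt if w.samples.size > 1 else 0.0
    axis_slew = slew_shape * np.max(np.abs(w.axis_scales)) * 1e-3  # T/m/s

    rf_ok = True
    t = w.times
    for start, stop in w.rf_windows:
        inside = (t > start + 1e-12) & (t < stop - 1e-12)
        if np.any(np.abs(w.samples[inside]) > 1e-12):
            rf_ok = False
    m0 = moment(w, 0)
    m1 = moment(w, 1)
    gmax_here = max(np.max(np.abs(w.samples)), 1e-30)
    tol0 = moment_tol * gmax_here * w.duration
    tol1 = moment_tol * gmax_here * w.duration**2
    return ValidationReport(
        max_amplitude=float(axis_amp),
        max_slew=float(axis_slew),
        amplitude_ok=bool(axis_amp <= limits.g_max * (1 + 1e-9)),
        slew_ok=bool(axis_slew <= limits.s_max * (1 + 1e-9)),
        rf_windows_ok=rf_ok,
        m0=m0,
        m1=m1,
        m0_ok=bool(abs(m0) <= tol0),
        m1_ok=bool(abs(m1) <= tol1),
        maxwell_residual=concomitant_residual(w),
    )


def scale_to_b(w: GradientWaveform, b_target: float) -> GradientWaveform:
    """Scale amplitudes so the waveform reaches a smaller target b-value.

    Moments scale linearly with amplitude, so M0/M1 nulls are preserved;
    b scales quadratically, hence the sqrt scaling factor.
    """
    b_now = bvalue(w)
    if b_target > b_now * (1 + 1e-9):
        raise ValueError(
            f"cannot scale up: target {b_target} s/mm^2 exceeds current {b_now:.1f}"
        )
    if b_target < 0:
        raise ValueError("b_target must be non-negative")
    return w.scaled(float(np.sqrt(b_target / b_now)))


def flow_phase(w: GradientWaveform, x0: float, v: float) -> float:
    """First-order motion phase accrued by a spin at x0 moving with velocity v.

    ``phi = gamma * (M0 * x0 + M1 * v)`` along the encoding direction, with
    the shared-shape moments.  An M0- and M1-nulled preparation yields zero
    phase for any (x0, v); an M0-only preparation leaves the velocity term.
    Units: x0 in m, v in m/s, phase in rad.
    """
    m0 = moment(w, 0) * 1e-3  # s*T/m
    m1 = moment(w, 1) * 1e-3  # s^2*T/m
    return float(GAMMA * (m0 * x0 + m1 * v))


def write_waveform(w: GradientWaveform, path: str | Path) -> None:
    """Plain-text waveform table: header line then one amplitude per line."""
    path = Path(path)
    refocus = ",".join(f"{t:.12g}" for t in w.refocus_times)
    windows = ";".join(f"{a:.12g},{b:.12g}" for a, b in w.rf_windows)
    direction = ",".join(f"{d:.12g}" for d in w.direction)
    lines = [
        f"# dt={w.dt:.12g} duration={w.duration:.12g} "
        f"refocus={refocus} direction={direction} rf_windows={windows}"
    ]
    lines += [f"{s:.12g}" for s in w.samples]
    path.write_text("\n".join(lines) + "\n")


def read_waveform(path: str | Path) -> GradientWaveform:
    text = Path(path).read_text().strip().splitlines()
    header = text[0].lstrip("# ").split()
    fields = dict(item.split("=", 1) for item in header)
    refocus = tuple(float(x) for x in fields["refocus"].split(",") if x)
    direction = np.array([float(x) for x in fields["direction"].split(",")])
    windows = tuple(
        tuple(float(x) for x in pair.split(","))
        for pair in fields.get("rf_windows", "").split(";")
        if pair
    )
    samples = np.array([float(line) for line in text[1:]])
    return GradientWaveform(
        samples=samples,
        dt=float(fields["dt"]),
        refocus_times=refocus,
        rf_windows=windows,  # type: ignore[arg-type]
        direction=direction,
    )
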