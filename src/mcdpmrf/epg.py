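"""Extended-phase-graph (EPG) engine with relaxation and diffusion.

The configuration states F+(k), F-(k), Z(k) are tracked up to a finite
dephasing order ``k_max`` and are vectorized over an arbitrary batch of
tissue parameter sets, so an entire dictionary is simulated in one pass.

Diffusion enters through the standard per-state b-factors: over an interval
of length ``dt`` during which the gradient increments the dephasing order by
``dk`` (in units of the physical spoiler moment ``dk_phys``, rad/m), a
transverse state of starting order k attenuates with

    b_T = (k^2 + k*dk + dk^2/3) * dk_phys^2 * dt

and a longitudinal state with ``b_L = k^2 * dk_phys^2 * dt``.  F- states use
k -> -k.  Magnetization preparations (inversion, T2-prep, diffusion-prep)
are modeled as instantaneous weightings of Z0 with a perfect crusher, the
diffusion preparation contributing the analytic ``exp(-b * ADC)`` factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueParams",
    "EPGState",
    "epg_rf",
    "epg_relax_shift_diffuse",
    "apply_prep",
]


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and diffusion parameters of one tissue.

    t1, t2 in ms; adc in 1e-3 mm^2/s (i.e. um^2/ms); pd is an arbitrary
    proton-density scale.
    """

    t1: float
    t2: float
    adc: float
    pd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t1 >= self.t2 > 0):
            raise ValueError("require t1 >= t2 > 0")
        if self.adc < 0:
            raise ValueError("adc must be non-negative")


class EPGState:
    """Batch of EPG configuration states.

    Arrays have shape ``(k_max + 1, n)`` with ``n`` the batch size.  The
    stored F-(k) is the conjugate of F(-k), so F-(0) == conj(F+(0)).
    """

    __slots__ = ("f_plus", "f_minus", "z", "k_max")

    def __init__(self, n: int = 1, k_max: int = 20, pd: np.ndarray | float = 1.0):
        self.k_max = int(k_max)
        shape = (self.k_max + 1, n)
        self.f_plus = np.zeros(shape, dtype=complex)
        self.f_minus = np.zeros(shape, dtype=complex)
        self.z = np.zeros(shape, dtype=complex)
        self.z[0] = pd

    @property
    def n(self) -> int:
        return self.f_plus.shape[1]

    def copy(self) -> "EPGState":
        out = EPGState(self.n, self.k_max, pd=0.0)
        out.f_plus = self.f_plus.copy()
        out.f_minus = self.f_minus.copy()
        out.z = self.z.copy()
        return out

    @property
    def orders(self) -> np.ndarray:
        return np.arange(self.k_max + 1)


def epg_rf(state: EPGState, flip: float, phase: float = 0.0) -> EPGState:
    """Apply an RF rotation (flip and phase in degrees) to every order.

    Standard EPG rotation mixing (F+, F-, Z); modifies and returns the state.
    """
    a = np.deg2rad(flip)
    p = np.deg2rad(phase)
    c2 = np.cos(a / 2) ** 2
    s2 = np.sin(a / 2) ** 2
    sa = np.sin(a)
    ca = np.cos(a)
    e_p = np.exp(1j * p)

    fp, fm, z = state.f_plus, state.f_minus, state.z
    fp_new = c2 * fp + s2 * e_p**2 * fm - 1j * e_p * sa * z
    fm_new = s2 * e_p**-2 * fp + c2 * fm + 1j * e_p**-1 * sa * z
    z_new = -0.5j * e_p**-1 * sa * fp + 0.5j * e_p * sa * fm + ca * z
    state.f_plus, state.f_minus, state.z = fp_new, fm_new, z_new
    return state


def epg_relax_shift_diffuse(
    state: EPGState,
    dt: float,
    t1: np.ndarray | float,
    t2: np.ndarray | float,
    adc: np.ndarray | float = 0.0,
    pd: np.ndarray | float = 1.0,
    dephasing: int = 0,
    dk_phys: float = 0.0,
) -> EPGState:
    """Relaxation, diffusion attenuation and integer state shift over ``dt``.

    Parameters
    ----------
    dt : interval in ms.
    t1, t2 : relaxation times in ms (scalars or length-n arrays).
    adc : diffusivity in 1e-3 mm^2/s.
    pd : equilibrium Z0 the longitudinal magnetization recovers toward.
    dephasing : integer dephasing increment dk over the interval.
    dk_phys : physical dephasing per unit order, rad/m.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0 and dephasing == 0:
        return state
    e1 = np.exp(-dt / np.asarray(t1))
    e2 = np.exp(-dt / np.asarray(t2))

    state.f_plus *= e2
    state.f_minus *= e2
    recovery = (1.0 - e1) * np.asarray(pd)
    state.z *= e1
    state.z[0] += recovery

    if dk_phys != 0.0:
        # D in m^2/s; adc is in 1e-3 mm^2/s = 1e-9 m^2/s; dt in ms = 1e-3 s.
        d_si = np.asarray(adc) * 1e-9
        dt_si = dt * 1e-3
        k = state.orders[:, None].astype(float)
        dk = float(dephasing)
        b_t_plus = (k**2 + k * dk + dk**2 / 3.0) * dk_phys**2 * dt_si
        b_t_minus = (k**2 - k * dk + dk**2 / 3.0) * dk_phys**2 * dt_si
        b_l = k**2 * dk_phys**2 * dt_si
        state.f_plus *= np.exp(-b_t_plus * d_si)
        state.f_minus *= np.exp(-b_t_minus * d_si)
        # Z recovery happens at k=0 where b_l = 0, so the order of operations
        # is immaterial for the recovered component.
        state.z *= np.exp(-b_l * d_si)

    for _ in range(abs(int(dephasing))):
        _shift(state, up=dephasing > 0)
    return state


def _shift(state: EPGState, up: bool = True) -> None:
    """Shift transverse orders by one (states beyond k_max are truncated)."""
    fp, fm = state.f_plus, state.f_minus
    if up:
        fp[1:] = fp[:-1]
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
        fp[0] = np.conj(fm[0])
    else:
        fm[1:] = fm[:-1]
        fp[:-1] = fp[1:]
        fp[-1] = 0.0
        fm[0] = np.conj(fp[0])


def apply_prep(
    state: EPGState,
    prep: tuple[str, dict],
    t1: np.ndarray | float,
    t2: np.ndarray | float,
    adc: np.ndarray | float = 0.0,
    pd: np.ndarray | float = 1.0,
) -> EPGState:
    """Apply a magnetization-preparation module to the state.

    ``prep`` is ``(kind, params)`` with kind one of ``none``, ``inversion``
    (params: ti in ms, eff inversion efficiency), ``t2prep`` (params: dur in
    ms) or ``diffprep`` (params: dur in ms, b in s/mm^2).  T2- and
    diffusion-preparations act on Z0 with a perfect crusher zeroing all
    other states; a diffusion prep of b = 0 is identical to a T2-prep of
    equal duration.
    """
    kind, params = prep
    if kind == "none":
        return state
    if kind == "inversion":
        eff = params.get("eff", 1.0)
        ti = params.get("ti", 20.0)
        state.z *= -eff
        return epg_relax_shift_diffuse(state, ti, t1, t2, adc, pd)
    if kind in ("t2prep", "diffprep"):
        dur = params["dur"]
        weight = np.exp(-dur / np.asarray(t2))
        if kind == "diffprep":
            b = params.get("b", 0.0)  # s/mm^2; adc in 1e-3 mm^2/s
            weight = weight * np.exp(-b * np.asarray(adc) * 1e-3)
        z0 = state.z[0] * weight
        state.f_plus[:] = 0.0
        state.f_minus[:] = 0.0
        state.z[:] = 0.0
        state.z[0] = z0
        return state
    raise ValueError(f"unknown preparation kind: {kind!r}")
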