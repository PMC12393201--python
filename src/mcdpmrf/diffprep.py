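"""Optimization of motion-compensated diffusion-preparation gradients.

The preparation is a 90deg tip-down, two adiabatic refocusing pulses, and a
90deg tip-up packed into a fixed duration (default 50 ms).  Gradients may
only play in the free segments between RF pulses, with a 1 ms eddy-current
gap separating every gradient lobe from its neighbouring RF pulse.  The
waveform is modeled as a piecewise-linear function of node amplitudes on a
coarse grid (default 25.6 us, four dwell times) and the b-value of the
linearly interpolated waveform is maximized subject to:

* per-axis amplitude and slew-rate caps,
* zeroth (and optionally first/second) moment nulling at the end of the
  preparation, making the encoding robust to static offset and constant
  velocity (cardiac/vascular motion),
* optionally a vanishing concomitant (Maxwell) phase residual.

Maximizing a convex quadratic is nonconvex, so the interior-point solve is
started from all nodes at the amplitude ceiling and, as a fallback, from a
small fixed family of segment-wise sign patterns; the best feasible
incumbent wins.  The result is deterministic for fixed settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from .constants import GAMMA
from .gradwave import (
    GradientWaveform,
    HardwareLimits,
    MomentVector,
    bvalue,
    concomitant_residual,
    moment,
    validate,
)

__all__ = [
    "PrepTiming",
    "ConstraintSpec",
    "OptimizationResult",
    "build_timing",
    "optimize_prep",
    "interpolate_to_dwell",
]


class InfeasibleTimingError(ValueError):
    """The RF pulses and gaps do not fit inside the preparation duration."""


@dataclass(frozen=True)
class PrepTiming:
    """Timing layout of the diffusion/T2 preparation block."""

    duration: float = 0.050
    refocus_duration: float = 0.0103
    refocus_centers: tuple[float, ...] = (0.0125, 0.0375)
    gap: float = 0.001
    tip_duration: float = 0.0

    @property
    def n_refocus(self) -> int:
        return len(self.refocus_centers)

    @property
    def rf_windows(self) -> tuple[tuple[float, float], ...]:
        """Gradient-forbidden intervals: RF pulses plus eddy gaps.

        The eddy-current gap separates gradient lobes from RF pulses of
        finite duration; the tip-down/tip-up pulses are modeled as
        instantaneous by default and only contribute a forbidden window
        (with gaps) when ``tip_duration`` is nonzero.
        """
        win = []
        if self.tip_duration > 0:
            win.append((0.0, self.tip_duration + self.gap))
            win.append(
                (self.duration - self.tip_duration - self.gap, self.duration)
            )
        half = self.refocus_duration / 2
        for c in self.refocus_centers:
            win.append((c - half - self.gap, c + half + self.gap))
        return tuple(win)

    @property
    def segments(self) -> tuple[tuple[float, float], ...]:
        """Free gradient intervals between RF windows."""
        segs = []
        windows = sorted(self.rf_windows)
        cursor = 0.0
        for start, stop in windows:
            if start > cursor:
                segs.append((cursor, start))
            cursor = max(cursor, stop)
        if cursor < self.duration:
            segs.append((cursor, self.duration))
        return tuple(segs)


def build_timing(
    duration: float = 0.050,
    n_refocus: int = 2,
    refocus_duration: float = 0.0103,
    gap: float = 0.001,
    tip_duration: float = 0.0,
    refocus_centers: tuple[float, ...] | None = None,
) -> PrepTiming:
    """Lay out the preparation timing; refocusing pulses default to symmetric
    placement at odd multiples of T/(2*n)."""
    if min(duration, refocus_duration) <= 0 or gap < 0 or tip_duration < 0:
        raise InfeasibleTimingError("durations must be positive")
    if refocus_centers is None:
        refocus_centers = tuple(
            (2 * i + 1) * duration / (2 * n_refocus) for i in range(n_refocus)
        )
    timing = PrepTiming(
        duration=duration,
        refocus_duration=refocus_duration,
        refocus_centers=refocus_centers,
        gap=gap,
        tip_duration=tip_duration,
    )
    segs = timing.segments
    if len(segs) != n_refocus + 1 or any(b - a <= 0 for a, b in segs):
        raise InfeasibleTimingError(
            "RF pulses and gaps leave no positive-length gradient segments"
        )
    return timing


@dataclass(frozen=True)
class ConstraintSpec:
    """Which compensation constraints the optimizer enforces."""

    null_m0: bool = True
    null_m1: bool = True
    null_m2: bool = False
    maxwell: bool = True
    eddy_gap: bool = True

    def __post_init__(self) -> None:
        if (self.null_m1 or self.null_m2) and not self.null_m0:
            # First/second-order compensation subsumes zeroth-order nulling.
            object.__setattr__(self, "null_m0", True)


@dataclass
class OptimizationResult:
    nodes: np.ndarray  # full node-grid amplitudes, mT/m
    node_times: np.ndarray  # s
    waveform: GradientWaveform
    b_achieved: float  # s/mm^2
    constraint_residuals: dict
    solver_status: str  # "converged" | "failed"
    iterations: int

    @property
    def converged(self) -> bool:
        return self.solver_status == "converged"


def _timing_for_gap(timing: PrepTiming, spec: ConstraintSpec) -> PrepTiming:
    if spec.eddy_gap:
        return timing
    return PrepTiming(
        duration=timing.duration,
        refocus_duration=timing.refocus_duration,
        refocus_centers=timing.refocus_centers,
        gap=0.0,
        tip_duration=timing.tip_duration,
    )


def _node_layout(timing: PrepTiming, limits: HardwareLimits):
    """Node times per segment; first/last node of each segment is pinned to 0."""
    h = limits.node_spacing
    seg_nodes = []
    for start, stop in timing.segments:
        i0 = int(np.ceil(start / h - 1e-9))
        i1 = int(np.floor(stop / h + 1e-9))
        idx = np.arange(i0, i1 + 1)
        if idx.size < 3:
            raise InfeasibleTimingError("segment too short for the node grid")
        seg_nodes.append(idx)
    return seg_nodes


def _interp_matrix(fine_times: np.ndarray, node_times: np.ndarray) -> np.ndarray:
    """Linear-interpolation matrix from one segment's nodes to the fine raster
    (zero outside the node span)."""
    n = node_times.size
    L = np.zeros((fine_times.size, n))
    inside = (fine_times >= node_times[0] - 1e-15) & (fine_times <= node_times[-1] + 1e-15)
    t = fine_times[inside]
    j = np.clip(np.searchsorted(node_times, t, side="right") - 1, 0, n - 2)
    u = (t - node_times[j]) / (node_times[j + 1] - node_times[j])
    rows = np.nonzero(inside)[0]
    L[rows, j] = 1.0 - u
    L[rows, j + 1] = u
    return L


def _assemble(timing: PrepTiming, limits: HardwareLimits):
    """Build the fine-raster quadrature matrices for the node variables.

    Returns the variable-to-fine interpolation matrix restricted to the free
    (un-pinned) nodes, the b-value quadratic form, the moment row vectors,
    the Maxwell quadratic form, and the slew difference operator.
    """
    dt = limits.dwell
    n_fine = int(np.floor(timing.duration / dt + 1e-9)) + 1
    t_fine = np.arange(n_fine) * dt

    seg_nodes = _node_layout(timing, limits)
    h = limits.node_spacing

    cols = []  # fine-raster column per free node
    node_times_all = []
    free_mask = []
    slew_rows = []
    col_offset = 0
    for idx in seg_nodes:
        nt = idx * h
        L = _interp_matrix(t_fine, nt)
        cols.append(L)
        node_times_all.append(nt)
        m = np.ones(nt.size, dtype=bool)
        m[0] = m[-1] = False  # pin segment edges to zero
        free_mask.append(m)
        for k in range(nt.size - 1):
            slew_rows.append((col_offset + k, col_offset + k + 1))
        col_offset += nt.size

    L_all = np.concatenate(cols, axis=1)  # fine x all-nodes
    free = np.concatenate(free_mask)
    node_times = np.concatenate(node_times_all)
    L_free = L_all[:, free]

    # Effective-gradient segment signs on the fine raster.
    sign = np.ones(n_fine)
    count = np.searchsorted(np.asarray(timing.refocus_centers), t_fine, side="left")
    sign = np.where(count % 2 == 0, 1.0, -1.0)

    w_trap = np.full(n_fine, dt)
    w_trap[0] = w_trap[-1] = dt / 2

    # Running integral of the signed waveform: F = C (sign * g_fine).
    signed_L = sign[:, None] * L_free
    steps = 0.5 * dt * (signed_L[1:] + signed_L[:-1])
    A = np.vstack([np.zeros(L_free.shape[1]), np.cumsum(steps, axis=0)])
    Q = A.T @ (w_trap[:, None] * A)  # b-value form (single-axis, (mT/m)^2 -> see scale)

    m_rows = {
        n: (w_trap * sign * t_fine**n) @ L_free for n in (0, 1, 2)
    }
    S = L_free.T @ ((w_trap * sign)[:, None] * L_free)  # Maxwell form
    S = 0.5 * (S + S.T)

    # Slew operator on the free variables (differences of consecutive nodes
    # within a segment; pinned zeros participate as fixed endpoints).
    n_all = node_times.size
    D_all = sparse.lil_matrix((len(slew_rows), n_all))
    for r, (a, b) in enumerate(slew_rows):
        D_all[r, a] = -1.0
        D_all[r, b] = 1.0
    D = sparse.csr_matrix(D_all)[:, free]

    return L_free, free, node_times, Q, m_rows, S, D, t_fine


def _segment_pattern_starts(timing, limits, free_mask, seg_nodes):
    """Deterministic multi-start sign patterns.

    Besides constant-per-segment alternation, include patterns whose played
    polarity flips halfway through the interior segments: those seed the
    single-large-excursion solutions in which the dephasing keeps growing
    through the middle of the preparation (the high-b family).
    """
    n_seg = len(seg_nodes)

    def build(signs_fn):
        x = []
        for s, idx in enumerate(seg_nodes):
            u = np.linspace(0.0, 1.0, idx.size)
            x.append(np.array([float(signs_fn(s, ui)) for ui in u]))
        return np.concatenate(x)[free_mask]

    def split_updown(s, u):
        if s == 0:
            return 1
        if s == n_seg - 1:
            return -1
        return -1 if u < 0.5 else 1  # played flip -> monotone effective lobe

    starts = [
        build(split_updown),
        build(lambda s, u: -split_updown(s, u)),
        build(lambda s, u: 1 if s % 2 == 0 else -1),
    ]
    return starts


def optimize_prep(
    timing: PrepTiming | None = None,
    limits: HardwareLimits | None = None,
    spec: ConstraintSpec | None = None,
    maxiter: int = 400,
) -> OptimizationResult:
    """Maximize the 3-axis b-value of the preparation under the enabled
    constraints.  See the module docstring for the problem statement."""
    timing = timing or build_timing()
    limits = limits or HardwareLimits()
    spec = spec or ConstraintSpec()
    timing = _timing_for_gap(timing, spec)

    L_free, free, node_times, Q, m_rows, S, D, t_fine = _assemble(timing, limits)
    n = Q.shape[0]
    seg_nodes = _node_layout(timing, limits)

    g_ref = limits.g_max  # variables are x = g / g_max in [-1, 1]
    T = timing.duration

    # b in s/mm^2 of the 3-axis waveform for x: 3 * gamma^2 * (1e-3 g_ref)^2 x'Qx * 1e-6
    b_scale = 3.0 * GAMMA**2 * (1e-3 * g_ref) ** 2 * 1e-6
    bQ = b_scale * Q

    # Slew between consecutive nodes, per axis (the shared shape carries the
    # worst-axis factor max|sqrt(3) d_a| = 1 for the default direction).
    slew_cap = limits.s_max * limits.node_spacing * 1e3 / g_ref  # in x units
    eq_rows = []
    if spec.null_m0:
        eq_rows.append(m_rows[0] / T)
    if spec.null_m1:
        eq_rows.append(m_rows[1] / T**2)
    if spec.null_m2:
        eq_rows.append(m_rows[2] / T**3)

    starts = [np.ones(n)]  # paper-style start: every node at G_max
    starts += _segment_pattern_starts(timing, limits, free, seg_nodes)

    Aeq = np.vstack(eq_rows) if eq_rows else np.zeros((0, n))
    Sn = S / T if spec.maxwell else None

    best_x, best_b, total_iter = None, -np.inf, 0
    for k, x0 in enumerate(starts):
        x, iters = _slp_maximize(
            bQ, Aeq, Sn, D, slew_cap, x0, maxiter=maxiter
        )
        total_iter += iters
        if x is None:
            continue
        if not _feasible(x, D, slew_cap, eq_rows, Sn):
            continue
        b_here = x @ bQ @ x
        if b_here > best_b:
            best_x, best_b = x, b_here

    status = "converged" if best_x is not None else "failed"
    x_best = best_x if best_x is not None else np.zeros(n)

    nodes_free = x_best * g_ref
    nodes_full = np.zeros(free.size)
    nodes_full[free] = nodes_free
    waveform = interpolate_to_dwell(nodes_full, timing, limits)
    b = bvalue(waveform)
    residuals = {
        "m0": moment(waveform, 0),
        "m1": moment(waveform, 1),
        "m2": moment(waveform, 2),
        "maxwell": concomitant_residual(waveform),
    }
    return OptimizationResult(
        nodes=nodes_full,
        node_times=node_times,
        waveform=waveform,
        b_achieved=b,
        constraint_residuals=residuals,
        solver_status=status,
        iterations=int(total_iter),
    )


def _slp_maximize(
    bQ: np.ndarray,
    Aeq: np.ndarray,
    Sn: np.ndarray | None,
    D: sparse.csr_matrix,
    slew_cap: float,
    x0: np.ndarray,
    maxiter: int = 400,
) -> tuple[np.ndarray | None, int]:
    """Maximize x'bQx by successive linear programming with a trust region.

    Box, slew and moment constraints are linear and enforced exactly in every
    LP; the Maxwell quadratic equality is linearized about the incumbent, so
    its violation after a step is second order in the step size and is driven
    to zero by the shrinking trust region plus a final null-space Newton
    polish.  An l1 exact-penalty merit function governs step acceptance.
    """
    n = x0.size
    b_typ = max(float(np.ones(n) @ bQ @ np.ones(n)), 1.0)
    mu = 50.0  # exact-penalty weight on the normalized Maxwell residual

    A_ub = sparse.vstack([D, -D]).toarray()

    def c_maxwell(x):
        return float(x @ Sn @ x) if Sn is not None else 0.0

    def violation(x):
        v = abs(c_maxwell(x))
        if Aeq.size:
            v += float(np.sum(np.abs(Aeq @ x)))
        v += float(np.sum(np.maximum(np.abs(D @ x) - slew_cap, 0.0)))
        return v

    def merit(x):
        return float(x @ bQ @ x) / b_typ - mu * violation(x)

    x = x0.copy()
    delta = 2.0  # wide open initially so the first LP can restore feasibility
    iters = 0
    for it in range(maxiter):
        iters += 1
        cgrad = -2.0 * (bQ @ x) / b_typ  # minimize => steepest b increase
        lb = np.maximum(-1.0 - x, -delta)
        ub = np.minimum(1.0 - x, delta)
        b_ub = np.concatenate([slew_cap - D @ x, slew_cap + D @ x])
        a_eq_rows, b_eq = [], []
        if Aeq.size:
            a_eq_rows.append(Aeq)
            b_eq.extend((-Aeq @ x).tolist())
        if Sn is not None:
            a_eq_rows.append((2.0 * (Sn @ x))[None, :])
            b_eq.append(-c_maxwell(x))
        res = optimize.linprog(
            cgrad,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=np.vstack(a_eq_rows) if a_eq_rows else None,
            b_eq=np.array(b_eq) if b_eq else None,
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if not res.success:
            delta *= 0.5
            if delta < 1e-9:
                break
            continue
        d = res.x
        x_new = np.clip(x + d, -1.0, 1.0)
        if merit(x_new) > merit(x) + 1e-14:
            x = x_new
            step = float(np.max(np.abs(d)))
            if step > 0.9 * delta:
                delta = min(2.0 * delta, 2.0)
        else:
            delta *= 0.5
        if delta < 1e-9:
            break

    # Null-space Newton polish: drive the Maxwell equality to machine level
    # with a minimal-norm correction that stays on the moment null-space.
    if Sn is not None:
        for _ in range(5):
            c = c_maxwell(x)
            if abs(c) < 1e-13:
                break
            rows = [2.0 * (Sn @ x)[None, :]]
            rhs = [-c]
            if Aeq.size:
                rows.append(Aeq)
                rhs.extend([0.0] * Aeq.shape[0])
            A = np.vstack(rows)
            delta_x = np.linalg.lstsq(A, np.array(rhs), rcond=None)[0]
            x = np.clip(x + delta_x, -1.0, 1.0)
    return x, iters


def _feasible(x, D, slew_cap, eq_rows, Sn, tol: float = 1e-6) -> bool:
    if np.max(np.abs(x)) > 1 + tol:
        return False
    if np.max(np.abs(D @ x)) > slew_cap * (1 + tol):
        return False
    for row in eq_rows:
        if abs(row @ x) > 1e-6:
            return False
    if Sn is not None and abs(x @ Sn @ x) > 1e-6:
        return False
    return True


def interpolate_to_dwell(
    nodes_full: np.ndarray,
    timing: PrepTiming,
    limits: HardwareLimits | None = None,
) -> GradientWaveform:
    """Resample the node amplitudes to the hardware dwell raster.

    Linear interpolation preserves the piecewise-linear model exactly, so
    moment nulls and the Maxwell residual carry over to the fine raster up
    to quadrature refinement.
    """
    limits = limits or HardwareLimits()
    dt = limits.dwell
    n_fine = int(np.floor(timing.duration / dt + 1e-9)) + 1
    t_fine = np.arange(n_fine) * dt
    seg_nodes = _node_layout(timing, limits)
    samples = np.zeros(n_fine)
    offset = 0
    for idx in seg_nodes:
        nt = idx * limits.node_spacing
        vals = nodes_full[offset : offset + idx.size]
        L = _interp_matrix(t_fine, nt)
        samples += L @ vals
        offset += idx.size
    return GradientWaveform(
        samples=samples,
        dt=dt,
        refocus_times=tuple(timing.refocus_centers),
        rf_windows=timing.rf_windows,
    )
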