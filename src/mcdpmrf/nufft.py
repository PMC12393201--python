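"""Multicoil non-uniform Fourier forward model in the temporal subspace.

The forward operator maps r singular-coefficient images to multicoil radial
k-space: for spoke ``j`` acquired at fingerprint timepoint ``t_j``, the
contrast image is the basis-weighted combination of the coefficient images,
multiplied by each coil sensitivity and evaluated at the spoke's k-space
locations with a direct (exact) non-uniform DFT.  The transform factorizes
separably per sample, so no gridding approximation is needed at the matrix
sizes this package targets.

Image pixel p is at position (p - matrix//2) in FOV/matrix units and k is
in cycles/FOV, so the phase is exp(-2*pi*i * k.(p - c) / matrix).  A 1/matrix
factor makes the fully sampled Cartesian analogue unitary.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SubspaceRadialOperator"]


class SubspaceRadialOperator:
    """Linear operator A: (r, n, n) coefficient images -> (coils, spokes, S).

    Parameters
    ----------
    traj : RadialTrajectory
    coil_maps : (n_coils, n, n) complex sensitivities
    basis : (n_timepoints, r) temporal subspace basis (columns orthonormal)
    """

    def __init__(self, traj, coil_maps, basis, chunk: int = 32):
        self.traj = traj
        self.coil_maps = np.asarray(coil_maps, dtype=complex)
        self.basis = np.asarray(basis, dtype=complex)
        self.n = self.coil_maps.shape[-1]
        if self.coil_maps.ndim != 3 or self.coil_maps.shape[-2] != self.n:
            raise ValueError("coil_maps must be (n_coils, n, n)")
        self.rank = self.basis.shape[1]
        self.chunk = chunk
        if np.max(traj.spoke_to_timepoint) >= self.basis.shape[0]:
            raise ValueError("spoke_to_timepoint exceeds basis length")
        pix = np.arange(self.n) - self.n // 2
        self._pix = pix
        # Per-spoke unit vectors.
        theta = np.deg2rad(traj.angles)
        self._ux = np.cos(theta)
        self._uy = np.sin(theta)

    # -- phase tables ------------------------------------------------------
    def _tables(self, spokes: np.ndarray):
        """exp(-2 pi i radii (u . p)/n), separably per axis: (J, S, n) each."""
        r = self.traj.radii  # (S,)
        kx = self._ux[spokes, None] * r[None, :]  # (J, S)
        ky = self._uy[spokes, None] * r[None, :]
        w = -2j * np.pi / self.n
        ex = np.exp(w * kx[:, :, None] * self._pix[None, None, :])
        ey = np.exp(w * ky[:, :, None] * self._pix[None, None, :])
        return ex, ey

    # -- forward / adjoint -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """A x: sample the subspace model along every spoke."""
        x = np.asarray(x, dtype=complex)
        if x.shape != (self.rank, self.n, self.n):
            raise ValueError(f"expected x of shape {(self.rank, self.n, self.n)}")
        n_coils = self.coil_maps.shape[0]
        out = np.zeros(
            (n_coils, self.traj.n_spokes, self.traj.samples_per_spoke),
            dtype=complex,
        )
        t_of = self.traj.spoke_to_timepoint
        for lo in range(0, self.traj.n_spokes, self.chunk):
            spokes = np.arange(lo, min(lo + self.chunk, self.traj.n_spokes))
            # Contrast image of each spoke in the chunk: (J, n, n).
            phi = self.basis[t_of[spokes]]  # (J, r)
            imgs = np.tensordot(phi, x, axes=(1, 0))
            cimgs = self.coil_maps[:, None] * imgs[None]  # (c, J, n, n)
            ex, ey = self._tables(spokes)
            out[:, spokes] = np.einsum(
                "jsx,jsy,cjxy->cjs", ex, ey, cimgs, optimize=True
            ) / self.n
        return out

    def adjoint(self, y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        """A^H y (optionally with per-sample weights, e.g. a DCF)."""
        y = np.asarray(y, dtype=complex)
        if weights is not None:
            y = y * weights[None]
        x = np.zeros((self.rank, self.n, self.n), dtype=complex)
        t_of = self.traj.spoke_to_timepoint
        for lo in range(0, self.traj.n_spokes, self.chunk):
            spokes = np.arange(lo, min(lo + self.chunk, self.traj.n_spokes))
            ex, ey = self._tables(spokes)
            # Per-spoke coil-combined image: (J, n, n).
            imgs = np.einsum(
                "cjs,jsx,jsy,cxy->jxy",
                y[:, spokes],
                np.conj(ex),
                np.conj(ey),
                np.conj(self.coil_maps),
                optimize=True,
            ) / self.n
            phi = self.basis[t_of[spokes]]  # (J, r)
            x += np.tensordot(np.conj(phi).T, imgs, axes=(1, 0))
        return x

    def normal(self, x: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        return self.adjoint(self.forward(x), weights=weights)
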