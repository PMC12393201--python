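"""Tiny-golden-angle radial k-space trajectory."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RadialTrajectory", "tiny_golden_angles", "make_trajectory"]

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def tiny_golden_angles(n_spokes: int, order: int = 7) -> np.ndarray:
    """Spoke azimuths (degrees, in [0, 180)) for the N-th tiny golden angle.

    The increment is ``psi_N = 180 / (phi + N - 1)`` with ``phi`` the golden
    ratio; order 1 recovers the classic golden angle 111.2461 deg and order
    7 the 23.6281 deg increment used for liver MRF.
    """
    if order < 1:
        raise ValueError("tiny golden angle order must be >= 1")
    psi = 180.0 / (_PHI + order - 1)
    return (np.arange(n_spokes) * psi) % 180.0


@dataclass
class RadialTrajectory:
    """Radial sampling pattern: one full spoke through k-space center per shot.

    ``k_coords`` has shape (n_spokes, samples_per_spoke, 2) in cycles/FOV;
    radii span [-matrix/2, matrix/2) with 2x readout oversampling by
    default.  ``spoke_to_timepoint`` maps each spoke to the fingerprint
    timepoint (contrast frame) it samples.
    """

    matrix: int
    angles: np.ndarray  # degrees
    samples_per_spoke: int
    spoke_to_timepoint: np.ndarray

    k_coords: np.ndarray = field(init=False)
    radii: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.spoke_to_timepoint = np.asarray(self.spoke_to_timepoint, dtype=int)
        if self.spoke_to_timepoint.size != self.angles.size:
            raise ValueError("spoke_to_timepoint must have one entry per spoke")
        dk = self.matrix / self.samples_per_spoke
        self.radii = (
            np.arange(self.samples_per_spoke) - self.samples_per_spoke // 2
        ) * dk
        theta = np.deg2rad(self.angles)
        u = np.stack([np.cos(theta), np.sin(theta)], axis=-1)  # (spokes, 2)
        self.k_coords = self.radii[None, :, None] * u[:, None, :]

    @property
    def n_spokes(self) -> int:
        return self.angles.size

    @property
    def k_max(self) -> float:
        return float(np.max(np.abs(self.radii)))

    @property
    def radial_step(self) -> float:
        return self.matrix / self.samples_per_spoke


def make_trajectory(
    matrix: int,
    n_spokes: int = 480,
    oversampling: int = 2,
    order: int = 7,
    spoke_to_timepoint: np.ndarray | None = None,
) -> RadialTrajectory:
    """Standard acquisition pattern: one tiny-golden-angle spoke per shot."""
    if spoke_to_timepoint is None:
        spoke_to_timepoint = np.arange(n_spokes)
    return RadialTrajectory(
        matrix=matrix,
        angles=tiny_golden_angles(n_spokes, order=order),
        samples_per_spoke=oversampling * matrix,
        spoke_to_timepoint=spoke_to_timepoint,
    )
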