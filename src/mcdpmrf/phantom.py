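"""Digital phantoms and synthetic coil sensitivities.

These phantoms replace scanner data: piecewise-constant label images with
known (T1, T2, ADC, PD) per label, smooth synthetic coil maps, and an
optional vessel velocity map for flow-corruption experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epg import TissueParams

__all__ = ["DigitalPhantom", "FlowModel", "make_phantom", "make_coil_maps"]


@dataclass
class DigitalPhantom:
    label_image: np.ndarray  # (n, n) int
    tissues: dict[int, TissueParams]
    coil_maps: np.ndarray  # (n_coils, n, n) complex
    pixel_size: float = 1.0  # mm

    def __post_init__(self) -> None:
        labels = set(np.unique(self.label_image)) - {0}
        missing = labels - set(self.tissues)
        if missing:
            raise ValueError(f"labels without tissue entries: {sorted(missing)}")

    @property
    def matrix(self) -> int:
        return self.label_image.shape[0]

    @property
    def mask(self) -> np.ndarray:
        return self.label_image > 0

    def truth_maps(self) -> dict[str, np.ndarray]:
        """Voxelwise ground-truth T1/T2/ADC/PD maps."""
        out = {k: np.zeros(self.label_image.shape) for k in ("t1", "t2", "adc", "pd")}
        for lab, tp in self.tissues.items():
            m = self.label_image == lab
            out["t1"][m] = tp.t1
            out["t2"][m] = tp.t2
            out["adc"][m] = tp.adc
            out["pd"][m] = tp.pd
        return out


@dataclass
class FlowModel:
    """Per-voxel velocity (m/s) along the diffusion-encoding direction."""

    velocity_image: np.ndarray
    enabled: bool = True


def _disc(n: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[:n, :n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def make_phantom(
    kind: str,
    matrix: int = 64,
    seed: int = 0,
    n_coils: int = 1,
    tissues: dict[int, TissueParams] | None = None,
) -> DigitalPhantom:
    """Create a digital phantom.

    Kinds
    -----
    ``tubes_t1mes``
        Nine circular tubes spanning the clinical T1/T2 range (fixed ADC),
        emulating a standardized T1/T2 calibration phantom.
    ``tubes_pvp``
        Nine tubes sharing T1 = 700 ms and T2 = 40 ms with an ADC ladder
        from 0.3 to 2.0 x 1e-3 mm^2/s, emulating polymer-solution diffusion
        phantoms doped to physiological relaxation times.
    ``liver``
        An elliptical "liver" (T1 800 ms, T2 40 ms, ADC 1.2) with embedded
        vessel discs (blood-like T1/T2, high ADC).
    ``sectors``
        An ellipse split into three large angular sectors with widely
        separated tissues — the grid-tissue layout used for end-to-end
        pipeline validation, where every region is large compared with the
        reconstruction point-spread function.
    """
    if matrix < 32:
        raise ValueError("matrix must be >= 32")
    rng = np.random.default_rng(seed)
    n = matrix
    label = np.zeros((n, n), dtype=int)

    if kind == "tubes_t1mes":
        t1s = [250, 400, 600, 800, 1000, 1200, 1500, 2000, 2500]
        t2s = [30, 40, 50, 40, 60, 80, 100, 150, 250]
        default_tissues = {
            i + 1: TissueParams(t1=t1s[i], t2=t2s[i], adc=1.0) for i in range(9)
        }
    elif kind == "tubes_pvp":
        adcs = np.linspace(0.3, 2.0, 9)
        default_tissues = {
            i + 1: TissueParams(t1=700.0, t2=40.0, adc=float(adcs[i]))
            for i in range(9)
        }
    elif kind == "liver":
        default_tissues = {
            1: TissueParams(t1=800.0, t2=40.0, adc=1.2),  # parenchyma
            2: TissueParams(t1=1800.0, t2=150.0, adc=3.0),  # vessels (blood-like)
            3: TissueParams(t1=1200.0, t2=50.0, adc=2.0),  # lesion-like insert
        }
    elif kind == "sectors":
        default_tissues = {
            1: TissueParams(t1=400.0, t2=30.0, adc=0.5),
            2: TissueParams(t1=1000.0, t2=60.0, adc=1.5),
            3: TissueParams(t1=2200.0, t2=150.0, adc=3.0),
        }
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")
    if tissues is not None:
        default_tissues = tissues

    if kind == "sectors":
        yy, xx = np.mgrid[:n, :n]
        ellipse = ((yy - n / 2) / (0.40 * n)) ** 2 + (
            (xx - n / 2) / (0.44 * n)
        ) ** 2 <= 1.0
        ang = np.arctan2(yy - n / 2, xx - n / 2)
        label[ellipse & (ang < -np.pi / 3)] = 1
        label[ellipse & (ang >= -np.pi / 3) & (ang < np.pi / 3)] = 2
        label[ellipse & (ang >= np.pi / 3)] = 3
    elif kind in ("tubes_t1mes", "tubes_pvp"):
        radius = n / 10.0
        centers = [
            (n / 2 + 0.3 * n * np.cos(a), n / 2 + 0.3 * n * np.sin(a))
            for a in np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ] + [(n / 2, n / 2)]
        for i, (cy, cx) in enumerate(centers):
            label[_disc(n, cy, cx, radius)] = i + 1
    else:  # liver
        yy, xx = np.mgrid[:n, :n]
        ellipse = ((yy - n / 2) / (0.38 * n)) ** 2 + (
            (xx - n / 2) / (0.42 * n)
        ) ** 2 <= 1.0
        label[ellipse] = 1
        vessel_pos = [(0.42, 0.40), (0.58, 0.62), (0.40, 0.62)]
        for fy, fx in vessel_pos:
            label[_disc(n, fy * n, fx * n, n / 22.0)] = 2
        label[_disc(n, 0.62 * n, 0.38 * n, n / 16.0)] = 3

    coil_maps = make_coil_maps(n, n_coils, seed=seed)
    return DigitalPhantom(label_image=label, tissues=default_tissues, coil_maps=coil_maps)


def make_coil_maps(matrix: int, n_coils: int, seed: int = 0) -> np.ndarray:
    """Smooth complex Gaussian-profile coil sensitivities.

    ``n_coils = 1`` returns a uniform unit map.  Profiles are centered on
    points around the FOV with a gentle linear phase, deterministic per
    seed.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    n = matrix
    if n_coils == 1:
        return np.ones((1, n, n), dtype=complex)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[:n, :n] / n
    maps = np.zeros((n_coils, n, n), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.1)
        cy, cx = 0.5 + 0.6 * np.sin(ang), 0.5 + 0.6 * np.cos(ang)
        sigma = 0.55 + 0.1 * rng.random()
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        phase = 2 * np.pi * (0.1 * rng.random() * (xx - 0.5) + 0.1 * rng.random() * (yy - 0.5))
        maps[c] = mag * np.exp(1j * phase)
    # Keep the sum-of-squares comfortably away from zero over the FOV.
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= max(np.max(sos), 1e-12)
    return maps
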