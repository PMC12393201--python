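"""Parameter-map container and NIfTI serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ParameterMaps", "save_maps", "load_maps"]

_UNITS = {"t1": "ms", "t2": "ms", "adc": "1e-3 mm^2/s", "pd": "a.u.", "corr": ""}


@dataclass
class ParameterMaps:
    """Voxelwise quantitative maps produced by dictionary matching."""

    t1: np.ndarray
    t2: np.ndarray
    adc: np.ndarray
    pd: np.ndarray
    corr: np.ndarray
    pixel_size: float = 1.0  # mm

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "t1": self.t1,
            "t2": self.t2,
            "adc": self.adc,
            "pd": self.pd,
            "corr": self.corr,
        }

    @classmethod
    def from_match(
        cls, params: np.ndarray, pd: np.ndarray, corr: np.ndarray, shape, pixel_size=1.0
    ) -> "ParameterMaps":
        return cls(
            t1=params[:, 0].reshape(shape),
            t2=params[:, 1].reshape(shape),
            adc=params[:, 2].reshape(shape),
            pd=np.asarray(pd).reshape(shape),
            corr=np.asarray(corr).reshape(shape),
            pixel_size=pixel_size,
        )


def save_maps(maps: ParameterMaps, out_dir: str | Path, prefix: str = "mrf") -> list[Path]:
    """One NIfTI per parameter; the header description names the quantity."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    affine = np.diag([maps.pixel_size, maps.pixel_size, 1.0, 1.0])
    for name, img in maps.as_dict().items():
        ni = nib.Nifti1Image(np.asarray(img, dtype=np.float64), affine)
        desc = f"{name} [{_UNITS[name]}]".encode()[:79]
        ni.header["descrip"] = desc
        path = out_dir / f"{prefix}_{name}.nii"
        nib.save(ni, path)
        written.append(path)
    return written


def load_maps(out_dir: str | Path, prefix: str = "mrf") -> ParameterMaps:
    out_dir = Path(out_dir)
    arrays = {}
    for name in _UNITS:
        img = nib.load(out_dir / f"{prefix}_{name}.nii")
        arrays[name] = np.asarray(img.dataobj, dtype=float)
        pix = float(img.affine[0, 0])
    return ParameterMaps(pixel_size=pix, **arrays)
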