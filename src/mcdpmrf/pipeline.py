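"""High-level pipeline: k-space -> singular images -> parameter maps, and
the end-to-end demo run used by the command-line front end."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acquire import KSpaceData, save_kspace, simulate_acquisition
from .dcf import voronoi_dcf
from .dictionary import Dictionary, build_dictionary, compress, match, save_dictionary
from .diffprep import ConstraintSpec, build_timing, optimize_prep
from .gradwave import HardwareLimits, scale_to_b, write_waveform
from .maps_io import ParameterMaps, save_maps
from .phantom import make_phantom
from .recon import ReconConfig, lowrank_inversion
from .schedule import SequenceSchedule, load_schedule, save_schedule
from .stats import ROISet, bland_altman, roi_stats
from .trajectory import make_trajectory

__all__ = ["RunConfig", "reconstruct_maps", "run_pipeline"]


def reconstruct_maps(
    kspace: KSpaceData,
    dictionary: Dictionary,
    coil_maps: np.ndarray,
    cfg: ReconConfig | None = None,
    pixel_size: float = 1.0,
) -> ParameterMaps:
    """Reconstruct singular images and match them against the dictionary."""
    cfg = cfg or ReconConfig()
    if dictionary.basis is None:
        compress(dictionary)
    dcf = voronoi_dcf(kspace.traj)
    x = lowrank_inversion(
        kspace.data, kspace.traj, coil_maps, dictionary.basis, cfg, dcf=dcf
    )
    rank = dictionary.basis.shape[1]
    params, pd, corr = match(x.reshape(rank, -1).T, dictionary)
    n = coil_maps.shape[-1]
    return ParameterMaps.from_match(params, pd, corr, (n, n), pixel_size=pixel_size)


@dataclass
class RunConfig:
    """Configuration of an end-to-end demo run."""

    out_dir: Path
    schedule_path: Path | None = None
    phantom_kind: str = "liver"
    matrix: int = 64
    n_coils: int = 1
    grids: dict | None = None  # {"t1": [...], "t2": [...], "adc": [...]}
    noise_sigma: float = 0.0
    seed: int = 0
    limits: HardwareLimits = field(default_factory=HardwareLimits)
    recon: ReconConfig = field(default_factory=ReconConfig)
    optimize_prep_waveform: bool = False


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the demo pipeline and write all artifacts plus a manifest.

    Stages: (optionally) optimize the diffusion preparation, build and
    compress the dictionary, simulate the phantom acquisition, reconstruct,
    match, and evaluate ROI statistics against the phantom truth.  Every
    stage is deterministic for a fixed config, so reruns are bit-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed}
    t_start = time.time()

    if config.schedule_path is not None:
        path = Path(config.schedule_path)
        if not path.exists():
            raise FileNotFoundError(f"schedule file not found: {path}")
        schedule = load_schedule(path)
    else:
        schedule = SequenceSchedule()
    save_schedule(schedule, out / "schedule.yaml")
    manifest["stages"]["schedule"] = {"file": "schedule.yaml"}

    if config.optimize_prep_waveform:
        result = optimize_prep(build_timing(), config.limits, ConstraintSpec())
        if not result.converged:
            raise RuntimeError("diffusion-prep optimization failed to converge")
        write_waveform(result.waveform, out / "prep.wav.txt")
        manifest["stages"]["optimize-dp"] = {
            "b_achieved": result.b_achieved,
            "file": "prep.wav.txt",
        }

    grids = config.grids or {
        "t1": [300.0, 800.0, 1200.0, 1800.0, 2400.0],
        "t2": [20.0, 40.0, 80.0, 150.0, 250.0],
        "adc": [0.5, 1.2, 2.0, 3.0],
    }
    dictionary = compress(
        build_dictionary(
            schedule,
            np.asarray(grids["t1"]),
            np.asarray(grids["t2"]),
            np.asarray(grids["adc"]),
        )
    )
    save_dictionary(dictionary, out / "dict.h5")
    manifest["stages"]["build-dict"] = {
        "entries": dictionary.n_entries,
        "rank": dictionary.rank,
        "file": "dict.h5",
    }

    phantom = make_phantom(
        config.phantom_kind, config.matrix, seed=config.seed, n_coils=config.n_coils
    )
    traj = make_trajectory(config.matrix, n_spokes=schedule.n_readouts)
    kspace = simulate_acquisition(
        phantom, schedule, traj, noise_sigma=config.noise_sigma, seed=config.seed
    )
    save_kspace(kspace, out / "kspace.h5")
    manifest["stages"]["simulate"] = {
        "file": "kspace.h5",
        "noise_sigma": config.noise_sigma,
    }

    maps = reconstruct_maps(kspace, dictionary, phantom.coil_maps, config.recon)
    map_files = save_maps(maps, out / "maps")
    manifest["stages"]["recon+match"] = {"files": [f.name for f in map_files]}

    # ROI evaluation against the phantom's own truth maps.
    truth = phantom.truth_maps()
    labels = sorted(set(np.unique(phantom.label_image)) - {0})
    centers = []
    for lab in labels:
        ys, xs = np.nonzero(phantom.label_image == lab)
        centers.append((float(ys.mean()), float(xs.mean())))
    rois = ROISet(centers=tuple(centers), diameter=5.0, pixel_size=maps.pixel_size)
    report = {}
    for name in ("t1", "t2", "adc"):
        est_mean, est_sd = roi_stats(maps.as_dict()[name], rois)
        true_mean, _ = roi_stats(truth[name], rois)
        ba = bland_altman(est_mean, true_mean) if len(labels) >= 3 else None
        report[name] = {
            "roi_mean": est_mean.tolist(),
            "roi_sd": est_sd.tolist(),
            "roi_truth": true_mean.tolist(),
            "bias": None if ba is None else ba.bias,
            "loa": None if ba is None else [ba.loa_low, ba.loa_high],
        }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    manifest["stages"]["eval"] = {"file": "report.json"}

    manifest["elapsed_s"] = time.time() - t_start
    manifest["hashes"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
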