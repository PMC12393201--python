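"""Fingerprint dictionary: construction, SVD compression and matching."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .schedule import SequenceSchedule, simulate_fingerprints

__all__ = [
    "Dictionary",
    "colon_range",
    "in_vivo_grids",
    "t1mes_grids",
    "demo_grids",
    "build_dictionary",
    "compress",
    "match",
    "save_dictionary",
    "load_dictionary",
]


def colon_range(start: float, step: float, stop: float) -> np.ndarray:
    """MATLAB-style colon expansion ``start:step:stop`` (stop included only
    when hit within floating tolerance)."""
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def _merge(*pieces: np.ndarray) -> np.ndarray:
    vals = np.concatenate(pieces)
    return np.unique(np.round(vals, 9))


def in_vivo_grids() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """T1/T2/ADC grids used for liver and diffusion-phantom dictionaries.

    T1 [100:100:500, 500:40:1000, 1000:200:3000] ms,
    T2 [6:3:60, 60:20:100, 100:50:300] ms,
    ADC [0.1:0.1:2.5, 3.0:1.0:5.0] x 1e-3 mm^2/s.
    """
    t1 = _merge(
        colon_range(100, 100, 500),
        colon_range(500, 40, 1000),
        colon_range(1000, 200, 3000),
    )
    t2 = _merge(
        colon_range(6, 3, 60), colon_range(60, 20, 100), colon_range(100, 50, 300)
    )
    adc = _merge(colon_range(0.1, 0.1, 2.5), colon_range(3.0, 1.0, 5.0))
    return t1, t2, adc


def t1mes_grids() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grids for the T1/T2 calibration-phantom dictionary."""
    t1 = _merge(
        colon_range(50, 50, 900),
        colon_range(900, 25, 1400),
        colon_range(1400, 200, 3000),
    )
    t2 = _merge(
        colon_range(5, 5, 30),
        colon_range(30, 2, 80),
        colon_range(80, 20, 200),
        colon_range(200, 100, 600),
    )
    adc = _merge(colon_range(0.0, 0.05, 2.5), colon_range(2.5, 0.5, 5.0))
    return t1, t2, adc


def demo_grids() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coarse desk-scale grids covering the physiological range.

    Used for fast demos and end-to-end pipeline validation, where the grid
    spacing is deliberately wide compared with the reconstruction error so
    nearest-atom matching is unambiguous.
    """
    t1 = np.array([100.0, 400.0, 700.0, 1000.0, 1600.0, 2200.0, 2800.0])
    t2 = np.array([15.0, 30.0, 60.0, 100.0, 150.0, 250.0])
    adc = np.array([0.1, 0.5, 1.5, 3.0, 4.5])
    return t1, t2, adc


@dataclass
class Dictionary:
    """Simulated fingerprint atoms on a T1 x T2 x ADC grid.

    ``atoms`` holds unit-L2-norm rows (entries x timepoints); ``norms`` the
    pre-normalization L2 norms; ``params`` the (T1, T2, ADC) of each row.
    After :func:`compress`, ``basis`` holds the dominant right singular
    vectors (timepoints x rank).
    """

    grid_t1: np.ndarray
    grid_t2: np.ndarray
    grid_adc: np.ndarray
    params: np.ndarray  # (entries, 3)
    atoms: np.ndarray  # (entries, timepoints), unit rows
    norms: np.ndarray  # (entries,)
    basis: np.ndarray | None = None  # (timepoints, rank)
    rank: int | None = None
    energy_fraction: float | None = None
    singular_values: np.ndarray | None = None

    @property
    def n_entries(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.atoms.shape[1]

    _catoms_cache: np.ndarray | None = None
    _cnorms_cache: np.ndarray | None = None

    @property
    def compressed_atoms(self) -> np.ndarray:
        """Projected atoms, renormalized to unit norm in the subspace."""
        if self.basis is None:
            raise ValueError("dictionary is not compressed; call compress()")
        if self._catoms_cache is None or self._catoms_cache.shape[1] != self.rank:
            c = self.atoms @ np.conj(self.basis)
            self._cnorms_cache = np.linalg.norm(c, axis=1)
            self._catoms_cache = c / self._cnorms_cache[:, None]
        return self._catoms_cache

    @property
    def compressed_norms(self) -> np.ndarray:
        """Subspace norm of each projected unit atom (<= 1)."""
        _ = self.compressed_atoms
        return self._cnorms_cache


def build_dictionary(
    schedule: SequenceSchedule,
    grid_t1: np.ndarray,
    grid_t2: np.ndarray,
    grid_adc: np.ndarray,
    k_max: int = 20,
    chunk: int = 4096,
) -> Dictionary:
    """Simulate every (T1, T2, ADC) tuple and store L2-normalized atoms.

    Tuples with T2 > T1 are unphysical and excluded.  Grids are sorted and
    deduplicated.
    """
    grid_t1 = np.unique(np.asarray(grid_t1, dtype=float))
    grid_t2 = np.unique(np.asarray(grid_t2, dtype=float))
    grid_adc = np.unique(np.asarray(grid_adc, dtype=float))
    if min(grid_t1.size, grid_t2.size, grid_adc.size) == 0:
        raise ValueError("empty dictionary grid")
    if grid_t1.min() <= 0 or grid_t2.min() <= 0 or grid_adc.min() < 0:
        raise ValueError("grid values must be positive (ADC non-negative)")

    tt1, tt2, aa = np.meshgrid(grid_t1, grid_t2, grid_adc, indexing="ij")
    params = np.column_stack([tt1.ravel(), tt2.ravel(), aa.ravel()])
    params = params[params[:, 1] <= params[:, 0]]  # drop T2 > T1

    n = params.shape[0]
    atoms = np.empty((n, schedule.n_readouts), dtype=complex)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        atoms[lo:hi] = simulate_fingerprints(
            schedule,
            params[lo:hi, 0],
            params[lo:hi, 1],
            params[lo:hi, 2],
            k_max=k_max,
        )
    norms = np.linalg.norm(atoms, axis=1)
    ok = norms > 0
    atoms[ok] /= norms[ok, None]
    return Dictionary(
        grid_t1=grid_t1,
        grid_t2=grid_t2,
        grid_adc=grid_adc,
        params=params,
        atoms=atoms,
        norms=norms,
    )


def compress(dictionary: Dictionary, energy_fraction: float = 0.96) -> Dictionary:
    """Attach the temporal SVD basis capturing the requested energy.

    The rank is the smallest r whose cumulative singular values reach
    ``energy_fraction`` of their total sum — the energy-ratio convention of
    the MRF-SVD compression literature.  Computed from the Gram matrix of
    the atom matrix, which is exact and cheap for long-and-thin shapes.
    """
    a = dictionary.atoms
    gram = np.conj(a.T) @ a  # (timepoints, timepoints)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)  # sigma^2
    evals[evals < evals[0] * 1e-12] = 0.0  # numerical-noise floor of the Gram
    evecs = evecs[:, order]
    sv = np.sqrt(evals)
    cum = np.cumsum(sv) / np.sum(sv)
    rank = int(np.searchsorted(cum, energy_fraction - 1e-12) + 1)
    # Atom time series (as columns) span the conjugate of the Gram
    # eigenvectors: store the conjugate so signals expand exactly as
    # y = basis @ coeff with coeff = basis^H y.
    dictionary.basis = np.conj(evecs[:, :rank])
    dictionary.rank = rank
    dictionary.energy_fraction = float(energy_fraction)
    dictionary.singular_values = np.sqrt(evals)
    return dictionary


def match(signals: np.ndarray, dictionary: Dictionary, chunk: int = 512):
    """Dictionary matching by maximum normalized inner product.

    ``signals`` is (n_voxels, d) with d either the full number of
    timepoints or the compressed rank.  Returns ``(params, pd, corr)``:
    per-voxel best (T1, T2, ADC), complex proton-density scale magnitude,
    and the match correlation.  Ties break toward the lowest atom index.
    """
    signals = np.atleast_2d(np.asarray(signals))
    scale_norms = dictionary.norms
    if signals.shape[1] == dictionary.n_timepoints:
        atoms = dictionary.atoms
    elif dictionary.rank is not None and signals.shape[1] == dictionary.rank:
        atoms = dictionary.compressed_atoms
        scale_norms = dictionary.norms * dictionary.compressed_norms
    else:
        raise ValueError(
            f"signal dimension {signals.shape[1]} matches neither the "
            f"{dictionary.n_timepoints} timepoints nor the compressed rank"
        )

    n_vox = signals.shape[0]
    best_idx = np.zeros(n_vox, dtype=int)
    best_ip = np.zeros(n_vox, dtype=complex)
    sig_norm = np.linalg.norm(signals, axis=1)
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        ip = signals[lo:hi] @ np.conj(atoms.T)  # (chunk, entries)
        idx = np.argmax(np.abs(ip), axis=1)
        best_idx[lo:hi] = idx
        best_ip[lo:hi] = ip[np.arange(hi - lo), idx]

    params = dictionary.params[best_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sig_norm > 0, np.abs(best_ip) / sig_norm, 0.0)
    pd = np.abs(best_ip) / scale_norms[best_idx]
    return params, pd, corr


def save_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    """HDF5 container with a JSON attribute carrying the grid metadata."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("atoms", data=dictionary.atoms)
        f.create_dataset("norms", data=dictionary.norms)
        f.create_dataset("params", data=dictionary.params)
        if dictionary.basis is not None:
            f.create_dataset("basis", data=dictionary.basis)
            f.create_dataset("singular_values", data=dictionary.singular_values)
        meta = {
            "grid_t1": dictionary.grid_t1.tolist(),
            "grid_t2": dictionary.grid_t2.tolist(),
            "grid_adc": dictionary.grid_adc.tolist(),
            "rank": dictionary.rank,
            "energy_fraction": dictionary.energy_fraction,
        }
        f.attrs["meta"] = json.dumps(meta)


def load_dictionary(path: str | Path) -> Dictionary:
    with h5py.File(Path(path), "r") as f:
        meta = json.loads(f.attrs["meta"])
        d = Dictionary(
            grid_t1=np.asarray(meta["grid_t1"]),
            grid_t2=np.asarray(meta["grid_t2"]),
            grid_adc=np.asarray(meta["grid_adc"]),
            params=f["params"][...],
            atoms=f["atoms"][...],
            norms=f["norms"][...],
            basis=f["basis"][...] if "basis" in f else None,
            rank=meta["rank"],
            energy_fraction=meta["energy_fraction"],
            singular_values=(
                f["singular_values"][...] if "singular_values" in f else None
            ),
        )
    return d
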