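"""Voronoi density-compensation weights for radial sampling."""

from __future__ import annotations

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

__all__ = ["voronoi_dcf"]


def voronoi_dcf(traj) -> np.ndarray:
    """Per-sample density-compensation weights from Voronoi cell areas.

    Duplicate sample positions (every spoke crosses k = 0) share their
    cell's area equally.  Open outer cells are clipped at the sampling
    circle of radius ``k_max`` plus half a radial step.  Returns weights
    with the same (n_spokes, samples_per_spoke) shape as the trajectory.
    """
    pts = traj.k_coords.reshape(-1, 2)
    uniq, inverse, counts = np.unique(
        np.round(pts, 9), axis=0, return_inverse=True, return_counts=True
    )
    if uniq.shape[0] < 4:
        raise ValueError("need at least 4 unique k-space points for Voronoi DCF")

    radius = traj.k_max + traj.radial_step / 2
    circle = Point(0.0, 0.0).buffer(radius, quad_segs=64)
    vor = Voronoi(uniq)

    # Bounding box far outside the sampling circle to close open regions.
    bound = 4.0 * radius
    vert_r = np.linalg.norm(vor.vertices, axis=1) if len(vor.vertices) else np.array([])
    neighbours: dict[int, list[int]] = {}
    for a, b in vor.ridge_points:
        neighbours.setdefault(int(a), []).append(int(b))
        neighbours.setdefault(int(b), []).append(int(a))
    areas = np.zeros(uniq.shape[0])
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if -1 in region or len(region) == 0:
            poly = _closed_cell(vor, i, neighbours.get(i, []), bound)
        elif np.all(vert_r[region] <= radius):
            # Bounded cell fully inside the sampling circle: shoelace area.
            v = vor.vertices[region]
            areas[i] = 0.5 * abs(
                np.dot(v[:, 0], np.roll(v[:, 1], -1))
                - np.dot(v[:, 1], np.roll(v[:, 0], -1))
            )
            continue
        else:
            poly = Polygon(vor.vertices[region])
        if poly is None or poly.is_empty:
            continue
        areas[i] = poly.intersection(circle).area

    weights = areas[inverse] / counts[inverse]
    return weights.reshape(traj.k_coords.shape[:2])


def _closed_cell(
    vor: Voronoi, i: int, neighbour_ids: list[int], bound: float
) -> Polygon | None:
    """Clip an unbounded Voronoi cell against a large square box.

    Reconstructs the cell as the intersection of half-planes bisecting the
    point and each of its Voronoi neighbours — robust and simple at the
    small boundary-cell counts encountered here.
    """
    from shapely.geometry import box

    p = vor.points[i]
    cell = box(-bound, -bound, bound, bound)
    for j in neighbour_ids:
        q = vor.points[j]
        mid = 0.5 * (p + q)
        n = q - p
        nn = np.linalg.norm(n)
        if nn == 0:
            continue
        n = n / nn
        # Half-plane {x : (x - mid) . n <= 0} as a large clipped polygon.
        t = np.array([-n[1], n[0]])
        far = 8 * bound
        half = Polygon(
            [
                mid + t * far,
                mid - t * far,
                mid - t * far - n * far,
                mid + t * far - n * far,
            ]
        )
        cell = cell.intersection(half)
        if cell.is_empty:
            return None
    return cell
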