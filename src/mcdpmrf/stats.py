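"""Quantitative evaluation statistics for parameter maps.

ROI means, method-comparison regression with an F-test of slope = 1,
Bland-Altman limits of agreement, coefficient of variation and the
two-way mixed-effects absolute-agreement intraclass correlation for
multiple measurements, ICC(A,k) in the McGraw-Wong naming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROISet",
    "AgreementReport",
    "roi_stats",
    "correlation_with_slope_test",
    "bland_altman",
    "repeatability",
]


@dataclass(frozen=True)
class ROISet:
    """Circular regions of interest on a map.

    ``centers`` are (y, x) pixel coordinates; ``diameter`` in mm converts
    to pixels through ``pixel_size``.
    """

    centers: tuple[tuple[float, float], ...]
    diameter: float  # mm
    pixel_size: float = 1.0  # mm
    labels: tuple[str, ...] | None = None

    def membership(self, shape: tuple[int, int]) -> list[np.ndarray]:
        radius_px = (self.diameter / self.pixel_size) / 2.0
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        out = []
        for cy, cx in self.centers:
            out.append((yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2)
        return out


def roi_stats(map_image: np.ndarray, rois: ROISet):
    """Per-ROI mean and sample SD. Raises on empty ROIs."""
    means, sds = [], []
    for m in rois.membership(map_image.shape):
        vals = map_image[m]
        if vals.size == 0:
            raise ValueError("empty ROI")
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0)
    return np.array(means), np.array(sds)


def correlation_with_slope_test(a: np.ndarray, b: np.ndarray):
    """OLS best fit of a on b with r^2 and an F-test of slope == 1.

    Returns (slope, intercept, r2, p_slope_ne_1).  The F statistic is the
    squared t statistic of (slope - 1) / SE(slope) on n - 2 dof.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length inputs of at least 3 points")
    res = sps.linregress(b, a)
    if res.stderr > 0:
        f_stat = ((res.slope - 1.0) / res.stderr) ** 2
    else:
        f_stat = 0.0 if np.isclose(res.slope, 1.0) else np.inf
    p = float(sps.f.sf(f_stat, 1, a.size - 2))
    return float(res.slope), float(res.intercept), float(res.rvalue**2), p


@dataclass(frozen=True)
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    slope_p: float  # trend of difference vs mean (slope != 0)
    r2: float

    def __post_init__(self) -> None:
        assert self.loa_low <= self.bias <= self.loa_high


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementReport:
    """Bland-Altman agreement: bias, 95% limits (bias +/- 1.96 SD), and a
    test of a linear trend of the differences against the pairwise means."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must have the same length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    mean_pair = 0.5 * (a + b)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.allclose(d, d[0]) or np.allclose(mean_pair, mean_pair[0]):
        slope_p, r2 = 1.0, 0.0
    else:
        res = sps.linregress(mean_pair, d)
        t2 = (res.slope / res.stderr) ** 2 if res.stderr > 0 else np.inf
        slope_p = float(sps.f.sf(t2, 1, d.size - 2))
        r2 = float(res.rvalue**2)
    return AgreementReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        slope_p=slope_p,
        r2=r2,
    )


def repeatability(measurements: np.ndarray) -> tuple[float, float]:
    """Coefficient of variation (%) and ICC(A,k) of a subjects x repeats table.

    CV is the subject-mean of (SD across repeats / mean across repeats) x 100.
    ICC is the two-way mixed-effects, absolute-agreement, multiple-
    measurement form::

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    with MSR/MSC/MSE the rows (subjects), columns (repeats) and error mean
    squares of the two-way ANOVA and n the number of subjects.  If every
    cell is identical the data are perfectly repeatable and ICC is 1 by
    convention.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) x (repeats >= 2) matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not supported")
    n, k = m.shape

    with np.errstate(invalid="ignore", divide="ignore"):
        cv = float(
            np.mean(np.std(m, axis=1, ddof=1) / np.mean(m, axis=1)) * 100.0
        )

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if np.isclose(denom, 0.0):
        icc = 1.0 if np.allclose(m, m.flat[0]) else 0.0
    else:
        icc = float((msr - mse) / denom)
    return cv, icc
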