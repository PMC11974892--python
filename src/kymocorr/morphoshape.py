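"""Cell-shape morphometrics and PCA of the metric table.

Two dimensionless descriptors separate sheet-like (lamellipodial) from
spiky (filopodial) morphologies:

* circularity = 4 * pi * area / perimeter**2 (1 for a disk), with the
  perimeter measured on the marching-squares contour resampled to ~4 px
  chords so a rasterized disk scores ~1 rather than suffering
  digital-staircase perimeter bias;
* solidity = area / convex-hull area (1 for any convex shape).

A standardized PCA of the per-cell metric table summarizes group
differences; the sign convention is fixed so PC1 correlates negatively with
circularity (spikier cells score higher on PC1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.stats import chi2
from skimage import measure

__all__ = ["ShapeMetrics", "PcaSummary", "shape_metrics", "pca_shapes"]


@dataclass
class ShapeMetrics:
    area_um2: float
    perimeter_um: float
    circularity: float
    solidity: float


@dataclass
class PcaSummary:
    loadings: np.ndarray  # (n_metrics, n_components), columns orthonormal
    scores: np.ndarray  # (n_cells, n_components)
    variance_fractions: np.ndarray
    metric_names: list
    group_means: dict  # label -> mean score vector
    group_ellipses: dict  # label -> (center, widths, angle_rad) at 95%
    standardized: bool = True
    means_: np.ndarray | None = None
    scales_: np.ndarray | None = None


def shape_metrics(mask: np.ndarray, pixel_size_um: float = 1.0) -> ShapeMetrics:
    """Area, perimeter, circularity and solidity of a single-component mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    _, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"mask must contain exactly one connected component, found {n}")
    area_px = float(mask.sum())
    # perimeter and convex hull from the marching-squares polygon (longest
    # contour), avoiding the digital-perimeter and pixelated-hull biases
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    main = max(contours, key=lambda c: np.linalg.norm(np.diff(c, axis=0), axis=1).sum())
    # perimeter from the contour resampled to ~4 px chords: the marching-squares
    # polygon staircases at a <= 2.8 px wavelength, inflating raw length ~5% on
    # smooth boundaries, and 4 px chords span the zigzag without rounding
    # genuine corners appreciably
    seg = np.linalg.norm(np.diff(main, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_chords = max(int(round(arc[-1] / 4.0)), 8)
    s_grid = np.linspace(0.0, arc[-1], n_chords + 1)
    resampled = np.stack(
        [np.interp(s_grid, arc, main[:, i]) for i in range(2)], axis=1
    )
    perim_px = float(np.linalg.norm(np.diff(resampled, axis=0), axis=1).sum())
    hull_area = float(ConvexHull(main).volume)  # 2-D "volume" is the area
    solidity = float(min(area_px / hull_area, 1.0))
    area = area_px * pixel_size_um**2
    perim = perim_px * pixel_size_um
    circularity = 4.0 * np.pi * area / perim**2
    return ShapeMetrics(
        area_um2=area, perimeter_um=perim, circularity=circularity, solidity=solidity
    )


def pca_shapes(
    table: pd.DataFrame,
    metric_columns=("circularity", "solidity"),
    group_column: str | None = "group",
    standardize: bool = True,
) -> PcaSummary:
    """Principal components of the shape-metric table.

    Metrics are centered and (by default) scaled to unit variance, then the
    covariance matrix is eigen-decomposed.  Loadings are orthonormal;
    variance fractions sum to 1.  Loadings are sign-flipped so the first
    component loads negatively on the first metric (circularity), matching
    the convention that spikier, less circular cells score high on PC1.
    Per-group mean scores and 95% bivariate-normal concentration ellipses
    (center, axis widths, rotation) are reported when a group column exists.
    """
    metric_columns = list(metric_columns)
    X = table[metric_columns].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cells for PCA")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 metrics for PCA")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(metric_columns, sds):
        if sd == 0:
            raise ValueError(f"metric {name!r} has zero variance")
    Z = (X - means) / sds if standardize else X - means
    cov = np.cov(Z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.maximum(eigvals[order], 0.0), eigvecs[:, order]
    # sign convention: PC1 anti-correlated with the first metric
    for j in range(eigvecs.shape[1]):
        lead = eigvecs[0, j]
        if j == 0 and lead > 0:
            eigvecs[:, j] *= -1
        elif j > 0 and eigvecs[np.argmax(np.abs(eigvecs[:, j])), j] < 0:
            eigvecs[:, j] *= -1
    scores = Z @ eigvecs
    var_frac = eigvals / eigvals.sum() if eigvals.sum() > 0 else eigvals

    group_means, group_ellipses = {}, {}
    if group_column and group_column in table.columns:
        labels = table[group_column].to_numpy()
        for lbl in pd.unique(labels):
            sel = scores[labels == lbl][:, :2]
            group_means[lbl] = sel.mean(axis=0)
            if sel.shape[0] >= 3:
                c = np.cov(sel, rowvar=False, ddof=1)
                evals, evecs = np.linalg.eigh(c)
                k = np.sqrt(chi2.ppf(0.95, df=2))
                widths = 2 * k * np.sqrt(np.maximum(evals, 0))
                angle = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
                group_ellipses[lbl] = (sel.mean(axis=0), widths[::-1], angle)
    return PcaSummary(
        loadings=eigvecs,
        scores=scores,
        variance_fractions=var_frac,
        metric_names=metric_columns,
        group_means=group_means,
        group_ellipses=group_ellipses,
        standardized=standardize,
        means_=means,
        scales_=sds if standardize else np.ones_like(sds),
    )
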