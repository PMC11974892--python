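"""Space-time correlation of probe versus reference kymographs.

This is the quantitative heart of the pipeline.  For each cell, the probe
and reference adaptive kymographs are aligned row by row (each spatial row
is cross-correlated in time and shifted to its best lag), the aligned
intensity pairs are pooled, and a least-squares line through the origin
gives the raw slope ``s`` together with an R-squared.  Slopes are then
normalized between two calibration cohorts measured the same way:

* ``b`` — the baseline slope of a probe that cannot enter the network
  (soluble eGFP): the apparent correlation floor of the assay;
* ``a`` — the self-correlation standard, labelled actin against the actin
  reference: a "perfect" incorporation of 1.

The normalized incorporation rate is ``r = (s - b) / (a - b)``, clamped to
[0, 1] (a slope below baseline reports 0).  When a wildtype probe (total
incorporation ``r_total``) and a polymerase-binding-deficient probe
(solution-only incorporation ``r_soln``) are both measured, the fraction of
network actin delivered by membrane-associated polymerases is

    f_surf = (r_total - r_soln) / r_total
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edgetrack import Kymograph, RectROI, build_adaptive_kymograph, track_edges
from .stackio import CellMask, MovieStack, preprocess

__all__ = [
    "CorrelationResult",
    "IncorporationRates",
    "align_rows_by_xcorr",
    "fit_slope_through_origin",
    "normalized_incorporation",
    "surface_fraction",
    "correlate_movie",
    "incorporation_analysis",
]


@dataclass
class CorrelationResult:
    """Pooled aligned intensity pairs and the through-origin fit for one cell."""

    x: np.ndarray  # reference intensities
    y: np.ndarray  # probe intensities
    slope: float
    r_squared: float  # squared Pearson correlation of (x, y)
    r_squared_origin: float  # uncentered R^2 of the through-origin fit
    lags: np.ndarray  # per-row lag in frames
    n_pairs: int
    flagged_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class IncorporationRates:
    """Group-level slopes and the normalized incorporation rate."""

    s: float  # mean probe slope
    b: float  # mean baseline slope
    a: float  # mean standard slope
    r: float  # (s - b) / (a - b), clamped to [0, 1]
    percent: int  # r as integer percent
    f_surf: float | None = None
    per_cell: dict = field(default_factory=dict)
    per_replicate: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Row alignment
# ---------------------------------------------------------------------------

def _best_lag(ref_row: np.ndarray, probe_row: np.ndarray, max_lag: int):
    """Lag of probe relative to reference maximizing normalized cross-correlation.

    A positive lag means the probe trace trails the reference by that many
    frames.  Ties go to the smallest |lag|, then negative before positive.
    Zero-variance rows return (0, True) -- flagged.
    """
    ref = ref_row - ref_row.mean()
    probe = probe_row - probe_row.mean()
    if np.allclose(ref, 0) or np.allclose(probe, 0):
        return 0, True
    T = ref.size
    best = (-np.inf, 0)
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            a, b = ref[: T - lag], probe[lag:]
        else:
            a, b = ref[-lag:], probe[:lag]
        if a.size < 2:
            continue
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        if denom == 0:
            continue
        c = float(np.dot(a, b) / denom)
        if c > best[0] + 1e-12:
            best = (c, lag)
    return best[1], False


def align_rows_by_xcorr(
    kymo_probe: np.ndarray | Kymograph,
    kymo_ref: np.ndarray | Kymograph,
    max_lag_frames: int = 10,
):
    """Align each spatial row of the probe kymograph to the reference.

    For every row the lag maximizing the normalized cross-correlation of the
    mean-subtracted traces (within ``|lag| <= max_lag_frames``) is found; the
    probe row is shifted by that lag and pairs that fall off the window are
    dropped.  Rows containing NaNs contribute only their finite overlap.

    Returns ``(x, y, lags, flagged_rows)`` with pooled reference intensities
    ``x`` and matching probe intensities ``y``.
    """
    P = kymo_probe.values if isinstance(kymo_probe, Kymograph) else np.asarray(kymo_probe, float)
    R = kymo_ref.values if isinstance(kymo_ref, Kymograph) else np.asarray(kymo_ref, float)
    if P.shape != R.shape:
        raise ValueError(f"kymograph shapes differ: {P.shape} vs {R.shape}")
    if max_lag_frames < 0:
        raise ValueError("max_lag_frames must be >= 0")
    S, T = P.shape
    xs, ys, lags, flagged = [], [], np.zeros(S, dtype=int), []
    for i in range(S):
        finite = np.isfinite(P[i]) & np.isfinite(R[i])
        if finite.sum() < 2:
            flagged.append(i)
            continue
        p, r = P[i, finite], R[i, finite]
        if max_lag_frames == 0:
            lag, flag = 0, False
        else:
            lag, flag = _best_lag(r, p, max_lag_frames)
        if flag:
            flagged.append(i)
        lags[i] = lag
        n = p.size
        if lag >= 0:
            xr, yp = r[: n - lag], p[lag:]
        else:
            xr, yp = r[-lag:], p[:lag]
        xs.append(xr)
        ys.append(yp)
    if not xs:
        raise ValueError("no usable kymograph rows to align")
    return (
        np.concatenate(xs),
        np.concatenate(ys),
        lags,
        np.asarray(flagged, dtype=int),
    )


# ---------------------------------------------------------------------------
# Through-origin regression
# ---------------------------------------------------------------------------

def fit_slope_through_origin(x: np.ndarray, y: np.ndarray):
    """Least-squares slope of y = s*x and the squared Pearson correlation.

    The slope is ``sum(x*y) / sum(x**2)``.  The reported r_squared is the
    squared Pearson correlation of (x, y); the uncentered coefficient of
    determination of the through-origin fit, ``1 - SS_res / sum(y**2)``, is
    returned as a third value.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 paired observations")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("all x values are zero: slope undefined")
    slope = float(np.dot(x, y)) / sxx
    if np.std(x) == 0 or np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1]) ** 2
    syy = float(np.dot(y, y))
    r2_origin = 1.0 - float(np.sum((y - slope * x) ** 2)) / syy if syy > 0 else 0.0
    return slope, r2, r2_origin


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalized_incorporation(s: float, b: float, a: float):
    """Normalize a probe slope between the baseline b and the standard a.

    ``r = (s - b) / (a - b)`` clamped to [0, 1]; also returned as integer
    percent for table-style reporting.  A slope at or below baseline reports
    0 (the floor rule), a slope at the standard reports 100.
    """
    if not a > b:
        raise ValueError(f"standard slope a={a} must exceed baseline slope b={b}")
    raw = (s - b) / (a - b)
    r = float(min(max(raw, 0.0), 1.0))
    return r, int(round(r * 100))


def surface_fraction(r_total: float, r_soln: float) -> float:
    """Fraction of network actin delivered by membrane-associated polymerases.

    ``f_surf = (r_total - r_soln) / r_total`` where ``r_total`` is the
    incorporation rate of the wildtype probe (both pathways) and ``r_soln``
    that of the proline-binding-deficient probe (solution pathway only).
    """
    if r_total <= 0:
        raise ValueError("r_total must be positive")
    if not 0 <= r_soln <= r_total:
        raise ValueError(
            f"r_soln={r_soln} must lie in [0, r_total={r_total}] for the "
            "two-pathway model to hold"
        )
    return (r_total - r_soln) / r_total


# ---------------------------------------------------------------------------
# Per-movie and cohort pipelines
# ---------------------------------------------------------------------------

def correlate_movie(
    movie: MovieStack,
    roi: RectROI | None = None,
    n_edge_samples: int = 64,
    band_depth_um: float = 1.0,
    max_lag_frames: int = 10,
    blur_sigma_px: float = 1.0,
    reference_channel=0,
    probe_channel=1,
) -> CorrelationResult:
    """Full per-cell analysis: preprocess, track, kymograph, align, fit."""
    masks = _segment_for_masks(movie, reference_channel, blur_sigma_px)
    pre, _ = preprocess(movie, masks)
    track, _ = track_edges(
        pre, roi=roi, n_samples=n_edge_samples, channel=reference_channel,
        blur_sigma_px=blur_sigma_px,
    )
    if not track.usable.any():
        raise ValueError("no frame yielded a usable leading edge")
    kref = build_adaptive_kymograph(pre, track, band_depth_um, reference_channel)
    kprobe = build_adaptive_kymograph(pre, track, band_depth_um, probe_channel)
    x, y, lags, flagged = align_rows_by_xcorr(kprobe, kref, max_lag_frames)
    slope, r2, r2o = fit_slope_through_origin(x, y)
    return CorrelationResult(
        x=x, y=y, slope=slope, r_squared=r2, r_squared_origin=r2o,
        lags=lags, n_pairs=x.size, flagged_rows=flagged,
    )


def _segment_for_masks(movie: MovieStack, channel, blur_sigma_px: float) -> CellMask:
    from .edgetrack import segment_movie

    return segment_movie(movie, channel=channel, blur_sigma_px=blur_sigma_px)


def _group_slopes(movies, name: str, replicates=None, **kwargs):
    if not movies:
        raise ValueError(f"movie group {name!r} is empty")
    slopes, results = [], []
    for m in movies:
        res = correlate_movie(m, **kwargs)
        slopes.append(res.slope)
        results.append(res)
    return np.asarray(slopes), results


def incorporation_analysis(
    probe_movies,
    baseline_movies,
    standard_movies,
    soln_movies=None,
    replicates=None,
    **kwargs,
) -> IncorporationRates:
    """Cohort-level normalized incorporation rate.

    Each movie is analysed with :func:`correlate_movie`; slopes are averaged
    per cell within each cohort.  ``s`` is the mean probe slope, ``b`` the
    mean baseline (non-incorporating probe) slope and ``a`` the mean
    standard (actin self-correlation) slope; ``r = (s - b)/(a - b)``.

    If ``soln_movies`` (a polymerase-binding-deficient probe cohort) is
    supplied, its rate ``r_soln`` and the surface-delivered fraction
    ``f_surf`` are computed as well.  ``replicates`` optionally maps group
    name to an array of replicate labels (one per movie); per-replicate mean
    slopes and rates are then reported alongside pooled values.
    """
    s_slopes, s_res = _group_slopes(probe_movies, "probe", **kwargs)
    b_slopes, b_res = _group_slopes(baseline_movies, "baseline", **kwargs)
    a_slopes, a_res = _group_slopes(standard_movies, "standard", **kwargs)
    s, b, a = s_slopes.mean(), b_slopes.mean(), a_slopes.mean()
    r, percent = normalized_incorporation(s, b, a)

    per_cell = {
        "probe": s_res,
        "baseline": b_res,
        "standard": a_res,
    }
    f_surf = None
    if soln_movies is not None:
        q_slopes, q_res = _group_slopes(soln_movies, "soln", **kwargs)
        r_soln, _ = normalized_incorporation(q_slopes.mean(), b, a)
        per_cell["soln"] = q_res
        if r > 0:
            f_surf = surface_fraction(r, min(r_soln, r))

    per_replicate = {}
    if replicates:
        for gname, slopes in (("probe", s_slopes), ("baseline", b_slopes), ("standard", a_slopes)):
            labels = np.asarray(replicates.get(gname, []))
            if labels.size == slopes.size:
                per_replicate[gname] = {
                    str(lbl): float(slopes[labels == lbl].mean())
                    for lbl in np.unique(labels)
                }
    return IncorporationRates(
        s=float(s), b=float(b), a=float(a), r=r, percent=percent,
        f_surf=f_surf, per_cell=per_cell, per_replicate=per_replicate,
    )
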