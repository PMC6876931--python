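"""Per-lead trace extraction: crop -> binary mask -> one pixel per column.

Pipeline for one bounding-box crop (already color-inverted so the signal
is bright): Otsu thresholding scaled by 1.2, small-object removal,
Hough-based centerline estimation, iterative path growth from the
centerline, farthest-pixel fallback, gap interpolation and span-5
peak-preserving smoothing.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import hough_line, hough_line_peaks

from ecgdigitize.errors import ExtractionError, ParameterError
from ecgdigitize.types import RasterImage, TracePath

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def invert_crop(crop: np.ndarray) -> np.ndarray:
    """Color-invert a crop so the dark trace becomes bright."""
    return 1.0 - np.asarray(crop, dtype=float)


def binarize(crop: np.ndarray | RasterImage, otsu_scale: float = 1.2) -> np.ndarray:
    """Threshold an inverted crop at ``otsu_scale`` times the Otsu level.

    The Otsu level maximizes between-class variance of the intensity
    histogram; the scaled threshold is capped at 1. Pixels strictly
    above the threshold are set.

    Raises
    ------
    ExtractionError
        If the crop is constant (the histogram has no two classes).
    """
    arr = crop.pixels if isinstance(crop, RasterImage) else np.asarray(crop, float)
    if arr.size == 0:
        raise ExtractionError("empty crop")
    if np.ptp(arr) == 0:
        raise ExtractionError("constant crop: Otsu threshold undefined")
    t_star = threshold_otsu(arr, nbins=256)
    return arr > min(1.0, otsu_scale * t_star)


def remove_small_objects(mask: np.ndarray, min_frac: float = 0.02) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_frac`` of the largest.

    The largest component always survives. An all-false mask is returned
    unchanged with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        warnings.warn("remove_small_objects: mask has no objects")
        return mask
    counts = np.bincount(labels.ravel())[1:]  # skip background
    cutoff = min_frac * counts.max()
    keep = np.flatnonzero(counts >= cutoff) + 1
    return np.isin(labels, keep)


def centerline(mask: np.ndarray, angle_tol_deg: float = 5.0) -> float:
    """Estimate the lead's isoelectric row from near-horizontal Hough lines.

    Runs a Hough transform restricted to line angles within
    ``angle_tol_deg`` of horizontal (0.5 deg steps, accumulator peaks at
    >= 50% of the strongest cell) and returns the median of the detected
    lines' row intercepts evaluated at the crop's horizontal midpoint.
    Falls back to the row with the most set pixels when no line is found.

    Raises
    ------
    ExtractionError
        If the mask is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ExtractionError("empty mask: no centerline")

    # skimage: rho = col*cos(theta) + row*sin(theta); a horizontal line
    # has theta at +-90 deg. Scan both signs of the tolerance band.
    step = np.deg2rad(0.5)
    tol = np.deg2rad(angle_tol_deg)
    thetas = np.concatenate([
        np.arange(np.pi / 2 - tol, np.pi / 2, step),
        np.arange(-np.pi / 2, -np.pi / 2 + tol + step / 2, step),
    ])
    h, angles, dists = hough_line(mask.astype(np.uint8), theta=thetas)
    _, peak_angles, peak_dists = hough_line_peaks(
        h, angles, dists, min_distance=1, min_angle=1,
        threshold=0.5 * h.max(),
    )
    x_mid = (mask.shape[1] - 1) / 2.0
    rows = []
    for theta, rho in zip(peak_angles, peak_dists):
        s = np.sin(theta)
        if s == 0:
            continue
        rows.append((rho - x_mid * np.cos(theta)) / s)
    rows = [r for r in rows if 0 <= r < mask.shape[0]]
    if not rows:
        return float(np.argmax(mask.sum(axis=1)))
    return float(np.median(rows))


def grow_selection(
    mask: np.ndarray, center_row: float, max_iter: int = 20, seed_band: float = 2.0
) -> np.ndarray:
    """Pixels reachable from the centerline band in ``max_iter`` dilations.

    Seeds are set pixels within ``seed_band`` rows of ``center_row``;
    each round performs one 8-neighbor dilation restricted to set
    pixels, stopping early once the selection is stable.
    """
    mask = np.asarray(mask, dtype=bool)
    row_idx = np.arange(mask.shape[0])[:, None]
    selected = mask & (np.abs(row_idx - center_row) <= seed_band)
    for _ in range(max_iter):
        grown = ndimage.binary_dilation(selected, structure=_EIGHT, mask=mask)
        if (grown == selected).all():
            break
        selected = grown
    return selected


def trace_path(
    mask: np.ndarray,
    center_row: float,
    max_iter: int = 20,
    seed_band: float = 2.0,
) -> TracePath:
    """Extract one row coordinate per column from a binary trace mask.

    Per column, pixels grown from the centerline are preferred (the one
    closest to the centerline is taken; ties go to the smaller row).
    Columns with set pixels but no grown ones take the pixel farthest
    from the centerline (ties go to the pixel nearer the previous
    column's choice; above at the first column). Remaining empty columns
    are linearly interpolated between their flanks; leading/trailing
    gaps copy the nearest value.

    Raises
    ------
    ExtractionError
        If no column contains a set pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ExtractionError("mask has no set pixels")
    n_rows, n_cols = mask.shape
    if not (0 <= center_row < n_rows):
        raise ExtractionError(f"center_row {center_row} outside mask height {n_rows}")

    selected = grow_selection(mask, center_row, max_iter=max_iter, seed_band=seed_band)

    rows = np.full(n_cols, np.nan)
    flags = ["interpolated"] * n_cols
    prev_row: float | None = None
    for c in range(n_cols):
        sel = np.flatnonzero(selected[:, c])
        if sel.size:
            # median of the grown pixels: on steep strokes the column's
            # pixels form a vertical run and the midpoint tracks the
            # curve; taking the pixel nearest the centerline instead
            # flattens every steep flank
            rows[c] = float(np.median(sel))
            flags[c] = "grown"
        else:
            cand = np.flatnonzero(mask[:, c])
            if cand.size:
                dist = np.abs(cand - center_row)
                far = cand[dist == dist.max()]
                if far.size > 1:
                    if prev_row is None:
                        choice = far.min()  # above the centerline
                    else:
                        choice = far[np.argmin(np.abs(far - prev_row))]
                else:
                    choice = far[0]
                rows[c] = choice
                flags[c] = "farthest"
        if not np.isnan(rows[c]):
            prev_row = rows[c]

    filled = np.flatnonzero(~np.isnan(rows))
    empty = np.flatnonzero(np.isnan(rows))
    if empty.size:
        rows[empty] = np.interp(empty, filled, rows[filled])
    return TracePath(rows, tuple(flags))


def smooth(
    values: np.ndarray, span: int = 5, peak_factor: float = 5.0
) -> np.ndarray:
    """Centered moving average with edge shrink, preserving peak samples.

    Positions whose absolute deviation from the baseline (the median of
    ``values``) exceeds ``peak_factor`` times the median deviation are
    copied through unchanged so that wave peaks are not flattened. At
    the edges the window shrinks symmetrically.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ParameterError("values must be a non-empty 1-D vector")
    if span % 2 == 0 or span < 1:
        raise ParameterError(f"span must be odd and positive, got {span}")

    baseline = np.median(values)
    dev = np.abs(values - baseline)
    med_dev = np.median(dev)
    is_peak = dev > peak_factor * med_dev

    half = span // 2
    n = values.size
    out = np.empty_like(values)
    for i in range(n):
        r = min(half, i, n - 1 - i)
        out[i] = values[i - r : i + r + 1].mean()
    out[is_peak] = values[is_peak]
    return out


def extract_lead(
    crop: np.ndarray,
    otsu_scale: float = 1.2,
    min_frac: float = 0.02,
    angle_tol_deg: float = 5.0,
    max_iter: int = 20,
    seed_band: float = 2.0,
    span: int = 5,
    peak_factor: float = 5.0,
) -> tuple[TracePath, float]:
    """Full per-crop pipeline; returns the smoothed path and centerline row.

    ``crop`` is the raw (dark-on-light) lead region; inversion happens
    here. Smoothing is applied to the row coordinates.
    """
    inv = invert_crop(crop)
    mask = binarize(inv, otsu_scale=otsu_scale)
    mask = remove_small_objects(mask, min_frac=min_frac)
    center = centerline(mask, angle_tol_deg=angle_tol_deg)
    path = trace_path(mask, center, max_iter=max_iter, seed_band=seed_band)
    smoothed = smooth(path.rows, span=span, peak_factor=peak_factor)
    return TracePath(smoothed, path.source_flags), center
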