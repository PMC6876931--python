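"""Region-of-interest detection: one bounding box per printed lead.

A five-row sliding mask produces a per-row standard-deviation profile;
its peaks mark the printed signal rows. A five-column mask over the
left 10% of columns locates the trace onset. The right half is handled
by mirroring the page left-right and mapping boxes back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

from ecgdigitize.errors import DetectionError, ParameterError
from ecgdigitize.types import (
    STANDARD_LEAD_ORDER,
    BoundingBox,
    LayoutConfig,
    LeadBox,
    LeadBoxSet,
    RasterImage,
)

LEFT_LEADS = STANDARD_LEAD_ORDER[:6]
RIGHT_LEADS = STANDARD_LEAD_ORDER[6:]


@dataclass(frozen=True)
class StdDevProfile:
    """Windowed standard-deviation statistic, one value per scan position."""

    values: np.ndarray
    axis: Literal["rows", "cols"]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or (vals < 0).any():
            raise ParameterError("profile must be a 1-D non-negative vector")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


def _windowed_std(
    pixels: np.ndarray,
    window: int,
    n_positions: int | None = None,
    method: str = "pooled",
) -> np.ndarray:
    """Std-dev of the clipped ``window``-row band around each row position.

    ``method="pooled"`` (default) pools all pixels in the band; the
    ``"mean_row_std"`` alternative averages per-row standard deviations.
    """
    n = pixels.shape[0]
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window > n:
        raise ParameterError(f"window {window} exceeds extent {n}")
    half = window // 2
    stop = n if n_positions is None else min(n_positions, n)
    out = np.empty(stop)
    for i in range(stop):
        band = pixels[max(0, i - half) : min(n, i + half + 1)]
        if method == "pooled":
            out[i] = band.std()
        elif method == "mean_row_std":
            out[i] = band.std(axis=1).mean()
        else:
            raise ParameterError(f"unknown profile method {method!r}")
    return out


def row_std_profile(
    img: RasterImage, window: int = 5, method: str = "pooled"
) -> StdDevProfile:
    """Per-row standard deviation of a sliding ``window``-row mask.

    ``values[r]`` is the standard deviation of all pixels in rows
    ``[r - window//2, r + window//2]`` (clipped at the edges) across
    every column; the profile has one entry per image row.
    """
    return StdDevProfile(_windowed_std(img.pixels, window, method=method), "rows")


def col_std_profile(
    img: RasterImage, window: int = 5, col_frac: float = 0.10, method: str = "pooled"
) -> StdDevProfile:
    """Column-windowed std-dev over the first ``col_frac`` of columns."""
    n_scan = int(img.n_cols * col_frac)
    if n_scan < window:
        raise ParameterError(
            f"scan region of {n_scan} columns is narrower than window {window}"
        )
    vals = _windowed_std(img.pixels.T, window, n_positions=n_scan, method=method)
    return StdDevProfile(vals, "cols")


def detect_profile_peaks(
    profile: StdDevProfile | np.ndarray,
    height_frac: float = 0.5,
    min_dist_frac: float = 0.05,
) -> np.ndarray:
    """Local maxima above ``height_frac * max`` with greedy spacing suppression.

    Peaks must exceed the height threshold and be pairwise separated by
    more than ``min_dist_frac * len(profile)`` positions. When two
    candidates are too close the higher one is kept (ties: the earlier).
    Returns indices sorted ascending; an all-zero profile yields none.
    """
    values = profile.values if isinstance(profile, StdDevProfile) else np.asarray(profile, float)
    if len(values) == 0:
        raise ParameterError("empty profile")
    vmax = values.max()
    if vmax <= 0:
        return np.array([], dtype=int)
    candidates, _ = find_peaks(values, height=height_frac * vmax)
    min_dist = min_dist_frac * len(values)
    # Greedy suppression: highest first, earlier index wins ties.
    order = sorted(candidates, key=lambda i: (-values[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) > min_dist for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def left_margin(
    img: RasterImage, window: int = 5, col_frac: float = 0.10
) -> int:
    """Column where the left-strip std-dev profile peaks (trace onset).

    Returns the argmax (first occurrence on ties) of the column-windowed
    profile computed over the first ``col_frac`` of columns. A blank
    strip returns 0 with a warning.
    """
    prof = col_std_profile(img, window=window, col_frac=col_frac)
    if prof.values.max() <= 0:
        warnings.warn("left-margin statistic is degenerate (blank strip)")
        return 0
    return int(np.argmax(prof.values))


def _row_extents(
    peaks: Sequence[int], profile: np.ndarray, n_rows: int, tail_frac: float = 0.10
) -> list[tuple[int, int]]:
    """Vertical box extents: midpoints between peaks; outer edges walk
    outward until the profile drops below ``tail_frac`` of its max."""
    cutoff = tail_frac * profile.max()
    extents = []
    for i, p in enumerate(peaks):
        if i == 0:
            r = int(p)
            while r > 0 and profile[r - 1] >= cutoff:
                r -= 1
            start = r
        else:
            start = (int(peaks[i - 1]) + int(p)) // 2
        if i == len(peaks) - 1:
            r = int(p)
            while r < n_rows - 1 and profile[r + 1] >= cutoff:
                r += 1
            end = r + 1
        else:
            end = (int(p) + int(peaks[i + 1])) // 2
        extents.append((max(0, start), min(n_rows, max(end, start + 1))))
    return extents


def _half_analysis(half_img: RasterImage, window: int):
    prof = row_std_profile(half_img, window=window)
    peaks = detect_profile_peaks(prof)
    margin = left_margin(half_img, window=window)
    return prof, peaks, margin


def detect_lead_boxes(
    img: RasterImage, layout: LayoutConfig, window: int = 5
) -> LeadBoxSet:
    """Locate every lead's bounding box on a two-column printed page.

    The left half of the page is analyzed directly; the right half by
    mirroring the page left-right, re-running the same analysis, and
    mapping columns back. With a 13-lead layout the bottom row is the
    full-width rhythm strip.

    Raises
    ------
    DetectionError
        If the number of row peaks found in either half does not match
        the layout (reports found vs expected counts).
    """
    mid = img.n_cols // 2
    expected = layout.rows_per_half

    left_img = RasterImage(img.pixels[:, :mid])
    mirrored = RasterImage(img.pixels[:, ::-1])
    right_img = RasterImage(mirrored.pixels[:, : img.n_cols - mid])

    l_prof, l_peaks, l_margin = _half_analysis(left_img, window)
    r_prof, r_peaks, r_margin = _half_analysis(right_img, window)

    for side, peaks in (("left", l_peaks), ("right", r_peaks)):
        if len(peaks) != expected:
            raise DetectionError(
                f"{side} half: found {len(peaks)} signal rows, "
                f"expected {expected} for a {layout.n_leads}-lead layout"
            )

    l_extents = _row_extents(l_peaks, l_prof.values, img.n_rows)
    r_extents = _row_extents(r_peaks, r_prof.values, img.n_rows)
    right_col_end = img.n_cols - r_margin  # mirrored margin mapped back

    boxes: list[LeadBox] = []
    for label, (r0, r1) in zip(LEFT_LEADS, l_extents):
        boxes.append(
            LeadBox(label, BoundingBox(r0, r1, l_margin, mid), "left")
        )
    for label, (r0, r1) in zip(RIGHT_LEADS, r_extents):
        boxes.append(
            LeadBox(label, BoundingBox(r0, r1, mid, right_col_end), "right")
        )
    if layout.has_rhythm_strip:
        r0, r1 = l_extents[-1]
        boxes.append(
            LeadBox(
                layout.rhythm_label,
                BoundingBox(r0, r1, l_margin, right_col_end),
                "full",
            )
        )
    return LeadBoxSet(tuple(boxes))
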