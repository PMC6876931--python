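"""Calibration-pulse location and pixel-to-physical scaling.

The reference pulse sits immediately left of the aVF lead. Its known
amplitude (1 mV) and duration (200 ms) fix the vertical and horizontal
scale of every extracted trace.
"""

from __future__ import annotations

import numpy as np

from ecgdigitize import trace
from ecgdigitize.errors import CalibrationError
from ecgdigitize.types import (
    BoundingBox,
    CalibrationScale,
    DigitizedSignal,
    RasterImage,
    TracePath,
)


def locate_scale_pulse(img: RasterImage, avf_box: BoundingBox) -> BoundingBox:
    """Search rectangle for the calibration pulse, left of the aVF box.

    The rectangle's height is 60% of the aVF box height, its width 75%
    of that height; it is vertically centered on the aVF box and abuts
    its left edge.

    Raises
    ------
    CalibrationError
        If the rectangle would fall outside the image (callers may fall
        back to a manual crop or a configured scale).
    """
    h = int(round(0.6 * avf_box.height))
    w = int(round(0.75 * h))
    if h < 2 or w < 2:
        raise CalibrationError(f"aVF box too small for a scale box ({h}x{w})")
    row_mid = (avf_box.row_start + avf_box.row_end) // 2
    r0 = row_mid - h // 2
    r1 = r0 + h
    c1 = avf_box.col_start
    c0 = c1 - w
    if c0 < 0 or r0 < 0 or r1 > img.n_rows or c1 > img.n_cols:
        raise CalibrationError(
            f"scale box [{r0}:{r1}, {c0}:{c1}] falls outside the "
            f"{img.n_rows}x{img.n_cols} image"
        )
    return BoundingBox(r0, r1, c0, c1)


def _pulse_outline(pulse_crop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Topmost set-pixel row and set-pixel count per column of the
    binarized pulse (NaN/0 for empty columns)."""
    inv = trace.invert_crop(pulse_crop)
    mask = trace.remove_small_objects(trace.binarize(inv))
    top = np.full(mask.shape[1], np.nan)
    counts = mask.sum(axis=0)
    for c in range(mask.shape[1]):
        rows = np.flatnonzero(mask[:, c])
        if rows.size:
            top[c] = rows[0]
    return top, counts


def _longest_run(cols: np.ndarray) -> np.ndarray:
    """Longest run of consecutive indices in a sorted index vector."""
    if cols.size == 0:
        return cols
    breaks = np.flatnonzero(np.diff(cols) > 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, cols.size - 1]
    k = int(np.argmax(ends - starts))
    return cols[starts[k] : ends[k] + 1]


def measure_scale(
    pulse_crop: np.ndarray | RasterImage,
    pulse_mv: float = 1.0,
    pulse_ms: float = 200.0,
    source: str = "auto",
) -> CalibrationScale:
    """Measure mv/px and ms/px from a crop containing the reference pulse.

    The pulse's top outline is split into a plateau and a baseline level.
    Pulse height is the level difference. The plateau is the longest
    contiguous run of columns above half pulse height; its width is the
    run length minus the stroke width (the drawn line has finite
    thickness, so the run spills half a stroke past each true edge).

    Raises
    ------
    CalibrationError
        If no step structure (two distinct row levels) is found.
    """
    arr = pulse_crop.pixels if isinstance(pulse_crop, RasterImage) else np.asarray(pulse_crop, float)
    try:
        top, counts = _pulse_outline(arr)
    except Exception as exc:
        raise CalibrationError(f"cannot binarize pulse crop: {exc}") from exc
    valid = top[~np.isnan(top)]
    if valid.size < 2 or np.ptp(valid) < 2:
        raise CalibrationError("no step structure in pulse crop")
    half_level = (np.nanmin(valid) + np.nanmax(valid)) / 2.0
    plateau_cols = _longest_run(np.flatnonzero(top < half_level))
    if plateau_cols.size == 0:
        raise CalibrationError("pulse crop lacks a plateau")
    a, b = int(plateau_cols[0]), int(plateau_cols[-1])
    # baseline level: columns flanking the plateau run at the lower level
    flank = np.r_[np.arange(max(0, a - 15), a), np.arange(b + 1, min(len(top), b + 16))]
    base_tops = top[flank]
    base_tops = base_tops[~np.isnan(base_tops) & (base_tops >= half_level)]
    if base_tops.size == 0:
        raise CalibrationError("pulse crop lacks two distinct row levels")
    height_px = float(np.median(base_tops) - np.median(top[plateau_cols]))
    # stroke thickness from the plateau's interior column pixel counts
    interior = plateau_cols[2:-2] if plateau_cols.size > 6 else plateau_cols
    stroke_px = float(np.median(counts[interior]))
    width_px = float(plateau_cols.size) - stroke_px
    if height_px <= 0 or width_px <= 0:
        raise CalibrationError("degenerate pulse geometry")
    return CalibrationScale(
        mv_per_px=pulse_mv / height_px,
        ms_per_px=pulse_ms / width_px,
        source=source,  # type: ignore[arg-type]
    )


def apply_scale(
    path: TracePath,
    center_row: float,
    scale: CalibrationScale,
    lead_label: str = "",
) -> DigitizedSignal:
    """Convert a pixel path to a calibrated (ms, mV) series.

    Voltage grows upward while image rows grow downward, so
    ``v[c] = (center_row - rows[c]) * mv_per_px``; time is
    ``t[c] = c * ms_per_px``.
    """
    v = (center_row - path.rows) * scale.mv_per_px
    t = np.arange(len(path)) * scale.ms_per_px
    return DigitizedSignal(t=t, v=v, lead_label=lead_label)
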