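"""Ground-truthed synthetic printed-ECG pages.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) on a zero
baseline; beats repeat at the programmed heart rate. Pages follow the
standard two-column printed layout (6 leads per column, optional
full-width rhythm strip at the bottom), with a faint background grid, a
calibration pulse floating left of the aVF trace, short lead-start and
lead-end delimiter ticks, stray glyphs and Gaussian pixel noise.

The renderer records everything it drew (per-lead signals on the
rendered pixel grid, bounding boxes, the pixel scale, fiducial truth)
so that every pipeline stage can be validated against ground truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import line_aa

from ecgdigitize.errors import SpecError
from ecgdigitize.types import (
    STANDARD_LEAD_ORDER,
    Beat,
    BoundingBox,
    CalibrationScale,
    DigitizedSignal,
    FiducialSet,
    LayoutConfig,
    LeadBox,
    LeadBoxSet,
    RasterImage,
)

#: (center offset ms from beat start, amplitude mV, Gaussian sigma ms).
#: Programmed intervals: PR (Q-P) 160 ms, QRS (S-Q) 90 ms, QT (T-Q) 380 ms.
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (95.0, 0.15, 20.0),
    "Q": (255.0, -0.10, 10.0),
    "R": (300.0, 1.00, 14.0),
    "S": (345.0, -0.15, 10.0),
    "T": (635.0, 0.35, 40.0),
}

WAVE_ORDER = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic page (geometry, morphology, defects)."""

    heart_rate_bpm: float = 60.0
    n_beats: Optional[int] = None  # None: fill the available duration
    wave_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    fs: float = 500.0
    page_px: tuple[int, int] = (1150, 1600)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    grid_spacing_px: int = 20
    trace_width_px: int = 3
    noise_sd: float = 0.02
    jpeg_quality: Optional[int] = None
    seed: int = 0
    # page geometry and physical scale
    margin_px: int = 75
    page_margin_rows: int = 50
    mv_per_px: float = 0.05
    pulse_plateau_px: int = 40
    pulse_mv: float = 1.0
    pulse_ms: float = 200.0
    paper_intensity: float = 0.97
    grid_intensity: float = 0.93
    trace_intensity: float = 0.08
    tick_half_px: int = 15
    n_glyphs: int = 5
    amp_variant_range: tuple[float, float] = (0.85, 1.10)
    end_guard_ms: float = 450.0

    def __post_init__(self) -> None:
        if not (30.0 <= self.heart_rate_bpm <= 240.0):
            raise SpecError(f"heart_rate_bpm {self.heart_rate_bpm} outside [30, 240]")
        rows, cols = self.page_px
        if rows < 600 or cols < 800:
            raise SpecError(f"page {rows}x{cols} below the 600x800 minimum")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        offsets = [self.wave_params[w][0] for w in WAVE_ORDER if w in self.wave_params]
        if len(offsets) != 5:
            raise SpecError("wave_params must define P, Q, R, S, T")
        if not all(a < b for a, b in zip(offsets, offsets[1:])):
            raise SpecError(f"wave offsets must be ordered P<Q<R<S<T, got {offsets}")

    @property
    def ms_per_px(self) -> float:
        return self.pulse_ms / self.pulse_plateau_px

    @property
    def period_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm

    @property
    def scale(self) -> CalibrationScale:
        return CalibrationScale(self.mv_per_px, self.ms_per_px, source="config")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the renderer drew, for validating the pipeline."""

    signals: dict[str, DigitizedSignal]  # on the rendered pixel grid
    boxes: LeadBoxSet
    scale: CalibrationScale
    fiducials: dict[str, FiducialSet]
    trace_cols: dict[str, tuple[int, int]]  # absolute [col_start, col_end)
    heart_rate_bpm: float
    pulse_box: BoundingBox
    margin_col: int


# ---------------------------------------------------------------------------
# waveform synthesis


def beat_waveform(t_ms: np.ndarray, waves: dict) -> np.ndarray:
    """One beat: sum of Gaussian bumps at ``t_ms`` (ms from beat start)."""
    v = np.zeros_like(t_ms, dtype=float)
    for off, amp, sigma in (waves[w] for w in WAVE_ORDER):
        v += amp * np.exp(-((t_ms - off) ** 2) / (2.0 * sigma**2))
    return v


def _n_beats_fitting(spec: SyntheticSpec, duration_ms: float) -> int:
    """Beats whose T wave ends comfortably before the duration guard."""
    t_off, _, t_sigma = spec.wave_params["T"]
    limit = duration_ms - spec.end_guard_ms
    n = 0
    while n * spec.period_ms + t_off + 3 * t_sigma <= limit:
        n += 1
    return n


def synthesize_lead(
    spec: SyntheticSpec, duration_ms: float, amp_scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Synthesize one lead at ``spec.fs``; returns (t_ms, v_mv, n_beats)."""
    n_fit = _n_beats_fitting(spec, duration_ms)
    n_beats = n_fit if spec.n_beats is None else min(spec.n_beats, n_fit)
    if n_beats < 1:
        raise SpecError(f"duration {duration_ms} ms fits no complete beat")
    n_samples = int(round(duration_ms * spec.fs / 1000.0))
    t = np.arange(n_samples) * (1000.0 / spec.fs)
    v = np.zeros(n_samples)
    for k in range(n_beats):
        v += beat_waveform(t - k * spec.period_ms, spec.wave_params)
    return t, amp_scale * v, n_beats


def _lead_geometry(spec: SyntheticSpec) -> list[tuple[str, int, int, int, str]]:
    """Per-lead (label, band_center_row, col_start, col_end, half)."""
    rows, cols = spec.page_px
    layout = spec.layout
    bands = layout.rows_per_half
    band_h = (rows - 2 * spec.page_margin_rows) / bands
    centers = [
        int(round(spec.page_margin_rows + (k + 0.5) * band_h)) for k in range(bands)
    ]
    mid = cols // 2
    left_cols = (spec.margin_px, mid)
    right_cols = (mid, cols - spec.margin_px)
    geom = []
    for k, label in enumerate(STANDARD_LEAD_ORDER[:6]):
        geom.append((label, centers[k], *left_cols, "left"))
    for k, label in enumerate(STANDARD_LEAD_ORDER[6:]):
        geom.append((label, centers[k], *right_cols, "right"))
    if layout.has_rhythm_strip:
        geom.append(
            (layout.rhythm_label, centers[-1], spec.margin_px,
             cols - spec.margin_px, "full")
        )
    return geom


# ---------------------------------------------------------------------------
# drawing primitives


def _stamp(page: np.ndarray, rr: np.ndarray, cc: np.ndarray, val: np.ndarray | float) -> None:
    ok = (rr >= 0) & (rr < page.shape[0]) & (cc >= 0) & (cc < page.shape[1])
    rr, cc = rr[ok], cc[ok]
    v = val[ok] if isinstance(val, np.ndarray) else np.full(rr.shape, val)
    np.minimum.at(page, (rr, cc), v)


def _draw_polyline(
    page: np.ndarray,
    pts_rc: np.ndarray,
    intensity: float,
    thickness: int,
) -> tuple[int, int]:
    """Anti-aliased polyline through integer-ish (row, col) points.

    Thickness is applied by stamping each segment at all (dr, dc)
    offsets centered on the line, so the stroke stays symmetric around
    the ideal path. Returns the (min_row, max_row) drawn.
    """
    rmin, rmax = page.shape[0], -1
    pts = np.asarray(pts_rc)
    offs = range(-(thickness // 2), thickness - thickness // 2)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc, ww = line_aa(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        for dr in offs:
            for dc in offs:
                val = page[np.clip(rr + dr, 0, page.shape[0] - 1),
                           np.clip(cc + dc, 0, page.shape[1] - 1)]
                blend = val * (1 - ww) + intensity * ww
                _stamp(page, rr + dr, cc + dc, blend)
        rmin = min(rmin, int(rr.min()) + min(offs))
        rmax = max(rmax, int(rr.max()) + max(offs))
    return rmin, rmax


def _draw_grid(page: np.ndarray, spacing: int, intensity: float) -> None:
    page[::spacing, :] = np.minimum(page[::spacing, :], intensity)
    page[:, ::spacing] = np.minimum(page[:, ::spacing], intensity)


# ---------------------------------------------------------------------------
# page rendering


def synthesize_ecg(spec: SyntheticSpec) -> tuple[dict[str, DigitizedSignal], dict[str, FiducialSet]]:
    """Per-lead synthesized signals (at ``spec.fs``) and fiducial truth.

    Lead durations follow the page geometry (column span times ms/px);
    amplitudes carry a small seeded per-lead variant.
    """
    rng = np.random.default_rng(spec.seed)
    geom = _lead_geometry(spec)
    lo, hi = spec.amp_variant_range
    signals: dict[str, DigitizedSignal] = {}
    fiducials: dict[str, FiducialSet] = {}
    for label, _center, c0, c1, _half in geom:
        amp = float(rng.uniform(lo, hi))
        duration = (c1 - c0) * spec.ms_per_px
        t, v, n_beats = synthesize_lead(spec, duration, amp_scale=amp)
        signals[label] = DigitizedSignal(t=t, v=v, lead_label=label)
        fiducials[label] = _truth_fiducials(spec, n_beats)
    return signals, fiducials


def _truth_fiducials(spec: SyntheticSpec, n_beats: int) -> FiducialSet:
    """Programmed fiducials as sample indices on the synthesis grid."""
    msps = 1000.0 / spec.fs
    beats = []
    for k in range(n_beats):
        start = k * spec.period_ms
        idx = {w: int(round((start + spec.wave_params[w][0]) / msps)) for w in WAVE_ORDER}
        beats.append(Beat(idx["P"], idx["Q"], idx["R"], idx["S"], idx["T"]))
    wp = spec.wave_params
    pr = wp["Q"][0] - wp["P"][0]
    qrs = wp["S"][0] - wp["Q"][0]
    qt = wp["T"][0] - wp["Q"][0]
    rr = spec.period_ms
    n_rr = max(1, n_beats - 1)
    return FiducialSet(
        beats=tuple(beats),
        pr_ms=pr, qrs_ms=qrs, qt_ms=qt, rr_ms=rr,
        pr_ms_all=(pr,) * n_beats,
        qrs_ms_all=(qrs,) * n_beats,
        qt_ms_all=(qt,) * n_beats,
        rr_ms_all=(rr,) * n_rr,
    )


def render_page(
    signals: dict[str, DigitizedSignal], spec: SyntheticSpec
) -> tuple[RasterImage, GroundTruth]:
    """Render per-lead signals as a printed-ECG-style page.

    Returns the page image and a :class:`GroundTruth` carrying the
    rendered-grid truth signals, bounding boxes (interior edges at band
    midpoints, outer edges at the tight trace extent), the pixel scale
    and fiducial truth.
    """
    rows, cols = spec.page_px
    geom = _lead_geometry(spec)
    want = {g[0] for g in geom}
    if set(signals) != want:
        raise SpecError(f"signal labels {sorted(signals)} != layout {sorted(want)}")

    rng = np.random.default_rng(spec.seed)
    # keep rng call order in sync with synthesize_ecg (amp variants first)
    rng.uniform(*spec.amp_variant_range, size=len(geom))

    page = np.full((rows, cols), spec.paper_intensity)
    if spec.grid_spacing_px > 0:
        _draw_grid(page, spec.grid_spacing_px, spec.grid_intensity)

    truth_signals: dict[str, DigitizedSignal] = {}
    trace_cols: dict[str, tuple[int, int]] = {}
    extents: dict[str, tuple[int, int]] = {}
    tw = spec.trace_width_px

    for label, center, c0, c1, _half in geom:
        sig = signals[label]
        width = c1 - c0
        t_px = np.arange(width) * spec.ms_per_px
        v_px = np.interp(t_px, sig.t, sig.v, right=0.0)
        rr = center - v_px / spec.mv_per_px
        pts = np.column_stack([rr, np.arange(c0, c1)])
        rmin, rmax = _draw_polyline(page, pts, spec.trace_intensity, tw)
        # lead-start/end delimiter ticks
        for tick_c in (c0, c1 - tw):
            _draw_polyline(
                page,
                np.array([[center - spec.tick_half_px, tick_c],
                          [center + spec.tick_half_px, tick_c]]),
                spec.trace_intensity, tw,
            )
        if rmax >= rows or rmin < 0:
            raise SpecError(f"lead {label} trace overflows the page")
        truth_signals[label] = DigitizedSignal(t=t_px, v=v_px, lead_label=label)
        trace_cols[label] = (c0, c1)
        extents[label] = (
            min(rmin, center - spec.tick_half_px),
            max(rmax, center + spec.tick_half_px) + 1,
        )

    boxes = _truth_boxes(spec, geom, extents)
    pulse_box = _draw_pulse(page, spec, boxes["aVF"].box)

    # stray glyphs: a few small dark marks within the band region
    for _ in range(spec.n_glyphs):
        gr = int(rng.integers(spec.page_margin_rows + 80, rows - spec.page_margin_rows - 80))
        gc = int(rng.integers(spec.margin_px + 30, cols - spec.margin_px - 30))
        size = int(rng.integers(2, 5))
        page[gr : gr + size, gc : gc + size] = np.minimum(
            page[gr : gr + size, gc : gc + size], spec.trace_intensity + 0.1
        )

    if spec.noise_sd > 0:
        # scan-like defect model: iid pixel noise followed by a slight
        # point-spread blur, so the noise is spatially correlated and
        # perturbs the binarized trace edges instead of vanishing under
        # the median prefilter
        page = page + rng.normal(0.0, spec.noise_sd, size=page.shape)
        page = ndimage.gaussian_filter(page, sigma=0.7)
    page = np.clip(page, 0.0, 1.0)

    if spec.jpeg_quality is not None:
        buf = io.BytesIO()
        Image.fromarray(np.rint(page * 255).astype(np.uint8), mode="L").save(
            buf, format="JPEG", quality=spec.jpeg_quality
        )
        buf.seek(0)
        page = np.asarray(Image.open(buf), dtype=float) / 255.0

    fiducials = {
        label: _truth_fiducials(spec, _count_beats(spec, signals[label]))
        for label in signals
    }
    truth = GroundTruth(
        signals=truth_signals,
        boxes=boxes,
        scale=CalibrationScale(spec.mv_per_px, spec.ms_per_px, source="config"),
        fiducials=fiducials,
        trace_cols=trace_cols,
        heart_rate_bpm=spec.heart_rate_bpm,
        pulse_box=pulse_box,
        margin_col=spec.margin_px,
    )
    return RasterImage(page), truth


def _count_beats(spec: SyntheticSpec, sig: DigitizedSignal) -> int:
    n_fit = _n_beats_fitting(spec, float(sig.t[-1]))
    return n_fit if spec.n_beats is None else min(spec.n_beats, n_fit)


def _draw_pulse(page: np.ndarray, spec: SyntheticSpec, avf_box: BoundingBox) -> BoundingBox:
    """Calibration pulse floating left of the aVF trace, vertically
    centered on the aVF bounding box (where the pipeline searches)."""
    center = (avf_box.row_start + avf_box.row_end) // 2
    c0 = avf_box.col_start
    h = int(round(spec.pulse_mv / spec.mv_per_px))
    base_row = center + h // 2
    top_row = base_row - h
    fall = c0 - 14
    rise = fall - spec.pulse_plateau_px
    lead_in = max(2, rise - 6)
    lead_out_end = c0 - 6
    pts = np.array([
        [base_row, lead_in],
        [base_row, rise],
        [top_row, rise],
        [top_row, fall],
        [base_row, fall],
        [base_row, lead_out_end],
    ])
    if rise < 2 or top_row < 0:
        raise SpecError("no room for the calibration pulse")
    _draw_polyline(page, pts, spec.trace_intensity, spec.trace_width_px)
    lo_off = spec.trace_width_px // 2
    hi_off = spec.trace_width_px - lo_off
    return BoundingBox(top_row - lo_off, base_row + hi_off,
                       lead_in - lo_off, lead_out_end + hi_off)


def _truth_boxes(spec: SyntheticSpec, geom, extents) -> LeadBoxSet:
    """Interior edges at midpoints between band centers, outer edges at
    the tight drawn extent of the outer leads."""
    rows, cols = spec.page_px
    bands = spec.layout.rows_per_half
    band_h = (rows - 2 * spec.page_margin_rows) / bands
    centers = [
        int(round(spec.page_margin_rows + (k + 0.5) * band_h)) for k in range(bands)
    ]
    mids = [(a + b) // 2 for a, b in zip(centers, centers[1:])]

    def band_rows(k: int, label: str) -> tuple[int, int]:
        top = extents[label][0] if k == 0 else mids[k - 1]
        bot = extents[label][1] if k == bands - 1 else mids[k]
        return top, bot

    boxes = []
    for i, (label, _center, c0, c1, half) in enumerate(geom):
        if half == "left":
            k = i
        elif half == "right":
            k = i - 6
        else:
            k = bands - 1
        r0, r1 = band_rows(k, label)
        boxes.append(LeadBox(label, BoundingBox(r0, r1, c0, c1), half))
    return LeadBoxSet(tuple(boxes))


def render(spec: SyntheticSpec) -> tuple[RasterImage, GroundTruth]:
    """Synthesize signals and render the page in one call."""
    signals, _ = synthesize_ecg(spec)
    return render_page(signals, spec)
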