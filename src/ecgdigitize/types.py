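"""Shared domain types for the ECG digitization pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from ecgdigitize.errors import InputError, ParameterError

#: Standard printed order: left column top-to-bottom, then right column.
STANDARD_LEAD_ORDER = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

MIN_IMAGE_SIDE = 50


@dataclass(frozen=True)
class RasterImage:
    """A 2-D grayscale image with intensities in [0, 1], row 0 at top."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InputError(f"expected a 2-D intensity grid, got ndim={px.ndim}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise InputError(
                f"image {px.shape[0]}x{px.shape[1]} smaller than "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
            )
        if px.min() < 0.0 or px.max() > 1.0:
            raise InputError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LayoutConfig:
    """Printed-page layout: 12 leads in two columns, optional rhythm strip."""

    n_leads: int = 13
    leads_per_column: int = 6
    rhythm_lead_name: Optional[str] = "II"

    def __post_init__(self) -> None:
        if self.n_leads not in (12, 13):
            raise ParameterError(f"n_leads must be 12 or 13, got {self.n_leads}")
        if self.n_leads == 13 and not self.rhythm_lead_name:
            raise ParameterError("13-lead layout requires rhythm_lead_name")
        if self.leads_per_column != 6:
            raise ParameterError(
                "only 2-column x 6-row layouts are supported "
                f"(leads_per_column={self.leads_per_column})"
            )

    @property
    def has_rhythm_strip(self) -> bool:
        return self.n_leads == 13

    @property
    def rhythm_label(self) -> str:
        """Distinct label for the rhythm strip (e.g. ``II_rhythm``)."""
        return f"{self.rhythm_lead_name}_rhythm"

    @property
    def rows_per_half(self) -> int:
        """Printed signal rows expected in each half (incl. rhythm strip)."""
        return self.leads_per_column + (1 if self.has_rhythm_strip else 0)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel rectangle [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ParameterError(f"bad row extent [{self.row_start}, {self.row_end})")
        if not (0 <= self.col_start < self.col_end):
            raise ParameterError(f"bad col extent [{self.col_start}, {self.col_end})")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    def crop(self, img: RasterImage) -> np.ndarray:
        return img.pixels[self.row_start : self.row_end, self.col_start : self.col_end]


@dataclass(frozen=True)
class LeadBox:
    lead_label: str
    box: BoundingBox
    half: Literal["left", "right", "full"]


@dataclass(frozen=True)
class LeadBoxSet:
    """Ordered per-lead bounding boxes for one page."""

    boxes: tuple[LeadBox, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))

    def __iter__(self):
        return iter(self.boxes)

    def __len__(self) -> int:
        return len(self.boxes)

    def __getitem__(self, label: str) -> LeadBox:
        for lb in self.boxes:
            if lb.lead_label == label:
                return lb
        raise KeyError(label)


@dataclass(frozen=True)
class TracePath:
    """One real-valued row coordinate per crop column, with provenance flags.

    Flags are one of ``"grown"``, ``"farthest"``, ``"interpolated"``.
    """

    rows: np.ndarray
    source_flags: tuple[str, ...]

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 1:
            raise ParameterError("TracePath.rows must be 1-D")
        if len(rows) != len(self.source_flags):
            raise ParameterError("rows and source_flags length mismatch")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "source_flags", tuple(self.source_flags))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-physical conversion factors."""

    mv_per_px: float
    ms_per_px: float
    source: Literal["auto", "manual_crop", "config"] = "auto"

    def __post_init__(self) -> None:
        for name in ("mv_per_px", "ms_per_px"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be strictly positive and finite")


@dataclass(frozen=True)
class DigitizedSignal:
    """Calibrated (time ms, voltage mV) series, uniformly sampled from t=0."""

    t: np.ndarray
    v: np.ndarray
    lead_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ParameterError("t and v must be 1-D vectors of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ParameterError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    @property
    def ms_per_sample(self) -> float:
        if len(self.t) < 2:
            raise ParameterError("need >= 2 samples for a sampling interval")
        return float((self.t[-1] - self.t[0]) / (len(self.t) - 1))

    @property
    def fs(self) -> float:
        """Samples per second implied by the sampling interval."""
        return 1000.0 / self.ms_per_sample

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class Beat:
    """Per-beat fiducial sample indices (must be strictly increasing)."""

    p_idx: int
    q_idx: int
    r_idx: int
    s_idx: int
    t_idx: int

    def __post_init__(self) -> None:
        seq = (self.p_idx, self.q_idx, self.r_idx, self.s_idx, self.t_idx)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ParameterError(f"fiducials must satisfy P<Q<R<S<T, got {seq}")


@dataclass(frozen=True)
class FiducialSet:
    """Per-beat PQRST indices plus single-beat and per-beat intervals (ms)."""

    beats: tuple[Beat, ...]
    pr_ms: float
    qrs_ms: float
    qt_ms: float
    rr_ms: Optional[float]  # None when fewer than 2 R peaks were seen
    pr_ms_all: tuple[float, ...] = ()
    qrs_ms_all: tuple[float, ...] = ()
    qt_ms_all: tuple[float, ...] = ()
    rr_ms_all: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "beats", tuple(self.beats))
        for name in ("pr_ms", "qrs_ms", "qt_ms", "rr_ms"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ParameterError(f"{name} must be positive")
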