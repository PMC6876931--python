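"""PQRST fiducial detection and interval computation.

R peaks come from a Pan-Tompkins chain (5-15 Hz band-pass, five-point
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds with search-back). Q and S are the local minima flanking R
within 80 ms. P is the nearest peak before Q; T is the highest peak
within 400 ms after S. The module is agnostic to whether the signal
came from digitization or from a reference recording, so the same code
runs on both sides of a comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from ecgdigitize.errors import FiducialError
from ecgdigitize.types import Beat, DigitizedSignal, FiducialSet


@dataclass(frozen=True)
class QrsBeat:
    q_idx: int
    r_idx: int
    s_idx: int


def _preprocess(v: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass, derivative, squaring and moving-window integration."""
    nyq = fs / 2.0
    lo, hi = 5.0 / nyq, min(15.0 / nyq, 0.99)
    b, a = butter(2, [lo, hi], btype="band")
    filt = filtfilt(b, a, v)
    # five-point derivative: (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4])
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0
    deriv = np.convolve(filt, kernel, mode="same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    return np.convolve(squared, np.ones(win) / win, mode="same")


def _adaptive_peaks(integ: np.ndarray, fs: float) -> list[int]:
    """Adaptive dual-threshold selection with search-back on the
    integrated signal; returns accepted peak indices."""
    refractory = max(1, int(round(0.2 * fs)))
    cand, _ = find_peaks(integ, distance=refractory)
    if cand.size == 0:
        return []
    learn = integ[: max(1, int(2 * fs))]
    spki = 0.25 * learn.max()
    npki = 0.5 * learn.mean()
    accepted: list[int] = []
    rr_hist: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for i, p in enumerate(cand):
        if integ[p] > threshold1():
            spki = 0.125 * integ[p] + 0.875 * spki
            if accepted:
                rr_hist.append(p - accepted[-1])
                del rr_hist[:-8]
            accepted.append(int(p))
        else:
            npki = 0.125 * integ[p] + 0.875 * npki
            # search-back: too long since the last QRS?
            if accepted and rr_hist:
                avg_rr = float(np.mean(rr_hist))
                if p - accepted[-1] > 1.66 * avg_rr and integ[p] > 0.5 * threshold1():
                    spki = 0.25 * integ[p] + 0.75 * spki
                    rr_hist.append(p - accepted[-1])
                    del rr_hist[:-8]
                    accepted.append(int(p))
    return accepted


def pan_tompkins_qrs(sig: DigitizedSignal) -> list[QrsBeat]:
    """Detect per-beat (Q, R, S) sample indices.

    R is refined to the raw-signal maximum within 150 ms of each
    integrator peak; Q and S are the minima within 80 ms before/after R.

    Raises
    ------
    FiducialError
        If fewer than 2 R peaks are found.
    """
    fs = sig.fs
    v = sig.v
    if len(v) < int(fs):
        raise FiducialError("signal too short for QRS detection")
    integ = _preprocess(v, fs)
    peaks = _adaptive_peaks(integ, fs)

    half = max(1, int(round(0.150 * fs)))
    qs_win = max(1, int(round(0.080 * fs)))
    beats: list[QrsBeat] = []
    seen: set[int] = set()
    for p in peaks:
        lo = max(0, p - half)
        hi = min(len(v), p + half + 1)
        r = lo + int(np.argmax(v[lo:hi]))
        if r in seen or r - qs_win < 0 or r + qs_win >= len(v):
            continue
        seen.add(r)
        q = r - qs_win + int(np.argmin(v[r - qs_win : r]))
        s = r + 1 + int(np.argmin(v[r + 1 : r + qs_win + 1]))
        if q < r < s:
            beats.append(QrsBeat(q, r, s))
    beats.sort(key=lambda b: b.r_idx)
    # collapse duplicates that refined onto the same beat
    dedup: list[QrsBeat] = []
    for b in beats:
        if not dedup or b.r_idx - dedup[-1].r_idx > refractory_samples(fs):
            dedup.append(b)
    if len(dedup) < 2:
        raise FiducialError(f"found {len(dedup)} R peaks; need at least 2")
    return dedup


def refractory_samples(fs: float) -> int:
    return max(1, int(round(0.2 * fs)))


def locate_pt(
    sig: DigitizedSignal, qrs: list[QrsBeat], t_window_ms: float = 400.0
) -> FiducialSet:
    """Attach P and T to each QRS beat and compute intervals.

    P is the local maximum nearest before Q (searching back to the
    previous beat's T boundary); T is the highest local maximum within
    ``t_window_ms`` after S (ties: the earlier). Beats missing either
    wave are dropped with a warning.

    Raises
    ------
    FiducialError
        If no beat survives.
    """
    if not qrs:
        raise FiducialError("no QRS beats provided")
    v = sig.v
    msps = sig.ms_per_sample
    t_win = max(1, int(round(t_window_ms / msps)))

    beats: list[Beat] = []
    prev_bound = 0
    for b in qrs:
        seg = v[prev_bound : b.q_idx]
        p_idx = None
        if seg.size >= 3:
            pk, _ = find_peaks(seg)
            if pk.size:
                p_idx = prev_bound + int(pk[-1])  # nearest before Q
        t_hi = min(len(v), b.s_idx + 1 + t_win)
        seg_t = v[b.s_idx + 1 : t_hi]
        t_idx = None
        if seg_t.size >= 3:
            pk, _ = find_peaks(seg_t)
            if pk.size:
                t_idx = b.s_idx + 1 + int(pk[np.argmax(seg_t[pk])])
        if p_idx is None or t_idx is None:
            warnings.warn(f"beat at r={b.r_idx}: missing P or T, dropped")
            prev_bound = t_idx if t_idx is not None else b.s_idx
            continue
        beats.append(Beat(p_idx, b.q_idx, b.r_idx, b.s_idx, t_idx))
        prev_bound = t_idx

    if not beats:
        raise FiducialError("all beats dropped: no complete P..T set")

    pr = tuple((b.q_idx - b.p_idx) * msps for b in beats)
    qrs_w = tuple((b.s_idx - b.q_idx) * msps for b in beats)
    qt = tuple((b.t_idx - b.q_idx) * msps for b in beats)
    r_all = [b.r_idx for b in qrs]
    rr = tuple(float(np.diff(r_all)[i]) * msps for i in range(len(r_all) - 1))
    return FiducialSet(
        beats=tuple(beats),
        pr_ms=pr[0],
        qrs_ms=qrs_w[0],
        qt_ms=qt[0],
        rr_ms=rr[0] if rr else None,
        pr_ms_all=pr,
        qrs_ms_all=qrs_w,
        qt_ms_all=qt,
        rr_ms_all=rr,
    )


def intervals(
    fset: FiducialSet, sig: DigitizedSignal
) -> tuple[float, float, float, float]:
    """Single-beat (PR, QRS, QT, RR) in ms, from the first complete beat.

    Raises
    ------
    FiducialError
        If no complete beat exists, or fewer than 2 R peaks for RR.
    """
    if not fset.beats:
        raise FiducialError("no complete beat: PR/QRS/QT undefined")
    if not fset.rr_ms_all:
        raise FiducialError("fewer than 2 R peaks: RR undefined")
    b = fset.beats[0]
    msps = sig.ms_per_sample
    return (
        (b.q_idx - b.p_idx) * msps,
        (b.s_idx - b.q_idx) * msps,
        (b.t_idx - b.q_idx) * msps,
        fset.rr_ms_all[0],
    )


def heart_rate_bpm(sig: DigitizedSignal) -> float:
    """Heart rate from mean RR of Pan-Tompkins R peaks, in bpm."""
    qrs = pan_tompkins_qrs(sig)
    r = np.array([b.r_idx for b in qrs], dtype=float)
    rr_ms = np.diff(r) * sig.ms_per_sample
    return 60000.0 / float(rr_ms.mean())


def analyze(sig: DigitizedSignal) -> FiducialSet:
    """Full fiducial chain: Pan-Tompkins then P/T location."""
    return locate_pt(sig, pan_tompkins_qrs(sig))
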