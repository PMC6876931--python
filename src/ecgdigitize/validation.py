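"""Agreement between digitized and reference signals.

Both members of each pair are resampled to a common 1000-point grid and
compared with Pearson's correlation coefficient; single-beat intervals
are correlated across the batch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ecgdigitize import fiducials
from ecgdigitize.errors import InputError, ParameterError
from ecgdigitize.types import DigitizedSignal

INTERVAL_NAMES = ("pr", "qrs", "qt", "rr")


@dataclass(frozen=True)
class ValidationReport:
    per_lead_rho: tuple[tuple[str, float], ...]
    mean_rho: float
    sd_rho: float
    interval_rho: dict[str, Optional[float]]
    p_values: dict[str, float]
    excluded: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_lead_rho": [
                {"lead": lbl, "rho": rho} for lbl, rho in self.per_lead_rho
            ],
            "mean_rho": self.mean_rho,
            "sd_rho": self.sd_rho,
            "interval_rho": self.interval_rho,
            "p_values": self.p_values,
            "excluded": list(self.excluded),
        }


def resample(sig: DigitizedSignal, n: int = 1000) -> DigitizedSignal:
    """Linear interpolation onto ``n`` uniform time points over [t0, t_end].

    Endpoints are preserved exactly; ``n < 2`` is a parameter error.
    """
    if n < 2:
        raise ParameterError(f"resample target n must be >= 2, got {n}")
    if len(sig) < 2:
        raise ParameterError("need >= 2 samples to resample")
    t_new = np.linspace(sig.t[0], sig.t[-1], n)
    v_new = np.interp(t_new, sig.t, sig.v)
    return DigitizedSignal(t=t_new, v=v_new, lead_label=sig.lead_label)


def pearson(sig1: np.ndarray, sig2: np.ndarray) -> float:
    """Pearson's correlation rho = cov(sig1, sig2) / (sigma1 * sigma2).

    Raises
    ------
    ParameterError
        On length mismatch, fewer than 3 samples, or zero variance.
    """
    x = np.asarray(sig1, dtype=float)
    y = np.asarray(sig2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 samples")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ParameterError("zero-variance input: correlation undefined")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(np.clip(cov / (sx * sy), -1.0, 1.0))


def correlation_p_value(rho: float, n: int) -> float:
    """Two-sided p-value from the t-transform t = rho*sqrt((n-2)/(1-rho^2))."""
    if n < 3:
        raise ParameterError("need n >= 3 for a p-value")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _single_beat_intervals(sig: DigitizedSignal) -> tuple[float, float, float, float]:
    fset = fiducials.analyze(sig)
    return fiducials.intervals(fset, sig)


def validate_batch(
    pairs: Sequence[tuple[DigitizedSignal, DigitizedSignal]],
    n_resample: int = 1000,
) -> ValidationReport:
    """Correlate each (reference, digitized) pair and summarize the batch.

    Per pair: both signals are resampled to ``n_resample`` points and
    correlated. Across the batch: single-beat PR/QRS/QT/RR intervals are
    computed identically on both members and correlated. Pairs with an
    undefined correlation are excluded from summaries and listed.

    Raises
    ------
    InputError
        If the batch is empty or a pair's lead labels differ.
    """
    if not pairs:
        raise InputError("empty batch")
    per_lead: list[tuple[str, float]] = []
    excluded: list[str] = []
    ref_ints: dict[str, list[float]] = {k: [] for k in INTERVAL_NAMES}
    dig_ints: dict[str, list[float]] = {k: [] for k in INTERVAL_NAMES}

    for i, (ref, dig) in enumerate(pairs):
        if ref.lead_label != dig.lead_label:
            raise InputError(
                f"pair {i}: lead labels differ "
                f"({ref.lead_label!r} vs {dig.lead_label!r})"
            )
        label = ref.lead_label or f"pair{i}"
        try:
            rho = pearson(
                resample(ref, n_resample).v, resample(dig, n_resample).v
            )
        except ParameterError:
            excluded.append(label)
            continue
        per_lead.append((label, rho))
        try:
            r_iv = _single_beat_intervals(ref)
            d_iv = _single_beat_intervals(dig)
        except Exception:
            continue
        for k, rv, dv in zip(INTERVAL_NAMES, r_iv, d_iv):
            ref_ints[k].append(rv)
            dig_ints[k].append(dv)

    if not per_lead:
        raise InputError("no pair produced a defined correlation")
    rhos = np.array([r for _, r in per_lead])
    mean_rho = float(rhos.mean())
    sd_rho = float(rhos.std(ddof=1)) if len(rhos) > 1 else 0.0

    interval_rho: dict[str, Optional[float]] = {}
    p_values: dict[str, float] = {"signal": correlation_p_value(mean_rho, n_resample)}
    for k in INTERVAL_NAMES:
        try:
            rho_k = pearson(np.array(ref_ints[k]), np.array(dig_ints[k]))
            interval_rho[k] = rho_k
            p_values[k] = correlation_p_value(rho_k, len(ref_ints[k]))
        except ParameterError:
            interval_rho[k] = None
    return ValidationReport(
        per_lead_rho=tuple(per_lead),
        mean_rho=mean_rho,
        sd_rho=sd_rho,
        interval_rho=interval_rho,
        p_values=p_values,
        excluded=tuple(excluded),
    )


def overlap_pair(
    ref: DigitizedSignal,
    dig: DigitizedSignal,
    ref_start_col: int,
    dig_start_col: int,
) -> tuple[DigitizedSignal, DigitizedSignal]:
    """Trim two per-column signals to their common absolute-column span.

    Both signals are sampled one value per page column; ``*_start_col``
    give their absolute first columns. The returned pair covers the same
    columns (and therefore the same duration), as ``validate_batch``
    requires.

    Raises
    ------
    InputError
        If the signals do not overlap.
    """
    lo = max(ref_start_col, dig_start_col)
    hi = min(ref_start_col + len(ref), dig_start_col + len(dig))
    if hi - lo < 2:
        raise InputError("signals do not overlap")

    def cut(sig: DigitizedSignal, start: int) -> DigitizedSignal:
        a, b = lo - start, hi - start
        return DigitizedSignal(
            t=sig.t[a:b] - sig.t[a], v=sig.v[a:b], lead_label=sig.lead_label
        )

    return cut(ref, ref_start_col), cut(dig, dig_start_col)


def read_signal_csv(path: str | os.PathLike, lead_label: str = "") -> DigitizedSignal:
    """Read a (time_ms, voltage_mV) CSV with header into a signal."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_ms" not in cols or "voltage_mv" not in cols:
        raise InputError(f"{path}: expected columns time_ms, voltage_mV")
    return DigitizedSignal(
        t=df[cols["time_ms"]].to_numpy(float),
        v=df[cols["voltage_mv"]].to_numpy(float),
        lead_label=lead_label,
    )


def write_signal_csv(sig: DigitizedSignal, path: str | os.PathLike) -> None:
    pd.DataFrame({"time_ms": sig.t, "voltage_mV": sig.v}).to_csv(path, index=False)
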