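"""Temporal alignment, z-normalization, and min-max rescaling to mmHg.

End-tidal CO2 lags the respiration-belt signal by the sampling-line and
lung-to-artery transit delay, so the measured P_ET_CO2 is shifted earlier
in time to maximize its (expected negative) correlation with RVT.  The
mirror operation shifts an RRF-convolved RVT regressor later to maximize
positive correlation with an HRF-convolved P_ET_CO2.  Rescaling maps an
arbitrary-unit regressor onto the mmHg range spanned by the first k
sequential high-quality breath-hold blocks of the measured trace.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physio import Trace
from .quality import HIGH, BreathHoldBlock


@dataclass
class ShiftResult:
    """Outcome of an exhaustive integer-sample shift search."""

    shift: float  # seconds; <=0 for measurement alignment, >=0 for comparison
    score: float  # Pearson r at the optimum
    clipped: bool  # optimum sits on the search bound


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def _shift_search(a: np.ndarray, b: np.ndarray, fs: float, max_shift: float, mode: str) -> ShiftResult:
    """Exhaustive search over integer-sample lags of ``a`` against ``b``.

    mode 'earlier': a is advanced by k samples (a[k:] vs b[:-k]), score
    minimized (most negative r wins).  mode 'later': a is delayed
    (a[:-k] vs b[k:]), score maximized.
    """
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (constant) input to shift search")
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    kmax = int(round(max_shift * fs))
    if n - kmax < 2:
        raise ValueError("traces too short for the requested maximum shift")
    best_k, best_r = 0, None
    for k in range(kmax + 1):
        if mode == "earlier":
            r = _pearson(a[k:], b[: n - k])
            better = best_r is None or r < best_r
        else:
            r = _pearson(a[: n - k], b[k:])
            better = best_r is None or r > best_r
        if np.isnan(r):
            continue
        if better:
            best_k, best_r = k, r
    sign = -1.0 if mode == "earlier" else 1.0
    return ShiftResult(shift=sign * best_k / fs, score=best_r, clipped=best_k == kmax)


def best_negative_shift(petco2: Trace, rvt: Trace, max_shift: float = 30.0) -> ShiftResult:
    """Shift P_ET_CO2 earlier (<=0) to maximize negative correlation with RVT."""
    if petco2.fs != rvt.fs:
        raise ValueError("traces must share a sampling rate")
    return _shift_search(petco2.samples, rvt.samples, petco2.fs, max_shift, "earlier")


def best_positive_shift(rvt_rrf: Trace, petco2_hrf: Trace, max_shift: float = 30.0) -> ShiftResult:
    """Shift a regressor later (>=0) to maximize positive correlation."""
    if rvt_rrf.fs != petco2_hrf.fs:
        raise ValueError("traces must share a sampling rate")
    return _shift_search(rvt_rrf.samples, petco2_hrf.samples, rvt_rrf.fs, max_shift, "later")


def apply_shift(a: Trace, b: Trace, shift: float) -> tuple[Trace, Trace]:
    """Apply a shift from the searches above, trimming both to common support.

    Negative shift: ``a`` advanced, ``b`` trimmed from the end.  Positive:
    ``a`` trimmed from the end, ``b`` trimmed from the start.
    """
    k = int(round(abs(shift) * a.fs))
    n = min(len(a), len(b))
    if k == 0:
        return a.copy(samples=a.samples[:n]), b.copy(samples=b.samples[:n])
    if shift < 0:
        return a.copy(samples=a.samples[k:n]), b.copy(samples=b.samples[: n - k])
    return a.copy(samples=a.samples[: n - k]), b.copy(samples=b.samples[k:n])


def estimate_task_delay(
    petco2: Trace, timing, max_delay: float = 30.0, tau: float = 15.0
) -> float:
    """Estimate the lag between task clock and the recorded CO2 trace.

    Correlates the interpolated end-tidal trace against a task template —
    unit CO2 accumulation ramping over each non-skipped hold, cleared
    exponentially with time constant ``tau`` — over candidate delays in
    [0, max_delay].  Used to locate the exhalation peaks flanking each
    hold when the sampling line introduces a substantial measurement delay.
    """
    t = petco2.times()
    template = np.zeros_like(t)
    for i, (_, hs, he, _) in enumerate(timing.trials):
        if timing.skipped[i]:
            continue
        ramp = np.clip((t - hs) / max(he - hs, 1e-6), 0.0, 1.0)
        decay = np.where(t >= he, np.exp(-np.clip(t - he, 0, None) / tau), 1.0)
        template += ramp * decay
    if np.ptp(template) == 0:
        return 0.0
    kmax = int(round(max_delay * petco2.fs))
    best_k, best_r = 0, -np.inf
    x = petco2.samples
    n = len(x)
    for k in range(kmax + 1):
        r = _pearson(template[: n - k], x[k:])
        if not np.isnan(r) and r > best_r:
            best_k, best_r = k, r
    return best_k / petco2.fs


def znorm(trace: Trace) -> Trace:
    """Zero-mean, unit-SD (population SD) copy, tagged as zscore units."""
    sd = float(np.std(trace.samples))
    if sd == 0:
        raise ValueError("cannot z-normalize a constant trace")
    return trace.copy(samples=(trace.samples - trace.samples.mean()) / sd, units="zscore")


def first_sequential_high_blocks(blocks: list[BreathHoldBlock], k: int) -> list[BreathHoldBlock]:
    """Earliest run of k consecutive high-quality blocks (skipped breaks runs)."""
    run: list[BreathHoldBlock] = []
    for b in blocks:
        if b.quality == HIGH:
            run.append(b)
            if len(run) == k:
                return run
        else:
            run = []
    raise ValueError(f"no run of {k} sequential high-quality blocks")


def rescale_minmax(
    target: Trace,
    measured_petco2: Trace,
    blocks: list[BreathHoldBlock],
    k: int = 1,
    within_block_extrema: bool = False,
) -> Trace:
    """Map a regressor onto the mmHg range of the first k high-quality blocks.

    ``[lo, hi]`` is the min/max of the measured P_ET_CO2 over the union of
    the earliest k sequential high-quality blocks.  By default the target's
    *global* extrema are mapped onto [lo, hi]; with ``within_block_extrema``
    the target's extrema over the same block span are used instead.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    sel = first_sequential_high_blocks(blocks, k)
    seg = np.concatenate([measured_petco2.samples[b.slice()] for b in sel])
    lo, hi = float(seg.min()), float(seg.max())
    if hi == lo:
        raise ValueError("degenerate measured block range (hi == lo)")
    x = target.samples
    if within_block_extrema:
        span = np.concatenate([x[b.slice()] for b in sel])
        tmin, tmax = float(span.min()), float(span.max())
    else:
        tmin, tmax = float(x.min()), float(x.max())
    if tmax == tmin:
        raise ValueError("cannot rescale a constant target")
    out = lo + (x - tmin) * (hi - lo) / (tmax - tmin)
    return target.copy(samples=out, units="mmHg")
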