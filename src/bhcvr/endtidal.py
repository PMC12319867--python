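"""End-tidal CO2 extraction and respiration-volume-per-time (RVT).

The end-tidal CO2 series is the envelope through the exhalation peaks of
the raw capnograph trace: each exhalation ends in a local maximum whose
value approximates alveolar (and hence arterial) CO2 partial pressure.
RVT is the per-breath depth divided by breath period from a respiration
belt (Birn-style): (max - preceding min) / (time to next max).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .physio import TaskTiming, Trace


@dataclass
class PeakSet:
    """Sorted sample indices of one kind of extremum on a trace."""

    indices: np.ndarray
    kind: str  # endtidal_max | resp_max | resp_min
    verified: bool = False

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    def times(self, trace: Trace) -> np.ndarray:
        return trace.t0 + self.indices / trace.fs

    def values(self, trace: Trace) -> np.ndarray:
        return trace.samples[self.indices]


def apply_peak_edits(peaks: PeakSet, edits_path: str | Path) -> PeakSet:
    """Apply a manual-QC sidecar: JSON with "add" and "remove" index lists."""
    with open(edits_path) as fh:
        edits = json.load(fh)
    idx = set(int(i) for i in peaks.indices)
    idx -= set(int(i) for i in edits.get("remove", []))
    idx |= set(int(i) for i in edits.get("add", []))
    return PeakSet(np.array(sorted(idx)), kind=peaks.kind, verified=True)


def detect_endtidal_peaks(
    co2: Trace, min_prominence: float = 2.0, min_separation: float = 2.0
) -> PeakSet:
    """Find end-tidal (exhalation) maxima in the raw CO2 trace.

    Parameters
    ----------
    min_prominence : peak prominence in the trace's units (mmHg for a
        calibrated trace); default 2 mmHg rejects cardiogenic ripple.
    min_separation : minimum time between retained peaks, seconds; when two
        humps merge within this separation the larger one is kept.
    """
    if co2.units == "volts":
        warnings.warn("detecting end-tidal peaks on an uncalibrated (volts) trace")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    distance = max(1, int(round(min_separation * co2.fs)))
    idx, _ = find_peaks(co2.samples, prominence=min_prominence, distance=distance)
    if idx.size == 0 and np.ptp(co2.samples) > 0:
        warnings.warn("no end-tidal peaks found on a nonconstant trace")
    return PeakSet(idx, kind="endtidal_max")


def interpolate_endtidal(co2: Trace, peaks: PeakSet) -> Trace:
    """Linearly interpolate through the end-tidal peaks at the CO2 rate.

    Constant extrapolation before the first and after the last peak.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 end-tidal peaks to interpolate")
    t = co2.times()
    out = np.interp(t, peaks.times(co2), peaks.values(co2))
    return co2.copy(samples=out)


def detect_resp_extrema(
    resp: Trace,
    timing: TaskTiming | None = None,
    min_prominence: float | None = None,
    min_separation: float = 1.0,
) -> tuple[PeakSet, PeakSet]:
    """Alternating breath maxima and minima of the respiration-belt trace.

    A breath hold is flanked by an exhalation before and after, producing
    two consecutive belt minima with no maximum in between; only the
    pre-hold minimum is kept so that extrema strictly alternate.
    Consecutive maxima (rare, from detection asymmetry) keep the larger.

    A local maximum only counts as a breath if it rises above the trace
    median: the near-flat plateau between the two exhale troughs of a hold
    sits at exhale level and is not an inhalation, however prominent it is
    relative to the troughs beside it.
    """
    rng = np.ptp(resp.samples)
    if rng == 0:
        empty = np.array([], dtype=int)
        return PeakSet(empty, "resp_max"), PeakSet(empty, "resp_min")
    if min_prominence is None:
        min_prominence = 0.1 * rng
    distance = max(1, int(round(min_separation * resp.fs)))
    maxima, _ = find_peaks(resp.samples, prominence=min_prominence, distance=distance)
    midline = float(np.median(resp.samples))
    maxima = maxima[resp.samples[maxima] > midline]
    minima, _ = find_peaks(-resp.samples, prominence=min_prominence, distance=distance)

    events = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])
    kept_max: list[int] = []
    kept_min: list[int] = []
    i = 0
    while i < len(events):
        j = i
        while j + 1 < len(events) and events[j + 1][1] == events[i][1]:
            j += 1
        run = [events[k][0] for k in range(i, j + 1)]
        if events[i][1] == +1:
            kept_max.append(max(run, key=lambda k: resp.samples[k]))
        else:
            # run of consecutive minima straddles a hold: keep the earliest
            # (the pre-hold exhale trough)
            kept_min.append(run[0])
        i = j + 1
    return (
        PeakSet(np.array(kept_max, dtype=int), "resp_max"),
        PeakSet(np.array(kept_min, dtype=int), "resp_min"),
    )


def compute_rvt(resp: Trace, maxima: PeakSet, minima: PeakSet) -> Trace:
    """Respiration volume per time from alternating belt extrema.

    Per breath: (value at maximum - value at preceding minimum) divided by
    the period to the next maximum, anchored at the maximum's time and
    linearly interpolated back to the belt's sampling grid.  The last
    maximum reuses the preceding period (it has no successor).
    """
    if len(maxima) < 2:
        raise ValueError("need at least 2 breath maxima for RVT")
    mx = maxima.indices
    mn = minima.indices
    depths = np.empty(mx.size)
    for k, m in enumerate(mx):
        prev = mn[mn < m]
        if prev.size == 0:
            depths[k] = np.nan
            continue
        depths[k] = resp.samples[m] - resp.samples[prev[-1]]
    periods = np.empty(mx.size)
    periods[:-1] = np.diff(mx) / resp.fs
    periods[-1] = periods[-2]
    with np.errstate(invalid="ignore"):
        rvt = depths / periods
    valid = np.isfinite(rvt)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 breaths with a preceding minimum")
    t = resp.times()
    out = np.interp(t, maxima.times(resp)[valid], rvt[valid])
    return Trace(out, fs=resp.fs, units="arbitrary", t0=resp.t0)
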