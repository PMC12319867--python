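"""Breath-hold trial quality grading and block construction.

A breath hold that the participant performed well (nose breathing, full
exhalations before and after the hold) produces a clear rise in end-tidal
CO2.  The per-trial CO2 change is the difference between the exhalation
peaks immediately flanking the hold; trials whose change exceeds the
mean minus one standard deviation of the positive changes are graded
"high" quality.  Blocks tile the recording at halfway points between
adjacent holds; segments of consecutive eligible blocks feed model
training.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .endtidal import PeakSet
from .physio import TaskTiming, Trace

HIGH, LOW, SKIPPED = "high", "low", "skipped"
_TOL = 1e-9  # "greater than" with numeric tolerance so all-equal deltas pass


@dataclass
class TrialChange:
    """CO2 change induced by one breath hold (post-hold minus pre-hold peak)."""

    trial_index: int
    pre_peak: float | None
    post_peak: float | None
    delta: float | None

    @property
    def missing(self) -> bool:
        return self.delta is None


@dataclass
class BreathHoldBlock:
    """One trial's span on the working (10 Hz) grid, with its quality label."""

    trial_index: int
    start_sample: int
    end_sample: int  # exclusive
    quality: str = HIGH
    delta: float | None = None

    def __len__(self) -> int:
        return self.end_sample - self.start_sample

    def slice(self) -> slice:
        return slice(self.start_sample, self.end_sample)


def trial_deltas(
    co2: Trace,
    peaks: PeakSet,
    timing: TaskTiming,
    delay: float = 0.0,
    post_guard: float = 0.0,
) -> list[TrialChange]:
    """Per-trial CO2 change from the raw-trace peaks flanking each hold.

    ``delay`` (s) shifts the hold window later before matching peaks, to
    account for the transit + sampling-line delay with which CO2 arrives at
    the gas analyzer (estimate it with ``align.estimate_task_delay``, or
    leave 0 if peaks were verified against the task directly).
    ``post_guard`` widens the post-hold search earlier by that many seconds
    so an imprecise delay estimate cannot step past the exhalation peak.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    pk_t = peaks.times(co2)
    pk_v = peaks.values(co2)
    out: list[TrialChange] = []
    for i, (_, hs, he, _) in enumerate(timing.trials):
        if timing.skipped[i]:
            out.append(TrialChange(i, None, None, None))
            continue
        before = np.flatnonzero(pk_t <= hs + delay)
        after = np.flatnonzero(pk_t >= he + delay - post_guard)
        if before.size == 0 or after.size == 0:
            out.append(TrialChange(i, None, None, None))
            continue
        pre = float(pk_v[before[-1]])
        post = float(pk_v[after[0]])
        out.append(TrialChange(i, pre, post, post - pre))
    return out


def quality_threshold(deltas: list[float | None], ddof: int = 1) -> float:
    """Mean minus one SD of the positive CO2 changes, mmHg.

    ``ddof=1`` (sample SD) by default; a single positive delta gives SD 0.
    """
    pos = np.array([d for d in deltas if d is not None and d > 0], dtype=float)
    if pos.size == 0:
        raise ValueError("no usable trials: no positive CO2 changes")
    sd = 0.0 if pos.size == 1 else float(np.std(pos, ddof=ddof))
    return float(np.mean(pos)) - sd


def classify_trials(
    changes: list[TrialChange], threshold: float, timing: TaskTiming | None = None
) -> list[str]:
    """Grade each trial high / low / skipped against the delta threshold.

    Intentionally skipped trials are labelled ``skipped`` (they count as
    eligible for training segments — an absent hold is itself informative).
    Missing deltas (no flanking exhalation peak) are graded low.
    """
    labels = []
    for c in changes:
        if timing is not None and timing.skipped[c.trial_index]:
            labels.append(SKIPPED)
        elif c.missing:
            labels.append(LOW)
        elif c.delta > threshold - _TOL:
            labels.append(HIGH)
        else:
            labels.append(LOW)
    return labels


def build_blocks(
    timing: TaskTiming, labels: list[str], grid: Trace, deltas: list[TrialChange] | None = None
) -> list[BreathHoldBlock]:
    """Partition the working-grid trace into one block per trial.

    Boundaries sit at the halfway point between the end of each hold and
    the start of the next; the first block absorbs everything from the
    trace start and the last runs to the trace end.
    """
    n = len(timing)
    if n < 1:
        raise ValueError("need at least one trial")
    he = timing.hold_ends
    hs = timing.hold_starts
    if np.any(hs[1:] < he[:-1]):
        raise ValueError("overlapping trials")
    mids = (he[:-1] + hs[1:]) / 2.0
    bounds_t = np.concatenate([[grid.t0], mids, [grid.t0 + len(grid) / grid.fs]])
    bounds = np.round((bounds_t - grid.t0) * grid.fs).astype(int)
    bounds = np.clip(bounds, 0, len(grid))
    bounds[0], bounds[-1] = 0, len(grid)
    blocks = []
    for i in range(n):
        blocks.append(
            BreathHoldBlock(
                trial_index=i,
                start_sample=int(bounds[i]),
                end_sample=int(bounds[i + 1]),
                quality=labels[i],
                delta=None if deltas is None else deltas[i].delta,
            )
        )
    return blocks


def _eligible_runs(blocks: list[BreathHoldBlock], min_len: int = 2) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of consecutive blocks graded high or skipped."""
    runs = []
    start = None
    for i, b in enumerate(blocks):
        ok = b.quality in (HIGH, SKIPPED)
        if ok and start is None:
            start = i
        if (not ok or i == len(blocks) - 1) and start is not None:
            end = i + 1 if ok else i
            if end - start >= min_len:
                runs.append((start, end))
            start = None
    return runs


def segment_for_training(
    blocks: list[BreathHoldBlock], rng_seed: int, max_segments: int = 4
) -> list[tuple[int, int]]:
    """Randomly cut 1–4 training segments of >=2 consecutive eligible blocks.

    Returns half-open block-index ranges ``(first, last_exclusive)``; low
    blocks never appear inside a segment.  Deterministic given the seed.
    """
    runs = _eligible_runs(blocks)
    if not runs:
        warnings.warn("no run of >=2 consecutive high-quality blocks; no training segments")
        return []
    rng = np.random.default_rng(rng_seed)
    candidates = []
    for a, b in runs:
        for s in range(a, b - 1):
            for e in range(s + 2, b + 1):
                candidates.append((s, e))
    n = int(rng.integers(1, max_segments + 1))
    n = min(n, len(candidates))
    picks = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[p] for p in sorted(picks)]


def segment_samples(blocks: list[BreathHoldBlock], segment: tuple[int, int]) -> slice:
    """Sample span on the working grid covered by a block-index segment."""
    first, last = segment
    return slice(blocks[first].start_sample, blocks[last - 1].end_sample)


def qc_report(
    changes: list[TrialChange], labels: list[str], threshold: float
) -> pd.DataFrame:
    """Tidy per-trial QC table plus a summary row (trial index -1)."""
    rows = [
        {
            "trial": c.trial_index,
            "pre_peak": c.pre_peak,
            "post_peak": c.post_peak,
            "delta_mmHg": c.delta,
            "threshold_mmHg": threshold,
            "label": lab,
        }
        for c, lab in zip(changes, labels)
    ]
    rows.append(
        {
            "trial": -1,
            "pre_peak": None,
            "post_peak": None,
            "delta_mmHg": np.nanmean([c.delta for c in changes if c.delta is not None]),
            "threshold_mmHg": threshold,
            "label": f"{labels.count(HIGH)}/{len(labels)} high",
        }
    )
    return pd.DataFrame(rows)
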