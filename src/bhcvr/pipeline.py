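"""End-to-end physiological processing workflows.

Wires the extraction, quality-grading, alignment and rescaling stages into
the processing chain applied to every recording: raw CO2 + belt traces in,
delay-corrected 10 Hz P_ET_CO2 / RVT traces, quality labels, breath-hold
blocks and (optionally) training segments out.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align, endtidal, fcn, quality
from .physio import TaskTiming, Trace, resample

WORKING_FS = 10.0


@dataclass
class ProcessedRecording:
    """Everything the downstream stages need from one physio recording."""

    petco2: Trace  # delay-corrected measured P_ET_CO2, 10 Hz, mmHg
    rvt: Trace  # trimmed RVT, 10 Hz, arbitrary units
    petco2_uncorrected: Trace  # interpolated end-tidal trace before shifting
    shift: align.ShiftResult
    co2_delay: float  # estimated task-to-CO2 measurement delay, s
    deltas: list[quality.TrialChange]
    threshold: float
    labels: list[str]
    blocks: list[quality.BreathHoldBlock]
    timing: TaskTiming
    peaks: endtidal.PeakSet = field(repr=False, default=None)


def process_recording(
    co2: Trace,
    resp: Trace,
    timing: TaskTiming,
    max_shift: float = 30.0,
    min_prominence: float = 2.0,
    min_separation: float = 2.0,
) -> ProcessedRecording:
    """Run the full physiological processing chain on one recording.

    Steps: end-tidal peak detection and interpolation; belt extrema and
    RVT; downsampling to 10 Hz; alignment of P_ET_CO2 to RVT by bounded
    negative shift; per-trial CO2 changes (hold windows offset by the
    estimated measurement delay); quality grading; block construction on
    the aligned 10 Hz grid.
    """
    peaks = endtidal.detect_endtidal_peaks(co2, min_prominence, min_separation)
    petco2_raw = endtidal.interpolate_endtidal(co2, peaks)
    maxima, minima = endtidal.detect_resp_extrema(resp, timing)
    rvt_raw = endtidal.compute_rvt(resp, maxima, minima)

    petco2_10 = resample(petco2_raw, WORKING_FS)
    rvt_10 = resample(rvt_raw, WORKING_FS)

    shift = align.best_negative_shift(petco2_10, rvt_10, max_shift)
    petco2_al, rvt_al = align.apply_shift(petco2_10, rvt_10, shift.shift)

    co2_delay = align.estimate_task_delay(petco2_10, timing, max_shift)
    deltas = quality.trial_deltas(co2, peaks, timing, delay=co2_delay, post_guard=3.0)
    threshold = quality.quality_threshold([c.delta for c in deltas])
    labels = quality.classify_trials(deltas, threshold, timing)
    blocks = quality.build_blocks(timing, labels, rvt_al, deltas)
    return ProcessedRecording(
        petco2=petco2_al,
        rvt=rvt_al,
        petco2_uncorrected=petco2_10,
        shift=shift,
        co2_delay=co2_delay,
        deltas=deltas,
        threshold=threshold,
        labels=labels,
        blocks=blocks,
        timing=timing,
        peaks=peaks,
    )


def training_segments(
    rec: ProcessedRecording, subject_id: str, rng_seed: int
) -> list[fcn.TrainingSegment]:
    """Cut z-normalized training segments from a processed recording."""
    rvt_z = align.znorm(rec.rvt)
    pet_z = align.znorm(rec.petco2)
    segments = []
    for seg in quality.segment_for_training(rec.blocks, rng_seed):
        sl = quality.segment_samples(rec.blocks, seg)
        if sl.stop - sl.start < 64:
            continue
        segments.append(
            fcn.TrainingSegment(
                rvt_z=rvt_z.samples[sl],
                petco2_z=pet_z.samples[sl],
                subject_id=subject_id,
            )
        )
    return segments


def heldout_prediction_r(model: fcn.FcnModel, rec: ProcessedRecording, subject_id: str) -> float:
    """Pearson r between the model's prediction and the measured trace."""
    rvt_z = align.znorm(rec.rvt)
    pet_z = align.znorm(rec.petco2)
    pred = model.predict(rvt_z.samples, subject_id)
    return float(np.corrcoef(pred, pet_z.samples)[0, 1])
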