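"""Canonical hemodynamic and respiration response functions.

The HRF is the standard double-gamma (peak shape 6, undershoot shape 16,
unit scale, undershoot ratio 1/6).  The RRF is the published two-term
gamma-variate difference

    r(t) = 0.6 t^2.1 e^(-t/1.6) - 0.0023 t^3.54 e^(-t/4.25)

Both kernels are normalized to unit peak so that convolution roughly
preserves the peak-to-peak excursion of an mmHg regressor; exact
amplitude semantics live in the GLM beta.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .physio import Trace


@dataclass
class Kernel:
    samples: np.ndarray
    fs: float
    kind: str  # hrf | rrf

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def _unit_peak(h: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def hrf(fs: float, duration: float = 32.0, normalize: str = "peak") -> Kernel:
    """Double-gamma canonical hemodynamic response function."""
    if not fs > 0:
        raise ValueError("fs must be positive")
    t = np.arange(int(round(duration * fs))) / fs
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    h = _unit_peak(h) if normalize == "peak" else h / h.sum()
    return Kernel(h, fs=fs, kind="hrf")


def rrf(fs: float, duration: float = 60.0, normalize: str = "peak") -> Kernel:
    """Respiration response function: early positive lobe, late undershoot."""
    if not fs > 0:
        raise ValueError("fs must be positive")
    t = np.arange(int(round(duration * fs))) / fs
    r = 0.6 * t**2.1 * np.exp(-t / 1.6) - 0.0023 * t**3.54 * np.exp(-t / 4.25)
    r = _unit_peak(r) if normalize == "peak" else r / np.abs(r.sum())
    return Kernel(r, fs=fs, kind="rrf")


def convolve(trace: Trace, kernel: Kernel) -> Trace:
    """Causal linear convolution truncated to the input length.

    The input is convolved as-is (no demeaning); output sample i depends
    only on input samples <= i.
    """
    if kernel.fs != trace.fs:
        raise ValueError(f"kernel fs {kernel.fs} != trace fs {trace.fs}")
    out = np.convolve(trace.samples, kernel.samples)[: len(trace)]
    return trace.copy(samples=out)
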