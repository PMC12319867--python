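"""Shared fixtures: synthetic recordings and a trained predictor.

Everything is generated programmatically at session scope so expensive
artifacts (the training corpus, the trained network) are built once.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from bhcvr import fcn
from bhcvr.pipeline import process_recording, training_segments
from bhcvr.synthetic import SynthSpec, gen_physio

warnings.filterwarnings("ignore", message="no peaks in target")


@pytest.fixture(scope="session")
def compliant_session():
    """One fully compliant recording (no skips, no mouth breathing)."""
    spec = SynthSpec(seed=5, skip_probability=0.0, low_quality_probability=0.0)
    co2, resp, timing, truth = gen_physio(spec)
    return co2, resp, timing, truth


@pytest.fixture(scope="session")
def processed(compliant_session):
    co2, resp, timing, _ = compliant_session
    return process_recording(co2, resp, timing)


@pytest.fixture(scope="session")
def training_corpus():
    """~40 z-normalized RVT/P_ET_CO2 segments from mixed-quality recordings."""
    segments = []
    i = 0
    while len(segments) < 40:
        co2, resp, timing, _ = gen_physio(SynthSpec(seed=100 + i))
        rec = process_recording(co2, resp, timing)
        segments.extend(training_segments(rec, f"sub-{i:02d}", rng_seed=200 + i))
        i += 1
    return segments[:40]


@pytest.fixture(scope="session")
def trained_model(training_corpus):
    """The reference configuration: 12 layers, 20 epochs, peak weight 0.5."""
    cfg = fcn.FcnConfig(n_layers=12, epochs=20, peak_weight=0.5, seed=7)
    model, history = fcn.train(training_corpus, cfg)
    return model, history


@pytest.fixture(scope="session")
def heldout_recordings():
    """Ten compliant recordings unseen during training."""
    out = []
    for k in range(10):
        spec = SynthSpec(seed=900 + k, low_quality_probability=0.0)
        co2, resp, timing, _ = gen_physio(spec)
        out.append(process_recording(co2, resp, timing))
    return out
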