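"""Synthetic breath-hold physiology and BOLD phantoms with known truth.

The physiology generator emulates a breath-hold task recording: paced
breathing (3 s in / 3 s out), holds of 10-24 s flanked by exhalations,
end-tidal CO2 peaks rising by a per-trial delta (mean ~7, SD ~3 mmHg)
that decays back to baseline with a ~20 s time constant, a 10% chance of
an intentionally skipped hold, low-quality trials with an attenuated
post-hold peak (mouth breathing / missed exhale), and a configurable
measurement delay with which CO2 reaches the gas analyzer.

The BOLD phantom synthesizes voxel timeseries from known amplitude
(%BOLD/mmHg) and delay (s) fields driven by the HRF-convolved end-tidal
trace, plus polynomial drift and Gaussian noise, so the lagged GLM can be
validated by parameter recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physio import TaskTiming, Trace
from .respfuncs import convolve, hrf
from .quality import classify_trials, quality_threshold, TrialChange


@dataclass
class SynthSpec:
    """Study conditions for one synthetic breath-hold recording."""

    n_trials: int = 8
    fs: float = 25.0
    paced_breath_period: float = 6.0  # 3 s in / 3 s out
    n_paced_breaths: int = 4
    hold_durations: list[float] | None = None  # drawn U(10, 24) s if None
    deltas: list[float] | None = None  # per-trial CO2 rises, mmHg; drawn if None
    exhale_duration: float = 3.0
    recovery_duration: float = 15.0
    baseline_petco2: float = 38.0
    # CO2 accumulates roughly linearly over an apnea, so per-trial deltas
    # scale with hold duration: delta_i = hold_i * rate * jitter_i, with the
    # subject's accumulation rate drawn around delta_mean / 17 s (the mean
    # hold) and a per-trial multiplicative jitter.  delta_mean ~7 mmHg with
    # 10-24 s holds gives realized deltas of roughly 7 +/- 3 mmHg.
    delta_mean: float = 7.0
    rate_jitter: float = 0.15  # between-recording SD of the accumulation rate
    trial_jitter: float = 0.2  # within-recording SD of per-trial deltas
    envelope_tau: float = 15.0  # s, recovery breathing clears CO2 quickly
    skip_probability: float = 0.1
    low_quality_probability: float = 0.15
    low_quality_trials: list[int] | None = None  # overrides the probability
    attenuation: float = 0.15  # post-hold delta fraction kept on low-quality trials
    measurement_delay: float = 4.0  # s, sampling-line + transit lag of CO2
    resp_noise: float = 0.02
    co2_noise: float = 0.2  # mmHg
    seed: int = 0


@dataclass
class PhysioTruth:
    """Ground truth emitted alongside a generated recording."""

    deltas: list[float | None]  # effective per-trial CO2 change, mmHg
    labels: list[str]
    threshold: float
    exhale_times: list[float | None]  # post-hold exhale peak time (task clock)
    petco2_envelope: Trace  # noiseless end-tidal envelope, task clock


def _gauss_bump(t: np.ndarray, center: float, width: float = 0.8) -> np.ndarray:
    return np.exp(-(((t - center) / width) ** 2))


def gen_physio(spec: SynthSpec) -> tuple[Trace, Trace, TaskTiming, PhysioTruth]:
    """Generate (co2, resp, timing, truth) for one breath-hold session."""
    if not 0 <= spec.skip_probability <= 1:
        raise ValueError("skip_probability must be in [0, 1]")
    if spec.attenuation < 0 or spec.measurement_delay < 0:
        raise ValueError("inconsistent spec")
    rng = np.random.default_rng(spec.seed)
    P = spec.paced_breath_period

    # --- timing -----------------------------------------------------------
    trials = []
    skipped = []
    holds = []
    t = P  # one lead-in breath
    for i in range(spec.n_trials):
        paced_start = t
        t += spec.n_paced_breaths * P
        hold_start = t
        if spec.hold_durations is not None:
            hd = float(spec.hold_durations[i % len(spec.hold_durations)])
        else:
            hd = float(rng.uniform(10.0, 24.0))
        skip = bool(rng.random() < spec.skip_probability)
        t += hd
        hold_end = t
        t += spec.exhale_duration + spec.recovery_duration
        trials.append((paced_start, hold_start, hold_end, t))
        skipped.append(skip)
        holds.append(hd)
    total = t + 2 * P + spec.measurement_delay
    timing = TaskTiming(trials=trials, skipped=skipped)

    n = int(round(total * spec.fs))
    tt = np.arange(n) / spec.fs

    # --- per-trial deltas and quality ------------------------------------
    mean_hold = 17.0  # midpoint of the 10-24 s hold range
    rate = abs(rng.normal(spec.delta_mean / mean_hold, spec.rate_jitter * spec.delta_mean / mean_hold))
    jitter = np.abs(rng.normal(1.0, spec.trial_jitter, size=spec.n_trials))
    deltas_drawn = np.asarray(holds) * rate * jitter
    if spec.deltas is not None:
        if len(spec.deltas) != spec.n_trials:
            raise ValueError("deltas must have one entry per trial")
        deltas_drawn = np.asarray(spec.deltas, dtype=float)
    if spec.low_quality_trials is not None:
        low_mask = np.zeros(spec.n_trials, dtype=bool)
        low_mask[list(spec.low_quality_trials)] = True
    else:
        low_mask = rng.random(spec.n_trials) < spec.low_quality_probability
    eff_deltas = np.where(low_mask, spec.attenuation * deltas_drawn, deltas_drawn)

    # --- respiration belt -------------------------------------------------
    resp = np.zeros(n)

    def add_breaths(t_start, t_end, amplitude):
        sel = (tt >= t_start) & (tt < t_end)
        tau = (tt[sel] - t_start) % P
        resp[sel] += amplitude * 0.5 * (1 - np.cos(2 * np.pi * tau / P))

    exhale_times: list[float | None] = [None] * spec.n_trials
    for i, (ps, hs, he, re_) in enumerate(trials):
        if i == 0:
            add_breaths(0.0, ps, 1.0)
        if skipped[i]:
            # hold replaced by rest: keep breathing straight through
            add_breaths(ps, re_, 1.0)
            continue
        add_breaths(ps, hs, 1.0)
        # hold: belt flat slightly above the exhale troughs, with dips
        sel = (tt >= hs) & (tt < he)
        resp[sel] = 0.06
        resp -= 0.18 * _gauss_bump(tt, hs - 0.2, 0.4)  # pre-hold exhale trough
        resp -= 0.22 * _gauss_bump(tt, he + 1.0, 0.5)  # post-hold exhale trough
        # recovery: two deep breaths then normal
        t_rec = he + spec.exhale_duration
        add_breaths(t_rec, t_rec + 2 * P, 1.25)
        add_breaths(t_rec + 2 * P, re_, 1.0)
        exhale_times[i] = he + spec.exhale_duration / 2.0
    add_breaths(trials[-1][3], total, 1.0)

    # --- CO2 --------------------------------------------------------------
    envelope = np.full(n, spec.baseline_petco2)
    for i in range(spec.n_trials):
        if skipped[i] or exhale_times[i] is None:
            continue
        hs = trials[i][1]
        tex = exhale_times[i]
        # CO2 accumulates over the apnea (linear ramp to the full delta at the
        # post-hold exhale) and is cleared exponentially by recovery breathing
        ramp = np.clip((tt - hs) / (tex - hs), 0.0, 1.0)
        decay = np.where(tt >= tex, np.exp(-np.clip(tt - tex, 0, None) / spec.envelope_tau), 1.0)
        envelope += eff_deltas[i] * ramp * decay

    # one exhalation bump per breath (peak at 3/4 of each 6 s breath cycle,
    # i.e. mid-exhale), none during the holds themselves
    w = np.zeros(n)
    for i, (ps, hs, he, re_) in enumerate(trials):
        if skipped[i]:
            seg_bounds = [(ps - P if i == 0 else ps, re_)]
        else:
            seg_bounds = [(ps - P if i == 0 else ps, hs)]
            seg_bounds.append((he + spec.exhale_duration, re_))
        for a, b in seg_bounds:
            nb = int(np.ceil((b - a) / P))
            for k in range(nb):
                c = a + k * P + 0.75 * P
                if c < b:
                    w += _gauss_bump(tt, c)
    nb_tail = int(np.ceil((total - trials[-1][3]) / P))
    for k in range(nb_tail):
        c = trials[-1][3] + k * P + 0.75 * P
        w += _gauss_bump(tt, c)
    for i in range(spec.n_trials):
        if exhale_times[i] is not None:
            w += _gauss_bump(tt, exhale_times[i])
    w = np.clip(w, 0.0, 1.0)
    co2 = envelope * w + 1.0  # ~1 mmHg inspired baseline

    # measurement delay: CO2 arrives late at the analyzer
    kd = int(round(spec.measurement_delay * spec.fs))
    co2 = np.concatenate([np.full(kd, co2[0]), co2])[:n]

    co2 += rng.normal(0, spec.co2_noise, n)
    resp_out = resp + rng.normal(0, spec.resp_noise, n)

    # --- ground truth -----------------------------------------------------
    truth_deltas: list[float | None] = []
    for i, (ps, hs, he, re_) in enumerate(trials):
        if skipped[i]:
            truth_deltas.append(None)
            continue
        pre_t = hs - 0.25 * P  # final pre-hold exhale bump
        pre = float(np.interp(pre_t, tt, envelope))
        post = float(np.interp(exhale_times[i], tt, envelope))
        truth_deltas.append(post - pre)
    thr = quality_threshold(truth_deltas)
    changes = [
        TrialChange(i, None, None, d) for i, d in enumerate(truth_deltas)
    ]
    labels = classify_trials(changes, thr, timing)

    truth = PhysioTruth(
        deltas=truth_deltas,
        labels=labels,
        threshold=thr,
        exhale_times=exhale_times,
        petco2_envelope=Trace(envelope, fs=spec.fs, units="mmHg"),
    )
    co2_trace = Trace(co2, fs=spec.fs, units="mmHg")
    resp_trace = Trace(resp_out, fs=spec.fs, units="arbitrary")
    return co2_trace, resp_trace, timing, truth


# --- BOLD phantom ---------------------------------------------------------


@dataclass
class PhantomSpec:
    """Voxel grid, acquisition, and ground-truth fields for a BOLD phantom."""

    shape: tuple[int, int, int] = (12, 12, 4)
    tr: float = 1.5
    n_volumes: int = 200
    baseline: float = 1000.0
    amplitude_field: np.ndarray | None = None  # %BOLD/mmHg
    delay_field: np.ndarray | None = None  # s
    drift_coeffs: tuple[float, ...] = (0.0, 2.0, -1.5)  # polynomial in t/T
    noise_sigma: float = 0.05  # percent of baseline
    gm_mask: np.ndarray | None = None
    scan_onset: float = 30.0  # s into the physiological recording
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_field is None:
            self.amplitude_field = default_amplitude_field(self.shape)
        if self.delay_field is None:
            self.delay_field = default_delay_field(self.shape)
        if self.gm_mask is None:
            m = np.zeros(self.shape, dtype=bool)
            m[1:-1, 1:-1, :] = True
            self.gm_mask = m
        self.amplitude_field = np.asarray(self.amplitude_field, dtype=float)
        self.delay_field = np.asarray(self.delay_field, dtype=float)
        if not np.all(np.isfinite(self.amplitude_field)):
            raise ValueError("amplitude_field must be finite")


def default_amplitude_field(shape) -> np.ndarray:
    """Smooth amplitude gradient spanning 0.1-0.5 %BOLD/mmHg."""
    i = np.arange(shape[0])[:, None, None]
    j = np.arange(shape[1])[None, :, None]
    k = np.zeros((1, 1, shape[2]))
    g = (i / max(shape[0] - 1, 1) + j / max(shape[1] - 1, 1)) / 2 + k
    return 0.1 + 0.4 * g


def default_delay_field(shape, lag_step: float = 0.3, max_delay: float = 6.0) -> np.ndarray:
    """Delay gradient from -6 to +6 s quantized to the lag grid."""
    j = np.arange(shape[1])[None, :, None]
    g = np.broadcast_to(j / max(shape[1] - 1, 1), shape)
    d = -max_delay + 2 * max_delay * g
    return np.round(d / lag_step) * lag_step


def hrf_convolved_demeaned(petco2: Trace) -> Trace:
    """Demean a P_ET_CO2 trace and convolve with the canonical HRF."""
    x = petco2.copy(samples=petco2.samples - petco2.samples.mean())
    return convolve(x, hrf(petco2.fs))


def gen_phantom(spec: PhantomSpec, petco2_true: Trace) -> np.ndarray:
    """4D BOLD phantom driven by the HRF-convolved end-tidal trace.

    Voxel v:  y_v(t) = B (1 + a_v/100 * x(t - d_v)) + drift(t) + noise,
    where x is the HRF-convolved, demeaned P_ET_CO2 (mmHg) and t runs on
    the TR grid starting ``scan_onset`` seconds into the recording.  The
    modulation term is re-centered within each voxel's sampled window so
    that B is exactly the temporal-mean baseline (the %BOLD convention a
    percent-signal-change analysis assumes).
    """
    if petco2_true.units != "mmHg":
        raise ValueError("petco2_true must be in mmHg")
    x = hrf_convolved_demeaned(petco2_true)
    t_scan = spec.scan_onset + np.arange(spec.n_volumes) * spec.tr
    dmin, dmax = float(spec.delay_field.min()), float(spec.delay_field.max())
    tgrid = x.times()
    if t_scan[0] - dmax < tgrid[0] or t_scan[-1] - dmin > tgrid[-1]:
        raise ValueError("delay field exceeds the regressor's time coverage")
    rng = np.random.default_rng(spec.seed)
    tnorm = np.arange(spec.n_volumes) / max(spec.n_volumes - 1, 1)
    drift = np.polynomial.polynomial.polyval(tnorm, np.asarray(spec.drift_coeffs))
    B = spec.baseline

    out = np.empty(spec.shape + (spec.n_volumes,))
    flat_a = spec.amplitude_field.reshape(-1)
    flat_d = spec.delay_field.reshape(-1)
    flat = out.reshape(-1, spec.n_volumes)
    uniq = {}
    for v in range(flat.shape[0]):
        d = float(flat_d[v])
        if d not in uniq:
            xd = np.interp(t_scan - d, tgrid, x.samples)
            uniq[d] = xd - xd.mean()
        flat[v] = B * (1.0 + flat_a[v] / 100.0 * uniq[d]) + drift
    if spec.noise_sigma > 0:
        out += rng.normal(0.0, spec.noise_sigma * B / 100.0, size=out.shape)
    return out


def phantom_regressor(petco2_true: Trace, spec: PhantomSpec) -> Trace:
    """The phantom's driving regressor re-expressed on the scan clock.

    Feeding this to ``map_cvr`` makes recovered delays directly comparable
    with the phantom's delay field.
    """
    x = hrf_convolved_demeaned(petco2_true)
    return x.copy(t0=x.t0 - spec.scan_onset)
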