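"""Voxelwise lagged-GLM estimation of CVR amplitude and delay.

Each voxel's percent-signal-change timeseries is regressed on a family of
temporally shifted copies of the (mmHg, response-function-convolved) CO2
regressor plus Legendre polynomial drift terms.  The shift maximizing the
full-model R-squared gives the hemodynamic delay (seconds); the regressor
beta at that shift is the CVR amplitude in %BOLD/mmHg.  A single bulk
shift aligning the regressor to the mean gray-matter signal is applied
first, so the voxelwise lag grid covers residual regional delays only.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .align import ShiftResult
from .physio import Trace


@dataclass
class CvrConfig:
    """Lagged-GLM settings.

    ``max_lag`` 9 s for healthy cohorts; pathology mode widens to 15 s and
    keeps boundary voxels (steno-occlusive disease produces genuinely long
    delays that would otherwise be discarded).
    """

    max_lag: float = 9.0
    lag_step: float = 0.3
    boundary_threshold: bool = True
    polynomial_order: int = 4
    bulk_align_bound: float = 30.0

    def __post_init__(self) -> None:
        n = self.max_lag / self.lag_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("max_lag must be a multiple of lag_step")

    @classmethod
    def pathology(cls) -> "CvrConfig":
        return cls(max_lag=15.0, boundary_threshold=False)

    def lags(self) -> np.ndarray:
        n = int(round(self.max_lag / self.lag_step))
        return np.arange(-n, n + 1) * self.lag_step


@dataclass
class CvrMaps:
    """Voxelwise outputs of the lagged GLM."""

    amplitude: np.ndarray  # %BOLD/mmHg
    delay: np.ndarray  # s, bulk shift included
    delay_normalized: np.ndarray  # s, gray-matter median removed
    r2: np.ndarray
    boundary_mask: np.ndarray
    valid_mask: np.ndarray
    bulk_shift: float = 0.0
    config: CvrConfig = field(default_factory=CvrConfig)


def percent_signal_change(bold: np.ndarray, mask: np.ndarray | None = None):
    """Convert a 4D BOLD series to percent signal change around each voxel mean.

    Voxels with non-positive temporal mean are excluded; returns the PSC
    array and the updated mask.
    """
    bold = np.asarray(bold, dtype=float)
    if mask is None:
        mask = np.ones(bold.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool).copy()
    mean = bold.mean(axis=-1)
    bad = mask & ~(mean > 0)
    mask[bad] = False
    out = np.zeros_like(bold)
    m = mean[mask][..., None]
    out[mask] = 100.0 * (bold[mask] - m) / m
    return out, mask


def _regressor_at(regressor: Trace, t: np.ndarray) -> np.ndarray:
    # edge-value padding outside the regressor's support
    return np.interp(t, regressor.times(), regressor.samples)


def bulk_align(regressor: Trace, gm_mean_bold: Trace, bound: float = 30.0) -> ShiftResult:
    """Global shift of the regressor maximizing |r| with the GM-mean signal.

    The absolute correlation is used because an RVT-derived regressor keeps
    its natural anti-correlated polarity; the signed r at the optimum is
    reported.
    """
    if np.ptp(regressor.samples) == 0 or np.ptp(gm_mean_bold.samples) == 0:
        raise ValueError("degenerate input to bulk alignment")
    fs = regressor.fs
    tt = gm_mean_bold.times()
    y = gm_mean_bold.samples - gm_mean_bold.samples.mean()
    kmax = int(round(bound * fs))
    best_k, best_score, best_r = 0, -np.inf, 0.0
    ny = float(np.sqrt(y @ y))
    for k in range(-kmax, kmax + 1):
        x = _regressor_at(regressor, tt - k / fs)
        x = x - x.mean()
        nx = float(np.sqrt(x @ x))
        if nx == 0 or ny == 0:
            continue
        r = float(x @ y) / (nx * ny)
        if abs(r) > best_score:
            best_k, best_score, best_r = k, abs(r), r
    return ShiftResult(shift=best_k / fs, score=best_r, clipped=abs(best_k) == kmax)


def lag_family(regressor: Trace, config: CvrConfig, tr: float, n_volumes: int) -> np.ndarray:
    """Matrix of lag-shifted regressor columns on the scanner's TR grid.

    Column j holds the regressor delayed by ``lags()[j]`` seconds (positive
    lag = response arrives later), sampled at the n_volumes acquisition
    times.  Values outside the regressor's support take the edge value.
    """
    if regressor.fs < 2.0 / config.lag_step:
        raise ValueError("regressor must be sampled finely enough for sub-TR lags")
    t_scan = np.arange(n_volumes) * tr
    lags = config.lags()
    fam = np.empty((n_volumes, lags.size))
    for j, lag in enumerate(lags):
        fam[:, j] = _regressor_at(regressor, t_scan - lag)
    return fam


def _legendre_basis(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1, 1, n)
    return np.polynomial.legendre.legvander(x, order)


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def fit_voxel(
    y_psc: np.ndarray, family: np.ndarray, nuisance: np.ndarray, config: CvrConfig | None = None
) -> tuple[float, float, float, bool]:
    """Lagged-GLM fit for a single voxel.

    OLS of the PSC timeseries on [lagged regressor, nuisance] at every lag;
    the lag maximizing R-squared wins (ties broken toward the smallest
    |lag|).  Returns (amplitude beta, delay in s relative to the bulk
    shift, full-model R-squared, at-boundary flag).
    """
    if config is None:
        config = CvrConfig(max_lag=(family.shape[1] - 1) // 2 * 0.3)
    amp, lag_idx, r2, boundary = _fit_many(y_psc[:, None], family, nuisance, config)
    return float(amp[0]), float(config.lags()[lag_idx[0]]), float(r2[0]), bool(boundary[0])


def _fit_many(Y: np.ndarray, family: np.ndarray, nuisance: np.ndarray, config: CvrConfig):
    """Vectorized lagged-GLM for Y (T x V). Returns (amp, lag_idx, r2, boundary)."""
    T, V = Y.shape
    Q, _ = np.linalg.qr(nuisance)
    Yr = _residualize(Y, Q)
    Xr = _residualize(family, Q)
    ssy = np.sum(Yr**2, axis=0)  # residual variance after nuisance
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    xnorm2 = np.sum(Xr**2, axis=0)
    ok_lag = xnorm2 > 1e-12
    C = Xr.T @ Yr  # L x V
    with np.errstate(divide="ignore", invalid="ignore"):
        # increment in explained sum of squares from the regressor at each lag
        ess = np.where(ok_lag[:, None], C**2 / np.where(ok_lag, xnorm2, 1.0)[:, None], -np.inf)
    lags = config.lags()
    # tie-break toward |lag| = 0: scan lags in order of increasing |lag|
    order = np.argsort(np.abs(lags), kind="stable")
    ess_ord = ess[order]
    pick_ord = np.argmax(ess_ord, axis=0)
    lag_idx = order[pick_ord]
    amp = C[lag_idx, np.arange(V)] / xnorm2[lag_idx]
    ssr = ssy - ess[lag_idx, np.arange(V)]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, 0.0)
    n_edge = 2  # the two outermost lags on each side count as boundary
    boundary = (lag_idx < n_edge) | (lag_idx >= lags.size - n_edge)
    return amp, lag_idx, r2, boundary


def map_cvr(
    bold: np.ndarray,
    mask: np.ndarray,
    gm_mask: np.ndarray,
    regressor: Trace,
    config: CvrConfig | None = None,
    tr: float = 1.5,
    extra_nuisance: np.ndarray | None = None,
) -> CvrMaps:
    """Whole-brain CVR amplitude/delay maps from a convolved mmHg regressor.

    Pipeline: percent signal change, bulk alignment of the regressor to the
    mean gray-matter signal, then the voxelwise lagged GLM.  The delay map
    reports bulk shift + selected lag; ``delay_normalized`` removes the
    gray-matter median.  With ``boundary_threshold`` voxels whose lag sits
    in the outermost two grid points are blanked (NaN) in the delay maps.
    """
    if config is None:
        config = CvrConfig()
    gm = np.asarray(gm_mask, dtype=bool)
    if not gm.any():
        raise ValueError("empty gray-matter mask")
    psc, mask = percent_signal_change(bold, mask)
    gm = gm & mask
    n_vol = bold.shape[-1]
    gm_mean = Trace(psc[gm].mean(axis=0), fs=1.0 / tr, units="arbitrary")
    bulk = bulk_align(regressor, gm_mean, config.bulk_align_bound)
    shifted = regressor.copy(t0=regressor.t0 + bulk.shift)
    family = lag_family(shifted, config, tr, n_vol)
    nuisance = _legendre_basis(n_vol, config.polynomial_order)
    if extra_nuisance is not None:
        extra = np.asarray(extra_nuisance, dtype=float)
        if extra.shape[0] != n_vol:
            raise ValueError("extra nuisance regressors must have one row per volume")
        nuisance = np.column_stack([nuisance, extra])

    Y = psc[mask].T  # T x V
    amp, lag_idx, r2, boundary = _fit_many(Y, family, nuisance, config)
    lags = config.lags()

    shape = bold.shape[:3]
    amplitude = np.full(shape, np.nan)
    delay = np.full(shape, np.nan)
    r2_map = np.full(shape, np.nan)
    bmask = np.zeros(shape, dtype=bool)
    amplitude[mask] = amp
    delay[mask] = bulk.shift + lags[lag_idx]
    r2_map[mask] = r2
    bmask[mask] = boundary

    gm_median = float(np.nanmedian(delay[gm]))
    delay_norm = delay - gm_median
    if config.boundary_threshold:
        delay = delay.copy()
        delay[bmask] = np.nan
        delay_norm[bmask] = np.nan
    return CvrMaps(
        amplitude=amplitude,
        delay=delay,
        delay_normalized=delay_norm,
        r2=r2_map,
        boundary_mask=bmask,
        valid_mask=mask,
        bulk_shift=bulk.shift,
        config=config,
    )


def extreme_delay_mask(
    delay: np.ndarray, threshold: float = 10.0, min_cluster: int = 15, connectivity: int = 1
) -> np.ndarray:
    """Binary mask of clusters of long-delay voxels.

    Voxels with delay >= ``threshold`` seconds are grouped by face
    connectivity (``connectivity``=1; 2 or 3 for edge/corner) and clusters
    smaller than ``min_cluster`` voxels are dropped.
    """
    delay = np.asarray(delay, dtype=float)
    with np.errstate(invalid="ignore"):
        binary = delay >= threshold
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return np.zeros_like(binary)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_cluster)
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def maps_sidecar(maps: CvrMaps, provenance: str) -> dict:
    """JSON-serializable record of how a map set was produced."""
    return {
        "regressor": provenance,
        "bulk_shift_s": maps.bulk_shift,
        "config": asdict(maps.config),
    }
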