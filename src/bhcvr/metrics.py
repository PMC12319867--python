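"""Comparison metrics between regressors and between CVR maps."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .physio import Trace

_R_CAP = 1.0 - 1e-12  # |r| ceiling before the Fisher transform diverges


@dataclass
class RegressorComparison:
    fisher_z: float
    mae: float
    rmse: float
    rmse_at_peaks: float | None


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, z = atanh(r)."""
    if not abs(r) < 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.pearsonr(a, b).statistic)


def trace_metrics_arrays(a: np.ndarray, b: np.ndarray, peak_indices) -> dict:
    """MAE, RMSE, RMSE-at-peaks and Fisher z of r(a, b) on raw arrays.

    ``a`` is the reference (measured) trace; peaks index into it.  A
    perfect correlation is capped just below 1 so the Fisher transform
    stays finite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must have equal length")
    err = a - b
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    peak_indices = np.asarray(peak_indices, dtype=int)
    rmse_pk = (
        float(np.sqrt(np.mean(err[peak_indices] ** 2))) if peak_indices.size else None
    )
    r = _pearson(a, b)
    # degenerate (near-constant) traces have no meaningful correlation
    fz = fisher_z(float(np.clip(r, -_R_CAP, _R_CAP))) if np.isfinite(r) else None
    return {"fisher_z": fz, "mae": mae, "rmse": rmse, "rmse_at_peaks": rmse_pk}


def trace_metrics(a: Trace, b: Trace, peak_indices) -> RegressorComparison:
    m = trace_metrics_arrays(a.samples, b.samples, peak_indices)
    return RegressorComparison(**m)


def map_metrics(
    test: np.ndarray, truth: np.ndarray, gm_mask: np.ndarray, exclude_pct: float = 98.0
) -> tuple[float, float, float]:
    """(Fisher z, MAE, RMSE) over gray matter, excluding extreme-truth voxels.

    Voxels whose truth-map amplitude exceeds the truth map's
    ``exclude_pct`` percentile within gray matter are dropped, so every
    test map faces the same exclusion set.
    """
    gm = np.asarray(gm_mask, dtype=bool)
    if not gm.any():
        raise ValueError("empty gray-matter mask")
    tv = np.asarray(truth, dtype=float)[gm]
    sv = np.asarray(test, dtype=float)[gm]
    cut = np.percentile(tv, exclude_pct)
    keep = tv <= cut
    if keep.sum() < 3:
        raise ValueError("no voxels left after percentile exclusion")
    tv, sv = tv[keep], sv[keep]
    r = np.clip(_pearson(tv, sv), -_R_CAP, _R_CAP)
    err = sv - tv
    return fisher_z(r), float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def mae_map(pairs, gm_mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Voxelwise mean absolute error across (test, truth) map pairs.

    Returns the MAE map and its median over gray matter.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one map pair")
    shape = np.asarray(pairs[0][0]).shape
    acc = np.zeros(shape)
    for test, truth in pairs:
        test = np.asarray(test, dtype=float)
        truth = np.asarray(truth, dtype=float)
        if test.shape != shape or truth.shape != shape:
            raise ValueError("map grids do not match")
        acc += np.abs(test - truth)
    out = acc / len(pairs)
    gm = np.asarray(gm_mask, dtype=bool)
    return out, float(np.median(out[gm]))


def spearman_rank_medians(truth_medians, test_medians) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) with two-sided p-value."""
    a = np.asarray(truth_medians, dtype=float)
    b = np.asarray(test_medians, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector has no rank ordering")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity of two binary masks; both-empty counts as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both masks empty; Dice defined as 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def spatial_corr_gm(a: np.ndarray, b: np.ndarray, gm_mask: np.ndarray) -> float:
    """Pearson correlation of two maps over gray-matter voxels."""
    gm = np.asarray(gm_mask, dtype=bool)
    if not gm.any():
        raise ValueError("empty gray-matter mask")
    av = np.asarray(a, dtype=float)[gm]
    bv = np.asarray(b, dtype=float)[gm]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("constant map within the mask")
    return _pearson(av, bv)


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; thin wrapper for group comparisons."""
    res = stats.ttest_rel(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)
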