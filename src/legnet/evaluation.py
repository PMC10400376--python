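"""Correlation metrics, paired bootstrap and stratified diagnostics.

Model quality on held-out data is summarised by Pearson and Spearman
correlation between predicted and measured expression, with uncertainty
from a percentile bootstrap (default 10,000 resamples). When two prediction
sets are compared, the bootstrap is paired: both sets are resampled with the
same indices and the per-resample difference is summarised, which respects
the dependence between models evaluated on the same sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import substream

__all__ = [
    "EvaluationReport",
    "correlations",
    "bootstrap_correlations",
    "expression_wall_report",
]


def _validate(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1-D and equal length")
    if len(pred) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("non-finite values")
    return pred, truth


def correlations(pred, truth) -> tuple[float, float]:
    """(Pearson, Spearman) between predictions and truth; NaN if constant.

    Spearman uses midranks for ties.
    """
    pred, truth = _validate(pred, truth)
    if np.std(pred) == 0 or np.std(truth) == 0:
        return (float("nan"), float("nan"))
    r = float(stats.pearsonr(pred, truth).statistic)
    rho = float(stats.spearmanr(pred, truth).statistic)
    return r, rho


@dataclass
class EvaluationReport:
    n: int
    pearson: float
    spearman: float
    resamples: int
    bootstrap_summary: dict = field(default_factory=dict)
    degenerate_resamples: int = 0


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (m, n) arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1, method="average")


def _percentiles(x: np.ndarray) -> dict:
    return {
        "p2.5": float(np.percentile(x, 2.5)),
        "p50": float(np.percentile(x, 50)),
        "p97.5": float(np.percentile(x, 97.5)),
        "mean": float(np.mean(x)),
    }


def bootstrap_correlations(
    pred_a,
    pred_b,
    truth,
    resamples: int = 10_000,
    seed: int = 0,
) -> EvaluationReport:
    """Percentile bootstrap of Pearson/Spearman (paired when two sets given).

    ``pred_b`` may be None. With two prediction sets, the identical resample
    indices are applied to both and the A - B correlation difference is
    summarised alongside the individual correlations. Degenerate resamples
    (constant vectors) are dropped from the percentiles and counted.
    """
    a, t = _validate(pred_a, truth)
    b = None
    if pred_b is not None:
        b, _ = _validate(pred_b, truth)
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    n = len(a)
    rng = substream(seed, "bootstrap")
    idx = rng.integers(0, n, size=(resamples, n))
    at, tt = a[idx], t[idx]
    valid = (at.std(axis=1) > 0) & (tt.std(axis=1) > 0)
    r_a = _pearson_rows(at, tt)
    rho_a = _pearson_rows(_rank_rows(at), _rank_rows(tt))
    summary = {
        "pearson_a": _percentiles(r_a[valid]),
        "spearman_a": _percentiles(rho_a[valid]),
    }
    if b is not None:
        bt = b[idx]
        valid &= bt.std(axis=1) > 0
        r_b = _pearson_rows(bt, tt)
        rho_b = _pearson_rows(_rank_rows(bt), _rank_rows(tt))
        summary["pearson_b"] = _percentiles(r_b[valid])
        summary["spearman_b"] = _percentiles(rho_b[valid])
        summary["pearson_diff"] = _percentiles((r_a - r_b)[valid])
        summary["spearman_diff"] = _percentiles((rho_a - rho_b)[valid])
    r, rho = correlations(a, t)
    return EvaluationReport(
        n=n,
        pearson=r,
        spearman=rho,
        resamples=resamples,
        bootstrap_summary=summary,
        degenerate_resamples=int(resamples - valid.sum()),
    )


def expression_wall_report(pred, truth, threshold: float) -> dict:
    """Diagnostic of the low-expression prediction 'wall'.

    Splits sequences at a truth threshold and reports per-stratum counts and
    correlations; sorting-bin data are known to be poorly resolved below
    roughly bin 2.5-4 where the sorter signal-to-noise collapses.
    """
    pred, truth = _validate(pred, truth)
    out: dict = {"threshold": float(threshold), "n": len(pred)}
    for name, mask in (("below", truth < threshold), ("above", truth >= threshold)):
        stratum: dict = {"n": int(mask.sum())}
        if mask.sum() < 3:
            stratum["reason"] = "fewer than 3 sequences in stratum"
            stratum["pearson"] = stratum["spearman"] = float("nan")
        else:
            r, rho = correlations(pred[mask], truth[mask])
            stratum["pearson"], stratum["spearman"] = r, rho
            if np.isnan(r):
                stratum["reason"] = "constant predictions or truth in stratum"
        out[name] = stratum
    return out
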