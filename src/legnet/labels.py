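"""Soft-classification targets for sorting-bin expression data.

A measured expression ``e`` (the mean observed bin number) is an uncertain
estimate of the true expression; the sorter noise is modelled as

    true expression ~ Normal(mu = e + 0.5, sd = 0.5)

and the regression target becomes the 18-vector of probabilities of that
Gaussian falling into the bin ranges: bin 0 covers (-inf, 1], bins i = 1..16
cover [i, i+1), and bin 17 covers [17, +inf). The open-ended boundary bins
absorb the Gaussian tails, so the vector sums to 1 by construction.

Training minimises KL(target || model) — equal to cross-entropy up to a
target-entropy constant — and a scalar prediction is decoded from a predicted
bin distribution by soft-argmax, the expected bin number sum_i i * p_i.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr  # high-accuracy standard normal CDF

__all__ = [
    "N_BINS",
    "BIN_SD",
    "expression_to_bins",
    "soft_argmax",
    "kl_loss",
]

N_BINS = 18
BIN_SD = 0.5
_BIN_INDEX = np.arange(N_BINS, dtype=np.float64)
_EPS = 1e-12


def expression_to_bins(e: float | np.ndarray) -> np.ndarray:
    """Map expression value(s) in [0, 17] to 18-bin target distribution(s).

    Scalar input returns shape (18,), array input shape (..., 18).
    """
    e_arr = np.asarray(e, dtype=np.float64)
    if not np.all(np.isfinite(e_arr)) or np.any(e_arr < 0) or np.any(e_arr > 17):
        raise ValueError("expression outside [0, 17]")
    mu = e_arr[..., None] + 0.5
    # CDF at the interior edges 1..17; boundary bins take the full tails
    edges = np.arange(1.0, 18.0)
    cdf = ndtr((edges - mu) / BIN_SD)  # (..., 17)
    probs = np.empty(e_arr.shape + (N_BINS,), dtype=np.float64)
    probs[..., 0] = cdf[..., 0]
    probs[..., 1:17] = np.diff(cdf, axis=-1)
    probs[..., 17] = 1.0 - cdf[..., 16]
    return probs


def _check_distribution(d: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.shape[-1] != N_BINS:
        raise ValueError(f"expected {N_BINS} bins, got {d.shape[-1]}")
    if np.any(d < -tol):
        raise ValueError("negative probabilities")
    if np.any(np.abs(d.sum(axis=-1) - 1.0) > tol):
        raise ValueError("bin distribution does not sum to 1")
    return d


def soft_argmax(d: np.ndarray) -> float | np.ndarray:
    """Expected bin number of distribution(s): sum_i i * p_i, in [0, 17]."""
    d = _check_distribution(d)
    out = d @ _BIN_INDEX
    return float(out) if out.shape == () else out


def kl_loss(target: np.ndarray, predicted: np.ndarray) -> float:
    """Mean KL(target || predicted) over leading axes, in nats.

    Zero target mass contributes 0; predicted probabilities are clamped at
    1e-12 so that exact zeros (impossible after a softmax, possible in
    hand-built inputs) do not produce infinities.
    """
    t = _check_distribution(target)
    p = _check_distribution(predicted)
    p = np.clip(p, _EPS, None)
    terms = np.where(t > 0, t * (np.log(np.clip(t, _EPS, None)) - np.log(p)), 0.0)
    kl = terms.sum(axis=-1)
    return float(np.mean(kl))
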