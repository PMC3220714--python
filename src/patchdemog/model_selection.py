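"""Small-sample Akaike model selection and model averaging.

AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1); Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).  Model-averaged estimates use
the weights with an unconditional standard error that absorbs between-model
spread:  SE = sum_i w_i * sqrt(var_i + (theta_i - theta_bar)^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def aicc(loglik: float, k: int, n: float) -> float:
    """Akaike information criterion corrected for small samples.

    Raises ``ValueError`` when ``n <= k + 1`` (the correction term blows up).
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def deltas_and_weights(aicc_values: Sequence[float]) -> pd.DataFrame:
    """Delta-AICc and Akaike weights for a set of models.

    Returns a DataFrame with columns ``aicc, delta, weight`` sorted ascending
    by AICc; the index preserves the input positions (or a provided index if
    ``aicc_values`` is a pandas Series).  Weights sum to 1.
    """
    if isinstance(aicc_values, pd.Series):
        s = aicc_values.astype(float)
    else:
        s = pd.Series(np.asarray(aicc_values, dtype=float))
    if len(s) == 0 or not np.isfinite(s).any():
        raise ValueError("need at least one finite AICc value")
    delta = s - s.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    out = pd.DataFrame({"aicc": s, "delta": delta, "weight": w})
    return out.sort_values("aicc", kind="mergesort")


@dataclass(frozen=True)
class AveragedEstimate:
    """A model-averaged point estimate with unconditional SE."""

    value: float
    se: float


def model_average(
    estimates: Sequence[float],
    variances: Sequence[float],
    weights: Sequence[float],
) -> AveragedEstimate:
    """Weighted average of per-model estimates with unconditional SE."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (est.shape == var.shape == w.shape):
        raise ValueError("estimates, variances and weights must have equal length")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("weights must sum to 1")
    value = float(np.sum(w * est))
    se = float(np.sum(w * np.sqrt(var + (est - value) ** 2)))
    return AveragedEstimate(value=value, se=se)


def selection_table(
    model_ids: Sequence[str],
    logliks: Sequence[float],
    ks: Sequence[int],
    n: float,
) -> pd.DataFrame:
    """Build a ranked selection table (model, K, loglik, AICc, delta, weight)."""
    if not (len(model_ids) == len(logliks) == len(ks)):
        raise ValueError("mismatched lengths")
    aiccs = pd.Series(
        [aicc(ll, k, n) for ll, k in zip(logliks, ks)], index=list(model_ids)
    )
    tab = deltas_and_weights(aiccs)
    tab.insert(0, "model", tab.index)
    tab.insert(1, "K", [ks[list(model_ids).index(m)] for m in tab.index])
    tab.insert(2, "loglik", [logliks[list(model_ids).index(m)] for m in tab.index])
    return tab.reset_index(drop=True)
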