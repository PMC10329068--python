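"""Samejima graded-response-model math.

For an item with slope ``a`` and ordered thresholds ``b_1 < ... <
b_{m-1}``, the cumulative probability of responding in category k or
above (k = 2..m) follows a logistic curve

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k))),

with the convention ``P*_0 = 1`` and ``P*_m = 0``, so the probability of
category k is ``P_k = P*_{k-1} - P*_k``.  The logistic metric is used
throughout (no 1.7 scaling constant), matching the parameterization of
the bundled bank.

Fisher information of an item is

    I(theta) = sum_k (P'_k)^2 / P_k,
    P'_k = a [P*_{k-1}(1 - P*_{k-1}) - P*_k(1 - P*_k)],

and test information is the sum over items.  The expected sum score
(test characteristic curve) maps theta to the model-implied raw score,
which the linear 0-100 transform turns into the instrument's reporting
metric (higher = fewer limitations, i.e. orientation is reversed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .bank import GradedItem, ItemBank

__all__ = [
    "THETA_GRID",
    "category_probabilities",
    "cumulative_probabilities",
    "expected_sum_score",
    "item_information",
    "simulate_responses",
    "test_information",
    "to_scale_score",
    "theta_grid",
]


def theta_grid(lo: float = -6.0, hi: float = 6.0, step: float = 0.01) -> np.ndarray:
    """Default evaluation grid for maxima, limits and curve scans."""
    n = int(round((hi - lo) / step))
    return np.linspace(lo, hi, n + 1)


THETA_GRID = theta_grid()


def cumulative_probabilities(item: GradedItem, theta) -> np.ndarray:
    """P*_k(theta) for k = 1..m-1; shape ``theta.shape + (m-1,)``."""
    th = np.asarray(theta, dtype=float)
    b = np.asarray(item.b, dtype=float)
    return expit(item.a * (th[..., None] - b))


def _cumulative_padded(item: GradedItem, theta) -> np.ndarray:
    """P*_k for k = 0..m with the boundary conventions P*_0=1, P*_m=0."""
    pstar = cumulative_probabilities(item, theta)
    pad = np.ones(pstar.shape[:-1] + (1,))
    return np.concatenate([pad, pstar, 0.0 * pad], axis=-1)


def category_probabilities(item: GradedItem, theta) -> np.ndarray:
    """P_k(theta) for k = 1..m; a strict simplex at every finite theta."""
    ps = _cumulative_padded(item, theta)
    return -np.diff(ps, axis=-1)


def item_information(item: GradedItem, theta) -> np.ndarray:
    """Fisher information of one item at *theta* (nonnegative)."""
    ps = _cumulative_padded(item, theta)
    p = -np.diff(ps, axis=-1)
    w = ps * (1.0 - ps)  # P* Q* at each boundary
    dp = item.a * (w[..., :-1] - w[..., 1:])  # P'_k
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, dp * dp / np.where(p > 0, p, 1.0), 0.0)
    return terms.sum(axis=-1)


def test_information(bank: ItemBank, theta) -> np.ndarray:
    """Sum of item informations; 0 (with a warning) for an empty bank."""
    th = np.asarray(theta, dtype=float)
    if len(bank) == 0:
        import warnings

        warnings.warn("test_information of an empty bank is 0", stacklevel=2)
        return np.zeros(th.shape)
    return sum(item_information(it, th) for it in bank)


def expected_sum_score(bank: ItemBank, theta) -> np.ndarray:
    """Model-expected summed score E[S | theta] = sum_i sum_k k P_ik.

    Strictly increasing in theta, ranging over (s_min, s_max).
    """
    th = np.asarray(theta, dtype=float)
    total = np.zeros(th.shape)
    for it in bank:
        k = np.arange(1, it.n_categories + 1, dtype=float)
        total = total + category_probabilities(it, th) @ k
    return total


def to_scale_score(s, bank: ItemBank):
    """Linear 0-100 transform of a summed score, orientation reversed.

    100 at the all-lowest-category pattern (fewest limitations), 0 at
    the all-highest pattern.
    """
    s = np.asarray(s, dtype=float)
    lo, hi = bank.s_min, bank.s_max
    if np.any(s < lo - 1e-9) or np.any(s > hi + 1e-9):
        raise ValueError(f"sum score outside [{lo}, {hi}]")
    return 100.0 * (hi - s) / (hi - lo)


def simulate_responses(
    bank: ItemBank,
    thetas,
    seed: int | np.random.Generator | None = None,
    respondent_ids=None,
) -> pd.DataFrame:
    """Draw one response per item and respondent from the GRM.

    Returns a complete respondent-by-item DataFrame of integer category
    codes 1..m_i, reproducible for a fixed *seed*.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    th = np.asarray(thetas, dtype=float)
    n = th.shape[0]
    data = {}
    for it in bank:
        probs = category_probabilities(it, th)  # (n, m)
        u = rng.random(n)[:, None]
        data[it.id] = 1 + (probs.cumsum(axis=1) < u).sum(axis=1)
    if respondent_ids is None:
        respondent_ids = pd.RangeIndex(n, name="respondent_id")
    return pd.DataFrame(data, index=respondent_ids)
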