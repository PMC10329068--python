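"""IRT-assumption diagnostics for polytomous response data.

The battery mirrors the standard patient-reported-outcomes validation
workflow:

* Mokken scalability (Loevinger's H) and monotonicity via rest-score
  groups — do item-step probabilities rise with the trait?
* Local independence screened through Q3-style residual correlations
  after removing the fitted latent trait.
* Orlando-Thissen S-X2 item fit: observed vs model-implied item-category
  frequencies conditional on the summed score, with the generalized
  Lord-Wingersky recursion supplying the summed-score distributions.
* Differential item functioning via nested proportional-odds models and
  McFadden pseudo-R2 change.
* A never-modal-category scan of the fitted curves, the analytical
  analogue of eyeballing category response curves for disordered
  thresholds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .bank import GradedItem, ItemBank
from .estimation import DEFAULT_GRID, QuadratureGrid, score_respondents
from .grm import category_probabilities, theta_grid

__all__ = [
    "DIFResult",
    "ItemFitResult",
    "LocalDependenceResult",
    "MokkenResult",
    "dif_scan",
    "lord_wingersky",
    "local_dependence_q3",
    "modal_category_check",
    "mokken_analysis",
    "sx2_item_fit",
]


# ---------------------------------------------------------------------------
# Mokken scale analysis


@dataclass
class MokkenResult:
    H: float
    H_i: pd.Series
    H_ij: pd.DataFrame
    monotonicity_violations: pd.Series
    n_complete: int


def _pair_cov_and_max(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Covariance and its maximum over same-margin couplings.

    The maximum is attained by the comonotone (sorted-against-sorted)
    arrangement, by the rearrangement inequality.
    """
    cov = float(np.mean(x * y) - x.mean() * y.mean())
    xs, ys = np.sort(x), np.sort(y)
    cov_max = float(np.mean(xs * ys) - x.mean() * y.mean())
    return cov, cov_max


def mokken_analysis(
    responses: pd.DataFrame,
    minsize: int | None = None,
    minvi: float = 0.03,
) -> MokkenResult:
    """Loevinger scalability coefficients plus monotonicity checks.

    Pairwise H_ij = cov(X_i, X_j) / cov_max(X_i, X_j), aggregated over
    pairs to item-level H_i and the scale H.  Monotonicity is assessed
    on rest-score groups of at least *minsize* members: for every item
    step P(X_i >= k), a drop exceeding *minvi* between successive
    groups counts as a violation.  Complete cases only.
    """
    data = responses.dropna().astype(int)
    n, n_items = data.shape
    if n_items < 2:
        raise ValueError("need at least 2 items")
    cols = list(data.columns)
    arr = data.to_numpy()
    if any(arr[:, i].std() == 0 for i in range(n_items)):
        bad = [cols[i] for i in range(n_items) if arr[:, i].std() == 0]
        raise ValueError(f"zero-variance item(s): {bad}")

    cov = np.zeros((n_items, n_items))
    cov_max = np.zeros((n_items, n_items))
    for i, j in itertools.combinations(range(n_items), 2):
        c, cm = _pair_cov_and_max(arr[:, i], arr[:, j])
        cov[i, j] = cov[j, i] = c
        cov_max[i, j] = cov_max[j, i] = cm
    H_ij = np.divide(cov, cov_max, out=np.full_like(cov, np.nan),
                     where=cov_max != 0)
    np.fill_diagonal(H_ij, np.nan)
    H_i = cov.sum(axis=1) / cov_max.sum(axis=1)
    H = cov[np.triu_indices(n_items, 1)].sum() / cov_max[np.triu_indices(n_items, 1)].sum()

    if minsize is None:
        minsize = int(min(max(n // 10, 1), 50))
    violations = {}
    total = arr.sum(axis=1)
    for i in range(n_items):
        rest = total - arr[:, i]
        order = np.argsort(rest, kind="stable")
        groups: list[np.ndarray] = []
        start = 0
        sorted_rest = rest[order]
        # contiguous rest-score groups of >= minsize, respecting ties
        while start < n:
            end = start + minsize
            if end >= n:
                end = n
            else:
                while end < n and sorted_rest[end] == sorted_rest[end - 1]:
                    end += 1
            if n - end < minsize:
                end = n
            groups.append(order[start:end])
            start = end
        count = 0
        m = int(arr[:, i].max())
        for k in range(2, m + 1):
            props = [np.mean(arr[g, i] >= k) for g in groups]
            count += sum(1 for p0, p1 in zip(props, props[1:]) if p0 - p1 > minvi)
        violations[cols[i]] = count

    return MokkenResult(
        H=float(H),
        H_i=pd.Series(H_i, index=cols, name="H_i"),
        H_ij=pd.DataFrame(H_ij, index=cols, columns=cols),
        monotonicity_violations=pd.Series(violations, name="violations"),
        n_complete=n,
    )


# ---------------------------------------------------------------------------
# Local independence (Q3-style residual correlations)


@dataclass
class LocalDependenceResult:
    residual_correlations: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float


def local_dependence_q3(
    responses: pd.DataFrame,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
    threshold: float = 0.20,
) -> LocalDependenceResult:
    """Pairwise correlations of item residuals about the fitted trait.

    Residual e_ri = x_ri - E[X_i | theta_r] with theta_r the
    full-pattern EAP estimate.  Pairs with |r| above *threshold*
    (default 0.20) are flagged as locally dependent.
    """
    data = responses[bank.ids].dropna().astype(int)
    for it in bank:
        if data[it.id].nunique() < 2:
            raise ValueError(f"item {it.id!r} has < 2 observed categories")
    theta = score_respondents(bank, data, grid)["theta"].to_numpy()
    resid = np.empty(data.shape)
    for j, it in enumerate(bank):
        k = np.arange(1, it.n_categories + 1, dtype=float)
        expected = category_probabilities(it, theta) @ k
        resid[:, j] = data[it.id].to_numpy() - expected
    r = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(r, np.nan)
    rdf = pd.DataFrame(r, index=bank.ids, columns=bank.ids)
    flagged = [
        (bank.ids[i], bank.ids[j], float(r[i, j]))
        for i, j in itertools.combinations(range(len(bank)), 2)
        if abs(r[i, j]) > threshold
    ]
    return LocalDependenceResult(rdf, flagged, threshold)


# ---------------------------------------------------------------------------
# S-X2 item fit (Orlando-Thissen)


def lord_wingersky(items: list[GradedItem], theta) -> np.ndarray:
    """Summed-score distribution at *theta* by the generalized recursion.

    Returns probabilities for scores ``len(items) .. sum(m_i)`` (index 0
    corresponds to every item in category 1); last axis is the score,
    leading axes broadcast over theta.
    """
    th = np.asarray(theta, dtype=float)
    dist = np.ones(th.shape + (1,))
    for it in items:
        p = category_probabilities(it, th)  # (..., m)
        m = it.n_categories
        new = np.zeros(th.shape + (dist.shape[-1] + m - 1,))
        for k in range(m):
            new[..., k : k + dist.shape[-1]] += dist * p[..., k : k + 1]
        dist = new
    return dist


@dataclass
class ItemFitResult:
    table: pd.DataFrame  # per item: statistic, df, p_value, flagged
    alpha: float


def _collapse_rows(
    obs: list[np.ndarray], exp: list[np.ndarray], min_count: float = 5.0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Merge adjacent summed-score rows until each holds >= min_count
    respondents (near-empty category cells are pooled separately,
    within each row)."""
    obs = [row.copy() for row in obs]
    exp = [row.copy() for row in exp]
    while len(obs) > 1 and min(r.sum() for r in obs) < min_count:
        totals = [r.sum() for r in obs]
        i = int(np.argmin(totals))
        j = i + 1 if i == 0 else (i - 1 if i == len(obs) - 1 else
                                  (i - 1 if totals[i - 1] < totals[i + 1] else i + 1))
        lo, hi = min(i, j), max(i, j)
        obs[lo] = obs[lo] + obs[hi]
        exp[lo] = exp[lo] + exp[hi]
        del obs[hi], exp[hi]
    return obs, exp


def _collapse_categories_in_row(o: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent category cells with expected < 1 into a neighbor."""
    o, e = list(o), list(e)
    k = 0
    while k < len(e):
        if e[k] < 1.0 and len(e) > 1:
            j = k + 1 if k + 1 < len(e) else k - 1
            e[j] += e[k]
            o[j] += o[k]
            del e[k], o[k]
            k = 0
        else:
            k += 1
    return np.asarray(o), np.asarray(e)


def sx2_item_fit(
    responses: pd.DataFrame,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
    alpha: float = 0.003,
    params_estimated: bool = True,
) -> ItemFitResult:
    """S-X2 fit statistic for every bank item.

    For each item, observed item-category frequencies conditional on the
    total summed score are compared with the model-implied conditionals

        P(X_i = k | S = s) proportional to
            sum_q w_q P_ik(theta_q) S_minus_i(s - k | theta_q),

    using the Lord-Wingersky recursion for the with- and without-item
    summed-score distributions integrated over the quadrature prior.
    Sparse score groups are merged (and near-empty category cells pooled)
    before the Pearson statistic; df = free cells minus, when
    *params_estimated* (the usual case: the bank was calibrated on these
    data), the item's parameter count.  Pass ``params_estimated=False``
    when scoring data against fixed, externally calibrated parameters.
    Items with p below *alpha* (default 0.003, a Bonferroni-style level
    for a 17-item scale) are flagged as misfitting.
    """
    data = responses[bank.ids].dropna().astype(int)
    n = len(data)
    if n < 50:
        raise ValueError("too few complete respondents for S-X2")
    arr = data.to_numpy()
    total = arr.sum(axis=1)
    nodes, w = grid.nodes, grid.weights
    items = list(bank)

    # full-bank summed-score distribution per node: (q, scores)
    full = lord_wingersky(items, nodes)
    s_min, s_max = bank.s_min, bank.s_max
    marg_full = w @ full  # P(S = s)

    rows_out = []
    for i, it in enumerate(items):
        others = [x for j, x in enumerate(items) if j != i]
        rest = lord_wingersky(others, nodes)  # scores (s_min-1 .. s_max-m)
        p_item = category_probabilities(it, nodes)  # (q, m)
        m = it.n_categories
        rest_min = s_min - 1  # the other items all at category 1

        scores = np.arange(s_min, s_max + 1)
        obs_rows, exp_rows = [], []
        for s in scores:
            n_s = int(np.sum(total == s))
            if n_s == 0:
                continue
            joint = np.zeros(m)
            for k in range(1, m + 1):
                idx = s - k - rest_min
                if 0 <= idx < rest.shape[-1]:
                    joint[k - 1] = w @ (p_item[:, k - 1] * rest[:, idx])
            denom = marg_full[s - s_min]
            cond = joint / denom if denom > 0 else np.zeros(m)
            o = np.array([np.sum((total == s) & (arr[:, i] == k))
                          for k in range(1, m + 1)], dtype=float)
            obs_rows.append(o)
            exp_rows.append(n_s * cond)

        # escalate row merging until expected counts are adequate:
        # every pooled cell >= 1 and at least 80% of cells >= 5
        min_count = 5.0
        while True:
            obs_c, exp_c = _collapse_rows(obs_rows, exp_rows, min_count)
            pooled = []
            for o, e in zip(obs_c, exp_c):
                o2, e2 = _collapse_categories_in_row(o, e)
                if e2.sum() > 0:  # renormalize to the observed row total
                    e2 = e2 * (o2.sum() / e2.sum())
                pooled.append((o2, e2))
            cells = np.concatenate([e2[e2 > 0] for _, e2 in pooled])
            adequate = cells.min() >= 1.0 and np.mean(cells >= 5.0) >= 0.8
            if adequate or len(obs_c) <= 3:
                break
            min_count *= 2
        stat, free_cells = 0.0, 0
        for o2, e2 in pooled:
            keep = e2 > 0
            stat += float(((o2[keep] - e2[keep]) ** 2 / e2[keep]).sum())
            free_cells += int(keep.sum()) - 1
        n_params = m if params_estimated else 0  # one slope + (m-1) thresholds
        df = free_cells - n_params
        p = float(chi2.sf(stat, df)) if df >= 1 else np.nan
        rows_out.append({"item": it.id, "statistic": stat, "df": df,
                         "p_value": p, "flagged": bool(p < alpha) if df >= 1 else False})

    table = pd.DataFrame(rows_out).set_index("item")
    return ItemFitResult(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# DIF by ordinal logistic regression


@dataclass
class DIFResult:
    table: pd.DataFrame  # per item: r2_change, flagged, note
    threshold: float


def _ordinal_llf(y: pd.Series, X: pd.DataFrame | None) -> float:
    if X is None or X.shape[1] == 0:
        counts = y.value_counts(normalize=True)
        return float((np.log(counts.loc[y.to_numpy()]).sum()))
    model = OrderedModel(y, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", disp=False, maxiter=200)
    return float(fit.llf)


def dif_scan(
    responses: pd.DataFrame,
    groups: pd.Series,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
    threshold: float = 0.02,
) -> DIFResult:
    """Screen every item for DIF between two groups.

    The matching variable is the full-pattern EAP theta.  Per item,
    proportional-odds models

        M0: X ~ theta          M2: X ~ theta + group + theta:group

    are fitted by maximum likelihood; the McFadden pseudo-R2 change
    (ll_M2 - ll_M0) / (-ll_null) pools uniform and non-uniform DIF and
    items at or above *threshold* (default 2%) are flagged.  Swapping
    the group labels leaves the change unchanged.
    """
    data = responses[bank.ids].dropna().astype(int)
    g = groups.loc[data.index]
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError("groups must be binary")
    if min((g == lv).sum() for lv in levels) < 2:
        raise ValueError("each group needs at least 2 members")
    gnum = (g == levels[1]).astype(float).to_numpy()
    theta = score_respondents(bank, data, grid)["theta"].to_numpy()

    rows = []
    for it in bank:
        y = data[it.id]
        if y.nunique() < 2:
            rows.append({"item": it.id, "r2_change": np.nan, "flagged": False,
                         "note": "degenerate item"})
            continue
        X0 = pd.DataFrame({"theta": theta}, index=data.index)
        X2 = pd.DataFrame({"theta": theta, "group": gnum,
                           "theta_x_group": theta * gnum}, index=data.index)
        try:
            ll_null = _ordinal_llf(y, None)
            ll0 = _ordinal_llf(y, X0)
            ll2 = _ordinal_llf(y, X2)
        except Exception as exc:  # separation / non-convergence
            rows.append({"item": it.id, "r2_change": np.nan, "flagged": False,
                         "note": f"fit failed: {type(exc).__name__}"})
            continue
        change = max(0.0, (ll2 - ll0) / (-ll_null))
        rows.append({"item": it.id, "r2_change": change,
                     "flagged": bool(change >= threshold), "note": ""})
    return DIFResult(pd.DataFrame(rows).set_index("item"), threshold)


# ---------------------------------------------------------------------------
# Disordered-threshold (never-modal category) diagnostic


def modal_category_check(
    bank: ItemBank,
    lo: float = -6.0,
    hi: float = 6.0,
    step: float = 0.01,
) -> dict[str, list[int]]:
    """Categories that are never the modal response anywhere on the grid.

    A well-separated graded item makes every category modal on some
    theta interval; a category that never dominates signals crowded
    (disordered-looking) thresholds.  Returns ``{item_id: [categories]}``
    with an entry for every item (empty list = no problem).
    """
    grid = theta_grid(lo, hi, step)
    out: dict[str, list[int]] = {}
    for it in bank:
        p = category_probabilities(it, grid)  # (g, m)
        modal = set(np.unique(np.argmax(p, axis=1) + 1))
        out[it.id] = [k for k in range(1, it.n_categories + 1) if k not in modal]
    return out
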