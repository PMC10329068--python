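"""Cohort simulation and CAT-version comparison reporting.

Generates synthetic cohorts (true thetas from a standard normal, the
latent calibration of the bundled bank; responses drawn from the GRM),
replays the adaptive algorithm post-hoc against each complete pattern
under several stopping rules, and aggregates the comparison a CAT
feasibility study reports: test-length distributions, score agreement
with the original sum-based 0-100 scores (RMSE, bias, Pearson r),
per-item exposure rates, and conditional test-length / standard-error
profiles by score decile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .bank import ItemBank
from .catsim import CATRecord, StoppingRule, run_cohort
from .estimation import DEFAULT_GRID, QuadratureGrid, score_respondents
from .grm import simulate_responses

__all__ = [
    "StudyReport",
    "SyntheticCohort",
    "compare_versions",
    "conditional_profiles",
    "exposure_rates",
    "generate_cohort",
]


@dataclass
class SyntheticCohort:
    """A simulated sample: true thetas, complete responses, scores."""

    thetas: np.ndarray
    responses: pd.DataFrame
    scores: pd.DataFrame  # output of score_respondents on the full pattern
    config: dict

    @property
    def n(self) -> int:
        return len(self.responses)


def generate_cohort(
    bank: ItemBank,
    n: int = 1408,
    seed: int | None = None,
    theta_mean: float = 0.0,
    theta_sd: float = 1.0,
    grid: QuadratureGrid = DEFAULT_GRID,
) -> SyntheticCohort:
    """Simulate *n* respondents with theta ~ N(theta_mean, theta_sd^2).

    The default cohort size matches the calibration-study sample
    (n = 1408) and the default latent distribution its standard-normal
    scaling.  Reproducible from (n, seed, mean, sd).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    thetas = rng.normal(theta_mean, theta_sd, size=n)
    responses = simulate_responses(bank, thetas, seed=rng)
    scores = score_respondents(bank, responses, grid)
    return SyntheticCohort(
        thetas=thetas,
        responses=responses,
        scores=scores,
        config={"n": n, "seed": seed, "theta_mean": theta_mean, "theta_sd": theta_sd},
    )


def exposure_rates(records: Sequence[CATRecord], bank: ItemBank) -> pd.Series:
    """Fraction of sessions in which each item was administered."""
    counts = {it.id: 0 for it in bank}
    for rec in records:
        for item_id in rec.administered:
            counts[item_id] += 1
    n = max(len(records), 1)
    return pd.Series({k: v / n for k, v in counts.items()}, name="exposure")


def conditional_profiles(
    records: Sequence[CATRecord],
    scores: Sequence[float] | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean test length and SE by decile of the estimated 0-100 score.

    *scores* defaults to each record's own final CAT score.  Bins are
    equal-count (populations within 1 of n / n_bins), ordered from the
    lowest-score decile (most limitation) upward.
    """
    if not records:
        raise ValueError("no CAT records")
    if scores is None:
        scores = [rec.score_0_100 for rec in records]
    scores = np.asarray(scores, dtype=float)
    if len(scores) < n_bins:
        raise ValueError("fewer respondents than bins")
    lengths = np.array([rec.n_items for rec in records], dtype=float)
    ses = np.array([rec.final.se for rec in records], dtype=float)
    order = np.argsort(scores, kind="stable")
    rows = []
    for d, idx in enumerate(np.array_split(order, n_bins), start=1):
        rows.append(
            {
                "decile": d,
                "n": len(idx),
                "mean_score": float(scores[idx].mean()),
                "mean_test_length": float(lengths[idx].mean()),
                "mean_se": float(ses[idx].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("decile")


def _version_metrics(
    cat_scores: np.ndarray,
    original: np.ndarray,
    lengths: np.ndarray,
) -> dict:
    diff = cat_scores - original
    r = float(pearsonr(cat_scores, original)[0])
    return {
        "mean_test_length": float(lengths.mean()),
        "min_test_length": int(lengths.min()),
        "max_test_length": int(lengths.max()),
        "score_mean": float(cat_scores.mean()),
        "score_sd": float(cat_scores.std(ddof=1)),
        "score_min": float(cat_scores.min()),
        "score_max": float(cat_scores.max()),
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "bias": float(diff.mean()),
        "r_with_original": r,
    }


def _criterion_correlations(
    scores: np.ndarray, criteria: pd.DataFrame, methods: Mapping[str, str]
) -> dict:
    out = {}
    for col in criteria.columns:
        vals = criteria[col].to_numpy(dtype=float)
        keep = ~np.isnan(vals)
        method = methods.get(col, "pearson")
        fn = spearmanr if method == "spearman" else pearsonr
        out[col] = {"method": method, "r": float(fn(scores[keep], vals[keep])[0])}
    return out


@dataclass
class StudyReport:
    """JSON-serializable comparison of CAT versions with the full test."""

    versions: dict = field(default_factory=dict)
    exposure: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    full_irt: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "versions": self.versions,
            "exposure": self.exposure,
            "profiles": self.profiles,
            "full_irt": self.full_irt,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        doc = json.loads(text)
        return cls(**doc)


def compare_versions(
    cohort: SyntheticCohort | pd.DataFrame,
    bank: ItemBank,
    rules: Sequence[StoppingRule],
    criteria: pd.DataFrame | None = None,
    criterion_methods: Mapping[str, str] | None = None,
    grid: QuadratureGrid = DEFAULT_GRID,
    n_bins: int = 10,
) -> StudyReport:
    """Post-hoc CAT comparison across stopping rules.

    *cohort* is a :class:`SyntheticCohort` or a complete respondent-
    by-item matrix.  Per rule (named ``CAT-<max_items>``): test-length
    summary, 0-100 score summary, RMSE / bias / Pearson r against the
    original sum-based scores, exposure rates and decile profiles.  The
    full-pattern IRT score enters as the ``full_irt`` reference row.
    Optional criterion columns are correlated with every version's
    scores (Pearson by default, Spearman per *criterion_methods*).
    """
    if isinstance(cohort, SyntheticCohort):
        responses = cohort.responses
        scores_full = cohort.scores
        config = dict(cohort.config)
    else:
        responses = cohort[bank.ids].dropna()
        scores_full = score_respondents(bank, responses, grid)
        config = {"n": len(responses)}
    if len(responses) < 2:
        raise ValueError("need at least 2 complete respondents")

    original = scores_full["original_0_100"].to_numpy()
    irt_full = scores_full["irt_0_100"].to_numpy()
    methods = dict(criterion_methods or {})

    report = StudyReport(config={**config, "rules": [
        {"se_threshold": r.se_threshold, "max_items": r.max_items,
         "min_items": r.min_items} for r in rules
    ]})

    diff = irt_full - original
    report.full_irt = {
        "mean_test_length": float(len(bank)),
        "score_mean": float(irt_full.mean()),
        "score_sd": float(irt_full.std(ddof=1)),
        "score_min": float(irt_full.min()),
        "score_max": float(irt_full.max()),
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "bias": float(diff.mean()),
        "r_with_original": float(pearsonr(irt_full, original)[0]),
    }
    if criteria is not None:
        report.full_irt["criteria"] = _criterion_correlations(irt_full, criteria, methods)

    for rule in rules:
        name = f"CAT-{rule.max_items}"
        records = run_cohort(bank, responses, rule, grid=grid)
        cat_scores = np.array([rec.score_0_100 for rec in records])
        lengths = np.array([rec.n_items for rec in records])
        metrics = _version_metrics(cat_scores, original, lengths)
        metrics["stop_reasons"] = dict(
            pd.Series([rec.stop_reason for rec in records]).value_counts()
        )
        metrics["stop_reasons"] = {k: int(v) for k, v in metrics["stop_reasons"].items()}
        if criteria is not None:
            metrics["criteria"] = _criterion_correlations(cat_scores, criteria, methods)
        report.versions[name] = metrics
        report.exposure[name] = {
            k: float(v) for k, v in exposure_rates(records, bank).items()
        }
        prof = conditional_profiles(records, n_bins=n_bins)
        report.profiles[name] = prof.reset_index().to_dict(orient="records")

    return report
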