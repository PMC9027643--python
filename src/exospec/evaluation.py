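"""Discrimination and association statistics for the risk models.

* ROC AUC as the Mann-Whitney concordance probability (ties count 1/2),
  with percentile confidence intervals from 1000 stratified bootstrap
  resamples (positives and negatives resampled separately).
* Paired one-sided bootstrap p-values for comparing two models' AUCs on
  the same patients.
* A cumulative-logit proportional-odds model of the ordinal biopsy
  outcome on the risk score, reported as an odds ratio per 0.1 score
  increase with a Wald 95% CI.
* Bias-corrected and accelerated (BCa) bootstrap intervals for
  between-group mean score differences, as used in estimation plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import bootstrap as _scipy_bootstrap
from scipy.stats import rankdata
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .strata import GleasonStratum

__all__ = [
    "Endpoint",
    "ENDPOINTS",
    "IntervalEstimate",
    "roc_auc",
    "auc_ci",
    "auc_diff_pvalue",
    "prop_odds_or",
    "bca_mean_diff",
]


@dataclass(frozen=True)
class Endpoint:
    """A binary clinical endpoint derived from the Gleason stratum."""

    name: str
    predicate: Callable[[GleasonStratum], bool]

    def labels(self, strata: Sequence[GleasonStratum]) -> np.ndarray:
        return np.array([self.predicate(s) for s in strata], dtype=bool)


ENDPOINTS: dict[str, Endpoint] = {
    "any_cancer": Endpoint("any_cancer", lambda s: s.any_cancer),
    "ge_3_4": Endpoint("ge_3_4", lambda s: s.ge_3_4),
    "ge_4_3": Endpoint("ge_4_3", lambda s: s.ge_4_3),
}


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "stratified_bootstrap"

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise ValueError(
                f"interval [{self.lower}, {self.upper}] does not contain point {self.point}"
            )


def _auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2 (midrank method)."""
    n_pos, n_neg = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    return (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _split(scores, endpoint, strata):
    scores = np.asarray(scores, dtype=float)
    labels = endpoint.labels(strata)
    if len(scores) != len(labels):
        raise ValueError("scores and strata lengths differ")
    if labels.all() or not labels.any():
        raise ValueError(f"endpoint {endpoint.name}: both classes must be present")
    return scores[labels], scores[~labels]


def roc_auc(scores, endpoint: Endpoint, strata: Sequence[GleasonStratum]) -> float:
    """AUC = probability a random positive outscores a random negative."""
    pos, neg = _split(scores, endpoint, strata)
    return float(_auc(pos, neg))


def auc_ci(
    scores,
    endpoint: Endpoint,
    strata: Sequence[GleasonStratum],
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> IntervalEstimate:
    """Percentile CI of the AUC from B stratified bootstrap resamples."""
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    pos, neg = _split(scores, endpoint, strata)
    rng = np.random.default_rng(seed)
    aucs = np.empty(B)
    for b in range(B):
        aucs[b] = _auc(
            pos[rng.integers(0, len(pos), len(pos))],
            neg[rng.integers(0, len(neg), len(neg))],
        )
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    point = _auc(pos, neg)
    return IntervalEstimate(
        float(point), float(min(lo, point)), float(max(hi, point)), level,
        "stratified_bootstrap",
    )


def auc_diff_pvalue(
    scores_a,
    scores_b,
    endpoint: Endpoint,
    strata: Sequence[GleasonStratum],
    B: int = 1000,
    seed: int = 0,
) -> float:
    """One-sided paired bootstrap p-value for AUC(a) > AUC(b).

    Both score vectors must be on the same patients; each stratified
    resample is shared so the comparison is paired.  p = (1 + #{resamples
    with AUC(a) - AUC(b) <= 0}) / (B + 1), never exactly zero.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if len(scores_a) != len(scores_b):
        raise ValueError("paired score vectors must have equal length")
    labels = endpoint.labels(strata)
    if labels.all() or not labels.any():
        raise ValueError(f"endpoint {endpoint.name}: both classes must be present")
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(B):
        p = pos_idx[rng.integers(0, len(pos_idx), len(pos_idx))]
        q = neg_idx[rng.integers(0, len(neg_idx), len(neg_idx))]
        delta = _auc(scores_a[p], scores_a[q]) - _auc(scores_b[p], scores_b[q])
        if delta <= 0:
            n_le += 1
    return (1 + n_le) / (B + 1)


def prop_odds_or(
    scores,
    strata: Sequence[GleasonStratum],
    unit: float = 0.1,
    level: float = 0.95,
) -> IntervalEstimate:
    """Proportional-odds OR per ``unit`` risk-score increase.

    Fits a cumulative-logit ordinal regression of the biopsy category
    (NC < 3+3 < 3+4 < 4+3 < >=4+4; the two no-cancer subtypes are merged)
    on the score and reports exp(unit * beta) with a Wald CI.
    """
    scores = np.asarray(scores, dtype=float)
    ordinals = np.array([s.ordinal for s in strata])
    if len(np.unique(ordinals)) < 3:
        raise ValueError("proportional-odds model needs at least 3 ordinal levels")
    endog = pd.Series(pd.Categorical(ordinals, categories=sorted(set(ordinals)), ordered=True))
    model = OrderedModel(endog, scores[:, None], distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=200, disp=False)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"ordinal regression did not converge: {res.mle_retvals}"
        )
    beta = float(np.asarray(res.params)[0])
    se = float(np.asarray(res.bse)[0])
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - level) / 2)
    return IntervalEstimate(
        float(np.exp(unit * beta)),
        float(np.exp(unit * (beta - z * se))),
        float(np.exp(unit * (beta + z * se))),
        level,
        "wald",
    )


def bca_mean_diff(
    group_a,
    group_b,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> IntervalEstimate:
    """BCa bootstrap interval for mean(group_b) - mean(group_a).

    Bias correction comes from the proportion of bootstrap statistics
    below the point estimate; acceleration from jackknife skewness.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")

    def stat(b_s, a_s, axis=-1):
        return np.mean(b_s, axis=axis) - np.mean(a_s, axis=axis)

    res = _scipy_bootstrap(
        (b, a),
        stat,
        n_resamples=B,
        method="BCa",
        confidence_level=level,
        rng=np.random.default_rng(seed),
        vectorized=True,
    )
    point = float(b.mean() - a.mean())
    lo = float(res.confidence_interval.low)
    hi = float(res.confidence_interval.high)
    return IntervalEstimate(
        point, min(lo, point), max(hi, point), level, "bca_bootstrap"
    )
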