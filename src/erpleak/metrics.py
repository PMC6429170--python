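"""Evaluation metrics: cross-validated perceived information, bootstrap
confidence intervals, per-tag success rate and average rank.

Perceived information (PI) measures, in bits, how much a *fitted* model
extracts about the class variable from the observations:

    PI = H[P] + sum_p Pr[p] * E_{o|p}[ log2 Pr_model[p | o] ]

With a perfect model PI equals the mutual information; estimation and
assumption errors can only lower it, and a misleading model drives it
negative.  The expectation is estimated by k-fold cross-validation (default:
leave-one-out): the model is fitted on each profiling set and the log2
posterior of the true class evaluated on the held-out observations.  The
per-observation log terms are pooled over folds and the class weights applied
once, which coincides with fold averaging for equal-size folds and remains
well defined for leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import density as dens

__all__ = [
    "CVPlan", "PIResult", "AttackReport",
    "make_cv", "cv_posteriors", "estimate_pi", "bootstrap_ci",
    "pi_from_log_terms", "model_posteriors", "true_class_log_terms",
    "success_rate", "average_rank",
]

_LN2 = np.log(2.0)


@dataclass
class CVPlan:
    """Non-overlapping, exhaustive fold assignment (default: leave-one-out)."""

    folds: list                  # list of test-index arrays
    n: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate([np.asarray(f) for f in self.folds])
        if sorted(all_idx.tolist()) != list(range(self.n)):
            raise ValueError("folds must partition the observations exactly")

    @property
    def k(self) -> int:
        return len(self.folds)


def make_cv(n: int, k: Optional[int] = None, labels: Optional[np.ndarray] = None,
            seed: Optional[int] = None) -> CVPlan:
    """Build a CV plan.  ``k=None`` (or ``k >= n``) gives leave-one-out;
    otherwise stratified k-fold (stratified on ``labels`` when given)."""
    if k is None or k >= n:
        return CVPlan(folds=[np.array([i]) for i in range(n)], n=n)
    if labels is None:
        labels = np.zeros(n, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros((n, 1)), labels)]
    return CVPlan(folds=folds, n=n)


def cv_posteriors(
    scores: np.ndarray,
    labels: np.ndarray,
    cv: Optional[CVPlan] = None,
    backend: str = "kde",
    prior_mode: str = "uniform",
    clip_floor: Optional[float] = None,
) -> tuple[dens.PosteriorArray, np.ndarray]:
    """Held-out posteriors for every observation under cross-validation.

    For each fold the density model is fitted on the profiling set and the
    posterior computed on the fold's test observations, so no observation is
    scored by a model that saw it.  Returns the assembled posterior array and
    the matching log2-posterior matrix (computed in the log domain; if
    ``clip_floor`` is set the posteriors are floored first and the log terms
    taken on the clipped values).
    """
    scores = dens._as_scores(scores)
    labels = np.asarray(labels)
    n = scores.shape[0]
    classes = np.unique(labels)
    if cv is None:
        cv = make_cv(n)
    probs = np.empty((n, classes.size))
    log2_post = np.empty((n, classes.size))
    for test in cv.folds:
        test = np.asarray(test)
        train = np.setdiff1d(np.arange(n), test)
        train_labels = labels[train]
        if np.unique(train_labels).size < classes.size:
            raise ValueError("a fold's profiling set does not contain every class")
        model = dens.fit(scores[train], train_labels, backend=backend)
        ll2 = dens.log2_likelihood(model, scores[test])
        ln = ll2 * _LN2
        if prior_mode == "empirical":
            ln = ln + np.log(model.priors)[None, :]
        log_norm = logsumexp(ln, axis=1, keepdims=True)
        lp = (ln - log_norm) / _LN2              # exact log2 posteriors
        probs[test] = np.exp(lp * _LN2)
        log2_post[test] = lp
    post = dens.PosteriorArray(probs=probs, classes=classes, prior_mode=prior_mode)
    if clip_floor is not None:
        post = dens.clip_posteriors(post, floor=clip_floor)
        log2_post = np.log2(post.probs)
    return post, log2_post


@dataclass
class PIResult:
    """Point estimate, prior entropy and bootstrap interval of the PI."""

    pi: float
    h_prior: float
    ci_low: float
    ci_high: float
    log_terms: np.ndarray        # per observation: log2 Pr_model[true class | o]
    labels: np.ndarray
    classes: np.ndarray
    weights: np.ndarray          # class weights used in the PI sum
    n_per_class: np.ndarray


def _pi_functional(log_terms: np.ndarray, labels: np.ndarray,
                   classes: np.ndarray, weights: np.ndarray,
                   h_prior: float) -> float:
    total = h_prior
    for c, w in zip(classes, weights):
        total += w * log_terms[labels == c].mean()
    return float(total)


def bootstrap_ci(
    log_terms: np.ndarray,
    labels: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
    h_prior: float = 0.0,
    B: int = 100,
    percentiles: tuple = (5, 95),
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval of the PI functional.

    ``B`` resamples with replacement of the per-observation log terms,
    resampled *within class* so the class weighting of the functional is
    preserved; the interval endpoints are the requested percentiles of the
    ``B`` recomputed statistics.
    """
    log_terms = np.asarray(log_terms, dtype=float)
    if log_terms.size < 2:
        raise ValueError("bootstrap needs at least 2 log terms")
    if labels is None:
        labels = np.zeros(log_terms.size, dtype=int)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if weights is None:
        weights = np.array([(labels == c).mean() for c in classes])
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    groups = [log_terms[labels == c] for c in classes]
    for b in range(B):
        total = h_prior
        for g, w in zip(groups, weights):
            total += w * rng.choice(g, size=g.size, replace=True).mean()
        stats[b] = total
    lo, hi = np.percentile(stats, percentiles)
    return float(lo), float(hi)


def true_class_log_terms(log2_post: np.ndarray, labels: np.ndarray,
                         classes: np.ndarray) -> np.ndarray:
    """Extract each observation's log2 posterior of its true class."""
    class_col = {c: i for i, c in enumerate(classes)}
    idx = np.array([class_col[c] for c in labels])
    return log2_post[np.arange(len(labels)), idx]


def pi_from_log_terms(
    log_terms: np.ndarray,
    labels: np.ndarray,
    pi_priors: str = "empirical",
    B: int = 100,
    percentiles: tuple = (5, 95),
    seed: int = 0,
) -> PIResult:
    """Assemble the PI point estimate and bootstrap CI from per-observation
    log2 posterior-of-true-class terms."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in classes])
    if pi_priors == "empirical":
        weights = counts / counts.sum()
    elif pi_priors == "uniform":
        weights = np.full(classes.size, 1.0 / classes.size)
    else:
        raise ValueError("pi_priors must be 'empirical' or 'uniform'")
    h_prior = float(-(weights * np.log2(weights)).sum())
    pi = _pi_functional(log_terms, labels, classes, weights, h_prior)
    ci_low, ci_high = bootstrap_ci(log_terms, labels, weights, h_prior,
                                   B=B, percentiles=percentiles, seed=seed)
    return PIResult(
        pi=pi, h_prior=h_prior, ci_low=ci_low, ci_high=ci_high,
        log_terms=log_terms, labels=labels, classes=classes,
        weights=weights, n_per_class=counts,
    )


def model_posteriors(
    model,
    scores: np.ndarray,
    prior_mode: str = "uniform",
    clip_floor: Optional[float] = None,
) -> tuple:
    """Posteriors and log2 posteriors of a fixed (already fitted) model.

    Same output contract as :func:`cv_posteriors`, used when a model profiled
    elsewhere is applied to fresh observations (portability scenarios).
    """
    ll2 = dens.log2_likelihood(model, scores)
    ln = ll2 * _LN2
    if prior_mode == "empirical":
        ln = ln + np.log(model.priors)[None, :]
    lp = (ln - logsumexp(ln, axis=1, keepdims=True)) / _LN2
    post = dens.PosteriorArray(probs=np.exp(lp * _LN2),
                               classes=model.classes.copy(), prior_mode=prior_mode)
    log2_post = lp
    if clip_floor is not None:
        post = dens.clip_posteriors(post, floor=clip_floor)
        log2_post = np.log2(post.probs)
    return post, log2_post


def estimate_pi(
    scores: np.ndarray,
    labels: np.ndarray,
    cv: Optional[CVPlan] = None,
    backend: str = "kde",
    prior_mode: str = "uniform",
    pi_priors: str = "empirical",
    clip_floor: Optional[float] = None,
    B: int = 100,
    percentiles: tuple = (5, 95),
    seed: int = 0,
) -> PIResult:
    """Cross-validated PI estimate with a bootstrap confidence interval.

    ``prior_mode`` controls the Bayes inversion inside the log (uniform =
    maximum likelihood, the attack default); ``pi_priors`` controls the class
    weighting of the PI sum and of H[P] (default: empirical frequencies,
    about 1/6 and 5/6 in PIN mode).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    _, log2_post = cv_posteriors(scores, labels, cv=cv, backend=backend,
                                 prior_mode=prior_mode, clip_floor=clip_floor)
    log_terms = true_class_log_terms(log2_post, labels, classes)
    return pi_from_log_terms(log_terms, labels, pi_priors=pi_priors,
                             B=B, percentiles=percentiles, seed=seed)


@dataclass
class AttackReport:
    """Security-metric curves of one profiled attack."""

    success: pd.DataFrame        # columns: tag, q, success_rate
    avg_rank: pd.DataFrame       # columns: q, avg_rank
    q_grid: Sequence[int]
    resamples: int
    seed: int


def _draws(rng: np.random.Generator, pool_size: int, q: int, R: int) -> np.ndarray:
    """R independent draws of q distinct indices from ``range(pool_size)``."""
    return np.argsort(rng.random((R, pool_size)), axis=1)[:, :q]


def success_rate(
    log2_post: np.ndarray,
    classes: np.ndarray,
    tags: np.ndarray,
    q_grid: Sequence[int],
    R: int = 1000,
    seed: int = 0,
    real_tag: int = 1,
) -> pd.DataFrame:
    """Per-tag probability of classifying q pooled observations correctly.

    For each tag and each q, q observations of that tag are drawn without
    replacement; the attack succeeds when the product of the true-class
    posteriors exceeds the product of the wrong-class posteriors (computed as
    a sum of log2 terms).  Averaged over ``R`` draws.
    """
    rng = np.random.default_rng(seed)
    tags = np.asarray(tags)
    col = {c: i for i, c in enumerate(classes)}
    rows = []
    for tag in np.unique(tags):
        pool = np.flatnonzero(tags == tag)
        p_true = 1 if tag == real_tag else 0
        delta = log2_post[pool, col[p_true]] - log2_post[pool, col[1 - p_true]]
        for q in q_grid:
            if q > pool.size:
                raise ValueError(f"q={q} exceeds the {pool.size} observations of tag {tag}")
            sel = _draws(rng, pool.size, q, R)
            wins = delta[sel].sum(axis=1) > 0
            rows.append({"tag": int(tag), "q": int(q),
                         "success_rate": float(wins.mean())})
    return pd.DataFrame(rows)


def average_rank(
    log2_post_real: np.ndarray,
    tags: np.ndarray,
    q_grid: Sequence[int],
    R: int = 1000,
    seed: int = 0,
    real_tag: int = 1,
) -> pd.DataFrame:
    """Average rank of the familiar code among all tags.

    Every tag is scored with the *real-code* model only: per draw, each tag
    contributes the sum over its q sampled observations of
    log2 Pr_model[p=1 | o]; tags are sorted by decreasing score and the rank
    of the true familiar tag recorded (ties averaged).  1 is a perfect
    attack, (n_tags + 1) / 2 is chance.
    """
    rng = np.random.default_rng(seed)
    tags = np.asarray(tags)
    tag_values = np.unique(tags)
    pools = [np.flatnonzero(tags == t) for t in tag_values]
    real_pos = int(np.flatnonzero(tag_values == real_tag)[0])
    rows = []
    for q in q_grid:
        scores = np.empty((R, tag_values.size))
        for ti, pool in enumerate(pools):
            if q > pool.size:
                raise ValueError(f"q={q} exceeds the {pool.size} observations of tag {tag_values[ti]}")
            sel = _draws(rng, pool.size, q, R)
            scores[:, ti] = log2_post_real[pool][sel].sum(axis=1)
        ranks = rankdata(-scores, axis=1, method="average")
        rows.append({"q": int(q), "avg_rank": float(ranks[:, real_pos].mean())})
    return pd.DataFrame(rows)
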