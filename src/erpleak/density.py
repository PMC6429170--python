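"""Class-conditional density models, Bayes inversion and outlier clipping.

After PCA the components are orthogonal; treating them additionally as
independent reduces the N_d-variate density estimation per class to N_d
univariate ones.  Two backends are provided: a nonparametric Gaussian-kernel
KDE with Silverman's rule-of-thumb bandwidth (the default — no distributional
assumption), and Gaussian templates (mean/SD per class and dimension).
All likelihoods are handled in the log domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ClassConditionalDensity", "PosteriorArray",
    "silverman_bandwidth", "fit", "log2_likelihood", "posterior", "clip_posteriors",
]

_LN2 = np.log(2.0)
#: Per-dimension floor on log2 densities; keeps extreme outliers finite.
LOG2_DENSITY_FLOOR = -1000.0


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule-of-thumb: ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``.

    Sample SD uses the n-1 denominator; the IQR uses linear interpolation.
    If the IQR is zero from heavy ties but the SD is positive, the SD alone is
    used; a fully degenerate sample (zero spread) is an error.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("bandwidth needs at least 2 samples")
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if sd <= 0:
        raise ValueError("zero spread: cannot set a kernel bandwidth")
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


@dataclass
class ClassConditionalDensity:
    """Per-class, per-dimension univariate density models with class priors.

    ``backend='kde'`` stores the training samples and a Silverman bandwidth per
    (class, dimension); ``backend='gaussian'`` stores mean and SD.  ``priors``
    are the empirical class frequencies of the training set (used when the
    posterior is computed in maximum-a-posteriori mode).
    """

    classes: np.ndarray                       # (n_classes,)
    priors: np.ndarray                        # (n_classes,), sums to 1
    backend: str                              # "kde" | "gaussian"
    n_d: int
    kde_samples: Optional[list] = None        # [class][dim] -> 1-D array
    kde_bandwidths: Optional[np.ndarray] = None  # (n_classes, n_d)
    means: Optional[np.ndarray] = None        # (n_classes, n_d)
    sds: Optional[np.ndarray] = None          # (n_classes, n_d)

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")

    def class_index(self, label) -> int:
        return int(np.flatnonzero(self.classes == label)[0])

    def to_json(self, path) -> None:
        d = {
            "classes": self.classes.tolist(),
            "priors": self.priors.tolist(),
            "backend": self.backend,
            "n_d": self.n_d,
        }
        if self.backend == "kde":
            d["kde_samples"] = [[s.tolist() for s in per_class]
                                for per_class in self.kde_samples]
            d["kde_bandwidths"] = self.kde_bandwidths.tolist()
        else:
            d["means"] = self.means.tolist()
            d["sds"] = self.sds.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "ClassConditionalDensity":
        with open(path) as fh:
            d = json.load(fh)
        kw = dict(
            classes=np.asarray(d["classes"]),
            priors=np.asarray(d["priors"], dtype=float),
            backend=d["backend"],
            n_d=d["n_d"],
        )
        if d["backend"] == "kde":
            kw["kde_samples"] = [[np.asarray(s, dtype=float) for s in per_class]
                                 for per_class in d["kde_samples"]]
            kw["kde_bandwidths"] = np.asarray(d["kde_bandwidths"], dtype=float)
        else:
            kw["means"] = np.asarray(d["means"], dtype=float)
            kw["sds"] = np.asarray(d["sds"], dtype=float)
        return cls(**kw)


@dataclass
class PosteriorArray:
    """Model posteriors Pr_model[class | o] per observation (rows) and class."""

    probs: np.ndarray            # (n_obs, n_classes)
    classes: np.ndarray
    prior_mode: str              # "uniform" | "empirical"
    clipped: bool = False


def _as_scores(x: np.ndarray) -> np.ndarray:
    """Coerce to (n_obs, n_d); 1-D input is interpreted as n_obs scalars."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("scores must be 1-D or 2-D")
    return x


def fit(scores: np.ndarray, labels: np.ndarray, backend: str = "kde") -> ClassConditionalDensity:
    """Fit per-class, per-dimension univariate models on projected scores."""
    scores = _as_scores(scores)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes to profile")
    n, n_d = scores.shape
    priors = np.array([(labels == c).sum() for c in classes], dtype=float) / n

    if backend == "kde":
        kde_samples, bws = [], np.empty((classes.size, n_d))
        for ci, c in enumerate(classes):
            rows = scores[labels == c]
            if rows.shape[0] < 2:
                raise ValueError(f"class {c} has fewer than 2 samples")
            per_dim = []
            for d in range(n_d):
                x = rows[:, d]
                bws[ci, d] = silverman_bandwidth(x)
                per_dim.append(x.copy())
            kde_samples.append(per_dim)
        return ClassConditionalDensity(
            classes=classes, priors=priors, backend="kde", n_d=n_d,
            kde_samples=kde_samples, kde_bandwidths=bws,
        )
    elif backend == "gaussian":
        means = np.empty((classes.size, n_d))
        sds = np.empty((classes.size, n_d))
        for ci, c in enumerate(classes):
            rows = scores[labels == c]
            if rows.shape[0] < 2:
                raise ValueError(f"class {c} has fewer than 2 samples")
            means[ci] = rows.mean(axis=0)
            sds[ci] = rows.std(axis=0, ddof=1)
            if np.any(sds[ci] <= 0):
                raise ValueError(f"class {c} has zero spread in some dimension")
        return ClassConditionalDensity(
            classes=classes, priors=priors, backend="gaussian", n_d=n_d,
            means=means, sds=sds,
        )
    raise ValueError(f"unknown backend {backend!r}")


def _kde_log_density(x: np.ndarray, train: np.ndarray, h: float) -> np.ndarray:
    """Natural-log Gaussian-KDE density of points ``x`` given ``train``."""
    z = (x[:, None] - train[None, :]) / h
    return logsumexp(-0.5 * z * z, axis=1) - np.log(train.size * h * np.sqrt(2 * np.pi))


def log2_likelihood(model: ClassConditionalDensity, scores: np.ndarray) -> np.ndarray:
    """log2 of the product over dimensions of the univariate class densities.

    Each per-dimension log2 density is floored at ``LOG2_DENSITY_FLOOR``
    before summing, which keeps the sum finite for arbitrarily extreme
    observations.  Returns an (n_obs, n_classes) array.
    """
    scores = _as_scores(scores)
    if scores.shape[1] != model.n_d:
        raise ValueError(
            f"model has n_d={model.n_d}, scores have {scores.shape[1]} dimensions"
        )
    n = scores.shape[0]
    out = np.zeros((n, model.classes.size))
    for ci in range(model.classes.size):
        for d in range(model.n_d):
            if model.backend == "kde":
                ln = _kde_log_density(
                    scores[:, d], model.kde_samples[ci][d], model.kde_bandwidths[ci, d]
                )
            else:
                mu, sd = model.means[ci, d], model.sds[ci, d]
                z = (scores[:, d] - mu) / sd
                ln = -0.5 * z * z - np.log(sd * np.sqrt(2 * np.pi))
            out[:, ci] += np.maximum(ln / _LN2, LOG2_DENSITY_FLOOR)
    return out


def posterior(model: ClassConditionalDensity, scores: np.ndarray,
              prior_mode: str = "uniform") -> PosteriorArray:
    """Bayes inversion of the class-conditional densities.

    ``prior_mode='uniform'`` drops the prior term (maximum-likelihood mode,
    the default for attacks — it avoids the heavy a-priori bias toward the
    random-code class); ``'empirical'`` uses the training-set frequencies.
    Rows sum to one.
    """
    if prior_mode not in ("uniform", "empirical"):
        raise ValueError("prior_mode must be 'uniform' or 'empirical'")
    ll2 = log2_likelihood(model, scores)          # log2 f(o|c)
    ln = ll2 * _LN2
    if prior_mode == "empirical":
        ln = ln + np.log(model.priors)[None, :]
    ln -= ln.max(axis=1, keepdims=True)
    probs = np.exp(ln)
    probs /= probs.sum(axis=1, keepdims=True)
    return PosteriorArray(probs=probs, classes=model.classes.copy(),
                          prior_mode=prior_mode)


def clip_posteriors(post: PosteriorArray, floor: float = 0.001) -> PosteriorArray:
    """Raise posterior entries below ``floor`` to ``floor`` (no renormalization).

    This bounds the weight of outlier log-probabilities in the information
    estimate; it is intended for raw-PCA pipelines, where outliers are a known
    hazard of the less informative projection.
    """
    if not (0 < floor < 0.5):
        raise ValueError("floor must lie in (0, 0.5)")
    return PosteriorArray(
        probs=np.maximum(post.probs, floor),
        classes=post.classes.copy(),
        prior_mode=post.prior_mode,
        clipped=True,
    )
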