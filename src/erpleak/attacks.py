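"""Orchestrated attack scenarios.

Four adversaries are evaluated, all on top of the same pipeline
(bandpass -> blink rejection -> electrode concatenation -> PCA -> per-class
densities -> Bayes):

* **profiled** — the adversary owns labelled observations of the target and
  fits the real-vs-random model by leave-one-out cross-validation;
* **non-profiled** — no labels: the PI metric is estimated once per assumed
  familiar tag with on-the-fly models, and the tag with maximal PI wins;
* **portability** — a model profiled on one user (or pooled over all other
  users) is applied to a fresh user;
* **identification** — the class variable is the user identity rather than
  the code, estimating PI(U; O) from real-code epochs of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import density as dens
from . import dimred, metrics
from .preprocess import ObservationSet, bandpass, reject_artifacts, select_concat
from .simulate import EpochSet

__all__ = [
    "ProfiledResult", "NonProfiledResult", "IdentificationResult",
    "preprocess_session", "reduce_observations", "pin_labels",
    "profiled_attack", "pi_learning_curve", "nonprofiled_attack",
    "fit_profile_model", "portability_attack", "all_against_one",
    "identify_user",
]


def pin_labels(tags: np.ndarray, real_tag: int = 1) -> np.ndarray:
    """Binary real(1)/random(0) labels from presentation tags."""
    return (np.asarray(tags) == real_tag).astype(int)


def preprocess_session(
    session: EpochSet,
    channels: Sequence[str] = ("P7", "P8"),
    lo: float = 0.5,
    hi: float = 30.0,
    reject: bool = True,
    threshold: float = 100.0,
) -> ObservationSet:
    """Standard preprocessing: blink rejection, bandpass, channel concatenation.

    Filtering is a per-channel operation, so only the selected channels are
    filtered (the result on those channels is identical to filtering the full
    montage); rejection uses the EOG channels before they are dropped.
    """
    if reject:
        session, _ = reject_artifacts(session, threshold=threshold)
    session = session.subset_channels(channels)
    session = bandpass(session, lo=lo, hi=hi)
    return select_concat(session, channels=channels)


def reduce_observations(obs: ObservationSet, variant: str = "average",
                        n_d: int = 5) -> dimred.ReducedObservations:
    """Project observations with the requested PCA variant."""
    if variant == "average":
        basis = dimred.average_pca(dimred.tag_means(obs), n_d=n_d)
    elif variant == "raw":
        basis = dimred.raw_pca(obs, n_d=n_d)
    else:
        raise ValueError("variant must be 'average' or 'raw'")
    return dimred.project(obs, basis)


def _clip_floor_for(variant: str, clip: object) -> Optional[float]:
    """Outlier clipping is applied for raw-PCA pipelines only, unless overridden."""
    if clip == "auto":
        return 0.001 if variant == "raw" else None
    return clip


@dataclass
class ProfiledResult:
    """Outcome of a supervised evaluation of one session."""

    pi: metrics.PIResult
    report: metrics.AttackReport
    learning_curve: Optional[pd.DataFrame]
    variant: str
    backend: str
    reduced: dimred.ReducedObservations


def profiled_attack(
    session: EpochSet,
    variant: str = "average",
    backend: str = "kde",
    prior_mode: str = "uniform",
    n_d: int = 5,
    channels: Sequence[str] = ("P7", "P8"),
    clip: object = "auto",
    q_grid: Sequence[int] = (1, 2, 5, 10, 20, 40),
    R: int = 1000,
    B: int = 100,
    seed: int = 0,
    learning_curve_sizes: Optional[Sequence[int]] = None,
) -> ProfiledResult:
    """Full supervised evaluation with leave-one-out cross-validation.

    Returns the PI estimate with its bootstrap CI, the per-tag success-rate
    and average-rank curves over ``q_grid`` (computed from the held-out
    posteriors, so no observation is scored by a model that saw it), and
    optionally the PI-vs-profiling-set-size learning curve.
    """
    obs = preprocess_session(session, channels=channels)
    reduced = reduce_observations(obs, variant=variant, n_d=n_d)
    labels = pin_labels(reduced.tags)
    clip_floor = _clip_floor_for(variant, clip)
    _, log2_post = metrics.cv_posteriors(
        reduced.scores, labels, backend=backend,
        prior_mode=prior_mode, clip_floor=clip_floor,
    )
    classes = np.unique(labels)
    log_terms = metrics.true_class_log_terms(log2_post, labels, classes)
    pi = metrics.pi_from_log_terms(log_terms, labels, B=B, seed=seed)
    success = metrics.success_rate(log2_post, classes, reduced.tags, q_grid,
                                   R=R, seed=seed)
    real_col = int(np.flatnonzero(classes == 1)[0])
    rank = metrics.average_rank(log2_post[:, real_col], reduced.tags, q_grid,
                                R=R, seed=seed)
    report = metrics.AttackReport(success=success, avg_rank=rank,
                                  q_grid=list(q_grid), resamples=R, seed=seed)
    curve = None
    if learning_curve_sizes is not None:
        curve = pi_learning_curve(
            reduced.scores, labels, learning_curve_sizes,
            backend=backend, prior_mode=prior_mode,
            clip_floor=clip_floor, B=B, seed=seed,
        )
    return ProfiledResult(pi=pi, report=report, learning_curve=curve,
                          variant=variant, backend=backend, reduced=reduced)


def pi_learning_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    sizes: Sequence[int],
    backend: str = "kde",
    prior_mode: str = "uniform",
    clip_floor: Optional[float] = None,
    B: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """PI of models fitted on growing profiling sets, tested on the rest.

    For each size a class-stratified profiling subset is drawn, a single model
    fitted, and the PI evaluated on the held-out observations.  Tracks how
    many observations the offline profiling phase needs before the model
    becomes informative.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    n = labels.size
    classes = np.unique(labels)
    rows = []
    for m in sizes:
        if not (4 <= m < n):
            raise ValueError(f"profiling size {m} out of range [4, {n})")
        prof_idx = []
        for c in classes:
            pool = np.flatnonzero(labels == c)
            take = max(2, int(round(m * pool.size / n)))
            prof_idx.append(rng.choice(pool, size=min(take, pool.size - 2),
                                       replace=False))
        prof_idx = np.concatenate(prof_idx)
        test_idx = np.setdiff1d(np.arange(n), prof_idx)
        model = dens.fit(np.asarray(scores)[prof_idx], labels[prof_idx],
                         backend=backend)
        _, log2_post = metrics.model_posteriors(
            model, np.asarray(scores)[test_idx], prior_mode=prior_mode,
            clip_floor=clip_floor,
        )
        log_terms = metrics.true_class_log_terms(log2_post, labels[test_idx],
                                                 model.classes)
        res = metrics.pi_from_log_terms(log_terms, labels[test_idx],
                                        B=B, seed=seed)
        rows.append({"size": int(prof_idx.size), "pi": res.pi,
                     "ci_low": res.ci_low, "ci_high": res.ci_high})
    return pd.DataFrame(rows)


@dataclass
class NonProfiledResult:
    """Six-way on-the-fly PI sweep over the assumed familiar tag."""

    pi_by_tag: dict              # assumed tag -> PIResult
    ranking: list                # tags sorted by decreasing PI
    q: int

    @property
    def winner(self) -> int:
        return self.ranking[0]


def _stratified_parts(rng: np.random.Generator, tags: np.ndarray,
                      splits: int, q: Optional[int]) -> list[np.ndarray]:
    """Disjoint parts (no resampling), tag-stratified; optionally truncated so
    each part holds about ``q`` epochs with balanced tags."""
    parts = [[] for _ in range(splits)]
    for t in np.unique(tags):
        pool = rng.permutation(np.flatnonzero(tags == t))
        for s in range(splits):
            chunk = pool[s::splits]
            if q is not None:
                per_tag = int(np.ceil(q / np.unique(tags).size))
                chunk = chunk[:per_tag]
            parts[s].append(chunk)
    out = []
    for s in range(splits):
        idx = np.concatenate(parts[s])
        if q is not None and idx.size > q:
            idx = idx[:q]
        out.append(np.sort(idx))
    return out


def nonprofiled_attack(
    obs: ObservationSet,
    q: Optional[int] = None,
    splits: int = 1,
    variant: str = "average",
    backend: str = "kde",
    prior_mode: str = "uniform",
    n_d: int = 5,
    clip: object = "auto",
    B: int = 100,
    seed: int = 0,
) -> list[NonProfiledResult]:
    """Unsupervised attack: one PI estimate per assumed familiar tag.

    The observation set is split into ``splits`` disjoint parts (without
    resampling); within each part and for every assumed tag t the binary
    labels 1{tag = t} are formed, a model is estimated on-the-fly under
    leave-one-out cross-validation, and the PI recorded with its bootstrap
    CI.  The attack's guess is the tag attaining the maximal PI.
    """
    rng = np.random.default_rng(seed)
    tag_values = np.unique(obs.tags)
    parts = _stratified_parts(rng, obs.tags, splits, q)
    results = []
    for idx in parts:
        sub = ObservationSet(
            vectors=obs.vectors[idx], tags=obs.tags[idx], user_id=obs.user_id,
            channels=list(obs.channels), epoch_len=obs.epoch_len, fs=obs.fs,
        )
        counts = np.array([(sub.tags == t).sum() for t in tag_values])
        if counts.min() < 3:
            raise ValueError(
                f"subset too small for on-the-fly cross-validation: "
                f"a tag has only {counts.min()} epochs (need >= 3)"
            )
        reduced = reduce_observations(sub, variant=variant, n_d=n_d)
        clip_floor = _clip_floor_for(variant, clip)
        pi_by_tag = {}
        for t in tag_values:
            labels = pin_labels(sub.tags, real_tag=int(t))
            pi_by_tag[int(t)] = metrics.estimate_pi(
                reduced.scores, labels, backend=backend, prior_mode=prior_mode,
                clip_floor=clip_floor, B=B, seed=seed,
            )
        ranking = sorted(pi_by_tag, key=lambda t: pi_by_tag[t].pi, reverse=True)
        results.append(NonProfiledResult(pi_by_tag=pi_by_tag, ranking=ranking,
                                         q=int(idx.size)))
    return results


def fit_profile_model(
    session: EpochSet,
    variant: str = "average",
    backend: str = "kde",
    n_d: int = 5,
    channels: Sequence[str] = ("P7", "P8"),
) -> tuple[dimred.ProjectionBasis, dens.ClassConditionalDensity]:
    """Profile one user with the maximum profiling set: returns the projection
    basis and the fitted real-vs-random density model, both serializable."""
    obs = preprocess_session(session, channels=channels)
    reduced = reduce_observations(obs, variant=variant, n_d=n_d)
    model = dens.fit(reduced.scores, pin_labels(reduced.tags), backend=backend)
    return reduced.basis, model


def portability_attack(
    model: dens.ClassConditionalDensity,
    basis: dimred.ProjectionBasis,
    obs: ObservationSet,
    prior_mode: str = "uniform",
    clip: object = "auto",
    B: int = 100,
    seed: int = 0,
) -> metrics.PIResult:
    """Apply a model profiled on one user to another user's observations.

    The target's observations are projected with the *source* user's basis
    and scored with the source model; the PI is evaluated against the
    target's true labels.  Negative PI means the transferred model misleads.
    """
    if obs.dim != basis.dim:
        raise ValueError(
            f"montage/epoch mismatch: observations have D={obs.dim}, "
            f"basis expects D={basis.dim}"
        )
    reduced = dimred.project(obs, basis)
    clip_floor = _clip_floor_for(basis.source, clip)
    labels = pin_labels(reduced.tags)
    _, log2_post = metrics.model_posteriors(model, reduced.scores,
                                            prior_mode=prior_mode,
                                            clip_floor=clip_floor)
    log_terms = metrics.true_class_log_terms(log2_post, labels, model.classes)
    return metrics.pi_from_log_terms(log_terms, labels, B=B, seed=seed)


def all_against_one(
    sessions: Sequence[EpochSet],
    target: int,
    variant: str = "average",
    backend: str = "kde",
    n_d: int = 5,
    channels: Sequence[str] = ("P7", "P8"),
    prior_mode: str = "uniform",
    clip: object = "auto",
    B: int = 100,
    seed: int = 0,
) -> metrics.PIResult:
    """Target one user with a model profiled on all the other users pooled.

    The non-target sessions' observations are concatenated, the basis and a
    single density model are fitted on the pool, and the PI is evaluated on
    the target's observations.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 1 non-target user")
    others = [preprocess_session(s, channels=channels)
              for i, s in enumerate(sessions) if i != target]
    pooled = ObservationSet(
        vectors=np.vstack([o.vectors for o in others]),
        tags=np.concatenate([o.tags for o in others]),
        user_id=-1,
        channels=list(others[0].channels),
        epoch_len=others[0].epoch_len,
        fs=others[0].fs,
    )
    reduced = reduce_observations(pooled, variant=variant, n_d=n_d)
    model = dens.fit(reduced.scores, pin_labels(reduced.tags), backend=backend)
    target_obs = preprocess_session(sessions[target], channels=channels)
    return portability_attack(model, reduced.basis, target_obs,
                              prior_mode=prior_mode, clip=clip, B=B, seed=seed)


@dataclass
class IdentificationResult:
    """PI(U; O): how much the real-code epochs reveal about *who* is watching."""

    partial_pi: dict             # user id -> PI(U = u; O), bits
    overall_pi: float            # bits, <= h_prior
    ci_low: float
    ci_high: float
    h_prior: float               # H[U] = log2(n_users) under uniform priors
    confusion: pd.DataFrame      # true user x predicted user counts


def identify_user(
    sessions: Sequence[EpochSet],
    cv_k: Optional[int] = None,
    variant: str = "average",
    backend: str = "kde",
    n_d: int = 5,
    channels: Sequence[str] = ("P7", "P8"),
    B: int = 100,
    seed: int = 0,
) -> IdentificationResult:
    """Multi-class (per-user) density evaluation on real-code epochs only.

    Follows the same pipeline with the user identity as the class variable:
    uniform priors over users and cross-validated posteriors (``cv_k=None`` =
    leave-one-out).  Unlike the PIN pipeline — where the PCA input (per-tag
    means) is public — the per-user mean traces *are* the class labels here,
    so the reduction is recomputed inside every fold from the profiling set
    only; otherwise identical users would appear identifiable through basis
    overfitting.  The partial PI of user u is H[U] + the mean log2 posterior
    of u over u's held-out epochs; the overall PI is their uniform-prior
    average.  (The 'raw' variant refits a full PCA per fold: prefer a
    moderate ``cv_k`` there.)
    """
    if len(sessions) < 2:
        raise ValueError("identification needs at least 2 users")
    vec_blocks, label_blocks = [], []
    ref = None
    for s in sessions:
        obs = preprocess_session(s, channels=channels)
        keep = obs.tags == 1
        if keep.sum() < 2:
            raise ValueError(f"user {s.user_id} has fewer than 2 real-code epochs")
        vec_blocks.append(obs.vectors[keep])
        label_blocks.append(np.full(int(keep.sum()), s.user_id))
        ref = obs
    X = np.vstack(vec_blocks)
    users = np.concatenate(label_blocks)
    user_ids = np.unique(users)
    n = len(X)

    cv = metrics.make_cv(n, k=cv_k, labels=users, seed=seed)
    # per-user sums allow O(1) fold-wise mean updates under leave-one-out
    sums = {u: X[users == u].sum(axis=0) for u in user_ids}
    counts_all = {u: int((users == u).sum()) for u in user_ids}
    probs = np.empty((n, user_ids.size))
    log2_post = np.empty((n, user_ids.size))
    for test in cv.folds:
        test = np.asarray(test)
        train = np.setdiff1d(np.arange(n), test)
        if variant == "average":
            means = np.empty((user_ids.size, X.shape[1]))
            for ui, u in enumerate(user_ids):
                drop = test[users[test] == u]
                cnt = counts_all[u] - drop.size
                if cnt < 1:
                    raise ValueError(f"user {u} absent from a profiling set")
                means[ui] = (sums[u] - X[drop].sum(axis=0)) / cnt
            tm = dimred.TagMeans(
                means=means,
                counts=np.array([counts_all[u] for u in user_ids]),
                tag_values=user_ids,
            )
            basis = dimred.average_pca(tm, n_d=min(n_d, user_ids.size - 1))
        else:
            pooled = ObservationSet(vectors=X[train],
                                    tags=np.ones(train.size, dtype=int),
                                    user_id=-1, channels=list(ref.channels),
                                    epoch_len=ref.epoch_len, fs=ref.fs)
            basis = dimred.raw_pca(pooled, n_d=n_d)
        train_scores = (X[train] - basis.center) @ basis.components.T
        test_scores = (X[test] - basis.center) @ basis.components.T
        model = dens.fit(train_scores, users[train], backend=backend)
        post_f, lp_f = metrics.model_posteriors(model, test_scores,
                                                prior_mode="uniform")
        probs[test] = post_f.probs
        log2_post[test] = lp_f
    post = dens.PosteriorArray(probs=probs, classes=user_ids,
                               prior_mode="uniform")
    h_prior = float(np.log2(user_ids.size))
    log_terms = metrics.true_class_log_terms(log2_post, users, user_ids)
    partial = {
        int(u): float(h_prior + log_terms[users == u].mean()) for u in user_ids
    }
    overall = float(h_prior + np.mean([log_terms[users == u].mean()
                                       for u in user_ids]))
    weights = np.full(user_ids.size, 1.0 / user_ids.size)
    ci_low, ci_high = metrics.bootstrap_ci(log_terms, users, weights,
                                           h_prior, B=B, seed=seed)
    pred = user_ids[np.argmax(post.probs, axis=1)]
    confusion = pd.crosstab(pd.Series(users, name="true"),
                            pd.Series(pred, name="predicted"))
    return IdentificationResult(
        partial_pi=partial, overall_pi=overall, ci_low=ci_low,
        ci_high=ci_high, h_prior=h_prior, confusion=confusion,
    )
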