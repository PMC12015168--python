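"""Dirichlet-multinomial mixture (DMM) community typing.

Relative-abundance profiles are converted to integer pseudo-counts at a
fixed depth (largest-remainder rounding, so every sample sums exactly to
the depth) and modelled as a K-component mixture of Dirichlet-multinomial
distributions fit by expectation-maximization. Component Dirichlet
parameters are updated with Minka's fixed-point iteration, which keeps
the observed-data log-likelihood non-decreasing across EM iterations.

This supplies an operational stand-in for the five previously described
preterm gut community types (PGCTs): samples are assigned by maximum
posterior, and "probiotic-associated" types are the components whose
expected composition is led by a probiotic species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, psi
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .cohort_io import PROBIOTIC_SPECIES

logger = logging.getLogger(__name__)


def pseudo_counts(abundances, depth: int = 10000) -> np.ndarray:
    """Largest-remainder rounding of relative abundances to integer counts.

    Each row of the result sums exactly to ``depth``; per-taxon error of
    ``counts / depth`` versus the input is at most ``1/depth``.
    """
    if depth < 100:
        raise ValueError("depth must be at least 100")
    p = np.atleast_2d(np.asarray(abundances, dtype=float))
    if np.any(p < 0):
        raise ValueError("negative abundances")
    p = p / p.sum(axis=1, keepdims=True)
    scaled = p * depth
    base = np.floor(scaled).astype(np.int64)
    short = depth - base.sum(axis=1)
    frac = scaled - base
    counts = base.copy()
    for i in range(p.shape[0]):
        if short[i] > 0:
            # stable argsort: ties go to the lower taxon index
            order = np.argsort(-frac[i], kind="stable")
            counts[i, order[: short[i]]] += 1
    return counts


def _dm_loglik(counts, totals, alpha) -> np.ndarray:
    """Log Dirichlet-multinomial likelihood (without the multinomial coefficient).

    counts: (n, T); alpha: (K, T). Returns (n, K).
    """
    a0 = alpha.sum(axis=1)  # (K,)
    term0 = gammaln(a0)[None, :] - gammaln(totals[:, None] + a0[None, :])
    term1 = gammaln(counts[:, None, :] + alpha[None, :, :]).sum(axis=2)
    term2 = gammaln(alpha).sum(axis=1)[None, :]
    return term0 + term1 - term2


def _fixed_point_update(counts, totals, resp_k, alpha_k, inner_iter=30, tol=1e-8):
    """Minka fixed-point MLE update of one component's Dirichlet parameters."""
    alpha = alpha_k.copy()
    w = resp_k
    wsum = w.sum()
    if wsum <= 0:
        return alpha
    for _ in range(inner_iter):
        a0 = alpha.sum()
        num = (w[:, None] * (psi(counts + alpha[None, :]) - psi(alpha)[None, :])).sum(axis=0)
        den = (w * (psi(totals + a0) - psi(a0))).sum()
        if den <= 0:
            break
        new = alpha * num / den
        new = np.maximum(new, 1e-10)
        if np.max(np.abs(new - alpha)) < tol * np.max(alpha):
            alpha = new
            break
        alpha = new
    return alpha


class DirichletMultinomialMixture(ClusterMixin, BaseEstimator):
    """EM-fit Dirichlet-multinomial mixture over compositional profiles.

    Parameters
    ----------
    n_components : number of community types K (default 5).
    depth : pseudo-count total per sample (default 10000).
    n_init : random restarts; best final log-likelihood wins.
    max_iter, tol : EM iteration cap and relative log-likelihood tolerance.
    random_state : seed; fixed seed gives identical fitted parameters.

    Attributes (after ``fit``)
    --------------------------
    alpha_ : (K, T) component Dirichlet parameters (all positive).
    weights_ : (K,) mixing weights (sum to 1).
    log_likelihood_ : final observed-data log-likelihood.
    ll_history_ : per-EM-iteration log-likelihoods of the winning restart
        (non-decreasing).
    labels_ : maximum-posterior assignment of the training samples.
    taxa_ : taxon names when fit from a profile matrix.
    """

    def __init__(self, n_components=5, depth=10000, n_init=3, max_iter=200, tol=1e-6, random_state=None):
        self.n_components = n_components
        self.depth = depth
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _to_counts(self, X):
        taxa = None
        if hasattr(X, "values") and hasattr(X, "taxa"):  # TaxonProfileMatrix
            taxa = list(X.taxa)
            X = X.values
        elif isinstance(X, pd.DataFrame):
            taxa = list(X.columns)
            X = X.to_numpy(dtype=float)
        return pseudo_counts(X, self.depth), taxa

    def fit(self, X, y=None):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        counts, taxa = self._to_counts(X)
        n, T = counts.shape
        if self.n_components > n:
            raise ValueError(f"n_components={self.n_components} exceeds n_samples={n}")
        self.taxa_ = taxa
        totals = counts.sum(axis=1).astype(float)
        rng = np.random.default_rng(self.random_state)

        best = None
        for _ in range(max(1, self.n_init)):
            state = self._fit_once(counts, totals, rng)
            if best is None or state["ll"] > best["ll"]:
                best = state
        self.alpha_ = best["alpha"]
        self.weights_ = best["weights"]
        self.log_likelihood_ = best["ll"]
        self.ll_history_ = best["history"]
        self.n_iter_ = len(best["history"])
        log_post = self._log_posterior(counts, totals)
        self.labels_ = np.argmax(log_post, axis=1)
        return self

    def _fit_once(self, counts, totals, rng):
        n, T = counts.shape
        K = self.n_components
        # seed components at K distinct samples, smoothed toward the pooled mean
        seeds = rng.choice(n, size=K, replace=False)
        pooled = counts.sum(axis=0) / counts.sum()
        comp = 0.7 * (counts[seeds] / totals[seeds, None]) + 0.3 * pooled[None, :]
        alpha = comp * 20.0 + 1e-3
        weights = np.full(K, 1.0 / K)

        history = []
        prev_ll = -np.inf
        for _ in range(self.max_iter):
            log_joint = _dm_loglik(counts, totals, alpha) + np.log(weights)[None, :]
            ll = float(logsumexp(log_joint, axis=1).sum())
            history.append(ll)
            resp = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))

            weights = resp.mean(axis=0)
            # prune numerically dead components
            dead = weights < 1.0 / n**2
            if dead.any() and (~dead).sum() >= 1:
                warnings.warn(
                    f"pruning {int(dead.sum())} degenerate mixture component(s)",
                    RuntimeWarning,
                    stacklevel=2,
                )
                keep = ~dead
                alpha = alpha[keep]
                resp = resp[:, keep]
                resp /= resp.sum(axis=1, keepdims=True)
                weights = resp.mean(axis=0)
            weights = weights / weights.sum()
            for k in range(alpha.shape[0]):
                alpha[k] = _fixed_point_update(counts, totals, resp[:, k], alpha[k])

            if ll - prev_ll < self.tol * max(1.0, abs(ll)) and ll >= prev_ll:
                prev_ll = ll
                break
            prev_ll = ll
        log_joint = _dm_loglik(counts, totals, alpha) + np.log(weights)[None, :]
        final_ll = float(logsumexp(log_joint, axis=1).sum())
        history.append(final_ll)
        return {"alpha": alpha, "weights": weights, "ll": final_ll, "history": history}

    def _log_posterior(self, counts, totals):
        check_is_fitted(self, "alpha_")
        return _dm_loglik(counts, totals, self.alpha_) + np.log(self.weights_)[None, :]

    def predict_proba(self, X) -> np.ndarray:
        counts, taxa = self._to_counts(X)
        if taxa is not None and self.taxa_ is not None and taxa != self.taxa_:
            raise ValueError("taxa do not match the fitted model")
        totals = counts.sum(axis=1).astype(float)
        log_post = self._log_posterior(counts, totals)
        return np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        # argmax takes the first maximum: ties break to the lower type id
        return np.argmax(self.predict_proba(X), axis=1)

    @property
    def component_means_(self) -> np.ndarray:
        check_is_fitted(self, "alpha_")
        return self.alpha_ / self.alpha_.sum(axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "alpha_")
        cols = self.taxa_ if self.taxa_ is not None else range(self.alpha_.shape[1])
        return pd.DataFrame(self.alpha_, columns=cols)


def fit_community_types(
    profiles, k: int = 5, depth: int = 10000, seed=None, restarts: int = 3, **kwargs
) -> DirichletMultinomialMixture:
    """Fit a K-type DMM to a profile matrix (functional wrapper)."""
    return DirichletMultinomialMixture(
        n_components=k, depth=depth, n_init=restarts, random_state=seed, **kwargs
    ).fit(profiles)


def assign_type(model: DirichletMultinomialMixture, profile) -> tuple[int, np.ndarray]:
    """Maximum-posterior community type for one composition."""
    proba = model.predict_proba(np.atleast_2d(np.asarray(profile, dtype=float)))[0]
    return int(np.argmax(proba)), proba


def probiotic_associated_types(
    model: DirichletMultinomialMixture, species=PROBIOTIC_SPECIES
) -> set[int]:
    """Types whose expected composition is dominated by a probiotic species."""
    if model.taxa_ is None:
        raise ValueError("model has no taxon names; fit from a profile matrix")
    species = [s for s in species if s in model.taxa_]
    if not species:
        raise ValueError("no probiotic species present in the model's taxa")
    sp_idx = {model.taxa_.index(s) for s in species}
    hits = {
        k
        for k, mean in enumerate(model.component_means_)
        if int(np.argmax(mean)) in sp_idx
    }
    if not hits:
        logger.warning("no probiotic-dominant community type found")
    return hits


@dataclass
class TypeProportions:
    counts: pd.DataFrame  # groups x types
    proportions: pd.DataFrame  # groups x types, rows sum to 1
    probiotic_associated: pd.Series  # per-group combined proportion
    probiotic_types: set[int]


def type_proportions_by_group(
    assignments: pd.Series,
    samples,
    infants,
    probiotic_types: set[int] | None = None,
    during_probiotic_only: bool = True,
) -> TypeProportions:
    """Per-group community-type counts/proportions (optionally during use only)."""
    by_infant = {inf.infant_id: inf for inf in infants}
    rows = []
    for s in samples:
        if during_probiotic_only and not s.during_probiotic_use:
            continue
        if s.sample_id not in assignments.index:
            continue
        rows.append(
            {
                "group": by_infant[s.infant_id].group,
                "type": int(assignments.loc[s.sample_id]),
            }
        )
    if not rows:
        raise ValueError("no samples left after filtering")
    df = pd.DataFrame(rows)
    counts = df.groupby(["group", "type"]).size().unstack(fill_value=0)
    proportions = counts.div(counts.sum(axis=1), axis=0)
    probiotic_types = probiotic_types or set()
    present = [t for t in sorted(probiotic_types) if t in proportions.columns]
    assoc = (
        proportions[present].sum(axis=1)
        if present
        else pd.Series(0.0, index=proportions.index)
    )
    return TypeProportions(
        counts=counts,
        proportions=proportions,
        probiotic_associated=assoc,
        probiotic_types=set(probiotic_types),
    )
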