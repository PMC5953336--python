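"""Single-occasion latent class analysis by multi-start EM.

The model: respondent i belongs to one of S latent classes with prevalence
gamma_s; conditional on class, the J categorical items are independent with
category probabilities rho[s, j, c]. Missing items are marginalized out of
each response pattern's likelihood (full-information ML under MAR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .errors import EstimationError, IdentificationWarning
from .panel import MISSING, PatternTable

_BEST_TOL = 1e-4  # two starts "agree" when their log-likelihoods differ less


@dataclass
class LCAParameters:
    """rho: (S, J, C) item-response probabilities; gamma: (S,) prevalences."""

    rho: np.ndarray
    gamma: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.gamma.shape[0]


@dataclass
class ConvergenceReport:
    """Multi-start EM diagnostics.

    ``n_starts_at_best`` counts starts whose final log-likelihood lies within
    1e-4 of the best — a best solution found only once is a classic sign of an
    under-identified or barely-identified model.
    """

    n_starts: int
    best_loglik: float
    n_starts_at_best: int
    iterations: list = field(default_factory=list)
    converged: bool = False


def _as_pattern_arrays(X, n_categories=None):
    """Accept a PatternTable or raw (N, J) code array; return patterns, freq, C."""
    if isinstance(X, PatternTable):
        if X.n_occasions != 1:
            raise ValueError("LCA expects a single-occasion pattern table")
        return X.patterns[:, 0, :], X.frequencies.astype(float), X.n_categories
    X = np.asarray(X, dtype=np.int64)
    if X.ndim != 2:
        raise ValueError("X must be (N, J) integer codes (0 = missing)")
    if n_categories is None:
        n_categories = X.max(axis=0)
        n_categories = np.maximum(n_categories, 1)
    uniq, counts = np.unique(X, axis=0, return_counts=True)
    return uniq, counts.astype(float), np.asarray(n_categories, dtype=np.int64)


def _log_emissions(patterns, log_rho):
    """log P(observed part of pattern | class): (n_pat, S)."""
    n, j_items = patterns.shape
    out = np.zeros((n, log_rho.shape[0]))
    for j in range(j_items):
        codes = patterns[:, j]
        obs = codes != MISSING
        if obs.any():
            out[obs] += log_rho[:, j, codes[obs] - 1].T
    return out


def _clamp_simplex(p, clamp, axis=-1):
    p = np.clip(p, clamp, 1.0 - clamp)
    return p / p.sum(axis=axis, keepdims=True)


def _random_init(rng, s, n_categories, clamp):
    c_max = int(n_categories.max())
    j_items = len(n_categories)
    rho = np.zeros((s, j_items, c_max))
    for j in range(j_items):
        c = int(n_categories[j])
        # uniform perturbations around the flat profile
        w = 1.0 + rng.uniform(-0.8, 0.8, size=(s, c))
        rho[:, j, :c] = w / w.sum(axis=1, keepdims=True)
    gamma = rng.dirichlet(np.ones(s))
    gamma = _clamp_simplex(gamma, clamp)
    return rho, gamma


def _em_single_start(patterns, freq, n_categories, rho, gamma, tol, max_iter,
                     clamp):
    n_total = freq.sum()
    c_max = rho.shape[2]
    history = []
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            log_rho = np.log(rho)
            log_joint = _log_emissions(patterns, log_rho) + np.log(gamma)[None, :]
        ll_pattern = logsumexp(log_joint, axis=1)
        new_ll = float(freq @ ll_pattern)
        history.append(new_ll)
        if np.isfinite(loglik) and new_ll - loglik <= tol * (abs(loglik) + 1.0):
            converged = True
            break
        loglik = new_ll
        post = np.exp(log_joint - ll_pattern[:, None])
        w = freq[:, None] * post                          # (n_pat, S)
        gamma = _clamp_simplex(w.sum(axis=0) / n_total, clamp)
        for j in range(patterns.shape[1]):
            codes = patterns[:, j]
            counts = np.zeros((rho.shape[0], c_max))
            for c in range(1, int(n_categories[j]) + 1):
                sel = codes == c
                if sel.any():
                    counts[:, c - 1] = w[sel].sum(axis=0)
            denom = counts.sum(axis=1, keepdims=True)
            denom[denom == 0] = 1.0
            c_j = int(n_categories[j])
            rho[:, j, :c_j] = _clamp_simplex(counts[:, :c_j] / denom, clamp)
    return rho, gamma, history[-1], history, converged


class LatentClassAnalysis(BaseEstimator):
    """Latent class model for categorical items, fitted by multi-start EM.

    Parameters
    ----------
    n_classes : int
        Number of latent classes S.
    n_starts : int, default 100
        Random EM initializations; the reported solution maximizes the
        observed-data log-likelihood over starts.
    tol : float, default 1e-8
        Relative log-likelihood convergence tolerance.
    max_iter : int, default 5000
    random_state : int or None
        Seeds the full start sequence.
    clamp : float, default 1e-6
        Probabilities are kept in [clamp, 1-clamp] to avoid log(0) while
        preserving near-boundary solutions.

    Attributes
    ----------
    rho_ : ndarray (S, J, C_max)
        Item-response probabilities (per-item slices beyond C_j are zero).
    gamma_ : ndarray (S,)
        Class prevalences, sorted descending.
    loglik_ : float
    convergence_ : ConvergenceReport
    loglik_path_ : list of float
        Per-iteration log-likelihood of the winning start (non-decreasing).
    """

    def __init__(self, n_classes=2, *, n_starts=100, tol=1e-8, max_iter=5000,
                 random_state=None, clamp=1e-6):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.clamp = clamp

    def fit(self, X, y=None, n_categories=None):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        patterns, freq, n_cat = _as_pattern_arrays(X, n_categories)
        self.n_categories_ = n_cat
        s = int(self.n_classes)
        if s > patterns.shape[0]:
            warnings.warn(
                f"{s} classes requested but only {patterns.shape[0]} distinct "
                "patterns observed; the model is likely not identified",
                IdentificationWarning, stacklevel=2)
        n_params = (s - 1) + s * int((n_cat - 1).sum())
        if freq.sum() / max(n_params, 1) < 5:
            warnings.warn(
                f"data-to-parameter ratio {freq.sum() / max(n_params, 1):.1f} < 5; "
                "estimates may be unstable even with positive df",
                IdentificationWarning, stacklevel=2)

        rng = np.random.default_rng(self.random_state)
        best = None
        logliks, iter_counts, any_converged = [], [], False
        for _ in range(int(self.n_starts)):
            rho0, gamma0 = _random_init(rng, s, n_cat, self.clamp)
            if s == 1:
                rho0 = rho0.copy()
                gamma0 = np.ones(1)
            rho, gamma, ll, history, conv = _em_single_start(
                patterns, freq, n_cat, rho0, gamma0, self.tol, self.max_iter,
                self.clamp)
            logliks.append(ll)
            iter_counts.append(len(history))
            any_converged |= conv
            if best is None or ll > best[2]:
                best = (rho, gamma, ll, history, conv)
        if best is None or not any_converged:
            report = ConvergenceReport(int(self.n_starts),
                                       best[2] if best else np.nan,
                                       0, iter_counts, False)
            raise EstimationError(
                f"no EM start converged in {self.max_iter} iterations "
                f"(report: {report})")

        rho, gamma, ll, history, conv = best
        order = np.argsort(-gamma, kind="stable")
        self.rho_ = rho[order]
        self.gamma_ = gamma[order]
        self.loglik_ = ll
        self.loglik_path_ = history
        n_at_best = int(sum(abs(l - ll) < _BEST_TOL for l in logliks))
        self.convergence_ = ConvergenceReport(
            int(self.n_starts), ll, n_at_best, iter_counts, conv)
        if self.n_starts > 1 and n_at_best < 2:
            warnings.warn(
                "best log-likelihood found by a single start only; solution "
                "may not be the global maximum", IdentificationWarning,
                stacklevel=2)
        return self

    @property
    def params_(self) -> LCAParameters:
        return LCAParameters(self.rho_, self.gamma_)

    def predict_proba(self, X):
        """Posterior class-membership probabilities per row of X (Bayes rule,
        missing items marginalized). Rows with no observed item get gamma."""
        patterns = X.patterns[:, 0, :] if isinstance(X, PatternTable) \
            else np.asarray(X, dtype=np.int64)
        with np.errstate(divide="ignore"):
            log_joint = _log_emissions(patterns, np.log(self.rho_)) \
                + np.log(self.gamma_)[None, :]
        norm = logsumexp(log_joint, axis=1)
        if not np.all(np.isfinite(norm)):
            raise EstimationError("zero total likelihood for some pattern")
        return np.exp(log_joint - norm[:, None])

    def predict(self, X):
        post, _ = modal_assignment(self.predict_proba(X))
        return post

    def score(self, X, y=None):
        """Mean per-respondent log-likelihood."""
        patterns, freq, _ = _as_pattern_arrays(X, self.n_categories_)
        with np.errstate(divide="ignore"):
            log_joint = _log_emissions(patterns, np.log(self.rho_)) \
                + np.log(self.gamma_)[None, :]
        return float(freq @ logsumexp(log_joint, axis=1) / freq.sum())

    def to_frame(self) -> pd.DataFrame:
        """rho as a (class x item) by category table, with gamma attached."""
        s, j_items, c_max = self.rho_.shape
        idx = pd.MultiIndex.from_product(
            [[f"class{k + 1}" for k in range(s)], range(j_items)],
            names=["class", "item"])
        df = pd.DataFrame(self.rho_.reshape(s * j_items, c_max), index=idx,
                          columns=[f"cat{c + 1}" for c in range(c_max)])
        df.attrs["gamma"] = self.gamma_.tolist()
        return df


def fit_lca(table, S, *, n_starts=100, tol=1e-8, max_iter=5000,
            random_state=None):
    """Functional wrapper: returns (LCAParameters, ConvergenceReport, loglik)."""
    est = LatentClassAnalysis(S, n_starts=n_starts, tol=tol, max_iter=max_iter,
                              random_state=random_state).fit(table)
    return est.params_, est.convergence_, est.loglik_


def lca_posteriors(params: LCAParameters, table) -> np.ndarray:
    """Per-pattern posterior class probabilities under ``params``."""
    est = LatentClassAnalysis(params.n_classes)
    est.rho_, est.gamma_ = params.rho, params.gamma
    return est.predict_proba(table)


def modal_assignment(posteriors):
    """Argmax class per row (0-based); ties broken toward the lowest index.

    Returns ``(labels, tie_flags)``.
    """
    post = np.asarray(posteriors, dtype=float)
    labels = post.argmax(axis=1)
    best = post[np.arange(post.shape[0]), labels]
    ties = (np.isclose(post, best[:, None], rtol=0, atol=1e-12).sum(axis=1)) > 1
    return labels, ties
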