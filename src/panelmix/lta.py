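"""Latent transition analysis: a latent Markov chain over statuses with
categorical emissions, fitted by multi-start EM with forward-backward
recursions.

The observed-data likelihood of a response pattern y over T occasions is

    P(y) = sum over status sequences (s_1..s_T) of
           delta[s_1] * prod_t tau_t[s_t, s_{t+1}] * prod_{t,j} rho[s_t, j, y_tj]

The E-step never enumerates the S^T sequences; it runs scaled forward-backward
recursions per distinct observed pattern, weighted by pattern frequency.
Missing items (and entire missing occasions, i.e. attrition) contribute no
emission term, which is the full-information MAR treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator
from scipy.optimize import linear_sum_assignment

from ._logit import fit_weighted_multinomial, softmax_rows
from .errors import (ConfigurationError, EstimationError,
                     IdentificationWarning, SparsenessError)
from .lca import ConvergenceReport, _BEST_TOL, _clamp_simplex, _log_emissions
from .panel import MISSING, PatternTable, ResponsePanel, pattern_frequencies


@dataclass
class ModelSpec:
    """Structure and estimation settings of a latent transition model.

    ``rho_constraints`` is a list of dicts, 0-based indices:
      ``{"type": "fix", "status": s, "item": j, "category": c,
         "occasion": t_or_None, "value": v}`` pins one rho entry;
      ``{"type": "equal", "cells": [(s, j, c) or (t, s, j, c), ...]}`` ties
      entries together. At most one constrained cell per (status, item[,
      occasion]) probability slice is supported; the remaining categories of a
      slice renormalize around the constrained mass.
    """

    n_statuses: int
    n_occasions: int
    n_categories: tuple
    measurement_invariance: bool = True
    transition_invariance: bool = False
    rho_constraints: list = None
    n_covariates: int = 0
    covariate_effects: str = "none"   # none | prevalence | prevalence+transitions
    n_groups: int = 1
    group_delta: bool = False
    group_tau: bool = False
    n_starts: int = 50
    tol: float = 1e-8
    max_iter: int = 5000
    random_state: int = None

    def __post_init__(self):
        if self.n_statuses < 1:
            raise ConfigurationError("n_statuses must be >= 1")
        if self.covariate_effects not in ("none", "prevalence",
                                          "prevalence+transitions"):
            raise ConfigurationError(
                f"unknown covariate_effects {self.covariate_effects!r}")
        if self.covariate_effects != "none" and self.n_covariates < 1:
            raise ConfigurationError("covariate effects need n_covariates >= 1")
        if self.covariate_effects != "none" and (self.group_delta or self.group_tau):
            raise ConfigurationError(
                "covariate effects and group-specific parameters cannot be "
                "combined")
        self.n_categories = tuple(int(c) for c in self.n_categories)
        for con in self.rho_constraints or []:
            self._check_constraint(con)

    def _check_constraint(self, con):
        kind = con.get("type")
        if kind == "fix":
            cells = [(con.get("occasion"), con["status"], con["item"],
                      con["category"])]
            v = con.get("value")
            if v is None or not 0.0 <= v <= 1.0:
                raise ConfigurationError("fixed rho values must lie in [0, 1]")
        elif kind == "equal":
            raw = con.get("cells") or []
            if len(raw) < 2:
                raise ConfigurationError("equality groups need >= 2 cells")
            cells = [c if len(c) == 4 else (None,) + tuple(c) for c in raw]
        else:
            raise ConfigurationError(f"unknown constraint type {kind!r}")
        for t, s, j, c in cells:
            if not 0 <= s < self.n_statuses:
                raise ConfigurationError(f"constraint status {s} out of range")
            if not 0 <= j < len(self.n_categories):
                raise ConfigurationError(f"constraint item {j} out of range")
            if not 0 <= c < self.n_categories[j]:
                raise ConfigurationError(f"constraint category {c} out of range")
            if t is not None and not 0 <= t < self.n_occasions:
                raise ConfigurationError(f"constraint occasion {t} out of range")
            if t is not None and self.measurement_invariance:
                raise ConfigurationError(
                    "occasion-specific constraints conflict with measurement "
                    "invariance")


@dataclass
class LTAParameters:
    """Estimated latent-chain parameters.

    rho: (S, J, C) under measurement invariance, else (T, S, J, C).
    delta: (S,) first-occasion prevalences, or (G, S) per group.
    tau: (n_mat, S, S) with n_mat = 1 (transition invariance) or T-1;
         (G, n_mat, S, S) when group-specific.
    beta: optional (S, 1+K) prevalence-logit coefficients (reference row 0).
    beta_tau: optional (n_mat, S, S, 1+K) transition-logit coefficients.
    """

    rho: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    beta: np.ndarray = None
    beta_tau: np.ndarray = None

    @property
    def n_statuses(self) -> int:
        return self.tau.shape[-1]


# ---------------------------------------------------------------------------
# forward-backward core


def _forward_backward(B, delta_rows, taus):
    """Scaled forward-backward over statuses.

    B : (n, T, S) linear emission probabilities per row/occasion/status.
    delta_rows : (n, S) initial distribution per row.
    taus : (T-1, S, S) or (n, T-1, S, S) transition matrices.

    Returns (ll_rows, gamma, xi) with gamma (n, T, S) occasion marginals and
    xi (n, T-1, S, S) pairwise posteriors.
    """
    n, T, S = B.shape
    per_row_tau = taus.ndim == 4

    def trans(t):
        return taus[:, t] if per_row_tau else taus[t]

    alpha = np.empty((n, T, S))
    scale = np.empty((n, T))
    a = delta_rows * B[:, 0]
    scale[:, 0] = a.sum(axis=1)
    if np.any(scale[:, 0] <= 0):
        raise EstimationError("zero forward mass: numerical underflow")
    alpha[:, 0] = a / scale[:, 0][:, None]
    for t in range(1, T):
        tt = trans(t - 1)
        prior = np.einsum("ns,nsk->nk", alpha[:, t - 1], tt) if per_row_tau \
            else alpha[:, t - 1] @ tt
        a = prior * B[:, t]
        scale[:, t] = a.sum(axis=1)
        if np.any(scale[:, t] <= 0):
            raise EstimationError("zero forward mass: numerical underflow")
        alpha[:, t] = a / scale[:, t][:, None]

    bw = np.empty((n, T, S))
    bw[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        tmp = B[:, t + 1] * bw[:, t + 1]
        tt = trans(t)
        prod = np.einsum("nsk,nk->ns", tt, tmp) if per_row_tau else tmp @ tt.T
        bw[:, t] = prod / scale[:, t + 1][:, None]

    gamma = alpha * bw
    xi = np.empty((n, T - 1, S, S)) if T > 1 else np.zeros((n, 0, S, S))
    for t in range(T - 1):
        tt = trans(t)
        right = (B[:, t + 1] * bw[:, t + 1]) / scale[:, t + 1][:, None]
        xi[:, t] = alpha[:, t][:, :, None] * tt * right[:, None, :]
    ll_rows = np.log(scale).sum(axis=1)
    return ll_rows, gamma, xi


# ---------------------------------------------------------------------------
# constraint handling for rho


def _apply_rho_constraints(counts, spec, clamp):
    """Turn expected counts into constrained, normalized rho.

    counts has the storage shape of rho: (S, J, C) under measurement
    invariance or (T, S, J, C) otherwise. Each constrained cell gets its ML
    value (fixed value, or pooled ratio for an equality group); the free
    categories of its slice share the remaining mass proportionally.
    """
    has_t = counts.ndim == 4
    denom = counts.sum(axis=-1, keepdims=True)
    denom[denom == 0] = 1.0
    rho = counts / denom

    pinned = []  # (slice index tuple, category, value)
    for con in spec.rho_constraints or []:
        if con["type"] == "fix":
            t, s, j, c = con.get("occasion"), con["status"], con["item"], con["category"]
            idx = (t, s, j) if has_t else (s, j)
            if has_t and t is None:
                for tt in range(counts.shape[0]):
                    pinned.append(((tt, s, j), c, con["value"]))
            else:
                pinned.append((idx, c, con["value"]))
        else:  # equality group: pooled count ratio
            cells = [cc if len(cc) == 4 else (None,) + tuple(cc)
                     for cc in con["cells"]]
            num = 0.0
            den = 0.0
            expanded = []
            for t, s, j, c in cells:
                if has_t:
                    ts = range(counts.shape[0]) if t is None else [t]
                    for tt in ts:
                        expanded.append(((tt, s, j), c))
                else:
                    expanded.append(((s, j), c))
            for idx, c in expanded:
                num += counts[idx][c]
                den += counts[idx].sum()
            value = num / den if den > 0 else 0.0
            pinned.extend((idx, c, value) for idx, c in expanded)

    for idx, c, value in pinned:
        value = float(np.clip(value, clamp, 1.0 - clamp))
        slice_ = rho[idx].copy()
        others = np.delete(np.arange(slice_.shape[0]), c)
        rest = slice_[others]
        rest_sum = rest.sum()
        if rest_sum <= 0:
            rest = np.full(others.shape[0], 1.0 / max(others.shape[0], 1))
            rest_sum = 1.0
        slice_[others] = (1.0 - value) * rest / rest_sum
        slice_[c] = value
        rho[idx] = slice_
    return rho


def _n_constrained_params(spec: ModelSpec) -> int:
    """Free-parameter reduction from rho constraints."""
    reduction = 0
    occ = spec.n_occasions if not spec.measurement_invariance else 1
    for con in spec.rho_constraints or []:
        if con["type"] == "fix":
            reduction += occ if (con.get("occasion") is None
                                 and not spec.measurement_invariance) else 1
        else:
            cells = con["cells"]
            size = 0
            for cc in cells:
                t = cc[0] if len(cc) == 4 else None
                size += occ if (t is None and not spec.measurement_invariance) else 1
            reduction += size - 1
    return reduction


# ---------------------------------------------------------------------------
# estimator


class LatentTransitionAnalysis(BaseEstimator):
    """Latent transition model fitted by multi-start EM.

    Parameters mirror :class:`ModelSpec`: ``measurement_invariance`` shares
    the item-response probabilities rho across occasions;
    ``transition_invariance`` shares one transition matrix across all adjacent
    occasion pairs; ``covariate_effects`` lets respondent covariates shift the
    first-occasion prevalences (and optionally the transition rows) through
    multinomial logits estimated simultaneously with the rest of the model.

    Attributes (after fit)
    ----------------------
    rho_, delta_, tau_, beta_, beta_tau_ : see :class:`LTAParameters`.
    loglik_ : float, best observed-data log-likelihood.
    loglik_path_ : per-iteration log-likelihood of the winning start.
    convergence_ : ConvergenceReport.
    n_effective_ : respondents contributing any observed data.
    """

    def __init__(self, n_statuses=2, *, measurement_invariance=True,
                 transition_invariance=False, rho_constraints=None,
                 covariate_effects="none", reference_status=None,
                 group_delta=False, group_tau=False, n_starts=50, tol=1e-8,
                 max_iter=5000, random_state=None, clamp=1e-6,
                 sparseness_threshold=1.0, sort_statuses=True):
        self.n_statuses = n_statuses
        self.measurement_invariance = measurement_invariance
        self.transition_invariance = transition_invariance
        self.rho_constraints = rho_constraints
        self.covariate_effects = covariate_effects
        self.reference_status = reference_status
        self.group_delta = group_delta
        self.group_tau = group_tau
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.clamp = clamp
        self.sparseness_threshold = sparseness_threshold
        self.sort_statuses = sort_statuses

    # -- data preparation ---------------------------------------------------

    def _prepare(self, X, covariates, group):
        if isinstance(X, (PatternTable, ResponsePanel)):
            self.items_ = list(X.items)
        if isinstance(X, PatternTable):
            if covariates is not None or group is not None:
                raise ConfigurationError(
                    "covariates/groups require respondent-level input, not a "
                    "pattern table")
            return (X.patterns, X.frequencies.astype(float), X.n_categories,
                    None, None, [None], X.n)
        if isinstance(X, ResponsePanel):
            panel = X
            resp = panel.responses
            n_cat = panel.n_categories
            if isinstance(covariates, (list, tuple)) or isinstance(covariates, str):
                names = [covariates] if isinstance(covariates, str) else list(covariates)
                if panel.covariates is None:
                    raise ConfigurationError("panel has no covariates")
                covariates = panel.covariates[names].to_numpy(dtype=float)
            elif covariates is not None and hasattr(covariates, "to_numpy"):
                covariates = covariates.to_numpy(dtype=float)
            if isinstance(group, str):
                if panel.group is None:
                    raise ConfigurationError("panel has no group labels")
                group = panel.group
        else:
            resp = np.asarray(X, dtype=np.int64)
            if resp.ndim != 3:
                raise ConfigurationError("X must be (N, T, J) codes")
            n_cat = np.maximum(resp.max(axis=(0, 1)), 1)
            if covariates is not None:
                covariates = np.asarray(covariates, dtype=float)

        n, t_occ, j_items = resp.shape
        flat = resp.reshape(n, t_occ * j_items)
        keep = (flat != MISSING).any(axis=1)
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != n:
                covariates = covariates.T
            ok = np.isfinite(covariates).all(axis=1)
            if (~ok).any():
                warnings.warn(
                    f"excluding {int((~ok).sum())} respondents with missing "
                    "covariate values from the covariate model", UserWarning,
                    stacklevel=3)
            keep &= ok
        flat = flat[keep]
        n_eff = int(keep.sum())
        if n_eff == 0:
            raise EstimationError("no respondents with observed data")

        cols = [flat.astype(float)]
        group_levels = [None]
        if group is not None:
            group = np.asarray(group)[keep]
            group_levels, group_codes = np.unique(group, return_inverse=True)
            group_levels = list(group_levels)
            cols.append(group_codes[:, None].astype(float))
        if covariates is not None:
            cols.append(covariates[keep])
        stacked = np.hstack(cols)
        uniq, counts = np.unique(stacked, axis=0, return_counts=True)
        tj = t_occ * j_items
        patterns = uniq[:, :tj].astype(np.int64).reshape(-1, t_occ, j_items)
        pos = tj
        g_rows = None
        if group is not None:
            g_rows = uniq[:, pos].astype(np.int64)
            pos += 1
        z_rows = uniq[:, pos:] if covariates is not None else None
        return (patterns, counts.astype(float), np.asarray(n_cat),
                z_rows, g_rows, group_levels, n_eff)

    # -- parameter plumbing -------------------------------------------------

    def _spec(self, n_cat, t_occ, n_groups, n_cov):
        return ModelSpec(
            n_statuses=int(self.n_statuses), n_occasions=t_occ,
            n_categories=tuple(int(c) for c in n_cat),
            measurement_invariance=bool(self.measurement_invariance),
            transition_invariance=bool(self.transition_invariance),
            rho_constraints=self.rho_constraints,
            n_covariates=n_cov, covariate_effects=self.covariate_effects,
            n_groups=n_groups, group_delta=bool(self.group_delta),
            group_tau=bool(self.group_tau), n_starts=int(self.n_starts),
            tol=self.tol, max_iter=int(self.max_iter),
            random_state=self.random_state)

    def _random_params(self, rng, spec):
        s, t_occ = spec.n_statuses, spec.n_occasions
        j_items = len(spec.n_categories)
        c_max = max(spec.n_categories)
        occ_axis = 1 if spec.measurement_invariance else t_occ
        rho = np.zeros((occ_axis, s, j_items, c_max))
        for j, c in enumerate(spec.n_categories):
            w = 1.0 + rng.uniform(-0.8, 0.8, size=(occ_axis, s, c))
            rho[:, :, j, :c] = w / w.sum(axis=2, keepdims=True)
        if spec.measurement_invariance:
            rho = rho[0]
        n_mat = 1 if spec.transition_invariance else max(t_occ - 1, 1)
        base_tau = rng.dirichlet(np.ones(s), size=(n_mat, s))
        base_tau += 0.8 * np.eye(s)[None, :, :]       # mild persistence prior
        base_tau /= base_tau.sum(axis=2, keepdims=True)
        if spec.group_tau:
            tau = np.tile(base_tau, (spec.n_groups, 1, 1, 1))
        else:
            tau = base_tau
        delta = _clamp_simplex(rng.dirichlet(np.ones(s)), self.clamp)
        if spec.group_delta:
            delta = np.tile(delta, (spec.n_groups, 1))
        beta = beta_tau = None
        if spec.covariate_effects != "none":
            beta = np.zeros((s, 1 + spec.n_covariates))
            ref = self._ref(s)
            d0 = delta if delta.ndim == 1 else delta[0]
            with np.errstate(divide="ignore"):
                beta[:, 0] = np.log(d0 / d0[ref])
            beta[ref] = 0.0
        if spec.covariate_effects == "prevalence+transitions":
            beta_tau = np.zeros((n_mat, s, s, 1 + spec.n_covariates))
            with np.errstate(divide="ignore"):
                for m in range(n_mat):
                    for i in range(s):
                        beta_tau[m, i, :, 0] = np.log(base_tau[m, i]
                                                      / base_tau[m, i, i])
                        beta_tau[m, i, i, :] = 0.0
        return LTAParameters(rho, delta, tau, beta, beta_tau)

    def _ref(self, s):
        """Reference status used *during* EM (an arbitrary but fixed
        parameterization); the reported solution re-references to the
        highest-prevalence status after sorting."""
        if self.reference_status is not None:
            return int(self.reference_status)
        return 0

    def _emissions(self, patterns, rho, spec):
        n, t_occ, _ = patterns.shape
        s = spec.n_statuses
        B = np.empty((n, t_occ, s))
        with np.errstate(divide="ignore"):
            if spec.measurement_invariance:
                log_rho = np.log(np.where(rho > 0, rho, 1.0))
                for t in range(t_occ):
                    B[:, t] = np.exp(_log_emissions(patterns[:, t], log_rho))
            else:
                for t in range(t_occ):
                    log_rho = np.log(np.where(rho[t] > 0, rho[t], 1.0))
                    B[:, t] = np.exp(_log_emissions(patterns[:, t], log_rho))
        return B

    def _delta_rows(self, params, spec, z_rows, g_rows, n_rows):
        if spec.covariate_effects != "none":
            Z = np.hstack([np.ones((n_rows, 1)), z_rows])
            return softmax_rows(Z @ params.beta.T), Z
        if spec.group_delta:
            return params.delta[g_rows], None
        d = params.delta if params.delta.ndim == 1 else params.delta[0]
        return np.broadcast_to(d, (n_rows, d.shape[0])), None

    def _taus_for(self, params, spec, g, z_rows_g, t_occ):
        """(T-1, S, S) or per-row (n_g, T-1, S, S) transition matrices."""
        n_mat = 1 if spec.transition_invariance else t_occ - 1
        if spec.covariate_effects == "prevalence+transitions":
            n_g = z_rows_g.shape[0]
            Z = np.hstack([np.ones((n_g, 1)), z_rows_g])
            s = spec.n_statuses
            out = np.empty((n_g, t_occ - 1, s, s))
            for t in range(t_occ - 1):
                m = 0 if spec.transition_invariance else t
                for i in range(s):
                    out[:, t, i, :] = softmax_rows(Z @ params.beta_tau[m, i].T)
            return out
        tau = params.tau[g] if spec.group_tau else params.tau
        idx = np.zeros(t_occ - 1, dtype=int) if spec.transition_invariance \
            else np.arange(t_occ - 1)
        return tau[idx]

    # -- EM -----------------------------------------------------------------

    def _em(self, patterns, freq, spec, params, z_rows, g_rows, n_groups):
        n_rows, t_occ, j_items = patterns.shape
        s = spec.n_statuses
        c_max = max(spec.n_categories)
        n_mat = 1 if spec.transition_invariance else max(t_occ - 1, 1)
        n_total = freq.sum()
        groups = [np.arange(n_rows)] if g_rows is None else [
            np.where(g_rows == g)[0] for g in range(n_groups)]

        params = replace(params)
        history = []
        loglik = -np.inf
        converged = False
        for _ in range(spec.max_iter):
            B = self._emissions(patterns, params.rho, spec)
            delta_rows, Z = self._delta_rows(params, spec, z_rows, g_rows, n_rows)

            ll = 0.0
            gamma_all = np.empty((n_rows, t_occ, s))
            xi_all = np.empty((n_rows, max(t_occ - 1, 0), s, s))
            for g, idx in enumerate(groups):
                if idx.size == 0:
                    continue
                taus = self._taus_for(params, spec, g,
                                      z_rows[idx] if z_rows is not None else None,
                                      t_occ)
                ll_rows, gamma, xi = _forward_backward(
                    B[idx], delta_rows[idx], taus)
                ll += float(freq[idx] @ ll_rows)
                gamma_all[idx] = gamma
                if t_occ > 1:
                    xi_all[idx] = xi
            history.append(ll)
            if np.isfinite(loglik) and ll - loglik <= spec.tol * (abs(loglik) + 1.0):
                converged = True
                break
            loglik = ll

            # ---- M-step
            w1 = freq[:, None] * gamma_all[:, 0]        # (n_rows, S)
            if spec.covariate_effects != "none":
                ref = self._ref(s)
                beta = fit_weighted_multinomial(Z, w1, ref, beta0=params.beta,
                                                max_iter=25)
                delta = w1.sum(axis=0) / n_total
                params = replace(params, beta=beta, delta=delta)
            elif spec.group_delta:
                delta = np.empty((n_groups, s))
                for g, idx in enumerate(groups):
                    tot = freq[idx].sum()
                    delta[g] = _clamp_simplex(
                        w1[idx].sum(axis=0) / max(tot, 1e-300), self.clamp)
                params = replace(params, delta=delta)
            else:
                params = replace(params, delta=_clamp_simplex(
                    w1.sum(axis=0) / n_total, self.clamp))

            if t_occ > 1:
                params = self._m_step_tau(params, spec, freq, xi_all, groups,
                                          z_rows, n_mat, t_occ)

            counts = self._rho_counts(patterns, freq, gamma_all, spec, c_max)
            rho = _apply_rho_constraints(counts, spec, self.clamp)
            # zero out padding categories
            for j, c in enumerate(spec.n_categories):
                rho[..., j, c:] = 0.0
            params = replace(params, rho=rho)

        return params, history[-1], history, converged

    def _m_step_tau(self, params, spec, freq, xi_all, groups, z_rows, n_mat,
                    t_occ):
        s = spec.n_statuses
        fxi = freq[:, None, None, None] * xi_all      # (n_rows, T-1, S, S)
        if spec.covariate_effects == "prevalence+transitions":
            counts = fxi.sum(axis=0)                  # (T-1, S, S)
            if spec.transition_invariance:
                counts = counts.sum(axis=0, keepdims=True)
            sparse = np.argwhere(counts < self.sparseness_threshold)
            if sparse.size:
                cells = [tuple(map(int, c)) for c in sparse]
                raise SparsenessError(
                    "expected transition counts below threshold "
                    f"{self.sparseness_threshold} for cells (matrix, origin, "
                    f"destination): {cells}; the transition-covariate model is "
                    "not estimable on these data", cells=cells)
            Z = np.hstack([np.ones((z_rows.shape[0], 1)), z_rows])
            beta_tau = params.beta_tau.copy()
            for m in range(n_mat):
                ts = range(t_occ - 1) if spec.transition_invariance else [m]
                for i in range(s):
                    w = sum(fxi[:, t, i, :] for t in ts)
                    beta_tau[m, i] = fit_weighted_multinomial(
                        Z, w, i, beta0=params.beta_tau[m, i], max_iter=25)
            return replace(params, beta_tau=beta_tau)
        if spec.group_tau:
            tau = np.empty((spec.n_groups, n_mat, s, s))
            for g, idx in enumerate(groups):
                c = fxi[idx].sum(axis=0)
                if spec.transition_invariance:
                    c = c.sum(axis=0, keepdims=True)
                tau[g] = _clamp_simplex(
                    c / np.maximum(c.sum(axis=2, keepdims=True), 1e-300),
                    self.clamp, axis=2)
            return replace(params, tau=tau)
        c = fxi.sum(axis=0)
        if spec.transition_invariance:
            c = c.sum(axis=0, keepdims=True)
        tau = _clamp_simplex(
            c / np.maximum(c.sum(axis=2, keepdims=True), 1e-300),
            self.clamp, axis=2)
        return replace(params, tau=tau)

    def _rho_counts(self, patterns, freq, gamma_all, spec, c_max):
        n_rows, t_occ, j_items = patterns.shape
        s = spec.n_statuses
        shape = (s, j_items, c_max) if spec.measurement_invariance \
            else (t_occ, s, j_items, c_max)
        counts = np.zeros(shape)
        for t in range(t_occ):
            w = freq[:, None] * gamma_all[:, t]       # (n_rows, S)
            tgt = counts if spec.measurement_invariance else counts[t]
            for j in range(j_items):
                codes = patterns[:, t, j]
                for c in range(1, spec.n_categories[j] + 1):
                    sel = codes == c
                    if sel.any():
                        tgt[:, j, c - 1] += w[sel].sum(axis=0)
        return counts

    # -- public API ---------------------------------------------------------

    def fit(self, X, y=None, *, covariates=None, group=None, init_params=None):
        (patterns, freq, n_cat, z_rows, g_rows, group_levels,
         n_eff) = self._prepare(X, covariates, group)
        t_occ = patterns.shape[1]
        n_groups = len(group_levels)
        n_cov = 0 if z_rows is None else z_rows.shape[1]
        if self.covariate_effects != "none" and n_cov == 0:
            raise ConfigurationError("covariate_effects set but no covariates "
                                     "supplied")
        spec = self._spec(n_cat, t_occ, n_groups, n_cov)
        if int(self.n_statuses) > patterns.shape[0]:
            warnings.warn(
                f"{self.n_statuses} statuses but only {patterns.shape[0]} "
                "distinct patterns; model likely not identified",
                IdentificationWarning, stacklevel=2)

        rng = np.random.default_rng(self.random_state)
        starts = [self._random_params(rng, spec)
                  for _ in range(int(self.n_starts))]
        for extra in (init_params or []):
            starts.append(self._coerce_init(extra, spec))

        best = None
        logliks, iter_counts, any_converged = [], [], False
        sparse_error = None
        for p0 in starts:
            try:
                params, ll, history, conv = self._em(
                    patterns, freq, spec, p0, z_rows, g_rows, n_groups)
            except SparsenessError:
                raise
            except EstimationError as exc:
                sparse_error = exc
                continue
            logliks.append(ll)
            iter_counts.append(len(history))
            any_converged |= conv
            if best is None or ll > best[1]:
                best = (params, ll, history, conv)
        if best is None:
            raise EstimationError(
                f"all {len(starts)} EM starts failed") from sparse_error
        if not any_converged:
            raise EstimationError(
                f"no EM start converged within {self.max_iter} iterations "
                f"(best log-likelihood {best[1]:.6f})")

        params, ll, history, conv = best
        params = self._sorted(params, spec, z_rows, g_rows, freq)
        self.spec_ = spec
        self.rho_ = params.rho
        self.delta_ = params.delta
        self.tau_ = params.tau
        self.beta_ = params.beta
        self.beta_tau_ = params.beta_tau
        self.loglik_ = ll
        self.loglik_path_ = history
        self.n_effective_ = n_eff
        self.group_levels_ = group_levels
        self.n_categories_ = n_cat
        n_at_best = int(sum(abs(l - ll) < _BEST_TOL for l in logliks))
        self.convergence_ = ConvergenceReport(len(starts), ll, n_at_best,
                                              iter_counts, conv)
        if len(starts) > 1 and n_at_best < 2:
            warnings.warn(
                "best log-likelihood reproduced by a single start only; "
                "treat the solution as possibly non-identified",
                IdentificationWarning, stacklevel=2)
        return self

    def _coerce_init(self, p, spec):
        """Adapt a warm-start parameter set to this model's storage shapes
        (e.g. expand an invariant rho across occasions for a free-rho fit,
        add zero covariate slopes to a covariate-free solution)."""
        if not isinstance(p, LTAParameters):
            raise ConfigurationError("init_params entries must be LTAParameters")
        rho = np.array(p.rho, dtype=float)
        if spec.measurement_invariance and rho.ndim == 4:
            rho = rho.mean(axis=0)
        elif not spec.measurement_invariance and rho.ndim == 3:
            rho = np.tile(rho, (spec.n_occasions, 1, 1, 1))
        tau = np.array(p.tau, dtype=float)
        if tau.ndim == 4:  # drop group axis, pool
            tau = tau.mean(axis=0)
        n_mat = 1 if spec.transition_invariance else max(spec.n_occasions - 1, 1)
        if tau.shape[0] != n_mat:
            tau = tau.mean(axis=0, keepdims=True) if n_mat == 1 \
                else np.tile(tau.mean(axis=0, keepdims=True), (n_mat, 1, 1))
        delta = np.array(p.delta, dtype=float)
        if delta.ndim == 2:
            delta = delta.mean(axis=0)
        if spec.group_delta:
            delta = np.tile(delta, (spec.n_groups, 1))
        if spec.group_tau:
            tau = np.tile(tau, (spec.n_groups, 1, 1, 1))
        s = spec.n_statuses
        beta = p.beta
        if spec.covariate_effects != "none" and beta is None:
            beta = np.zeros((s, 1 + spec.n_covariates))
            ref = self._ref(s)
            d = np.clip(delta if delta.ndim == 1 else delta[0],
                        self.clamp, None)
            beta[:, 0] = np.log(d / d[ref])
            beta[ref] = 0.0
        elif spec.covariate_effects == "none":
            beta = None
        beta_tau = p.beta_tau
        if spec.covariate_effects == "prevalence+transitions" and beta_tau is None:
            beta_tau = np.zeros((n_mat, s, s, 1 + spec.n_covariates))
            with np.errstate(divide="ignore"):
                t_clip = np.clip(tau if tau.ndim == 3 else tau[0],
                                 self.clamp, None)
                for m in range(n_mat):
                    for i in range(s):
                        beta_tau[m, i, :, 0] = np.log(t_clip[m, i]
                                                      / t_clip[m, i, i])
                        beta_tau[m, i, i, :] = 0.0
        elif spec.covariate_effects != "prevalence+transitions":
            beta_tau = None
        return LTAParameters(rho, delta, tau, beta, beta_tau)

    def _sorted(self, params, spec, z_rows, g_rows, freq):
        # rho constraints pin status identities to their indices, so the
        # reported solution must not be relabelled under them
        if not self.sort_statuses or spec.n_statuses == 1 \
                or spec.rho_constraints:
            return params
        if spec.covariate_effects != "none":
            d = params.delta
        elif spec.group_delta:
            d = params.delta.mean(axis=0)
        else:
            d = params.delta
        order = np.argsort(-np.asarray(d), kind="stable")
        return permute_statuses(params, order)

    @property
    def params_(self) -> LTAParameters:
        return LTAParameters(self.rho_, self.delta_, self.tau_, self.beta_,
                             self.beta_tau_)

    def posteriors(self, X, covariates=None, group=None):
        """Marginal and pairwise status posteriors for new data.

        Returns a dict with ``marginal`` (n, T, S), ``pairwise``
        (n, T-1, S, S), and ``loglik`` (n,). Rows follow the distinct-row
        order of ``rows`` in the result when input had to be compressed;
        raw (N, T, J) arrays are scored row-by-row in input order.
        """
        if isinstance(X, np.ndarray) and X.ndim == 3:
            patterns = np.asarray(X, dtype=np.int64)
            freq = np.ones(patterns.shape[0])
            z_rows = None if covariates is None else np.atleast_2d(
                np.asarray(covariates, dtype=float))
            if z_rows is not None and z_rows.shape[0] != patterns.shape[0]:
                z_rows = z_rows.T
            g_rows = None
            if group is not None:
                lookup = {lev: i for i, lev in enumerate(self.group_levels_)}
                g_rows = np.array([lookup[g] for g in np.asarray(group)])
        else:
            (patterns, freq, _, z_rows, g_rows, _, _) = self._prepare(
                X, covariates, group)
        spec = self.spec_
        t_occ = patterns.shape[1]
        params = self.params_
        B = self._emissions(patterns, params.rho, spec)
        delta_rows, _ = self._delta_rows(params, spec, z_rows, g_rows,
                                         patterns.shape[0])
        n_rows, s = patterns.shape[0], spec.n_statuses
        marginal = np.empty((n_rows, t_occ, s))
        pairwise = np.empty((n_rows, max(t_occ - 1, 0), s, s))
        ll_rows = np.empty(n_rows)
        groups = [np.arange(n_rows)] if g_rows is None else [
            np.where(g_rows == g)[0] for g in range(len(self.group_levels_))]
        for g, idx in enumerate(groups):
            if idx.size == 0:
                continue
            taus = self._taus_for(params, spec, g,
                                  z_rows[idx] if z_rows is not None else None,
                                  t_occ)
            ll_g, gamma, xi = _forward_backward(B[idx], delta_rows[idx], taus)
            marginal[idx], ll_rows[idx] = gamma, ll_g
            if t_occ > 1:
                pairwise[idx] = xi
        return {"marginal": marginal, "pairwise": pairwise,
                "loglik": ll_rows, "frequencies": freq}

    def predict_proba(self, X, **kw):
        return self.posteriors(X, **kw)["marginal"]

    def predict(self, X, **kw):
        return self.predict_proba(X, **kw).argmax(axis=2)

    def score(self, X, y=None, **kw):
        out = self.posteriors(X, **kw)
        return float(out["frequencies"] @ out["loglik"]
                     / out["frequencies"].sum())


def permute_statuses(params: LTAParameters, order) -> LTAParameters:
    """Relabel statuses of a parameter set by ``order`` (new i = old order[i])."""
    order = np.asarray(order)
    rho = params.rho[..., order, :, :] if params.rho.ndim == 4 \
        else params.rho[order]
    delta = params.delta[..., order]
    tau = params.tau[..., order, :][..., :, order]
    beta = None
    if params.beta is not None:
        # re-reference the logits to the first listed status (the largest one
        # when statuses are prevalence-sorted, as in the reported solution)
        beta = params.beta[order]
        beta = beta - beta[0]
    beta_tau = None
    if params.beta_tau is not None:
        beta_tau = params.beta_tau[:, order][:, :, order]
        for m in range(beta_tau.shape[0]):
            for i in range(beta_tau.shape[1]):
                beta_tau[m, i] = beta_tau[m, i] - beta_tau[m, i, i]
    return LTAParameters(rho, delta, tau, beta, beta_tau)


def fit_lta(table, spec: ModelSpec, *, init_params=None):
    """Functional wrapper over :class:`LatentTransitionAnalysis` for a joint
    pattern table. Returns (LTAParameters, ConvergenceReport, loglik)."""
    est = LatentTransitionAnalysis(
        spec.n_statuses, measurement_invariance=spec.measurement_invariance,
        transition_invariance=spec.transition_invariance,
        rho_constraints=spec.rho_constraints, n_starts=spec.n_starts,
        tol=spec.tol, max_iter=spec.max_iter, random_state=spec.random_state)
    est.fit(table, init_params=init_params)
    return est.params_, est.convergence_, est.loglik_


def status_posteriors(params: LTAParameters, table, n_categories=None):
    """Per-pattern marginal status posteriors per occasion and pairwise joint
    posteriors per adjacent-occasion pair, under fixed ``params``."""
    if isinstance(table, PatternTable):
        patterns = table.patterns
        n_categories = table.n_categories
    else:
        patterns = np.asarray(table, dtype=np.int64)
        if n_categories is None:
            n_categories = np.maximum(patterns.max(axis=(0, 1)), 1)
    s = params.n_statuses
    t_occ = patterns.shape[1]
    mi = params.rho.ndim == 3
    est = LatentTransitionAnalysis(s, measurement_invariance=mi,
                                   transition_invariance=params.tau.shape[0] == 1)
    est.spec_ = est._spec(n_categories, t_occ, 1, 0)
    est.rho_, est.delta_, est.tau_ = params.rho, params.delta, params.tau
    est.beta_ = est.beta_tau_ = None
    est.group_levels_ = [None]
    est.n_categories_ = np.asarray(n_categories)
    return est.posteriors(patterns)


def align_statuses(params_a, params_b):
    """Optimal status matching between two solutions by total absolute rho
    difference (exact assignment-problem solution).

    Returns ``(perm, distance)`` such that reordering b's statuses by ``perm``
    best matches a (``b.rho[perm[i]] ~ a.rho[i]``).
    """
    rho_a = params_a.rho if hasattr(params_a, "rho") else np.asarray(params_a)
    rho_b = params_b.rho if hasattr(params_b, "rho") else np.asarray(params_b)
    if rho_a.ndim == 4:
        rho_a = rho_a.mean(axis=0)
    if rho_b.ndim == 4:
        rho_b = rho_b.mean(axis=0)
    if rho_a.shape != rho_b.shape:
        raise ConfigurationError("status alignment requires matching "
                                 f"dimensions, got {rho_a.shape} vs {rho_b.shape}")
    s = rho_a.shape[0]
    cost = np.zeros((s, s))
    for i in range(s):
        for k in range(s):
            cost[i, k] = np.abs(rho_a[i] - rho_b[k]).sum()
    rows, cols = linear_sum_assignment(cost)
    return cols, float(cost[rows, cols].sum())
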