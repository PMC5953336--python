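"""Weighted multinomial logit by Newton-Raphson.

Used as the inner loop of the covariate M-step: expected status memberships
(fractional weights) regressed on respondent covariates with a reference
status. Dimensions are tiny ((S-1) x (K+1) coefficients), so an explicit
Hessian solve is cheap and robust.
"""

from __future__ import annotations

import numpy as np

from .errors import EstimationError


def softmax_rows(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def prevalence_probs(beta, Z, reference):
    """Per-row status probabilities. beta: (S, K+1) with reference row zero;
    Z: (n, K+1) design including intercept column."""
    return softmax_rows(Z @ beta.T)


def fit_weighted_multinomial(Z, W, reference, beta0=None, tol=1e-10,
                             max_iter=100, ridge=1e-10):
    """Maximize sum_i sum_s W[i,s] * log softmax_s(Z_i beta) over beta.

    Parameters
    ----------
    Z : (n, K+1) design matrix including the intercept column.
    W : (n, S) nonnegative weights (posterior memberships times frequency).
    reference : int, status whose coefficient row is pinned at zero.
    beta0 : optional warm start, shape (S, K+1).

    Returns
    -------
    beta : (S, K+1) with the reference row exactly zero.
    """
    n, p = Z.shape
    s = W.shape[1]
    free = [k for k in range(s) if k != reference]
    beta = np.zeros((s, p)) if beta0 is None else np.array(beta0, dtype=float)
    beta[reference] = 0.0
    w_i = W.sum(axis=1)

    def loglik(b):
        logits = Z @ b.T
        logits -= logits.max(axis=1, keepdims=True)
        lse = np.log(np.exp(logits).sum(axis=1))
        return float((W * logits).sum() - (w_i * lse).sum())

    ll = loglik(beta)
    for _ in range(max_iter):
        probs = prevalence_probs(beta, Z, reference)
        # gradient, free statuses stacked: g[(a,j)] over a in free, j in 0..p-1
        resid = W[:, free] - w_i[:, None] * probs[:, free]
        grad = (Z.T @ resid).T.reshape(-1)          # (len(free)*p,)
        if np.max(np.abs(grad)) < 1e-9 * (1.0 + abs(ll)):
            break
        nf = len(free)
        hess = np.zeros((nf * p, nf * p))
        for a_i, a in enumerate(free):
            for b_i, b in enumerate(free):
                coef = w_i * probs[:, a] * ((a == b) - probs[:, b])
                block = Z.T @ (coef[:, None] * Z)
                hess[a_i * p:(a_i + 1) * p, b_i * p:(b_i + 1) * p] = block
        hess[np.diag_indices_from(hess)] += ridge
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular Hessian in multinomial logit") from exc
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta.copy()
            cand[free] += scale * step.reshape(nf, p)
            new_ll = loglik(cand)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        if not np.all(np.isfinite(cand)):
            raise EstimationError("divergent multinomial-logit coefficients")
        improved = new_ll - ll
        beta, ll = cand, new_ll
        if improved < tol * (abs(ll) + 1.0):
            break
    return beta
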