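"""Fit statistics for latent class/transition models.

Conventions:

* ``W`` is the number of possible complete-response cells,
  ``(prod_j C_j) ** T`` — e.g. six binary items over three occasions give
  ``(2**6) ** 3 = 262144``.
* ``P`` counts free parameters from the model structure alone.
* Residual degrees of freedom are ``df = W - P - 1``.
* ``G2 = 2 * (loglik_saturated - loglik_model)`` against the saturated
  pattern model. With missing data the saturated reference is computed within
  each missingness-pattern stratum (each stratum's observed sub-patterns at
  their empirical proportions), which keeps G2 nonnegative and comparable
  across nested fits.
* Criteria: ``AIC = G2 + 2P``, ``BIC = G2 + ln(N) P``,
  ``CAIC = G2 + (ln(N) + 1) P``, ``ABIC = G2 + ln((N + 2) / 24) P``. The
  identities ``AIC - G2 = 2P`` and ``CAIC - BIC = P`` hold exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .errors import (ConfigurationError, EstimationError,
                     UnderIdentifiedError, UndefinedStatisticWarning)
from .lta import ModelSpec, _n_constrained_params
from .panel import MISSING, PatternTable


@dataclass
class FitStatistics:
    """Summary statistics of one converged ML fit."""

    loglik: float
    G2: float
    P: int
    W: int
    df: int
    AIC: float
    BIC: float
    CAIC: float
    ABIC: float
    entropy: float
    N_effective: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("loglik", "G2", "P", "W", "df", "AIC", "BIC", "CAIC",
                 "ABIC", "entropy", "N_effective")}


@dataclass
class ComparisonResult:
    """Likelihood-ratio difference test between nested fits, with criterion
    deltas (restricted minus free) and the decision the configured rule
    produced."""

    G2_delta: float
    df_delta: int
    p_value: float
    delta_AIC: float
    delta_BIC: float
    decision: str
    rule: str
    conflict: bool = False
    notes: list = field(default_factory=list)


def count_parameters(spec: ModelSpec) -> int:
    """Free parameters implied by a model structure.

    rho contributes ``S * sum_j (C_j - 1)`` per distinct occasion set, delta
    ``S - 1`` per group (or ``(S - 1)(1 + K)`` logit coefficients with
    prevalence covariates), tau ``S (S - 1)`` per distinct transition matrix
    per group (times ``1 + K`` with transition covariates). Constraints on
    rho reduce the count accordingly.
    """
    s = spec.n_statuses
    t = spec.n_occasions
    k = spec.n_covariates if spec.covariate_effects != "none" else 0

    rho_sets = 1 if spec.measurement_invariance else t
    p_rho = s * sum(c - 1 for c in spec.n_categories) * rho_sets
    p_rho -= _n_constrained_params(spec)

    delta_groups = spec.n_groups if spec.group_delta else 1
    if spec.covariate_effects != "none":
        p_delta = (s - 1) * (1 + k)
    else:
        p_delta = (s - 1) * delta_groups

    if t < 2:
        p_tau = 0
    else:
        n_mat = 1 if spec.transition_invariance else t - 1
        if spec.group_tau:
            n_mat *= spec.n_groups
        per_row = (s - 1) * (1 + k) if spec.covariate_effects == \
            "prevalence+transitions" else (s - 1)
        p_tau = n_mat * s * per_row
    return int(p_rho + p_delta + p_tau)


def residual_df(spec: ModelSpec, W: int = None) -> int:
    """``df = W - P - 1``. Raises when negative (under-identified)."""
    if W is None:
        per_occ = int(np.prod([int(c) for c in spec.n_categories]))
        W = per_occ ** spec.n_occasions
    df = int(W) - count_parameters(spec) - 1
    if df < 0:
        raise UnderIdentifiedError(
            f"negative residual df ({df}): W={W}, P={count_parameters(spec)}")
    return df


def saturated_loglik(table: PatternTable) -> float:
    """Log-likelihood of the saturated pattern model, stratified by
    missingness pattern: within each stratum every observed sub-pattern gets
    its empirical proportion."""
    masks = table.patterns.reshape(table.n_patterns, -1) == MISSING
    _, stratum = np.unique(masks, axis=0, return_inverse=True)
    f = table.frequencies.astype(float)
    n_stratum = np.bincount(stratum, weights=f)
    ll = float(np.sum(f * (np.log(f) - np.log(n_stratum[stratum]))))
    return ll


def gsquared(loglik_model: float, table: PatternTable) -> float:
    """Likelihood-ratio statistic of a fitted model against the saturated
    pattern model on the same data."""
    g2 = 2.0 * (saturated_loglik(table) - loglik_model)
    if g2 < -1e-6:
        raise EstimationError(
            f"negative G2 ({g2:.3g}): the fit is not a converged ML solution "
            "for this table")
    return max(g2, 0.0)


def information_criteria(G2: float, P: int, N_effective: int) -> dict:
    """AIC/BIC/CAIC/ABIC on the G2 scale."""
    if P < 0 or N_effective < 1:
        raise ConfigurationError("P must be >= 0 and N >= 1")
    ln_n = np.log(N_effective)
    return {
        "AIC": G2 + 2.0 * P,
        "BIC": G2 + ln_n * P,
        "CAIC": G2 + (ln_n + 1.0) * P,
        "ABIC": G2 + np.log((N_effective + 2.0) / 24.0) * P,
    }


def relative_entropy(posteriors, weights=None) -> float:
    """Relative entropy of a posterior classification, in [0, 1].

    ``1 - sum_i w_i sum_s (-p_is ln p_is) / (N ln S)``: 1 means perfectly
    crisp assignment, 0 an uninformative classification. Undefined at S = 1
    (returns NaN with a warning).
    """
    post = np.asarray(posteriors, dtype=float)
    n, s = post.shape
    if s == 1:
        warnings.warn("entropy is undefined for a one-class model",
                      UndefinedStatisticWarning, stacklevel=2)
        return np.nan
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    total = -(w @ plogp.sum(axis=1))
    return float(1.0 - total / (w.sum() * np.log(s)))


def fit_statistics(loglik: float, table: PatternTable, spec: ModelSpec,
                   posteriors=None, weights=None,
                   N_effective: int = None) -> FitStatistics:
    """Assemble the full statistics block for a converged fit."""
    if N_effective is None:
        N_effective = table.n
    g2 = gsquared(loglik, table)
    p = count_parameters(spec)
    w_cells = table.W
    df = residual_df(spec, w_cells)
    crit = information_criteria(g2, p, N_effective)
    if posteriors is not None and spec.n_statuses > 1:
        ent = relative_entropy(posteriors, weights)
    else:
        ent = np.nan
    return FitStatistics(loglik=loglik, G2=g2, P=p, W=w_cells, df=df,
                         entropy=ent, N_effective=int(N_effective), **crit)


def lrdt(fit_restricted: FitStatistics, fit_free: FitStatistics,
         alpha: float = 0.05, rule: str = "lrdt") -> ComparisonResult:
    """Likelihood-ratio difference test of nested fits on the same data.

    ``G2_delta = G2_restricted - G2_free`` is referred to a chi-square with
    ``df_delta = P_free - P_restricted``. The chi-square reference is only
    regular for nested fits with the same number of statuses; class
    enumeration must use information criteria instead.
    """
    df_delta = fit_free.P - fit_restricted.P
    if df_delta < 0:
        raise ConfigurationError(
            "the free model must have more parameters than the restricted one")
    g2_delta = fit_restricted.G2 - fit_free.G2
    if g2_delta < -1e-6:
        raise EstimationError(
            f"negative G2 difference ({g2_delta:.3g}); the models are not "
            "nested or one fit did not converge")
    g2_delta = max(g2_delta, 0.0)
    p_value = float(chi2.sf(g2_delta, df_delta)) if df_delta > 0 else 1.0
    if df_delta == 0 and g2_delta <= 1e-6:
        p_value = 1.0
    delta_aic = fit_restricted.AIC - fit_free.AIC
    delta_bic = fit_restricted.BIC - fit_free.BIC

    lrdt_says_restricted = p_value > alpha
    aic_says_restricted = delta_aic <= 0
    decision = "restricted_retained" if lrdt_says_restricted else "free_preferred"
    conflict = lrdt_says_restricted != aic_says_restricted
    notes = []
    if conflict:
        notes.append(
            f"LRDT (p={p_value:.4g}) and AIC (delta={delta_aic:.2f}) disagree; "
            f"decision follows rule {rule!r}")
    return ComparisonResult(G2_delta=g2_delta, df_delta=int(df_delta),
                            p_value=p_value, delta_AIC=delta_aic,
                            delta_BIC=delta_bic, decision=decision,
                            rule=f"{rule}@alpha={alpha}", conflict=conflict,
                            notes=notes)
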