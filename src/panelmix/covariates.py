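"""Covariates on the latent structure: one-step multinomial-logit effects.

Respondent covariates enter the first-occasion status prevalences (and
optionally the transition rows) through multinomial logits estimated
simultaneously with the measurement model — the one-step approach, not a
classify-and-analyze correction. Effects are tested by the likelihood-ratio
difference between the model with slopes and the model with slopes pinned at
zero; odds ratios are entrywise ``exp(beta)`` per unit of the supplied
covariate (raw scale by default; centering is the caller's choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluation import ComparisonResult, FitStatistics, lrdt
from .lta import LatentTransitionAnalysis, LTAParameters


@dataclass
class LogitCoefficients:
    """Multinomial-logit coefficients on latent prevalence (or one transition
    row): ``beta[s, 0]`` intercepts, ``beta[s, 1:]`` covariate slopes, with
    the reference status row identically zero."""

    beta: np.ndarray
    reference_status: int
    covariate_names: list
    scope: str = "prevalence"

    def to_frame(self) -> pd.DataFrame:
        s = self.beta.shape[0]
        rows = ["intercept"] + list(self.covariate_names)
        data = {}
        for k in range(s):
            col = f"status{k + 1}"
            if k == self.reference_status:
                data[col] = ["Reference"] * len(rows)
            else:
                data[col] = [f"{v:.4f}" for v in self.beta[k]]
        return pd.DataFrame(data, index=rows)


def fit_lta_with_covariates(panel, spec_or_estimator, covariate_names,
                            *, on_transitions=False, init_params=None,
                            random_state=None):
    """One-step LTA with covariates on prevalence (optionally transitions).

    ``spec_or_estimator`` may be a fitted or unfitted
    :class:`LatentTransitionAnalysis` (its structure settings are reused) or
    a :class:`~panelmix.lta.ModelSpec`. Returns the fitted estimator; its
    ``beta_`` holds the prevalence coefficients.
    """
    if isinstance(spec_or_estimator, LatentTransitionAnalysis):
        base = spec_or_estimator.get_params()
    else:
        sp = spec_or_estimator
        base = dict(n_statuses=sp.n_statuses,
                    measurement_invariance=sp.measurement_invariance,
                    transition_invariance=sp.transition_invariance,
                    rho_constraints=sp.rho_constraints,
                    n_starts=sp.n_starts, tol=sp.tol, max_iter=sp.max_iter,
                    random_state=sp.random_state)
    base["covariate_effects"] = ("prevalence+transitions" if on_transitions
                                 else "prevalence")
    if random_state is not None:
        base["random_state"] = random_state
    est = LatentTransitionAnalysis(base.pop("n_statuses"), **base)
    est.fit(panel, covariates=list(covariate_names), init_params=init_params)
    return est


def coefficients(estimator, covariate_names=None) -> LogitCoefficients:
    """Extract prevalence-logit coefficients from a covariate LTA fit."""
    if estimator.beta_ is None:
        raise ConfigurationError("fit has no covariate coefficients")
    ref = int(np.argmin(np.abs(estimator.beta_).sum(axis=1)))
    names = covariate_names or [f"x{k + 1}"
                                for k in range(estimator.beta_.shape[1] - 1)]
    return LogitCoefficients(estimator.beta_, ref, list(names))


def odds_ratios(coef: LogitCoefficients) -> pd.DataFrame:
    """Entrywise ``exp(beta)``; the reference status column reads 'Reference'."""
    if not np.all(np.isfinite(coef.beta)):
        raise ConfigurationError("coefficients must be finite")
    s = coef.beta.shape[0]
    rows = ["intercept"] + list(coef.covariate_names)
    data = {}
    for k in range(s):
        col = f"status{k + 1}"
        if k == coef.reference_status:
            data[col] = ["Reference"] * len(rows)
        else:
            data[col] = np.exp(coef.beta[k]).tolist()
    return pd.DataFrame(data, index=rows)


def covariate_effect_test(fit_with: FitStatistics, fit_without: FitStatistics,
                          alpha: float = 0.05) -> ComparisonResult:
    """LRDT of the covariate effect: the restricted model pins all slopes at
    zero, so ``df_delta`` equals the number of slope parameters."""
    return lrdt(fit_without, fit_with, alpha=alpha, rule="lrdt")
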