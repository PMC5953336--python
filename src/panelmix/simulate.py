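"""Synthetic categorical panels drawn from fully specified latent-chain truths.

The generator mirrors the structure of a school-survey panel: a handful of
binary (or polytomous) items measured at a few occasions, a small set of
latent statuses with status-specific item-response profiles, first-occasion
prevalences, occasion-specific transition matrices, an optional covariate
shifting the prevalence logits, and monotone attrition at later waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel import MISSING, ResponsePanel


@dataclass
class SimulationTruth:
    """Generating parameters for a latent-chain categorical panel.

    Attributes
    ----------
    rho : ndarray
        Item-response probabilities, shape (S, J, C) when shared across
        occasions or (T, S, J, C) when occasion-varying.
    delta : ndarray, shape (S,)
        First-occasion status prevalences.
    tau : ndarray
        Transition matrices, shape (T-1, S, S) or (1, S, S) shared.
    n_occasions : int
    n_categories : ndarray of int, shape (J,)
    covariate_slopes : ndarray or None, shape (S,)
        Prevalence-logit slopes per status (reference status slope 0). When
        set, each respondent draws a standard-normal covariate ``z`` (unless
        ``covariate_values`` supplies them) and starts the chain from
        ``softmax(log(delta / delta_ref) + slopes * z)``.
    covariate_values : ndarray or None
        Per-respondent covariate values overriding the normal draw.
    attrition : tuple of float
        Per-wave overall missing-everything rates, length T, first entry 0.
        Dropout is monotone: once out, out for good.
    item_missing_rate : float
        Sporadic per-cell missingness applied on top of attrition.
    n_respondents : int
    items : list of str
    """

    rho: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    n_occasions: int
    n_categories: np.ndarray
    covariate_slopes: np.ndarray = None
    covariate_values: np.ndarray = None
    attrition: tuple = None
    item_missing_rate: float = 0.0
    n_respondents: int = 1000
    items: list = None

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.rho.ndim not in (3, 4):
            raise ConfigurationError("rho must be (S,J,C) or (T,S,J,C)")
        s = self.delta.shape[0]
        if not np.isclose(self.delta.sum(), 1.0, atol=1e-8):
            raise ConfigurationError("delta must sum to 1")
        if self.tau.ndim != 3 or self.tau.shape[1:] != (s, s):
            raise ConfigurationError("tau must be (n_mat, S, S)")
        if not np.allclose(self.tau.sum(axis=2), 1.0, atol=1e-8):
            raise ConfigurationError("tau rows must sum to 1")
        if self.attrition is None:
            self.attrition = tuple([0.0] * self.n_occasions)
        if len(self.attrition) != self.n_occasions:
            raise ConfigurationError("attrition needs one rate per occasion")
        if any(not 0 <= a < 1 for a in self.attrition):
            raise ConfigurationError("attrition rates must be in [0, 1)")
        if any(b < a - 1e-12 for a, b in zip(self.attrition, self.attrition[1:])):
            raise ConfigurationError("attrition rates must be non-decreasing")
        if self.items is None:
            self.items = [f"item{j + 1}" for j in range(self.rho.shape[-2])]

    @property
    def n_statuses(self) -> int:
        return self.delta.shape[0]

    @property
    def n_items(self) -> int:
        return self.rho.shape[-2]

    def rho_at(self, t: int) -> np.ndarray:
        return self.rho if self.rho.ndim == 3 else self.rho[t]

    def tau_at(self, t: int) -> np.ndarray:
        """Transition matrix from occasion t to t+1 (0-based)."""
        return self.tau[0] if self.tau.shape[0] == 1 else self.tau[t]


def simulate_panel(truth: SimulationTruth, seed=None):
    """Draw a panel from ``truth``.

    Returns ``(panel, states)`` where ``states`` is the (N, T) array of true
    status indices (0-based) — attrition does not erase the latent path, so
    recovery tests can score every occasion. Identical seeds give identical
    panels.
    """
    rng = np.random.default_rng(seed)
    n, t_occ, j_items = truth.n_respondents, truth.n_occasions, truth.n_items
    s = truth.n_statuses

    if truth.covariate_slopes is not None:
        slopes = np.asarray(truth.covariate_slopes, dtype=float)
        if truth.covariate_values is not None:
            z = np.asarray(truth.covariate_values, dtype=float)
        else:
            z = rng.standard_normal(n)
        ref = int(np.argmax(truth.delta))
        intercepts = np.log(truth.delta / truth.delta[ref])
        logits = intercepts[None, :] + slopes[None, :] * z[:, None]
        logits -= logits.max(axis=1, keepdims=True)
        delta_i = np.exp(logits)
        delta_i /= delta_i.sum(axis=1, keepdims=True)
    else:
        z = None
        delta_i = np.broadcast_to(truth.delta, (n, s))

    states = np.zeros((n, t_occ), dtype=np.int64)
    u = rng.random(n)
    states[:, 0] = (u[:, None] >= np.cumsum(delta_i, axis=1)).sum(axis=1)
    for t in range(1, t_occ):
        tau = truth.tau_at(t - 1)
        cum = np.cumsum(tau, axis=1)
        u = rng.random(n)
        states[:, t] = (u[:, None] >= cum[states[:, t - 1]]).sum(axis=1)

    responses = np.zeros((n, t_occ, j_items), dtype=np.int64)
    for t in range(t_occ):
        rho = truth.rho_at(t)
        for j in range(j_items):
            c = int(truth.n_categories[j])
            cum = np.cumsum(rho[:, j, :c], axis=1)
            u = rng.random(n)
            responses[:, t, j] = 1 + (u[:, None] >= cum[states[:, t]]).sum(axis=1)

    # monotone attrition: wave-t overall missing rate = attrition[t]
    dropped = np.zeros(n, dtype=bool)
    for t in range(1, t_occ):
        target, prev = truth.attrition[t], truth.attrition[t - 1]
        hazard = 0.0 if target <= prev else (target - prev) / (1.0 - prev)
        dropped |= (~dropped) & (rng.random(n) < hazard)
        responses[dropped, t, :] = MISSING

    if truth.item_missing_rate > 0:
        sporadic = rng.random(responses.shape) < truth.item_missing_rate
        responses[sporadic] = MISSING

    cov = None
    if z is not None:
        cov = pd.DataFrame({"z": z})
    panel = ResponsePanel(responses, truth.n_categories, list(truth.items),
                          covariates=cov)
    return panel, states


# Printed 4-status estimates from the bullying-concerns illustration:
# item-response "Yes" probabilities, first-occasion prevalences, and the two
# transition matrices. Items: six concern forms, binary No/Yes after
# dichotomization. Status rows follow the published table order (the third
# status, concerned about all forms, is the smallest, not the third-largest).
_ITEMS = ["Physical", "Talking", "Cultural", "Belief", "Spread", "Verbal"]

_RHO_YES_4 = np.array([
    [0.0380, 0.0375, 0.0035, 0.0087, 0.0549, 0.0156],   # not concerned
    [0.3386, 0.3568, 0.0715, 0.1437, 0.7499, 0.5932],   # rumor-concerned
    [0.7844, 0.8232, 0.7326, 0.9664, 0.9597, 0.9890],   # concerned about all forms
    [0.2357, 0.2919, 0.3276, 0.6014, 0.5069, 0.3083],   # exclusion-concerned
])

_DELTA_4 = np.array([0.5691, 0.2395, 0.0804, 0.1109])

_TAU_12 = np.array([
    [0.8252, 0.0925, 0.0208, 0.0615],
    [0.2780, 0.5734, 0.0893, 0.0594],
    [0.2707, 0.3309, 0.3785, 0.0198],
    [0.3432, 0.0000, 0.0739, 0.5829],
])

_TAU_23 = np.array([
    [0.8518, 0.0703, 0.0143, 0.0637],
    [0.3666, 0.5473, 0.0861, 0.0000],
    [0.2639, 0.0287, 0.4959, 0.2114],
    [0.5492, 0.0000, 0.0000, 0.4508],
])

# wave-2 and wave-3 attrition rates of the survey panel
_ATTRITION = (0.0, 0.0559, 0.1534)


def make_paper_like_truth(S: int = 4, n_respondents: int = 1180,
                          attrition: tuple = _ATTRITION) -> SimulationTruth:
    """A realistic generating truth shaped like the published survey analysis.

    ``S=4`` uses the printed 4-status item-response profiles, first-occasion
    prevalences, and both transition matrices (rows renormalized to absorb
    printing rounding). ``S=3`` is synthesized from the same tables by a
    prevalence-weighted merge of the two middle statuses (indices 1 and 3),
    which are the pair that collapses in the 3-status solution; it is a
    package construction, not a published estimate.
    """
    if S not in (3, 4):
        raise ConfigurationError("paper-like truths exist for S in {3, 4}")
    rho_yes, delta = _RHO_YES_4, _DELTA_4
    tau12 = _TAU_12 / _TAU_12.sum(axis=1, keepdims=True)
    tau23 = _TAU_23 / _TAU_23.sum(axis=1, keepdims=True)
    if S == 3:
        w = delta[[1, 3]] / delta[[1, 3]].sum()
        rho_yes = np.vstack([
            rho_yes[0],
            w[0] * rho_yes[1] + w[1] * rho_yes[3],
            rho_yes[2],
        ])
        merge = np.zeros((4, 3))
        merge[0, 0] = merge[2, 2] = 1.0
        merge[1, 1] = merge[3, 1] = 1.0
        # rows: weight origin statuses by prevalence; columns: sum destinations
        row_w = np.array([[1, 0, 0, 0], [0, w[0], 0, w[1]], [0, 0, 1, 0]])
        tau12 = row_w @ tau12 @ merge
        tau23 = row_w @ tau23 @ merge
        tau12 /= tau12.sum(axis=1, keepdims=True)
        tau23 /= tau23.sum(axis=1, keepdims=True)
        delta = np.array([delta[0], delta[1] + delta[3], delta[2]])
    rho = np.stack([1.0 - rho_yes, rho_yes], axis=2)  # categories (No, Yes)
    return SimulationTruth(
        rho=rho,
        delta=delta / delta.sum(),
        tau=np.stack([tau12, tau23]),
        n_occasions=3,
        n_categories=np.full(6, 2),
        attrition=attrition,
        n_respondents=n_respondents,
        items=list(_ITEMS),
    )
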