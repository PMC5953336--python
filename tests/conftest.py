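"""Shared fixtures: simulated panels and brute-force oracles.

The brute-force helpers here enumerate status sequences directly (O(S^T));
they are deliberately independent of the forward-backward implementation
they check.
"""

import itertools

import numpy as np
import pytest

from panelmix import SimulationTruth, make_paper_like_truth, simulate_panel


def brute_force_loglik(patterns, rho, delta, tau):
    """Log-likelihood per pattern by explicit enumeration of all S^T status
    sequences. rho (S, J, C) or (T, S, J, C); tau (T-1, S, S); code 0 is
    missing and contributes nothing."""
    s = delta.shape[0]
    n, t_occ, j_items = patterns.shape
    out = np.empty(n)
    for i, p in enumerate(patterns):
        total = 0.0
        for seq in itertools.product(range(s), repeat=t_occ):
            pr = delta[seq[0]]
            for t in range(t_occ - 1):
                pr *= tau[t, seq[t], seq[t + 1]]
            for t in range(t_occ):
                r = rho if rho.ndim == 3 else rho[t]
                for j in range(j_items):
                    c = p[t, j]
                    if c > 0:
                        pr *= r[seq[t], j, c - 1]
            total += pr
        out[i] = np.log(total)
    return out


def brute_force_marginals(patterns, rho, delta, tau):
    """Per-occasion status posteriors by sequence enumeration."""
    s = delta.shape[0]
    n, t_occ, j_items = patterns.shape
    marg = np.zeros((n, t_occ, s))
    for i, p in enumerate(patterns):
        for seq in itertools.product(range(s), repeat=t_occ):
            pr = delta[seq[0]]
            for t in range(t_occ - 1):
                pr *= tau[t, seq[t], seq[t + 1]]
            for t in range(t_occ):
                r = rho if rho.ndim == 3 else rho[t]
                for j in range(j_items):
                    c = p[t, j]
                    if c > 0:
                        pr *= r[seq[t], j, c - 1]
            for t in range(t_occ):
                marg[i, t, seq[t]] += pr
        marg[i] /= marg[i].sum(axis=1, keepdims=True)
    return marg


def crisp_truth(n_respondents=700, tau_diag=0.8, hi=0.9, lo=0.1):
    """Well-separated 3-status truth on 6 binary items over 3 occasions."""
    j = 6
    rho_yes = np.array([[lo] * j, [hi] * 3 + [lo] * 3, [hi] * j])
    rho = np.stack([1.0 - rho_yes, rho_yes], axis=2)
    off = (1.0 - tau_diag) / 2.0
    tau_one = np.full((3, 3), off) + (tau_diag - off) * np.eye(3)
    return SimulationTruth(
        rho=rho, delta=np.array([0.5, 0.3, 0.2]),
        tau=np.stack([tau_one, tau_one]), n_occasions=3,
        n_categories=np.full(j, 2), n_respondents=n_respondents)


@pytest.fixture(scope="session")
def paper_truth():
    return make_paper_like_truth(4)


@pytest.fixture(scope="session")
def paper_panel(paper_truth):
    panel, states = simulate_panel(paper_truth, seed=20240501)
    return panel, states


@pytest.fixture(scope="session")
def crisp_panel():
    panel, states = simulate_panel(crisp_truth(), seed=11)
    return panel, states


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
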