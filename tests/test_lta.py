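"""Latent transition EM: enumeration oracles, nesting, recovery, alignment."""

import itertools
import warnings

import numpy as np
import pytest

import panelmix as pm
from panelmix.lta import LatentTransitionAnalysis, LTAParameters
from conftest import brute_force_loglik, brute_force_marginals, crisp_truth


def random_params(rng, s, t, j=2, c=2):
    rho = rng.dirichlet(np.ones(c), size=(s, j))
    delta = rng.dirichlet(np.ones(s))
    tau = rng.dirichlet(np.ones(s), size=(max(t - 1, 1), s))
    return LTAParameters(rho, delta, tau)


def random_patterns(rng, n, t, j=2, c=2, with_missing=True):
    lo = 0 if with_missing else 1
    pats = rng.integers(lo, c + 1, size=(n, t, j))
    # ensure nothing is entirely missing
    pats[:, 0, 0] = rng.integers(1, c + 1, size=n)
    return pats


def quiet_fit(est, X, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", pm.IdentificationWarning)
        return est.fit(X, **kw)


@pytest.mark.parametrize("s,t", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 2),
                                 (4, 4)])
def test_forward_backward_matches_enumeration(s, t, rng):
    params = random_params(rng, s, t)
    pats = random_patterns(rng, 10, t)
    out = pm.status_posteriors(params, pats, n_categories=np.full(2, 2))
    ll = brute_force_loglik(pats, params.rho, params.delta, params.tau)
    marg = brute_force_marginals(pats, params.rho, params.delta, params.tau)
    assert np.abs(out["loglik"] - ll).max() < 1e-10
    assert np.abs(out["marginal"] - marg).max() < 1e-10
    # pairwise joints marginalize to adjacent marginals
    pair = out["pairwise"]
    assert np.abs(pair.sum(axis=3) - out["marginal"][:, :-1]).max() < 1e-10
    assert np.abs(pair.sum(axis=2) - out["marginal"][:, 1:]).max() < 1e-10


def test_loglik_at_fitted_params_matches_enumeration(rng):
    pats = random_patterns(rng, 12, 3, with_missing=False)
    table = pm.PatternTable(pats, np.ones(12, dtype=int), np.full(2, 2))
    est = quiet_fit(LatentTransitionAnalysis(2, n_starts=5, random_state=3),
                    table)
    ll = brute_force_loglik(pats, est.rho_, est.delta_, est.tau_)
    assert est.loglik_ == pytest.approx(float(ll.sum()), abs=1e-10)


class TestOneStatus:
    def test_closed_form_and_unit_transition(self, crisp_panel):
        panel, _ = crisp_panel
        table = pm.pattern_frequencies(panel)
        est = quiet_fit(LatentTransitionAnalysis(1, n_starts=1,
                                                 random_state=0), table)
        assert np.allclose(est.tau_, 1.0)
        # closed form: independent multinomials over all observed item cells
        ll = 0.0
        for p, f in zip(table.patterns, table.frequencies):
            for t in range(3):
                for j in range(6):
                    c = p[t, j]
                    if c > 0:
                        ll += f * np.log(est.rho_[0, j, c - 1])
        assert est.loglik_ == pytest.approx(ll, abs=1e-6)

    def test_posteriors_all_one(self, rng):
        params = random_params(rng, 1, 3)
        out = pm.status_posteriors(params, random_patterns(rng, 5, 3),
                                   n_categories=np.full(2, 2))
        assert np.allclose(out["marginal"], 1.0)


def test_uninformative_items_give_prior_chain_marginals(rng):
    s, t = 3, 3
    params = random_params(rng, s, t)
    params.rho[:] = 0.5
    pats = random_patterns(rng, 6, t, with_missing=False)
    out = pm.status_posteriors(params, pats, n_categories=np.full(2, 2))
    prior = params.delta
    for occ in range(t):
        assert np.allclose(out["marginal"][:, occ], prior, atol=1e-12)
        if occ < t - 1:
            prior = prior @ params.tau[occ]


def test_em_loglik_monotone_per_iteration(crisp_panel):
    panel, _ = crisp_panel
    table = pm.pattern_frequencies(panel)
    est = quiet_fit(LatentTransitionAnalysis(3, n_starts=2, random_state=0),
                    table)
    assert np.all(np.diff(est.loglik_path_) >= -1e-9)


def test_parameter_recovery_three_status_invariant(rng):
    truth = crisp_truth(n_respondents=3000, tau_diag=0.8)
    panel, _ = pm.simulate_panel(truth, seed=21)
    table = pm.pattern_frequencies(panel)
    est = quiet_fit(LatentTransitionAnalysis(3, n_starts=8, random_state=2),
                    table)
    perm, _ = pm.align_statuses(truth.rho, est.rho_)
    assert np.abs(est.rho_[perm] - truth.rho).max() < 0.04
    assert np.abs(est.delta_[perm] - truth.delta).max() < 0.04
    assert np.abs(est.tau_[:, perm][:, :, perm] - truth.tau).max() < 0.04


class TestAlignment:
    def test_identity(self, rng):
        p = random_params(rng, 3, 3)
        perm, dist = pm.align_statuses(p, p)
        assert perm.tolist() == [0, 1, 2] and dist == pytest.approx(0.0)

    def test_recovers_constructed_swap(self, rng):
        a = random_params(rng, 3, 3)
        order = [2, 1, 0]
        b = pm.permute_statuses(a, order)
        perm, dist = pm.align_statuses(a, b)
        # b[perm[i]] must equal a[i]: b[k]=a[order[k]] so perm inverts order
        assert np.allclose(b.rho[perm], a.rho)
        assert dist == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("s", [2, 3, 4])
    def test_matches_exhaustive_search(self, s, rng):
        a = random_params(rng, s, 2, j=3)
        b = random_params(rng, s, 2, j=3)
        perm, dist = pm.align_statuses(a, b)
        best = min(
            sum(np.abs(a.rho[i] - b.rho[p[i]]).sum() for i in range(s))
            for p in itertools.permutations(range(s)))
        assert dist == pytest.approx(best, abs=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(pm.ConfigurationError):
            pm.align_statuses(random_params(rng, 2, 2).rho,
                              random_params(rng, 3, 2).rho)


def test_nested_models_order_logliks(paper_panel):
    panel, _ = paper_panel
    table = pm.pattern_frequencies(panel)
    inv = quiet_fit(LatentTransitionAnalysis(3, n_starts=6, random_state=5),
                    table)
    free = quiet_fit(
        LatentTransitionAnalysis(3, measurement_invariance=False, n_starts=4,
                                 random_state=5),
        table, init_params=[inv.params_])
    con = [{"type": "fix", "status": 0, "item": 0, "category": 1,
            "value": 0.05}]
    restricted = quiet_fit(
        LatentTransitionAnalysis(3, rho_constraints=con, n_starts=4,
                                 random_state=5),
        table, init_params=[inv.params_])
    assert free.loglik_ >= inv.loglik_ - 1e-8
    assert inv.loglik_ >= restricted.loglik_ - 1e-8


def test_g2_difference_equals_twice_loglik_difference(paper_panel):
    panel, _ = paper_panel
    table = pm.pattern_frequencies(panel)
    inv = quiet_fit(LatentTransitionAnalysis(3, n_starts=5, random_state=7),
                    table)
    ti = quiet_fit(
        LatentTransitionAnalysis(3, transition_invariance=True, n_starts=5,
                                 random_state=7), table)
    st_free = pm.fit_statistics(inv.loglik_, table, inv.spec_)
    st_ti = pm.fit_statistics(ti.loglik_, table, ti.spec_)
    cmp_ = pm.lrdt(st_ti, st_free)
    assert cmp_.G2_delta == pytest.approx(2 * (inv.loglik_ - ti.loglik_),
                                          abs=1e-8)
    assert cmp_.df_delta == st_free.P - st_ti.P


def test_identical_repeated_data_reduces_to_single_occasion_lca(rng):
    # each respondent repeats the same crisp response at all occasions
    rho_yes = np.array([[0.95] * 4, [0.05] * 4])
    n = 800
    classes = rng.choice(2, size=n, p=[0.55, 0.45])
    once = 1 + (rng.random((n, 4)) < rho_yes[classes]).astype(int)
    resp = np.repeat(once[:, None, :], 3, axis=1)
    lta = quiet_fit(LatentTransitionAnalysis(2, n_starts=6, random_state=1),
                    resp)
    lca = pm.LatentClassAnalysis(2, n_starts=6, random_state=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lca.fit(once)
    # transitions collapse to (near) identity and rho matches the LCA rho
    assert np.abs(np.diagonal(lta.tau_, axis1=1, axis2=2) - 1.0).max() < 1e-3
    perm, _ = pm.align_statuses(lca.rho_[:, :, :2], lta.rho_[:, :, :2])
    assert np.abs(lta.rho_[perm] - lca.rho_).max() < 0.02


def test_missing_covariate_rows_listwise_with_warning(paper_panel):
    import pandas as pd
    panel, _ = paper_panel
    z = np.random.default_rng(0).normal(size=panel.n_respondents)
    z[:25] = np.nan
    panel2 = pm.ResponsePanel(panel.responses, panel.n_categories,
                              panel.items, covariates=pd.DataFrame({"z": z}))
    est = LatentTransitionAnalysis(2, covariate_effects="prevalence",
                                   n_starts=2, random_state=0)
    with pytest.warns(UserWarning, match="excluding 25"):
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            est.fit(panel2, covariates=["z"])
    assert est.n_effective_ == panel.n_respondents - 25


def test_sparseness_guard_on_transition_covariates():
    import pandas as pd
    truth = pm.make_paper_like_truth(4, n_respondents=80)
    panel, _ = pm.simulate_panel(truth, seed=3)
    panel.covariates = pd.DataFrame(
        {"z": np.random.default_rng(0).normal(size=80)})
    spec = pm.ModelSpec(4, 3, (2,) * 6, n_starts=1, random_state=0)
    with pytest.raises(pm.SparsenessError) as err:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pm.fit_lta_with_covariates(panel, spec, ["z"],
                                       on_transitions=True)
    assert err.value.cells  # offending cells are named


def test_grouped_fit_shapes_and_shared_measurement(crisp_panel):
    panel, _ = crisp_panel
    grp = np.where(np.arange(panel.n_respondents) % 2 == 0, "a", "b")
    est = quiet_fit(
        LatentTransitionAnalysis(2, group_delta=True, group_tau=True,
                                 n_starts=3, random_state=0),
        panel, group=grp)
    assert est.delta_.shape == (2, 2)
    assert est.tau_.shape == (2, 2, 2, 2)
    assert est.rho_.shape[0] == 2  # rho shared across groups


def test_status_order_is_descending_prevalence(crisp_panel):
    panel, _ = crisp_panel
    table = pm.pattern_frequencies(panel)
    est = quiet_fit(LatentTransitionAnalysis(3, n_starts=6, random_state=9),
                    table)
    assert np.all(np.diff(est.delta_) <= 1e-12)
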