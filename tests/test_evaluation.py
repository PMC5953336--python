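"""Parameter counting, degrees of freedom, G2, criteria, entropy, LRDT."""

import numpy as np
import pytest
from scipy.integrate import quad

import panelmix as pm
from panelmix.evaluation import saturated_loglik
from panelmix.lta import ModelSpec

BIN6 = (2,) * 6


def lca_spec(s):
    return ModelSpec(n_statuses=s, n_occasions=1, n_categories=BIN6)


class TestParameterCounts:
    @pytest.mark.parametrize("s,p,df", [
        (2, 13, 50), (3, 20, 43), (4, 27, 36),
        (5, 34, 29), (6, 41, 22), (7, 48, 15),
    ])
    def test_single_occasion_grid(self, s, p, df):
        spec = lca_spec(s)
        assert pm.count_parameters(spec) == p
        assert pm.residual_df(spec) == df

    @pytest.mark.parametrize("s,mi,ti,p,df", [
        (3, True, False, 32, 262111),
        (3, False, False, 68, 262075),
        (4, True, False, 51, 262092),
        (4, False, False, 99, 262044),
        (4, True, True, 39, 262104),
    ])
    def test_three_occasion_transition_models(self, s, mi, ti, p, df):
        spec = ModelSpec(n_statuses=s, n_occasions=3, n_categories=BIN6,
                         measurement_invariance=mi, transition_invariance=ti)
        assert pm.count_parameters(spec) == p
        assert pm.residual_df(spec) == df

    def test_invariance_test_parameter_differences(self):
        def p(s, mi, ti=False):
            return pm.count_parameters(ModelSpec(
                n_statuses=s, n_occasions=3, n_categories=BIN6,
                measurement_invariance=mi, transition_invariance=ti))
        assert p(3, False) - p(3, True) == 36
        assert p(4, False) - p(4, True) == 48
        assert p(4, True) - p(4, True, True) == 12

    def test_one_status_counts_only_item_margins(self):
        spec = ModelSpec(n_statuses=1, n_occasions=3,
                         n_categories=(2, 3, 4))
        assert pm.count_parameters(spec) == (1 + 2 + 3)

    def test_prevalence_covariate_adds_one_slope_per_nonreference_status(self):
        base = ModelSpec(n_statuses=4, n_occasions=3, n_categories=BIN6)
        cov = ModelSpec(n_statuses=4, n_occasions=3, n_categories=BIN6,
                        n_covariates=1, covariate_effects="prevalence")
        assert pm.count_parameters(cov) - pm.count_parameters(base) == 3

    def test_constraints_reduce_count(self):
        con = [{"type": "fix", "status": 0, "item": 0, "category": 0,
                "value": 0.5},
               {"type": "equal", "cells": [(0, 1, 0), (1, 1, 0)]}]
        base = ModelSpec(n_statuses=2, n_occasions=3, n_categories=BIN6)
        restricted = ModelSpec(n_statuses=2, n_occasions=3,
                               n_categories=BIN6, rho_constraints=con)
        assert pm.count_parameters(base) - pm.count_parameters(restricted) == 2

    def test_group_specific_parameters(self):
        spec = ModelSpec(n_statuses=3, n_occasions=3, n_categories=BIN6,
                         n_groups=2, group_delta=True, group_tau=True)
        base = ModelSpec(n_statuses=3, n_occasions=3, n_categories=BIN6)
        assert pm.count_parameters(spec) - pm.count_parameters(base) == \
            (3 - 1) + 2 * 3 * 2   # extra delta block + extra tau matrices


class TestResidualDf:
    def test_saturated_gives_zero(self):
        spec = lca_spec(2)
        assert pm.residual_df(spec, W=pm.count_parameters(spec) + 1) == 0

    def test_negative_df_raises(self):
        with pytest.raises(pm.UnderIdentifiedError):
            pm.residual_df(lca_spec(7), W=40)

    def test_default_w_from_categories(self):
        assert pm.residual_df(ModelSpec(1, 3, BIN6)) == 262144 - 6 - 1


class TestGSquared:
    def test_perfect_fit_is_zero(self):
        pats = np.array([[[1, 1]], [[2, 2]]])
        table = pm.PatternTable(pats, np.array([60, 40]), np.array([2, 2]))
        ll = 60 * np.log(0.6) + 40 * np.log(0.4)
        assert pm.gsquared(ll, table) == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_sum_formula(self):
        pats = np.array([[[1, 1]], [[1, 2]], [[2, 1]], [[2, 2]]])
        f = np.array([30, 20, 10, 40])
        table = pm.PatternTable(pats, f, np.array([2, 2]))
        # independence model probabilities
        pa, pb = 0.5, 0.4
        pi = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb,
                       (1 - pa) * (1 - pb)])
        ll = float(f @ np.log(pi))
        expected = 2 * float(f @ np.log(f / (100 * pi)))
        assert pm.gsquared(ll, table) == pytest.approx(expected, abs=1e-10)

    def test_grows_linearly_with_n_at_fixed_proportions(self):
        pats = np.array([[[1, 1]], [[1, 2]], [[2, 1]], [[2, 2]]])
        pi = np.array([0.25, 0.25, 0.25, 0.25])
        g2 = []
        for scale in (1, 10):
            f = scale * np.array([30, 20, 10, 40])
            table = pm.PatternTable(pats, f, np.array([2, 2]))
            g2.append(pm.gsquared(float(f @ np.log(pi)), table))
        assert g2[1] == pytest.approx(10 * g2[0], rel=1e-9)

    def test_negative_g2_signals_bad_fit(self):
        pats = np.array([[[1]], [[2]]])
        table = pm.PatternTable(pats, np.array([5, 5]), np.array([2]))
        too_good = saturated_loglik(table) + 1.0
        with pytest.raises(pm.EstimationError):
            pm.gsquared(too_good, table)

    def test_stratified_saturated_reference_with_missingness(self):
        # two missingness strata: complete rows and item-2-missing rows
        pats = np.array([[[1, 1]], [[2, 2]], [[1, 0]], [[2, 0]]])
        f = np.array([3, 1, 4, 4])
        table = pm.PatternTable(pats, f, np.array([2, 2]))
        expected = (3 * np.log(3 / 4) + 1 * np.log(1 / 4)
                    + 4 * np.log(4 / 8) + 4 * np.log(4 / 8))
        assert saturated_loglik(table) == pytest.approx(expected, abs=1e-12)


class TestInformationCriteria:
    @pytest.mark.parametrize("g2,p,aic", [
        (35.00, 27, 89.00),        # four-class single-occasion fit
        (3722.93, 39, 3800.93),    # transition-invariant four-status fit
        (53.52, 20, 93.52),
    ])
    def test_aic_reproduces_published_arithmetic(self, g2, p, aic):
        crit = pm.information_criteria(g2, p, 1000)
        assert crit["AIC"] == pytest.approx(aic, abs=1e-9)

    def test_zero_parameters_collapse_to_g2(self):
        crit = pm.information_criteria(12.5, 0, 500)
        assert all(v == pytest.approx(12.5) for v in crit.values())

    @pytest.mark.parametrize("g2,p,n", [(35.0, 27, 1172), (100.0, 51, 997)])
    def test_exact_identities(self, g2, p, n):
        crit = pm.information_criteria(g2, p, n)
        assert crit["AIC"] - g2 == pytest.approx(2 * p, abs=1e-12)
        assert crit["CAIC"] - crit["BIC"] == pytest.approx(p, abs=1e-12)
        assert crit["ABIC"] == pytest.approx(
            g2 + np.log((n + 2) / 24) * p, abs=1e-12)


class TestEntropy:
    def test_crisp_is_one(self):
        post = np.eye(3)[np.array([0, 1, 2, 0])]
        assert pm.relative_entropy(post) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert pm.relative_entropy(np.full((5, 4), 0.25)) == pytest.approx(0.0)

    def test_hand_computed_half(self):
        post = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert pm.relative_entropy(post) == pytest.approx(0.5)

    def test_single_class_flagged_undefined(self):
        with pytest.warns(pm.errors.UndefinedStatisticWarning):
            out = pm.relative_entropy(np.ones((4, 1)))
        assert np.isnan(out)

    def test_weighted_matches_expanded(self, rng):
        post = rng.dirichlet(np.ones(3), size=4)
        w = np.array([2.0, 1.0, 3.0, 1.0])
        expanded = np.repeat(post, w.astype(int), axis=0)
        assert pm.relative_entropy(post, w) == pytest.approx(
            pm.relative_entropy(expanded), abs=1e-12)


def _stats(g2, p, n=1000):
    crit = pm.information_criteria(g2, p, n)
    return pm.FitStatistics(loglik=-g2 / 2, G2=g2, P=p, W=262144,
                            df=262144 - p - 1, entropy=np.nan,
                            N_effective=n, **crit)


class TestLRDT:
    @pytest.mark.parametrize("g2d,dfd,p_expected,tol", [
        (49.74, 36, 0.063492, 1e-6),
        (56.24, 48, 0.193694, 1e-6),
        (21.84, 12, 0.039, 5e-4),
        (8.88, 3, 0.0309, 5e-4),
    ])
    def test_published_p_values(self, g2d, dfd, p_expected, tol):
        out = pm.lrdt(_stats(100.0 + g2d, 50), _stats(100.0, 50 + dfd))
        assert out.G2_delta == pytest.approx(g2d, abs=1e-9)
        assert out.df_delta == dfd
        assert out.p_value == pytest.approx(p_expected, abs=tol)

    def test_identical_fits_give_p_one(self):
        out = pm.lrdt(_stats(50.0, 30), _stats(50.0, 30))
        assert out.G2_delta == 0.0 and out.p_value == 1.0

    def test_matches_numerically_integrated_chi_square_tail(self):
        # independent oracle: integrate the chi-square density directly
        for g2d, dfd in [(49.74, 36), (21.84, 12), (5.0, 2)]:
            def dens(x, k=dfd):
                from scipy.special import gammaln
                return np.exp((k / 2 - 1) * np.log(x) - x / 2
                              - gammaln(k / 2) - (k / 2) * np.log(2))
            tail, _ = quad(dens, g2d, np.inf)
            out = pm.lrdt(_stats(100.0 + g2d, 50), _stats(100.0, 50 + dfd))
            assert out.p_value == pytest.approx(tail, abs=1e-6)

    def test_negative_difference_rejected(self):
        with pytest.raises(pm.EstimationError):
            pm.lrdt(_stats(40.0, 30), _stats(50.0, 40))

    def test_wrong_nesting_direction_rejected(self):
        with pytest.raises(pm.ConfigurationError):
            pm.lrdt(_stats(60.0, 40), _stats(50.0, 30))

    def test_conflict_flag_when_aic_disagrees(self):
        # restricted retained by LRDT (p ~ 0.083) but AIC prefers the free
        # model (delta AIC = +1)
        out = pm.lrdt(_stats(103.0, 50), _stats(100.0, 51))
        assert out.decision == "restricted_retained"
        assert out.conflict and out.notes
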