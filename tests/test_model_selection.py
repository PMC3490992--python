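"""Rank tests, ML fits, the Gaussian-correlation GLS and AICc machinery.

The GLS fits are checked against values obtained independently with
nlme::gls (corGaus over the unscaled predictor columns, method="ML") on
the packaged specimen table; those oracle numbers are frozen here.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dentaltopo.model_selection import (
    FitResult, ModelSpec, SelectionTable, aicc, akaike_weights,
    build_selection_table, candidate_models, gls_fit, mann_whitney_u,
    model_average, ols_fit, pearson_r,
)

# nlme::gls(..., correlation=corGaus(form=~<predictors>), method="ML")
# on the packaged table; (response, model number) -> maximized loglik
NLME_ORACLE = {
    ("ln_upper", 2): 23.87979,
    ("ln_upper", 3): 26.85017,
    ("ln_upper", 4): 26.91497,
    ("ln_upper", 5): 19.70704,
    ("ln_lower", 2): 18.45834,
    ("ln_lower", 3): 19.38844,
    ("ln_lower", 4): 22.00033,
    ("ln_lower", 5): 13.70463,
}


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney_u([1, 2], [3, 4]).U == 0.0

    def test_statistic_is_first_sample_count(self):
        r = mann_whitney_u([5, 6], [1, 2, 3])
        assert r.U == 6.0  # every x beats every y

    def test_u_sum_identity(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=9)
        assert mann_whitney_u(x, y).U + mann_whitney_u(y, x).U == 12 * 9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_monotone_transform_invariance(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=8), r.normal(size=6)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(np.exp(x), np.exp(y))
        assert a.U == b.U and a.p == pytest.approx(b.p)

    def test_exact_method_for_small_untied(self):
        assert mann_whitney_u([1.5, 2.5], [3.5]).method == "exact"

    def test_tie_falls_back_to_asymptotic(self):
        assert mann_whitney_u([1, 2, 2], [2, 3]).method == "asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPearson:
    def test_exact_line(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestOls:
    def test_table1_upper_lower_regression(self, table1_derived):
        f = ols_fit(table1_derived.ln_upper, table1_derived.ln_lower,
                    names=("ln_lower",))
        assert f.r_squared == pytest.approx(0.92, abs=0.005)
        assert f.loglik == pytest.approx(19.43, abs=0.005)
        assert f.K == 3
        assert f.aicc == pytest.approx(-32.06, abs=0.005)
        assert f.coefficients["intercept"] == pytest.approx(1.37, abs=0.005)
        assert f.coefficients["ln_lower"] == pytest.approx(0.79, abs=0.005)
        assert f.p_values["ln_lower"] < 1e-5

    def test_noiseless_fit_r2_one(self, rng):
        x = rng.normal(size=20)
        f = ols_fit(3 * x - 1, x)
        assert f.r_squared == pytest.approx(1.0)
        assert f.sigma == pytest.approx(0.0, abs=1e-10)

    def test_singular_design_rejected(self, rng):
        x = rng.normal(size=15)
        with pytest.raises(np.linalg.LinAlgError):
            ols_fit(rng.normal(size=15), np.column_stack([x, x]))


class TestGls:
    @pytest.mark.parametrize("response,number", sorted(NLME_ORACLE))
    def test_matches_nlme_oracle(self, table1_derived, response, number):
        spec = next(s for s in candidate_models(response) if s.number == number)
        f = gls_fit(table1_derived[response].to_numpy(),
                    table1_derived[list(spec.predictors)].to_numpy(),
                    names=spec.predictors, spec=spec)
        assert f.loglik == pytest.approx(NLME_ORACLE[(response, number)], abs=2e-3)
        assert f.K == len(spec.predictors) + 3  # coefs + sigma + rho

    def test_rho_to_zero_limit_equals_ols(self, table1_derived):
        y = table1_derived.ln_upper.to_numpy()
        X = table1_derived[["ln_lower", "rd"]].to_numpy()
        ols = ols_fit(y, X)
        from dentaltopo.model_selection import _gauss_profile_loglik
        import statsmodels.api as sm
        from scipy.spatial.distance import pdist, squareform
        ll, _, _ = _gauss_profile_loglik(1e-8, y, sm.add_constant(X),
                                         squareform(pdist(X)))
        assert ll == pytest.approx(ols.loglik, abs=1e-6)

    def test_identical_positions_rejected(self, rng):
        y = rng.normal(size=10)
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="identical"):
            gls_fit(y, X, positions=np.ones((10, 1)))


class TestAicc:
    # printed (logLik, df, AICc) triples of both selection tables; the
    # logLik inputs are 2 dp roundings, which propagates up to ~0.01
    # into the recomputed AICc
    TRIPLES = [
        (27.73, 5, -43.32), (27.84, 6, -40.58), (24.93, 5, -37.71),
        (19.43, 3, -32.06), (22.03, 5, -31.92),
        (20.21, 5, -28.29), (19.73, 5, -27.33), (21.21, 6, -27.30),
        (12.78, 3, -18.76), (14.48, 5, -16.82),
    ]

    @pytest.mark.parametrize("ll,k,expected", TRIPLES)
    def test_printed_triples(self, ll, k, expected):
        assert aicc(ll, k, 34) == pytest.approx(expected, abs=0.015)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            aicc(0.0, 33, 34)

    def test_converges_to_aic_for_large_n(self):
        n, k, ll = 10 ** 5, 5, -123.4
        aic = -2 * ll + 2 * k
        assert abs(aicc(ll, k, n) - aic) / abs(aic) < 1e-3


class TestAkaikeWeights:
    def test_table2_weights(self):
        w = akaike_weights([-43.32, -40.58, -37.71, -32.06, -31.92])
        np.testing.assert_allclose(w, [0.757, 0.192, 0.046, 0.003, 0.003],
                                   atol=5e-3)

    def test_single_model(self):
        assert akaike_weights([10.0]) == pytest.approx([1.0])

    def test_equal_models_split(self):
        np.testing.assert_allclose(akaike_weights([3.3, 3.3]), [0.5, 0.5])

    def test_sum_to_one_and_shift_invariant(self, rng):
        a = rng.normal(size=6) * 10
        w1, w2 = akaike_weights(a), akaike_weights(a + 100.0)
        assert w1.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(w1, w2)


class TestSelectionTable:
    def test_upper_best_model_is_lower_plus_rd(self, selection_tables):
        best = selection_tables["ln_upper"].best
        assert set(best.spec.predictors) == {"ln_lower", "rd"}

    def test_lower_best_model_includes_rd(self, selection_tables):
        best = selection_tables["ln_lower"].best
        assert "rd" in best.spec.predictors and "ln_upper" in best.spec.predictors

    def test_weights_sum_to_one_min_delta_zero(self, selection_tables):
        for t in selection_tables.values():
            assert t.weight.sum() == pytest.approx(1.0)
            assert t.delta[0] == 0.0

    def test_confidence_set_is_smallest_prefix(self, selection_tables):
        for t in selection_tables.values():
            k = int(t.in_conf_set.sum())
            assert t.weight[:k].sum() >= 0.95
            assert t.weight[:k - 1].sum() < 0.95

    def test_frame_layout(self, selection_tables):
        df = selection_tables["ln_upper"].to_frame()
        assert list(df.columns[:2]) == ["model", "intercept"]
        assert {"df", "logLik", "AICc", "delta_AICc", "akaike_weight"} <= set(df.columns)

    def test_mixed_responses_rejected(self, table1_derived):
        specs = candidate_models("ln_upper")[:1] + candidate_models("ln_lower")[:1]
        with pytest.raises(ValueError):
            build_selection_table(specs, table1_derived)


class TestModelAverage:
    @staticmethod
    def _toy_table(weights, coef_sets):
        rows = []
        for i, coefs in enumerate(coef_sets):
            spec = ModelSpec(number=i + 1, response="ln_upper",
                             predictors=tuple(k for k in coefs if k != "intercept"),
                             use_correlation=False)
            rows.append(FitResult(spec=spec, coefficients=coefs, sigma=0.1,
                                  loglik=0.0, K=3, n=34, aicc=float(i)))
        w = np.asarray(weights, dtype=float)
        return SelectionTable(rows=rows, delta=np.arange(len(rows), dtype=float),
                              weight=w, in_conf_set=np.ones(len(rows), bool))

    def test_single_model_unchanged(self):
        t = self._toy_table([1.0], [{"intercept": 1.0, "rd": -0.2}])
        assert model_average(t) == {"intercept": 1.0, "rd": -0.2}

    def test_equal_weights_equal_slopes(self):
        t = self._toy_table([0.5, 0.5], [{"intercept": 0.0, "rd": 0.8},
                                         {"intercept": 0.0, "rd": 0.8}])
        assert model_average(t)["rd"] == pytest.approx(0.8)

    def test_zero_substitution_confidence_set_arithmetic(self):
        """Three-model set with one model lacking the rt term: the printed
        upper-table weights {0.757, 0.192, 0.046} renormalize to
        {0.761, 0.193, 0.046} and average rt = -0.0155."""
        t = self._toy_table(
            [0.757, 0.192, 0.046],
            [{"intercept": 0.98, "ln_lower": 0.77, "rd": -0.21},
             {"intercept": 0.87, "ln_lower": 0.78, "rt": -0.04, "rd": -0.18},
             {"intercept": 0.76, "ln_lower": 0.81, "rt": -0.17}])
        avg = model_average(t, convention="zero_substitution")
        assert avg["rt"] == pytest.approx(-0.0155, abs=5e-4)

    def test_natural_averages_only_over_containing_models(self):
        t = self._toy_table(
            [0.6, 0.4],
            [{"intercept": 0.0, "rd": -0.2}, {"intercept": 0.0, "rt": -0.1}])
        avg = model_average(t, convention="natural")
        assert avg["rd"] == pytest.approx(-0.2)
        assert avg["rt"] == pytest.approx(-0.1)
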