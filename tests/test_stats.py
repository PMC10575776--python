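"""Firth and binomial logistic regression, pseudo-R2, exact tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import expit

from triocog.stats import (
    binomial_logistic,
    clopper_pearson,
    firth_logistic,
    fisher_exact,
    nagelkerke_delta_r2,
    nagelkerke_r2,
    tdt_chisq,
    two_sample_t,
)


def _design(x, name="x"):
    return pd.DataFrame({"const": np.ones(len(x)), name: x})


def _two_by_two(a, b, c, d):
    """Outcome/exposure vectors for a 2x2 layout: a exposed cases, b exposed
    controls, c unexposed cases, d unexposed controls."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, x


class TestFirth:
    def test_two_by_two_closed_form(self):
        """For one binary predictor the Firth estimate equals the
        add-one-half-to-each-cell odds ratio; checked on the carrier layout
        (12, 1; 281, 368)."""
        y, x = _two_by_two(12, 1, 281, 368)
        res = firth_logistic(y, _design(x, "carrier"), plr_terms=["carrier"])
        expected_or = (12.5 * 368.5) / (1.5 * 281.5)
        assert np.exp(res.params["carrier"]) == pytest.approx(expected_or, rel=1e-4)
        assert res.converged

    def test_penalized_score_vanishes_at_estimate(self):
        """Direct verification that the returned estimate maximises the
        penalised likelihood: numerical gradient of pll is ~0."""
        from triocog.stats import _penalized_loglik

        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        y = rng.binomial(1, expit(0.5 * x - 0.2))
        X = _design(x)
        res = firth_logistic(y, X)
        beta = res.params.to_numpy()
        Xa = X.to_numpy()
        eps = 1e-6
        for j in range(2):
            up, dn = beta.copy(), beta.copy()
            up[j] += eps
            dn[j] -= eps
            grad = (_penalized_loglik(y, Xa, up)[0] - _penalized_loglik(y, Xa, dn)[0]) / (2 * eps)
            assert abs(grad) < 1e-4

    def test_complete_separation_finite(self):
        y = np.r_[np.ones(8), np.zeros(8)]
        x = y.copy()  # all carriers are cases
        res = firth_logistic(y, _design(x))
        assert np.isfinite(res.params["x"])
        assert np.isfinite(res.conf_int.loc["x"]).all()
        assert res.converged

    def test_rank_deficiency_names_columns(self):
        x = np.arange(20.0)
        X = pd.DataFrame({"const": 1.0, "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            firth_logistic(np.tile([0, 1], 10), X)

    def test_large_n_agreement_with_ml(self):
        """Without separation the penalty is O(1/n): Firth and ML betas
        agree closely at n = 20,000."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=20_000)
        y = rng.binomial(1, expit(0.4 * x))
        X = _design(x)
        fi = firth_logistic(y, X)
        ml = binomial_logistic(y, X)
        assert abs(fi.params["x"] - ml.params["x"]) < 5e-3

    def test_null_type_one_error(self):
        """Penalised-LR test at alpha 0.05 rejects ~5% of null datasets
        (1000 replicates, n = 500, binary covariate)."""
        rng = np.random.default_rng(2)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.binomial(1, 0.1, size=500).astype(float)
            y = rng.binomial(1, 0.5, size=500).astype(float)
            res = firth_logistic(y, _design(x), plr_terms=["x"])
            hits += res.p["x"] < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se

    def test_profile_ci_contains_estimate_and_brackets_wald(self):
        y, x = _two_by_two(12, 1, 281, 368)
        res = firth_logistic(y, _design(x, "carrier"), ci="profile")
        lo, hi = res.conf_int.loc["carrier"]
        assert lo < res.params["carrier"] < hi


class TestBinomialLogistic:
    def test_intercept_only_balanced(self):
        y = np.tile([0, 1], 50)
        X = pd.DataFrame({"const": np.ones(100)})
        res = binomial_logistic(y, X)
        assert res.params["const"] == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery(self):
        """Recovers a generating log-odds coefficient of 0.3 within 0.1
        at n = 5000."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        y = rng.binomial(1, expit(0.3 * x - 0.1))
        res = binomial_logistic(y, _design(x))
        assert res.params["x"] == pytest.approx(0.3, abs=0.1)

    def test_separation_falls_back_to_firth(self):
        y = np.r_[np.ones(6), np.zeros(6)]
        with pytest.warns(UserWarning, match="Firth"):
            res = binomial_logistic(y, _design(y.copy()))
        assert res.method == "ml_fallback_firth"
        assert np.isfinite(res.params["x"])


class TestNagelkerke:
    def _fits(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        z = rng.normal(size=400)
        y = rng.binomial(1, expit(0.8 * x))
        full = binomial_logistic(y, pd.DataFrame({"const": 1.0, "x": x, "z": z}))
        red = binomial_logistic(y, pd.DataFrame({"const": np.ones(400), "z": z}))
        return y, full, red

    def test_full_equals_reduced_gives_zero(self):
        y, full, _ = self._fits()
        assert nagelkerke_delta_r2(full, full) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_recomputation(self):
        """Delta-R2 agrees with recomputing Nagelkerke's formula directly
        from the stored log-likelihoods."""
        y, full, red = self._fits()
        n = len(y)
        ll0 = full.loglik_null

        def r2(ll):
            return (1 - np.exp(2 * (ll0 - ll) / n)) / (1 - np.exp(2 * ll0 / n))

        expected = r2(full.loglik) - r2(red.loglik)
        assert nagelkerke_delta_r2(full, red) == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= nagelkerke_delta_r2(full, red) <= 1.0

    def test_perfect_predictor_approaches_one(self):
        y = np.tile([0, 1], 100).astype(float)
        x = 2 * y - 1
        res = firth_logistic(y, _design(x))  # ML would not converge
        r2 = nagelkerke_r2(res.loglik, res.loglik_null, len(y))
        assert r2 > 0.9


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,point,lo,hi",
        [
            (12, 13, 92.3, 64.0, 99.8),
            (40, 66, 60.6, 47.8, 72.4),
        ],
    )
    def test_published_carrier_proportions(self, k, n, point, lo, hi):
        ci = clopper_pearson(k, n)
        assert 100 * ci.estimate == pytest.approx(point, abs=0.05)
        assert 100 * ci.lower == pytest.approx(lo, abs=0.05)
        assert 100 * ci.upper == pytest.approx(hi, abs=0.05)

    def test_boundaries(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 1.0

    def test_coverage_at_least_nominal(self):
        """Empirical coverage >= 95% across p in {0.1, 0.5, 0.9} and
        n in {13, 66, 300}, 5000 replicates each (vectorised)."""
        rng = np.random.default_rng(5)
        alpha = 0.05
        for p in (0.1, 0.5, 0.9):
            for n in (13, 66, 300):
                k = rng.binomial(n, p, size=5000)
                lo = np.where(k == 0, 0.0, sps.beta.ppf(alpha / 2, k, n - k + 1))
                hi = np.where(k == n, 1.0, sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
                cover = np.mean((lo <= p) & (p <= hi))
                assert cover >= 0.95 - 3 * np.sqrt(0.05 * 0.95 / 5000)


class TestFisherExact:
    def test_id_comorbidity_table(self):
        """The conditional-MLE odds ratio for the mild-ID x carrier table
        (5, 7; 12, 269) is 15.6 with exact CI (3.4, 67.7)."""
        res = fisher_exact([[5, 7], [12, 269]])
        assert res["odds_ratio"] == pytest.approx(15.6, abs=0.05)
        assert res["p"] == pytest.approx(2.2e-4, rel=0.05)
        assert res["ci"][0] == pytest.approx(3.4, abs=0.05)
        assert res["ci"][1] == pytest.approx(67.7, abs=0.15)

    def test_balanced_table_null(self):
        res = fisher_exact([[5, 5], [5, 5]])
        assert res["odds_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert res["p"] == 1.0

    def test_p_matches_hypergeometric_enumeration(self):
        """Two-tailed p equals full enumeration over the hypergeometric
        support for all tables with margins <= 30 derived from a grid."""
        rng = np.random.default_rng(6)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 12, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            M, n1, N = a + b + c + d, a + b, a + c
            support = np.arange(max(0, N - (M - n1)), min(n1, N) + 1)
            pmf = sps.hypergeom.pmf(support, M, n1, N)
            p_obs = sps.hypergeom.pmf(a, M, n1, N)
            expected = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
            assert fisher_exact([[a, b], [c, d]])["p"] == pytest.approx(expected, rel=1e-8)

    def test_transposition_and_column_swap(self):
        t = [[5, 7], [12, 269]]
        r = fisher_exact(t)
        assert fisher_exact(np.transpose(t))["p"] == pytest.approx(r["p"], rel=1e-9)
        swapped = fisher_exact([[7, 5], [269, 12]])
        assert swapped["odds_ratio"] == pytest.approx(1 / r["odds_ratio"], rel=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])


class TestTdt:
    def test_balanced_transmission_null(self):
        stat, p = tdt_chisq(50, 50)
        assert stat == 0.0 and p == 1.0

    def test_ten_zero(self):
        stat, p = tdt_chisq(10, 0)
        assert stat == 10.0
        assert p == pytest.approx(sps.chi2.sf(10, 1), rel=1e-12)
        assert p == pytest.approx(0.00157, abs=2e-5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tdt_chisq(0, 0)

    def test_null_type_one_error(self):
        """Under binomial(n, 1/2) transmission, rejection at alpha 0.05 is
        ~5% over 10,000 replicates."""
        rng = np.random.default_rng(7)
        total = 100
        t = rng.binomial(total, 0.5, size=10_000)
        stat = (2 * t - total) ** 2 / total
        rate = np.mean(sps.chi2.sf(stat, 1) < 0.05)
        assert abs(rate - 0.05) < 0.01


class TestTwoSampleT:
    def test_identical_groups(self):
        g = np.arange(5.0)
        t, p = two_sample_t(g, g)
        assert t == 0.0 and p == 1.0

    def test_hand_computed_fixture(self):
        """5+5 fixture: means 3 and 5, pooled SD sqrt(2.5), t = -2."""
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [3.0, 4.0, 5.0, 6.0, 7.0]
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(-2.0)
        assert p == pytest.approx(2 * sps.t.sf(2.0, 8), rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])
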