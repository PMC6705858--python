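import numpy as np
import pytest

import statsmodels.api as sm
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

from pinfish.errors import ConvergenceError, DegenerateSeriesError, InsufficientDataError
from pinfish.hurdle import (
    HurdleNegativeBinomial,
    build_design,
    fit_alternatives,
    fit_presence,
    fit_truncated_nb,
    fit_zero_inflated,
    stepwise_aic,
    vif_report,
    _nb_logpmf,
)
from pinfish.simulate import EstuaryConfig, MetapopConfig, simulate_survey
from pinfish.survey import HaulTable

from test_survey import make_record


def flat_survey(seed=3, density=40.0, years=(1998, 2016), hauls=(20, 25), **est_kw):
    """Generator data with constant latent density: pure hurdle-NB counts."""
    est = EstuaryConfig(estuary="TB", density_scale=density, base_level=1.0, **est_kw)
    cfg = MetapopConfig(estuaries=[est], shared_forcing_sd=0.0, estuary_noise_sd=0.0,
                        hauls_per_month=hauls, years=years, lag_months={}, seed=seed)
    return simulate_survey(cfg)[0], est


@pytest.fixture(scope="module")
def flat_design():
    table, est = flat_survey(seed=3, hauls=(9, 12), years=(1998, 2005))
    return build_design(table, ("sav", "salinity", "temperature", "depth")), est


class TestDesign:
    def test_columns_standardized(self, flat_design):
        d, _ = flat_design
        assert np.allclose(d.X[:, 1:].mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(d.X[:, 1:].std(axis=0), 1.0, atol=1e-10)
        assert np.allclose(d.offset, np.log(140.0))

    def test_derived_before_standardization(self):
        recs = [make_record(i, sav_pct=float(s), count=1, lengths_mm=(50.0,))
                for i, s in enumerate([0, 10, 50, 90, 100])]
        d = build_design(HaulTable(recs), ("sav", "sav2"))
        sav_raw = np.array([0.0, 10, 50, 90, 100])
        sq = sav_raw**2
        expect = (sq - sq.mean()) / sq.std()
        assert np.allclose(d.X[:, 1 + d.terms.index("sav2")], expect)

    def test_zero_variance_dropped_with_warning(self):
        recs = [make_record(i, sav_pct=50.0, count=i % 3, lengths_mm=())
                for i in range(10)]
        with pytest.warns(UserWarning, match="zero variance"):
            d = build_design(HaulTable(recs), ("sav", "depth"))
        assert "sav" not in d.terms and "sav" in d.dropped_terms

    def test_listwise_deletion_counted(self):
        recs = [make_record(0, salinity=float("nan"), count=2, lengths_mm=()),
                make_record(1, count=3, lengths_mm=())]
        d = build_design(HaulTable(recs), ("salinity", "depth"))
        assert d.n_dropped_rows == 1 and len(d.y) == 1


class TestPresence:
    def test_intercept_only_balanced(self):
        X = np.ones((4, 1))
        beta, ll, _ = fit_presence(np.array([1.0, 0, 1, 0]), X)
        assert beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_one_class_rejected(self):
        with pytest.raises(ConvergenceError, match="single class"):
            fit_presence(np.ones(10), np.ones((10, 1)))

    def test_separation_detected(self):
        x = np.linspace(-2, 2, 50)
        y = (x > 0).astype(float)
        with pytest.raises(ConvergenceError, match="separation"):
            fit_presence(y, np.column_stack([np.ones(50), x]))

    def test_simulated_recovery(self, rng):
        n = 5000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        p = 1 / (1 + np.exp(-(0.5 + 1.0 * x)))
        y = (rng.random(n) < p).astype(float)
        beta, _, _ = fit_presence(y, X)
        assert np.allclose(beta, [0.5, 1.0], atol=0.1)

    def test_matches_statsmodels(self, flat_design):
        d, _ = flat_design
        y01 = (d.y > 0).astype(float)
        beta, ll, _ = fit_presence(y01, d.X)
        ref = sm.Logit(y01, d.X).fit(disp=0)
        assert np.allclose(beta, ref.params, atol=1e-7)
        assert ll == pytest.approx(ref.llf, abs=1e-7)


class TestTruncatedNB:
    def test_zeros_rejected(self):
        with pytest.raises(ValueError):
            fit_truncated_nb(np.array([0, 1, 2]), np.ones((3, 1)))

    def test_recovery_mu_theta(self, rng):
        """Truncated NB(mu=5, theta=2) at n=10^4: both within 5%."""
        n, mu, theta = 10**4, 5.0, 2.0
        lam = rng.gamma(theta, mu / theta, size=3 * n)
        y = rng.poisson(lam)
        y = y[y > 0][:n].astype(float)
        beta, th, ll, _ = fit_truncated_nb(y, np.ones((len(y), 1)))
        assert np.exp(beta[0]) == pytest.approx(mu, rel=0.05)
        assert th == pytest.approx(theta, rel=0.05)

    def test_large_theta_approaches_truncated_poisson(self):
        """NB(mu, theta -> inf) pmf converges to Poisson in total variation."""
        mu, theta = 3.0, 1e4
        y = np.arange(1, 60)
        from scipy.special import gammaln

        nb = np.exp(_nb_logpmf(y, mu, theta)) / (1 - (theta / (theta + mu)) ** theta)
        po = np.exp(y * np.log(mu) - mu - gammaln(y + 1.0)) / (1 - np.exp(-mu))
        assert 0.5 * np.abs(nb - po).sum() < 0.01

    def test_matches_statsmodels(self, flat_design):
        d, _ = flat_design
        pos = d.y > 0
        beta, theta, ll, _ = fit_truncated_nb(d.y[pos], d.X[pos], d.offset[pos])
        ref = TruncatedLFNegativeBinomialP(
            d.y[pos], d.X[pos], offset=d.offset[pos], truncation=0
        ).fit(disp=0, maxiter=500)
        assert ll == pytest.approx(ref.llf, abs=1e-4)
        assert np.allclose(beta, ref.params[:-1], atol=1e-4)


class TestHurdle:
    def test_loglik_additive_and_aic(self, flat_design):
        d, _ = flat_design
        fit = HurdleNegativeBinomial(d).fit()
        assert fit.llf == pytest.approx(fit.presence.logL + fit.count.logL, abs=1e-9)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.llf, abs=1e-9)
        assert fit.k == len(fit.presence.coef) + len(fit.count.coef) + 1

    def test_deterministic_refit(self, flat_design):
        d, _ = flat_design
        f1 = HurdleNegativeBinomial(d).fit()
        f2 = HurdleNegativeBinomial(d).fit()
        assert np.array_equal(f1.presence.coef, f2.presence.coef)
        assert np.array_equal(f1.count.coef, f2.count.coef)
        assert f1.theta == f2.theta

    def test_sign_recovery_on_generator_truth(self):
        table, est = flat_survey(seed=17)
        d = build_design(table, ("sav", "salinity", "temperature", "depth"))
        fit = HurdleNegativeBinomial(d).fit()
        truth_signs = {"sav": 1, "salinity": 1, "temperature": -1, "depth": 1}
        for part in (fit.presence, fit.count):
            for i, t in enumerate(part.terms):
                assert np.sign(part.coef[i + 1]) == truth_signs[t]

    def test_standardized_coefs_invariant_to_raw_rescaling(self, flat_design):
        d, est = flat_design
        table, _ = flat_survey(seed=3, hauls=(9, 12), years=(1998, 2005))
        df = table.to_dataframe()
        df["salinity"] = df["salinity"] * 10 + 3  # affine rescale of a covariate
        d2 = build_design(df, ("sav", "salinity", "temperature", "depth"))
        f1 = HurdleNegativeBinomial(d).fit()
        f2 = HurdleNegativeBinomial(d2).fit()
        assert np.allclose(f1.count.coef, f2.count.coef, atol=1e-6)

    def test_summary_text(self, flat_design):
        d, _ = flat_design
        s = HurdleNegativeBinomial(d).fit().summary()
        assert "Zero-altered negative binomial" in s and "theta" in s


class TestZeroInflated:
    def test_matches_statsmodels(self, flat_design):
        d, _ = flat_design
        X = d.columns(("sav", "temperature"))
        _, ll, _ = fit_zero_inflated(d.y, X, X, d.offset, negbin=True)
        ref = ZeroInflatedNegativeBinomialP(
            d.y, X, exog_infl=X, offset=d.offset, p=2
        ).fit(disp=0, maxiter=500)
        assert ll >= ref.llf - 1e-3  # same optimum (allow our fit to be tighter)

    def test_alternatives_table_shape(self, flat_design):
        d, _ = flat_design
        out = fit_alternatives(d, terms=("sav", "temperature"))
        assert list(out.columns) == ["model", "logL", "k", "aic", "pseudo_r2"]
        assert sorted(out["model"]) == ["ZANB", "ZAP", "ZINB", "ZIP"]
        assert out["aic"].is_monotonic_increasing

    def test_equidispersed_data_poisson_competitive(self):
        """Hurdle-Poisson data: ZAP/ZIP within ~2 AIC of the NB variants."""
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.normal(size=n)
        present = rng.random(n) < 0.7
        mu = np.exp(1.2 + 0.5 * x)
        y = np.zeros(n, dtype=int)
        for i in np.flatnonzero(present):
            while True:  # rejection draw from the zero-truncated Poisson
                draw = rng.poisson(mu[i])
                if draw > 0:
                    y[i] = draw
                    break
        import pandas as pd

        df = pd.DataFrame(
            {"count": y, "area_swept_m2": 140.0, "sav_pct": 0.0,
             "temperature_c": x, "salinity": 0.0, "depth_m": 0.0}
        )
        d = build_design(df, ("temperature",))
        out = fit_alternatives(d).set_index("model")
        assert out.loc["ZAP", "aic"] <= out.loc["ZANB", "aic"] + 2.5
        assert out.loc["ZIP", "aic"] <= out.loc["ZINB", "aic"] + 2.5


class TestStepwise:
    def test_empty_candidates_intercept_model(self, flat_design):
        d, _ = flat_design
        sel, aic, hist = stepwise_aic(d, candidate_terms=(), part="presence")
        assert sel == ()
        assert len(hist) == 1

    def test_deterministic_path(self, flat_design):
        d, _ = flat_design
        r1 = stepwise_aic(d, part="presence")
        r2 = stepwise_aic(d, part="presence")
        assert r1 == r2

    def test_strong_true_term_selected(self):
        table, _ = flat_survey(
            seed=23, years=(1998, 2005), hauls=(9, 12),
            temp_beta=0.0, sal_beta=0.0, depth_beta=0.0,
            presence_betas=(1.2, 0.0, 0.0, 0.0),
        )
        d = build_design(table, ("sav", "salinity", "temperature", "depth"))
        for part in ("presence", "count"):
            sel, aic, _ = stepwise_aic(d, part=part)
            assert "sav" in sel
            intercept_aic = stepwise_aic(d, candidate_terms=(), part=part)[1]
            assert aic <= intercept_aic


class TestVif:
    def test_orthogonal_near_one(self, flat_design):
        d, _ = flat_design
        rep = vif_report(d)
        assert all(abs(v - 1.0) < 0.05 for v in rep.vif.values())
        assert rep.passed

    def test_duplicated_column_singular(self, rng):
        import pandas as pd

        x = rng.normal(25, 3, 400)
        df = pd.DataFrame(
            {"count": rng.poisson(2, 400), "area_swept_m2": 140.0,
             "temperature_c": x, "salinity": x, "depth_m": rng.normal(1, 0.2, 400),
             "sav_pct": 0.0}
        )
        d = build_design(df, ("salinity", "temperature", "depth"))
        with pytest.raises(DegenerateSeriesError, match="collinear"):
            vif_report(d, ("salinity", "temperature", "depth"))

    def test_known_correlation_closed_form(self, rng):
        """x2 = r x1 + noise with r^2 = 0.9025 gives VIF ~ 10.3."""
        import pandas as pd

        n = 20000
        x1 = rng.normal(size=n)
        x2 = 0.95 * x1 + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
        df = pd.DataFrame(
            {"count": 1, "area_swept_m2": 140.0, "temperature_c": x1,
             "salinity": x2, "depth_m": rng.normal(size=n), "sav_pct": 0.0}
        )
        d = build_design(df, ("temperature", "salinity"))
        rep = vif_report(d, ("temperature", "salinity"))
        assert rep.vif["salinity"] == pytest.approx(1 / (1 - 0.9025), rel=0.08)
        assert not rep.passed

    def test_needs_two_terms(self, flat_design):
        d, _ = flat_design
        with pytest.raises(InsufficientDataError):
            vif_report(d, ("sav",))
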