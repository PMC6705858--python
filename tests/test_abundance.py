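import numpy as np
import pandas as pd
import pytest

from pinfish.abundance import (
    BIOMASS,
    DENSITY,
    MonthlySeries,
    annual_mean,
    anomalies,
    climatology,
    fit_length_weight,
    haul_biomass,
    haul_density,
    long_term_mean,
    monthly_mean,
    moving_average,
    predict_weight,
    standardized_ratio,
)
from pinfish.errors import DegenerateSeriesError, InsufficientDataError
from pinfish.survey import HaulTable, LengthWeightParams

from test_survey import make_record

LW = LengthWeightParams("TB", a=1e-5, b=3.0)


def series_from(values_by_ym, estuary="TB", metric=DENSITY):
    idx = pd.MultiIndex.from_tuples(values_by_ym.keys(), names=["year", "month"])
    frame = pd.DataFrame(
        {"mean": list(values_by_ym.values()), "se": 0.0, "n": 5}, index=idx
    )
    return MonthlySeries(estuary, metric, frame)


def full_years(year_month_fn, years, estuary="TB"):
    return series_from(
        {(y, m): year_month_fn(y, m) for y in years for m in range(1, 13)},
        estuary=estuary,
    )


class TestHaulLevel:
    @pytest.mark.parametrize(
        "count,area,expected", [(140, 140.0, 100.0), (0, 140.0, 0.0), (35, 140.0, 25.0)]
    )
    def test_density(self, count, area, expected):
        assert haul_density(count, area) == pytest.approx(expected)

    def test_density_bad_area(self):
        with pytest.raises(ValueError):
            haul_density(10, 0.0)

    @pytest.mark.parametrize(
        "a,b,sl,expected",
        [(1.0, 3.0, 10.0, 1000.0), (0.37, 2.1, 1.0, 0.37), (1e-5, 3.0, 50.0, 1.25)],
    )
    def test_predict_weight(self, a, b, sl, expected):
        assert predict_weight(sl, LengthWeightParams("x", a, b)) == pytest.approx(expected)

    def test_biomass_extrapolation_rule(self):
        # count=4, two 50 mm fish measured: 4 x 1.25 g over 140 m2
        r = make_record(count=4, lengths_mm=(50.0, 50.0))
        assert haul_biomass(r, LW) == pytest.approx(100 * 4 * 1.25 / 140)

    def test_biomass_zero_count(self):
        assert haul_biomass(make_record(count=0, lengths_mm=()), LW) == 0.0

    def test_biomass_single_length(self):
        r = make_record(count=10, lengths_mm=(50.0,))
        assert haul_biomass(r, LW) == pytest.approx(100 * 10 * 1.25 / 140)

    def test_biomass_positive_iff_count_positive(self, small_survey):
        _, table, _ = small_survey
        for r in list(table)[:200]:
            if r.lengths_mm or r.count == 0:
                b = haul_biomass(r, LW)
                assert (b > 0) == (r.count > 0)

    def test_biomass_missing_lengths_needs_fallback(self):
        r = make_record(count=3, lengths_mm=())
        with pytest.raises(InsufficientDataError):
            haul_biomass(r, LW)
        assert haul_biomass(r, LW, fallback_mean_weight=2.0) == pytest.approx(
            100 * 3 * 2.0 / 140
        )


class TestLengthWeightFit:
    def test_exact_power_law_recovered(self):
        sl = np.array([10.0, 20.0, 30.0])
        p = fit_length_weight(sl, 2.0 * sl**3)
        assert p.a == pytest.approx(2.0, abs=1e-9)
        assert p.b == pytest.approx(3.0, abs=1e-9)

    def test_noisy_recovery_at_survey_scale(self, rng):
        # lognormal multiplicative noise, sd 0.1, n = 3517 pairs
        sl = rng.uniform(20, 150, size=3517)
        w = 1e-5 * sl**3.0 * rng.lognormal(0.0, 0.1, size=sl.size)
        p = fit_length_weight(sl, w)
        assert abs(p.b - 3.0) < 0.05

    def test_constant_lengths_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            fit_length_weight([50, 50, 50], [1, 1, 1])

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_length_weight([10, 20], [1, 8])


class TestMonthlyMean:
    def test_mean_and_se_convention(self):
        # three hauls with densities 0, 50, 100
        recs = [
            make_record(i, count=c, lengths_mm=())
            for i, c in enumerate([0, 70, 140])
        ]
        s = monthly_mean(HaulTable(recs))["TB"]
        row = s.frame.loc[(2005, 6)]
        assert row["mean"] == pytest.approx(50.0)
        assert row["se"] == pytest.approx(50.0 / np.sqrt(3))
        assert row["n"] == 3

    def test_single_haul_se_missing(self):
        s = monthly_mean(HaulTable([make_record(0, count=7, lengths_mm=())]))["TB"]
        assert np.isnan(s.frame["se"].iloc[0])

    def test_equal_hauls_zero_se(self):
        recs = [make_record(i, count=70, lengths_mm=()) for i in range(4)]
        s = monthly_mean(HaulTable(recs))["TB"]
        assert s.frame["se"].iloc[0] == 0.0

    def test_permutation_invariance(self, small_survey):
        _, table, _ = small_survey
        fwd = monthly_mean(table)["TB"].frame
        rev = monthly_mean(HaulTable(list(table)[::-1]))["TB"].frame
        pd.testing.assert_frame_equal(fwd, rev)

    def test_biomass_fallback_uses_estuary_month_mean(self):
        recs = [
            make_record(0, count=2, lengths_mm=(50.0, 50.0)),
            make_record(1, count=3, lengths_mm=()),  # no measured lengths
        ]
        s = monthly_mean(HaulTable(recs), BIOMASS, lw_params={"TB": LW})["TB"]
        v1 = 100 * 2 * 1.25 / 140
        v2 = 100 * 3 * 1.25 / 140  # fallback mean weight = 1.25 g
        assert s.frame["mean"].iloc[0] == pytest.approx((v1 + v2) / 2)


class TestClimatologyAnomalies:
    def test_anomalies_of_pure_climatology_vanish(self):
        s = full_years(lambda y, m: 10.0 + m, years=range(2000, 2004))
        a = anomalies(s)
        assert np.allclose(a.frame["mean"], 0.0, atol=1e-12)

    def test_single_year_bump_closed_form(self):
        years = range(2000, 2005)
        Y = len(list(years))
        s = full_years(lambda y, m: 10.0 + (5.0 if y == 2002 else 0.0), years=years)
        a = anomalies(s)
        bumped = a.frame.xs(2002, level="year")["mean"]
        assert np.allclose(bumped, 5.0 * (1 - 1 / Y))

    def test_climatology_has_twelve_months(self):
        s = full_years(lambda y, m: float(m), years=range(2000, 2002))
        assert list(climatology(s).frame.index) == list(range(1, 13))

    def test_requires_two_years(self):
        s = full_years(lambda y, m: 1.0, years=[2000])
        with pytest.raises(InsufficientDataError):
            climatology(s)

    def test_reconstruction(self):
        s = full_years(lambda y, m: 3.0 * m + (y - 2000), years=range(2000, 2004))
        c = climatology(s)
        a = anomalies(s, c)
        months = a.frame.index.get_level_values("month")
        recon = a.frame["mean"].to_numpy() + c.frame["mean"].reindex(months).to_numpy()
        assert np.allclose(recon, s.frame["mean"].to_numpy())


class TestAnnualSummaries:
    def test_constant_series_unit_ratios(self):
        s = full_years(lambda y, m: 7.0, years=range(2000, 2005))
        assert np.allclose(standardized_ratio(s), 1.0)

    def test_one_doubled_year_closed_form(self):
        years = list(range(2000, 2007))
        Y = len(years)
        s = full_years(lambda y, m: 8.0 if y == 2003 else 4.0, years=years)
        r = standardized_ratio(s)
        assert r.loc[2003] == pytest.approx(2 * Y / (Y + 1))

    def test_ratios_average_to_one(self, small_survey):
        _, table, _ = small_survey
        s = monthly_mean(table)["TB"]
        assert standardized_ratio(s).mean() == pytest.approx(1.0)

    def test_long_term_mean_of_constant(self):
        s = full_years(lambda y, m: 7.0, years=range(2000, 2002))
        mean, se = long_term_mean(s)
        assert mean == pytest.approx(7.0)
        assert se == pytest.approx(0.0)

    def test_missing_year_absent(self):
        s = series_from({(2000, m): 1.0 for m in range(1, 13)} | {(2002, 1): 2.0})
        assert list(annual_mean(s).index) == [2000, 2002]


class TestMovingAverage:
    def test_constant_unchanged(self):
        assert np.allclose(moving_average([4.0] * 10), 4.0)

    def test_centre_value(self):
        assert moving_average([0.0, 3.0, 6.0])[1] == pytest.approx(3.0)

    def test_window_one_identity(self):
        v = [5.0, 1.0, 8.0]
        assert np.allclose(moving_average(v, window=1), v)

    def test_truncated_edges(self):
        out = moving_average([0.0, 3.0, 6.0])
        assert out[0] == pytest.approx(1.5)
        assert out[2] == pytest.approx(4.5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1.0, 2.0], window=2)
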