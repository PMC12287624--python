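import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foragevar import community, trend_models as tm
from foragevar.errors import InsufficientDataError, ValidationError


def _sites(values):
    return pd.Series(values, index=[f"S{i+1}" for i in range(len(values))])


class TestSiteRegression:
    def test_perfect_line(self):
        rain = _sites([700.0, 800.0, 900.0, 1000.0])
        res = tm.site_regression(2 - 0.001 * rain, rain)
        assert res.r2_adjusted == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-10)
        assert res.slope == pytest.approx(-0.001)

    def test_closed_form_three_points(self):
        # x=(0,1,2), y=(1,2,2): slope 1/2, intercept 7/6, R2 3/4, adj 1/2,
        # F=3, p = P(|t_1| > sqrt(3)) = 1/3 exactly
        res = tm.site_regression(_sites([1.0, 2.0, 2.0]), _sites([0.0, 1.0, 2.0]))
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(7 / 6)
        assert res.r2 == pytest.approx(0.75)
        assert res.r2_adjusted == pytest.approx(0.5)
        assert res.F == pytest.approx(3.0)
        assert res.p == pytest.approx(1 / 3)
        assert res.df == (1, 1)

    def test_adjusted_r2_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        y = _sites(rng.normal(size=9))
        x = _sites(np.linspace(600, 1000, 9))
        res = tm.site_regression(y, x)
        ols = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
        assert res.r2_adjusted == pytest.approx(ols.rsquared_adj, abs=1e-10)
        assert res.F == pytest.approx(ols.fvalue, abs=1e-8)
        assert res.p == pytest.approx(ols.f_pvalue, abs=1e-10)

    def test_null_slope_rarely_large(self):
        rng = np.random.default_rng(8)
        x = _sites(np.linspace(600, 1000, 9))
        big = 0
        for _ in range(100):
            y = _sites(rng.normal(size=9))
            res = tm.site_regression(y, x)
            se = abs(res.slope / np.sqrt(res.F)) if res.F > 0 else np.inf
            big += abs(res.slope) > 3 * se
        assert big <= 5

    def test_adjusted_r2_can_be_negative(self):
        res = tm.site_regression(_sites([1.0, 5.0, 1.0, 5.0, 1.0]),
                                 _sites([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.r2_adjusted < 0

    def test_log10_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            tm.site_regression(_sites([1.0, -1.0, 2.0]),
                               _sites([1.0, 2.0, 3.0]), transform="log10")

    def test_too_few_sites(self):
        with pytest.raises(InsufficientDataError):
            tm.site_regression(_sites([1.0, 2.0]), _sites([1.0, 2.0]))


def _mixed_samples(rng, n_species=8, n_sites=9, slope=0.0, noise=0.1):
    rain = np.linspace(681, 999, n_sites)
    rows = []
    for k in range(n_species):
        intercept = 2.0 + rng.normal(0, 0.3)
        for j in range(n_sites):
            rows.append((f"sp{k}", rain[j],
                         intercept + slope * (rain[j] - rain.mean())
                         + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["species", "rainfall", "content"])


class TestWithinSpeciesMixed:
    def test_single_species_collapses_to_ols(self):
        rng = np.random.default_rng(3)
        samples = _mixed_samples(rng, n_species=1, slope=-0.002)
        res = tm.within_species_mixed(samples)
        fit = stats.linregress(samples["rainfall"], samples["content"])
        assert res.slope == pytest.approx(fit.slope, abs=1e-6)
        assert res.singular
        assert res.species_var == 0.0

    def test_balanced_design_matches_within_estimator(self):
        # with every species at every site, the REML slope equals the
        # species-demeaned (within) OLS slope
        rng = np.random.default_rng(5)
        samples = _mixed_samples(rng, slope=-0.002)
        res = tm.within_species_mixed(samples)
        d = samples.copy()
        d["content"] -= d.groupby("species")["content"].transform("mean")
        d["rainfall_c"] = d["rainfall"] - d.groupby("species")["rainfall"].transform("mean")
        within = stats.linregress(d["rainfall_c"], d["content"]).slope
        assert res.slope == pytest.approx(within, rel=1e-4)

    def test_null_slope_within_three_se(self):
        rng = np.random.default_rng(9)
        misses = 0
        for _ in range(20):
            samples = _mixed_samples(rng, slope=0.0)
            res = tm.within_species_mixed(samples)
            misses += abs(res.slope) > 3 * res.se
        assert misses <= 2

    def test_ci_contains_estimate_and_df_rules(self):
        rng = np.random.default_rng(7)
        samples = _mixed_samples(rng, slope=-0.001)
        res = tm.within_species_mixed(samples, df_rule="residual")
        assert res.ci_low < res.slope < res.ci_high
        assert res.df == res.n_obs - 2
        alt = tm.within_species_mixed(samples, df_rule="species")
        assert alt.df == alt.n_obs - 1 - alt.n_species
        assert alt.slope == pytest.approx(res.slope)

    def test_min_sites_inclusion_rule(self):
        rng = np.random.default_rng(2)
        samples = _mixed_samples(rng, n_species=4)
        # cripple one species down to 2 sites: it must be excluded
        trimmed = samples[~((samples["species"] == "sp0")
                            & (samples["rainfall"] > 720))]
        res = tm.within_species_mixed(trimmed, min_sites=3)
        assert res.n_species == 3

    def test_no_eligible_species(self):
        samples = pd.DataFrame({"species": ["a", "a"], "rainfall": [700.0, 800.0],
                                "content": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            tm.within_species_mixed(samples, min_sites=3)

    def test_zero_between_species_variance_flagged_singular(self):
        # identical observations in every group force the boundary estimate
        rng = np.random.default_rng(1)
        rain = np.linspace(681, 999, 9)
        values = 2.0 + rng.normal(0, 0.05, 9)
        rows = [(f"sp{k}", rain[j], values[j]) for k in range(5) for j in range(9)]
        samples = pd.DataFrame(rows, columns=["species", "rainfall", "content"])
        res = tm.within_species_mixed(samples)
        assert res.singular
        assert res.species_var == pytest.approx(0.0, abs=1e-8)


class TestRatios:
    def test_site_ratio_of_specific_cwms(self, toy_survey, toy_chemistry):
        table = community.cwm_table(toy_survey, toy_chemistry)
        site, _ = tm.build_ratios(table, toy_chemistry, pairs=("N:P",))
        # contents were built with P = N/10, so every ratio is exactly 10
        assert np.allclose(site["specific"], 10.0)
        assert np.allclose(site["fixed"], 10.0)

    def test_sample_ratio_values(self):
        chem = pd.DataFrame({"site": ["S1", "S1"], "species": ["A", "A"],
                             "element": ["K", "Na"], "content": [1.0, 0.1]})
        samples = tm.sample_ratios(chem, pairs=("K:Na",))
        assert samples["value"].iloc[0] == pytest.approx(10.0)

    def test_ratio_of_fixed_cwms_differs_from_cwm_of_ratios(self):
        # two species, equal weights: N {2, 1}, P {0.2, 0.5}
        counts = pd.DataFrame({"site": ["S1", "S1"], "species": ["A", "B"],
                               "layer_count": [4, 4]})
        chem = pd.DataFrame({
            "site": "S1", "species": ["A", "B", "A", "B"],
            "element": ["N", "N", "P", "P"], "content": [2.0, 1.0, 0.2, 0.5]})
        table = community.cwm_table(counts, chem)
        site, samples = tm.build_ratios(table, chem, pairs=("N:P",))
        ratio_of_cwms = site["specific"].iloc[0]
        cwm_of_ratios = samples["value"].mean()
        assert ratio_of_cwms == pytest.approx(1.5 / 0.35)
        assert cwm_of_ratios == pytest.approx(6.0)
        assert ratio_of_cwms != pytest.approx(cwm_of_ratios)

    def test_zero_denominator_rejected(self):
        chem = pd.DataFrame({"site": ["S1", "S1"], "species": ["A", "A"],
                             "element": ["K", "Na"], "content": [1.0, 0.0]})
        with pytest.raises(ValidationError):
            tm.sample_ratios(chem, pairs=("K:Na",))
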