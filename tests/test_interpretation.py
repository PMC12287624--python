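import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from foragevar import data_io, interpretation as itp
from foragevar.decomposition import ComponentSS, DecompositionResult
from foragevar.errors import ValidationError
from foragevar.trend_models import RegressionResult


def _decomp(turnover_share, intraspecific_share, target="X"):
    ss_total = 1.0
    cov = ss_total - turnover_share - intraspecific_share
    nan = math.nan
    return DecompositionResult(
        target=target, transform="identity", n_sites=9, ss_total=ss_total,
        turnover=ComponentSS(nan, nan, turnover_share),
        intraspecific=ComponentSS(nan, nan, intraspecific_share),
        covariation=ComponentSS(nan, nan, cov),
        degenerate=(ss_total == 0))


def _trend(p, slope=-1.0, target="X"):
    return RegressionResult(target=target, transform="identity", slope=slope,
                            intercept=0.0, r2=0.5, r2_adjusted=0.4, F=5.0,
                            df=(1, 7), p=p, n=9)


class TestClassifier:
    @pytest.mark.parametrize("turn,intra,p,label", [
        (0.64, 0.07, 0.059, "a"),
        (0.35, 0.25, 0.001, "a+b"),
        (0.70, 0.05, 0.85, "c"),
        (0.05, 0.80, 0.02, "b"),
        (0.05, 0.80, 0.50, "d"),
        (0.45, 0.40, 0.50, "c+d"),
    ])
    def test_labels(self, turn, intra, p, label):
        call = itp.classify_hypothesis(_decomp(turn, intra), _trend(p))
        assert call.label == label

    def test_mechanisms_never_empty(self):
        call = itp.classify_hypothesis(_decomp(0.10, 0.05), _trend(0.01))
        assert call.mechanisms == ("turnover",)
        assert call.label == "a"

    def test_degenerate_is_unclassifiable(self):
        d = _decomp(0.0, 0.0)
        d.ss_total, d.degenerate = 0.0, True
        call = itp.classify_hypothesis(d, _trend(0.5))
        assert call.unclassifiable and call.label is None

    def test_label_mapping_is_bijective(self):
        seen = {}
        mechs = [("turnover",), ("intraspecific",), ("turnover", "intraspecific")]
        for mechanisms, related in itertools.product(mechs, (True, False)):
            label = itp.label_for(mechanisms, related)
            assert label not in seen
            seen[label] = (mechanisms, related)
        assert set(seen) == {"a", "b", "c", "d", "a+b", "c+d"}


class TestVariability:
    def test_variable_requires_share_and_significance(self):
        mixed = _mixed(p=1e-4)
        label, _ = itp.label_intraspecific_variability(_decomp(0.35, 0.25), mixed)
        assert label == "variable"

    def test_share_gate_blocks_significant_slope(self):
        mixed = _mixed(p=0.03)
        label, _ = itp.label_intraspecific_variability(_decomp(0.79, 0.07), mixed)
        assert label == "uniform"

    def test_significance_gate_blocks_large_share(self):
        mixed = _mixed(p=0.4)
        label, _ = itp.label_intraspecific_variability(_decomp(0.30, 0.40), mixed)
        assert label == "uniform"

    def test_outlier_species_flagged(self):
        samples = pd.DataFrame({
            "species": ["cen mez"] * 2 + ["the tri"] * 2,
            "content": [0.03, 0.50, 0.10, 0.12]})
        label, outliers = itp.label_intraspecific_variability(
            _decomp(0.70, 0.05), _mixed(p=0.5), samples)
        assert label == "uniform"
        assert outliers == ["cen mez"]


def _mixed(p):
    from foragevar.trend_models import MixedModelResult
    return MixedModelResult(target="X", transform="identity", slope=-1e-3,
                            se=2e-4, ci_low=-1.4e-3, ci_high=-6e-4, t=-5.0,
                            df=34, df_rule="residual", p=p, species_var=0.01,
                            residual_var=0.02, n_obs=36, n_species=10,
                            singular=False)


@pytest.fixture()
def reqs():
    return data_io.load_requirements()


def _grade_inputs(site_values, sample_values, element="Na"):
    sites = [f"S{i+1}" for i in range(len(site_values))]
    cwm = pd.DataFrame({"site": sites, "element": element,
                        "specific": site_values, "fixed": site_values,
                        "intraspecific_dev": 0.0, "coverage": 1.0})
    chem = pd.DataFrame({"site": np.repeat(sites, 1), "species": "A",
                         "element": element, "content": sample_values})
    empty = pd.DataFrame({"site": [], "ratio": [], "specific": [], "fixed": []})
    empty_s = pd.DataFrame({"site": [], "species": [], "ratio": [], "value": []})
    return cwm, chem, empty, empty_s


class TestLimitation:
    def test_everything_above_thresholds_is_sufficient(self, reqs):
        cwm, chem, er, es = _grade_inputs([5.0] * 9, [5.0] * 9, element="K")
        grades = itp.grade_limitation(cwm, chem, er, es, reqs, targets=("K",))
        assert grades[0].summary == "sufficient"

    def test_one_site_in_nine_is_severely_limiting(self, reqs):
        vals = [0.01] * 8 + [0.9]
        cwm, chem, er, es = _grade_inputs(vals, vals, element="Na")
        grades = itp.grade_limitation(cwm, chem, er, es, reqs, targets=("Na",))
        g = grades[0]
        assert g.summary == "severely limiting"
        for d in g.per_herbivore.values():
            assert d["site_fraction"] == pytest.approx(1 / 9)

    def test_tie_meets_threshold(self, reqs):
        # cattle lactating Na requirement is exactly 0.12
        vals = [0.12] * 9
        cwm, chem, er, es = _grade_inputs(vals, vals, element="Na")
        grades = itp.grade_limitation(cwm, chem, er, es, reqs, targets=("Na",))
        assert grades[0].per_herbivore["cattle"]["site_fraction"] == 1.0

    def test_absent_cell_skips_herbivore_with_notice(self, reqs):
        vals = [3.0] * 9
        cwm, chem, er, es = _grade_inputs(vals, vals, element="N")
        grades = itp.grade_limitation(cwm, chem, er, es, reqs, targets=("N",))
        g = grades[0]
        assert "wildebeest" not in g.per_herbivore          # no N cell
        assert any("wildebeest" in n for n in g.notices)

    def test_ratio_positions(self, reqs):
        sites = [f"S{i+1}" for i in range(3)]
        cwm = pd.DataFrame({"site": sites, "element": "N", "specific": 2.0,
                            "fixed": 2.0, "intraspecific_dev": 0.0, "coverage": 1.0})
        site_r = pd.DataFrame({"site": sites, "ratio": "K:Na",
                               "specific": [20.0, 30.0, 40.0],
                               "fixed": [20.0, 30.0, 40.0]})
        samp_r = pd.DataFrame({"site": sites, "species": "A", "ratio": "K:Na",
                               "value": [15.0, 3.0, 50.0]})
        grades = itp.grade_limitation(cwm, pd.DataFrame(
            {"site": sites, "species": "A", "element": "N", "content": 2.0}),
            site_r, samp_r, reqs, targets=("K:Na",))
        g = grades[0]
        assert g.summary == "too high everywhere"           # optimal 1-5, all sites above
        assert g.per_herbivore["cattle"]["sample"]["within"] == pytest.approx(1 / 3)

    @given(delta=st.floats(min_value=0.0, max_value=2.0, allow_nan=False),
           seed=st.integers(min_value=0, max_value=50))
    def test_raising_contents_never_worsens_grade(self, delta, seed):
        reqs = data_io.load_requirements()
        order = {"severely limiting": 0, "moderately limiting": 1, "sufficient": 2}
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.0001, 0.6, 9)
        cwm, chem, er, es = _grade_inputs(vals, vals, element="Na")
        before = itp.grade_limitation(cwm, chem, er, es, reqs, targets=("Na",))[0]
        cwm2, chem2, _, _ = _grade_inputs(vals + delta, vals + delta, element="Na")
        after = itp.grade_limitation(cwm2, chem2, er, es, reqs, targets=("Na",))[0]
        assert order[after.summary] >= order[before.summary]


class TestReport:
    def test_trend_direction_rules(self):
        assert itp.trend_direction(_trend(0.059, slope=-1)) == "decreasing"
        assert itp.trend_direction(_trend(0.05, slope=1)) == "increasing"
        assert itp.trend_direction(_trend(0.43, slope=-1)) == "unresponsive"

    def test_build_and_format_report(self, reqs):
        calls = {"Na": itp.classify_hypothesis(_decomp(0.7, 0.05, "Na"), _trend(0.43))}
        trends = {"Na": _trend(0.43, target="Na")}
        variability = {"Na": ("uniform", ["cen mez"])}
        vals = [0.01] * 8 + [0.9]
        cwm, chem, er, es = _grade_inputs(vals, vals, element="Na")
        grades = itp.grade_limitation(cwm, chem, er, es, reqs, targets=("Na",))
        report = itp.build_report(calls, trends, variability, grades)
        row = report.iloc[0]
        assert row["mechanism"] == "c"
        assert row["overall_trend"] == "unresponsive"
        assert row["limitation"] == "severely limiting"
        text = itp.format_report(report, grades)
        assert "severely limiting" in text and "cattle" in text
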