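"""Hypothesis classification and herbivore nutrient-limitation grading.

Each element or ratio is assigned to one of four mechanisms of across-site
variation, from the decomposition shares and the site-level trend:

* ``a`` — gradient-related species turnover,
* ``b`` — gradient-related intraspecific variation,
* ``c`` — gradient-unrelated species turnover,
* ``d`` — gradient-unrelated intraspecific variation,

with the combined forms ``a+b`` / ``c+d`` when both components contribute.
A component "contributes" when its total SS share reaches ``theta_contrib``
(default 15% — large enough to separate a genuinely mixed case from noise
shares, small enough to keep a ~25% intraspecific component in). The
gradient link uses the site-trend p-value at ``trend_alpha`` (default 0.1,
the solid-vs-dashed trendline convention).

Limitation grading compares site-level weighted means and individual
samples against per-herbivore minimum dietary contents, and CWM ratios
against optimal ranges. The verbal summary is an operationalisation of
those comparisons: *sufficient* when every site and every sample meets
every reference herbivore's minimum, *severely limiting* when at most a
fifth of sites meet any herbivore's minimum, *moderately limiting*
otherwise. The underlying fractions are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data_io import RequirementTable, ELEMENTS, RATIOS
from .decomposition import DecompositionResult
from .errors import ValidationError
from .trend_models import MixedModelResult, RegressionResult

MECHANISMS = ("turnover", "intraspecific")

_LABELS = {
    (("turnover",), True): "a",
    (("intraspecific",), True): "b",
    (("turnover", "intraspecific"), True): "a+b",
    (("turnover",), False): "c",
    (("intraspecific",), False): "d",
    (("turnover", "intraspecific"), False): "c+d",
}


def label_for(mechanisms: tuple[str, ...], gradient_related: bool) -> str:
    """Map a (mechanism set, gradient link) pair to its scenario label."""
    key = (tuple(m for m in MECHANISMS if m in mechanisms), bool(gradient_related))
    if key not in _LABELS:
        raise ValidationError(f"no label for mechanisms {mechanisms!r}")
    return _LABELS[key]


@dataclass(frozen=True)
class HypothesisCall:
    """Scenario assignment for one target, with the evidence used."""

    target: str
    mechanisms: tuple[str, ...]
    gradient_related: bool
    label: str | None
    turnover_share: float
    intraspecific_share: float
    trend_p: float
    unclassifiable: bool = False


def classify_hypothesis(decomposition: DecompositionResult,
                        site_trend: RegressionResult,
                        theta_contrib: float = 0.15,
                        trend_alpha: float = 0.1) -> HypothesisCall:
    """Assign a target to scenarios a/b/c/d (or a combination).

    Mechanisms are the components whose total share of the across-site SS
    reaches ``theta_contrib``; if neither does, the larger one is taken so
    the call is never empty. The gradient link is the site-level trend
    p-value tested at ``trend_alpha``.
    """
    if decomposition.degenerate:
        return HypothesisCall(target=decomposition.target, mechanisms=(),
                              gradient_related=False, label=None,
                              turnover_share=float("nan"),
                              intraspecific_share=float("nan"),
                              trend_p=site_trend.p, unclassifiable=True)
    shares = {m: decomposition.share(m) for m in MECHANISMS}
    mechanisms = tuple(m for m in MECHANISMS if shares[m] >= theta_contrib)
    if not mechanisms:
        mechanisms = (max(shares, key=shares.get),)
    related = site_trend.p < trend_alpha
    return HypothesisCall(target=decomposition.target, mechanisms=mechanisms,
                          gradient_related=related,
                          label=label_for(mechanisms, related),
                          turnover_share=shares["turnover"],
                          intraspecific_share=shares["intraspecific"],
                          trend_p=site_trend.p)


def outlier_species(samples: pd.DataFrame, theta_outlier: float = 5.0) -> list[str]:
    """Species whose within-species max/min content ratio exceeds the cutoff.

    ``samples`` needs columns ``species, content``; species observed at a
    single site cannot be flagged.
    """
    out = []
    for species, grp in samples.groupby("species"):
        vals = grp["content"].astype(float)
        if len(vals) >= 2 and vals.min() > 0 and vals.max() / vals.min() > theta_outlier:
            out.append(str(species))
    return sorted(out)


def label_intraspecific_variability(decomposition: DecompositionResult,
                                    mixed_result: MixedModelResult,
                                    samples: pd.DataFrame | None = None,
                                    theta_contrib: float = 0.15,
                                    mixed_alpha: float = 0.05,
                                    theta_outlier: float = 5.0,
                                    ) -> tuple[str, list[str]]:
    """"variable" vs "uniform" within-species behaviour, plus outlier species.

    *Variable* requires both a substantial intraspecific SS share
    (>= ``theta_contrib``) and a significant within-species trend
    (mixed-model p < ``mixed_alpha``); a significant but tiny component
    stays *uniform*. Species with extreme within-species spread are listed
    separately so a "mostly uniform" element can carry its exception.
    """
    share = decomposition.share("intraspecific")
    variable = (share >= theta_contrib) and (mixed_result.p < mixed_alpha)
    outliers = outlier_species(samples, theta_outlier) if samples is not None else []
    return ("variable" if variable else "uniform"), outliers


@dataclass
class LimitationGrade:
    """Requirement comparison for one target and life stage.

    ``per_herbivore`` maps herbivore -> dict of fractions: for elements
    ``site_fraction`` / ``sample_fraction`` meeting the minimum (ties
    meet); for ratios the below/within/above position fractions at site
    and sample level.
    """

    target: str
    kind: str               # "element" | "ratio"
    life_stage: str
    per_herbivore: dict[str, dict[str, float]]
    summary: str | None
    notices: list[str] = field(default_factory=list)


def summarize_element_limitation(site_fractions: dict[str, float],
                                 sample_fractions: dict[str, float],
                                 sufficient_cut: float = 1.0,
                                 severe_cut: float = 0.2) -> str:
    """Verbal grade from per-herbivore meeting fractions (see module docs)."""
    herbs = site_fractions.keys()
    if all(site_fractions[h] >= sufficient_cut and sample_fractions[h] >= sufficient_cut
           for h in herbs):
        return "sufficient"
    if all(site_fractions[h] <= severe_cut for h in herbs):
        return "severely limiting"
    return "moderately limiting"


def _positions(values, low: float, high: float) -> dict[str, float]:
    v = pd.Series(values, dtype=float)
    n = len(v)
    return {"below": float((v < low).sum()) / n,
            "within": float(((v >= low) & (v <= high)).sum()) / n,
            "above": float((v > high).sum()) / n}


def summarize_ratio_limitation(site_positions: dict[str, dict[str, float]]) -> str:
    """Verbal summary of where the site ratio sits relative to optimal ranges."""
    if all(p["above"] == 1.0 for p in site_positions.values()):
        return "too high everywhere"
    if all(p["below"] == 1.0 for p in site_positions.values()):
        return "too low everywhere"
    if all(p["within"] == 1.0 for p in site_positions.values()):
        return "suitable everywhere"
    return "mixed"


def grade_limitation(cwm: pd.DataFrame, chemistry: pd.DataFrame,
                     site_ratios: pd.DataFrame, sample_ratios: pd.DataFrame,
                     requirements: RequirementTable,
                     life_stage: str = "lactating",
                     sufficient_cut: float = 1.0, severe_cut: float = 0.2,
                     targets: tuple[str, ...] | None = None,
                     ) -> list[LimitationGrade]:
    """Grade every element and ratio against the requirement table.

    A site "meets" an element requirement when its specific CWM is at or
    above the herbivore's minimum; a sample meets it when the measured
    content is. Targets with no populated requirement cell for any
    herbivore are reported with a notice and no summary.
    """
    if targets is None:
        targets = tuple(pd.unique(cwm["element"])) + tuple(pd.unique(site_ratios["ratio"]))
    grades: list[LimitationGrade] = []
    for target in targets:
        if target in ELEMENTS:
            site_vals = cwm.loc[cwm["element"] == target].set_index("site")["specific"]
            sample_vals = chemistry.loc[chemistry["element"] == target, "content"]
            per: dict[str, dict[str, float]] = {}
            notices: list[str] = []
            for herb in requirements.herbivores:
                thr = requirements.minimum(herb, life_stage, target)
                if thr is None:
                    notices.append(f"no {life_stage} {target} requirement for {herb}")
                    continue
                per[herb] = {
                    "threshold": thr,
                    "site_fraction": float((site_vals >= thr).mean()),
                    "sample_fraction": float((sample_vals >= thr).mean()),
                    "n_sites": int(len(site_vals)),
                    "n_samples": int(len(sample_vals)),
                }
            if not per:
                grades.append(LimitationGrade(target, "element", life_stage, {},
                                              None, notices + ["target skipped"]))
                continue
            summary = summarize_element_limitation(
                {h: d["site_fraction"] for h, d in per.items()},
                {h: d["sample_fraction"] for h, d in per.items()},
                sufficient_cut=sufficient_cut, severe_cut=severe_cut)
            grades.append(LimitationGrade(target, "element", life_stage, per,
                                          summary, notices))
        elif target in RATIOS:
            site_vals = site_ratios.loc[site_ratios["ratio"] == target, "specific"]
            sample_vals = sample_ratios.loc[sample_ratios["ratio"] == target, "value"]
            per, notices = {}, []
            for herb in requirements.herbivores:
                rng = requirements.ratio_range(herb, life_stage, target)
                if rng is None:
                    notices.append(f"no {life_stage} {target} range for {herb}")
                    continue
                low, high = rng
                per[herb] = {"low": low, "high": high,
                             "site": _positions(site_vals, low, high),
                             "sample": _positions(sample_vals, low, high)}
            if not per:
                grades.append(LimitationGrade(target, "ratio", life_stage, {},
                                              None, notices + ["target skipped"]))
                continue
            summary = summarize_ratio_limitation({h: d["site"] for h, d in per.items()})
            grades.append(LimitationGrade(target, "ratio", life_stage, per,
                                          summary, notices))
        else:
            raise ValidationError(f"unknown target {target!r}")
    return grades


def trend_direction(site_trend: RegressionResult, trend_alpha: float = 0.1) -> str:
    """"decreasing" / "increasing" at the trend threshold, else "unresponsive"."""
    if site_trend.p >= trend_alpha:
        return "unresponsive"
    return "decreasing" if site_trend.slope < 0 else "increasing"


def build_report(calls: dict[str, HypothesisCall],
                 site_trends: dict[str, RegressionResult],
                 variability: dict[str, tuple[str, list[str]]],
                 grades: list[LimitationGrade],
                 trend_alpha: float = 0.1) -> pd.DataFrame:
    """One-row-per-target summary mirroring the classic results-table layout."""
    grade_by_target = {g.target: g for g in grades}
    rows = []
    for target, call in calls.items():
        grade = grade_by_target.get(target)
        var_label, outliers = variability.get(target, (None, []))
        rows.append({
            "target": target,
            "overall_trend": trend_direction(site_trends[target], trend_alpha)
            if target in site_trends else None,
            "intraspecific_variability": var_label,
            "outlier_species": ";".join(outliers),
            "mechanism": call.label,
            "turnover_share_pct": 100 * call.turnover_share,
            "intraspecific_share_pct": 100 * call.intraspecific_share,
            "trend_p": call.trend_p,
            "limitation": grade.summary if grade else None,
        })
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame, grades: list[LimitationGrade]) -> str:
    """Human-readable text rendering of the report plus grading fractions."""
    lines = [report.to_string(index=False, float_format=lambda v: f"{v:.3g}"), ""]
    for g in grades:
        lines.append(f"{g.target} ({g.kind}, {g.life_stage}): {g.summary}")
        for herb, d in g.per_herbivore.items():
            if g.kind == "element":
                lines.append(
                    f"  {herb}: threshold {d['threshold']}% — "
                    f"{d['site_fraction']:.0%} of {d['n_sites']} sites, "
                    f"{d['sample_fraction']:.0%} of {d['n_samples']} samples meet")
            else:
                s = d["site"]
                lines.append(
                    f"  {herb}: optimal {d['low']}-{d['high']} — sites "
                    f"{s['below']:.0%} below / {s['within']:.0%} within / "
                    f"{s['above']:.0%} above")
        for note in g.notices:
            lines.append(f"  note: {note}")
    return "\n".join(lines)
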