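"""Sum-of-squares partition of across-site trait variation.

With per-site specific CWM :math:`S_j`, fixed CWM :math:`F_j` and
intraspecific deviation :math:`I_j = S_j - F_j`, the centred sums of
squares across sites satisfy

.. math::

    \\sum_j (S_j-\\bar S)^2 = \\sum_j (F_j-\\bar F)^2
        + \\sum_j (I_j-\\bar I)^2 + 2\\sum_j (F_j-\\bar F)(I_j-\\bar I),

i.e. total = species turnover + intraspecific + covariation. The
covariation term is signed: positive when sites dominated by trait-rich
species also host above-average individuals of the species present,
negative in the opposite case.

Each component is further split along an environmental gradient
(rainfall) by fitting straight-line models to S, F and I separately:
the gradient-explained SS of a component comes from its fitted values,
the residual SS from its residuals, and the covariation cross-term is
split the same way. Because a least-squares line is additive in the
response, the full 3 x 3 grid stays exactly additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ratio_parts
from .errors import InsufficientDataError, ValidationError

#: elements / ratios whose right-skewed values are log10-transformed by default
DEFAULT_LOG10_TARGETS: tuple[str, ...] = ("Ca", "Mg", "Na", "Ca:P")


@dataclass(frozen=True)
class ComponentSS:
    """One decomposition row: gradient-explained, residual and total SS."""

    explained: float
    residual: float
    total: float


@dataclass
class DecompositionResult:
    """3 x 3 SS grid for one element or ratio.

    Raw SS are on the (possibly log10) scale of the input series; shares
    are signed fractions of ``ss_total`` (covariation may be negative).
    """

    target: str
    transform: str
    n_sites: int
    ss_total: float
    turnover: ComponentSS
    intraspecific: ComponentSS
    covariation: ComponentSS
    degenerate: bool = False
    has_gradient: bool = False
    notes: str = ""

    _ROWS = ("turnover", "intraspecific", "covariation")

    def component(self, name: str) -> ComponentSS:
        if name not in self._ROWS:
            raise KeyError(name)
        return getattr(self, name)

    def share(self, name: str, column: str = "total") -> float:
        """Signed share of ``ss_total`` for one grid cell (NaN if degenerate)."""
        if self.degenerate:
            return math.nan
        return getattr(self.component(name), column) / self.ss_total

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-component table with raw SS and percentage shares."""
        rows = []
        for name in self._ROWS:
            comp = self.component(name)
            rows.append({
                "target": self.target, "transform": self.transform,
                "component": name,
                "explained_ss": comp.explained, "residual_ss": comp.residual,
                "total_ss": comp.total,
                "explained_pct": 100 * self.share(name, "explained")
                if self.has_gradient else math.nan,
                "residual_pct": 100 * self.share(name, "residual")
                if self.has_gradient else math.nan,
                "total_pct": 100 * self.share(name, "total"),
                "n_sites": self.n_sites,
            })
        return pd.DataFrame(rows)


def _prepare(specific: pd.Series, fixed: pd.Series, transform: str):
    s = pd.Series(specific).astype(float)
    f = pd.Series(fixed).astype(float)
    common = s.index.intersection(f.index)
    if len(common) < len(s) or len(common) < len(f):
        raise ValidationError("specific and fixed series must cover the same sites")
    if len(common) < 3:
        raise InsufficientDataError(f"need >= 3 sites, got {len(common)}")
    s, f = s.loc[common], f.loc[common]
    if transform == "log10":
        if (s <= 0).any() or (f <= 0).any():
            raise ValidationError("log10 transform requires positive values")
        s, f = np.log10(s), np.log10(f)
    elif transform != "identity":
        raise ValidationError(f"unknown transform {transform!r}")
    return s.to_numpy(), f.to_numpy(), list(common)


def _css(x: np.ndarray) -> float:
    d = x - x.mean()
    return float(d @ d)


def _cross(a: np.ndarray, b: np.ndarray) -> float:
    return float((a - a.mean()) @ (b - b.mean()))


def decompose_ss(specific: pd.Series, fixed: pd.Series, target: str = "",
                 transform: str = "identity") -> DecompositionResult:
    """Totals-only decomposition (no gradient split).

    ``specific`` and ``fixed`` are site-indexed CWM series for one target.
    """
    s, f, sites = _prepare(specific, fixed, transform)
    i = s - f
    ss_total = _css(s)
    turn, intra = _css(f), _css(i)
    cov = 2.0 * _cross(f, i)
    nan = math.nan
    return DecompositionResult(
        target=target, transform=transform, n_sites=len(sites), ss_total=ss_total,
        turnover=ComponentSS(nan, nan, turn),
        intraspecific=ComponentSS(nan, nan, intra),
        covariation=ComponentSS(nan, nan, cov),
        degenerate=(ss_total == 0.0), has_gradient=False)


def _linear_fit(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Least-squares straight-line fitted values of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    return slope * x + intercept


def decompose_with_gradient(specific: pd.Series, fixed: pd.Series,
                            rainfall: pd.Series, target: str = "",
                            transform: str = "identity") -> DecompositionResult:
    """Full 3 x 3 decomposition with the gradient-explained / residual split.

    ``rainfall`` must be defined for every site of the CWM series. With a
    constant gradient the totals are still returned but the split columns
    are NaN (flagged in ``notes``).
    """
    result = decompose_ss(specific, fixed, target=target, transform=transform)
    s, f, sites = _prepare(specific, fixed, transform)
    rain = pd.Series(rainfall).astype(float)
    if not set(sites) <= set(rain.index):
        missing = sorted(set(sites) - set(rain.index))
        raise ValidationError(f"rainfall missing for site(s) {missing}")
    x = rain.loc[sites].to_numpy()
    if np.ptp(x) == 0:
        result.notes = "constant gradient: explained/residual split undefined"
        return result
    i = s - f
    f_hat, i_hat = _linear_fit(f, x), _linear_fit(i, x)
    turn = ComponentSS(_css(f_hat), _css(f - f_hat), result.turnover.total)
    intra = ComponentSS(_css(i_hat), _css(i - i_hat), result.intraspecific.total)
    cov_expl = 2.0 * _cross(f_hat, i_hat)
    cov = ComponentSS(cov_expl, result.covariation.total - cov_expl,
                      result.covariation.total)
    result.turnover, result.intraspecific, result.covariation = turn, intra, cov
    result.has_gradient = True
    return result


def ratio_series(cwm: pd.DataFrame, ratio: str) -> pd.DataFrame:
    """Site-level specific and fixed CWM ratio series for one ratio label.

    The site ratio is the ratio of the two elements' specific CWMs (and of
    their fixed CWMs for the turnover component), not the CWM of per-sample
    ratios.
    """
    num, den = ratio_parts(ratio)
    for el in (num, den):
        if el not in cwm["element"].unique():
            raise ValidationError(f"element {el} missing from the CWM table for {ratio}")
    wide = cwm.pivot(index="site", columns="element", values=["specific", "fixed"])
    spec = wide[("specific", num)] / wide[("specific", den)]
    fix = wide[("fixed", num)] / wide[("fixed", den)]
    if not np.isfinite(spec).all() or not np.isfinite(fix).all():
        raise ValidationError(f"zero denominator building ratio {ratio}")
    out = pd.DataFrame({"site": spec.index, "ratio": ratio,
                        "specific": spec.to_numpy(), "fixed": fix.to_numpy()})
    return out.reset_index(drop=True)


def decompose_all(cwm: pd.DataFrame, environment: pd.DataFrame,
                  elements: tuple[str, ...] | None = None,
                  ratios: tuple[str, ...] = ("N:P", "Ca:P", "K:Na"),
                  log10_targets: tuple[str, ...] = DEFAULT_LOG10_TARGETS,
                  ) -> dict[str, DecompositionResult]:
    """Run the gradient decomposition for every element and ratio target."""
    rain = environment.set_index("site")["rainfall"]
    if elements is None:
        elements = tuple(pd.unique(cwm["element"]))
    results: dict[str, DecompositionResult] = {}
    for element in elements:
        sub = cwm[cwm["element"] == element].set_index("site")
        results[element] = decompose_with_gradient(
            sub["specific"], sub["fixed"], rain, target=element,
            transform="log10" if element in log10_targets else "identity")
    for ratio in ratios:
        rs = ratio_series(cwm, ratio).set_index("site")
        results[ratio] = decompose_with_gradient(
            rs["specific"], rs["fixed"], rain, target=ratio,
            transform="log10" if ratio in log10_targets else "identity")
    return results


def decomposition_frame(results: dict[str, DecompositionResult]) -> pd.DataFrame:
    """Concatenate per-target tidy tables into one output frame."""
    return pd.concat([r.to_frame() for r in results.values()], ignore_index=True)
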