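"""Site-level trend regressions, within-species mixed models, and ratios.

Site-level trends are ordinary least-squares fits of a (possibly
log10-transformed) site series on mean annual rainfall. The reported R^2
is the *adjusted* R^2 throughout — with a single predictor and few sites
it can be negative, which matches how such fits are conventionally
summarised for short environmental gradients.

Within-species trends use a linear mixed model: content ~ rainfall with a
random intercept per species, fit by REML. Only species sampled at a
minimum number of sites (default 3) enter the fit. The Wald t statistic
for the slope uses a configurable residual degree-of-freedom rule:
``"residual"`` (n_obs - 2) or ``"species"`` (n_obs - 1 - n_species); the
rule used is recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ratio_parts
from .errors import InsufficientDataError, ValidationError

DF_RULES = ("residual", "species")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a site series on rainfall (single predictor)."""

    target: str
    transform: str
    slope: float          # per mm/yr, on the (transformed) response scale
    intercept: float
    r2: float
    r2_adjusted: float
    F: float
    df: tuple[int, int]
    p: float
    n: int

    def to_row(self) -> dict:
        return {"target": self.target, "transform": self.transform,
                "estimate": self.slope, "intercept": self.intercept,
                "r2": self.r2, "r2_adjusted": self.r2_adjusted,
                "stat": self.F, "df1": self.df[0], "df2": self.df[1],
                "p": self.p, "n": self.n}


@dataclass(frozen=True)
class MixedModelResult:
    """REML mixed-model fit of sample contents on rainfall (random species intercepts)."""

    target: str
    transform: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    df_rule: str
    p: float
    species_var: float
    residual_var: float
    n_obs: int
    n_species: int
    singular: bool

    def to_row(self) -> dict:
        return {"target": self.target, "transform": self.transform,
                "estimate": self.slope, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "stat": self.t, "df": self.df, "df_rule": self.df_rule,
                "p": self.p, "species_var": self.species_var,
                "residual_var": self.residual_var,
                "n": self.n_obs, "n_species": self.n_species,
                "singular": self.singular}


def _apply_transform(values: pd.Series, transform: str) -> pd.Series:
    if transform == "identity":
        return values.astype(float)
    if transform == "log10":
        if (values <= 0).any():
            raise ValidationError("log10 transform requires positive values")
        return np.log10(values.astype(float))
    raise ValidationError(f"unknown transform {transform!r}")


def site_regression(values_by_site: pd.Series, rainfall: pd.Series,
                    transform: str = "identity", target: str = "") -> RegressionResult:
    """OLS of a site series on rainfall, reporting adjusted R^2, F and p."""
    y = _apply_transform(pd.Series(values_by_site), transform)
    rain = pd.Series(rainfall).astype(float)
    if not set(y.index) <= set(rain.index):
        raise ValidationError("rainfall missing for some sites")
    x = rain.loc[y.index]
    n = len(y)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 sites, got {n}")
    fit = stats.linregress(x.to_numpy(), y.to_numpy())
    r2 = fit.rvalue ** 2
    df2 = n - 2
    r2_adj = 1 - (1 - r2) * (n - 1) / df2
    # guard the perfect-fit corner where 1 - r2 underflows
    if 1 - r2 <= 0:
        F, p = np.inf, 0.0
    else:
        F = r2 / (1 - r2) * df2
        p = float(stats.f.sf(F, 1, df2))
    return RegressionResult(target=target, transform=transform,
                            slope=float(fit.slope), intercept=float(fit.intercept),
                            r2=float(r2), r2_adjusted=float(r2_adj), F=float(F),
                            df=(1, df2), p=p, n=n)


def _ols_slope(y: np.ndarray, x: np.ndarray):
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    sigma2 = float(resid @ resid) / (len(y) - 2)
    return float(fit.slope), float(fit.stderr), sigma2


def within_species_mixed(samples: pd.DataFrame, transform: str = "identity",
                         min_sites: int = 3, df_rule: str = "residual",
                         target: str = "") -> MixedModelResult:
    """REML mixed model of sample contents on rainfall with species intercepts.

    ``samples`` needs columns ``species, rainfall, content``. Species with
    fewer than ``min_sites`` observations are dropped before fitting (the
    repeat-species inclusion rule). A single remaining species collapses
    the model to OLS on that species; a between-species variance estimated
    at (numerically) zero is flagged as singular but still returned.
    """
    if df_rule not in DF_RULES:
        raise ValidationError(f"df_rule must be one of {DF_RULES}")
    df = samples[["species", "rainfall", "content"]].dropna().copy()
    counts = df.groupby("species")["rainfall"].size()
    keep = counts[counts >= min_sites].index
    df = df[df["species"].isin(keep)]
    if df.empty:
        raise InsufficientDataError(
            f"no species with >= {min_sites} observations")
    y = _apply_transform(df["content"], transform).to_numpy()
    x = df["rainfall"].to_numpy(dtype=float)
    groups = df["species"].to_numpy()
    n_obs, n_species = len(y), len(keep)

    if n_species == 1:
        slope, se, sigma2 = _ols_slope(y, x)
        species_var, singular = 0.0, True
    else:
        import statsmodels.api as sm
        exog = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=groups)
            res = model.fit(reml=True)
        slope = float(res.fe_params[1])
        se = float(res.bse_fe[1])
        species_var = float(np.asarray(res.cov_re)[0, 0])
        sigma2 = float(res.scale)
        singular = species_var <= 1e-8 * max(sigma2, 1e-300)

    dof = n_obs - 2 if df_rule == "residual" else n_obs - 1 - n_species
    if dof < 1:
        raise InsufficientDataError("not enough observations for the df rule")
    t = slope / se
    p = float(2 * stats.t.sf(abs(t), dof))
    crit = float(stats.t.ppf(0.975, dof))
    return MixedModelResult(target=target, transform=transform, slope=slope, se=se,
                            ci_low=slope - crit * se, ci_high=slope + crit * se,
                            t=float(t), df=int(dof), df_rule=df_rule, p=p,
                            species_var=species_var, residual_var=sigma2,
                            n_obs=n_obs, n_species=int(n_species), singular=singular)


def sample_ratios(chemistry: pd.DataFrame,
                  pairs: tuple[str, ...] = ("N:P", "Ca:P", "K:Na")) -> pd.DataFrame:
    """Within-sample ratios of raw contents per (site, species, ratio)."""
    wide = chemistry.pivot(index=["site", "species"], columns="element",
                           values="content")
    frames = []
    for ratio in pairs:
        num, den = ratio_parts(ratio)
        if num not in wide.columns or den not in wide.columns:
            raise ValidationError(f"element missing from chemistry for ratio {ratio}")
        sub = wide[[num, den]].dropna()
        if (sub[den] == 0).any():
            raise ValidationError(f"zero denominator in sample ratio {ratio}")
        frames.append(pd.DataFrame({
            "site": sub.index.get_level_values("site"),
            "species": sub.index.get_level_values("species"),
            "ratio": ratio, "value": (sub[num] / sub[den]).to_numpy()}))
    return pd.concat(frames, ignore_index=True)


def build_ratios(cwm: pd.DataFrame, chemistry: pd.DataFrame,
                 pairs: tuple[str, ...] = ("N:P", "Ca:P", "K:Na")):
    """Site-level CWM-ratio series plus per-sample ratios.

    The site series divides the specific (and fixed) CWMs of the two
    elements; it is *not* the community mean of per-sample ratios — the
    two differ whenever abundance and stoichiometry covary.
    """
    from .decomposition import ratio_series
    site = pd.concat([ratio_series(cwm, r) for r in pairs], ignore_index=True)
    return site, sample_ratios(chemistry, pairs)
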