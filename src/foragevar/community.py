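"""Layer abundance, relative abundance and community-weighted means.

The abundance currency is the *layer count*: the number of plot x height
layer cells a species occupies along a site's transect (at most
``n_plots * n_layers`` = 84 under the 21-plot, 4-layer design). Relative
abundance at a site is computed over the subset of species with leaf
chemistry ("collected" species); species that were surveyed but not
sampled contribute only to the coverage denominator.

Two community-weighted means (CWM) are computed per (site, element):

* the *specific* CWM uses each species' site-specific content;
* the *fixed* CWM uses each species' cross-site mean content, so it varies
  between sites only through species composition.

Their difference is the site's intraspecific deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptySiteError, ValidationError


def layer_abundance(survey: pd.DataFrame, n_plots: int = 21, n_layers: int = 4) -> pd.DataFrame:
    """Total layer counts per (site, species).

    Accepts either survey dialect (see :mod:`foragevar.data_io`). For the
    layered dialect the count is the number of distinct (plot, layer) cells
    occupied; sites where a species is absent get no row.
    """
    if "layer_count" in survey.columns:
        counts = survey[["site", "species", "layer_count"]].copy()
    else:
        counts = (survey.drop_duplicates(["site", "plot", "species", "layer"])
                  .groupby(["site", "species"], sort=True).size()
                  .rename("layer_count").reset_index())
    cap = n_plots * n_layers
    if (counts["layer_count"] > cap).any():
        raise ValidationError(f"layer_count exceeds the design maximum {cap}")
    if (counts["layer_count"] < 1).any():
        raise ValidationError("layer_count must be >= 1")
    return counts.sort_values(["site", "species"]).reset_index(drop=True)


def relative_abundance(abundance: pd.DataFrame, chemistry: pd.DataFrame) -> pd.DataFrame:
    """Per-site weights over the sampled (chemistry-bearing) species subset.

    Returns one row per sampled (site, species) with columns
    ``site, species, layer_count, weight, coverage``, where ``weight`` is
    the species' share of the sampled subset's layer total (summing to 1
    within a site) and ``coverage`` is the sampled subset's share of the
    site's total layer abundance.
    """
    sampled = chemistry[["site", "species"]].drop_duplicates()
    total_all = abundance.groupby("site")["layer_count"].sum()
    sub = abundance.merge(sampled, on=["site", "species"], how="inner")
    missing = set(total_all.index) - set(sub["site"])
    if missing:
        raise EmptySiteError(f"no sampled species at site(s) {sorted(missing)}")
    total_sampled = sub.groupby("site")["layer_count"].transform("sum")
    sub = sub.assign(weight=sub["layer_count"] / total_sampled,
                     coverage=(total_sampled / sub["site"].map(total_all)))
    return sub.sort_values(["site", "species"]).reset_index(drop=True)


def species_fixed_means(chemistry: pd.DataFrame) -> pd.DataFrame:
    """Cross-site mean content per (species, element), with the site count.

    The mean is unweighted over the sites where the species was sampled.
    Values are summed in sorted order so the result is invariant to site
    ordering, and when every site-level value is identical the common
    value is returned as-is (no sum/n round-off), so a species with
    genuinely constant content has a fixed mean exactly equal to it.
    """
    def _mean(values: np.ndarray) -> float:
        if np.all(values == values[0]):
            return float(values[0])
        return float(np.sort(values).mean())

    grouped = chemistry.groupby(["species", "element"], sort=True)["content"]
    out = grouped.agg(fixed_content=lambda s: _mean(s.to_numpy()),
                      n_sites_sampled="size").reset_index()
    out["n_sites_sampled"] = out["n_sites_sampled"].astype(int)
    return out


def cwm(weights: pd.Series, contents: pd.Series) -> float:
    """Weighted mean of ``contents`` under ``weights`` (both indexed by species).

    Raises if a positively-weighted species has no content value or if the
    weights do not sum to 1.
    """
    w = weights[weights > 0]
    if abs(float(w.sum()) - 1.0) > 1e-9:
        raise ValidationError("weights must sum to 1 over the included species")
    aligned = contents.reindex(w.index)
    if aligned.isna().any():
        missing = list(aligned[aligned.isna()].index)
        raise ValidationError(f"species with weight but no content: {missing}")
    return float(np.dot(w.to_numpy(), aligned.to_numpy()))


def cwm_table(survey_or_abundance: pd.DataFrame, chemistry: pd.DataFrame,
              elements: tuple[str, ...] | None = None,
              n_plots: int = 21, n_layers: int = 4) -> pd.DataFrame:
    """Specific and fixed CWM per (site, element).

    Weights are recomputed per element over the species having that element
    measured at the site, which keeps the weighted mean well-defined under
    partial chemistry (with complete 6-element samples this coincides with
    the per-site weights). Output columns:
    ``site, element, specific, fixed, intraspecific_dev, coverage``.
    """
    if {"plot", "layer"} <= set(survey_or_abundance.columns) or \
            "layer_count" not in survey_or_abundance.columns:
        abundance = layer_abundance(survey_or_abundance, n_plots=n_plots, n_layers=n_layers)
    else:
        abundance = survey_or_abundance
    if elements is None:
        elements = tuple(sorted(chemistry["element"].unique(),
                                key=["N", "P", "K", "Ca", "Mg", "Na"].index))
    fixed = species_fixed_means(chemistry)
    total_all = abundance.groupby("site")["layer_count"].sum()
    rows = []
    for element in elements:
        chem_e = chemistry[chemistry["element"] == element]
        merged = abundance.merge(chem_e[["site", "species", "content"]],
                                 on=["site", "species"], how="inner")
        merged = merged.merge(fixed.loc[fixed["element"] == element,
                                        ["species", "fixed_content"]],
                              on="species", how="left")
        missing = set(total_all.index) - set(merged["site"])
        if missing:
            raise EmptySiteError(
                f"no sampled species with element {element} at site(s) {sorted(missing)}")
        for site, grp in merged.groupby("site", sort=True):
            grp = grp.sort_values("species")
            w = grp["layer_count"].to_numpy(dtype=float)
            w = w / w.sum()
            specific = float(np.dot(w, grp["content"].to_numpy()))
            fixed_cwm = float(np.dot(w, grp["fixed_content"].to_numpy()))
            rows.append({
                "site": site, "element": element,
                "specific": specific, "fixed": fixed_cwm,
                "intraspecific_dev": specific - fixed_cwm,
                "coverage": float(grp["layer_count"].sum() / total_all[site]),
            })
    return pd.DataFrame(rows)
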