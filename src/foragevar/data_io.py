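"""Reading, validation and writing of the pipeline's tables.

All tables are long (tidy) CSV, UTF-8, "." decimal separator. Element
contents are stored in percent of dry mass throughout, matching the scale
of published requirement tables. Canonical keys are the element symbols
``N, P, K, Ca, Mg, Na`` and the ratio labels ``"N:P", "Ca:P", "K:Na"``.

Two survey dialects are accepted:

* *layered*: one row per (site, plot, species, occupied height layer),
  with layers ``L1``..``L4`` (0-10, 10-30, 30-50, 50-200 cm) or ``1``..``4``;
* *pre-aggregated*: one row per (site, species) with a ``layer_count``
  column giving the total number of plot x layer cells occupied along the
  transect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError

ELEMENTS: tuple[str, ...] = ("N", "P", "K", "Ca", "Mg", "Na")
RATIOS: tuple[str, ...] = ("N:P", "Ca:P", "K:Na")
LAYERS: tuple[str, ...] = ("L1", "L2", "L3", "L4")
LIFE_STAGES: tuple[str, ...] = ("lactating", "non_lactating")

#: default column names; override via the ``columns`` mapping of the readers
SURVEY_COLUMNS = {"site": "site", "plot": "plot", "species": "species",
                  "layer": "layer", "layer_count": "layer_count"}
CHEMISTRY_COLUMNS = {"site": "site", "species": "species",
                     "element": "element", "content": "content"}
ENVIRONMENT_COLUMNS = {"site": "site", "rainfall": "rainfall"}


def ratio_parts(ratio: str) -> tuple[str, str]:
    """Split a ratio label like ``"N:P"`` into its numerator and denominator."""
    try:
        num, den = ratio.split(":")
    except ValueError as exc:
        raise SchemaError(f"malformed ratio label {ratio!r}") from exc
    for el in (num, den):
        if el not in ELEMENTS:
            raise SchemaError(f"unknown element {el!r} in ratio {ratio!r}")
    return num, den


def _resolve(columns: dict[str, str] | None, defaults: dict[str, str]) -> dict[str, str]:
    out = dict(defaults)
    if columns:
        out.update(columns)
    return out


def _require_columns(df: pd.DataFrame, needed, path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _normalise_layer(value) -> str:
    s = str(value).strip()
    if s in LAYERS:
        return s
    if s.isdigit() and 1 <= int(s) <= len(LAYERS):
        return LAYERS[int(s) - 1]
    raise ValidationError(f"unknown height layer {value!r}; expected L1..L4 or 1..4")


def read_survey(path, columns: dict[str, str] | None = None,
                n_plots: int = 21, n_layers: int = 4) -> pd.DataFrame:
    """Read a vegetation survey in either dialect.

    Returns a tidy frame with columns ``site, plot, species, layer`` (layered
    dialect) or ``site, species, layer_count`` (pre-aggregated). Duplicate
    layered rows are collapsed with a warning; plot indices must lie in
    ``1..n_plots``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"survey file not found: {path}")
    cols = _resolve(columns, SURVEY_COLUMNS)
    raw = pd.read_csv(path)
    if cols["layer_count"] in raw.columns and cols["layer"] not in raw.columns:
        _require_columns(raw, [cols["site"], cols["species"], cols["layer_count"]], path)
        df = raw.rename(columns={cols["site"]: "site", cols["species"]: "species",
                                 cols["layer_count"]: "layer_count"})
        df = df[["site", "species", "layer_count"]].copy()
        df["site"] = df["site"].astype(str)
        df["species"] = df["species"].astype(str)
        counts = pd.to_numeric(df["layer_count"], errors="coerce")
        if counts.isna().any() or (counts < 1).any() or (counts % 1 != 0).any():
            raise ValidationError(f"{path}: layer_count must be a positive integer")
        df["layer_count"] = counts.astype(int)
        if (df["layer_count"] > n_plots * n_layers).any():
            raise ValidationError(
                f"{path}: layer_count exceeds the design maximum {n_plots * n_layers}")
        if df.duplicated(["site", "species"]).any():
            raise ValidationError(f"{path}: duplicate (site, species) rows")
        return df

    _require_columns(raw, [cols["site"], cols["plot"], cols["species"], cols["layer"]], path)
    df = raw.rename(columns={cols["site"]: "site", cols["plot"]: "plot",
                             cols["species"]: "species", cols["layer"]: "layer"})
    df = df[["site", "plot", "species", "layer"]].copy()
    df["site"] = df["site"].astype(str)
    df["species"] = df["species"].astype(str)
    plots = pd.to_numeric(df["plot"], errors="coerce")
    if plots.isna().any():
        raise ValidationError(f"{path}: non-numeric plot index")
    df["plot"] = plots.astype(int)
    bad = df[(df["plot"] < 1) | (df["plot"] > n_plots)]
    if not bad.empty:
        raise ValidationError(
            f"{path}: plot index outside 1..{n_plots} "
            f"(e.g. {bad['plot'].iloc[0]} at site {bad['site'].iloc[0]})")
    df["layer"] = df["layer"].map(_normalise_layer)
    n_before = len(df)
    df = df.drop_duplicates(["site", "plot", "species", "layer"]).reset_index(drop=True)
    if len(df) < n_before:
        warnings.warn(f"{path}: collapsed {n_before - len(df)} duplicate survey row(s)",
                      stacklevel=2)
    return df


def read_chemistry(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read leaf chemistry: one row per (site, species, element), content in %."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"chemistry file not found: {path}")
    cols = _resolve(columns, CHEMISTRY_COLUMNS)
    raw = pd.read_csv(path)
    _require_columns(raw, list(cols.values()), path)
    df = raw.rename(columns={v: k for k, v in cols.items()})[
        ["site", "species", "element", "content"]].copy()
    df["site"] = df["site"].astype(str)
    df["species"] = df["species"].astype(str)
    df["element"] = df["element"].astype(str)
    unknown = set(df["element"]) - set(ELEMENTS)
    if unknown:
        raise SchemaError(f"{path}: unknown element symbol(s) {sorted(unknown)}")
    df["content"] = pd.to_numeric(df["content"], errors="coerce")
    if df["content"].isna().any():
        raise ValidationError(f"{path}: non-numeric content value")
    if (df["content"] <= 0).any():
        raise ValidationError(f"{path}: element contents must be > 0 (percent dry mass)")
    if df.duplicated(["site", "species", "element"]).any():
        raise ValidationError(f"{path}: duplicate (site, species, element) rows")
    return df.reset_index(drop=True)


def read_environment(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read the site table: one row per site with mean annual rainfall (mm/yr)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"environment file not found: {path}")
    cols = _resolve(columns, ENVIRONMENT_COLUMNS)
    raw = pd.read_csv(path)
    _require_columns(raw, list(cols.values()), path)
    df = raw.rename(columns={v: k for k, v in cols.items()})[["site", "rainfall"]].copy()
    df["site"] = df["site"].astype(str)
    df["rainfall"] = pd.to_numeric(df["rainfall"], errors="coerce")
    if df["rainfall"].isna().any() or (df["rainfall"] <= 0).any():
        raise ValidationError(f"{path}: rainfall must be a positive number (mm/yr)")
    if df["site"].duplicated().any():
        raise ValidationError(f"{path}: duplicate site rows")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class RequirementTable:
    """Minimum dietary contents and optimal ratio ranges per reference herbivore.

    ``minima`` maps (herbivore, life_stage, element) -> minimum % dry mass;
    ``ranges`` maps (herbivore, life_stage, ratio) -> (low, high). Cells
    absent from the source table are simply missing from the mappings.
    """

    minima: dict[tuple[str, str, str], float]
    ranges: dict[tuple[str, str, str], tuple[float, float]]
    body_mass_kg: dict[str, float]

    @property
    def herbivores(self) -> tuple[str, ...]:
        return tuple(sorted(self.body_mass_kg, key=self.body_mass_kg.get, reverse=True))

    def minimum(self, herbivore: str, life_stage: str, element: str) -> float | None:
        """Minimum content cell, or None where the source table has no value."""
        return self.minima.get((herbivore, life_stage, element))

    def ratio_range(self, herbivore: str, life_stage: str, ratio: str) -> tuple[float, float] | None:
        """Optimal ratio range cell, or None where absent."""
        return self.ranges.get((herbivore, life_stage, ratio))


def _parse_range(cell: str) -> tuple[float, float]:
    low_s, high_s = str(cell).split("-")
    low, high = float(low_s), float(high_s)
    if low > high:
        raise ValidationError(f"requirement range {cell!r} has low > high")
    return low, high


def load_requirements() -> RequirementTable:
    """Load the bundled literature-derived herbivore requirement table."""
    with resources.files("foragevar.data").joinpath(
            "herbivore_requirements.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str)
    minima: dict[tuple[str, str, str], float] = {}
    ranges: dict[tuple[str, str, str], tuple[float, float]] = {}
    mass: dict[str, float] = {}
    for _, row in df.iterrows():
        herb, stage = row["herbivore"], row["life_stage"]
        if stage not in LIFE_STAGES:
            raise SchemaError(f"unknown life stage {stage!r} in requirement table")
        mass[herb] = float(row["body_mass_kg"])
        for el in ELEMENTS:
            cell = row[el]
            if pd.notna(cell) and str(cell).strip():
                minima[(herb, stage, el)] = float(cell)
        for ratio in RATIOS:
            cell = row[ratio]
            if pd.notna(cell) and str(cell).strip():
                ranges[(herb, stage, ratio)] = _parse_range(cell)
    return RequirementTable(minima=minima, ranges=ranges, body_mass_kg=mass)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a result table as CSV (full float precision, round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_table`."""
    return pd.read_csv(path, float_precision="round_trip")
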