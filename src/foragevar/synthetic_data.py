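"""Synthetic communities with known variance structure.

The generator emulates the field design the rest of the package analyses:
a short rainfall gradient (9 sites, 681-999 mm/yr), a herbaceous species
pool (~45 species) surveyed in 21 plots x 4 height layers per site, and
per-(site, species) pooled leaf chemistry for six elements.

Mechanisms, one per scenario of across-site variation:

* species turnover along the gradient comes from Gaussian occupancy
  niches on the rainfall axis; coupling species' baseline contents to
  their niche optima makes the turnover gradient-related (scenario ``a``);
* computing occupancy against a site permutation chosen to be maximally
  uncorrelated with rainfall gives gradient-*unrelated* turnover (``c``);
* a shared, site-invariant composition plus a common within-species
  linear trend of content on rainfall gives gradient-related
  intraspecific variation (``b``);
* shared composition plus random per-site content offsets residualised
  against rainfall gives gradient-unrelated intraspecific variation
  (``d``). The residualisation makes "unrelated" a property of the
  construction rather than a lucky draw.

Ca/Mg/Na-like elements get lognormal baselines and multiplicative noise
(mirroring the strong right skew of those contents in forbs vs grasses);
N/P/K-like elements are additive with truncated-normal baselines.
All randomness flows from one seed through spawned child generators, so
identical specs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ELEMENTS, LAYERS, write_table
from .errors import ValidationError

#: element -> (typical community mean content in % dry mass, distribution family)
ELEMENT_MODELS: dict[str, tuple[float, str]] = {
    "N": (2.0, "normal"),
    "P": (0.2, "normal"),
    "K": (1.5, "normal"),
    "Ca": (0.6, "lognormal"),
    "Mg": (0.3, "lognormal"),
    "Na": (0.1, "lognormal"),
}

PRESETS = ("a", "b", "c", "d")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic study.

    Defaults reproduce the sampled design: 9 sites evenly spaced over
    681-999 mm/yr, 45 species, 21 plots x 4 layers. ``turnover_coupling``
    is the relative change in species baseline content per unit of
    normalised niche position (0.3 = +-30% across the gradient);
    ``within_species_slope_rel`` is the within-species trend per mm of
    rainfall relative to the element mean (additive for normal elements,
    on the log scale for lognormal ones); ``site_offset_sd`` is the
    relative SD of rainfall-orthogonal site effects; ``noise_sd_rel`` is
    the relative residual noise SD (default 5% of the element mean).
    """

    n_sites: int = 9
    rain_min: float = 681.0
    rain_max: float = 999.0
    n_species: int = 45
    n_plots: int = 21
    n_layers: int = 4
    niche_width: float = 120.0
    occupancy_max: float = 0.35
    shared_composition: bool = False
    permute_niches: bool = False
    turnover_coupling: float = 0.0
    within_species_slope_rel: float = 0.0
    site_offset_sd: float = 0.0
    noise_sd_rel: float = 0.05
    baseline_scatter_normal: float = 0.15
    baseline_scatter_log: float = 0.4
    elements: tuple[str, ...] = tuple(ELEMENT_MODELS)
    seed: int = 0
    scenario: str | None = None

    def validate(self) -> None:
        if self.n_sites < 3 or self.n_species < 2:
            raise ValidationError("need at least 3 sites and 2 species")
        if self.rain_max <= self.rain_min:
            raise ValidationError("rainfall range must be strictly increasing")
        if not 0 < self.occupancy_max <= 1:
            raise ValidationError("occupancy_max must be in (0, 1]")
        if self.noise_sd_rel < 0 or self.site_offset_sd < 0:
            raise ValidationError("noise and offset SDs must be >= 0")
        unknown = set(self.elements) - set(ELEMENT_MODELS)
        if unknown:
            raise ValidationError(f"unknown element(s) {sorted(unknown)}")


def preset(name: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Scenario presets ``a``-``d`` (see module docstring for the mechanisms)."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {PRESETS}")
    base = {
        "a": dict(turnover_coupling=0.3),
        "b": dict(shared_composition=True, within_species_slope_rel=-0.0015),
        "c": dict(turnover_coupling=0.3, permute_niches=True),
        "d": dict(shared_composition=True, site_offset_sd=0.15),
    }[name]
    base.update(overrides)
    return ScenarioSpec(seed=seed, scenario=name, **base)


def _decorrelated_permutation(rng: np.random.Generator, x: np.ndarray,
                              n_candidates: int = 256) -> np.ndarray:
    """Index permutation of x minimising |corr(x[perm], x)| over seeded draws."""
    best, best_r = None, np.inf
    for _ in range(n_candidates):
        perm = rng.permutation(len(x))
        r = abs(np.corrcoef(x[perm], x)[0, 1])
        if r < best_r:
            best, best_r = perm, r
    return best


def _orthogonal_offsets(rng: np.random.Generator, rain: np.ndarray,
                        sd: float) -> np.ndarray:
    """Unit-SD site effects residualised against (1, rainfall), scaled by sd."""
    if sd == 0:
        return np.zeros_like(rain)
    X = np.column_stack([np.ones_like(rain), rain])
    for _ in range(64):
        o = rng.standard_normal(len(rain))
        resid = o - X @ np.linalg.lstsq(X, o, rcond=None)[0]
        if resid.std() > 1e-8:
            return sd * resid / resid.std()
    raise ValidationError("failed to draw non-degenerate site offsets")


def generate(spec: ScenarioSpec):
    """Draw one synthetic dataset.

    Returns ``(survey, chemistry, environment, ground_truth)`` where the
    frames use the CSV dialects the readers accept (layered survey) and
    ``ground_truth`` records every generating parameter and latent draw.
    Chemistry is produced for every species present at a site, so the
    survey coverage of the sampled subset is 1 by construction.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_comp, rng_chem, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    rain = np.linspace(spec.rain_min, spec.rain_max, spec.n_sites)
    sites = [f"S{i + 1}" for i in range(spec.n_sites)]
    species = [f"sp{k + 1:02d}" for k in range(spec.n_species)]
    mid = rain.mean()
    half = (spec.rain_max - spec.rain_min) / 2
    n_cells = spec.n_plots * spec.n_layers

    # niche optima spread a little beyond the gradient so the edges turn over too
    optima = np.linspace(spec.rain_min - 0.5 * spec.niche_width,
                         spec.rain_max + 0.5 * spec.niche_width, spec.n_species)
    optima = rng_comp.permutation(optima)

    perm = None
    if spec.shared_composition:
        p = rng_comp.uniform(0.08, 0.45, spec.n_species)
        base_counts = np.maximum(rng_comp.binomial(n_cells, p), 1)
        counts = np.tile(base_counts, (spec.n_sites, 1))
    else:
        comp_grad = rain
        if spec.permute_niches:
            perm = _decorrelated_permutation(rng_comp, rain)
            comp_grad = rain[perm]
        prob = spec.occupancy_max * np.exp(
            -0.5 * ((comp_grad[:, None] - optima[None, :]) / spec.niche_width) ** 2)
        if (prob > 1).any():
            raise ValidationError("occupancy probability exceeds 1")
        counts = rng_comp.binomial(n_cells, prob)
        for j in range(spec.n_sites):          # a site must host at least one species
            if counts[j].sum() == 0:
                counts[j, np.argmax(prob[j])] = 1

    survey_rows = []
    for j, site in enumerate(sites):
        for k, sp in enumerate(species):
            c = counts[j, k]
            if c == 0:
                continue
            cells = rng_comp.choice(n_cells, size=c, replace=False)
            for cell in np.sort(cells):
                survey_rows.append((site, int(cell // spec.n_layers) + 1, sp,
                                    LAYERS[int(cell % spec.n_layers)]))
    survey = pd.DataFrame(survey_rows, columns=["site", "plot", "species", "layer"])

    g = (optima - mid) / half          # normalised niche position, roughly [-1.2, 1.2]
    chem_rows = []
    truth_elements: dict[str, dict] = {}
    for element in spec.elements:
        mean, family = ELEMENT_MODELS[element]
        offsets = _orthogonal_offsets(rng_chem, rain, spec.site_offset_sd)
        if family == "normal":
            scatter = rng_chem.normal(0.0, spec.baseline_scatter_normal, spec.n_species)
            baseline = mean * (1 - spec.turnover_coupling * g) * (1 + scatter)
            baseline = np.maximum(baseline, 0.05 * mean)
            slope_abs = spec.within_species_slope_rel * mean
            content = (baseline[None, :]
                       + slope_abs * (rain - mid)[:, None]
                       + mean * offsets[:, None])
            if spec.noise_sd_rel > 0:
                content = content + rng_noise.normal(
                    0.0, spec.noise_sd_rel * mean, content.shape)
            content = np.maximum(content, 0.01 * mean)
        else:
            scatter = rng_chem.normal(0.0, spec.baseline_scatter_log, spec.n_species)
            baseline = mean * np.exp(-spec.turnover_coupling * g + scatter)
            slope_abs = spec.within_species_slope_rel
            content = (baseline[None, :]
                       * np.exp(slope_abs * (rain - mid))[:, None]
                       * np.exp(offsets)[:, None])
            if spec.noise_sd_rel > 0:
                content = content * np.exp(
                    rng_noise.normal(0.0, spec.noise_sd_rel, content.shape))
        for j, site in enumerate(sites):
            for k, sp in enumerate(species):
                if counts[j, k] > 0:
                    chem_rows.append((site, sp, element, float(content[j, k])))
        truth_elements[element] = {
            "family": family, "mean": mean,
            "baseline": baseline.tolist(),
            "within_species_slope": float(slope_abs),
            "site_offsets": offsets.tolist(),
        }
    chemistry = pd.DataFrame(chem_rows, columns=["site", "species", "element", "content"])
    environment = pd.DataFrame({"site": sites, "rainfall": rain})

    ground_truth = {
        "spec": dataclasses.asdict(spec),
        "sites": sites, "rainfall": rain.tolist(), "species": species,
        "niche_optima": optima.tolist(),
        "niche_permutation": None if perm is None else perm.tolist(),
        "layer_counts": counts.tolist(),
        "elements": truth_elements,
    }
    return survey, chemistry, environment, ground_truth


def write_dataset(out_dir, survey: pd.DataFrame, chemistry: pd.DataFrame,
                  environment: pd.DataFrame, ground_truth: dict) -> dict[str, Path]:
    """Write the generated tables and ground-truth JSON into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": write_table(survey, out / "survey.csv"),
        "chemistry": write_table(chemistry, out / "chemistry.csv"),
        "environment": write_table(environment, out / "environment.csv"),
    }
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(ground_truth, indent=2, sort_keys=True))
    paths["ground_truth"] = truth_path
    return paths
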