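"""End-to-end orchestration: inputs -> CWMs -> decomposition -> models -> report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import community, data_io, decomposition, interpretation, synthetic_data, trend_models
from .config import PipelineConfig
from .errors import ForagevarError, InsufficientDataError

log = logging.getLogger("foragevar")


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output plus the written paths."""

    cwm: pd.DataFrame
    decomposition: pd.DataFrame
    site_models: pd.DataFrame
    mixed_models: pd.DataFrame
    report: pd.DataFrame
    calls: dict
    grades: list
    paths: dict[str, Path] = field(default_factory=dict)


def _load_inputs(config: PipelineConfig, out: Path):
    if config.preset is not None:
        spec = synthetic_data.preset(config.preset, seed=config.seed,
                                     elements=config.elements)
        survey, chemistry, environment, truth = synthetic_data.generate(spec)
        synthetic_data.write_dataset(out / "inputs", survey, chemistry,
                                     environment, truth)
        return survey, chemistry, environment
    survey = data_io.read_survey(config.survey, n_plots=config.n_plots,
                                 n_layers=config.n_layers)
    chemistry = data_io.read_chemistry(config.chemistry)
    environment = data_io.read_environment(config.environment)
    return survey, chemistry, environment


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write all result tables.

    Outputs land in ``config.output_dir``: cwm.csv, decomposition.csv,
    site_models.csv, mixed_models.csv, interpretation.csv / .txt and a
    manifest.json stamped with the config hash and seed. Stage errors
    propagate after an error manifest is written, so partial outputs are
    retained for inspection.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        survey, chemistry, environment = _load_inputs(config, out)
        rain_by_site = environment.set_index("site")["rainfall"]

        cwm = community.cwm_table(survey, chemistry, elements=config.elements,
                                  n_plots=config.n_plots, n_layers=config.n_layers)
        paths["cwm"] = data_io.write_table(cwm, out / "cwm.csv")

        decomps = decomposition.decompose_all(
            cwm, environment, elements=config.elements, ratios=config.ratios,
            log10_targets=config.log10_targets)
        paths["decomposition"] = data_io.write_table(
            decomposition.decomposition_frame(decomps), out / "decomposition.csv")

        site_ratios, samp_ratios = trend_models.build_ratios(
            cwm, chemistry, pairs=config.ratios)

        site_trends: dict[str, trend_models.RegressionResult] = {}
        for element in config.elements:
            series = cwm[cwm["element"] == element].set_index("site")["specific"]
            site_trends[element] = trend_models.site_regression(
                series, rain_by_site, target=element,
                transform="log10" if element in config.log10_targets else "identity")
        for ratio in config.ratios:
            series = site_ratios[site_ratios["ratio"] == ratio].set_index("site")["specific"]
            site_trends[ratio] = trend_models.site_regression(
                series, rain_by_site, target=ratio,
                transform="log10" if ratio in config.log10_targets else "identity")
        paths["site_models"] = data_io.write_table(
            pd.DataFrame([r.to_row() for r in site_trends.values()]),
            out / "site_models.csv")

        chem_samples = chemistry.assign(rainfall=chemistry["site"].map(rain_by_site))
        mixed: dict[str, trend_models.MixedModelResult] = {}
        for element in config.elements:
            sub = chem_samples[chem_samples["element"] == element]
            try:
                mixed[element] = trend_models.within_species_mixed(
                    sub, target=element, min_sites=config.min_sites_within,
                    df_rule=config.df_rule,
                    transform="log10" if element in config.log10_targets else "identity")
            except InsufficientDataError as exc:
                log.warning("mixed model skipped for %s: %s", element, exc)
        ratio_samples = samp_ratios.rename(columns={"value": "content"}).assign(
            rainfall=lambda d: d["site"].map(rain_by_site))
        for ratio in config.ratios:
            sub = ratio_samples[ratio_samples["ratio"] == ratio]
            try:
                mixed[ratio] = trend_models.within_species_mixed(
                    sub, target=ratio, min_sites=config.min_sites_within,
                    df_rule=config.df_rule,
                    transform="log10" if ratio in config.log10_targets else "identity")
            except InsufficientDataError as exc:
                log.warning("mixed model skipped for %s: %s", ratio, exc)
        paths["mixed_models"] = data_io.write_table(
            pd.DataFrame([m.to_row() for m in mixed.values()]),
            out / "mixed_models.csv")

        calls = {t: interpretation.classify_hypothesis(
            decomps[t], site_trends[t], theta_contrib=config.theta_contrib,
            trend_alpha=config.trend_alpha) for t in decomps}
        variability = {}
        for target, m in mixed.items():
            if target in config.elements:
                samples = chemistry[chemistry["element"] == target]
            else:
                samples = samp_ratios[samp_ratios["ratio"] == target].rename(
                    columns={"value": "content"})
            variability[target] = interpretation.label_intraspecific_variability(
                decomps[target], m, samples, theta_contrib=config.theta_contrib,
                mixed_alpha=config.mixed_alpha, theta_outlier=config.theta_outlier)
        grades = interpretation.grade_limitation(
            cwm, chemistry, site_ratios, samp_ratios, data_io.load_requirements(),
            life_stage=config.life_stage, sufficient_cut=config.sufficient_cut,
            severe_cut=config.severe_cut,
            targets=tuple(config.elements) + tuple(config.ratios))
        report = interpretation.build_report(calls, site_trends, variability,
                                             grades, trend_alpha=config.trend_alpha)
        paths["report"] = data_io.write_table(report, out / "interpretation.csv")
        text = interpretation.format_report(report, grades)
        (out / "interpretation.txt").write_text(text + "\n")
        paths["report_txt"] = out / "interpretation.txt"

        manifest = {"config": config.to_dict(), "config_hash": config.config_hash(),
                    "seed": config.seed, "outputs": {k: str(v) for k, v in paths.items()}}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = out / "manifest.json"

        return PipelineResult(
            cwm=cwm, decomposition=decomposition.decomposition_frame(decomps),
            site_models=pd.DataFrame([r.to_row() for r in site_trends.values()]),
            mixed_models=pd.DataFrame([m.to_row() for m in mixed.values()]),
            report=report, calls=calls, grades=grades, paths=paths)
    except ForagevarError as exc:
        (out / "error_manifest.json").write_text(json.dumps(
            {"error": str(exc), "type": type(exc).__name__,
             "config": config.to_dict(), "completed": {k: str(v) for k, v in paths.items()}},
            indent=2, sort_keys=True))
        raise
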