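"""End-to-end orchestration: simulate -> composite -> classify -> condition
index -> trends -> change, driven by one serializable configuration.

Every paper-gap convention resolved at run time (thresholds, variants,
windows) is recorded in the run report so a run is fully reproducible from
its resolved configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change as change_mod
from . import indices, landcover, rsei as rsei_mod, synthetic, trends
from .preprocess import composite_year
from .raster_io import write_raster

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    run_classification: bool = True
    n_train_per_class: int = 300
    n_trees: int = 200
    split_fraction: float = 0.75
    n_stratified_per_class: int = 1500
    filter_window: int = 5
    reference_year_step: int = 5
    coverage_threshold: float = 0.8
    si_variant: str = "table_verbatim"
    transition_mode: str = "start_to_end"
    change_rule: str = "std_multiple"
    change_rule_value: float = 0.5
    change_connectivity: int = 8
    climate_window: str = "jja"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["class_spectra"] = {
            str(k): {"reflectance": list(v["reflectance"]), "thermal_k": v["thermal_k"]}
            for k, v in d["simulation"]["class_spectra"].items()}
        d["simulation"]["years"] = list(d["simulation"]["years"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if sim:
            sim = dict(sim)
            if "class_spectra" in sim:
                sim["class_spectra"] = {
                    int(k): synthetic.ClassSpectrum(tuple(v["reflectance"]), v["thermal_k"])
                    for k, v in sim["class_spectra"].items()}
            if "climate" in sim and isinstance(sim["climate"], dict):
                sim["climate"] = synthetic.ClimateConfig(**{
                    k: synthetic.MonthlyVariableConfig(**v)
                    for k, v in sim["climate"].items()})
            if "years" in sim:
                sim["years"] = tuple(sim["years"])
            for tup in ("initial_shares", "scene_doys"):
                if tup in sim:
                    sim[tup] = tuple(sim[tup])
            sim_cfg = synthetic.SimulationConfig(**sim)
        else:
            sim_cfg = synthetic.SimulationConfig()
        return cls(simulation=sim_cfg, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunReport:
    config: dict
    status: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)       # name -> DataFrame
    summary: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)     # name -> written path

    # objects kept in memory for downstream use / testing
    climate: trends.ClimateSeries | None = None
    landscape: list | None = None
    composites: dict | None = None
    maps_raw: list | None = None
    maps_filtered: list | None = None
    accuracy: landcover.AccuracyReport | None = None
    transitions: landcover.TransitionMatrix | None = None
    rsei_results: dict | None = None
    change_summary: change_mod.ChangeSummary | None = None
    patches: change_mod.PatchTable | None = None


def _rsei_components(composite, variant: indices.SIVariant) -> dict:
    lst = indices.lst_from_product(composite.thermal - 273.15)
    return {
        "NDVI": indices.ndvi(composite).values,
        "WET": indices.tasseled_cap_wetness(composite, sensor_id="SYNTHETIC").values,
        "NDBSI": indices.ndbsi(composite, variant).values,
        "LST": lst.values,
    }


def run_pipeline(config: PipelineConfig, output_dir=None) -> RunReport:
    """Execute every stage in order; any stage failure aborts with its name."""
    report = RunReport(config=config.to_dict())
    sim = config.simulation
    years = list(sim.years)
    pixel_area_ha = sim.grid.pixel_area_ha
    stage = "simulate"
    try:
        climate = synthetic.simulate_climate(sim)
        landscape = synthetic.simulate_landscape(sim, climate)
        report.climate = climate
        report.landscape = landscape
        report.status[stage] = "ok"

        stage = "preprocess"
        all_scenes = [sc for ly in landscape for sc in ly.scenes]
        composites = {}
        for y in years:
            comp = composite_year(all_scenes, y,
                                  coverage_threshold=config.coverage_threshold)
            if comp is None:
                log.warning("year %d has no valid observations; skipped", y)
            else:
                composites[y] = comp
        if not composites:
            raise RuntimeError("no year produced a composite")
        report.composites = composites
        report.status[stage] = "ok"

        stage = "classify"
        maps_filtered = None
        if config.run_classification:
            ref_years = [y for y in years[::config.reference_year_step] if y in composites]
            truth0 = landscape[0].truth.true_map
            stats = landcover.class_statistics_from_samples(
                indices.classification_predictors(composites[ref_years[0]]),
                truth0, seed=sim.seed)
            ml_maps = [landcover.maximum_likelihood_classify(composites[y], stats)
                       for y in ref_years]
            stable = landcover.stable_pixel_mask(ml_maps)
            training = landcover.sample_balanced_training(
                stable, config.n_train_per_class, ref_years, composites,
                seed=sim.seed + 11)
            train, validation = landcover.split_train_validation(
                training, config.split_fraction, seed=sim.seed + 13)
            clf = landcover.train_random_forest(train, config.n_trees,
                                                seed=sim.seed + 17)
            report.accuracy = landcover.assess_accuracy(
                clf, validation, config.n_stratified_per_class, seed=sim.seed + 19)
            maps_raw = [landcover.classify_with_forest(clf, composites[y])
                        for y in years if y in composites]
            maps_filtered = landcover.temporal_majority_filter(
                maps_raw, config.filter_window)
            report.maps_raw = maps_raw
            report.maps_filtered = maps_filtered
            report.tables["areas"] = landcover.area_table(maps_filtered, pixel_area_ha)
            report.transitions = landcover.transition_matrix(
                maps_filtered[0], maps_filtered[-1],
                annual_maps=maps_filtered, mode=config.transition_mode)
            report.tables["accuracy"] = report.accuracy.per_class.assign(
                overall_accuracy=report.accuracy.overall_accuracy,
                kappa=report.accuracy.kappa)
            report.tables["transitions"] = pd.DataFrame(
                report.transitions.matrix,
                index=[landcover.CLASS_NAMES[c] for c in landcover.CLASS_CODES],
                columns=[landcover.CLASS_NAMES[c] for c in landcover.CLASS_CODES])
            report.status[stage] = "ok"
        else:
            report.status[stage] = "skipped"

        stage = "rsei"
        variant = indices.SIVariant(config.si_variant)
        rsei_results = {}
        roi_rows = []
        class_rows = []
        map_by_year = ({m.year: m for m in maps_filtered} if maps_filtered else {})
        for y in years:
            if y not in composites:
                continue
            res = rsei_mod.rsei_for_year(y, _rsei_components(composites[y], variant),
                                         grid=composites[y].grid)
            rsei_results[y] = res
            roi_rows.append({
                "year": y, "rsei_mean": float(np.nanmean(res.rsei)),
                "pc1_variance_share": res.pc1_variance_share,
                "orientation_flipped": res.orientation_flipped,
                **{f"loading_{n.lower()}": float(l)
                   for n, l in zip(rsei_mod.COMPONENT_ORDER, res.pc1_loadings)}})
            if y in map_by_year:
                for code, (mean, n) in rsei_mod.stratified_mean(
                        res.rsei, map_by_year[y]).items():
                    class_rows.append({"year": y, "code": code,
                                       "class": landcover.CLASS_NAMES[code],
                                       "rsei_mean": mean, "n": n})
        report.rsei_results = rsei_results
        report.tables["rsei_roi"] = pd.DataFrame(roi_rows)
        if class_rows:
            report.tables["rsei_class"] = pd.DataFrame(class_rows)
        report.status[stage] = "ok"

        stage = "trends"
        annual = trends.aggregate_climate(climate, config.climate_window)
        report.tables["climate_annual"] = annual
        trend_rows = []
        roi = report.tables["rsei_roi"]
        tr = trends.trend_test(roi.year.to_numpy(), roi.rsei_mean.to_numpy())
        trend_rows.append({"series_id": "rsei_roi", **tr.as_dict()})
        if class_rows:
            cls_tbl = report.tables["rsei_class"]
            for code in landcover.CLASS_CODES:
                sub = cls_tbl[cls_tbl.code == code].dropna(subset=["rsei_mean"])
                if len(sub) >= 5:
                    tr = trends.trend_test(sub.year.to_numpy(), sub.rsei_mean.to_numpy())
                    trend_rows.append({
                        "series_id": f"rsei_{landcover.CLASS_NAMES[code].lower()}",
                        **tr.as_dict()})
        for var in ("tmean", "ppt", "cwb"):
            tr = trends.trend_test(annual.year.to_numpy(), annual[var].to_numpy())
            trend_rows.append({"series_id": f"climate_{var}", **tr.as_dict()})
        report.tables["trends"] = pd.DataFrame(trend_rows)

        corr_rows = []
        if class_rows:
            cls_tbl = report.tables["rsei_class"]
            for var in ("tmean", "ppt", "cwb"):
                anom = trends.anomalies(annual, var)
                for code in landcover.CLASS_CODES:
                    sub = cls_tbl[cls_tbl.code == code].dropna(subset=["rsei_mean"])
                    if len(sub) >= 5:
                        c = trends.climate_rsei_correlation(
                            sub.year.to_numpy(), sub.rsei_mean.to_numpy(), anom,
                            class_label=landcover.CLASS_NAMES[code])
                        corr_rows.append({"class": c.class_label, "variable": var,
                                          "pearson_r": c.pearson_r, "n": c.n})
            report.tables["correlations"] = pd.DataFrame(corr_rows)
        report.status[stage] = "ok"

        stage = "change"
        ys = sorted(rsei_results)
        delta = change_mod.delta_rsei(rsei_results[ys[-1]].rsei, rsei_results[ys[0]].rsei)
        mask, threshold = change_mod.threshold_change(
            delta, config.change_rule, config.change_rule_value)
        summary = change_mod.summarize_delta(delta, mask, pixel_area_ha, threshold)
        patches = change_mod.label_patches(mask, delta, pixel_area_ha,
                                           config.change_connectivity)
        report.change_summary = summary
        report.patches = patches
        report.tables["patches"] = patches.patches
        report.summary["change"] = dataclasses.asdict(summary)
        report.summary["change"]["n_patches"] = patches.n_patches
        report.summary["change"]["largest_patch_ha"] = patches.largest_patch_ha
        report.status[stage] = "ok"
    except Exception as exc:
        report.status[stage] = f"failed: {exc}"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.summary["years"] = [int(y) for y in years]
    report.summary["seed"] = sim.seed
    if report.accuracy is not None:
        report.summary["overall_accuracy"] = report.accuracy.overall_accuracy
        report.summary["kappa"] = report.accuracy.kappa

    if output_dir is not None:
        write_report(report, output_dir)
    return report


def write_report(report: RunReport, output_dir) -> dict:
    """Persist tables as CSV, the summary as JSON, and key rasters as TIFF."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in report.tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=name == "transitions")
        report.manifest[name] = str(p)
    cfg_path = out / "resolved_config.yaml"
    cfg_path.write_text(yaml.safe_dump(report.config, sort_keys=False))
    report.manifest["resolved_config"] = str(cfg_path)

    if report.rsei_results:
        ys = sorted(report.rsei_results)
        for tag, y in (("first", ys[0]), ("last", ys[-1])):
            res = report.rsei_results[y]
            p = out / f"rsei_{tag}_{y}.tif"
            write_raster(p, res.rsei.astype(np.float64), res.grid)
            report.manifest[f"rsei_{tag}"] = str(p)
    if report.maps_filtered:
        for tag, m in (("first", report.maps_filtered[0]),
                       ("last", report.maps_filtered[-1])):
            p = out / f"landcover_{tag}_{m.year}.tif"
            write_raster(p, m.classes.astype(np.int16), m.grid, nodata=0)
            report.manifest[f"landcover_{tag}"] = str(p)

    summary = {"status": report.status, **report.summary}
    sum_path = out / "summary.json"
    sum_path.write_text(json.dumps(summary, indent=1, default=float))
    report.manifest["summary"] = str(sum_path)
    return report.manifest
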