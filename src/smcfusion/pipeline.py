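"""End-to-end orchestration: scenes -> features -> screening -> evaluation.

The pipeline runs nine stages in order: scenes, masks, vegetation indices,
textures, texture indices, thermal calibration, thermal indices, screening,
evaluation. It can generate a synthetic experiment in memory (``mode:
synthetic``) or ingest one previously written to disk (``mode: ingest``);
both paths share every computation downstream of scene loading, including
NDVI re-masking, so results are identical.

All randomness flows from a single top-level seed: the scene generator uses
it directly, the train/validation split uses ``seed + 1000``, and per-model
seeds are derived inside :func:`smcfusion.models.evaluate_combinations`.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models, screening, spectral, synthetic, texture, thermal
from .errors import ConfigurationError, SMCFusionError

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("smcfusion")

LAYERS = ("0-20", "20-40", "40-60")
_LAYER_COLS = {"0-20": "smc_0_20", "20-40": "smc_20_40", "40-60": "smc_40_60"}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; YAML-serializable."""

    mode: str = "synthetic"  # synthetic | ingest
    scene: synthetic.SceneConfig = field(default_factory=synthetic.SceneConfig)
    input_dir: str | None = None  # ingest mode
    vi_threshold: float = 0.3
    glcm_levels: int = 32
    alpha: float = 0.01
    train_fraction: float = 2.0 / 3.0
    learners: models.LearnerConfig = field(default_factory=models.LearnerConfig)
    combinations: tuple[str, ...] = models.COMBINATIONS
    model_kinds: tuple[str, ...] = models.MODEL_KINDS
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "ingest"):
            raise ConfigurationError(f"mode must be synthetic|ingest, got {self.mode}")
        if self.mode == "ingest" and not self.input_dir:
            raise ConfigurationError("ingest mode requires input_dir")
        if self.glcm_levels < 2:
            raise ConfigurationError("glcm_levels must be >= 2")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must be in (0, 1]")
        if (self.output_dir and self.input_dir
                and Path(self.output_dir).resolve() == Path(self.input_dir).resolve()):
            raise ConfigurationError("output_dir must differ from input_dir")
        self.scene.validate()


def load_config(path, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file, optionally overriding the seed."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    scene_raw = raw.pop("scene", {})
    coupling = scene_raw.pop("coupling_strengths", None)
    if coupling is not None:
        scene_raw["coupling_strengths"] = synthetic.CouplingStrengths(**coupling)
    if "smc_range_by_layer" in scene_raw:
        scene_raw["smc_range_by_layer"] = tuple(
            tuple(p) for p in scene_raw["smc_range_by_layer"])
    learners_raw = raw.pop("learners", {})
    gabp = learners_raw.pop("gabp", None)
    if gabp is not None:
        learners_raw["gabp"] = models.GABPConfig(**gabp)
    cfg = PipelineConfig(
        scene=synthetic.SceneConfig(**scene_raw),
        learners=models.LearnerConfig(**learners_raw),
        **raw,
    )
    if seed is not None:
        cfg = replace(cfg, seed=seed,
                      scene=replace(cfg.scene, seed=seed))
    cfg.validate()
    return cfg


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: PipelineConfig, resume: bool):
        self.config = config
        self.resume = resume
        self.out = Path(config.output_dir) if config.output_dir else None
        if self.out:
            self.out.mkdir(parents=True, exist_ok=True)
        self.report: dict = {"seed": config.seed, "stages": [], "warnings": []}
        self.scenes: list = []
        self.truths: list = []
        self.masks: list = []
        self.soil_masks: list = []
        self.feature_tables: dict[str, pd.DataFrame] = {}
        self.families: dict[str, dict[str, str]] = {}
        self.ti_report: pd.DataFrame | None = None
        self.records: dict[str, list] = {}
        self.evaluation: pd.DataFrame | None = None

    def stage(self, name):
        run = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                status = "ok" if exc is None else f"error: {exc}"
                run.report["stages"].append({
                    "name": name,
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "status": status,
                })
                logger.info("stage %s: %s", name, status)
                return False

        return _Ctx()


def _smc_frame(truths) -> pd.DataFrame:
    return synthetic.truths_to_frame(truths)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the run report.

    When ``output_dir`` is set, writes feature tables, the texture-index
    search report, the screening report, the evaluation table, and the run
    report JSON. With ``resume=True``, stages whose output CSVs already
    exist are loaded from disk instead of recomputed.
    """
    config.validate()
    run = _Run(config, resume)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _run_stages(run)
        run.report["warnings"] = sorted({str(w.message) for w in caught})
    finally:
        if run.out:
            serializable = {k: v for k, v in run.report.items()
                            if k != "evaluation"}
            with open(run.out / "run_report.json", "w", encoding="utf-8") as fh:
                json.dump(serializable, fh, indent=2)
    return run.report


def _features_path(run: _Run, layer: str) -> Path | None:
    return run.out / f"features_{layer.replace('-', '_')}.csv" if run.out else None


def _run_stages(run: _Run) -> None:
    cfg = run.config

    with run.stage("scenes"):
        if cfg.mode == "synthetic":
            scene_cfg = replace(cfg.scene, seed=cfg.seed)
            run.scenes, run.truths = synthetic.generate_experiment(scene_cfg)
        else:
            run.scenes, run.truths = synthetic.read_experiment(cfg.input_dir)
    smc_df = _smc_frame(run.truths)
    smc_by_layer = {lay: smc_df[_LAYER_COLS[lay]].to_numpy() for lay in LAYERS}
    n = len(run.scenes)
    split = models.SplitSpec(n_total=n, train_fraction=cfg.train_fraction,
                             seed=cfg.seed + 1000)
    train_ids, _ = models.split_data(list(range(n)), split)

    resumed = (run.resume and run.out is not None
               and all(_features_path(run, lay).exists() for lay in LAYERS)
               and (run.out / "ti_search.csv").exists())
    if resumed:
        for stage_name in ("masks", "vegetation_indices", "textures",
                           "texture_indices", "thermal_calibration",
                           "thermal_indices"):
            with run.stage(stage_name):
                pass
        for lay in LAYERS:
            run.feature_tables[lay] = pd.read_csv(_features_path(run, lay),
                                                  index_col=0)
        run.ti_report = pd.read_csv(run.out / "ti_search.csv")
        logger.info("resume: feature tables loaded from %s", run.out)
    else:
        _compute_features(run, smc_by_layer, train_ids)

    # family mapping is reconstructible from column names
    for lay in LAYERS:
        fam = {}
        for col in run.feature_tables[lay].columns:
            if col in spectral.VI_NAMES:
                fam[col] = "VIs"
            elif col in thermal.TVI_NAMES:
                fam[col] = "TVIs"
            elif col.startswith("TI_"):
                fam[col] = "TIs"
            else:
                fam[col] = "TF"
        run.families[lay] = fam

    with run.stage("screening"):
        for lay in LAYERS:
            run.records[lay] = screening.screen_features(
                run.feature_tables[lay], {lay: smc_by_layer[lay]},
                run.families[lay], alpha=cfg.alpha)
        if run.out:
            reports = [screening.screening_report(run.records[lay])
                       for lay in LAYERS]
            pd.concat(reports, ignore_index=True).to_csv(
                run.out / "screening.csv", index=False)

    with run.stage("evaluation"):
        frames = []
        for lay in LAYERS:
            frames.append(models.evaluate_combinations(
                run.feature_tables[lay], run.records[lay],
                {lay: smc_by_layer[lay]}, split, cfg.learners,
                combinations=cfg.combinations, models=cfg.model_kinds))
        run.evaluation = pd.concat(frames, ignore_index=True)
        if run.out:
            run.evaluation.to_csv(run.out / "evaluation.csv", index=False,
                                  float_format="%.6f")
    run.report["n_evaluation_rows"] = int(len(run.evaluation))
    run.report["n_plots"] = n
    # in-memory result for library callers; dropped from the JSON report
    run.report["evaluation"] = run.evaluation


def _compute_features(run: _Run, smc_by_layer, train_ids) -> None:
    cfg = run.config

    with run.stage("masks"):
        for scene in run.scenes:
            mask, _ = spectral.canopy_mask(scene, cfg.vi_threshold)
            run.masks.append(mask)
            run.soil_masks.append(~mask)

    with run.stage("vegetation_indices"):
        refls = [spectral.plot_reflectance(s, m)
                 for s, m in zip(run.scenes, run.masks)]
        vi800 = pd.DataFrame([spectral.compute_all_vis(r, 800) for r in refls])
        vi900 = pd.DataFrame([spectral.compute_all_vis(r, 900) for r in refls])
        y_train = smc_by_layer[LAYERS[0]][train_ids]
        choice = spectral.select_nir_band(
            {nm: vi800[nm].to_numpy()[train_ids] for nm in spectral.VI_NAMES},
            {nm: vi900[nm].to_numpy()[train_ids] for nm in spectral.VI_NAMES},
            y_train)
        vis = pd.DataFrame({
            nm: (vi800 if choice[nm] == 800 else vi900)[nm]
            for nm in choice})
        run.report["nir_band_choice"] = choice

    with run.stage("textures"):
        tf_rows = []
        for scene, mask in zip(run.scenes, run.masks):
            tab = texture.plot_texture(scene, mask, cfg.glcm_levels)
            tf_rows.append(dict(zip(tab["identity"], tab["value"])))
        tf = pd.DataFrame(tf_rows)[texture.identity_names()]

    with run.stage("texture_indices"):
        ti_frames = []
        ti_cols: dict[str, pd.DataFrame] = {}
        for lay in LAYERS:
            best = texture.search_texture_indices(tf, smc_by_layer[lay])
            best.insert(0, "layer", lay)
            ti_frames.append(best)
            cols = {}
            for _, row in best.iterrows():
                name = f"TI_{row['form']}"
                cols[name] = texture.texture_index(
                    row["form"], tf[row["t1"]].to_numpy(),
                    tf[row["t2"]].to_numpy())
            ti_cols[lay] = pd.DataFrame(cols)
        run.ti_report = pd.concat(ti_frames, ignore_index=True)
        if run.out:
            run.ti_report.to_csv(run.out / "ti_search.csv", index=False)

    with run.stage("thermal_calibration"):
        if cfg.mode == "ingest":
            points = thermal.read_calibration_points(
                Path(cfg.input_dir) / "calibration_points.csv")
        else:
            points = [thermal.CalibrationPoint(**rec)
                      for rec in synthetic._calibration_points(run.scenes)
                      .to_dict("records")]
        calibrated = []
        for scene in run.scenes:
            cal, fit = thermal.calibrate_thermal(scene.thermal, points)
            calibrated.append(cal)
        run.report["thermal_calibration"] = {"a": fit.a, "b": fit.b, "r2": fit.r2}

    with run.stage("thermal_indices"):
        extremes = thermal.field_canopy_extremes(calibrated, run.masks)
        tvi_rows = []
        for scene, mask, soil, cal in zip(run.scenes, run.masks,
                                          run.soil_masks, calibrated):
            summ = thermal.thermal_summary(scene, mask, soil, extremes,
                                           thermal=cal)
            tvi_rows.append(thermal.thermal_indices(summ))
        tvis = pd.DataFrame(tvi_rows)

    for lay in LAYERS:
        table = pd.concat([vis, tf, ti_cols[lay], tvis], axis=1)
        run.feature_tables[lay] = table
        if run.out:
            table.to_csv(_features_path(run, lay))
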