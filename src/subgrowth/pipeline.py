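"""End-to-end pipeline: simulate -> fit volumes -> growth tables -> surface.

Each stage reads its inputs from, and writes its outputs under, one output
directory, so a run is resumable: a stage whose outputs already exist is
skipped (delete an output to recompute it).  Per-stage seeds are derived
from one master seed by fixed offsets, making every stage independently
reproducible.  All tables carry the config hash and master seed in header
comments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sgio
from .association import (
    AssociationSpec,
    association_table,
    compare_models,
    vertex_association,
)
from .cohort import (
    STRUCTURES,
    CohortConfig,
    generate_cohort,
    generate_mullen,
)
from .gamm import derivative_curve, fit_gamm, normalized_curve, predict_curve
from .growth import (
    DEFAULT_INTERVALS,
    growth_table,
    sex_effect_test,
    stratified_bootstrap,
    asymmetry_index,
)
from .meshes import generate_meshes
from .surface import (
    MONTH_GRID,
    bootstrap_rate_maps,
    detect_growth_regions,
    expansion_rate_map,
    fit_vertex_trajectories,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

# seed offsets per randomness source
_SEED_COHORT = 0
_SEED_MULLEN = 101
_SEED_MESH = 202
_SEED_BOOT_VOL = 303
_SEED_BOOT_SURF = 404


@dataclass
class PipelineConfig:
    """Options of a full pipeline run (YAML-loadable)."""

    output_dir: str = "results/run"
    # simulation
    n_subjects: int = 231
    noise_sd: float = 60.0
    random_intercept_sd: float = 60.0
    mesh_vertices: int = 162
    mesh_structure: str = "thalamus"
    mesh_hemisphere: str = "L"
    # model options
    k: int = 10
    k_sex: int = 5
    reml: bool = False
    span: tuple = (0, 810)
    structures: tuple = STRUCTURES
    hemispheres: tuple = ("L", "R")
    # bootstrap options
    bootstrap_replicates: int = 1000
    refit_lambda: bool = False
    # detection options
    detect_q: float = 0.20
    alpha: float = 0.05
    detect_months: tuple = (3, 6, 12, 18, 24)
    # association options
    fdr_within: str = "score"
    vertex_assoc_score: str = "RL"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.detect_q < 0.5):
            raise ValueError("detect_q must be in (0, 0.5)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.bootstrap_replicates < 2:
            raise ValueError("bootstrap_replicates must be >= 2")
        if self.mesh_vertices < 12:
            raise ValueError("mesh_vertices must be >= 12")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)  # a location, not an analysis parameter
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:10]

    def header(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _done(*paths) -> bool:
    return all(Path(p).exists() for p in paths)


# --------------------------------------------------------------------------- #
# stages
# --------------------------------------------------------------------------- #

def stage_simulate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    cohort_p = out / "cohort.tsv"
    truth_p = out / "truth.json"
    mesh_d = out / "meshes"
    if _done(cohort_p, truth_p, mesh_d / "meta.tsv"):
        log.info("simulate: outputs exist, skipping")
        return
    ccfg = CohortConfig(
        n_subjects=cfg.n_subjects,
        noise_sd=cfg.noise_sd,
        random_intercept_sd=cfg.random_intercept_sd,
        seed=cfg.seed + _SEED_COHORT,
    )
    records, truth = generate_cohort(ccfg)
    records = generate_mullen(records, truth, seed=cfg.seed + _SEED_MULLEN)
    series = generate_meshes(
        records,
        truth,
        n_vertices=cfg.mesh_vertices,
        seed=cfg.seed + _SEED_MESH,
        structure=cfg.mesh_structure,
        hemisphere=cfg.mesh_hemisphere,
    )
    sgio.write_cohort(records, cohort_p, cfg.header())
    sgio.write_truth(truth, truth_p)
    sgio.write_mesh_series(series, mesh_d)
    log.info("simulate: %d scans, %d mesh vertices", len(records),
             series.n_vertices)


def _fit_all_models(cfg: PipelineConfig, records):
    models = {}
    for s in cfg.structures:
        for h in cfg.hemispheres:
            name = f"{s}_{h}"
            m = fit_gamm(
                records, (s, h), with_sex=True, k=cfg.k, k_sex=cfg.k_sex,
                reml=cfg.reml, span=tuple(cfg.span),
            )
            log.info("fit %s: converged=%s edf=%.1f", name,
                     m.fit.converged, m.fit.edf)
            models[name] = m
    return models


def stage_fit_volumes(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    curves_p = out / "curves.tsv"
    models_d = out / "models"
    if _done(curves_p, models_d):
        log.info("fit-volumes: outputs exist, skipping")
        return
    records = sgio.read_cohort(out / "cohort.tsv")
    models = _fit_all_models(cfg, records)
    grid = MONTH_GRID * 30.0
    rows = []
    for name, m in models.items():
        sgio.save_model(m, models_d / f"{name}.json")
        for stratum in ("male", "female", "pooled"):
            for kind, fn in (
                ("fitted", predict_curve),
                ("derivative", derivative_curve),
                ("normalized", normalized_curve),
            ):
                c = fn(m, grid, stratum)
                f = c.to_frame()
                f.insert(0, "kind", kind)
                rows.append(f)
    curves = pd.concat(rows, ignore_index=True)
    sgio.write_table(curves, curves_p, cfg.header())
    # asymmetry-index trajectories per structure
    ai_rows = []
    for s in cfg.structures:
        l, r = models.get(f"{s}_L"), models.get(f"{s}_R")
        if l is None or r is None:
            continue
        ai = asymmetry_index(
            predict_curve(l, grid, "pooled"), predict_curve(r, grid, "pooled")
        )
        f = ai.to_frame()
        f.insert(0, "structure", s)
        ai_rows.append(f)
    if ai_rows:
        sgio.write_table(pd.concat(ai_rows, ignore_index=True),
                         out / "asymmetry.tsv", cfg.header())


def stage_growth_table(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    table_p = out / "growth_table.tsv"
    sex_p = out / "sex_effect.tsv"
    if _done(table_p, sex_p):
        log.info("growth-table: outputs exist, skipping")
        return
    records = sgio.read_cohort(out / "cohort.tsv")
    models = _fit_all_models(cfg, records)
    grid = MONTH_GRID * 30.0
    boots = {
        name: stratified_bootstrap(
            m, grid, B=cfg.bootstrap_replicates,
            seed=cfg.seed + _SEED_BOOT_VOL + i,
            refit_lambda=cfg.refit_lambda,
        )
        for i, (name, m) in enumerate(models.items())
    }
    tab = growth_table(models, boots, DEFAULT_INTERVALS)
    sgio.write_table(tab, table_p, cfg.header())
    sex_rows = []
    for name, m in models.items():
        se = sex_effect_test(m, grid, boots[name])
        se.insert(0, "response", name)
        sex_rows.append(se)
    sgio.write_table(pd.concat(sex_rows, ignore_index=True), sex_p,
                     cfg.header())


def stage_fit_surface(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    rates_p = out / "vertex_rates.tsv"
    if _done(rates_p):
        log.info("fit-surface: outputs exist, skipping")
        return
    series = sgio.read_mesh_series(out / "meshes")
    vt = fit_vertex_trajectories(series, k=8, span=tuple(cfg.span))
    rows = []
    for month in cfg.detect_months:
        rates = expansion_rate_map(vt, float(month))
        rows.append(pd.DataFrame({
            "month": month, "vertex": np.arange(len(rates)), "rate": rates,
        }))
    sgio.write_table(pd.concat(rows, ignore_index=True), rates_p,
                     cfg.header())


def stage_detect_regions(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    regions_p = out / "regions.tsv"
    regions_json = out / "regions.json"
    if _done(regions_p, regions_json):
        log.info("detect-regions: outputs exist, skipping")
        return
    series = sgio.read_mesh_series(out / "meshes")
    vt = fit_vertex_trajectories(series, k=8, span=tuple(cfg.span))
    months = [float(m) for m in cfg.detect_months]
    reps = bootstrap_rate_maps(
        vt, months, B=max(100, min(cfg.bootstrap_replicates, 400)),
        seed=cfg.seed + _SEED_BOOT_SURF,
    )
    frames = []
    index = {}
    for j, month in enumerate(months):
        rates = expansion_rate_map(vt, month)
        det = detect_growth_regions(rates, reps[:, j, :], q=cfg.detect_q,
                                    alpha=cfg.alpha)
        det.insert(0, "month", month)
        frames.append(det)
        index[str(int(month))] = {
            "high": det.loc[det.label == "high", "vertex"].tolist(),
            "low": det.loc[det.label == "low", "vertex"].tolist(),
        }
    sgio.write_table(pd.concat(frames, ignore_index=True), regions_p,
                     cfg.header())
    regions_json.write_text(json.dumps(index, indent=1))


def stage_associate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    assoc_p = out / "association.tsv"
    ftest_p = out / "ftests.tsv"
    vassoc_p = out / "vertex_association.tsv"
    if _done(assoc_p, ftest_p, vassoc_p):
        log.info("associate: outputs exist, skipping")
        return
    records = sgio.read_cohort(out / "cohort.tsv")
    tab = association_table(records, structures=cfg.structures,
                            fdr_within=cfg.fdr_within)
    sgio.write_table(tab, assoc_p, cfg.header())
    # confirmatory nested-model F-tests for the significant cells
    rows = []
    for score, grp in tab.groupby("score"):
        hits = grp.loc[grp.significant, "structure"].tolist()
        if not hits:
            continue
        F, p = compare_models(records, score, hits)
        rows.append({"score": score, "predictors": "+".join(hits),
                     "F": F, "p": p})
    sgio.write_table(pd.DataFrame(rows, columns=["score", "predictors", "F", "p"]),
                     ftest_p, cfg.header())
    # vertex-wise association for the mesh structure
    series = sgio.read_mesh_series(out / "meshes")
    areas = series.vertex_areas()
    scores = records[f"mullen_{cfg.vertex_assoc_score}"]
    sub = records.assign(**{f"mullen_{cfg.vertex_assoc_score}": scores})
    vtab = vertex_association(
        sub, areas,
        AssociationSpec(score=cfg.vertex_assoc_score, predictor="vertex_area"),
        alpha=cfg.alpha,
    )
    sgio.write_table(vtab, vassoc_p, cfg.header())


STAGES = {
    "simulate": stage_simulate,
    "fit-volumes": stage_fit_volumes,
    "growth-table": stage_growth_table,
    "fit-surface": stage_fit_surface,
    "detect-regions": stage_detect_regions,
    "associate": stage_associate,
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages in order; returns the output directory."""
    cfg.validate()
    out = _out(cfg)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("subgrowth")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    try:
        log.info("pipeline start: seed=%d hash=%s", cfg.seed,
                 cfg.config_hash())
        for name, stage in STAGES.items():
            log.info("stage %s", name)
            stage(cfg)
        log.info("pipeline done")
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        root.removeHandler(fh)
        fh.close()
    return out
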