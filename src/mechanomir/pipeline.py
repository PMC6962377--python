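"""End-to-end orchestration: simulate -> wound -> morpho -> filter -> interact.

A run is driven by a :class:`RunConfig` (built programmatically, from YAML,
or by the CLI).  Stages execute in dependency order; every output file
carries a provenance header and the run closes with a JSON manifest listing
inputs, outputs, seed and configuration hash.  For a fixed config and seed
the numeric outputs are bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .de_filter import FilterCriteria, de_fold_change_map, filter_de, split_by_type
from .interaction import (
    aggregate,
    build_interaction_matrix,
    compare_groups,
    default_rules,
    export_heatmaps,
    load_rules,
)
from .morpho import ar_histogram, fit_ar_pdf, percent_elongated, select_model
from .presets import get_preset
from .synthetic import (
    generate_ar_sample,
    generate_expression_set,
    generate_pathway_db,
    generate_wound_pair,
    load_mirna_panel,
    mirna_relevance_annotation,
)
from .wound import (
    BONFERRONI_ALPHA,
    WoundAreas,
    differential_closure,
    fold_increase,
    segment_cell_free_area,
    wound_closure,
)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("wound", "morpho", "filter", "interact")


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


class DataError(ValueError):
    """A stage received unusable data."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all stages synthetic by default)."""

    preset: str = "LN229-23Pa"
    seed: int = 42
    out_dir: str = "mechanomir_run"
    stages: tuple[str, ...] = ALL_STAGES
    # wound stage
    n_replicates: int = 6
    closure_noise_sd: float = 0.02  # day-to-day replicate variability
    # morpho stage
    n_cells: int = 2000
    bin_width: float = 0.1
    ar_threshold: float = 2.0
    # filter stage
    n_features: int = 2000
    n_de: int = 200
    p_max: float = 0.05
    fdr_max: float = 0.05
    abs_fc_min: float = 2.0
    # interact stage
    n_pathways_per_group: int = 3
    targets_per_pathway: int = 20
    rules_file: str | None = None
    alpha: float = 0.05

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ConfigError(f"stages: unknown stage {stage!r}")
        if not self.stages:
            raise ConfigError("stages: at least one stage required")
        if self.seed < 0:
            raise ConfigError("seed: must be non-negative")
        for fld in ("n_replicates", "n_cells", "n_features", "n_de",
                    "n_pathways_per_group", "targets_per_pathway"):
            if getattr(self, fld) < 1:
                raise ConfigError(f"{fld}: must be >= 1")
        if self.n_de > self.n_features:
            raise ConfigError("n_de: must not exceed n_features")
        if "interact" in self.stages and "filter" not in self.stages:
            raise ConfigError(
                "stages: interact requires the filter stage (DE list upstream)"
            )
        if self.rules_file is not None and not Path(self.rules_file).exists():
            raise ConfigError(f"rules_file: {self.rules_file} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)


def _seed_for(seed: int, stage: str) -> int:
    """Independent, reproducible per-stage substream, kept below 2**31."""
    tag = zlib.crc32(stage.encode()) % (2**16)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def _run_wound(cfg: RunConfig, preset, out: Path, h: str) -> dict:
    rng = np.random.default_rng(_seed_for(cfg.seed, "wound"))
    rows, pairs = [], []
    for rep in range(cfg.n_replicates):
        rid = f"rep{rep + 1}"
        wcs = {}
        for cond, closure in (
            ("control", preset.wound_closure_ctrl),
            (preset.name, preset.wound_closure_exp),
        ):
            c = float(np.clip(closure + rng.normal(0, cfg.closure_noise_sd), 0, 1))
            pair = generate_wound_pair(
                closure=c, texture_seed=int(rng.integers(2**31))
            )
            a_i = segment_cell_free_area(pair.image_initial, pair.pixel_size)
            a_f = segment_cell_free_area(pair.image_final, pair.pixel_size)
            res = wound_closure(
                WoundAreas(a_i, a_f, replicate_id=rid, condition=cond)
            )
            wcs[cond] = res.wc
            rows.append(
                {"condition": cond, "replicate_id": rid,
                 "area_initial": a_i, "area_final": a_f, "wc": res.wc}
            )
        pairs.append((wcs[preset.name], wcs["control"]))
    dc = differential_closure(pairs, alpha=BONFERRONI_ALPHA)
    closures = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [{
            "condition": preset.name,
            "delta_wc_pp": dc.delta_wc_mean,
            "sem_pp": dc.delta_wc_sem,
            "n_pairs": dc.n_pairs,
            "p_value": dc.p_value,
            "significant": dc.significant,
            "fold_increase": fold_increase(preset.wound_closure_ctrl, dc.delta_wc_mean),
        }]
    )
    p1 = io.write_tsv(closures, out / "wound_closures.tsv", cfg.seed, h)
    p2 = io.write_tsv(summary, out / "wound_differential.tsv", cfg.seed, h)
    return {"outputs": [str(p1), str(p2)], "delta_wc_pp": dc.delta_wc_mean}


def _run_morpho(cfg: RunConfig, preset, out: Path, h: str) -> dict:
    ars = generate_ar_sample(preset, cfg.n_cells, seed=_seed_for(cfg.seed, "morpho"))
    hist = ar_histogram(ars, bin_width=cfg.bin_width)
    sel = select_model(fit_ar_pdf(hist, 1), fit_ar_pdf(hist, 2))
    comps = list(sel.components) + [None] * (2 - sel.n_terms)
    row = {"condition": preset.name, "n_cells": cfg.n_cells,
           "n_terms": sel.n_terms, "sse": sel.sse, "r2": sel.r2,
           "percent_elongated": percent_elongated(ars, cfg.ar_threshold)}
    for i, c in enumerate(comps, start=1):
        row[f"a{i}"] = c.a if c else float("nan")
        row[f"mu{i}"] = c.mu if c else float("nan")
        row[f"sigma{i}"] = c.sigma if c else float("nan")
        row[f"mode{i}"] = c.mode if c else float("nan")
    p1 = io.write_tsv(pd.DataFrame([row]), out / "morpho_fits.tsv", cfg.seed, h)
    return {"outputs": [str(p1)], "n_terms": sel.n_terms, "r2": sel.r2}


def _run_filter(cfg: RunConfig, out: Path, h: str):
    expr = generate_expression_set(
        cfg.n_features, cfg.n_de, seed=_seed_for(cfg.seed, "filter")
    )
    criteria = FilterCriteria(cfg.p_max, cfg.fdr_max, cfg.abs_fc_min)
    de = filter_de(expr.records, criteria)
    coding, mirna = split_by_type(de)
    p0 = io.write_tsv(expr.records, out / "expression_full.tsv", cfg.seed, h)
    p1 = io.write_tsv(de, out / "expression_de.tsv", cfg.seed, h)
    p2 = io.write_tsv(coding, out / "de_coding.tsv", cfg.seed, h)
    p3 = io.write_tsv(mirna, out / "de_precursor_mirna.tsv", cfg.seed, h)
    meta = {
        "outputs": [str(p) for p in (p0, p1, p2, p3)],
        "n_de": int(len(de)), "n_coding": int(len(coding)),
        "n_mirna": int(len(mirna)),
    }
    return meta, de


def _run_interact(cfg: RunConfig, de: pd.DataFrame, out: Path, h: str) -> dict:
    if de.empty:
        raise DataError("interact: the DE table from the filter stage is empty")
    panel = load_mirna_panel()
    mirnas = list(panel["feature_id"])
    db = generate_pathway_db(
        n_pathways_per_group=cfg.n_pathways_per_group,
        mirnas=mirnas,
        targets_per_pathway=cfg.targets_per_pathway,
        seed=_seed_for(cfg.seed, "interact"),
        gene_pool=list(de["feature_id"]) + [f"NULL{i:04d}" for i in range(300)],
    )
    rules = load_rules(cfg.rules_file) if cfg.rules_file else default_rules()
    matrix = build_interaction_matrix(
        db.exports, de_fold_change_map(de), rules=rules,
        relevance=mirna_relevance_annotation(),
    )
    heat = export_heatmaps(matrix, out, prefix="heatmap")
    outputs = [str(p) for p in heat.values()]
    for by in ("pathway_group", "mirna", "relevance_group"):
        for metric in ("percent_overlap", "cumulative_abs_fc"):
            agg = aggregate(matrix, by=by, metric=metric)
            p = io.write_tsv(agg, out / f"aggregate_{by}_{metric}.tsv", cfg.seed, h)
            outputs.append(str(p))
    comp = compare_groups(matrix, by="pathway_group", metric="cumulative_abs_fc",
                          alpha=cfg.alpha)
    p = io.write_tsv(comp.tukey, out / "tukey_pathway_group_cumulative_abs_fc.tsv",
                     cfg.seed, h)
    outputs.append(str(p))
    p = io.write_pathway_exports(db.exports, out / "pathway_exports.tsv", cfg.seed, h)
    outputs.append(str(p))
    return {"outputs": outputs, "n_nodes": int(len(matrix.nodes)),
            "anova_p": comp.anova_p}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    The manifest (also written to ``<out_dir>/manifest.json``) lists, per
    stage, the files written and headline quantities computed.
    """
    config.validate()
    preset = get_preset(config.preset)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    # hash only the science-relevant fields: where outputs land must not
    # change what they contain
    h = io.config_hash({k: v for k, v in cfg_dict.items() if k != "out_dir"})

    manifest: dict = {
        "tool": "mechanomir", "version": __version__,
        "seed": config.seed, "config_hash": h, "config": cfg_dict,
        "stages": {},
    }
    de = None
    for stage in ALL_STAGES:  # dependency order
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        if stage == "wound":
            manifest["stages"]["wound"] = _run_wound(config, preset, out, h)
        elif stage == "morpho":
            manifest["stages"]["morpho"] = _run_morpho(config, preset, out, h)
        elif stage == "filter":
            meta, de = _run_filter(config, out, h)
            manifest["stages"]["filter"] = meta
        elif stage == "interact":
            manifest["stages"]["interact"] = _run_interact(config, de, out, h)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
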