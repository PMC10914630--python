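"""End-to-end orchestration of the analysis stages from one configuration.

A :class:`PipelineConfig` names the input matrices (or a simulation block),
the analysis thresholds, and the output directory.  :func:`run_pipeline`
executes differential expression, synapse-enrichment classification,
enriched-synaptosome DE, per-group rhythmicity, differential rhythmicity,
co-expression/MDC/hub analysis and optional ORA, writing each stage's
tables plus a manifest.  One global seed spawns a named substream per
stage, so identical config + seed reproduce byte-identical outputs and
adding a stage never perturbs another stage's draws.
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

from . import __version__
from .data import Dataset, align_dataset, load_expression, load_metadata, write_expression, write_metadata
from .diffexpr import DifferentialExpressionModel, classify_de, rrho_map
from .network import ModuleConnectivityModel
from .ora import load_gmt, run_ora
from .rhythm import phase_ordered_matrix, rhythm_fits, rhythmic_set
from .rhythmdiff import (delta_r2_table, gain_loss_by_set_difference,
                         rhythm_param_diff_table, rhythmic_overlap_test)
from .simulate import SimulationConfig, simulate_paired_preparations
from .synenrich import compute_enrichment, enriched_union, filter_to_enriched

logger = logging.getLogger(__name__)

_STAGE_KEYS = {"de": 1, "rhythm": 2, "drhythm": 3, "network": 4, "simulate": 5}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage integer seed from the global seed."""
    key = _STAGE_KEYS.get(stage)
    if key is None:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    Either ``inputs`` (paths per preparation) or ``simulate`` (a
    :class:`~circasyn.simulate.SimulationConfig` mapping) must be given.
    """

    inputs: dict = field(default_factory=dict)   # prep -> {"expression":..., "metadata":...}
    simulate: dict | None = None
    p_max: float = 0.05
    lfc_min: float = 0.26
    enrich_alpha: float = 0.05
    enrich_fold_min: float = 1.25
    rhythm_alpha: float = 0.05
    n_perm: int = 1000
    top_n: int = 200
    beta: float | None = None
    min_size: int = 30
    merge_cut: float = 0.25
    hub_quantile: float = 0.90
    n_hops: int = 1
    network_preparation: str = "synaptosome"
    gmt: str | None = None
    max_missing_frac: float = 0.0
    seed: int = 0
    outdir: str = "circasyn_out"

    def __post_init__(self):
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        for name in ("p_max", "enrich_alpha", "rhythm_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.lfc_min < 0 or self.enrich_fold_min <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.hub_quantile < 1.0):
            raise ValueError("hub_quantile outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _load_prep(cfg: PipelineConfig, prep: str) -> Dataset:
    spec = cfg.inputs[prep]
    expr_path = Path(spec["expression"])
    meta_path = Path(spec["metadata"])
    for p in (expr_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    expr = load_expression(expr_path, already_log2=spec.get("already_log2", True))
    subjects = load_metadata(meta_path)
    ds = align_dataset(expr, subjects)
    return ds.drop_incomplete(cfg.max_missing_frac)


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all applicable stages; returns (and writes) the run manifest."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    datasets: dict = {}
    stage = "load"
    try:
        if cfg.simulate is not None:
            sim_cfg = SimulationConfig.from_dict({**cfg.simulate, "seed": cfg.seed})
            hom, syn, truth = simulate_paired_preparations(sim_cfg)
            datasets["homogenate"], datasets["synaptosome"] = hom, syn
            write_expression(hom.expr, outdir / "homogenate_expression.tsv")
            write_metadata(hom.subjects, outdir / "homogenate_metadata.tsv")
            write_expression(syn.expr, outdir / "synaptosome_expression.tsv")
            write_metadata(syn.subjects, outdir / "synaptosome_metadata.tsv")
            _write_tsv(truth.proteins, outdir / "ground_truth_proteins.tsv")
            with open(outdir / "simulation_config.yaml", "w") as fh:
                yaml.safe_dump(sim_cfg.to_dict(), fh, sort_keys=True)
            manifest["stages"]["simulate"] = {"n_proteins": sim_cfg.n_proteins,
                                              "n_samples": 2 * sim_cfg.n_per_group}
        else:
            for prep in cfg.inputs:
                datasets[prep] = _load_prep(cfg, prep)
                manifest["stages"][f"load_{prep}"] = {
                    "n_proteins": datasets[prep].expr.n_proteins,
                    "n_samples": datasets[prep].expr.n_samples,
                }
    except Exception as exc:                       # noqa: BLE001 - re-raised with stage
        raise PipelineError(stage, exc) from exc

    de_tables = {}
    de_seedless = stage_seed(cfg.seed, "de")       # DE is deterministic; kept for manifest parity
    for prep, ds in datasets.items():
        stage = f"de_{prep}"
        try:
            res = DifferentialExpressionModel(ds).fit()
            table = classify_de(res.table, p_max=cfg.p_max, lfc_min=cfg.lfc_min)
            de_tables[prep] = table
            _write_tsv(table, outdir / f"de_{prep}.tsv")
            manifest["stages"][stage] = {
                "n_proteins": len(table),
                "n_up": int((table["de_flag"] == "up").sum()),
                "n_down": int((table["de_flag"] == "down").sum()),
            }
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if "homogenate" in datasets and "synaptosome" in datasets:
        stage = "enrichment"
        try:
            tables = {g: compute_enrichment(datasets["homogenate"], datasets["synaptosome"], g)
                      for g in ("unaffected", "OUD")}
            for g, t in tables.items():
                t = t.copy()
                from .synenrich import classify_enriched
                t = classify_enriched(t, alpha=cfg.enrich_alpha, fold_min=cfg.enrich_fold_min)
                tables[g] = t
                _write_tsv(t, outdir / f"enrichment_{g}.tsv")
            union = enriched_union(*tables.values())
            syn_enriched = filter_to_enriched(datasets["synaptosome"], union)
            write_expression(syn_enriched.expr, outdir / "synaptosome_enriched_expression.tsv")
            manifest["stages"][stage] = {
                "n_enriched_unaffected": int(tables["unaffected"]["enriched"].sum()),
                "n_enriched_oud": int(tables["OUD"]["enriched"].sum()),
                "n_union": len(union),
            }
            stage = "de_synaptosome_enriched"
            res = DifferentialExpressionModel(syn_enriched).fit()
            table = classify_de(res.table, p_max=cfg.p_max, lfc_min=cfg.lfc_min)
            de_tables["synaptosome_enriched"] = table
            _write_tsv(table, outdir / "de_synaptosome_enriched.tsv")
            manifest["stages"][stage] = {
                "n_proteins": len(table),
                "n_up": int((table["de_flag"] == "up").sum()),
                "n_down": int((table["de_flag"] == "down").sum()),
            }
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if len(de_tables) >= 2:
        stage = "rrho"
        try:
            preps = list(de_tables)
            a, b = preps[0], preps[1]
            step = max(1, min(50, len(de_tables[a]) // 10))
            rr = rrho_map(de_tables[a], de_tables[b], step=step)
            rr.grid.to_csv(outdir / f"rrho_{a}_vs_{b}.tsv", sep="\t")
            manifest["stages"][stage] = {"step": rr.step, "n_proteins": rr.n_proteins}
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    rhythm_tables = {}
    r_seed = stage_seed(cfg.seed, "rhythm")
    for prep, ds in datasets.items():
        for group in ("unaffected", "OUD"):
            stage = f"rhythm_{prep}_{group}"
            try:
                fits = rhythm_fits(ds, group, n_perm=cfg.n_perm, seed=r_seed)
                rhythm_tables[(prep, group)] = fits
                _write_tsv(fits, outdir / f"rhythm_{prep}_{group}.tsv")
                mat, rows, cols = phase_ordered_matrix(ds.select_group(group), fits,
                                                       top_n=cfg.top_n)
                mat.to_csv(outdir / f"rhythm_heatmap_{prep}_{group}.tsv", sep="\t")
                manifest["stages"][stage] = {
                    "n_proteins": len(fits),
                    "n_rhythmic": len(rhythmic_set(fits, cfg.rhythm_alpha)),
                }
            except Exception as exc:
                raise PipelineError(stage, exc) from exc

    d_seed = stage_seed(cfg.seed, "drhythm")
    for prep, ds in datasets.items():
        stage = f"drhythm_{prep}"
        try:
            fits_u = rhythm_tables[(prep, "unaffected")]
            fits_o = rhythm_tables[(prep, "OUD")]
            dr = delta_r2_table(ds, fits_u, fits_o, alpha=cfg.rhythm_alpha,
                                n_perm=cfg.n_perm, seed=d_seed)
            _write_tsv(dr, outdir / f"delta_r2_{prep}.tsv")
            set_u = rhythmic_set(fits_u, cfg.rhythm_alpha)
            set_o = rhythmic_set(fits_o, cfg.rhythm_alpha)
            overlap = rhythmic_overlap_test(set_u, set_o, ds.protein_ids)
            params = rhythm_param_diff_table(fits_u, fits_o, alpha=cfg.rhythm_alpha)
            _write_tsv(params, outdir / f"rhythm_params_{prep}.tsv")
            setdiff = gain_loss_by_set_difference(set_u, set_o)
            with open(outdir / f"rhythm_overlap_{prep}.json", "w") as fh:
                json.dump({
                    "table_counts": overlap.table_counts.tolist(),
                    "odds_ratio": overlap.odds_ratio,
                    "p_fisher": overlap.p_fisher,
                    "set_difference": {k: len(v) for k, v in setdiff.items()},
                }, fh, indent=2)
            manifest["stages"][stage] = {
                "n_tested": len(dr),
                "n_loss": int((dr["change_class"] == "loss").sum()),
                "n_gain": int((dr["change_class"] == "gain").sum()),
            }
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if cfg.network_preparation in datasets:
        stage = "network"
        try:
            ds = datasets[cfg.network_preparation]
            model = ModuleConnectivityModel(ds, beta=cfg.beta, min_size=cfg.min_size,
                                            merge_cut=cfg.merge_cut)
            net = model.fit(n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "network"),
                            hub_quantile=cfg.hub_quantile, n_hops=cfg.n_hops)
            net.assignment.rename_axis("protein_id").reset_index().to_csv(
                outdir / "module_assignment.tsv", sep="\t", index=False)
            _write_tsv(net.summary_table(), outdir / "mdc_summary.tsv")
            hub_rows = []
            for m in net.modules:
                for h in sorted(m.hubs_unaffected | m.hubs_oud):
                    hub_rows.append(dict(
                        module=m.label, protein_id=h,
                        hub_unaffected=h in m.hubs_unaffected,
                        hub_oud=h in m.hubs_oud,
                    ))
            _write_tsv(pd.DataFrame(hub_rows), outdir / "hubs.tsv")
            manifest["stages"][stage] = {
                "beta": net.beta,
                "n_modules": len(net.modules),
                "n_loss": int((net.summary_table()["direction"] == "loss").sum())
                if net.modules else 0,
            }
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if cfg.gmt:
        stage = "ora"
        try:
            collection = load_gmt(cfg.gmt)
            for prep, table in de_tables.items():
                query = set(table.loc[table["de_flag"] != "none", "protein_id"])
                if not query:
                    continue
                res = run_ora(query, set(table["protein_id"]), collection)
                _write_tsv(res, outdir / f"ora_de_{prep}.tsv")
            manifest["stages"][stage] = {"n_sets": len(collection.sets)}
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
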