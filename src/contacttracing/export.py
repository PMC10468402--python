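"""Publication-style exports and the end-to-end pipeline.

``export_circos_table`` emits one row per significant interaction link (the
data behind a Circos-style summary figure); ``run_pipeline`` chains database
construction, the three test families, summaries, response-matrix embedding,
subcluster mapping and exports from a single YAML-able config, writing TSV/CSV
outputs plus a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (ContactTracingResults, ResponseScoreMatrix, Thresholds,
                   build_response_matrix, contrast_name, embed_responses,
                   rank_interactions, run_tests, summarize_interactions,
                   summaries_to_frame)
from .lrdb import (InteractionDatabase, apply_complex_rule, filter_interactions,
                   load_pair_table, merge_databases)
from .expression import ExpressionDataset, read_expression
from .mapping import cluster_markers

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def export_circos_table(summaries, response: ResponseScoreMatrix | None = None,
                        cnames=None, abundance: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per significant interaction link.

    Ribbon weight is the larger per-contrast count of interaction effects;
    ribbon colour value is the ligand log2FC of the contrast with the larger
    absolute ligand log2FC.  DC1 coordinates are looked up per (gene, cell
    type) in the response embedding when available.  Optional per-(gene, cell
    type) abundance scores are joined for export only.
    """
    dc1 = response.dc1 if response is not None and response.dc1 is not None else None
    rows = []
    for s in summaries:
        if not s.significant:
            continue
        names = list(cnames or s.n_effects)
        best = max(names, key=lambda c: abs(s.ligand_log2fc[c]))
        row = {
            "ligand": s.ligand, "donor_type": s.donor_type,
            "receptor": s.receptor, "target_type": s.target_type,
            "dc1_ligand": _lookup(dc1, (s.ligand, s.donor_type)),
            "dc1_receptor": _lookup(dc1, (s.receptor, s.target_type)),
            "ribbon_weight": s.max_effects,
            "ribbon_color_value": s.ligand_log2fc[best],
        }
        for c in names:
            row[f"n_effects[{c}]"] = s.n_effects[c]
            row[f"ligand_log2fc[{c}]"] = s.ligand_log2fc[c]
        if abundance is not None:
            row["abundance_ligand"] = _lookup_df(abundance, s.ligand, s.donor_type)
            row["abundance_receptor"] = _lookup_df(abundance, s.receptor, s.target_type)
        rows.append(row)
    cols = ["ligand", "donor_type", "receptor", "target_type", "dc1_ligand",
            "dc1_receptor", "ribbon_weight", "ribbon_color_value"]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)


def _lookup(series, key):
    if series is None:
        return np.nan
    try:
        return float(series.loc[key])
    except KeyError:
        return np.nan


def _lookup_df(df, gene, cell_type):
    hit = df[(df["gene"] == gene) & (df["cell_type"] == cell_type)]
    return float(hit["abundance_log2fc"].iloc[0]) if len(hit) else np.nan


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _validate_config(cfg: dict) -> None:
    conditions = cfg.get("conditions")
    contrasts = cfg.get("contrasts")
    if not contrasts:
        raise PipelineError("config: at least one contrast is required")
    if conditions:
        declared = set(conditions)
        for c in contrasts:
            missing = set(c) - declared
            if missing:
                raise PipelineError(
                    f"config: contrast {c} names undeclared condition(s) {sorted(missing)}")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise PipelineError("config: provide either 'simulate' or 'inputs'")


def _load_inputs(cfg: dict, seed: int):
    if "simulate" in cfg:
        from .simulate import PlantedInteraction, TMEConfig, simulate_tme
        sim = dict(cfg["simulate"])
        planted = [PlantedInteraction(**p) for p in sim.pop("interactions", [])]
        tme = TMEConfig(**sim, interactions=tuple(planted)) if planted else TMEConfig(**sim)
        ds, db, truth = simulate_tme(tme, seed=seed)
        return ds, db
    inp = cfg["inputs"]
    ds = read_expression(inp["matrix"], inp.get("genes"), inp.get("cells"),
                         inp.get("annotations"), scale=inp.get("scale", 1e4))
    db = build_database(inp["db"], ds, min_detect_frac=cfg.get("min_detect_frac", 0.01))
    return ds, db


def build_database(db_cfg: dict, ds: ExpressionDataset | None = None,
                   min_detect_frac: float = 0.01) -> InteractionDatabase:
    """Load, merge, complex-expand and expression-filter the interaction DB."""
    dbs = []
    if "simple" in db_cfg:
        dbs.append(load_pair_table(db_cfg["simple"], dialect="simple",
                                   source=db_cfg.get("simple_source", "simple")))
    if "complex_aware" in db_cfg:
        dbs.append(load_pair_table(db_cfg["complex_aware"], dialect="complex-aware",
                                   source=db_cfg.get("complex_source", "complex"),
                                   complex_path=db_cfg.get("complex_table")))
    if not dbs:
        raise PipelineError("config: db requires 'simple' and/or 'complex_aware' tables")
    db = dbs[0]
    for other in dbs[1:]:
        db = merge_databases(db, other)
    if ds is not None:
        db = filter_interactions(db, ds, min_detect_frac=min_detect_frac)
    return db


def run_pipeline(config, out_dir, seed: int | None = None) -> Path:
    """Execute database -> tests -> summaries -> mapping -> export.

    ``config`` is a dict or a YAML path.  Any stage failure aborts with the
    stage name and cause.  Returns the output directory.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(config.get("seed", 0))
    _validate_config(config)
    thresholds = Thresholds(**config.get("thresholds", {}))
    contrasts = [tuple(c) for c in config["contrasts"]]
    manifest = {"version": __version__, "seed": seed,
                "thresholds": asdict(thresholds),
                "contrasts": [contrast_name(c) for c in contrasts]}
    timings = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    try:
        name = stage("inputs")
        ds, db = _load_inputs(config, seed)
        if config.get("apply_complexes", True) and db.complexes:
            ds = apply_complex_rule(ds, list(db.complexes.values()))
        db.write_tsv(out / "database.tsv")

        name = stage("tests")
        res = run_tests(ds, db, contrasts,
                        donor_types=config.get("donor_types"),
                        target_types=config.get("target_types"),
                        min_cells=config.get("min_cells", 20),
                        min_detect_frac=config.get("min_detect_frac", 0.01),
                        lfc_mode=config.get("lfc_mode", "combined"))
        _write_results(res, out)

        name = stage("summaries")
        summaries = summarize_interactions(res, db, thresholds=thresholds)
        ranked = rank_interactions(summaries)
        cnames = res.contrast_names()
        summaries_to_frame(ranked, cnames).to_csv(out / "interactions_ranked.tsv",
                                                  sep="\t", index=False)

        name = stage("response_matrix")
        response = None
        if res.target:
            response = embed_responses(build_response_matrix(res.target))
            response.scores.to_csv(out / "response_matrix.csv")
            if response.dc1 is not None:
                response.dc1.rename("dc1").to_csv(out / "dc1.tsv", sep="\t")

        name = stage("mapping")
        if config.get("map_subclusters", False):
            frames = []
            for ct in sorted(ds.obs["cell_type"].unique()):
                if ds.cells_of_type(ct).obs["subcluster"].nunique() >= 2:
                    frames.append(cluster_markers(ds, ct))
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(
                    out / "subcluster_markers.tsv", sep="\t", index=False)

        name = stage("export")
        circos = export_circos_table(ranked, response, cnames)
        circos.to_csv(out / "circos_links.tsv", sep="\t", index=False)

        manifest["counts"] = {
            "interactions_in_db": len(db),
            "target_tests": len(res.target),
            "interaction_tests": len(res.interaction),
            "ligand_tests": len(res.ligand),
            "summaries": len(summaries),
            "significant": int(sum(s.significant for s in summaries)),
            "circos_links": int(len(circos)),
        }
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(f"stage {name!r} failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _write_results(res: ContactTracingResults, out: Path) -> None:
    def cat(tables, keys):
        frames = []
        for key, df in sorted(tables.items()):
            df = df.copy()
            for kname, kval in zip(keys, key):
                df.insert(0, kname, kval)
            frames.append(df)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    cat(res.target, ["receptor", "cell_type"]).to_csv(
        out / "target_tests.tsv", sep="\t", index=False)
    cat(res.interaction, ["receptor", "cell_type", "contrast"]).to_csv(
        out / "interaction_tests.tsv", sep="\t", index=False)
    cat({k: v.reset_index() for k, v in res.ligand.items()},
        ["donor_type", "contrast"]).to_csv(out / "ligand_tests.tsv", sep="\t", index=False)
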