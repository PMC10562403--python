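"""End-to-end orchestration: simulate/load -> count -> QC -> demux -> assign
-> normalize -> score -> rank, with a deterministic run report.

The report (report.json) echoes every parameter, records per-stage cell
tallies — which are non-increasing from input droplets through QC, hashtag
singlets, guide-called cells and combination-filtered cells — and lists
every output file with its SHA-256 checksum.  It contains no timestamps, so
re-running the same config and seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, MissingReferenceError, StageError
from .expression import depth_normalize
from .guides import GuideAssignmentParams, call_guides_matrix, filter_combinations, PerturbationLabel
from .qc_demux import (
    CellQCProfile,
    QCParams,
    apply_qc_filters,
    calls_to_frame,
    classify_hashtags,
    clr_normalize,
)
from .scoring import (
    NormalizationParams,
    compute_hto_max,
    protein_score,
    rc_normalize,
    summarize_and_rank,
)
from .simulate import SimulationConfig, SimulatedDataset, simulate_dataset
from .tag_counting import read_count_matrix

log = logging.getLogger("perturbcite")


def _jsonable(obj):
    """Recursively convert dataclass/numpy content to JSON-safe values."""
    if isinstance(obj, dict):
        return {
            "+".join(map(str, k)) if isinstance(k, tuple) else str(k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_from(config: dict, key: str, cls):
    fields = {f.name for f in dataclasses.fields(cls)}
    raw = dict(config.get(key) or {})
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"unknown {key} keys: {sorted(unknown)}")
    return cls(**raw)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def simulation_config_from(config: dict) -> SimulationConfig:
    raw = dict(config.get("simulate") or {})
    if "guide_pool" in raw:
        raw["guide_pool"] = [tuple(x) for x in raw["guide_pool"]]
    if "interaction_terms" in raw:
        raw["interaction_terms"] = {
            tuple(k.split("+")): tuple(v) for k, v in raw["interaction_terms"].items()
        }
    if "effect_matrix" in raw:
        raw["effect_matrix"] = {k: tuple(v) for k, v in raw["effect_matrix"].items()}
    if "reads_per_umi" in raw:
        raw["reads_per_umi"] = {k: tuple(v) for k, v in raw["reads_per_umi"].items()}
    return _params_from({"simulate": raw}, "simulate", SimulationConfig)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the full pipeline and return the report dict.

    ``config`` keys (all optional): seed, simulate {...} or inputs
    {adt_dir, hto_dir, gdo_dir, gex_dir}, qc {...}, guides {...},
    normalization {...}, reference_label.  Outputs are written under
    ``out_dir``; on stage failure partial outputs stay in place next to a
    FAILED marker naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "stages": {},
        "parameters": {},
    }
    stage = "setup"
    try:
        qc_params = _params_from(config, "qc", QCParams)
        guide_params = _params_from(config, "guides", GuideAssignmentParams)
        norm_params = _params_from(config, "normalization", NormalizationParams)
        reference_label = str(config.get("reference_label", "NT"))
        report["parameters"] = {
            "qc": dataclasses.asdict(qc_params),
            "guides": dataclasses.asdict(guide_params),
            "normalization": dataclasses.asdict(norm_params),
            "reference_label": reference_label,
        }

        stage = "input"
        expression = None
        if "inputs" in config:
            paths = config["inputs"]
            for key in ("adt_dir", "hto_dir", "gdo_dir"):
                if key not in paths or not Path(paths[key]).exists():
                    raise ConfigError(f"missing input path for {key}")
            adt = read_count_matrix(paths["adt_dir"]).to_frame()
            hto = read_count_matrix(paths["hto_dir"]).to_frame()
            gdo = read_count_matrix(paths["gdo_dir"]).to_frame()
            guide_gene = dict(config.get("guide_to_gene") or {})
            if not guide_gene and "feature_reference" in paths:
                from .tag_counting import load_feature_reference

                guide_gene = load_feature_reference(paths["feature_reference"]).guide_to_gene()
            if not guide_gene:
                raise ConfigError("guide_to_gene map or feature_reference required")
            if "gex_dir" in paths and Path(paths["gex_dir"]).exists():
                expression = read_count_matrix(paths["gex_dir"]).to_frame()
        else:
            stage = "simulate"
            sim_cfg = simulation_config_from(config)
            log.info("simulating %d cells (seed %d)", sim_cfg.n_cells, seed)
            dataset = simulate_dataset(sim_cfg, seed=seed)
            dataset.write(out / "simulated")
            adt = dataset.tag_frame("ADT")
            hto = dataset.tag_frame("HTO")
            gdo = dataset.tag_frame("GDO")
            guide_gene = dict(sim_cfg.guide_pool)
            expression = dataset.expression
            report["parameters"]["simulate"] = _jsonable(dataclasses.asdict(sim_cfg))
        droplets = sorted(set(adt.index) | set(hto.index) | set(gdo.index))
        adt = adt.reindex(droplets, fill_value=0)
        hto = hto.reindex(droplets, fill_value=0)
        gdo = gdo.reindex(droplets, fill_value=0)
        report["stages"]["input"] = {"n_droplets": len(droplets)}

        stage = "qc"
        if expression is not None:
            expression = expression.reindex(droplets, fill_value=0)
            profiles = [
                CellQCProfile(
                    c,
                    int(gdo.loc[c].sum()),
                    int(expression.loc[c].sum()),
                    int((expression.loc[c] > 0).sum()),
                )
                for c in droplets
            ]
            retained, qc_report = apply_qc_filters(profiles, qc_params)
        else:  # tag-only runs skip transcriptome filters but keep the GDO tail cut
            totals = gdo.sum(axis=1)
            cutoff = float(np.quantile(totals.to_numpy(float), qc_params.gdo_total_quantile))
            retained = set(totals.index[totals <= cutoff])
            qc_report = {
                "n_input": len(droplets),
                "removed_gdo_total": len(droplets) - len(retained),
                "n_retained": len(retained),
                "gdo_total_cutoff": cutoff,
                "note": "no expression input; cDNA filters skipped",
            }
        qc_cells = [c for c in droplets if c in retained]
        report["stages"]["qc"] = qc_report

        stage = "demux"
        clr = clr_normalize(hto.loc[qc_cells].to_numpy())
        calls = classify_hashtags(clr, cell_ids=qc_cells, hto_ids=list(hto.columns))
        calls_df = calls_to_frame(calls)
        calls_df.to_csv(out / "hto_calls.tsv", sep="\t", index=False)
        singlets = [c for c in calls if c.status == "singlet"]
        report["stages"]["demux"] = {
            "n_singlet": len(singlets),
            "n_doublet": sum(c.status == "doublet" for c in calls),
            "n_negative": sum(c.status == "negative" for c in calls),
        }

        stage = "assign"
        singlet_ids = [c.cell_id for c in singlets]
        called = call_guides_matrix(gdo.loc[singlet_ids], guide_gene, guide_params)
        labels = {c: PerturbationLabel(tuple(l.split("+"))) for c, l in called["label"].items()}
        retained_labels, dropped = filter_combinations(labels, guide_params)
        called.to_csv(out / "guide_calls.tsv", sep="\t")
        dropped.to_csv(out / "dropped_combinations.tsv", sep="\t", index=False)
        report["stages"]["assign"] = {
            "n_guide_called": len(called),
            "n_after_combo_filter": len(retained_labels),
            "n_labels": len(set(map(str, retained_labels.values()))),
            "n_dropped_labels": len(dropped),
        }

        stage = "score"
        kept = sorted(retained_labels)
        rc = rc_normalize(adt.loc[kept], norm_params)
        kept_calls = [c for c in singlets if c.cell_id in retained_labels]
        hto_max = compute_hto_max(hto, kept_calls, norm_params)
        scores = protein_score(rc, hto_max, cd86="CD86", pdl1="PD-L1")
        scores.to_csv(out / "cell_scores.tsv", sep="\t")
        report["stages"]["score"] = {"n_scored": len(scores)}

        stage = "rank"
        ranking = summarize_and_rank(scores, retained_labels, reference_label=reference_label)
        ranking.to_csv(out / "combination_ranking.tsv", sep="\t")
        report["stages"]["rank"] = {
            "n_labels_ranked": len(ranking),
            "top_label": ranking.index[0],
            "top_relative_score": float(ranking["relative_score"].iloc[0]),
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        if isinstance(exc, (ConfigError, MissingReferenceError)):
            raise
        raise StageError(stage, str(exc)) from exc

    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "report.json":
            manifest[str(path.relative_to(out))] = _sha256(path)
    report["manifest"] = manifest
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
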