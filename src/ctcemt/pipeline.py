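"""End-to-end pipeline orchestration with provenance logging.

A single YAML config drives the stage sequence

    synth -> preprocess -> emt_score -> circuit_sim -> classify

Each enabled stage reads the previous stage's in-memory result (or files,
when the synthesis stage is disabled), writes its artifacts under the
output directory, and records them in a JSON manifest with SHA-256 hashes,
parameters and timings.  Re-running an identical config reproduces
identical hashes for every deterministic stage.

The global seed fans out to fixed per-stage sub-seeds
(``SeedSequence([seed, stage_index])``), so any stage can be re-run in
isolation and reproduce the full-pipeline result.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import circuit, classify, preprocess, scoring, synthetic

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineError"]

STAGES = ("synth", "preprocess", "emt_score", "circuit_sim", "classify")


class PipelineError(ValueError):
    pass


class ConfigError(PipelineError):
    pass


_DEFAULTS: dict = {
    "seed": 0,
    "outdir": "ctcemt_out",
    "stages": {s: (s != "circuit_sim") for s in STAGES},
    "inputs": {  # used when the synth stage is disabled
        "counts": None, "counts_format": "mtx", "annotation": None, "panel": None,
    },
    "synth": {},  # SynthConfig fields; seed is derived from the global seed
    "preprocess": {
        "min_expressed_fraction": 0.10, "min_count": 5, "min_cells": 10,
    },
    "emt_score": {
        "order_mode": "difference", "axis": "cell", "window": None,
        "trend_genes": ["CDH1", "EPCAM", "VIM", "CD24", "CD44"],
    },
    "circuit_sim": {
        "network": None, "n_models": 200, "n_inits": 20, "replicates": 3,
        "gene_a": "CDH1", "gene_b": "VIM",
    },
    "classify": {
        "algo": "gbm", "norm": "median", "n_components": 20,
        "mixed_pbmc_sample": None,
        "surface_genes": list(synthetic.SURFACE_GENES),
    },
}


@dataclass
class PipelineConfig:
    """Normalized pipeline configuration (defaults filled, range-checked)."""

    raw: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def stage_seed(self, stage: str) -> int:
        """Fixed fan-out: sub-seed derived from (global seed, stage index)."""
        i = STAGES.index(stage)
        ss = np.random.SeedSequence([self.seed, i])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=True)


class _StrictLoader(yaml.SafeLoader):
    pass


def _no_duplicates(loader, node, deep=False):
    keys = [loader.construct_object(k, deep=deep) for k, _ in node.value]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise ConfigError(f"duplicate config key(s): {sorted(dupes)}")
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates
)


def _merge_checked(user: dict, errors: list) -> dict:
    cfg = copy.deepcopy(_DEFAULTS)
    for key, val in user.items():
        if key not in cfg:
            errors.append(f"unknown top-level key: {key!r}")
            continue
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                errors.append(f"{key!r} must be a mapping")
                continue
            for k2, v2 in val.items():
                if key == "synth":  # validated by SynthConfig below
                    cfg[key][k2] = v2
                elif k2 not in cfg[key]:
                    errors.append(f"unknown key: {key}.{k2}")
                else:
                    cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


def validate_config(source) -> PipelineConfig:
    """Load, default-fill and range-check a config (path, dict or YAML text).

    All schema violations are reported together in one error.
    """
    if isinstance(source, dict):
        user = copy.deepcopy(source)
    else:
        text = source
        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                text = fh.read()
        user = yaml.load(text, Loader=_StrictLoader) or {}
        if not isinstance(user, dict):
            raise ConfigError("config must be a YAML mapping")

    errors: list = []
    cfg = _merge_checked(user, errors)

    if not isinstance(cfg["seed"], int):
        errors.append("seed must be an integer")
    for s, on in cfg["stages"].items():
        if not isinstance(on, bool):
            errors.append(f"stages.{s} must be true/false")

    # synth block validated via SynthConfig (carries its own ranges)
    try:
        synth_kwargs = dict(cfg["synth"])
        synth_kwargs.setdefault("seed", 0)
        known = set(synthetic.SynthConfig.__dataclass_fields__)
        bad = set(synth_kwargs) - known
        if bad:
            errors.append(f"unknown key(s) under synth: {sorted(bad)}")
        else:
            sc = synthetic.SynthConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in synth_kwargs.items()
            })
            sc.validate()
    except synthetic.SynthConfigError as e:
        errors.append(f"synth: {e}")

    p = cfg["preprocess"]
    if not 0 <= p["min_expressed_fraction"] <= 1:
        errors.append("preprocess.min_expressed_fraction must be in [0, 1]")
    if p["min_count"] < 0 or p["min_cells"] < 1:
        errors.append("preprocess.min_count >= 0 and min_cells >= 1 required")
    if cfg["emt_score"]["order_mode"] not in ("ratio", "difference"):
        errors.append("emt_score.order_mode must be 'ratio' or 'difference'")
    c = cfg["circuit_sim"]
    if c["n_models"] < 1 or c["n_inits"] < 1 or c["replicates"] < 1:
        errors.append("circuit_sim sizes must be >= 1")
    cl = cfg["classify"]
    if cl["algo"] not in ("nb", "rf", "gbm"):
        errors.append("classify.algo must be nb, rf or gbm")
    if cl["norm"] not in ("median", "median+pca"):
        errors.append("classify.norm must be 'median' or 'median+pca'")
    if cfg["stages"]["circuit_sim"] and c["network"] is not None and not os.path.exists(
        str(c["network"])
    ):
        errors.append(f"circuit_sim.network path not found: {c['network']}")
    if not cfg["stages"]["synth"]:
        for need in ("counts", "annotation"):
            if cfg["inputs"][need] is None:
                errors.append(f"inputs.{need} required when synth stage is off")

    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))
    return PipelineConfig(raw=cfg)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict | str) -> dict:
    """Execute the enabled stages in fixed order and write the manifest.

    Returns the manifest dict.  A stage failure raises
    :class:`PipelineError` naming the stage after writing a partial
    manifest.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    cfg = config.raw
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    manifest = {"seed": config.seed, "config": cfg, "stages": {}}
    manifest_path = os.path.join(outdir, "manifest.json")

    state: dict = {}

    def record(stage, t0, outputs, summary):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {os.path.relpath(p, outdir): _sha256(p) for p in outputs},
            "summary": summary,
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def fail(stage, exc):
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- synth / ingest ------------------------------------------------
    t0 = time.time()
    try:
        if cfg["stages"]["synth"]:
            synth_kwargs = dict(cfg["synth"])
            synth_kwargs["seed"] = config.stage_seed("synth")
            scfg = synthetic.SynthConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in synth_kwargs.items()
            })
            panel = synthetic.generate_marker_panel(
                scfg.panel_sizes, scfg.n_genes, scfg.seed
            )
            adata = synthetic.simulate_cohort(scfg, panel)
            mtx_dir = os.path.join(outdir, "counts")
            preprocess.write_matrix(adata, mtx_dir, fmt="mtx")
            ann_path = os.path.join(outdir, "annotation.tsv")
            adata.obs.to_csv(ann_path, sep="\t")
            truth_path = os.path.join(outdir, "truth.tsv")
            synthetic.truth_frame(adata).to_csv(truth_path, sep="\t", index=False)
            panel_path = os.path.join(outdir, "panel.tsv")
            panel.to_tsv(panel_path)
            cfg_path = os.path.join(outdir, "synth_config.yaml")
            with open(cfg_path, "w") as fh:
                yaml.safe_dump(scfg.to_dict(), fh)
            outputs = [os.path.join(mtx_dir, f) for f in
                       ("matrix.mtx", "genes.tsv", "cells.tsv")]
            outputs += [ann_path, truth_path, panel_path, cfg_path]
            record("synth", t0, outputs,
                   {"n_cells": adata.n_obs, "n_genes": adata.n_vars})
            state["adata"], state["panel"] = adata, panel
        else:
            fmt = cfg["inputs"]["counts_format"]
            adata = preprocess.read_matrix(cfg["inputs"]["counts"], fmt=fmt)
            ann = pd.read_csv(cfg["inputs"]["annotation"], sep="\t", index_col=0)
            adata.obs = ann.loc[adata.obs_names]
            state["adata"] = adata
            if cfg["inputs"]["panel"]:
                state["panel"] = synthetic.MarkerPanel.from_tsv(cfg["inputs"]["panel"])
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - reported with stage name
        fail("synth", e)

    # ---- preprocess ----------------------------------------------------
    if cfg["stages"]["preprocess"]:
        t0 = time.time()
        try:
            p = cfg["preprocess"]
            raw = state["adata"]
            proc = preprocess.preprocess(
                raw,
                min_expressed_fraction=p["min_expressed_fraction"],
                min_count=p["min_count"], min_cells=p["min_cells"],
            )
            out = os.path.join(outdir, "expression_normalized.tsv")
            preprocess.write_matrix(proc, out, fmt="tsv")
            record("preprocess", t0, [out], {
                "cells_in": raw.n_obs, "cells_kept": proc.n_obs,
                "genes_in": raw.n_vars, "genes_kept": proc.n_vars,
            })
            state["proc"] = proc
        except Exception as e:  # noqa: BLE001
            fail("preprocess", e)

    # ---- EMT scoring ---------------------------------------------------
    if cfg["stages"]["emt_score"]:
        t0 = time.time()
        try:
            es = cfg["emt_score"]
            panel = state.get("panel")
            if panel is None:
                raise PipelineError("emt_score requires a marker panel")
            proc = state.get("proc", state["adata"])
            mask = np.asarray(proc.obs.get("class_label", "CTC")).astype(str) == "CTC"
            ctc = proc[mask].copy()
            scores = scoring.score_cells(
                ctc, panel, axis=es["axis"], order_mode=es["order_mode"]
            )
            ordered = scoring.order_continuum(scores, mode=es["order_mode"])
            genes = [g for g in es["trend_genes"] if g in ctc.var_names]
            trends = scoring.moving_average_trend(ctc, ordered, genes, es["window"])
            rho = scoring.phenotype_anticorrelation(scores)
            clusters = scoring.cluster_em(
                ctc, genes=[g for g in (*panel.epithelial, *panel.mesenchymal)
                            if g in ctc.var_names]
            )
            outs = []
            for name, df in (("em_scores.tsv", scores),
                             ("em_trends.tsv", trends),
                             ("em_clusters.tsv", clusters.to_frame())):
                path = os.path.join(outdir, name)
                df.to_csv(path, sep="\t")
                outs.append(path)
            summary = {"n_ctc": int(mask.sum()),
                       "phenotype_anticorrelation": round(rho, 4)}
            try:
                chk = scoring.checkpoint_correlation(ctc)
                path = os.path.join(outdir, "checkpoint_correlation.tsv")
                chk.to_csv(path, sep="\t")
                outs.append(path)
            except scoring.ScoringError:
                summary["checkpoint_correlation"] = "skipped (genes absent)"
            record("emt_score", t0, outs, summary)
        except Exception as e:  # noqa: BLE001
            fail("emt_score", e)

    # ---- circuit simulation --------------------------------------------
    if cfg["stages"]["circuit_sim"]:
        t0 = time.time()
        try:
            c = cfg["circuit_sim"]
            net = (circuit.GeneNetwork.from_tsv(c["network"])
                   if c["network"] else circuit.load_emt_network())
            ens = circuit.run_ensemble(
                net, n_models=c["n_models"], n_inits=c["n_inits"],
                replicates=c["replicates"], seed=config.stage_seed("circuit_sim"),
            )
            corr = circuit.expression_correlation(ens, c["gene_a"], c["gene_b"])
            st_path = os.path.join(outdir, "circuit_states.tsv")
            ens.states.to_csv(st_path, sep="\t", index=False)
            pr_path = os.path.join(outdir, "circuit_parameters.tsv")
            ens.parameters.to_csv(pr_path, sep="\t", index=False)
            record("circuit_sim", t0, [st_path, pr_path], {
                "n_models": ens.n_models,
                "n_nonconvergent": ens.n_nonconvergent,
                "correlation": corr,
            })
        except Exception as e:  # noqa: BLE001
            fail("circuit_sim", e)

    # ---- classification -------------------------------------------------
    if cfg["stages"]["classify"]:
        t0 = time.time()
        try:
            cl = cfg["classify"]
            adata = state["adata"]
            panel = state.get("panel")
            markers = None
            if panel is not None:
                markers = list(panel.epithelial + panel.mesenchymal + panel.csc
                               + panel.leukocyte)
            rep = classify.leave_one_dataset_out(
                adata, algo=cl["algo"], norm=cl["norm"],
                n_components=cl["n_components"], marker_list=markers,
                seed=config.stage_seed("classify"),
                mixed_pbmc_sample=cl["mixed_pbmc_sample"],
            )
            rep_path = os.path.join(outdir, "classifier_report.csv")
            rep.to_csv(rep_path)
            outs = [rep_path]
            summary = {"mean_accuracy": round(float(rep["accuracy"].mean()), 4)}
            try:
                surf = classify.rank_surface_markers(adata, cl["surface_genes"])
                surf_path = os.path.join(outdir, "surface_markers.csv")
                surf.to_csv(surf_path, index=False)
                outs.append(surf_path)
            except classify.ClassifyError:
                summary["surface_markers"] = "skipped (genes absent)"
            record("classify", t0, outs, summary)
        except Exception as e:  # noqa: BLE001
            fail("classify", e)

    return manifest
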