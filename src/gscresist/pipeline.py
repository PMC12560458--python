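"""End-to-end pipeline orchestration and the run manifest.

Stages run in dependency order: simulate -> dss -> classify -> scores ->
methylome. Every intermediate artifact is written to the output directory
and a manifest summarizes stage-level counts and collected warnings so
that downstream assertions never have to scrape logs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from .classify import (cluster_cultures, compare_counts, count_responders,
                       linkage_to_newick, multiscale_bootstrap,
                       normalize_dss, restrict_common)
from .config import (ClassificationConfig, CohortConfig, DssParams,
                     MethylationConfig, SsgseaConfig, config_to_dict)
from .dose_response import build_dss_matrix, screen_dss
from .expression import (classify_subtype, gene_zscores,
                         normalize_expression, set_score, ssgsea_score)
from .methylation import (differential_islands, filter_depth,
                          island_methylation, mgmt_status)
from .synthetic import (gen_expression_matrix, gen_methylome,
                        gen_viability_screen)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Declarative configuration of a full synthetic-cohort run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    dss: DssParams = field(default_factory=DssParams)
    classification: ClassificationConfig = field(
        default_factory=ClassificationConfig)
    ssgsea: SsgseaConfig = field(default_factory=SsgseaConfig)
    methylation: MethylationConfig = field(
        default_factory=MethylationConfig)
    seed: int = 0
    outdir: str = "gscresist-run"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a nested dict (e.g. parsed YAML); unknown keys raise."""
        known = {"cohort": CohortConfig, "dss": DssParams,
                 "classification": ClassificationConfig,
                 "ssgsea": SsgseaConfig, "methylation": MethylationConfig}
        kwargs = {}
        for key, val in data.items():
            if key in known:
                sub_cls = known[key]
                valid = {f for f in sub_cls.__dataclass_fields__}
                stray = set(val) - valid
                if stray:
                    raise ValueError(
                        f"unknown keys in {key!r} config: {sorted(stray)}")
                if "scales" in val:
                    val = {**val, "scales": tuple(val["scales"])}
                kwargs[key] = sub_cls(**val)
            elif key in ("seed", "outdir", "log_level"):
                kwargs[key] = val
            else:
                raise ValueError(f"unknown top-level config key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "cohort": config_to_dict(self.cohort),
            "dss": config_to_dict(self.dss),
            "classification": config_to_dict(self.classification),
            "ssgsea": config_to_dict(self.ssgsea),
            "methylation": config_to_dict(self.methylation),
            "seed": self.seed,
            "outdir": str(self.outdir),
            "log_level": self.log_level,
        }


@dataclass
class RunManifest:
    """Summary of one pipeline run: versions, config hash, stage counts,
    collected warnings. ``content_hash`` excludes the timestamp so that
    identical inputs and config yield identical hashes."""

    version: str
    config_hash: str
    started: str
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def content_hash(self) -> str:
        payload = json.dumps(
            {"version": self.version, "config_hash": self.config_hash,
             "counts": self.counts, "warnings": sorted(self.warnings)},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "version": self.version,
                "config_hash": self.config_hash,
                "started": self.started,
                "counts": self.counts,
                "warnings": self.warnings,
                "content_hash": self.content_hash(),
            }, fh, indent=1)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run simulate -> dss -> classify -> scores -> methylome end to end.

    All randomness derives from ``config.seed``; the per-stage generator
    seeds are taken from the cohort/classification sub-configs, which are
    overridden by the global seed here so one integer pins the whole run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = CohortConfig(**{**config_to_dict(config.cohort),
                             "seed": config.seed})
    cls_cfg = ClassificationConfig(
        **{**{k: v for k, v in
              config_to_dict(config.classification).items()
              if k != "scales"},
           "scales": tuple(config.classification.scales),
           "seed": config.seed})
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(version=VERSION, config_hash=cfg_hash,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- simulate -------------------------------------------------
        screens, truth = _stage("simulate")(gen_viability_screen)(cohort)
        expr, gene_sets, _ = _stage("simulate")(gen_expression_matrix)(
            cohort)
        islands, meth_records, meth_truth = _stage("simulate")(
            gen_methylome)(cohort)
        truth.to_json(outdir / "truth.json")
        gio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
        gio.write_bed(islands, outdir / "islands.bed")

        # --- dss ------------------------------------------------------
        cols = [_stage("dss")(screen_dss)(s, config.dss) for s in screens]
        dss = _stage("dss")(build_dss_matrix)(cols)
        gio.write_matrix(dss, outdir / "dss_matrix.tsv", index_name="drug")
        manifest.counts["n_drugs"] = int(dss.shape[0])
        manifest.counts["n_samples"] = int(dss.shape[1])

        # --- classify -------------------------------------------------
        common = _stage("classify")(restrict_common)(dss)
        counts = _stage("classify")(count_responders)(
            common, cls_cfg.responder_threshold)
        centered = _stage("classify")(normalize_dss)(common)
        Z, labels = _stage("classify")(cluster_cultures)(
            centered, counts, cls_cfg.n_clusters)
        labels = labels.join(counts[["rank"]])
        welch = _stage("classify")(compare_counts)(counts, labels)
        stability = _stage("classify")(multiscale_bootstrap)(
            centered, cls_cfg)
        gio.write_labels(labels, outdir / "labels.tsv")
        with open(outdir / "dendrogram.nwk", "w") as fh:
            fh.write(linkage_to_newick(Z, list(centered.columns)) + "\n")
        with open(outdir / "cluster_stability.json", "w") as fh:
            json.dump({"b": stability.b,
                       "scales": list(stability.scales),
                       "clusters": stability.clusters}, fh, indent=1)
        manifest.counts["n_drugs_common"] = int(common.shape[0])
        sizes = labels["group"].value_counts().to_dict()
        manifest.counts["cluster_sizes"] = {k: int(v)
                                            for k, v in sizes.items()}
        manifest.counts["responder_welch_p"] = welch.pvalue

        # --- scores ---------------------------------------------------
        norm = _stage("scores")(normalize_expression)(expr)
        z = _stage("scores")(gene_zscores)(norm)
        stem = _stage("scores")(set_score)(
            z, gene_sets["STEMNESS"], labels)
        es_pn = _stage("scores")(ssgsea_score)(
            norm, gene_sets["PN"], config.ssgsea)
        es_mes = _stage("scores")(ssgsea_score)(
            norm, gene_sets["MES"], config.ssgsea)
        subtypes = _stage("scores")(classify_subtype)(es_pn, es_mes)
        scores = pd.DataFrame({
            "stemness_mean_z": stem.per_sample,
            "es_pn": es_pn, "es_mes": es_mes,
            "subtype": subtypes["subtype"],
        })
        scores.to_csv(outdir / "expression_scores.tsv", sep="\t",
                      index_label="sample")
        manifest.counts["stemness_group_scores"] = {
            k: float(v) for k, v in stem.group_scores.items()}
        manifest.counts["stemness_welch_p"] = stem.welch.pvalue
        manifest.counts["subtype_calls"] = (
            subtypes["subtype"].value_counts().to_dict())

        # --- methylome ------------------------------------------------
        mcfg = config.methylation
        filtered = {s: filter_depth(r, mcfg)
                    for s, r in meth_records.items()}
        mat, nmat = _stage("methylome")(island_methylation)(
            filtered, islands, mcfg)
        gio.write_matrix(mat, outdir / "island_methylation.tsv",
                         index_name="island_id")
        mgmt = {s: _stage("methylome")(mgmt_status)(r, mcfg)
                for s, r in filtered.items()}
        with open(outdir / "mgmt_report.json", "w") as fh:
            json.dump(mgmt, fh, indent=1)
        dm = _stage("methylome")(differential_islands)(mat, labels, mcfg)
        dm.to_csv(outdir / "differential_islands.tsv", sep="\t")
        manifest.counts["n_islands"] = int(mat.shape[0])
        manifest.counts["n_dm_islands"] = int(dm["significant"].sum())
        manifest.counts["mgmt_methylated"] = sum(
            1 for v in mgmt.values() if v["status"] == "methylated")

        manifest.warnings = sorted({str(w.message) for w in caught})

    manifest.to_json(outdir / "manifest.json")
    return manifest
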