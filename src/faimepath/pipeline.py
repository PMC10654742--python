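"""End-to-end orchestration of the analysis.

A single YAML config drives the run: it either points at user data
(counts, metadata, gene sets, optional hierarchy) or contains a
``simulate:`` block with synthetic-cohort parameters.  Stages run in a
fixed order — preprocess, score, differential pathways, clustering,
classification, change analysis — and every stage writes plain TSV or
JSON into the output directory.  A manifest records package and
library versions, all parameters, seeds, input hashes and per-stage row
counts; rerunning the same config reproduces every output byte for
byte (no timestamps enter any file).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .change import ancova_change_table, root_enrichment, split_pre_post
from .clustering import (
    cluster_composition,
    cluster_covariate_tests,
    collapse_to_root,
    ward_clusters,
)
from .dep import DR_MODERATE, dep_table
from .faime import minmax_normalize, score_matrix
from .io import (
    CountMatrix,
    GeneSetCollection,
    read_count_matrix,
    read_gene_sets,
    read_hierarchy,
    write_count_matrix,
    write_gene_sets,
    write_hierarchy,
)
from .models import repeated_cv_classifier
from .preprocess import preprocess
from .simulate import SyntheticSpec, generate_cohort, generate_gene_sets

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "score", "dep", "cluster", "classify", "change")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see package docs for schema)."""

    data: dict | None = None
    simulate: dict | None = None
    preprocess: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)
    dep: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    change: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.data is None) == (self.simulate is None):
            raise ValueError(
                "config must contain exactly one of 'data' or 'simulate'"
            )
        if self.data is not None:
            for key in ("counts", "metadata", "gene_sets"):
                if key not in self.data:
                    raise ValueError(f"data block missing {key!r}")
        g = self.dep.get("gamma", 0.2)
        if not 0 <= g < 0.5:
            raise ValueError("dep.gamma must be in [0, 0.5)")
        for key, lo in (("alpha", 0.0), ("dr_threshold", 0.0)):
            v = self.dep.get(key)
            if v is not None and v <= lo:
                raise ValueError(f"dep.{key} must be > {lo}")
        if self.cluster.get("k", 4) < 2:
            raise ValueError("cluster.k must be >= 2")
        for key in ("runs", "folds"):
            if self.classify.get(key, 1) < 1:
                raise ValueError(f"classify.{key} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_inputs(
    config: PipelineConfig, outdir: Path
) -> tuple[CountMatrix, GeneSetCollection, dict | None, dict]:
    hashes = {}
    if config.data is not None:
        cm = read_count_matrix(config.data["counts"], config.data["metadata"])
        sets = read_gene_sets(config.data["gene_sets"])
        if config.data.get("hierarchy"):
            sets.hierarchy.update(read_hierarchy(config.data["hierarchy"]))
            hashes["hierarchy"] = _sha256(config.data["hierarchy"])
        for key in ("counts", "metadata", "gene_sets"):
            hashes[key] = _sha256(config.data[key])
        return cm, sets, None, hashes
    spec = SyntheticSpec(**(config.simulate or {}))
    sets = generate_gene_sets(spec)
    cm, truth = generate_cohort(spec, sets)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    write_count_matrix(cm, inputs / "counts.tsv", inputs / "metadata.tsv")
    write_gene_sets(sets, inputs / "sets.gmt")
    write_hierarchy(sets.hierarchy, inputs / "hierarchy.tsv")
    (inputs / "truth.json").write_text(json.dumps(truth, indent=2))
    for f in inputs.iterdir():
        hashes[f.name] = _sha256(f)
    return cm, sets, truth, hashes


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "faimepath_version": __version__,
        "stages": [],
        "parameters": {
            "preprocess": config.preprocess,
            "score": config.score,
            "dep": config.dep,
            "cluster": config.cluster,
            "classify": config.classify,
            "change": config.change,
        },
    }
    import numpy, scipy, sklearn, statsmodels  # noqa: E401

    manifest["library_versions"] = {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }

    cm, sets, truth, hashes = _load_inputs(config, outdir)
    manifest["input_hashes"] = hashes
    if config.simulate is not None:
        manifest["simulate"] = config.simulate
    baseline = cm.metadata.loc[
        list(cm.counts.columns)
    ].query("timepoint == 'baseline'").index.tolist()

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
            return result

        return wrap

    @stage("preprocess")
    def expr():
        e = preprocess(cm, **config.preprocess)
        e.values.to_csv(outdir / "expr.tsv", sep="\t", index_label="gene")
        manifest["preprocess"] = e.provenance
        return e

    @stage("score")
    def psm():
        s = score_matrix(expr, sets, **config.score)
        s.scores.to_csv(outdir / "scores_raw.tsv", sep="\t", index_label="pathway")
        mm = minmax_normalize(s)
        mm.scores.to_csv(
            outdir / "scores_minmax.tsv", sep="\t", index_label="pathway"
        )
        manifest["score"] = {
            "n_pathways": len(s.pathways),
            "n_samples": len(s.samples),
        }
        return (s, mm)

    scores_raw, scores_minmax = psm

    @stage("dep")
    def dt():
        labels = cm.metadata.loc[baseline, "group"]
        d = dep_table(
            scores_raw.scores[baseline],
            labels,
            gamma=config.dep.get("gamma", 0.2),
            alpha_q=config.dep.get("alpha", 0.05),
            dr_threshold=config.dep.get("dr_threshold", DR_MODERATE),
            method=config.dep.get("method", "yuen"),
        )
        d.table.to_csv(outdir / "dep.tsv", sep="\t", index_label="pathway")
        manifest["dep"] = {
            "n_tested": len(d.table),
            "n_significant": d.n_significant,
            "groups": list(d.groups),
        }
        return d

    @stage("cluster")
    def clus():
        view = config.cluster.get("view", "minmax")
        sc = scores_minmax if view == "minmax" else scores_raw
        sig = list(dt.significant)
        rows = sig if sig else list(sc.scores.index)
        res = ward_clusters(
            sc.scores.loc[rows, baseline], k=config.cluster.get("k", 4)
        )
        res.assignment.to_frame().to_csv(
            outdir / "clusters.tsv", sep="\t", index_label="sample_id"
        )
        comp = cluster_composition(res.assignment, cm.metadata)
        res.ordering = comp["cluster"].tolist()
        comp.to_csv(outdir / "cluster_composition.tsv", sep="\t", index=False)
        cov = cluster_covariate_tests(res.assignment, cm.metadata)
        cov.to_csv(outdir / "cluster_covariate_tests.tsv", sep="\t")
        manifest["cluster"] = {
            "k": res.k,
            "view": view,
            "n_pathways_used": len(rows),
            "ordering": res.ordering,
        }
        return res

    @stage("classify")
    def report():
        labels = cm.metadata.loc[baseline, "group"]
        rep = repeated_cv_classifier(
            scores_raw.scores[baseline],
            labels,
            runs=config.classify.get("runs", 20),
            folds=config.classify.get("folds", 10),
            seed=config.classify.get("seed", 17),
            gamma=config.dep.get("gamma", 0.2),
            alpha_q=config.dep.get("alpha", 0.05),
            dr_threshold=config.dep.get("dr_threshold", DR_MODERATE),
        )
        payload = {
            "design": rep.design,
            "mean_auroc": rep.mean_auroc,
            "sd_auroc": rep.sd_auroc,
            "n_folds": len(rep.records),
            "n_skipped_folds": rep.n_skipped_folds,
            "folds": rep.records.to_dict(orient="records"),
        }
        (outdir / "report_classify.json").write_text(
            json.dumps(payload, indent=2)
        )
        manifest["classify"] = {
            "mean_auroc": rep.mean_auroc,
            "sd_auroc": rep.sd_auroc,
            "n_folds": len(rep.records),
        }
        return rep

    @stage("change")
    def change():
        pre, post, outcomes = split_pre_post(scores_raw, cm.metadata)
        subj_cluster = None
        base_md = cm.metadata.loc[baseline]
        sample_of = base_md.reset_index().set_index("subject_id")["sample_id"]
        subj_cluster = pd.Series(
            {
                s: clus.assignment[sample_of[s]]
                for s in pre.columns
                if s in sample_of.index
            }
        )
        ct = ancova_change_table(
            pre,
            post,
            outcomes,
            clusters=subj_cluster,
            alpha=config.change.get("alpha", 0.05),
        )
        ct.table.to_csv(outdir / "change.tsv", sep="\t", index_label="pathway")
        roots = collapse_to_root(sets).loc[ct.table.index]
        enr_rows = []
        for root in sorted(roots.unique()):
            enr = root_enrichment(ct.table["significant"], roots, root)
            enr_rows.append(
                {
                    "root": root,
                    "p_chisq": enr.p,
                    "prop_in_significant": enr.prop_target_in_significant,
                    "prop_in_nonsignificant": enr.prop_target_in_nonsignificant,
                    "degenerate": enr.degenerate,
                }
            )
        pd.DataFrame(enr_rows).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        manifest["change"] = {
            "n_tested": len(ct.table),
            "n_significant": ct.n_significant,
            "model": ct.model_spec,
        }
        return ct

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
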