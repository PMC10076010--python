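"""Stage orchestration: simulate -> process -> expression -> cluster -> roc.

Each stage reads the previous stage's artifacts from the output directory (or
pre-existing files named in the config), writes its declared outputs, and
records per-stage counts in a JSON run manifest.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .design import CohortDesign, crc_cohort_design
from .expression import (SampleExpressionTable, diff_expression, normalize,
                         tmm_factors)
from .panel import PanelDefinition, ReadLayout, default_panel
from .readproc import ExosomeProteinMatrix, process_fastq
from .roc import evaluate_marker
from .simulate import simulate_dataset
from .subpop import (SubpopulationTable, assign_and_summarize,
                     binarize_features, downsample_exosomes, embed_2d,
                     fit_cluster_model, normalize_rows, pool_matrices)

STAGES = ("simulate", "process", "expression", "cluster", "roc")

logger = logging.getLogger("exopba")


class PipelineError(RuntimeError):
    """A stage could not run; the message names the missing input."""


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise PipelineError(f"{what} not found: {path}")
    return path


def _read_metadata(path: Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(meta.columns):
        raise PipelineError(f"metadata {path} needs columns sample_id, group")
    return meta


def _default_comparisons(groups: Sequence[str]) -> list[tuple[str, str]]:
    seen = list(dict.fromkeys(groups))
    return list(itertools.combinations(seen, 2))


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the requested stages in order and write the run manifest."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    outdir = Path(config.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seeds": config.seeds.model_dump(),
        "version": __version__,
        "stages": {},
    }

    sim_dir = outdir / "sim"
    proc_dir = outdir / "proc"
    expr_dir = outdir / "expr"
    cluster_dir = outdir / "cluster"
    roc_dir = outdir / "roc"

    if "simulate" in stages:
        logger.info("[simulate] generating synthetic cohort")
        if config.paths.design is not None:
            design = CohortDesign.from_yaml(
                _require(Path(config.paths.design), "design file")
            )
        else:
            design = crc_cohort_design()
        if config.simulate.exosomes_per_sample is not None:
            design.exosomes_per_sample = config.simulate.exosomes_per_sample
        truth, fastqs = simulate_dataset(design, sim_dir,
                                         seed=config.seeds.simulate)
        manifest["stages"]["simulate"] = {
            "n_samples": len(truth.samples),
            "n_exosomes_true": int(sum(s.n_exosomes for s in truth.samples)),
            "n_molecules_true": int(sum(s.n_molecules for s in truth.samples)),
        }

    panel_path = Path(config.paths.panel) if config.paths.panel else \
        sim_dir / "panel.tsv"
    metadata_path = Path(config.paths.metadata) if config.paths.metadata else \
        sim_dir / "metadata.tsv"
    fastq_dir = Path(config.paths.fastq_dir) if config.paths.fastq_dir else sim_dir

    if "process" in stages:
        panel = PanelDefinition.from_tsv(_require(panel_path, "panel table"))
        meta = _read_metadata(_require(metadata_path, "sample metadata"))
        _require(fastq_dir, "FASTQ directory")
        proc_dir.mkdir(parents=True, exist_ok=True)
        counts = {}
        for sample_id in meta["sample_id"]:
            fq = _require(fastq_dir / f"{sample_id}.fastq",
                          f"FASTQ for sample {sample_id}")
            logger.info("[process] %s", sample_id)
            matrix, qc = process_fastq(
                fq, panel,
                layout=ReadLayout(),
                sample_id=sample_id,
                min_q=config.process.min_q,
                min_fraction=config.process.min_fraction,
                max_mismatch=config.process.max_mismatch,
                umi_method=config.process.umi_method,
                collapse_tags=config.process.collapse_exosome_tags,
            )
            matrix.save(proc_dir)
            qc.to_json(proc_dir / f"{sample_id}.qc.json")
            counts[sample_id] = {
                "n_reads_in": qc.n_reads_in,
                "n_reads_pass_quality": qc.n_reads_pass_quality,
                "n_parsed": qc.n_parsed,
                "n_matched": qc.n_matched,
                "n_exosomes": qc.n_exosomes,
                "n_molecules": qc.n_molecules,
                "mean_proteins_per_exosome": qc.mean_proteins_per_exosome,
            }
        manifest["stages"]["process"] = counts

    def _load_matrices() -> tuple[list[ExosomeProteinMatrix], pd.DataFrame]:
        meta = _read_metadata(_require(metadata_path, "sample metadata"))
        _require(proc_dir, "processed-matrix directory (run the process stage)")
        matrices = []
        for sample_id in meta["sample_id"]:
            _require(proc_dir / f"{sample_id}.mtx",
                     f"processed matrix for {sample_id}")
            matrices.append(ExosomeProteinMatrix.load(proc_dir, sample_id))
        return matrices, meta

    if "expression" in stages:
        logger.info("[expression] TMM + differential expression")
        matrices, meta = _load_matrices()
        groups = dict(zip(meta["sample_id"], meta["group"]))
        table = SampleExpressionTable.from_matrices(matrices, groups)
        factors = tmm_factors(table,
                              logratio_trim=config.expression.logratio_trim,
                              sum_trim=config.expression.sum_trim)
        normed = normalize(table, factors)
        expr_dir.mkdir(parents=True, exist_ok=True)
        table.counts.to_csv(expr_dir / "sample_counts.tsv", sep="\t")
        factors.factors.to_frame().assign(reference=factors.reference).to_csv(
            expr_dir / "tmm_factors.tsv", sep="\t"
        )
        normed.to_csv(expr_dir / "normalized.tsv", sep="\t")
        comparisons = config.expression.comparisons or \
            _default_comparisons(meta["group"])
        n_sig = {}
        for a, b in comparisons:
            res = diff_expression(
                normed, table.groups, group_a=a, group_b=b,
                alpha_normality=config.expression.alpha_normality,
                fallback=config.expression.fallback,
            )
            res.to_csv(expr_dir / f"diff_{a}_vs_{b}.tsv", sep="\t",
                       index_label="protein")
            n_sig[f"{a}_vs_{b}"] = int(res["significant"].sum())
        manifest["stages"]["expression"] = {
            "n_samples": len(table.counts),
            "n_proteins": table.counts.shape[1],
            "n_significant": n_sig,
        }

    if "cluster" in stages:
        logger.info("[cluster] SOM + consensus metaclustering")
        matrices, meta = _load_matrices()
        block = pool_matrices(matrices)
        block = downsample_exosomes(block, n=config.cluster.downsample_n,
                                    seed=config.seeds.downsample)
        block = binarize_features(block)
        if config.cluster.row_normalize:
            block = normalize_rows(block)
        model = fit_cluster_model(
            block,
            grid=(config.cluster.grid_rows, config.cluster.grid_cols),
            k=config.cluster.k,
            epochs=config.cluster.epochs,
            n_reps=config.cluster.reps,
            subsample=config.cluster.subsample,
            auto_k=config.cluster.auto_k,
            k_range=range(config.cluster.k_min, config.cluster.k_max + 1),
            criterion=config.cluster.criterion,
            seed=config.seeds.som,
        )
        table = assign_and_summarize(block, model)
        cluster_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "exosome_id": block.exosome_ids,
            "sample_id": block.sample_ids,
            "cluster": table.assignments.to_numpy(),
        }).to_csv(cluster_dir / "assignments.tsv", sep="\t", index=False)
        table.proportions.to_csv(cluster_dir / "proportions.tsv", sep="\t",
                                 index_label="sample_id")
        table.signatures.to_csv(cluster_dir / "signatures.tsv", sep="\t",
                                index_label="cluster")
        if model.selection:
            sel = {k: v for k, v in model.selection.items()}
            with open(cluster_dir / "k_selection.json", "w") as fh:
                json.dump(sel, fh, indent=2, default=str)
        if config.cluster.embed:
            coords = embed_2d(block, seed=config.seeds.embed)
            pd.DataFrame({
                "exosome_id": block.exosome_ids,
                "tsne1": coords[:, 0],
                "tsne2": coords[:, 1],
            }).to_csv(cluster_dir / "embedding.tsv", sep="\t", index=False)
        manifest["stages"]["cluster"] = {
            "n_exosomes_clustered": int(block.n_exosomes),
            "k": int(model.k),
        }

    if "roc" in stages:
        logger.info("[roc] marker AUC evaluation")
        meta = _read_metadata(_require(metadata_path, "sample metadata"))
        groups = dict(zip(meta["sample_id"], meta["group"]))
        comparisons = config.roc.comparisons or \
            _default_comparisons(meta["group"])
        roc_dir.mkdir(parents=True, exist_ok=True)
        summary_rows = []
        curve_rows = []
        score_tables: dict[str, pd.DataFrame] = {}
        if "expression" in config.roc.sources:
            score_tables["expression"] = pd.read_csv(
                _require(expr_dir / "normalized.tsv",
                         "normalized expression (run the expression stage)"),
                sep="\t", index_col=0,
            )
        if "proportion" in config.roc.sources:
            score_tables["proportion"] = pd.read_csv(
                _require(cluster_dir / "proportions.tsv",
                         "cluster proportions (run the cluster stage)"),
                sep="\t", index_col=0,
            )
        for a, b in comparisons:
            for source, scores_df in score_tables.items():
                samples = [s for s in scores_df.index if groups.get(s) in (a, b)]
                labels = np.array([groups[s] == b for s in samples])
                for marker in scores_df.columns:
                    scores = scores_df.loc[samples, marker].to_numpy()
                    if np.ptp(scores) == 0 or labels.all() or not labels.any():
                        continue
                    res = evaluate_marker(str(marker), scores, labels,
                                          source=source, positive_label=b)
                    summary_rows.append({
                        "comparison": f"{a}_vs_{b}", "source": source,
                        "marker": res.marker, "auc": res.auc,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "n_pos": res.n_pos, "n_neg": res.n_neg,
                    })
                    for f, t, thr in zip(res.fpr, res.tpr, res.thresholds):
                        curve_rows.append({
                            "comparison": f"{a}_vs_{b}", "source": source,
                            "marker": res.marker, "fpr": f, "tpr": t,
                            "threshold": thr,
                        })
        pd.DataFrame(summary_rows).to_csv(roc_dir / "summary.tsv", sep="\t",
                                          index=False)
        pd.DataFrame(curve_rows).to_csv(roc_dir / "curves.tsv", sep="\t",
                                        index=False)
        manifest["stages"]["roc"] = {"n_markers_evaluated": len(summary_rows)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
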