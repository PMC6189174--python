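"""Config-driven end-to-end orchestration with a machine-readable run report.

The pipeline composes the stages in analysis order: cell QC anchored on
control wells → TMM normalization and FPKM → expression gene filter → TPM
(re-normalised on the retained genes) → low-variability gene filter →
spike-in noise model → simulated technical replicates → consensus clustering
with silhouette-based k selection → group stability scores → one-vs-rest
permutation differential expression → entropy × links stem scores → marker
binarization tables. Every stage's output is written to the run directory and
summarised in ``report.json`` together with the resolved configuration, the
seed ledger and SHA-256 checksums of every artefact, so a rerun with the same
config reproduces the report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import consensus_cluster as cc
from . import diffexp_perm as de
from . import marker_logic as ml
from . import matrix_io as mio
from . import noise_replicates as nr
from . import qc_normalize as qn
from . import stem_entropy as se
from . import synthdata as sd
from ._utils import spawn_seeds
from .errors import ConfigurationError

logger = logging.getLogger("glandscape")


@dataclass
class RunConfig:
    """Resolved pipeline configuration (exactly one input source)."""

    seed: int = 0
    # input: either a synthdata block or paths to counts (+ optional metadata)
    synthdata: dict | None = None
    counts_tsv: str | None = None
    gene_lengths_tsv: str | None = None
    cell_metadata_tsv: str | None = None
    # QC / filters
    qc_override_threshold: int | None = None
    min_fpkm: float = 4.0
    min_cells: int = 3
    # replicates / clustering
    n_replicates: int = 250
    k_range: list[int] = field(default_factory=lambda: list(range(2, 9)))
    k: int | None = None  # manual override of the suggested k
    # differential expression
    de_permutations: int = 500
    de_fc_threshold: float = 4.0
    de_fdr_threshold: float = 1e-5
    # stem scoring
    stem_m_min: int | None = None
    # markers
    marker_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        has_synth = self.synthdata is not None
        has_paths = self.counts_tsv is not None
        if has_synth == has_paths:
            raise ConfigurationError(
                "exactly one of a synthdata block or input paths must be given"
            )
        if has_paths and self.gene_lengths_tsv is None:
            raise ConfigurationError("input paths require a gene_lengths_tsv")
        if not (250 <= self.de_permutations <= 1000):
            raise ConfigurationError("de_permutations must lie in [250, 1000]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    seeds: dict
    qc: dict
    gene_filters: dict
    k_selection: dict
    group_scores: dict
    de_summary: dict
    stem_scores: dict
    markers: dict
    manifest: dict  # file name → sha256

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_input(config: RunConfig) -> mio.CountMatrix:
    if config.synthdata is not None:
        block = dict(config.synthdata)
        panel = sd.build_panel(
            int(block.get("n_genes", 108)),
            int(block.get("n_spikeins", 12)),
            config.seed,
        )
        bio_genes = [g for g in panel.gene_id if not panel.is_spikein[panel.gene_id.index(g)]]
        groups = []
        group_blocks = block.get("groups")
        if group_blocks is None:
            group_blocks = [
                {"name": "G1", "n_cells": 100, "markers": bio_genes[0:20], "multiplier": 4.0},
                {"name": "G2", "n_cells": 100, "markers": bio_genes[20:40], "multiplier": 4.0},
                {"name": "G3", "n_cells": 100, "markers": bio_genes[40:60], "multiplier": 4.0},
            ]
        for g in group_blocks:
            groups.append(
                sd.GroupDesign(
                    name=g["name"],
                    n_cells=int(g["n_cells"]),
                    marker_gene_ids=list(g.get("markers", [])),
                    marker_multiplier=float(g.get("multiplier", 1.0)),
                )
            )
        design = sd.CellDesign(groups=groups, size_factor_sd=float(block.get("size_factor_sd", 0.25)))
        noise = sd.NoiseParams(
            dispersion=float(block.get("dispersion", 0.5)),
            dropout_midpoint=float(block.get("dropout_midpoint", 1.0)),
            dropout_slope=float(block.get("dropout_slope", 1.5)),
        )
        matrix = sd.simulate_counts(panel, design, noise, config.seed)
        return sd.add_control_wells(
            matrix, int(block.get("n_neg", 3)), int(block.get("n_pos", 3)), config.seed
        )
    lengths = mio.read_gene_lengths(config.gene_lengths_tsv)
    metadata = (
        mio.read_cell_metadata(config.cell_metadata_tsv)
        if config.cell_metadata_tsv
        else None
    )
    return mio.read_counts_tsv(config.counts_tsv, gene_lengths=lengths, cell_metadata=metadata)


def run_pipeline(config: RunConfig, out_dir) -> RunReport:
    """Run every stage, write artefacts under ``out_dir``, return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = dict(zip(["replicates", "de"], spawn_seeds(config.seed, 2, "pipeline")))

    def stage(name, fn, *args, **kwargs):
        start = time.time()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise
        logger.info("stage %-12s %.2fs", name, time.time() - start)
        return result

    matrix = stage("input", _build_input, config)
    mio.write_counts_tsv(matrix, out / "counts.tsv")
    mio.write_cell_metadata(matrix, out / "cells.tsv")
    mio.write_gene_table(matrix, out / "genes.tsv")

    qc = stage("qc", qn.qc_threshold, matrix, config.qc_override_threshold)
    filtered = stage("filter_cells", qn.filter_cells, matrix, qc)

    lengths = filtered.gene_table["length_bp"].to_dict()
    norm = stage("tmm", qn.tmm_factors, filtered)
    fpkm_expr = stage("fpkm", qn.fpkm, filtered, lengths, norm)
    fpkm_mask = qn.filter_genes_fpkm(fpkm_expr, config.min_fpkm, config.min_cells)
    kept_fpkm = fpkm_mask.index[fpkm_mask].tolist()
    tpm_expr = stage("tpm", qn.tpm, filtered, lengths, kept_fpkm)
    cv_mask = qn.filter_low_variability(tpm_expr)
    kept_genes = cv_mask.index[cv_mask].tolist()
    tpm_expr = qn.tpm(filtered, lengths, kept_genes)

    model = stage("noise_fit", nr.fit_noise_model, filtered)
    (out / "noise_model.json").write_text(json.dumps(model.to_dict(), indent=2))

    reps = nr.simulate_replicates(filtered, model, config.n_replicates, seeds["replicates"])
    ksel = stage("choose_k", cc.choose_k, reps, config.k_range, kept_genes)
    chosen_k = config.k if config.k is not None else ksel.suggested_k
    labelings = stage("replicate_labelings", cc.replicate_labelings, reps, chosen_k, kept_genes)
    consensus = cc.consensus_from_labels(labelings)
    labels = cc.final_clusters(consensus, chosen_k)
    # singleton clusters (outlier cells) carry no within-group consensus;
    # score only the multi-cell clusters
    sizes = labels.labels.value_counts()
    scored_cells = labels.labels.index[labels.labels.map(sizes) >= 2]
    scored_consensus = cc.ConsensusMatrix(consensus.matrix.loc[scored_cells, scored_cells])
    scores = cc.group_score(scored_consensus, labels.labels.loc[scored_cells].to_dict())

    consensus.matrix.to_csv(out / "consensus.tsv", sep="\t")
    labels.labels.to_frame().to_csv(out / "labels.tsv", sep="\t")
    ksel.summary().to_csv(out / "k_selection.tsv", sep="\t")
    scores.per_group.to_csv(out / "group_scores.tsv", sep="\t")

    de_summary = {}
    for c in sorted(labels.labels.unique()):
        in_c = labels.labels.index[labels.labels == c].tolist()
        rest = labels.labels.index[labels.labels != c].tolist()
        if len(in_c) < 2 or len(rest) < 2:
            de_summary[str(c)] = {"skipped": "cluster too small"}
            continue
        result = de.run_de(
            tpm_expr, in_c, rest, config.de_permutations, seeds["de"]
        )
        hits = de.de_genes(result, config.de_fc_threshold, config.de_fdr_threshold)
        relaxed = de.de_genes(result, config.de_fc_threshold, 0.05)
        result.table.to_csv(out / f"de_cluster{c}_vs_rest.tsv", sep="\t")
        de_summary[str(c)] = {
            "n_cells": len(in_c),
            "n_de_genes": len(hits),
            "n_de_genes_fdr05": len(relaxed),
            "top": relaxed[:10],
        }

    entropy = se.cell_entropy(tpm_expr)
    stem_table = {}
    if labels.k >= 2:
        graph = se.cluster_links(qn.log2_tpm(tpm_expr), labels, config.stem_m_min)
        stems = se.stem_scores(entropy, labels, graph)
        stems.table.to_csv(out / "stem_scores.tsv", sep="\t")
        stem_table = {str(c): row for c, row in stems.table.to_dict("index").items()}

    markers = {}
    marker_genes = [g for g in config.marker_genes if g in filtered.values.index]
    if marker_genes:
        table = ml.combination_table(marker_genes, filtered)
        table.to_csv(out / "marker_combinations.tsv", sep="\t")
        markers = {"genes": marker_genes, "combinations": table["percent"].to_dict()}

    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "report.json"}
    report = RunReport(
        config={k: v for k, v in config.__dict__.items()},
        seeds={"master": config.seed, **seeds},
        qc={
            "threshold": qc.threshold,
            "n_cells_in": matrix.n_cells,
            "n_cells_kept": filtered.n_cells,
            "excluded_cells": qc.excluded_cells,
        },
        gene_filters={
            "n_genes_in": int((~matrix.spike_mask).sum()),
            "n_after_fpkm_filter": len(kept_fpkm),
            "n_after_cv_filter": len(kept_genes),
        },
        k_selection={
            "suggested_k": ksel.suggested_k,
            "chosen_k": chosen_k,
            "median_silhouette_by_k": {
                str(k): float(np.median(v)) for k, v in ksel.silhouettes.items()
            },
        },
        group_scores={
            "mean_score": scores.mean_score,
            "per_group": {str(g): row for g, row in scores.per_group.to_dict("index").items()},
        },
        de_summary=de_summary,
        stem_scores=stem_table,
        markers=markers,
        manifest=manifest,
    )
    (out / "report.json").write_text(report.to_json())
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return report
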