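"""End-to-end orchestration of the pipeline stages over a run directory.

Stages: simulate (optional) -> parse -> count -> cellcall -> genotype ->
correct -> cluster -> concord -> gradient. Every stage reads and writes
documented artifacts inside one run directory, so stages can be chained
individually or via :func:`run_all`; both routes produce identical files.
A JSON manifest records seeds, parameters, per-stage row counts and
artifact checksums, and suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Callable, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as gio
from .antibody_correction import (
    build_design,
    build_quality_matrix,
    correct_counts,
    correction_diagnostics,
    transform_counts,
)
from .cell_calling import build_qc_table
from .concordance import concordance_report, genotype_cluster_labels
from .gradient_analysis import (
    blast_subset,
    fit_spline,
    gradient_correlations,
    moving_profiles,
    order_by_gradient,
)
from .phenotype_clustering import (
    annotate,
    cluster,
    cluster_mean_expression,
    embed,
)
from .read_structure import (
    AntibodyPanel,
    ParsedTagRead,
    Whitelist,
    parse_tag_read_pair,
    read_fastq_pairs,
    write_parse_log,
)
from .scenarios import SAMPLE_TYPE_PRESETS, get_scenario
from .umi_counting import build_count_matrix
from .genotype_matrix import read_genotype_matrix, write_genotype_h5
from .synthetic_data import (
    default_amplicon_panel,
    default_loci,
    default_panel,
    default_schema,
    default_whitelist,
    emit_antibody_reads,
    emit_dna_fixtures,
    simulate_truth,
)

__all__ = ["RunConfig", "run_all", "run_stage", "STAGES", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: str = "three_populations"
    scale: float = 1.0


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_dist: int = 1
    min_fraction: float = 0.6
    min_reads: int = 8
    min_umis: int = 100
    isotype_factor: float = 5.0
    min_gq: float = 30
    min_dp: float = 10


class ClusterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_neighbors: int = 15
    n_pcs: int | Literal["all"] = 16
    min_dist: float | None = None  # default from sample-type preset
    resolution: float | None = None
    annotation_rules: dict[str, str] = Field(default_factory=dict)


class GradientConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    blast_cluster_ids: list[int] | None = None
    blast_markers: list[str] = Field(default_factory=lambda: ["CD33"])
    window: int = 200


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    outdir: str
    seed: int = 0
    sample_type: Literal["patient", "pbmc", "cell_lines"] = "patient"
    n_vectors: int | None = None  # default from sample-type preset
    relevant_loci: list[str] | None = None
    merge_alternates: bool = True
    simulate: SimulateConfig | None = None
    filters: FilterConfig = Field(default_factory=FilterConfig)
    clustering: ClusterConfig = Field(default_factory=ClusterConfig)
    gradient: GradientConfig = Field(default_factory=GradientConfig)
    # external inputs; populated by the simulate stage when it runs
    reads_r1: str | None = None
    reads_r2: str | None = None
    whitelist_paths: list[str] | None = None
    panel_csv: str | None = None
    amplicon_bed: str | None = None
    vcf: str | None = None
    depth_table: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def preset(self, key: str):
        return SAMPLE_TYPE_PRESETS[self.sample_type][key]


def _p(cfg: RunConfig, name: str) -> str:
    return os.path.join(cfg.outdir, name)


def _require(cfg: RunConfig, stage: str, *paths: str | None) -> None:
    for p in paths:
        if p is None or not os.path.exists(p):
            raise PipelineError(stage, f"missing required artifact/input: {p}")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> dict:
    if cfg.simulate is None:
        raise PipelineError("simulate", "no simulate block in config")
    sc = get_scenario(cfg.simulate.scenario, cfg.simulate.scale)
    panel = default_panel()
    wl = default_whitelist()
    schema = default_schema()
    bed = default_amplicon_panel()
    truth = simulate_truth(sc.populations, sc.tech, cfg.seed, panel=panel,
                           loci=default_loci(), whitelist=wl)
    os.makedirs(cfg.outdir, exist_ok=True)
    r1, r2 = _p(cfg, "tags_R1.fastq.gz"), _p(cfg, "tags_R2.fastq.gz")
    n_pairs = emit_antibody_reads(truth, r1, r2, schema, sc.tech, cfg.seed)
    vcf = _p(cfg, "cells.vcf")
    depths = emit_dna_fixtures(truth, bed, sc.tech, vcf, cfg.seed)
    depths.to_csv(_p(cfg, "amplicon_depths.tsv"), sep="\t")
    bed[["chrom", "start", "end", "name"]].to_csv(
        _p(cfg, "amplicons.bed"), sep="\t", header=False, index=False
    )
    panel.to_csv(_p(cfg, "panel.csv"))
    wl_paths = []
    for i, seg in enumerate(wl.segments):
        p = _p(cfg, f"whitelist_seg{i + 1}.txt")
        with open(p, "w") as fh:
            fh.write("\n".join(sorted(seg)) + "\n")
        wl_paths.append(p)
    truth.write_tsv(_p(cfg, "truth.tsv"))
    cfg.reads_r1, cfg.reads_r2 = r1, r2
    cfg.whitelist_paths = wl_paths
    cfg.panel_csv = _p(cfg, "panel.csv")
    cfg.amplicon_bed = _p(cfg, "amplicons.bed")
    cfg.vcf = vcf
    cfg.depth_table = _p(cfg, "amplicon_depths.tsv")
    cfg.sample_type = {"patient": "patient", "pbmc": "pbmc",
                       "cell_lines": "cell_lines"}[sc.sample_type]
    if cfg.relevant_loci is None:
        cfg.relevant_loci = sc.relevant_loci
    return {"n_cells": int(truth.cells.shape[0]), "n_read_pairs": int(n_pairs)}


def _default_inputs(cfg: RunConfig) -> None:
    """Point unset input paths at the simulate stage's artifacts."""
    defaults = {
        "reads_r1": "tags_R1.fastq.gz",
        "reads_r2": "tags_R2.fastq.gz",
        "panel_csv": "panel.csv",
        "amplicon_bed": "amplicons.bed",
        "vcf": "cells.vcf",
        "depth_table": "amplicon_depths.tsv",
    }
    for attr, name in defaults.items():
        if getattr(cfg, attr) is None and os.path.exists(_p(cfg, name)):
            setattr(cfg, attr, _p(cfg, name))
    if cfg.whitelist_paths is None:
        paths = sorted(
            os.path.join(cfg.outdir, f)
            for f in os.listdir(cfg.outdir)
            if f.startswith("whitelist_seg")
        ) if os.path.isdir(cfg.outdir) else []
        if paths:
            cfg.whitelist_paths = paths


def stage_parse(cfg: RunConfig) -> dict:
    _default_inputs(cfg)
    _require(cfg, "parse", cfg.reads_r1, cfg.reads_r2, cfg.panel_csv)
    if not cfg.whitelist_paths:
        raise PipelineError("parse", "missing whitelist paths")
    wl = Whitelist.from_files(cfg.whitelist_paths)
    panel = AntibodyPanel.from_csv(cfg.panel_csv)
    schema = default_schema()
    reasons: dict[str, int] = {}
    n_valid = 0
    out = _p(cfg, "parsed_reads.tsv")
    with open(out, "w") as fh:
        fh.write("cell_barcode\tantibody\tumi\n")
        for s1, q1, s2, q2 in read_fastq_pairs(cfg.reads_r1, cfg.reads_r2):
            r = parse_tag_read_pair(s1, q1, s2, q2, schema, wl, panel,
                                    cfg.filters.max_dist)
            reasons[r.reason] = reasons.get(r.reason, 0) + 1
            if r.valid:
                n_valid += 1
                fh.write(f"{r.cell_barcode}\t{r.antibody}\t{r.umi}\n")
    write_parse_log(_p(cfg, "parse_log.tsv"), reasons)
    return {"n_valid_reads": n_valid, "reasons": reasons}


def stage_count(cfg: RunConfig) -> dict:
    _default_inputs(cfg)
    _require(cfg, "count", _p(cfg, "parsed_reads.tsv"), cfg.panel_csv)
    panel = AntibodyPanel.from_csv(cfg.panel_csv)
    parsed = pd.read_csv(_p(cfg, "parsed_reads.tsv"), sep="\t")
    reads = (
        ParsedTagRead(r.cell_barcode, r.antibody, r.umi, True)
        for r in parsed.itertuples()
    )
    counts, totals = build_count_matrix(reads, antibodies=panel.names)
    gio.write_counts_tsv(_p(cfg, "ab_counts.tsv"), counts)
    gio.write_counts_mtx(_p(cfg, "ab_counts"), counts)
    totals.to_csv(_p(cfg, "cell_totals.tsv"), sep="\t")
    return {"n_barcodes": int(counts.shape[0]), "n_antibodies": int(counts.shape[1])}


def stage_cellcall(cfg: RunConfig) -> dict:
    _default_inputs(cfg)
    _require(cfg, "cellcall", cfg.depth_table, _p(cfg, "ab_counts.tsv"),
             cfg.panel_csv)
    panel = AntibodyPanel.from_csv(cfg.panel_csv)
    depths = pd.read_csv(cfg.depth_table, sep="\t", index_col=0)
    counts = gio.read_counts_tsv(_p(cfg, "ab_counts.tsv"))
    counts = counts.reindex(depths.index, fill_value=0)
    f = cfg.filters
    qc = build_qc_table(
        depths, counts, panel.isotype_names,
        min_fraction=f.min_fraction, min_reads=f.min_reads,
        min_umis=f.min_umis, isotype_factor=f.isotype_factor,
    )
    qc.to_csv(_p(cfg, "qc_table.tsv"), sep="\t")
    cells = qc.index[qc.pass_all]
    with open(_p(cfg, "cells.txt"), "w") as fh:
        fh.write("\n".join(cells) + "\n")
    return {"n_candidates": int(qc.pass_knee.sum()), "n_cells": int(len(cells))}


def stage_genotype(cfg: RunConfig) -> dict:
    _default_inputs(cfg)
    _require(cfg, "genotype", cfg.vcf, _p(cfg, "cells.txt"))
    gm, variants = read_genotype_matrix(cfg.vcf, cfg.filters.min_gq,
                                        cfg.filters.min_dp)
    with open(_p(cfg, "cells.txt")) as fh:
        cells = [ln.strip() for ln in fh if ln.strip()]
    gm = gm.reindex([c for c in cells if c in gm.index])
    gm.to_csv(_p(cfg, "genotypes.tsv"), sep="\t")
    write_genotype_h5(_p(cfg, "genotypes.h5"), gm)
    variants.to_csv(_p(cfg, "variants.tsv"), sep="\t", index=False)
    return {"n_cells": int(gm.shape[0]), "n_variants": int(gm.shape[1])}


def stage_correct(cfg: RunConfig) -> dict:
    _default_inputs(cfg)
    for artifact in ("ab_counts.tsv", "cell_totals.tsv", "cells.txt"):
        if not os.path.exists(_p(cfg, artifact)):
            raise PipelineError("correct", f"missing artifact {artifact} "
                                "(run count/cellcall first)")
    _require(cfg, "correct", cfg.depth_table, cfg.panel_csv)
    panel = AntibodyPanel.from_csv(cfg.panel_csv)
    counts = gio.read_counts_tsv(_p(cfg, "ab_counts.tsv"))
    totals = pd.read_csv(_p(cfg, "cell_totals.tsv"), sep="\t", index_col=0)
    depths = pd.read_csv(cfg.depth_table, sep="\t", index_col=0)
    with open(_p(cfg, "cells.txt")) as fh:
        cells = [ln.strip() for ln in fh if ln.strip()]
    cells = [c for c in cells if c in counts.index]
    counts = counts.loc[cells]
    iso = counts[panel.isotype_names].sum(axis=1)
    q = build_quality_matrix(
        totals.loc[cells, "raw_reads"],
        totals.loc[cells, "umi_counts"],
        iso,
        depths.loc[cells].sum(axis=1),
    )
    n_vec = cfg.n_vectors if cfg.n_vectors is not None else cfg.preset("n_vectors")
    design = build_design(q, n_vec)
    u = correct_counts(transform_counts(counts), design)
    q.to_csv(_p(cfg, "quality_matrix.tsv"), sep="\t")
    u.to_csv(_p(cfg, "corrected.tsv"), sep="\t")
    gio.write_matrix_h5(_p(cfg, "corrected.h5"), u)
    diag = correction_diagnostics(u, design)
    diag.to_csv(_p(cfg, "correction_diagnostics.tsv"), sep="\t")
    pd.DataFrame(
        {"variance_explained": design.variance_explained}
    ).to_csv(_p(cfg, "design_variance.tsv"), sep="\t", index_label="component")
    return {"n_cells": int(u.shape[0]), "n_vectors": int(design.n_vectors)}


def stage_cluster(cfg: RunConfig) -> dict:
    if not os.path.exists(_p(cfg, "corrected.tsv")):
        raise PipelineError("cluster", "missing artifact corrected.tsv "
                            "(run correct first)")
    u = pd.read_csv(_p(cfg, "corrected.tsv"), sep="\t", index_col=0)
    cl_cfg = cfg.clustering
    min_dist = cl_cfg.min_dist if cl_cfg.min_dist is not None else cfg.preset("min_dist")
    resolution = (cl_cfg.resolution if cl_cfg.resolution is not None
                  else cfg.preset("resolution"))
    emb = embed(u, cl_cfg.n_neighbors, cl_cfg.n_pcs, min_dist, cfg.seed)
    assign = cluster(emb, resolution, cfg.seed)
    emb.coordinates.to_csv(_p(cfg, "embedding.tsv"), sep="\t")
    assign.labels.to_frame().to_csv(_p(cfg, "clusters.tsv"), sep="\t")
    means = cluster_mean_expression(u, assign.labels)
    means.to_csv(_p(cfg, "cluster_means.tsv"), sep="\t")
    names = annotate(means, cl_cfg.annotation_rules)
    with open(_p(cfg, "cluster_names.json"), "w") as fh:
        json.dump({str(k): v for k, v in names.items()}, fh, indent=1)
    _scatter_png(cfg, emb.coordinates, assign.labels)
    return {"n_clusters": int(assign.n_clusters), "resolution": resolution}


def _scatter_png(cfg: RunConfig, coords: pd.DataFrame, labels: pd.Series) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords.umap1, coords.umap2, c=labels, s=4, cmap="tab10")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    fig.savefig(_p(cfg, "embedding.png"), dpi=120)
    plt.close(fig)


def _clone_labels(cfg: RunConfig) -> pd.Series:
    gm = pd.read_csv(_p(cfg, "genotypes.tsv"), sep="\t", index_col=0)
    loci = cfg.relevant_loci
    if loci is None:
        loci = list(gm.columns)
    loci = [l for l in gm.columns if any(l == x or l.startswith(x) for x in loci)]
    if not loci:
        raise PipelineError("concord", "no relevant loci found in genotype matrix")
    return genotype_cluster_labels(gm, loci, cfg.merge_alternates)


def stage_concord(cfg: RunConfig) -> dict:
    for artifact in ("genotypes.tsv", "clusters.tsv"):
        if not os.path.exists(_p(cfg, artifact)):
            raise PipelineError("concord", f"missing artifact {artifact}")
    gm = pd.read_csv(_p(cfg, "genotypes.tsv"), sep="\t", index_col=0)
    clusters = pd.read_csv(_p(cfg, "clusters.tsv"), sep="\t", index_col=0)["cluster"]
    loci = cfg.relevant_loci
    if loci is None:
        loci = list(gm.columns)
    loci = [l for l in gm.columns if any(l == x or l.startswith(x) for x in loci)]
    report = concordance_report(gm, loci, clusters, cfg.merge_alternates)
    with open(_p(cfg, "concordance.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return {k: report[k] for k in ("n_cells", "ari", "applicable") if k in report}


def stage_gradient(cfg: RunConfig) -> dict:
    for artifact in ("corrected.tsv", "clusters.tsv", "genotypes.tsv",
                     "embedding.tsv", "cluster_means.tsv"):
        if not os.path.exists(_p(cfg, artifact)):
            raise PipelineError("gradient", f"missing artifact {artifact}")
    u = pd.read_csv(_p(cfg, "corrected.tsv"), sep="\t", index_col=0)
    clusters = pd.read_csv(_p(cfg, "clusters.tsv"), sep="\t", index_col=0)["cluster"]
    emb = pd.read_csv(_p(cfg, "embedding.tsv"), sep="\t", index_col=0)
    blast_ids = cfg.gradient.blast_cluster_ids
    if blast_ids is None:
        means = pd.read_csv(_p(cfg, "cluster_means.tsv"), sep="\t", index_col=0)
        markers = [m for m in cfg.gradient.blast_markers if m in means.columns]
        if not markers:
            raise PipelineError("gradient", "no blast clusters configured and "
                                "no blast markers found")
        score = means[markers].mean(axis=1)
        blast_ids = [int(i) for i in score.index[score > score.mean()]]
    ub = blast_subset(u, clusters, blast_ids)
    ordering = order_by_gradient(ub)
    clone = _clone_labels(cfg)
    clone = clone.reindex(ordering)
    clone = clone.map(lambda t: "no_call" if not isinstance(t, tuple) else str(t))
    window = min(cfg.gradient.window, max(2, len(ordering) // 2))
    prof = moving_profiles(ordering, ub, clone, emb, window)
    prof.antibody_profiles.to_csv(_p(cfg, "gradient_antibodies.tsv"), sep="\t")
    prof.clone_fractions.to_csv(_p(cfg, "gradient_clones.tsv"), sep="\t")
    if prof.smoothed_coords is not None and len(prof.smoothed_coords) >= 4:
        spline = fit_spline(prof.smoothed_coords)
        t = np.linspace(0, 1, 200)
        pd.DataFrame(spline(t), columns=["umap1", "umap2"]).to_csv(
            _p(cfg, "gradient_spline.tsv"), sep="\t", index=False
        )
    corr = gradient_correlations(prof)
    corr.to_csv(_p(cfg, "gradient_correlations.tsv"), sep="\t")
    return {"n_blast_cells": int(len(ordering)), "window": int(window),
            "blast_cluster_ids": blast_ids}


STAGES: dict[str, Callable[[RunConfig], dict]] = {
    "simulate": stage_simulate,
    "parse": stage_parse,
    "count": stage_count,
    "cellcall": stage_cellcall,
    "genotype": stage_genotype,
    "correct": stage_correct,
    "cluster": stage_cluster,
    "concord": stage_concord,
    "gradient": stage_gradient,
}


def run_stage(name: str, cfg: RunConfig) -> dict:
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}")
    os.makedirs(cfg.outdir, exist_ok=True)
    return STAGES[name](cfg)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order and write a reproducibility manifest.

    The simulate stage runs only when the config has a ``simulate`` block;
    otherwise external inputs must be provided. On stage failure a FAILED
    marker naming the stage is left in the run directory and the error is
    re-raised; completed artifacts are retained.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    order = list(STAGES)
    if cfg.simulate is None:
        order.remove("simulate")
    manifest: dict = {
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "stages": {},
    }
    for name in order:
        try:
            manifest["stages"][name] = run_stage(name, cfg)
        except Exception as exc:  # noqa: BLE001 - marker + re-raise
            with open(_p(cfg, "FAILED"), "w") as fh:
                fh.write(f"{name}: {exc}\n")
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(name, str(exc)) from exc
    manifest["checksums"] = {
        f: _sha256(os.path.join(cfg.outdir, f))
        for f in sorted(os.listdir(cfg.outdir))
        if os.path.isfile(os.path.join(cfg.outdir, f)) and f != "manifest.json"
    }
    with open(_p(cfg, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
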