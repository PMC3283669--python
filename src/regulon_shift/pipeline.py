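"""End-to-end pipeline: scan -> contrasts -> clusters -> stats -> activity.

Produces a bundle of TSV report tables per phase (contrast statistics,
differential calls, regulation profiles with influence/redundancy, cluster
assignments, DE-set overlap matrices, gene-set group responses, motif
enrichment/density tables, fitted motif activities) plus a JSON manifest
with the config hash and seed, sufficient to reproduce the bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from regulon_shift.activity import activity_table, build_design, fit_motif_activity
from regulon_shift.contrasts import (
    CONTRASTS,
    PHASES,
    ContrastResult,
    ExpressionMatrix,
    call_differential,
    compute_contrast,
    contrast_name,
    fit_eb_prior,
    moderated_t_test,
)
from regulon_shift.motifs import (
    DEFAULT_MOTIFS,
    MotifSpec,
    scan_promoters,
    summarize_density,
)
from regulon_shift.promoters import (
    extract_promoters_from_files,
    read_promoters_fasta,
)
from regulon_shift.regulon import (
    GeneSet,
    cluster_profiles,
    group_response_test,
    motif_enrichment_test,
    orientation_bias_test,
    profile_table,
    read_gene_sets,
    set_overlap_test,
)

logger = logging.getLogger("regulon_shift")


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    Either ``promoter_fasta`` or both ``genome_fasta`` and ``gff`` must be
    given, plus the expression matrix.  The overlap-test universe defaults
    to all genes on the expression matrix.
    """

    expression_tsv: str | Path
    promoter_fasta: str | Path | None = None
    genome_fasta: str | Path | None = None
    gff: str | Path | None = None
    gene_set_files: Sequence[str | Path] = field(default_factory=tuple)
    motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS
    max_promoter_len: int = 800
    fold_threshold: float = 2.0
    alpha: float = 0.01
    redundancy_cutoff: float = 0.5
    k_clusters: int = 6
    weighting: str = "abs_response"
    seed: int = 0
    outdir: str | Path = "results"

    def validate(self) -> None:
        if self.promoter_fasta is None and (self.genome_fasta is None or self.gff is None):
            raise ValueError(
                "need promoter_fasta, or genome_fasta together with gff"
            )
        for path in self._input_paths():
            if not Path(path).exists():
                raise FileNotFoundError(f"input does not exist: {path}")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.fold_threshold <= 0:
            raise ValueError("fold threshold must be positive")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")

    def _input_paths(self) -> list[Path]:
        paths = [Path(self.expression_tsv)]
        for p in (self.promoter_fasta, self.genome_fasta, self.gff):
            if p is not None:
                paths.append(Path(p))
        paths.extend(Path(p) for p in self.gene_set_files)
        return paths

    def manifest_dict(self) -> dict:
        from regulon_shift import __version__  # deferred: avoids import cycle

        payload = {
            "version": __version__,
            "seed": self.seed,
            "inputs": [str(p) for p in self._input_paths()],
            "motifs": [(m.name, m.forward) for m in self.motifs],
            "thresholds": {
                "fold": self.fold_threshold,
                "alpha": self.alpha,
                "redundancy_cutoff": self.redundancy_cutoff,
                "k_clusters": self.k_clusters,
                "max_promoter_len": self.max_promoter_len,
                "weighting": self.weighting,
            },
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        payload["config_hash"] = digest
        return payload


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus file paths."""

    contrasts: dict[tuple[str, str], ContrastResult]
    de_sets: dict[tuple[str, str, str], GeneSet]  # (phase, contrast, direction)
    profiles: dict[str, pd.DataFrame]  # per phase
    clusters: dict[str, pd.Series]  # per phase (may be missing if too few genes)
    overlaps: dict[str, pd.DataFrame]
    group_responses: pd.DataFrame
    enrichment: pd.DataFrame
    density: pd.DataFrame
    orientation: pd.DataFrame
    activity: pd.DataFrame
    manifest: dict
    files: dict[str, Path]


def _write_tsv(frame: pd.DataFrame, path: Path, **kwargs) -> Path:
    frame.to_csv(path, sep="\t", **kwargs)
    return path


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in dependency order; deterministic given inputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    # --- stage: promoters + motif scan -------------------------------------
    logger.info("stage scan: loading promoters and scanning motifs")
    if config.promoter_fasta is not None:
        promoters = read_promoters_fasta(config.promoter_fasta)
    else:
        promoters = extract_promoters_from_files(
            config.genome_fasta, config.gff, max_len=config.max_promoter_len
        )
    non_empty = [p for p in promoters if not p.is_empty]
    counts = scan_promoters(non_empty, list(config.motifs))
    counts.to_tsv(outdir / "motif_counts.tsv")
    files["motif_counts"] = outdir / "motif_counts.tsv"

    # --- stage: contrasts ----------------------------------------------------
    logger.info("stage contrasts: moderated t per phase")
    matrix = ExpressionMatrix.from_tsv(config.expression_tsv)
    phases = [p for p in PHASES if p in set(matrix.sample_info()["phase"])]
    contrasts: dict[tuple[str, str], ContrastResult] = {}
    de_sets: dict[tuple[str, str, str], GeneSet] = {}
    for phase in phases:
        base = compute_contrast(matrix, phase, *CONTRASTS[0])
        prior = fit_eb_prior(base.table["s2"].to_numpy(), float(base.table["df"].iloc[0]))
        for strain_a, strain_b in CONTRASTS:
            result = moderated_t_test(
                compute_contrast(matrix, phase, strain_a, strain_b), prior
            )
            name = result.name
            contrasts[(phase, name)] = result
            result.to_tsv(outdir / f"contrast_{phase}_{name}.tsv")
            files[f"contrast_{phase}_{name}"] = outdir / f"contrast_{phase}_{name}.tsv"
            called = call_differential(result, config.fold_threshold, config.alpha)
            for direction in ("up", "down"):
                members = called.index[called["direction"] == direction]
                de_sets[(phase, name, direction)] = GeneSet(
                    f"{direction}_{name}_{phase}", members
                )

    # --- stage: regulation profiles + clustering ----------------------------
    logger.info("stage profiles: influence/redundancy and clustering")
    profiles: dict[str, pd.DataFrame] = {}
    clusters: dict[str, pd.Series] = {}
    for phase in phases:
        prof = profile_table(
            contrasts[(phase, "gis1-wt")],
            contrasts[(phase, "rph1-wt")],
            contrasts[(phase, "gis1rph1-wt")],
        )
        profiles[phase] = prof
        _write_tsv(prof, outdir / f"profiles_{phase}.tsv", index_label="gene_id")
        files[f"profiles_{phase}"] = outdir / f"profiles_{phase}.tsv"

        regulated = sorted(
            set().union(
                *(de_sets[(phase, contrast_name(a, b), d)].members
                  for a, b in CONTRASTS for d in ("up", "down"))
            )
        )
        vectors = pd.DataFrame(
            {
                contrast_name(a, b): contrasts[(phase, contrast_name(a, b))].log2_ratio
                for a, b in CONTRASTS
            }
        ).loc[regulated]
        vectors = vectors[vectors.var(axis=1) > 0]
        if len(vectors) >= config.k_clusters:
            assignment = cluster_profiles(vectors, k=config.k_clusters)
            clusters[phase] = assignment.labels
            _write_tsv(
                assignment.labels.to_frame(),
                outdir / f"clusters_{phase}.tsv",
                index_label="gene_id",
            )
        else:
            clusters[phase] = pd.Series(dtype=int, name="cluster")
            _write_tsv(
                clusters[phase].to_frame(),
                outdir / f"clusters_{phase}.tsv",
                index_label="gene_id",
            )
        files[f"clusters_{phase}"] = outdir / f"clusters_{phase}.tsv"

    # --- stage: overlap matrices --------------------------------------------
    logger.info("stage overlap: hypergeometric DE-set overlaps")
    universe = GeneSet("expression-universe", matrix.genes)
    overlaps: dict[str, pd.DataFrame] = {}
    for phase in phases:
        keys = [
            (contrast_name(a, b), d) for a, b in CONTRASTS for d in ("up", "down")
        ]
        names = [f"{d}_{c}" for c, d in keys]
        mat_p = pd.DataFrame(1.0, index=names, columns=names)
        mat_n = pd.DataFrame(0, index=names, columns=names)
        for i, (ci, di) in enumerate(keys):
            for j, (cj, dj) in enumerate(keys):
                set_i = de_sets[(phase, ci, di)]
                set_j = de_sets[(phase, cj, dj)]
                if len(set_i) and len(set_j):
                    res = set_overlap_test(set_i, set_j, universe)
                    mat_p.iloc[i, j] = res.p_value
                    mat_n.iloc[i, j] = res.overlap
        overlaps[phase] = mat_p
        _write_tsv(mat_p, outdir / f"overlap_p_{phase}.tsv", index_label="set")
        _write_tsv(mat_n, outdir / f"overlap_n_{phase}.tsv", index_label="set")
        files[f"overlap_p_{phase}"] = outdir / f"overlap_p_{phase}.tsv"

    # --- stage: gene-set group responses ------------------------------------
    logger.info("stage group response: Wilcoxon rank-sum per gene set")
    gene_sets: list[GeneSet] = []
    for path in config.gene_set_files:
        gene_sets.extend(read_gene_sets(path))
    response_rows = []
    for gene_set in gene_sets:
        for (phase, name), result in contrasts.items():
            present = [g for g in gene_set.members if g in result.table.index]
            if not present or len(present) == len(result.table):
                continue
            res = group_response_test(GeneSet(gene_set.name, present), result)
            response_rows.append(
                {
                    "group": gene_set.name,
                    "phase": phase,
                    "contrast": name,
                    "n_genes": res.n_group,
                    "direction": res.direction,
                    "p_value": res.p_value,
                }
            )
    group_responses = pd.DataFrame(
        response_rows,
        columns=["group", "phase", "contrast", "n_genes", "direction", "p_value"],
    )
    _write_tsv(group_responses, outdir / "group_responses.tsv", index=False)
    files["group_responses"] = outdir / "group_responses.tsv"

    # --- stage: enrichment, density, orientation -----------------------------
    logger.info("stage motif stats: enrichment, density, orientation bias")
    scanned_genes = set(counts.frame["gene_id"])
    enrich_rows, orient_rows = [], []
    for (phase, name, direction), de_set in de_sets.items():
        in_table = [g for g in de_set.members if g in scanned_genes]
        if len(in_table) < 2 or len(in_table) > len(scanned_genes) - 2:
            continue
        sub = GeneSet(de_set.name, in_table)
        for motif in config.motifs:
            enr = motif_enrichment_test(sub, counts, motif.name)
            enrich_rows.append(
                {
                    "gene_set": de_set.name,
                    "phase": phase,
                    "contrast": name,
                    "direction": direction,
                    "motif": motif.name,
                    "set_mean": enr.set_mean,
                    "background_mean": enr.background_mean,
                    "p_enrichment": enr.p_enrichment,
                    "p_depletion": enr.p_depletion,
                }
            )
            try:
                bias = orientation_bias_test(sub, counts, motif.name)
            except ValueError:
                continue
            orient_rows.append(
                {
                    "gene_set": de_set.name,
                    "motif": motif.name,
                    "fwd": bias.set_fwd,
                    "total": bias.set_total,
                    "fwd_rev_ratio": bias.fwd_rev_ratio,
                    "direction": bias.direction,
                    "p_value": bias.p_value,
                }
            )
    enrichment = pd.DataFrame(
        enrich_rows,
        columns=["gene_set", "phase", "contrast", "direction", "motif",
                 "set_mean", "background_mean", "p_enrichment", "p_depletion"],
    )
    orientation = pd.DataFrame(
        orient_rows,
        columns=["gene_set", "motif", "fwd", "total", "fwd_rev_ratio",
                 "direction", "p_value"],
    )
    density = summarize_density(counts)
    _write_tsv(enrichment, outdir / "enrichment.tsv", index=False)
    _write_tsv(orientation, outdir / "orientation_bias.tsv", index=False)
    _write_tsv(density, outdir / "density.tsv")
    files["enrichment"] = outdir / "enrichment.tsv"
    files["density"] = outdir / "density.tsv"

    # --- stage: motif activity ----------------------------------------------
    logger.info("stage activity: weighted linear motif-activity model")
    shared = [g for g in matrix.genes if g in scanned_genes]
    design = build_design(counts, motifs=[m.name for m in config.motifs], genes=shared)
    fits = {}
    for (phase, name), result in contrasts.items():
        fits[(phase, name)] = fit_motif_activity(
            design, result.log2_ratio.loc[shared], weighting=config.weighting
        )
    activity = activity_table(fits)
    _write_tsv(activity, outdir / "activity.tsv", index=False)
    files["activity"] = outdir / "activity.tsv"

    # --- manifest -------------------------------------------------------------
    manifest = config.manifest_dict()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = outdir / "manifest.json"

    return ReportBundle(
        contrasts=contrasts,
        de_sets=de_sets,
        profiles=profiles,
        clusters=clusters,
        overlaps=overlaps,
        group_responses=group_responses,
        enrichment=enrichment,
        density=density,
        orientation=orientation,
        activity=activity,
        manifest=manifest,
        files=files,
    )
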