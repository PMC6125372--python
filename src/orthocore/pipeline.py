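"""End-to-end orchestration of the comparison and expression-scan stages.

``run_compare`` drives: all-vs-all alignment + filtering -> RBH per genome
pair -> synteny blocks against the reference -> conserved-region-weighted
re-resolution of reference RBH -> families -> presence/absence matrix ->
group cores, sharing calls, locus completeness, ring tracks.
``run_scan`` drives: quantile normalization -> log transform -> outlier
removal -> Welch tests -> sliding-window profile -> category summary.
All outputs are TSV; a manifest records the configuration hash so reruns
are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .core_genome import (classify_all, group_core, locus_completeness_table,
                          presence_matrix, ring_track_export,
                          sharing_calls_frame)
from .expression import (ScanConfig, category_summary, de_results_frame,
                         detect_outlier_samples, differential_expression,
                         log_transform, quantile_normalize,
                         read_expression_tsv, sliding_window_profile,
                         write_expression_tsv)
from .io_formats import (read_genbank_features, read_gff3_with_fasta,
                         read_group_table, read_locus_definitions)
from .model import Genome, GroupTable, LocusDefinition
from .orthology import (OrthologyThresholds, build_families,
                        copy_number_table, genome_pair_hits,
                        reciprocal_best_hits, write_family_tsv,
                        write_hits_tsv, write_rbh_tsv)
from .synteny import (SyntenyConfig, blocks_to_frame, detect_blocks,
                      mark_conserved, resolve_ambiguous)

log = logging.getLogger("orthocore")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative run description (also loadable from YAML via the CLI)."""

    genome_files: list[dict] = field(default_factory=list)
    # each: {"genome_id":..., "gff3":..., "fasta":...} or {"genbank":...}
    group_table: str = ""
    reference_genome_id: str = ""
    locus_definitions: str = ""
    expression_matrix: str = ""
    expression_detected: str = ""
    gene_categories: str = ""
    output_dir: str = "results"
    seed: int = 0
    verbosity: int = 1
    thresholds: OrthologyThresholds = field(default_factory=OrthologyThresholds)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_genomes(config: RunConfig) -> list[Genome]:
    genomes = []
    for entry in config.genome_files:
        if "genbank" in entry:
            genomes.append(read_genbank_features(
                entry["genbank"], genome_id=entry.get("genome_id")))
        else:
            genomes.append(read_gff3_with_fasta(
                entry["gff3"], entry["fasta"],
                genome_id=entry.get("genome_id")))
    return genomes


def _manifest(config: RunConfig, outdir: str, stage: str,
              counts: dict) -> None:
    manifest = {"stage": stage, "orthocore_version": __version__,
                "config_hash": config.config_hash(), "seed": config.seed,
                "counts": counts}
    with open(os.path.join(outdir, f"manifest_{stage}.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def compare_genomes(genomes: list[Genome], groups: GroupTable,
                    loci: list[LocusDefinition] | None = None,
                    thresholds: OrthologyThresholds | None = None,
                    synteny_config: SyntenyConfig | None = None) -> dict:
    """The in-memory comparison pipeline; returns every intermediate."""
    thresholds = thresholds or OrthologyThresholds()
    synteny_config = synteny_config or SyntenyConfig()
    loci = loci or []
    by_id = {g.genome_id: g for g in genomes}
    if groups.reference_genome_id not in by_id:
        raise ValueError("reference genome not supplied")
    for g in genomes:
        g.group_id = groups.group_of(g.genome_id)
    reference = by_id[groups.reference_genome_id]
    ids = sorted(by_id)

    all_hits = {}
    all_rbh = []
    ref_blocks = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            hits = genome_pair_hits(by_id[a], by_id[b], thresholds)
            all_hits[(a, b)] = hits
            pairs = reciprocal_best_hits(by_id[a], by_id[b], hits)
            # conserved-region weighting resolves tied assignments in
            # every genome pair; blocks against the reference also feed
            # the ring tracks
            pair_ref = by_id[a] if a == reference.genome_id else \
                (by_id[b] if b == reference.genome_id else by_id[a])
            pair_other = by_id[b] if pair_ref is by_id[a] else by_id[a]
            pairs = resolve_ambiguous(hits, pairs, pair_ref, pair_other,
                                      synteny_config)
            if reference.genome_id in (a, b):
                other = by_id[b if a == reference.genome_id else a]
                ref_blocks[other.genome_id] = detect_blocks(
                    reference, other, pairs, synteny_config)
                mark_conserved(pairs, ref_blocks[other.genome_id])
            all_rbh.extend(pairs)
            log.info("pair %s-%s: %d filtered hits, %d RBH", a, b,
                     len(hits) // 2, len(pairs))

    gene_genomes = {g.gene_id: genome.genome_id
                    for genome in genomes for g in genome.cds}
    flat_hits = [h for hits in all_hits.values() for h in hits]
    families = build_families(all_rbh, gene_genomes, hits=flat_hits)
    matrix = presence_matrix(families, genomes, reference)
    cores = {gid: group_core(matrix, groups, gid)
             for gid in sorted(groups.groups)}
    calls = classify_all(matrix, groups)
    completeness = locus_completeness_table(loci, matrix)
    conserved = {
        other: {p.gene_a if p.genome_a == reference.genome_id else p.gene_b
                for blocks_pair in [blocks] for blk in blocks_pair
                for p in blk.pairs}
        for other, blocks in ref_blocks.items()}
    tracks, annotations = ring_track_export(matrix, loci, conserved)
    return {"genomes": genomes, "groups": groups, "reference": reference,
            "hits": all_hits, "rbh": all_rbh, "blocks": ref_blocks,
            "families": families, "gene_genomes": gene_genomes,
            "copy_numbers": copy_number_table(families, genomes),
            "matrix": matrix, "cores": cores, "calls": calls,
            "completeness": completeness, "tracks": tracks,
            "annotations": annotations}


def run_compare(config: RunConfig, genomes: list[Genome] | None = None,
                groups: GroupTable | None = None,
                loci: list[LocusDefinition] | None = None) -> dict:
    """File-level comparison run: read inputs, compare, write the bundle."""
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    try:
        genomes = genomes if genomes is not None else load_genomes(config)
        if groups is None:
            groups = read_group_table(config.group_table,
                                      config.reference_genome_id)
        if loci is None:
            loci = read_locus_definitions(config.locus_definitions) \
                if config.locus_definitions else []
    except Exception as exc:
        raise StageError("io", exc) from exc
    if len(genomes) < 2:
        raise StageError("io", ValueError("need at least 2 genomes"))
    try:
        result = compare_genomes(genomes, groups, loci, config.thresholds,
                                 config.synteny)
    except Exception as exc:
        raise StageError("compare", exc) from exc

    write_hits_tsv(os.path.join(outdir, "hits.tsv"),
                   [h for hits in result["hits"].values() for h in hits])
    write_rbh_tsv(os.path.join(outdir, "rbh.tsv"), result["rbh"])
    write_family_tsv(os.path.join(outdir, "families.tsv"),
                     result["families"], result["gene_genomes"])
    blocks_frames = [blocks_to_frame(b) for b in result["blocks"].values()]
    (pd.concat(blocks_frames, ignore_index=True) if blocks_frames
     else blocks_to_frame([])) \
        .to_csv(os.path.join(outdir, "synteny_blocks.tsv"), sep="\t",
                index=False)
    matrix = result["matrix"]
    combined = matrix.presence.astype(int).rename_axis("gene_id")
    combined.to_csv(os.path.join(outdir, "presence_matrix.tsv"), sep="\t")
    matrix.counts.rename_axis("gene_id") \
        .to_csv(os.path.join(outdir, "copy_counts.tsv"), sep="\t")
    pd.DataFrame([(gid, gene) for gid, core in result["cores"].items()
                  for gene in sorted(core)],
                 columns=["group_id", "gene_id"]) \
        .to_csv(os.path.join(outdir, "group_cores.tsv"), sep="\t",
                index=False)
    sharing_calls_frame(result["calls"], result["groups"]) \
        .to_csv(os.path.join(outdir, "sharing_calls.tsv"), sep="\t",
                index=False)
    result["completeness"].to_csv(
        os.path.join(outdir, "locus_completeness.tsv"), sep="\t",
        index=False)
    result["tracks"].to_csv(os.path.join(outdir, "ring_tracks.tsv"),
                            sep="\t", index=False)
    result["annotations"].to_csv(
        os.path.join(outdir, "ring_annotations.tsv"), sep="\t", index=False)
    _manifest(config, outdir, "compare", {
        "genomes": len(genomes),
        "rbh_pairs": len(result["rbh"]),
        "families": len(result["families"]),
        "reference_genes": len(matrix.gene_ids)})
    return result


def scan_expression(matrix, reference_gene_order, config: RunConfig | None
                    = None, gene_category: dict[str, str] | None = None,
                    ) -> dict:
    """The in-memory expression scan; returns every intermediate."""
    scan = (config.scan if config else None) or ScanConfig()
    normalized = quantile_normalize(matrix.values)
    logged = log_transform(normalized, scan.pseudocount)
    outliers = detect_outlier_samples(logged, k=scan.outlier_k)
    working = matrix.__class__(values=logged,
                               conditions=dict(matrix.conditions),
                               detected=matrix.detected.copy())
    if outliers:
        working = working.drop_samples(outliers)
    for cond in ("treatment", "control"):
        if len(working.samples_of(cond)) < 2:
            raise ValueError(
                f"fewer than 2 {cond} replicates after outlier removal")
    de = differential_expression(working, scan)
    profile = sliding_window_profile(de, reference_gene_order, scan)
    summary = category_summary(de, gene_category or {})
    return {"normalized": working, "outliers": outliers, "de": de,
            "profile": profile, "summary": summary}


def run_scan(config: RunConfig, matrix=None,
             reference_gene_order=None) -> dict:
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    try:
        if matrix is None:
            matrix = read_expression_tsv(
                config.expression_matrix,
                config.expression_detected or None)
        if reference_gene_order is None:
            genomes = load_genomes(config)
            ref = next(g for g in genomes
                       if g.genome_id == config.reference_genome_id)
            reference_gene_order = [(g.replicon_id, g.gene_id)
                                    for g in ref.cds]
        gene_category = {}
        if config.gene_categories:
            cat = pd.read_csv(config.gene_categories, sep="\t")
            gene_category = dict(zip(cat.iloc[:, 0], cat.iloc[:, 1]))
    except Exception as exc:
        raise StageError("io", exc) from exc
    try:
        result = scan_expression(matrix, reference_gene_order, config,
                                 gene_category)
    except Exception as exc:
        raise StageError("scan", exc) from exc
    write_expression_tsv(os.path.join(outdir, "normalized_log2.tsv"),
                         result["normalized"])
    with open(os.path.join(outdir, "outlier_samples.txt"), "w") as fh:
        for s in result["outliers"]:
            fh.write(s + "\n")
    de_results_frame(result["de"]).to_csv(
        os.path.join(outdir, "de_results.tsv"), sep="\t", index=False)
    result["profile"].table.to_csv(
        os.path.join(outdir, "window_profile.tsv"), sep="\t", index=False)
    result["summary"].to_csv(
        os.path.join(outdir, "category_summary.tsv"), sep="\t", index=False)
    _manifest(config, outdir, "scan", {
        "samples_kept": len(result["normalized"].values.columns),
        "outliers": len(result["outliers"]),
        "n_up": sum(r.call == "up" for r in result["de"]),
        "n_down": sum(r.call == "down" for r in result["de"])})
    return result
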