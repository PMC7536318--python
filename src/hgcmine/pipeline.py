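"""End-to-end orchestration: screen -> verify -> call loci -> abundance ->
stratify -> place, from one declarative config.

Every stage is available separately through the library modules; this
module wires them together, keeps per-stage record counts consistent, and
writes the machine-readable report (JSON) plus the TSV/GFF3/Newick
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from Bio import SeqIO

from . import abundance as ab
from . import loci as lc
from . import placement as pl
from . import screen as sc
from . import synthetic as syn
from .io import (
    load_count_data,
    load_gene_catalog,
    load_sample_metadata,
)

logger = logging.getLogger("hgcmine")

HGC_TARGETS = ("hgcA", "hgcB")


@dataclass
class PipelineConfig:
    """Declarative run configuration; flags on the CLI override fields."""

    protein_fasta: str
    coords_table: str
    contig_lengths: str | None = None
    counts_tsv: str | None = None
    totals_tsv: str | None = None
    metadata_tsv: str | None = None
    # screening
    screen_source: str = "internal"  # internal | domain_table
    domain_table: str | None = None
    profile_alignments: dict[str, str] = field(default_factory=dict)
    e_threshold: float = 1e-3
    bits_per_column_threshold: float = 0.5
    motif_patterns: dict[str, str] = field(
        default_factory=lambda: {"hgcA": sc.HGCA_MOTIF, "hgcB": sc.HGCB_MOTIF}
    )
    # locus calling
    max_gene_gap: int = 1
    max_bp_gap: int = 500
    require_same_strand: bool = True
    locus_name_prefix: str = "LOC"
    # abundance
    redox_threshold_mL_per_L: float = 2.0
    rarefaction_sample: str | None = None
    rarefaction_depths: list[int] = field(default_factory=list)
    rarefaction_replicates: int = 10
    # placement
    reference_fastas: dict[str, str] = field(default_factory=dict)
    reference_taxonomy: str | None = None
    consensus_threshold: float = 0.75
    long_branch_quantile: float = 0.95
    bootstrap_replicates: int = 0
    seed: int = 0
    output_dir: str = "hgcmine_out"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    n_genes: int = 0
    n_contigs: int = 0
    n_candidates: int = 0
    n_verified: int = 0
    locus_counts: dict[str, int] = field(default_factory=dict)
    n_loci: int = 0
    zone_summaries: list[dict] = field(default_factory=list)
    enrichment: list[dict] = field(default_factory=list)
    assignments: list[dict] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str, sort_keys=True)


def _load_profiles(config: PipelineConfig) -> dict[str, sc.PositionProfile]:
    profiles: dict[str, sc.PositionProfile] = {}
    for target in HGC_TARGETS:
        if target in config.profile_alignments:
            aln = {
                rec.id: str(rec.seq)
                for rec in SeqIO.parse(config.profile_alignments[target], "fasta")
            }
        else:
            # bundled synthetic reference alignment
            aln = syn.reference_alignment(target)
        profiles[target] = sc.build_profile(aln, target)
    return profiles


def _locus_query_sequences(
    loci_list: list[lc.LocusCall], catalog_by_id: dict
) -> dict[str, dict[str, str]]:
    """Per placement mode, the query sequences for each locus."""
    queries: dict[str, dict[str, str]] = {"concat": {}, "hgcA": {}, "hgcB": {}}
    for locus in loci_list:
        if locus.category == "paired_cluster":
            seq = (
                catalog_by_id[locus.hgcA_gene_id].aa_sequence
                + catalog_by_id[locus.hgcB_gene_id].aa_sequence
            )
            queries["concat"][locus.locus_name] = seq
        elif locus.category == "hgcA_only":
            queries["hgcA"][locus.locus_name] = catalog_by_id[
                locus.hgcA_gene_id
            ].aa_sequence
        else:
            queries["hgcB"][locus.locus_name] = catalog_by_id[
                locus.hgcB_gene_id
            ].aa_sequence
    return queries


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all configured stages in order and write outputs."""
    t0 = time.monotonic()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(provenance={"config": dataclasses.asdict(config), "seed": config.seed})

    def stage(name: str) -> None:
        logger.info("[%.1fs] stage: %s", time.monotonic() - t0, name)

    stage("load catalog")
    genes, contigs = load_gene_catalog(
        config.protein_fasta, config.coords_table, config.contig_lengths
    )
    report.n_genes = len(genes)
    report.n_contigs = len(contigs)
    by_id = {g.gene_id: g for g in genes}

    if not genes:
        warnings.warn("empty gene catalog: nothing to screen", stacklevel=2)
        (outdir / "report.json").write_text(report.to_json())
        return report

    stage("screen")
    if config.screen_source == "domain_table":
        hits = sc.screen_candidates(
            genes,
            domain_table=config.domain_table,
            e_threshold=config.e_threshold,
        )
    else:
        hits = sc.screen_candidates(
            genes,
            profiles=_load_profiles(config),
            bits_per_column_threshold=config.bits_per_column_threshold,
        )
    report.n_candidates = len(hits)

    stage("verify")
    motifs = {
        t: sc.compile_motif(p, name=t) for t, p in config.motif_patterns.items()
    }
    verified = sc.verify_candidates(hits, genes, motifs)
    report.n_verified = len(verified)

    stage("call loci")
    loci_list = lc.call_loci(
        verified,
        genes,
        contigs,
        max_gene_gap=config.max_gene_gap,
        max_bp_gap=config.max_bp_gap,
        require_same_strand=config.require_same_strand,
        name_prefix=config.locus_name_prefix,
    )
    summary = lc.summarize_loci(loci_list)
    report.locus_counts = {
        "paired_cluster": summary.n_paired,
        "hgcA_only": summary.n_hgcA_only,
        "hgcB_only": summary.n_hgcB_only,
        "hgcA_genes": summary.n_hgcA_genes,
        "hgcB_genes": summary.n_hgcB_genes,
    }
    report.n_loci = summary.n_loci
    lc.write_loci_tsv(loci_list, outdir / "loci.tsv")
    lc.write_loci_gff3(loci_list, genes, outdir / "loci.gff3")

    if config.counts_tsv and config.totals_tsv and loci_list:
        stage("abundance")
        cm = load_count_data(config.counts_tsv, config.totals_tsv)
        records = ab.compute_abundance(cm, loci_list)
        per_locus = ab.compute_abundance(cm, loci_list, per_locus=True)
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "key": r.key,
                    "relative_abundance_pct": r.relative_abundance_pct,
                    "display_units_1e3": r.display_units_1e3,
                }
                for r in records + per_locus
            ]
        ).to_csv(outdir / "abundance.tsv", sep="\t", index=False)

        if config.metadata_tsv:
            stage("stratify")
            meta = load_sample_metadata(config.metadata_tsv)
            zones = ab.classify_all(meta, config.redox_threshold_mL_per_L)
            summaries = ab.summarize_by_zone(records, zones)
            report.zone_summaries = [dataclasses.asdict(s) for s in summaries]
            ab.zone_summary_frame(summaries).to_csv(
                outdir / "zone_summary.tsv", sep="\t", index=False
            )
            enrich = ab.fraction_enrichment(records, meta)
            report.enrichment = enrich.to_dict(orient="records")
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        if config.rarefaction_sample and config.rarefaction_depths:
            stage("rarefy")
            curve = ab.rarefaction(
                cm,
                loci_list,
                config.rarefaction_sample,
                config.rarefaction_depths,
                replicates=config.rarefaction_replicates,
                seed=config.seed,
            )
            curve.to_csv(outdir / "rarefaction.tsv", sep="\t", index=False)

    if config.reference_fastas and config.reference_taxonomy and loci_list:
        stage("place")
        refs = pl.load_reference_set(
            config.reference_fastas, config.reference_taxonomy
        )
        queries_by_mode = _locus_query_sequences(loci_list, by_id)
        all_assignments: list[pl.TaxonAssignment] = []
        for mode, queries in queries_by_mode.items():
            if not queries:
                continue
            usable = [r for r in refs if r.sequence(mode) is not None]
            if len(usable) < 2:
                warnings.warn(
                    f"too few references with {mode} sequences; placement skipped",
                    stacklevel=2,
                )
                continue
            dm = pl.compute_distances(queries, usable, mode=mode)
            tree = pl.nj_tree(dm, seed=config.seed)
            pl.write_newick(tree, outdir / f"tree_{mode}.nwk")
            all_assignments.extend(
                pl.assign_taxonomy(
                    tree,
                    dm,
                    usable,
                    sorted(queries),
                    consensus_threshold=config.consensus_threshold,
                    long_branch_quantile=config.long_branch_quantile,
                )
            )
        report.assignments = pl.assignments_to_frame(all_assignments).to_dict(
            orient="records"
        )
        pl.assignments_to_frame(all_assignments).to_csv(
            outdir / "assignments.tsv", sep="\t", index=False
        )

    # stage-count consistency
    genes_in_loci = summary.n_hgcA_genes + summary.n_hgcB_genes
    assert report.n_candidates >= report.n_verified >= genes_in_loci

    (outdir / "report.json").write_text(report.to_json())
    stage("done")
    return report
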