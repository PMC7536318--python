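"""Contig-aware locus calling for verified hgcA/hgcB candidates.

Verified genes are grouped into named loci: an hgcA and an hgcB found
side-by-side on one contig become a paired cluster (the canonical two-gene
operon of Hg methylators); leftover hgcA become lone-hgcA loci, where an
edge-truncated ORF explains the missing partner; leftover hgcB become
lone-hgcB loci, flagged when they sit in the central portion of their
contig (so a neighbouring hgcA cannot have been lost to assembly
truncation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import ContigRecord, GeneRecord
from .screen import CandidateHit


class LocusError(ValueError):
    pass


@dataclass
class LocusCall:
    locus_name: str
    category: str  # paired_cluster | hgcA_only | hgcB_only
    contig_id: str
    hgcA_gene_id: str | None = None
    hgcB_gene_id: str | None = None
    hgcA_motif: str | None = None
    hgcB_motif: str | None = None
    hgcA_truncated_at_edge: bool = False
    hgcB_central: bool = False
    hgcB_downstream_of_hgcA: bool | None = None
    intergenic_bp: int | None = None

    def gene_ids(self) -> list[str]:
        return [g for g in (self.hgcA_gene_id, self.hgcB_gene_id) if g is not None]


@dataclass
class LocusSummary:
    n_paired: int = 0
    n_hgcA_only: int = 0
    n_hgcB_only: int = 0
    n_hgcA_genes: int = 0
    n_hgcB_genes: int = 0
    motif_combinations: Counter = field(default_factory=Counter)
    n_hgcA_truncated: int = 0
    n_hgcB_central: int = 0

    @property
    def n_loci(self) -> int:
        return self.n_paired + self.n_hgcA_only + self.n_hgcB_only


def _intergenic_gap(a: GeneRecord, b: GeneRecord) -> int:
    first, second = (a, b) if a.start_bp <= b.start_bp else (b, a)
    return max(0, second.start_bp - first.end_bp - 1)


def call_loci(
    verified: Sequence[CandidateHit],
    catalog: Sequence[GeneRecord],
    contigs: Sequence[ContigRecord],
    max_gene_gap: int = 1,
    max_bp_gap: int = 500,
    require_same_strand: bool = True,
    name_prefix: str = "LOC",
) -> list[LocusCall]:
    """Group verified hits into named loci.

    Pairing is greedy by ascending intergenic distance (ties broken by gene
    id pair), each gene used at most once; candidate pairs must share a
    contig, sit within ``max_gene_gap`` gene ranks and ``max_bp_gap``
    intergenic base pairs, and (by default) lie on the same strand. Naming
    is ordinal with zero padding: paired clusters first, then lone hgcA,
    then lone hgcB, each block sorted by (contig_id, start_bp).
    """
    by_id = {g.gene_id: g for g in catalog}
    for hit in verified:
        if hit.gene_id not in by_id:
            raise LocusError(f"verified hit references unknown gene {hit.gene_id}")

    a_hits = sorted(
        (h for h in verified if h.target == "hgcA"), key=lambda h: h.gene_id
    )
    b_hits = sorted(
        (h for h in verified if h.target == "hgcB"), key=lambda h: h.gene_id
    )
    a_by_gene = {h.gene_id: h for h in a_hits}
    b_by_gene = {h.gene_id: h for h in b_hits}

    # enumerate admissible pairs, then greedily take the closest first
    pairs: list[tuple[int, str, str]] = []
    for ha in a_hits:
        ga = by_id[ha.gene_id]
        for hb in b_hits:
            if ha.gene_id == hb.gene_id:
                continue
            gb = by_id[hb.gene_id]
            if ga.contig_id != gb.contig_id:
                continue
            if abs(ga.gene_index - gb.gene_index) > max_gene_gap:
                continue
            gap = _intergenic_gap(ga, gb)
            if gap > max_bp_gap:
                continue
            if require_same_strand and ga.strand != gb.strand:
                continue
            pairs.append((gap, ha.gene_id, hb.gene_id))
    pairs.sort()

    used: set[str] = set()
    paired: list[LocusCall] = []
    for gap, a_id, b_id in pairs:
        if a_id in used or b_id in used:
            continue
        used.add(a_id)
        used.add(b_id)
        ga, gb = by_id[a_id], by_id[b_id]
        downstream = (
            gb.start_bp > ga.start_bp if ga.strand == "+" else gb.start_bp < ga.start_bp
        )
        paired.append(
            LocusCall(
                locus_name="",
                category="paired_cluster",
                contig_id=ga.contig_id,
                hgcA_gene_id=a_id,
                hgcB_gene_id=b_id,
                hgcA_motif=a_by_gene[a_id].motif_match,
                hgcB_motif=b_by_gene[b_id].motif_match,
                hgcA_truncated_at_edge=ga.at_contig_extremity,
                hgcB_downstream_of_hgcA=downstream,
                intergenic_bp=gap,
            )
        )

    lone_a: list[LocusCall] = []
    for ha in a_hits:
        if ha.gene_id in used:
            continue
        g = by_id[ha.gene_id]
        lone_a.append(
            LocusCall(
                locus_name="",
                category="hgcA_only",
                contig_id=g.contig_id,
                hgcA_gene_id=ha.gene_id,
                hgcA_motif=ha.motif_match,
                hgcA_truncated_at_edge=g.at_contig_extremity,
            )
        )
    lone_b: list[LocusCall] = []
    for hb in b_hits:
        if hb.gene_id in used:
            continue
        g = by_id[hb.gene_id]
        lone_b.append(
            LocusCall(
                locus_name="",
                category="hgcB_only",
                contig_id=g.contig_id,
                hgcB_gene_id=hb.gene_id,
                hgcB_motif=hb.motif_match,
                hgcB_central=not g.at_contig_extremity,
            )
        )

    def sort_key(locus: LocusCall):
        gid = locus.hgcA_gene_id or locus.hgcB_gene_id
        return (locus.contig_id, by_id[gid].start_bp, gid)

    loci = sorted(paired, key=sort_key) + sorted(lone_a, key=sort_key) + sorted(
        lone_b, key=sort_key
    )
    width = max(2, len(str(len(loci))))
    for i, locus in enumerate(loci, start=1):
        locus.locus_name = f"{name_prefix}-{i:0{width}d}"
    return loci


def summarize_loci(loci: Sequence[LocusCall]) -> LocusSummary:
    summary = LocusSummary()
    seen: set[str] = set()
    for locus in loci:
        for gid in locus.gene_ids():
            if gid in seen:
                raise LocusError(f"gene {gid} appears in more than one locus")
            seen.add(gid)
        if locus.category == "paired_cluster":
            summary.n_paired += 1
            summary.motif_combinations[(locus.hgcA_motif, locus.hgcB_motif)] += 1
        elif locus.category == "hgcA_only":
            summary.n_hgcA_only += 1
        elif locus.category == "hgcB_only":
            summary.n_hgcB_only += 1
        else:
            raise LocusError(f"unknown locus category {locus.category!r}")
        if locus.hgcA_gene_id is not None:
            summary.n_hgcA_genes += 1
            summary.n_hgcA_truncated += locus.hgcA_truncated_at_edge
        if locus.hgcB_gene_id is not None:
            summary.n_hgcB_genes += 1
        summary.n_hgcB_central += locus.hgcB_central
    return summary


def loci_to_frame(loci: Sequence[LocusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_name": l.locus_name,
                "category": l.category,
                "contig_id": l.contig_id,
                "hgcA_gene_id": l.hgcA_gene_id,
                "hgcB_gene_id": l.hgcB_gene_id,
                "hgcA_motif": l.hgcA_motif,
                "hgcB_motif": l.hgcB_motif,
                "hgcA_truncated_at_edge": l.hgcA_truncated_at_edge,
                "hgcB_central": l.hgcB_central,
                "hgcB_downstream_of_hgcA": l.hgcB_downstream_of_hgcA,
                "intergenic_bp": l.intergenic_bp,
            }
            for l in loci
        ]
    )


def write_loci_tsv(loci: Sequence[LocusCall], path: str | Path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def write_loci_gff3(
    loci: Sequence[LocusCall], catalog: Sequence[GeneRecord], path: str | Path
) -> None:
    """Emit called loci as a GFF3 feature track (one feature per member gene)."""
    by_id = {g.gene_id: g for g in catalog}
    lines = ["##gff-version 3"]
    for locus in loci:
        for target, gid in (("hgcA", locus.hgcA_gene_id), ("hgcB", locus.hgcB_gene_id)):
            if gid is None:
                continue
            g = by_id[gid]
            attrs = f"ID={gid};locus={locus.locus_name};target={target};category={locus.category}"
            lines.append(
                "\t".join(
                    [
                        g.contig_id,
                        "hgcmine",
                        "CDS",
                        str(g.start_bp),
                        str(g.end_bp),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
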