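"""Input surfaces for the gene-catalog mining pipeline.

Three surfaces are read into a shared data model:

* a predicted-protein catalog (amino-acid FASTA) joined to gene coordinates
  (GFF3 CDS features or a tab-separated coordinate table),
* a per-sample gene read-count matrix with per-sample total annotated reads,
* a sample metadata table (station, date, depth, oxygen, filter fractions).

Coordinates are 1-based and inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}

METADATA_COLUMNS = [
    "sample_id",
    "station",
    "date",
    "depth_m",
    "o2_detected",
    "o2_mL_per_L",
    "filter_um",
    "prefilter_um",
    "dataset",
]


class CatalogError(ValueError):
    """Raised when an input surface violates the data-model invariants."""


@dataclass
class GeneRecord:
    """One predicted protein with its contig placement.

    ``partial_flags`` is ``(five_prime_truncated, three_prime_truncated)``,
    true when the ORF is cut at a contig boundary.
    """

    gene_id: str
    contig_id: str
    start_bp: int
    end_bp: int
    strand: str
    gene_index: int
    aa_sequence: str
    partial_flags: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise CatalogError(
                f"gene {self.gene_id}: invalid coordinates "
                f"[{self.start_bp}, {self.end_bp}]"
            )
        if self.strand not in {"+", "-"}:
            raise CatalogError(f"gene {self.gene_id}: strand must be + or -")
        if not self.aa_sequence:
            raise CatalogError(f"gene {self.gene_id}: empty amino-acid sequence")
        bad = set(self.aa_sequence.upper()) - AA_ALPHABET_X
        if bad:
            raise CatalogError(
                f"gene {self.gene_id}: non-amino-acid characters {sorted(bad)}"
            )
        self.aa_sequence = self.aa_sequence.upper()

    @property
    def at_contig_extremity(self) -> bool:
        return self.partial_flags[0] or self.partial_flags[1]


@dataclass
class ContigRecord:
    contig_id: str
    length_bp: int
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise CatalogError(f"contig {self.contig_id}: non-positive length")


@dataclass
class SampleMetadata:
    """Descriptors of one metagenome sample.

    ``o2_mL_per_L`` is meaningful only when ``o2_detected`` is true; "no
    detectable O2" is an explicit flag, never inferred from a 0.0 reading,
    because detection limits vary between instruments and cruises.
    """

    sample_id: str
    station: str
    date: _dt.date
    depth_m: float
    o2_detected: bool
    o2_mL_per_L: float | None
    filter_um: float
    prefilter_um: float | None
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise CatalogError(f"sample {self.sample_id}: negative depth")
        if not self.o2_detected:
            self.o2_mL_per_L = None
        elif self.o2_mL_per_L is None or self.o2_mL_per_L < 0:
            raise CatalogError(
                f"sample {self.sample_id}: o2_detected requires a non-negative "
                "O2 concentration"
            )
        if self.filter_um <= 0:
            raise CatalogError(f"sample {self.sample_id}: filter_um must be > 0")
        if self.prefilter_um is not None and self.prefilter_um <= 0:
            raise CatalogError(f"sample {self.sample_id}: prefilter_um must be > 0")


class CountMatrix:
    """Per-(gene, sample) read counts plus per-sample total annotated reads.

    Backed by an integer pandas DataFrame (genes as rows) and a totals Series.
    """

    def __init__(self, counts: pd.DataFrame, total_annotated_reads: pd.Series):
        counts = counts.copy()
        totals = total_annotated_reads.astype("int64").copy()
        if list(counts.columns) != list(totals.index):
            raise CatalogError("count columns and totals index disagree")
        if counts.index.duplicated().any():
            raise CatalogError("duplicate gene_id in count matrix")
        if (counts.to_numpy() < 0).any():
            raise CatalogError("negative read count")
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise CatalogError(f"samples with non-positive totals: {bad}")
        if (counts.gt(totals, axis=1)).any().any():
            raise CatalogError("count exceeds total annotated reads for its sample")
        self.counts = counts.astype("int64")
        self.total_annotated_reads = totals

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.total_annotated_reads.equals(
            other.total_annotated_reads
        )


# ---------------------------------------------------------------------------
# gene catalog


def _read_coords_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "contig_id", "start", "end", "strand", "partial"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"coordinate table {path}: missing columns {missing}")
    return df


def _read_coords_gff3(path: Path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Parse CDS features and ``##sequence-region`` pragmas from a GFF3 file."""
    rows = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9 or cols[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise CatalogError(f"GFF3 {path}: CDS without ID attribute")
            partial = attrs.get("partial", "00")
            rows.append(
                {
                    "gene_id": attrs["ID"],
                    "contig_id": cols[0],
                    "start": cols[3],
                    "end": cols[4],
                    "strand": cols[6],
                    "partial": partial,
                }
            )
    return pd.DataFrame(rows), lengths


def load_gene_catalog(
    protein_fasta: str | Path,
    coords_table: str | Path,
    contig_lengths: str | Path | None = None,
) -> tuple[list[GeneRecord], list[ContigRecord]]:
    """Join an amino-acid FASTA to gene coordinates.

    ``coords_table`` is either a GFF3 file (CDS features, ``ID`` attribute
    holding the gene id, optional ``partial`` attribute) or a six-column TSV
    ``gene_id, contig_id, start, end, strand, partial`` where ``partial`` is a
    two-character flag (``10`` = 5'-truncated, ``01`` = 3'-truncated).

    Contig lengths come from, in order of preference: the optional
    ``contig_lengths`` TSV (``contig_id, length_bp``), GFF3 sequence-region
    pragmas, or the maximum gene end on each contig. Truncation flags combine
    the explicit ``partial`` annotation with coincidence of the gene with a
    contig boundary.
    """
    protein_fasta = Path(protein_fasta)
    coords_table = Path(coords_table)

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(protein_fasta), "fasta"):
        if rec.id in seqs:
            raise CatalogError(f"duplicate gene_id in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).rstrip("*")

    pragma_lengths: dict[str, int] = {}
    first = coords_table.read_text().lstrip().splitlines()
    is_gff = bool(first) and (first[0].startswith("##gff-version"))
    if is_gff:
        coords, pragma_lengths = _read_coords_gff3(coords_table)
    else:
        coords = _read_coords_tsv(coords_table)

    if coords["gene_id"].duplicated().any():
        dups = sorted(coords.loc[coords["gene_id"].duplicated(), "gene_id"])
        raise CatalogError(f"duplicate gene_id in coordinates: {dups}")

    fasta_ids = set(seqs)
    coord_ids = set(coords["gene_id"])
    only_fasta = sorted(fasta_ids - coord_ids)
    if only_fasta:
        raise CatalogError(f"genes in FASTA but not in coordinates: {only_fasta}")
    only_coords = sorted(coord_ids - fasta_ids)
    if only_coords:
        raise CatalogError(f"genes in coordinates but not in FASTA: {only_coords}")

    lengths: dict[str, int] = dict(pragma_lengths)
    if contig_lengths is not None:
        lt = pd.read_csv(contig_lengths, sep="\t", dtype={"contig_id": str})
        lengths.update(
            dict(zip(lt["contig_id"].astype(str), lt["length_bp"].astype(int)))
        )

    coords = coords.assign(
        start=coords["start"].astype(int), end=coords["end"].astype(int)
    )
    inferred = coords.groupby("contig_id")["end"].max().to_dict()
    for cid, end in inferred.items():
        lengths.setdefault(str(cid), int(end))

    genes: list[GeneRecord] = []
    contigs: dict[str, ContigRecord] = {}
    for contig_id, group in coords.groupby("contig_id", sort=True):
        contig_id = str(contig_id)
        clen = lengths[contig_id]
        group = group.sort_values(["start", "end", "gene_id"], kind="stable")
        contig = ContigRecord(contig_id=contig_id, length_bp=clen)
        for idx, row in enumerate(group.itertuples(index=False)):
            if row.end > clen:
                raise CatalogError(
                    f"gene {row.gene_id}: end {row.end} beyond contig "
                    f"{contig_id} length {clen}"
                )
            partial = str(row.partial) if not _is_na(row.partial) else "00"
            partial = partial.zfill(2)
            five = partial[0] == "1" or row.start == 1
            three = partial[1] == "1" or row.end == clen
            genes.append(
                GeneRecord(
                    gene_id=row.gene_id,
                    contig_id=contig_id,
                    start_bp=int(row.start),
                    end_bp=int(row.end),
                    strand=row.strand,
                    gene_index=idx,
                    aa_sequence=seqs[row.gene_id],
                    partial_flags=(five, three),
                )
            )
            contig.gene_ids.append(row.gene_id)
        contigs[contig_id] = contig

    return genes, list(contigs.values())


def _is_na(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def write_gene_catalog(
    genes: Sequence[GeneRecord],
    contigs: Sequence[ContigRecord],
    protein_fasta: str | Path,
    coords_table: str | Path,
    contig_lengths: str | Path,
) -> None:
    """Emit the FASTA + coordinate TSV + contig-length TSV surfaces."""
    records = [
        SeqRecord(Seq(g.aa_sequence), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, str(protein_fasta), "fasta")
    rows = [
        {
            "gene_id": g.gene_id,
            "contig_id": g.contig_id,
            "start": g.start_bp,
            "end": g.end_bp,
            "strand": g.strand,
            "partial": f"{int(g.partial_flags[0])}{int(g.partial_flags[1])}",
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(coords_table, sep="\t", index=False)
    pd.DataFrame(
        [{"contig_id": c.contig_id, "length_bp": c.length_bp} for c in contigs]
    ).to_csv(contig_lengths, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts


def load_count_data(counts_tsv: str | Path, totals_tsv: str | Path) -> CountMatrix:
    """Read the gene x sample count TSV and the per-sample totals TSV."""
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    totals_df = pd.read_csv(totals_tsv, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "total_annotated_reads"):
        if col not in totals_df.columns:
            raise CatalogError(f"totals table missing column {col}")
    totals = totals_df.set_index("sample_id")["total_annotated_reads"]
    if set(counts.columns) != set(totals.index):
        raise CatalogError("sample columns differ between counts and totals")
    totals = totals.reindex(counts.columns)
    return CountMatrix(counts, totals)


def write_count_data(
    cm: CountMatrix, counts_tsv: str | Path, totals_tsv: str | Path
) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_tsv, sep="\t")
    cm.total_annotated_reads.rename("total_annotated_reads").rename_axis(
        "sample_id"
    ).reset_index().to_csv(totals_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata


def load_sample_metadata(metadata_tsv: str | Path) -> list[SampleMetadata]:
    """Read the sample manifest (one row per metagenome)."""
    df = pd.read_csv(metadata_tsv, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns and c != "dataset"]
    if missing:
        raise CatalogError(f"metadata missing required columns: {missing}")
    out: list[SampleMetadata] = []
    for i, row in df.iterrows():
        detected = str(row["o2_detected"]).strip().lower() in {"true", "1", "yes"}
        o2: float | None = None
        if detected:
            try:
                o2 = float(row["o2_mL_per_L"])
            except (TypeError, ValueError):
                raise CatalogError(
                    f"metadata row {i} (sample {row['sample_id']}): "
                    f"unparseable O2 value {row['o2_mL_per_L']!r}"
                ) from None
        prefilter = None if _is_na(row["prefilter_um"]) else float(row["prefilter_um"])
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                station=str(row["station"]),
                date=_dt.date.fromisoformat(str(row["date"])),
                depth_m=float(row["depth_m"]),
                o2_detected=detected,
                o2_mL_per_L=o2,
                filter_um=float(row["filter_um"]),
                prefilter_um=prefilter,
                dataset=str(row.get("dataset", "")) if "dataset" in df.columns else "",
            )
        )
    ids = [m.sample_id for m in out]
    if len(ids) != len(set(ids)):
        raise CatalogError("duplicate sample_id in metadata")
    return out


def write_sample_metadata(
    samples: Iterable[SampleMetadata], metadata_tsv: str | Path
) -> None:
    rows = []
    for m in samples:
        rows.append(
            {
                "sample_id": m.sample_id,
                "station": m.station,
                "date": m.date.isoformat(),
                "depth_m": m.depth_m,
                "o2_detected": str(m.o2_detected).lower(),
                "o2_mL_per_L": "" if m.o2_mL_per_L is None else m.o2_mL_per_L,
                "filter_um": m.filter_um,
                "prefilter_um": "" if m.prefilter_um is None else m.prefilter_um,
                "dataset": m.dataset,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_tsv, sep="\t", index=False
    )
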