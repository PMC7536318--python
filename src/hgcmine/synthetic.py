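"""Synthetic survey generator: every pipeline stage testable without downloads.

Two generators are provided. :func:`build_figure2_fixture` is deterministic
and reproduces the published locus arrangement of the Baltic Sea survey it
emulates — nine contigs carrying an adjacent same-strand hgcA+hgcB pair,
thirteen contigs with a lone edge-truncated hgcA, three contigs with a lone
central hgcB — plus motif-broken decoys and random background genes.
:func:`simulate_survey` layers a statistical survey on top: negative-binomial
read counts whose expected summed hgc abundance follows a per-redox-zone
effect (anoxic > hypoxic > normoxic), and a particle-fraction enrichment
factor for 3 um filter samples.

All bundled sequence material is synthetic consensus-like sequence built
from a seeded generator, not copied database records.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    ContigRecord,
    CountMatrix,
    GeneRecord,
    SampleMetadata,
    write_count_data,
    write_gene_catalog,
    write_sample_metadata,
)
from .placement import ReferenceEntry
from .screen import default_motifs, scan_motif

import pandas as pd

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# anchor positions of the conserved motifs inside the synthetic consensus
HGCA_LEN = 280
HGCA_MOTIF_START = 90  # 0-based
HGCB_LEN = 96
HGCB_MOTIF_START = 30

_CONSENSUS_SEED = 20


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def hgca_consensus(variant: str = "A") -> str:
    """Synthetic hgcA-like consensus carrying NVWCA(A/G/S)GK at a fixed site."""
    rng = np.random.default_rng(_CONSENSUS_SEED)
    seq = list(_random_protein(rng, HGCA_LEN))
    motif = f"NVWCA{variant}GK"
    seq[HGCA_MOTIF_START : HGCA_MOTIF_START + len(motif)] = list(motif)
    return "".join(seq)


def hgcb_consensus(variant: str = "M") -> str:
    """Synthetic hgcB-like consensus carrying C(M/I)EC(G/S)(A/G)C."""
    rng = np.random.default_rng(_CONSENSUS_SEED + 1)
    seq = list(_random_protein(rng, HGCB_LEN))
    motif = f"C{variant}ECGAC"
    seq[HGCB_MOTIF_START : HGCB_MOTIF_START + len(motif)] = list(motif)
    return "".join(seq)


def mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: range | None = None,
) -> str:
    """Point-mutate ``seq`` at the given per-residue rate.

    Positions in ``protected`` (the motif window of a true positive) are
    never touched, keeping the ground truth well defined.
    """
    chars = list(seq)
    protected_set = set(protected) if protected is not None else set()
    for i in range(len(chars)):
        if i in protected_set:
            continue
        if rng.random() < rate:
            choices = [c for c in _ALPHABET if c != chars[i]]
            chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def reference_alignment(target: str, n: int = 8, rate: float = 0.08) -> dict[str, str]:
    """Bundled reference alignment used to build the internal screen profile.

    Equal-length, ungapped variants of the synthetic consensus with the
    motif window protected; deterministic.
    """
    rng = np.random.default_rng(_CONSENSUS_SEED + (2 if target == "hgcA" else 3))
    if target == "hgcA":
        base = hgca_consensus()
        protected = range(HGCA_MOTIF_START, HGCA_MOTIF_START + 8)
    elif target == "hgcB":
        base = hgcb_consensus()
        protected = range(HGCB_MOTIF_START, HGCB_MOTIF_START + 7)
    else:
        raise ValueError(f"unknown target {target!r}")
    return {
        f"{target}_ref_{i:02d}": mutate(base, rate, rng, protected)
        for i in range(n)
    }


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    gene_roles: dict[str, str] = field(default_factory=dict)  # gene_id -> role
    locus_plan: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def hgcA_gene_ids(self) -> list[str]:
        return sorted(g for g, r in self.gene_roles.items() if r == "hgcA")

    @property
    def hgcB_gene_ids(self) -> list[str]:
        return sorted(g for g, r in self.gene_roles.items() if r == "hgcB")

    @property
    def hgc_gene_ids(self) -> list[str]:
        return sorted(self.hgcA_gene_ids + self.hgcB_gene_ids)

    @property
    def decoy_gene_ids(self) -> list[str]:
        return sorted(g for g, r in self.gene_roles.items() if r == "decoy")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "gene_roles": self.gene_roles,
                    "locus_plan": self.locus_plan,
                    "params": self.params,
                },
                indent=1,
                default=str,
            )
        )


# ---------------------------------------------------------------------------
# figure-2 fixture

# (hgcA motif variant residue, hgcB motif variant residue) per paired locus,
# contigs in lexicographic order: clusters 1 and 9 carry NVWCASGK+CIECGAC,
# cluster 7 NVWCAAGK+CIECGAC, the remainder the common NVWCAAGK+CMECGAC.
_PAIR_VARIANTS = [
    ("S", "I"),  # cluster 01
    ("A", "M"),
    ("A", "M"),
    ("A", "M"),
    ("A", "M"),
    ("A", "M"),
    ("A", "I"),  # cluster 07
    ("A", "M"),
    ("S", "I"),  # cluster 09
]

_GENE_GAP_BP = 80
_CONTIG_MARGIN_BP = 150


class _ContigBuilder:
    """Lays genes left-to-right on one contig, 1-based inclusive coords."""

    def __init__(self, contig_id: str):
        self.contig_id = contig_id
        self.genes: list[GeneRecord] = []
        self._cursor = _CONTIG_MARGIN_BP + 1
        self._starts_at_edge = False
        self._ends_at_edge = False

    def add(
        self,
        gene_id: str,
        aa: str,
        strand: str = "+",
        partial: tuple[bool, bool] = (False, False),
    ) -> None:
        if partial[0]:  # 5'-truncated genes begin at the contig boundary
            if self.genes:
                raise ValueError("5'-truncated gene must be first on its contig")
            self._cursor = 1
            self._starts_at_edge = True
        start = self._cursor
        end = start + 3 * len(aa) - 1
        self.genes.append(
            GeneRecord(
                gene_id=gene_id,
                contig_id=self.contig_id,
                start_bp=start,
                end_bp=end,
                strand=strand,
                gene_index=len(self.genes),
                aa_sequence=aa,
                partial_flags=partial,
            )
        )
        if partial[1]:
            self._ends_at_edge = True
        self._cursor = end + 1 + _GENE_GAP_BP

    def finish(self) -> tuple[ContigRecord, list[GeneRecord]]:
        last_end = self.genes[-1].end_bp
        length = last_end if self._ends_at_edge else last_end + _CONTIG_MARGIN_BP
        contig = ContigRecord(
            contig_id=self.contig_id,
            length_bp=length,
            gene_ids=[g.gene_id for g in self.genes],
        )
        return contig, self.genes


def build_figure2_fixture(
    n_decoys: int = 120,
    n_background: int = 150,
    mutation_rate: float = 0.02,
    decoy_mutation_rate: float = 0.08,
) -> tuple[list[GeneRecord], list[ContigRecord], GroundTruth]:
    """Deterministic catalog reproducing the published locus arrangement.

    Nine paired-cluster contigs (motif variants per :data:`_PAIR_VARIANTS`),
    thirteen lone-hgcA contigs with the hgcA ORF truncated at a contig edge,
    three lone-hgcB contigs with the hgcB gene central, plus motif-broken
    decoys and random background genes. Two invocations produce identical
    records.
    """
    rng = np.random.default_rng(_CONSENSUS_SEED + 10)
    a_protect = range(HGCA_MOTIF_START, HGCA_MOTIF_START + 8)
    b_protect = range(HGCB_MOTIF_START, HGCB_MOTIF_START + 7)

    genes: list[GeneRecord] = []
    contigs: list[ContigRecord] = []
    truth = GroundTruth(
        params={
            "n_decoys": n_decoys,
            "n_background": n_background,
            "mutation_rate": mutation_rate,
        }
    )

    def bg_gene(builder: _ContigBuilder, gene_id: str) -> None:
        length = int(rng.integers(80, 350))
        builder.add(gene_id, _random_protein(rng, length))
        truth.gene_roles[gene_id] = "background"

    # nine paired clusters
    for k, (va, vb) in enumerate(_PAIR_VARIANTS, start=1):
        builder = _ContigBuilder(f"ctgP{k:02d}")
        bg_gene(builder, f"P{k:02d}_g0")
        a_id, b_id = f"P{k:02d}_hgcA", f"P{k:02d}_hgcB"
        a_seq = mutate(hgca_consensus(va), mutation_rate, rng, a_protect)
        b_seq = mutate(hgcb_consensus(vb), mutation_rate, rng, b_protect)
        builder.add(a_id, a_seq, strand="+")
        builder.add(b_id, b_seq, strand="+")
        bg_gene(builder, f"P{k:02d}_g3")
        truth.gene_roles[a_id] = "hgcA"
        truth.gene_roles[b_id] = "hgcB"
        truth.locus_plan.append(
            {
                "category": "paired_cluster",
                "contig_id": builder.contig_id,
                "hgcA_gene_id": a_id,
                "hgcB_gene_id": b_id,
                "hgcA_motif": f"NVWCA{va}GK",
                "hgcB_motif": f"C{vb}ECGAC",
            }
        )
        contig, g = builder.finish()
        contigs.append(contig)
        genes.extend(g)

    # thirteen lone hgcA, each truncated at a contig edge
    for k in range(1, 14):
        builder = _ContigBuilder(f"ctgA{k:02d}")
        a_id = f"A{k:02d}_hgcA"
        full = mutate(hgca_consensus("A"), mutation_rate, rng, a_protect)
        if k % 2 == 0:
            # 5'-truncated: leading residues lost at the left contig edge
            seq = full[60:]
            builder.add(a_id, seq, partial=(True, False))
            bg_gene(builder, f"A{k:02d}_g1")
        else:
            # 3'-truncated: gene runs into the right contig edge
            bg_gene(builder, f"A{k:02d}_g0")
            seq = full[:210]
            builder.add(a_id, seq, partial=(False, True))
        truth.gene_roles[a_id] = "hgcA"
        truth.locus_plan.append(
            {
                "category": "hgcA_only",
                "contig_id": builder.contig_id,
                "hgcA_gene_id": a_id,
                "hgcA_motif": "NVWCAAGK",
            }
        )
        contig, g = builder.finish()
        contigs.append(contig)
        genes.extend(g)

    # three lone hgcB, central on their contigs
    for k in range(1, 4):
        builder = _ContigBuilder(f"ctgB{k:02d}")
        bg_gene(builder, f"B{k:02d}_g0")
        b_id = f"B{k:02d}_hgcB"
        builder.add(b_id, mutate(hgcb_consensus("M"), mutation_rate, rng, b_protect))
        bg_gene(builder, f"B{k:02d}_g2")
        truth.gene_roles[b_id] = "hgcB"
        truth.locus_plan.append(
            {
                "category": "hgcB_only",
                "contig_id": builder.contig_id,
                "hgcB_gene_id": b_id,
                "hgcB_motif": "CMECGAC",
            }
        )
        contig, g = builder.finish()
        contigs.append(contig)
        genes.extend(g)

    # motif-broken decoys: profile-similar, must fail verification
    for k in range(n_decoys):
        builder = _ContigBuilder(f"ctgD{k:03d}")
        d_id = f"D{k:03d}_decoy"
        if k % 2 == 0:
            seq = list(mutate(hgca_consensus("A"), decoy_mutation_rate, rng, a_protect))
            seq[HGCA_MOTIF_START + 3] = "L"  # break the invariant motif cysteine
        else:
            seq = list(mutate(hgcb_consensus("M"), decoy_mutation_rate, rng, b_protect))
            seq[HGCB_MOTIF_START + 3] = "L"
        seq = "".join(seq)
        for motif in default_motifs().values():
            assert not scan_motif(motif, seq), "decoy accidentally carries a motif"
        builder.add(d_id, seq)
        truth.gene_roles[d_id] = "decoy"
        contig, g = builder.finish()
        contigs.append(contig)
        genes.extend(g)

    # random-composition background on multi-gene contigs
    per_contig = 3
    for k in range(0, n_background, per_contig):
        builder = _ContigBuilder(f"ctgN{k // per_contig:03d}")
        for j in range(min(per_contig, n_background - k)):
            bg_gene(builder, f"N{k + j:03d}_bg")
        contig, g = builder.finish()
        contigs.append(contig)
        genes.extend(g)

    assert len(truth.hgcA_gene_ids) == 22 and len(truth.hgcB_gene_ids) == 12
    return genes, contigs, truth


# ---------------------------------------------------------------------------
# reference fixture for placement


def build_reference_fixture(
    n_families: int = 5,
    n_per_family: int = 4,
    seed: int = 101,
    family_divergence: float = 0.20,
    within_family_divergence: float = 0.03,
) -> list[ReferenceEntry]:
    """Labeled synthetic reference set: families of related hgcAB clusters.

    Families diverge strongly from the shared consensus; members within a
    family are close. Lineages follow domain..genus with genus unique per
    entry, so clade consensus resolves to family rank for on-family
    queries. Stand-in for a curated reference collection; entirely
    synthetic.
    """
    rng = np.random.default_rng(seed)
    a_protect = range(HGCA_MOTIF_START, HGCA_MOTIF_START + 8)
    b_protect = range(HGCB_MOTIF_START, HGCB_MOTIF_START + 7)
    entries: list[ReferenceEntry] = []
    for f in range(n_families):
        founder_a = mutate(hgca_consensus("A"), family_divergence, rng, a_protect)
        founder_b = mutate(hgcb_consensus("M"), family_divergence, rng, b_protect)
        phylum = f"Phylum{f // 2 + 1:02d}"
        for m in range(n_per_family):
            a = mutate(founder_a, within_family_divergence, rng, a_protect)
            b = mutate(founder_b, within_family_divergence, rng, b_protect)
            entries.append(
                ReferenceEntry(
                    ref_id=f"REF_F{f + 1:02d}_{m + 1:02d}",
                    lineage=(
                        "Bacteria",
                        phylum,
                        f"Class{f + 1:02d}",
                        f"Order{f + 1:02d}",
                        f"Family{f + 1:02d}",
                        f"Genus{f + 1:02d}_{m + 1:02d}",
                    ),
                    hgcA_seq=a,
                    hgcB_seq=b,
                    concat_seq=a + b,
                )
            )
    return entries


def write_reference_fixture(
    entries: list[ReferenceEntry], outdir: str | Path
) -> dict[str, Path]:
    """Emit the reference FASTAs (hgcA/hgcB/concat) and taxonomy TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for mode in ("hgcA", "hgcB", "concat"):
        path = outdir / f"refs_{mode}.faa"
        with open(path, "w") as fh:
            for e in entries:
                seq = e.sequence(mode)
                if seq:
                    fh.write(f">{e.ref_id}\n{seq}\n")
        paths[mode] = path
    tax = outdir / "refs_taxonomy.tsv"
    pd.DataFrame(
        [{"ref_id": e.ref_id, "lineage": ";".join(e.lineage)} for e in entries]
    ).to_csv(tax, sep="\t", index=False)
    paths["taxonomy"] = tax
    return paths


# ---------------------------------------------------------------------------
# survey manifest (81-sample study structure)


def build_survey_manifest() -> list[SampleMetadata]:
    """The 81-metagenome manifest of the emulated survey.

    Three datasets: a 14-sample redoxcline profile set (including six
    matched 3 um / 0.2-3 um filter-fraction pairs), a 30-sample transect,
    and a 37-sample surface time series. Per-sample depths and O2 values
    are representative (the published description gives per-dataset
    structure, not per-sample values); zone totals are 65 normoxic, 9
    hypoxic and 7 anoxic.
    """
    samples: list[SampleMetadata] = []

    def add(sid, station, date, depth, o2, filt, pre, dataset):
        samples.append(
            SampleMetadata(
                sample_id=sid,
                station=station,
                date=date,
                depth_m=depth,
                o2_detected=o2 is not None,
                o2_mL_per_L=o2,
                filter_um=filt,
                prefilter_um=pre,
                dataset=dataset,
            )
        )

    ds1 = "Redoxcline 2014"
    # two unpaired 0.2 um samples
    add("RC14-01", "TF0271", _dt.date(2014, 10, 18), 5.0, 6.2, 0.2, None, ds1)
    add("RC14-02", "TF0271", _dt.date(2014, 10, 18), 200.0, None, 0.2, None, ds1)
    # four depth-matched fraction pairs at the deep station
    oct26 = _dt.date(2014, 10, 26)
    for i, (depth, o2) in enumerate(
        [(60.0, 0.9), (110.0, None), (140.0, None), (200.0, None)], start=0
    ):
        add(f"RC14-{3 + 2 * i:02d}", "TF0271", oct26, depth, o2, 3.0, None, ds1)
        add(f"RC14-{4 + 2 * i:02d}", "TF0271", oct26, depth, o2, 0.2, 3.0, ds1)
    # two pairs at the shallow coastal station
    sep23 = _dt.date(2014, 9, 23)
    for i, (depth, o2) in enumerate([(10.0, 5.5), (22.0, 1.2)], start=0):
        add(f"RC14-{11 + 2 * i:02d}", "BoknisEck", sep23, depth, o2, 3.0, None, ds1)
        add(f"RC14-{12 + 2 * i:02d}", "BoknisEck", sep23, depth, o2, 0.2, 3.0, ds1)

    ds2 = "Transect 2014"
    stations = ["AT1", "AT3", "AT4", "MO3", "MO6", "MO7", "S6", "S7", "S10", "TF245"]
    depths = [2.0, 30.0, 242.0]
    k = 0
    for si, station in enumerate(stations):
        date = _dt.date(2014, 6, 4) + _dt.timedelta(days=si)
        for d in depths:
            k += 1
            # five deep stations reach hypoxic water at depth
            hypoxic = d > 200 and si % 2 == 0
            o2 = 0.8 if hypoxic else round(2.5 + 0.5 * (si % 5), 1)
            add(f"TR14-{k:02d}", station, date, d, o2, 0.2, None, ds2)

    ds3 = "LMO 2012 time series"
    start = _dt.date(2012, 3, 14)
    span = (_dt.date(2012, 12, 20) - start).days
    for i in range(37):
        date = start + _dt.timedelta(days=round(i * span / 36))
        add(f"LMO-{i + 1:02d}", "LMO", date, 2.0, round(5.0 + (i % 7) * 0.4, 1), 0.2, 3.0, ds3)

    assert len(samples) == 81
    return samples


# ---------------------------------------------------------------------------
# survey simulation


@dataclass
class SurveyConfig:
    """Conditions for one simulated survey.

    Defaults are the emulated study's conditions: 65/9/7 samples per redox
    zone, summed hgc abundance of 0.05 / 1.0 / 2.1 (in 1e-3 % units) in
    normoxic / hypoxic / anoxic water, a 5-fold particle enrichment, and
    12.9 million annotated reads per sample.
    """

    seed: int
    n_samples_per_zone: dict[str, int] = field(
        default_factory=lambda: {"normoxic": 65, "hypoxic": 9, "anoxic": 7}
    )
    n_decoy_genes: int = 120
    n_background_genes: int = 150
    mutation_rate: float = 0.05
    zone_effect_1e3_pct: dict[str, float] = field(
        default_factory=lambda: {"normoxic": 0.05, "hypoxic": 1.0, "anoxic": 2.1}
    )
    particle_enrichment: float = 5.0
    nb_dispersion: float = 2.0
    total_reads: int = 12_900_000
    n_fraction_pairs: int = 3
    background_mean_reads: float = 50.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.mutation_rate <= 0.3):
            raise ValueError("mutation_rate must be in [0, 0.3]")
        if self.particle_enrichment < 1:
            raise ValueError("particle_enrichment must be >= 1")
        if any(v < 0 for v in self.n_samples_per_zone.values()):
            raise ValueError("negative sample count")
        worst = (
            max(self.zone_effect_1e3_pct.values())
            * self.particle_enrichment
            * self.total_reads
            / 1e5
            + self.n_background_genes * self.background_mean_reads
            + self.n_decoy_genes * self.background_mean_reads
        )
        if worst > 0.5 * self.total_reads:
            raise ValueError(
                "infeasible config: expected counts approach total reads"
            )


def simulate_survey(
    config: SurveyConfig,
) -> tuple[list[GeneRecord], list[ContigRecord], CountMatrix, list[SampleMetadata], GroundTruth]:
    """Simulate catalog + counts + metadata for one survey realisation.

    hgc gene counts are negative-binomial with per-sample mean chosen so
    the expected summed relative abundance equals the zone effect; 3 um
    particle samples get the enrichment multiplier. All randomness flows
    from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes, contigs, truth = build_figure2_fixture(
        n_decoys=config.n_decoy_genes,
        n_background=config.n_background_genes,
        mutation_rate=0.02,
    )
    # survey-level mutation noise on top of the fixture (motifs protected)
    b_protect = range(HGCB_MOTIF_START, HGCB_MOTIF_START + 7)
    if config.mutation_rate > 0:
        for g in genes:
            role = truth.gene_roles[g.gene_id]
            if role == "hgcA":
                offset = 60 if g.partial_flags[0] else 0
                protected = range(
                    HGCA_MOTIF_START - offset, HGCA_MOTIF_START - offset + 8
                )
            elif role == "hgcB":
                protected = b_protect
            else:
                protected = None
            g.aa_sequence = mutate(
                g.aa_sequence, config.mutation_rate, rng, protected
            )
    truth.params.update(dataclasses.asdict(config))

    # --- metadata
    samples: list[SampleMetadata] = []
    zones: dict[str, str] = {}
    particle: set[str] = set()
    idx = 0

    def o2_for(zone: str) -> float | None:
        if zone == "normoxic":
            return float(np.round(rng.uniform(2.0, 8.0), 2))
        if zone == "hypoxic":
            return float(np.round(rng.uniform(0.1, 1.9), 2))
        return None

    def depth_for(zone: str) -> float:
        lo, hi = {"normoxic": (2, 40), "hypoxic": (60, 95), "anoxic": (100, 220)}[zone]
        return float(np.round(rng.uniform(lo, hi), 1))

    base_date = _dt.date(2014, 6, 1)
    for zone in ("normoxic", "hypoxic", "anoxic"):
        for _ in range(config.n_samples_per_zone.get(zone, 0)):
            idx += 1
            sid = f"SIM-{idx:03d}"
            o2 = o2_for(zone)
            samples.append(
                SampleMetadata(
                    sample_id=sid,
                    station=f"ST{idx % 13 + 1:02d}",
                    date=base_date + _dt.timedelta(days=idx),
                    depth_m=depth_for(zone),
                    o2_detected=o2 is not None,
                    o2_mL_per_L=o2,
                    filter_um=0.2,
                    prefilter_um=3.0,
                    dataset="simulated",
                )
            )
            zones[sid] = zone
    for p in range(config.n_fraction_pairs):
        idx += 1
        station = f"PAIR{p + 1:02d}"
        date = base_date + _dt.timedelta(days=idx)
        depth = depth_for("anoxic")
        for filt, pre, tag in ((3.0, None, "3um"), (0.2, 3.0, "02um")):
            sid = f"SIM-{idx:03d}-{tag}"
            samples.append(
                SampleMetadata(
                    sample_id=sid,
                    station=station,
                    date=date,
                    depth_m=depth,
                    o2_detected=False,
                    o2_mL_per_L=None,
                    filter_um=filt,
                    prefilter_um=pre,
                    dataset="simulated",
                )
            )
            zones[sid] = "anoxic"
            if filt == 3.0:
                particle.add(sid)

    # --- counts
    hgc_ids = truth.hgc_gene_ids
    other_ids = [g.gene_id for g in genes if g.gene_id not in set(hgc_ids)]
    gene_order = [g.gene_id for g in genes]
    counts = np.zeros((len(gene_order), len(samples)), dtype=np.int64)
    row = {g: i for i, g in enumerate(gene_order)}
    r = config.nb_dispersion
    for j, m in enumerate(samples):
        effect = config.zone_effect_1e3_pct[zones[m.sample_id]]
        mu_total = effect * config.total_reads / 1e5
        if m.sample_id in particle:
            mu_total *= config.particle_enrichment
        mu_gene = mu_total / len(hgc_ids)
        if mu_gene > 0:
            p = r / (r + mu_gene)
            draws = rng.negative_binomial(r, p, size=len(hgc_ids))
            for g, c in zip(hgc_ids, draws):
                counts[row[g], j] = c
        bg = rng.poisson(config.background_mean_reads, size=len(other_ids))
        for g, c in zip(other_ids, bg):
            counts[row[g], j] = c

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_order, columns=[m.sample_id for m in samples]),
        pd.Series(config.total_reads, index=[m.sample_id for m in samples]),
    )
    return genes, contigs, cm, samples, truth


def write_survey(
    outdir: str | Path,
    genes: list[GeneRecord],
    contigs: list[ContigRecord],
    cm: CountMatrix,
    samples: list[SampleMetadata],
    truth: GroundTruth,
) -> dict[str, Path]:
    """Emit the exact file surfaces the loaders consume, plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "catalog.faa",
        "coords": outdir / "coords.tsv",
        "contigs": outdir / "contigs.tsv",
        "counts": outdir / "counts.tsv",
        "totals": outdir / "totals.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_gene_catalog(genes, contigs, paths["fasta"], paths["coords"], paths["contigs"])
    write_count_data(cm, paths["counts"], paths["totals"])
    write_sample_metadata(samples, paths["metadata"])
    truth.to_json(paths["truth"])
    return paths
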