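"""Relative abundance of called loci, redox stratification, rarefaction.

The abundance statistic is the paper-style ratio: reads mapped to the hgc
locus genes divided by total annotated reads per sample, expressed as a
percentage and displayed in 1e-3 % units. No gene-length normalization is
applied by default (a reads-per-kilobase mode exists for sensitivity
analysis only). Water samples are stratified into three redox zones from
measured O2: normoxic (>= 2 mL/L), hypoxic (detectable < 2 mL/L), anoxic
(no detectable O2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import CountMatrix, GeneRecord, SampleMetadata
from .loci import LocusCall

SUMMED_KEY = "all_hgc"

ZONES = ("normoxic", "hypoxic", "anoxic")


class AbundanceError(ValueError):
    pass


@dataclass
class AbundanceRecord:
    sample_id: str
    key: str  # locus_name or the summed aggregate key
    relative_abundance_pct: float

    @property
    def display_units_1e3(self) -> float:
        """Abundance in 1e-3 % units, the paper's display convention."""
        return self.relative_abundance_pct * 1e3


@dataclass
class ZoneSummary:
    zone: str
    n_samples: int
    mean: float  # all four moments in 1e-3 % units
    sd: float
    min: float
    max: float
    degenerate_n: bool = False


def classify_redox(meta: SampleMetadata, threshold_mL_per_L: float = 2.0) -> str:
    """Redox zone of a sample; the normoxic boundary is inclusive."""
    if not meta.o2_detected:
        return "anoxic"
    assert meta.o2_mL_per_L is not None
    return "normoxic" if meta.o2_mL_per_L >= threshold_mL_per_L else "hypoxic"


def classify_all(
    samples: Iterable[SampleMetadata], threshold_mL_per_L: float = 2.0
) -> dict[str, str]:
    return {m.sample_id: classify_redox(m, threshold_mL_per_L) for m in samples}


def _locus_gene_lengths(
    loci: Sequence[LocusCall], catalog: Sequence[GeneRecord] | None
) -> dict[str, float]:
    if catalog is None:
        raise AbundanceError("per-kilobase mode requires the gene catalog")
    by_id = {g.gene_id: g for g in catalog}
    return {
        gid: (by_id[gid].end_bp - by_id[gid].start_bp + 1) / 1000.0
        for locus in loci
        for gid in locus.gene_ids()
    }


def compute_abundance(
    counts: CountMatrix,
    loci: Sequence[LocusCall],
    per_locus: bool = False,
    per_kb: bool = False,
    catalog: Sequence[GeneRecord] | None = None,
) -> list[AbundanceRecord]:
    """Per-sample relative abundance of called loci.

    abundance = 100 * (sum of reads over the locus's member genes)
                    / total_annotated_reads.

    With ``per_locus`` one record per (sample, locus) is returned; otherwise
    one summed record per sample under :data:`SUMMED_KEY`. ``per_kb``
    divides each gene's reads by its length in kb before summing
    (sensitivity mode; changes units, off by default).
    """
    missing = sorted(
        {gid for l in loci for gid in l.gene_ids()} - set(counts.gene_ids)
    )
    if missing:
        raise AbundanceError(f"locus genes missing from count matrix: {missing}")

    kb = _locus_gene_lengths(loci, catalog) if per_kb else None
    totals = counts.total_annotated_reads
    records: list[AbundanceRecord] = []
    per_locus_frames: dict[str, pd.Series] = {}
    for locus in loci:
        sub = counts.counts.loc[locus.gene_ids()].astype(float)
        if kb is not None:
            sub = sub.div(pd.Series({g: kb[g] for g in locus.gene_ids()}), axis=0)
        per_locus_frames[locus.locus_name] = sub.sum(axis=0)
    if not per_locus_frames:
        summed = pd.Series(0.0, index=counts.sample_ids)
    else:
        summed = pd.DataFrame(per_locus_frames).sum(axis=1)

    if per_locus:
        for name, reads in per_locus_frames.items():
            pct = 100.0 * reads / totals
            records.extend(
                AbundanceRecord(sample_id=s, key=name, relative_abundance_pct=v)
                for s, v in pct.items()
            )
    else:
        pct = 100.0 * summed / totals
        records.extend(
            AbundanceRecord(sample_id=s, key=SUMMED_KEY, relative_abundance_pct=v)
            for s, v in pct.items()
        )
    return records


def summarize_by_zone(
    records: Sequence[AbundanceRecord],
    zones: Mapping[str, str],
) -> list[ZoneSummary]:
    """Per-zone n/mean/sd/min/max of summed abundance, plus an all-water row.

    Values are reported in 1e-3 % units; sd uses the n-1 denominator, and a
    single-sample zone reports sd 0 with a degenerate-n flag.
    """
    unzoned = sorted({r.sample_id for r in records} - set(zones))
    if unzoned:
        raise AbundanceError(f"samples without a redox zone: {unzoned}")
    values: dict[str, list[float]] = {z: [] for z in ZONES}
    all_values: list[float] = []
    for r in records:
        values[zones[r.sample_id]].append(r.display_units_1e3)
        all_values.append(r.display_units_1e3)
    out: list[ZoneSummary] = []
    for zone in ZONES:
        vals = np.asarray(values[zone], dtype=float)
        if vals.size == 0:
            warnings.warn(f"zone {zone!r} has no samples; omitted", stacklevel=2)
            continue
        out.append(_summary_row(zone, vals))
    out.append(_summary_row("all", np.asarray(all_values, dtype=float)))
    return out


def _summary_row(zone: str, vals: np.ndarray) -> ZoneSummary:
    degenerate = vals.size < 2
    return ZoneSummary(
        zone=zone,
        n_samples=int(vals.size),
        mean=float(vals.mean()),
        sd=0.0 if degenerate else float(vals.std(ddof=1)),
        min=float(vals.min()),
        max=float(vals.max()),
        degenerate_n=degenerate,
    )


def zone_summary_frame(summaries: Sequence[ZoneSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "zone": s.zone,
                "n": s.n_samples,
                "mean_1e3_pct": s.mean,
                "sd_1e3_pct": s.sd,
                "min_1e3_pct": s.min,
                "max_1e3_pct": s.max,
            }
            for s in summaries
        ]
    )


def fraction_enrichment(
    records: Sequence[AbundanceRecord],
    metadata: Sequence[SampleMetadata],
    pairing_keys: tuple[str, ...] = ("station", "date", "depth_m"),
    particle_filter_um: float = 3.0,
    free_filter_um: float = 0.2,
) -> pd.DataFrame:
    """Fold enrichment of hgc abundance on particles vs free-living fractions.

    A particle sample is captured on the 3 um filter without pre-filtration;
    its free-living partner is captured on 0.2 um after a 3 um pre-filter.
    Partners are matched exactly on ``pairing_keys``. The ratio is
    particle / free-living; a zero denominator is flagged undefined rather
    than reported as infinity.
    """
    by_sample = {
        r.sample_id: r.display_units_1e3 for r in records if r.key == SUMMED_KEY
    }

    def key_of(m: SampleMetadata):
        return tuple(getattr(m, k) for k in pairing_keys)

    particle = {}
    free = {}
    for m in metadata:
        if m.sample_id not in by_sample:
            continue
        if m.filter_um == particle_filter_um and m.prefilter_um is None:
            particle[key_of(m)] = m.sample_id
        elif m.filter_um == free_filter_um and m.prefilter_um == particle_filter_um:
            free[key_of(m)] = m.sample_id

    rows = []
    for key in sorted(set(particle) & set(free), key=str):
        p_id, f_id = particle[key], free[key]
        num, den = by_sample[p_id], by_sample[f_id]
        defined = den > 0
        rows.append(
            dict(
                zip(pairing_keys, key),
                particle_sample=p_id,
                free_sample=f_id,
                particle_1e3_pct=num,
                free_1e3_pct=den,
                ratio=num / den if defined else np.nan,
                defined=defined,
            )
        )
    if not rows:
        warnings.warn("no matched filter-fraction pairs found", stacklevel=2)
        return pd.DataFrame(
            columns=list(pairing_keys)
            + [
                "particle_sample",
                "free_sample",
                "particle_1e3_pct",
                "free_1e3_pct",
                "ratio",
                "defined",
            ]
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rarefaction


def _hgc_count_vector(
    counts: CountMatrix, loci: Sequence[LocusCall], sample_id: str
) -> tuple[list[str], np.ndarray, int]:
    gene_ids = sorted({gid for l in loci for gid in l.gene_ids()})
    vec = counts.counts.loc[gene_ids, sample_id].to_numpy()
    total = int(counts.total_annotated_reads[sample_id])
    return gene_ids, vec.astype(np.int64), total


def rarefaction(
    counts: CountMatrix,
    loci: Sequence[LocusCall],
    sample_id: str,
    depths: Sequence[int],
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefaction curve: mean number of hgc genes detected vs read depth.

    Reads are subsampled without replacement (multivariate hypergeometric
    over the hgc gene counts plus one bucket for all other annotated reads)
    and a gene counts as detected when at least one of its reads is drawn.
    Deterministic for a fixed seed.
    """
    gene_ids, vec, total = _hgc_count_vector(counts, loci, sample_id)
    for d in depths:
        if d > total:
            raise AbundanceError(
                f"depth {d} exceeds total annotated reads {total} of {sample_id}"
            )
        if d < 0:
            raise AbundanceError("negative rarefaction depth")
    rng = np.random.default_rng(seed)
    rest = total - int(vec.sum())
    colors = np.concatenate([vec, [rest]])
    rows = []
    for d in depths:
        detected = np.empty(replicates)
        for r in range(replicates):
            draw = rng.multivariate_hypergeometric(colors, d)
            detected[r] = int((draw[:-1] > 0).sum())
        rows.append(
            {
                "depth": int(d),
                "mean_detected": float(detected.mean()),
                "sd_detected": float(detected.std(ddof=1)) if replicates > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def rarefaction_expectation(
    counts: CountMatrix,
    loci: Sequence[LocusCall],
    sample_id: str,
    depths: Sequence[int],
) -> pd.DataFrame:
    """Closed-form expected detections: E = sum_g 1 - C(N-k_g, d)/C(N, d)."""
    _, vec, total = _hgc_count_vector(counts, loci, sample_id)

    def log_choose(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rows = []
    for d in depths:
        if d > total:
            raise AbundanceError(f"depth {d} exceeds total {total}")
        with np.errstate(invalid="ignore"):
            p_missed = np.where(
                total - vec >= d,
                np.exp(log_choose(total - vec, d) - log_choose(np.asarray(total), d)),
                0.0,
            )
        rows.append(
            {"depth": int(d), "expected_detected": float((1 - p_missed).sum())}
        )
    return pd.DataFrame(rows)
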