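"""Candidate hgcA/hgcB detection: profile screen plus degenerate-motif check.

The decisive filter is the conserved amino-acid motif — the cap-helix motif
NVWCA(A/G/S)GK for hgcA and the ferredoxin motif C(M/I)EC(G/S)(A/G)C for
hgcB. Screening narrows the catalog first, either by parsing a per-domain
table from an external ``hmmsearch`` run (keeping hits with full-sequence
E-value <= 1e-3, boundary inclusive) or with an internal position-specific
log-odds profile scored by ungapped sliding windows. The internal screen is
deliberately not a full profile HMM: it only needs to separate hgc-like
sequences from unrelated background at catalog scale, after which the motif
check decides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AA_ALPHABET, GeneRecord

HGCA_MOTIF = "NVWCA(A/G/S)GK"
HGCB_MOTIF = "C(M/I)EC(G/S)(A/G)C"

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_X_CODE = 20  # ambiguous residue: scores zero, matches no motif position


class MotifError(ValueError):
    pass


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: one allowed-residue set per position."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class CandidateHit:
    gene_id: str
    target: str  # "hgcA" or "hgcB"
    screen_score: float | None = None
    e_value: float | None = None
    screen_source: str = "internal"
    motif_match: str | None = None
    motif_position: int | None = None
    verified: bool = False


@dataclass
class PositionProfile:
    """Per-column log-odds (bits) over the 20-letter alphabet.

    Built from a reference alignment with Laplace pseudocounts; columns more
    than half gaps are dropped. ``scores`` has shape (n_columns, 21); the
    final code is the ambiguous residue X, scored 0 everywhere.
    """

    target: str
    scores: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )

    def __len__(self) -> int:
        return self.scores.shape[0]


def compile_motif(pattern_text: str, name: str | None = None) -> MotifPattern:
    """Parse a degenerate motif such as ``"NVWCA(A/G/S)GK"``.

    Single letters are fixed positions; parenthesized slash-separated groups
    are alternatives.
    """
    positions: list[frozenset[str]] = []
    i = 0
    text = pattern_text.strip()
    if not text:
        raise MotifError("empty motif pattern")
    while i < len(text):
        ch = text[i]
        if ch == "(":
            j = text.find(")", i)
            if j < 0:
                raise MotifError(f"unclosed group in motif {text!r}")
            residues = [r.strip() for r in text[i + 1 : j].split("/")]
            if not residues or any(not r for r in residues):
                raise MotifError(f"empty alternative in motif {text!r}")
            for r in residues:
                if r not in AA_ALPHABET:
                    raise MotifError(f"non-residue {r!r} in motif {text!r}")
            positions.append(frozenset(residues))
            i = j + 1
        else:
            if ch not in AA_ALPHABET:
                raise MotifError(f"non-residue {ch!r} in motif {text!r}")
            positions.append(frozenset(ch))
            i += 1
    return MotifPattern(name=name or text, positions=tuple(positions))


def scan_motif(motif: MotifPattern, seq: str) -> list[tuple[int, str]]:
    """All windows of ``seq`` matching ``motif``; 1-based starts, ascending.

    The ambiguous residue X matches no motif position (conservative: an X in
    the motif region cannot verify a candidate).
    """
    seq = seq.upper()
    k = len(motif)
    out: list[tuple[int, str]] = []
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        if all(window[i] in motif.positions[i] for i in range(k)):
            out.append((start + 1, window))
    return out


def build_profile(
    alignment: Sequence[tuple[str, str]] | Mapping[str, str],
    target: str,
    alpha: float = 0.1,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> PositionProfile:
    """Build a position-specific log-odds profile from an aligned FASTA.

    ``alignment`` maps sequence ids to equal-length aligned sequences (gaps
    as ``-``). Columns with a gap fraction above ``max_gap_fraction`` are
    dropped. Residue probabilities are Laplace-smoothed with ``alpha``
    pseudocounts per residue, and scores are log2(p / background).
    """
    if isinstance(alignment, Mapping):
        rows = list(alignment.values())
    else:
        rows = [s for _, s in alignment]
    if len(rows) < 2:
        raise ScreenError("profile needs at least 2 aligned sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ScreenError(f"ragged alignment: lengths {sorted(lengths)}")
    if background is None:
        background = np.full(20, 0.05)
    n_cols = lengths.pop()
    cols: list[np.ndarray] = []
    for c in range(n_cols):
        column = [r[c].upper() for r in rows]
        residues = [ch for ch in column if ch in _AA_INDEX]
        gap_fraction = 1 - len(residues) / len(column)
        if gap_fraction > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for ch in residues:
            counts[_AA_INDEX[ch]] += 1
        probs = (counts + alpha) / (len(residues) + 20 * alpha)
        scores = np.log2(probs / background)
        cols.append(scores)
    if not cols:
        raise ScreenError("no usable (non-gap) columns in alignment")
    mat = np.column_stack([np.vstack(cols), np.zeros(len(cols))[:, None]])
    return PositionProfile(target=target, scores=mat, background=background)


def encode_sequence(seq: str) -> np.ndarray:
    return np.fromiter(
        (_AA_INDEX.get(ch, _X_CODE) for ch in seq.upper()), dtype=np.int64
    )


def best_window_score(profile: PositionProfile, seq: str) -> float:
    """Best ungapped placement score (bits) of ``profile`` along ``seq``.

    The sequence is padded with ambiguous residues so partial overlaps at
    either end are scored over the overlapping columns only — this keeps
    edge-truncated ORFs detectable.
    """
    codes = encode_sequence(seq)
    L = len(profile)
    padded = np.concatenate(
        [np.full(L - 1, _X_CODE), codes, np.full(L - 1, _X_CODE)]
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, L)
    scores = profile.scores[np.arange(L)[None, :], windows].sum(axis=1)
    return float(scores.max())


# ---------------------------------------------------------------------------
# external hmmsearch per-domain table

_DOMTBL_MIN_FIELDS = 22


def parse_domain_table(path: str | Path) -> list[dict]:
    """Parse the whitespace-delimited per-domain table written by hmmsearch.

    Returns one dict per row with ``target_name``, ``query_name`` and the
    full-sequence ``e_value`` and ``score``. Comment lines start with '#'.
    """
    rows: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ScreenError(
                    f"{path}: malformed domain-table row at line {lineno} "
                    f"({len(fields)} fields, expected >= {_DOMTBL_MIN_FIELDS})"
                )
            try:
                e_value = float(fields[6])
                score = float(fields[7])
            except ValueError:
                raise ScreenError(
                    f"{path}: unparseable E-value/score at line {lineno}"
                ) from None
            rows.append(
                {
                    "target_name": fields[0],
                    "query_name": fields[3],
                    "e_value": e_value,
                    "score": score,
                }
            )
    return rows


def _target_from_query(query_name: str) -> str | None:
    q = query_name.lower()
    if "hgca" in q:
        return "hgcA"
    if "hgcb" in q:
        return "hgcB"
    return None


def screen_candidates(
    catalog: Sequence[GeneRecord],
    profiles: Mapping[str, PositionProfile] | None = None,
    domain_table: str | Path | None = None,
    e_threshold: float = 1e-3,
    bits_per_column_threshold: float = 0.5,
) -> list[CandidateHit]:
    """Profile-similarity screen of the catalog; returns unverified hits.

    Exactly one screen source must be given: internal position profiles
    (one per target) or an external hmmsearch per-domain table. The E-value
    cutoff is inclusive. A gene similar to both targets yields two hits;
    the motif check and locus classification disambiguate downstream.
    """
    if (profiles is None) == (domain_table is None):
        raise ScreenError(
            "select exactly one screen source: internal profiles or domain_table"
        )
    hits: list[CandidateHit] = []
    if domain_table is not None:
        known = {g.gene_id for g in catalog}
        seen: set[tuple[str, str]] = set()
        for row in parse_domain_table(domain_table):
            target = _target_from_query(row["query_name"])
            if target is None:
                warnings.warn(
                    f"unknown profile name {row['query_name']!r} in domain "
                    "table; row skipped",
                    stacklevel=2,
                )
                continue
            if row["e_value"] > e_threshold:
                continue
            if row["target_name"] not in known:
                continue
            key = (row["target_name"], target)
            if key in seen:  # one hit per (gene, target): keep the first
                continue
            seen.add(key)
            hits.append(
                CandidateHit(
                    gene_id=row["target_name"],
                    target=target,
                    e_value=row["e_value"],
                    screen_score=row["score"],
                    screen_source="domain_table",
                )
            )
    else:
        assert profiles is not None
        for gene in catalog:
            for target in sorted(profiles):
                profile = profiles[target]
                score = best_window_score(profile, gene.aa_sequence)
                if score / len(profile) >= bits_per_column_threshold:
                    hits.append(
                        CandidateHit(
                            gene_id=gene.gene_id,
                            target=target,
                            screen_score=score,
                            screen_source="internal",
                        )
                    )
    return hits


def verify_candidates(
    hits: Iterable[CandidateHit],
    catalog: Sequence[GeneRecord],
    motifs: Mapping[str, MotifPattern] | None = None,
) -> list[CandidateHit]:
    """Motif-verify screen hits; returns the verified subset.

    Each hit is verified iff its gene carries at least one window matching
    the target's degenerate motif; the leftmost match is recorded. Hits are
    annotated in place (``verified``, ``motif_match``, ``motif_position``)
    so the full list still supports drop-count summaries.
    """
    if motifs is None:
        motifs = default_motifs()
    by_id = {g.gene_id: g for g in catalog}
    verified: list[CandidateHit] = []
    for hit in hits:
        if hit.gene_id not in by_id:
            raise ScreenError(f"hit references unknown gene {hit.gene_id}")
        motif = motifs[hit.target]
        matches = scan_motif(motif, by_id[hit.gene_id].aa_sequence)
        if matches:
            hit.motif_position, hit.motif_match = matches[0]
            hit.verified = True
            verified.append(hit)
        else:
            hit.verified = False
            hit.motif_match = None
            hit.motif_position = None
    return verified


def verification_summary(hits: Sequence[CandidateHit]) -> dict:
    """Tallies over a screened-and-verified hit list."""
    n_verified = sum(h.verified for h in hits)
    by_target: dict[str, dict[str, int]] = {}
    for h in hits:
        t = by_target.setdefault(h.target, {"candidates": 0, "verified": 0})
        t["candidates"] += 1
        t["verified"] += h.verified
    return {
        "candidates": len(hits),
        "verified": n_verified,
        "dropped": len(hits) - n_verified,
        "by_target": by_target,
    }


def default_motifs() -> dict[str, MotifPattern]:
    return {
        "hgcA": compile_motif(HGCA_MOTIF, name="hgcA"),
        "hgcB": compile_motif(HGCB_MOTIF, name="hgcB"),
    }
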