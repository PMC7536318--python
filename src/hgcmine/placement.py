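"""Distance-based taxonomic placement of hgc loci against labeled references.

Queries are compared to a labeled reference set of hgcA / hgcB /
concatenated-hgcAB amino-acid sequences by pairwise global alignment
(BLOSUM62, affine gaps) with Poisson-corrected distances
d = -ln(1 - p), a neighbor-joining tree is built, and each query is
labeled by its nearest reference and by rank-consensus over the smallest
query-containing clade with at least two references. Queries whose
terminal branch is unusually long relative to the references carry a
"-like" caution suffix: fine-rank assignment on long branches is
unreliable.

Neighbor joining is implemented here with deterministic tie-breaking
(lexicographic on the smallest leaf label under each candidate pair) and
non-negative branch lengths (a negative estimate is clamped to zero and
the deficit moved to its sibling). An externally computed Newick tree can
be ingested instead for workflows that ran a maximum-likelihood program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import TreeNode

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
D_MAX = 5.0


class PlacementError(ValueError):
    pass


@dataclass
class ReferenceEntry:
    ref_id: str
    lineage: tuple[str, ...]
    hgcA_seq: str | None = None
    hgcB_seq: str | None = None
    concat_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.lineage:
            raise PlacementError(f"reference {self.ref_id}: empty lineage")
        if not (self.hgcA_seq or self.hgcB_seq or self.concat_seq):
            raise PlacementError(f"reference {self.ref_id}: no sequence")

    def sequence(self, mode: str) -> str | None:
        return {"hgcA": self.hgcA_seq, "hgcB": self.hgcB_seq, "concat": self.concat_seq}[
            mode
        ]


@dataclass
class TaxonAssignment:
    locus_name: str
    nearest_ref_id: str
    nearest_distance: float
    assigned_lineage: tuple[str, ...]
    like_flag: bool
    consensus_fraction: float

    @property
    def label(self) -> str:
        if not self.assigned_lineage:
            return "unidentified"
        parts = list(self.assigned_lineage)
        if self.like_flag:
            parts[-1] = parts[-1] + "-like"
        return ";".join(parts)


# ---------------------------------------------------------------------------
# references


def load_reference_set(
    fasta_files: Mapping[str, str | Path],
    taxonomy_tsv: str | Path,
) -> list[ReferenceEntry]:
    """Join reference sequences to lineages.

    ``fasta_files`` maps mode ("hgcA", "hgcB", "concat") to a FASTA path;
    ``taxonomy_tsv`` has columns ``ref_id`` and ``lineage``
    (semicolon-separated ranks, domain first). Entries lacking taxonomy are
    dropped with a warning; duplicate ref ids are an error.
    """
    import warnings

    tax = pd.read_csv(taxonomy_tsv, sep="\t", dtype=str)
    if tax["ref_id"].duplicated().any():
        dups = sorted(tax.loc[tax["ref_id"].duplicated(), "ref_id"])
        raise PlacementError(f"duplicate ref_id in taxonomy: {dups}")
    lineages = {
        row.ref_id: tuple(p.strip() for p in row.lineage.split(";") if p.strip())
        for row in tax.itertuples(index=False)
    }
    seqs: dict[str, dict[str, str]] = {}
    for mode, path in fasta_files.items():
        if mode not in {"hgcA", "hgcB", "concat"}:
            raise PlacementError(f"unknown reference mode {mode!r}")
        for rec in SeqIO.parse(str(path), "fasta"):
            bucket = seqs.setdefault(rec.id, {})
            if mode in bucket:
                raise PlacementError(f"duplicate ref_id {rec.id} in {mode} FASTA")
            bucket[mode] = str(rec.seq)
    entries: list[ReferenceEntry] = []
    for ref_id in sorted(seqs):
        if ref_id not in lineages:
            warnings.warn(
                f"reference {ref_id} has no taxonomy row; dropped", stacklevel=2
            )
            continue
        entries.append(
            ReferenceEntry(
                ref_id=ref_id,
                lineage=lineages[ref_id],
                hgcA_seq=seqs[ref_id].get("hgcA"),
                hgcB_seq=seqs[ref_id].get("hgcB"),
                concat_seq=seqs[ref_id].get("concat"),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# distances


def make_aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_distance(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Poisson-corrected distance from one optimal global alignment.

    p = mismatches / aligned non-gap columns; d = -ln(1 - p), capped at
    :data:`D_MAX`. A pair with no aligned columns gets the cap.
    """
    import warnings

    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    cols = 0
    mismatches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            cols += 1
            mismatches += a[i].upper() != b[j].upper()
    if cols == 0:
        warnings.warn("pair with zero aligned columns; distance capped", stacklevel=2)
        return D_MAX
    p = mismatches / cols
    if p >= 1 - math.exp(-D_MAX):
        return D_MAX
    return -math.log(1 - p)


def compute_distances(
    queries: Mapping[str, str],
    refs: Sequence[ReferenceEntry] | Mapping[str, str],
    mode: str = "concat",
    ref_block: DistanceMatrix | None = None,
) -> DistanceMatrix:
    """Distance matrix over queries plus references.

    ``refs`` is either a list of :class:`ReferenceEntry` (sequences picked
    by ``mode``; entries lacking that sequence are skipped) or a plain
    label-to-sequence mapping. ``ref_block`` optionally supplies a
    precomputed reference-versus-reference sub-matrix to avoid re-aligning
    the reference set when many query batches are placed.
    """
    if isinstance(refs, Mapping):
        ref_seqs = dict(refs)
    else:
        ref_seqs = {
            e.ref_id: e.sequence(mode) for e in refs if e.sequence(mode) is not None
        }
    overlap = set(queries) & set(ref_seqs)
    if overlap:
        raise PlacementError(f"labels present in both queries and refs: {sorted(overlap)}")
    labels = sorted(queries) + sorted(ref_seqs)
    seqs = {**queries, **ref_seqs}
    for label, seq in seqs.items():
        if not seq:
            raise PlacementError(f"empty sequence for {label}")
    n = len(labels)
    d = np.zeros((n, n))
    aligner = make_aligner()
    ref_offset = len(queries)
    if ref_block is not None:
        rb_ids = list(ref_block.ids)
        if sorted(rb_ids) != sorted(ref_seqs):
            raise PlacementError("ref_block labels do not match reference set")
        order = [rb_ids.index(l) for l in labels[ref_offset:]]
        d[ref_offset:, ref_offset:] = ref_block.data[np.ix_(order, order)]
    for i in range(n):
        for j in range(i + 1, n):
            if ref_block is not None and i >= ref_offset:
                continue
            d[i, j] = d[j, i] = pairwise_distance(seqs[labels[i]], seqs[labels[j]], aligner)
    return DistanceMatrix(d, ids=labels)


def msa_distances(msa: Mapping[str, str]) -> DistanceMatrix:
    """Poisson-corrected p-distances over shared non-gap columns of an MSA."""
    labels = sorted(msa)
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise PlacementError("MSA sequences must have equal length")
    arr = np.array([list(msa[l].upper()) for l in labels])
    n = len(labels)
    d = np.zeros((n, n))
    nongap = arr != "-"
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            cols = int(shared.sum())
            if cols == 0:
                d[i, j] = d[j, i] = D_MAX
                continue
            p = float((arr[i, shared] != arr[j, shared]).mean())
            d[i, j] = d[j, i] = (
                D_MAX if p >= 1 - math.exp(-D_MAX) else -math.log(1 - p)
            )
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(
    dm: DistanceMatrix,
    bootstrap_replicates: int = 0,
    seed: int = 0,
    msa: Mapping[str, str] | None = None,
) -> TreeNode:
    """Neighbor joining with deterministic tie-breaks.

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k); the pair
    minimizing Q is joined, ties broken by the lexicographically smallest
    (smallest-leaf-label) pair. Negative branch-length estimates are
    clamped to zero with the deficit moved to the sibling branch. The
    result is an unrooted tree stored with a trifurcating root.

    With ``bootstrap_replicates`` > 0 an MSA (equal-length aligned
    sequences covering all labels) must be supplied; alignment columns are
    resampled with replacement, distances and trees rebuilt, and each
    internal edge of the main tree annotated with its split frequency
    (``node.support`` in [0, 1]).
    """
    tree = _nj_once(dm)
    if bootstrap_replicates > 0:
        if msa is None:
            raise PlacementError("bootstrap requires an MSA")
        if set(msa) != set(dm.ids):
            raise PlacementError("MSA labels must match distance-matrix labels")
        rng = np.random.default_rng(seed)
        labels = sorted(msa)
        arr = np.array([list(msa[l]) for l in labels])
        n_cols = arr.shape[1]
        split_counts: dict[frozenset[str], int] = {}
        for _ in range(bootstrap_replicates):
            cols = rng.integers(0, n_cols, size=n_cols)
            resampled = {
                l: "".join(arr[i, cols]) for i, l in enumerate(labels)
            }
            bt = _nj_once(msa_distances(resampled))
            for split in _splits(bt):
                split_counts[split] = split_counts.get(split, 0) + 1
        for node in tree.non_tips():
            if node.is_root():
                continue
            split = _normalize_split(
                frozenset(t.name for t in node.tips()), set(dm.ids)
            )
            node.support = split_counts.get(split, 0) / bootstrap_replicates
    return tree


def _nj_once(dm: DistanceMatrix) -> TreeNode:
    labels = list(dm.ids)
    if len(labels) < 3:
        raise PlacementError("neighbor joining needs at least 3 labels")
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[(a, b)] = d[(b, a)] = float(dm[a, b])
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in labels}
    # tie-break key of an active node: smallest leaf label beneath it
    keys: dict[str, str] = {l: l for l in labels}
    active = sorted(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * d[(a, b)] - r[a] - r[b]
                ka, kb = sorted((keys[a], keys[b]))
                cand = (q, ka, kb, a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, a, b = best  # type: ignore[misc]
        la = d[(a, b)] / 2 + (r[a] - r[b]) / (2 * (len(active) - 2))
        lb = d[(a, b)] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        new_id = f"__internal_{counter}"
        counter += 1
        parent = TreeNode()
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = la
        child_b.length = lb
        parent.extend([child_a, child_b])
        nodes[new_id] = parent
        keys[new_id] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            d[(new_id, c)] = d[(c, new_id)] = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
        active = sorted(
            (x for x in active if x not in (a, b)), key=lambda x: keys[x]
        )
        active.append(new_id)
        active.sort(key=lambda x: keys[x])
    a, b, c = active
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
    root = TreeNode()
    for node_id, length in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(node_id)
        child.length = max(0.0, length)
        root.append(child)
    return root


def _normalize_split(side: frozenset[str], all_labels: set[str]) -> frozenset[str]:
    anchor = min(all_labels)
    return side if anchor not in side else frozenset(all_labels - side)


def _splits(tree: TreeNode) -> set[frozenset[str]]:
    all_labels = {t.name for t in tree.tips()}
    out: set[frozenset[str]] = set()
    for node in tree.non_tips():
        if node.is_root():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_labels) - 1:
            out.add(_normalize_split(side, all_labels))
    return out


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write the tree in Newick, support values as internal-node labels."""
    clone = tree.copy()
    for node in clone.non_tips():
        support = getattr(node, "support", None)
        if support is not None:
            node.name = f"{support:.3f}"
    clone.write(str(path))


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))


# ---------------------------------------------------------------------------
# taxonomy assignment


def _query_clade_refs(
    tree: TreeNode, query: str, ref_ids: set[str]
) -> list[str]:
    """References in the smallest query-containing clade with >= 2 of them.

    Clades are read off the unrooted tree: every edge splits the leaves in
    two, and the side holding the query is a candidate clade (this makes
    the choice independent of where the rooted representation happens to
    put its root). Among candidates with at least two references the one
    with fewest leaves wins; exact ties (a query equidistant between
    groups) are resolved conservatively by taking their union, which can
    only reduce the consensus resolution.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    candidates: list[frozenset[str]] = []
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset(
            {node.name}
        )
        comp = side if query in side else all_tips - side
        if len(comp & ref_ids) >= 2:
            candidates.append(comp)
    if not candidates:
        return []
    min_size = min(len(c) for c in candidates)
    union: set[str] = set()
    for c in candidates:
        if len(c) == min_size:
            union |= c
    return sorted(union & ref_ids)


def assign_taxonomy(
    tree: TreeNode,
    dm: DistanceMatrix,
    refs: Sequence[ReferenceEntry],
    query_labels: Sequence[str],
    consensus_threshold: float = 0.75,
    long_branch_quantile: float = 0.95,
    zero_epsilon: float = 1e-12,
) -> list[TaxonAssignment]:
    """Label queries by nearest reference and clade rank-consensus.

    For each query: the nearest reference minimizes patristic (tree-path)
    distance; the assigned lineage is the deepest rank prefix on which at
    least ``consensus_threshold`` of the references in the smallest
    query-containing clade with >= 2 references agree (an empty prefix is
    reported "unidentified"). A query whose patristic distance to a
    reference is (numerically) zero inherits that reference's full lineage.
    The ``-like`` caution flag is raised when the query's terminal branch
    exceeds the ``long_branch_quantile`` of reference terminal branch
    lengths.
    """
    lineages = {e.ref_id: e.lineage for e in refs}
    tips = {t.name: t for t in tree.tips()}
    missing = [q for q in query_labels if q not in tips]
    if missing:
        raise PlacementError(f"queries absent from tree: {missing}")
    patristic = tree.tip_tip_distances()
    ref_ids = [r for r in lineages if r in tips]
    if not ref_ids:
        raise PlacementError("no reference leaves in tree")
    ref_term = np.array([tips[r].length or 0.0 for r in ref_ids])
    long_branch_cut = float(np.quantile(ref_term, long_branch_quantile))

    out: list[TaxonAssignment] = []
    for q in query_labels:
        dists = sorted(
            ((float(patristic[q, r]), r) for r in ref_ids), key=lambda t: (t[0], t[1])
        )
        nearest_d, nearest_ref = dists[0]
        like = (tips[q].length or 0.0) > long_branch_cut

        if nearest_d <= zero_epsilon:
            assigned = lineages[nearest_ref]
            fraction = 1.0
        else:
            clade_refs = _query_clade_refs(tree, q, set(ref_ids))
            if not clade_refs:
                clade_refs = ref_ids
            assigned_list: list[str] = []
            fraction = 0.0
            for rank_i in range(max(len(lineages[r]) for r in clade_refs)):
                votes: dict[str, int] = {}
                for r in clade_refs:
                    if len(lineages[r]) > rank_i:
                        votes[lineages[r][rank_i]] = votes.get(lineages[r][rank_i], 0) + 1
                if not votes:
                    break
                top_label, top_n = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
                frac = top_n / len(clade_refs)
                if frac >= consensus_threshold:
                    assigned_list.append(top_label)
                    fraction = frac
                else:
                    break
            assigned = tuple(assigned_list)
        out.append(
            TaxonAssignment(
                locus_name=q,
                nearest_ref_id=nearest_ref,
                nearest_distance=nearest_d,
                assigned_lineage=tuple(assigned),
                like_flag=like,
                consensus_fraction=fraction,
            )
        )
    return out


def assignments_to_frame(assignments: Sequence[TaxonAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_name": a.locus_name,
                "nearest_ref_id": a.nearest_ref_id,
                "nearest_distance": a.nearest_distance,
                "assigned_lineage": ";".join(a.assigned_lineage) or "unidentified",
                "label": a.label,
                "like_flag": a.like_flag,
                "consensus_fraction": a.consensus_fraction,
            }
            for a in assignments
        ]
    )
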