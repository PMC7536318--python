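"""Independent oracles used by the test suite.

Each oracle re-derives an expected value along a different route than the
implementation it checks: exhaustive enumeration for motif scanning and
tree topologies, a from-scratch Gotoh dynamic program for alignment, and
the closed-form hypergeometric detection probability for rarefaction.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


def brute_force_scan(positions, seq):
    """All motif windows by direct enumeration: 1-based starts."""
    k = len(positions)
    seq = seq.upper()
    hits = []
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        if all(window[i] in positions[i] for i in range(k)):
            hits.append((start + 1, window))
    return hits


# ---------------------------------------------------------------------------
# Gotoh global alignment with affine gaps (end gaps penalized)

NEG = -1e18


def gotoh_global(a, b, matrix, gap_open=-10.0, gap_extend=-1.0):
    """Optimal global alignment score and one traceback.

    Gap of length L costs |gap_open| + (L-1)*|gap_extend|, end gaps
    included. Returns (score, aligned_a, aligned_b) with '-' gaps.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to '-')
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback (one optimal path)
    out_a, out_b = [], []
    i, j = n, m
    state = max(((M[n, m], "M"), (X[n, m], "X"), (Y[n, m], "Y")))[1]
    while i > 0 or j > 0:
        if state == "M":
            s = matrix[a[i - 1], b[j - 1]]
            prev = [(M[i - 1, j - 1], "M"), (X[i - 1, j - 1], "X"), (Y[i - 1, j - 1], "Y")]
            state = max(prev)[1]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == "X":
            cands = [(M[i - 1, j] + gap_open, "M"), (X[i - 1, j] + gap_extend, "X"),
                     (Y[i - 1, j] + gap_open, "Y")]
            state = max(cands)[1]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            cands = [(M[i, j - 1] + gap_open, "M"), (Y[i, j - 1] + gap_extend, "Y"),
                     (X[i, j - 1] + gap_open, "X")]
            state = max(cands)[1]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def poisson_distance_from_alignment(aligned_a, aligned_b, d_max=5.0):
    cols = mism = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            cols += 1
            mism += x != y
    p = mism / cols
    if p >= 1 - math.exp(-d_max):
        return d_max
    return -math.log(1 - p)


# ---------------------------------------------------------------------------
# exhaustive 5-taxon topology oracle


def five_taxon_topologies(labels):
    """All 15 unrooted binary shapes: (cherry1, cherry2, middle leaf)."""
    labels = sorted(labels)
    out = []
    for middle in labels:
        rest = [l for l in labels if l != middle]
        a = rest[0]
        for partner in rest[1:]:
            cherry1 = frozenset({a, partner})
            cherry2 = frozenset(set(rest) - cherry1)
            out.append((cherry1, cherry2, middle))
    return out


def topology_fit(dm_lookup, labels, topology):
    """Least-squares branch lengths for one 5-taxon shape; returns residual.

    Branch order: terminal x5 (sorted labels), internal e1 (cherry1 side),
    e2 (cherry2 side). Path matrix solved with numpy lstsq.
    """
    cherry1, cherry2, middle = topology
    labels = sorted(labels)
    col = {l: i for i, l in enumerate(labels)}
    n_params = 7

    def path_row(x, y):
        row = np.zeros(n_params)
        row[col[x]] = 1
        row[col[y]] = 1
        # internal edges crossed between the three attachment points
        def side(l):
            if l in cherry1:
                return 0
            if l in cherry2:
                return 2
            return 1
        sx, sy = sorted((side(x), side(y)))
        if (sx, sy) == (0, 1):
            row[5] = 1
        elif (sx, sy) == (1, 2):
            row[6] = 1
        elif (sx, sy) == (0, 2):
            row[5] = 1
            row[6] = 1
        return row

    rows, rhs = [], []
    for x, y in itertools.combinations(labels, 2):
        rows.append(path_row(x, y))
        rhs.append(dm_lookup(x, y))
    A = np.array(rows)
    b = np.array(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.abs(A @ sol - b).max())
    return residual, sol


def best_additive_topology(dm_lookup, labels):
    """The unique shape (if any) fitting the matrix additively."""
    fits = [
        (topology_fit(dm_lookup, labels, t)[0], t)
        for t in five_taxon_topologies(labels)
    ]
    fits.sort(key=lambda x: x[0])
    return fits[0]


def normalize_splits(splits, all_labels):
    """Express bipartitions by the side not containing the smallest label."""
    anchor = min(all_labels)
    return {
        s if anchor not in s else frozenset(set(all_labels) - s) for s in splits
    }


def tree_splits(tree):
    """Non-trivial bipartitions of an skbio TreeNode, normalized."""
    all_labels = {t.name for t in tree.tips()}
    anchor = min(all_labels)
    out = set()
    for node in tree.non_tips():
        if node.is_root():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_labels) - 1:
            out.add(side if anchor not in side else frozenset(all_labels - side))
    return out


# ---------------------------------------------------------------------------
# rarefaction closed form


def expected_detected(counts, total, depth):
    """E[detected genes] = sum_g (1 - P(gene g missed at this depth))."""
    e = 0.0
    for k in counts:
        e += 1.0 - hypergeom.pmf(0, total, k, depth)
    return e
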