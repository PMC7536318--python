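import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from _oracles import (
    best_additive_topology,
    gotoh_global,
    normalize_splits,
    poisson_distance_from_alignment,
    tree_splits,
)
from hgcmine import placement as pl
from hgcmine import synthetic as syn


class TestPairwiseDistance:
    def test_identical_sequences_distance_zero(self):
        seq = syn.hgca_consensus()
        assert pl.pairwise_distance(seq, seq) == 0.0

    def test_one_mismatch_in_hundred_gives_poisson_corrected_distance(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        b = a[:50] + ("W" if a[50] != "W" else "Y") + a[51:]
        assert pl.pairwise_distance(a, b) == pytest.approx(-math.log(0.99), abs=1e-9)

    def test_distances_match_independent_gotoh_oracle(self):
        rng = np.random.default_rng(9)
        base = syn.hgcb_consensus()
        seqs = [syn.mutate(base, r, rng) for r in (0.0, 0.05, 0.1, 0.2, 0.3)]
        blosum = substitution_matrices.load("BLOSUM62")
        aligner = pl.make_aligner()
        for a, b in itertools.combinations(seqs, 2):
            score, ga, gb = gotoh_global(a, b, blosum)
            assert aligner.score(a, b) == pytest.approx(score)
            d_oracle = poisson_distance_from_alignment(ga, gb)
            assert pl.pairwise_distance(a, b) == pytest.approx(d_oracle, abs=0.02)

    def test_matrix_symmetric_with_zero_diagonal(self, reference_fixture):
        queries = {"Q": syn.hgca_consensus()}
        dm = pl.compute_distances(queries, reference_fixture[:4], mode="hgcA")
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0.0)


class TestNeighborJoining:
    def test_three_taxon_closed_form_branch_lengths(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"])
        tree = pl.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @staticmethod
    def _additive_case():
        # generating tree: ((A:1,B:2):1, E:2, (C:3,D:1):2) — caterpillar
        labels = ["A", "B", "C", "D", "E"]
        term = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0, "E": 2.0}
        e1, e2 = 1.0, 2.0  # internal edges cherry(A,B)–center, center–cherry(C,D)

        def dist(x, y):
            if x == y:
                return 0.0
            side = {"A": 0, "B": 0, "C": 2, "D": 2, "E": 1}
            extra = {(0, 0): 0, (0, 1): e1, (1, 2): e2, (0, 2): e1 + e2, (2, 2): 0,
                     (1, 1): 0}
            sx, sy = sorted((side[x], side[y]))
            return term[x] + term[y] + extra[(sx, sy)]

        data = [[dist(x, y) for y in labels] for x in labels]
        return DistanceMatrix(data, ids=labels), dist

    def test_recovers_additive_five_taxon_tree_exactly(self):
        dm, dist = self._additive_case()
        tree = pl.nj_tree(dm)
        # path distances reproduce the additive matrix to machine precision
        patristic = tree.tip_tip_distances()
        for x, y in itertools.combinations(dm.ids, 2):
            assert patristic[x, y] == pytest.approx(dist(x, y), abs=1e-9)
        # topology equals the exhaustive-enumeration oracle's additive fit
        residual, (cherry1, cherry2, middle) = best_additive_topology(dist, dm.ids)
        assert residual < 1e-9
        assert middle == "E"
        assert tree_splits(tree) == normalize_splits(
            {frozenset(cherry1), frozenset(cherry2)}, list(dm.ids)
        )

    def test_agrees_with_skbio_reference_implementation(self):
        dm, _ = self._additive_case()
        ours = pl.nj_tree(dm)
        theirs = skbio_nj(dm)
        assert tree_splits(ours) == tree_splits(theirs)
        ours_d = ours.tip_tip_distances()
        theirs_d = theirs.tip_tip_distances()
        for x, y in itertools.combinations(dm.ids, 2):
            assert ours_d[x, y] == pytest.approx(theirs_d[x, y], abs=1e-9)

    def test_label_permutation_yields_isomorphic_tree(self):
        dm, _ = self._additive_case()
        perm = ["D", "A", "E", "C", "B"]
        data = [[dm[x, y] for y in perm] for x in perm]
        tree2 = pl.nj_tree(DistanceMatrix(data, ids=perm))
        tree1 = pl.nj_tree(dm)
        assert tree_splits(tree1) == tree_splits(tree2)
        d1, d2 = tree1.tip_tip_distances(), tree2.tip_tip_distances()
        for x, y in itertools.combinations(dm.ids, 2):
            assert d1[x, y] == pytest.approx(d2[x, y], abs=1e-12)

    def test_fewer_than_three_labels_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"])
        with pytest.raises(pl.PlacementError):
            pl.nj_tree(dm)

    def test_bootstrap_supports_well_separated_clades(self):
        rng = np.random.default_rng(12)
        base = syn.hgcb_consensus()
        far = syn.mutate(base, 0.4, rng)
        msa = {
            "A1": syn.mutate(base, 0.02, rng),
            "A2": syn.mutate(base, 0.02, rng),
            "B1": syn.mutate(far, 0.02, rng),
            "B2": syn.mutate(far, 0.02, rng),
            "C": syn.mutate(base, 0.25, rng),
        }
        dm = pl.msa_distances(msa)
        tree = pl.nj_tree(dm, bootstrap_replicates=50, seed=5, msa=msa)
        supports = [
            getattr(n, "support", None)
            for n in tree.non_tips()
            if not n.is_root()
        ]
        assert supports and all(s is not None for s in supports)
        assert max(supports) > 0.8

    def test_bootstrap_without_msa_rejected(self):
        dm, _ = self._additive_case()
        with pytest.raises(pl.PlacementError, match="MSA"):
            pl.nj_tree(dm, bootstrap_replicates=10)


class TestReferenceSet:
    def test_fixture_round_trip_and_modes(self, tmp_path, reference_fixture):
        paths = syn.write_reference_fixture(reference_fixture, tmp_path)
        entries = pl.load_reference_set(
            {"hgcA": paths["hgcA"], "hgcB": paths["hgcB"], "concat": paths["concat"]},
            paths["taxonomy"],
        )
        assert len(entries) == 20
        assert all(len(e.lineage) == 6 for e in entries)
        assert all(e.sequence("concat") for e in entries)

    def test_entry_without_taxonomy_dropped_with_warning(self, tmp_path):
        (tmp_path / "refs.faa").write_text(">r1\nMKL\n>r2\nMNP\n")
        (tmp_path / "tax.tsv").write_text("ref_id\tlineage\nr1\tBacteria;P1\n")
        with pytest.warns(UserWarning, match="r2"):
            entries = pl.load_reference_set(
                {"hgcA": tmp_path / "refs.faa"}, tmp_path / "tax.tsv"
            )
        assert [e.ref_id for e in entries] == ["r1"]

    def test_duplicate_ref_id_is_hard_error(self, tmp_path):
        (tmp_path / "refs.faa").write_text(">r1\nMKL\n")
        (tmp_path / "tax.tsv").write_text(
            "ref_id\tlineage\nr1\tBacteria\nr1\tArchaea\n"
        )
        with pytest.raises(pl.PlacementError, match="duplicate"):
            pl.load_reference_set({"hgcA": tmp_path / "refs.faa"}, tmp_path / "tax.tsv")


class TestAssignTaxonomy:
    def test_zero_distance_query_inherits_full_reference_lineage(self, reference_fixture):
        refs = reference_fixture
        query = {"Q0": refs[0].concat_seq}
        dm = pl.compute_distances(query, refs, mode="concat")
        tree = pl.nj_tree(dm)
        a = pl.assign_taxonomy(tree, dm, refs, ["Q0"])[0]
        assert a.nearest_ref_id == refs[0].ref_id
        assert a.nearest_distance == pytest.approx(0.0, abs=1e-12)
        assert a.assigned_lineage == refs[0].lineage
        assert not a.like_flag

    def test_divergent_query_gets_like_suffix(self, reference_fixture):
        rng = np.random.default_rng(21)
        query = {"Qfar": syn.mutate(reference_fixture[0].concat_seq, 0.35, rng)}
        dm = pl.compute_distances(query, reference_fixture, mode="concat")
        tree = pl.nj_tree(dm)
        a = pl.assign_taxonomy(tree, dm, reference_fixture, ["Qfar"])[0]
        assert a.like_flag
        if a.assigned_lineage:
            assert a.label.endswith("-like")
        else:
            assert a.label == "unidentified"

    def test_split_clade_truncates_above_disputed_rank(self):
        # additive tree with the query on the central edge, equidistant
        # between a PhylumX cherry and a PhylumY cherry
        labels = ["Q", "R0", "R1", "R2", "R3"]
        side = {"Q": 1, "R0": 0, "R1": 0, "R2": 2, "R3": 2}
        term = {"Q": 0.1, "R0": 0.1, "R1": 0.1, "R2": 0.1, "R3": 0.1}
        extra = {(0, 1): 0.4, (1, 2): 0.4, (0, 2): 0.8}

        def dist(x, y):
            if x == y:
                return 0.0
            sx, sy = sorted((side[x], side[y]))
            return term[x] + term[y] + extra.get((sx, sy), 0.0)

        dm = DistanceMatrix([[dist(x, y) for y in labels] for x in labels],
                            ids=labels)
        refs = [
            pl.ReferenceEntry(
                ref_id=f"R{i}",
                lineage=("Bacteria", phylum, f"Class{i}"),
                hgcB_seq="M",
            )
            for i, phylum in enumerate(
                ["PhylumX", "PhylumX", "PhylumY", "PhylumY"]
            )
        ]
        tree = pl.nj_tree(dm)
        a = pl.assign_taxonomy(tree, dm, refs, ["Q"], consensus_threshold=0.75)[0]
        # domain is unanimous; phylum splits 50/50 below the 75% threshold
        assert a.assigned_lineage == ("Bacteria",)

    def test_empty_consensus_reports_unidentified(self):
        base = syn.hgcb_consensus()
        rng = np.random.default_rng(31)
        refs = [
            pl.ReferenceEntry(
                ref_id=f"R{i}",
                lineage=(dom, f"P{i}"),
                hgcB_seq=syn.mutate(base, 0.3, rng),
            )
            for i, dom in enumerate(["Bacteria", "Archaea", "Bacteria", "Archaea"])
        ]
        query = {"Q": syn.mutate(base, 0.1, rng)}
        dm = pl.compute_distances(query, refs, mode="hgcB")
        tree = pl.nj_tree(dm)
        a = pl.assign_taxonomy(tree, dm, refs, ["Q"], consensus_threshold=0.75)[0]
        if not a.assigned_lineage:
            assert a.label == "unidentified"

    def test_assignment_invariant_to_reference_order(self, reference_fixture):
        rng = np.random.default_rng(40)
        query = {"Q": syn.mutate(reference_fixture[5].concat_seq, 0.04, rng)}
        dm = pl.compute_distances(query, reference_fixture, mode="concat")
        tree = pl.nj_tree(dm)
        fwd = pl.assign_taxonomy(tree, dm, reference_fixture, ["Q"])[0]
        rev = pl.assign_taxonomy(tree, dm, reference_fixture[::-1], ["Q"])[0]
        assert fwd == rev

    def test_query_missing_from_tree_is_error(self, reference_fixture):
        query = {"Q": reference_fixture[0].concat_seq}
        dm = pl.compute_distances(query, reference_fixture, mode="concat")
        tree = pl.nj_tree(dm)
        with pytest.raises(pl.PlacementError, match="ghost"):
            pl.assign_taxonomy(tree, dm, reference_fixture, ["ghost"])


def test_newick_round_trip(tmp_path):
    dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"])
    tree = pl.nj_tree(dm)
    pl.write_newick(tree, tmp_path / "t.nwk")
    back = pl.read_newick(tmp_path / "t.nwk")
    assert {t.name for t in back.tips()} == {"A", "B", "C"}
    d = back.tip_tip_distances()
    assert d["A", "C"] == pytest.approx(4.0)
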