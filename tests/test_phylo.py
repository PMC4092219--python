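"""Alignment, supermatrix, NJ exactness, bootstrap determinism."""

import math

import numpy as np
import pytest

from singlecopy import phylo
from singlecopy.phylo import (
    Supermatrix,
    bipartitions,
    bootstrap,
    concatenate,
    distance_matrix,
    gene_alignment,
    nj_tree,
    root_on_outgroup,
    sum_of_pairs_score,
)


class TestGeneAlignment:
    def test_identical_sequences_gapless(self):
        aln = gene_alignment({"A": "ACGTACGT", "B": "ACGTACGT", "C": "ACGTACGT"})
        assert all(v == "ACGTACGT" for v in aln.values())

    def test_insertion_makes_gap_block_in_others(self):
        aln = gene_alignment(
            {"A": "ACGTACGT", "B": "ACGTTTTTACGT", "C": "ACGTACGT"}
        )
        assert len(set(map(len, aln.values()))) == 1
        assert "----" in aln["A"] and "----" in aln["C"]
        assert "-" not in aln["B"]

    def test_sum_of_pairs_at_least_center_star_oracle(self):
        # oracle: naive center-star with the first taxon as center,
        # merged in input order
        fixtures = [
            {"A": "ACGTAC", "B": "ACTTAC", "C": "ACGAAC"},
            {"A": "AAGTTTCC", "B": "AAGTTCC", "C": "ACGTTTCC", "D": "AAGTTTGC"},
            {"A": "GATTACA", "B": "GATTA", "C": "ATTACA"},
        ]
        from singlecopy.phylo import _merge_into_profile

        for seqs in fixtures:
            taxa = list(seqs)
            profile = [seqs[taxa[0]]]
            for t in taxa[1:]:
                profile = _merge_into_profile(profile, seqs[t])
            oracle = dict(zip(taxa, profile))
            ours = gene_alignment(seqs)
            assert sum_of_pairs_score(ours) >= sum_of_pairs_score(oracle)

    def test_missing_sequence_raises(self):
        with pytest.raises(ValueError, match="missing"):
            gene_alignment({"A": "ACGT", "B": ""})


class TestConcatenate:
    def _alns(self):
        return {
            "g1": {"A": "ACGTACGTA", "B": "ACGTACGTA"},
            "g2": {"A": "ACGTACGTACGT", "B": "AGGTACGTACGT"},
        }

    def test_lengths_and_partitions(self):
        sm = concatenate(self._alns(), ["A", "B"])
        assert sm.length == 21
        assert sm.partitions == [("g1", 1, 9), ("g2", 10, 21)]

    def test_order_permutation_preserves_distances(self):
        alns = self._alns()
        sm1 = concatenate(alns, ["A", "B"])
        sm2 = concatenate(dict(reversed(alns.items())), ["A", "B"])
        d1 = distance_matrix(sm1, model="p")
        d2 = distance_matrix(sm2, model="p")
        assert np.allclose(d1, d2)
        assert sm1.partitions != sm2.partitions

    def test_missing_taxon_raises(self):
        with pytest.raises(ValueError, match="missing"):
            concatenate({"g1": {"A": "ACG"}}, ["A", "B"])


class TestDistances:
    def _sm(self, rows):
        taxa = list(rows)
        length = len(next(iter(rows.values())))
        return Supermatrix(taxa=taxa, rows=rows, partitions=[("all", 1, length)])

    def test_identical_rows_zero(self):
        d = distance_matrix(self._sm({"A": "ACGT" * 5, "B": "ACGT" * 5}))
        assert d[0, 1] == 0.0

    def test_jc_closed_form_at_p_ten_percent(self):
        rows = {"A": "A" * 100, "B": "C" * 10 + "A" * 90}
        d = distance_matrix(self._sm(rows), model="JC")
        assert d[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-9)
        assert round(d[0, 1], 6) == 0.107326

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        rows = {
            t: "".join("ACGT"[i] for i in rng.integers(0, 4, 60)) for t in "ABCD"
        }
        d = distance_matrix(self._sm(rows), model="p")
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_gap_columns_removed_pairwise(self):
        rows = {"A": "AC-T", "B": "ACGT"}
        d = distance_matrix(self._sm(rows), model="p")
        assert d[0, 1] == 0.0

    def test_jc_saturation_raises(self):
        rows = {"A": "A" * 10, "B": "C" * 10}
        with pytest.raises(ValueError, match="saturation"):
            distance_matrix(self._sm(rows), model="JC")


def _additive_matrix():
    # tree ((A:2,B:3):1,C:6,D:7) with internal edge 1 between {A,B} and {C,D}
    # pairwise path lengths are additive by construction
    taxa = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0.0, 5.0, 9.0, 10.0],
            [5.0, 0.0, 10.0, 11.0],
            [9.0, 10.0, 0.0, 13.0],
            [10.0, 11.0, 0.0 + 13.0, 0.0],
        ]
    )
    return d, taxa


class TestNeighborJoining:
    def test_additive_four_taxon_exact_recovery(self):
        d, taxa = _additive_matrix()
        tree = nj_tree(d, taxa)
        assert frozenset({"A", "B"}) in bipartitions(tree) or frozenset(
            {"C", "D"}
        ) in bipartitions(tree)
        # branch lengths: leaf edges recover the generating values
        lengths = {}

        def collect(node):
            for c in node.children:
                if not c.children:
                    lengths[c.name] = c.length
                collect(c)

        collect(tree)
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)

    def test_matches_skbio_topology_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 6
            taxa = [f"t{i}" for i in range(n)]
            # random additive-ish noisy matrix, symmetric, zero diagonal
            base = rng.uniform(0.1, 1.0, size=(n, n))
            d = (base + base.T) / 2
            np.fill_diagonal(d, 0.0)
            ours = nj_tree(d, taxa)
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
            assert (
                phylo.robinson_foulds(ours.newick(), str(ref).strip()) == 0
            )

    def test_star_distances_deterministic(self):
        taxa = ["A", "B", "C", "D"]
        d = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(d, taxa).newick()
        t2 = nj_tree(d, taxa).newick()
        assert t1 == t2

    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["A", "B"])


class TestRooting:
    def test_roots_on_monophyletic_outgroup(self):
        d, taxa = _additive_matrix()
        tree = nj_tree(d, taxa)
        nwk = root_on_outgroup(tree, ["C", "D"])
        assert nwk.count("(") >= 2

    def test_non_monophyletic_outgroup_raises(self):
        d, taxa = _additive_matrix()
        tree = nj_tree(d, taxa)
        with pytest.raises(ValueError, match="monophyletic"):
            root_on_outgroup(tree, ["A", "C"])

    def test_unknown_outgroup_raises(self):
        d, taxa = _additive_matrix()
        with pytest.raises(ValueError, match="unknown"):
            root_on_outgroup(nj_tree(d, taxa), ["Z"])


class TestBootstrap:
    def _signal_matrix(self):
        # two clades with abundant, consistent signal
        rows = {
            "A": "A" * 30 + "C" * 30,
            "B": "A" * 30 + "C" * 28 + "T" * 2,
            "C": "G" * 30 + "C" * 30,
            "D": "G" * 30 + "C" * 28 + "A" * 2,
        }
        return Supermatrix(taxa=list(rows), rows=rows, partitions=[("all", 1, 60)])

    def test_saturated_signal_gives_full_support(self):
        tree = bootstrap(self._signal_matrix(), replicates=50, seed=5, model="p")
        supports = []

        def collect(node):
            for c in node.children:
                if c.support is not None:
                    supports.append(c.support)
                collect(c)

        collect(tree)
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_reproducible(self):
        t1 = bootstrap(self._signal_matrix(), replicates=30, seed=9, model="p")
        t2 = bootstrap(self._signal_matrix(), replicates=30, seed=9, model="p")
        assert t1.newick() == t2.newick()

    def test_simulated_true_edges_outrank_false_edges(self, sim_result, pipeline_result):
        gs = sim_result.genome_set.index()
        taxa = sim_result.genome_set.genome_ids
        alns = {}
        for c in pipeline_result.shared[:6]:
            seqs = {m.split("|", 1)[0]: gs[m].cds for m in c.members}
            alns[c.cluster_id] = gene_alignment(seqs)
        sm = concatenate(alns, taxa)
        tree = bootstrap(sm, replicates=100, seed=2)
        true_nwk = sim_result.config.species_tree
        assert phylo.robinson_foulds(tree.newick(), true_nwk) == 0
        supports = []

        def collect(node):
            for c in node.children:
                if c.support is not None:
                    supports.append(c.support)
                collect(c)

        collect(tree)
        assert supports and min(supports) >= 90.0
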