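import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitolepi as ml
from mitolepi.phylo import (
    DistanceMatrix,
    build_supermatrix,
    distances,
    is_monophyletic,
    k2p_distance,
    nj_tree,
    read_partitions,
)
from mitolepi.simulate import DEFAULT_GENE_LENGTHS, same_topology

from oracles import best_ls_topology, random_additive_tree


def sets_from_lengths(lengths, taxa=("tax1",)):
    return {t: {g: "A" * n for g, n in lengths.items()} for t in taxa}


class TestSupermatrix:
    def test_published_pcg_lengths_concatenate_to_11222(self):
        sm = build_supermatrix(sets_from_lengths(DEFAULT_GENE_LENGTHS))
        assert sm.nchar == 11222
        assert len(sm.genes) == 13

    def test_identical_taxa_give_identical_rows(self):
        sm = build_supermatrix(sets_from_lengths(DEFAULT_GENE_LENGTHS, ("a", "b")))
        assert sm.rows["a"] == sm.rows["b"]

    def test_missing_gene_becomes_gap_block(self):
        sets = sets_from_lengths(DEFAULT_GENE_LENGTHS, ("a", "b"))
        del sets["b"]["nad6"]
        sm = build_supermatrix(sets)
        assert sm.nchar == 11222
        a, b = sm.block_ranges["nad6"]
        assert sm.rows["b"][a - 1:b] == "-" * 528

    def test_column_count_invariant_to_taxon_order(self):
        sets = sets_from_lengths(DEFAULT_GENE_LENGTHS, ("a", "b", "c"))
        reversed_sets = dict(reversed(list(sets.items())))
        assert build_supermatrix(sets).nchar == build_supermatrix(reversed_sets).nchar

    def test_unequal_prealigned_block_is_an_error_naming_the_gene(self):
        sets = sets_from_lengths({"nad2": 30}, ("a", "b"))
        sets["b"]["nad2"] = "A" * 33
        with pytest.raises(ValueError, match="nad2"):
            build_supermatrix(sets)

    def test_taxon_without_genes_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            build_supermatrix({"a": {"nad2": "AAA"}, "b": {}})

    def test_partition_schemes_and_round_trip(self, tmp_path):
        sm = build_supermatrix(sets_from_lengths(DEFAULT_GENE_LENGTHS))
        assert len(sm.partition_table("gene")) == 13
        assert len(sm.partition_table("codon")) == 39
        first = sm.partition_table("codon")[0]
        assert first == ("nad2_pos1", 1, 1014, 3)
        p = tmp_path / "parts.txt"
        sm.write_partitions(p, scheme="codon")
        assert read_partitions(p) == sm.partition_table("codon")
        # partitions tile the matrix without overlap
        cols = set()
        for _, a, b, _ in sm.partition_table("gene"):
            block = set(range(a, b + 1))
            assert not cols & block
            cols |= block
        assert cols == set(range(1, sm.nchar + 1))

    def test_phylip_and_nexus_writers(self, tmp_path):
        sm = build_supermatrix(sets_from_lengths({"nad2": 12}, ("a", "b")))
        sm.to_phylip(tmp_path / "m.phy")
        sm.to_nexus(tmp_path / "m.nex")
        assert (tmp_path / "m.phy").read_text().splitlines()[0] == "2 12"
        assert "NCHAR=12" in (tmp_path / "m.nex").read_text()


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        sm = build_supermatrix(sets_from_lengths({"nad2": 30}, ("a", "b")))
        for model in ("p", "K2P"):
            assert distances(sm, model=model).get("a", "b") == 0.0

    def test_k2p_closed_form_on_constructed_pair(self):
        # 100 sites: 10 transitions (A->G), 5 transversions (A->C)
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        sm = build_supermatrix({"a": {"nad2": s1}, "b": {"nad2": s2}})
        d = distances(sm, model="K2P").get("a", "b")
        assert d == pytest.approx(-0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1)))
        assert distances(sm, model="p").get("a", "b") == pytest.approx(0.15)

    def test_k2p_dominates_p_distance(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = 300
            s1 = "".join(rng.choice(list("ACGT"), size=n))
            # mutate a random fraction
            idx = rng.random(n) < rng.uniform(0.02, 0.4)
            bases = rng.choice(list("ACGT"), size=n)
            s2 = "".join(b if not m else nb for b, nb, m in zip(s1, bases, idx))
            sm = build_supermatrix({"a": {"nad2": s1}, "b": {"nad2": s2}})
            dk = distances(sm, model="K2P").get("a", "b")
            dp = distances(sm, model="p").get("a", "b")
            assert dk >= dp - 1e-12

    def test_pairwise_deletion_skips_gapped_sites(self):
        sm = build_supermatrix({"a": {"nad2": "AAAAAA"}, "b": {"nad2": "AAA--G"}})
        assert distances(sm, model="p").get("a", "b") == pytest.approx(1 / 4)

    def test_saturated_pair_capped_and_flagged(self):
        sm = build_supermatrix({"a": {"nad2": "A" * 40}, "b": {"nad2": "G" * 20 + "C" * 20}})
        dm = distances(sm, model="K2P", saturation_cap=7.5)
        assert dm.get("a", "b") == 7.5
        assert ("a", "b") in dm.saturated

    def test_zero_comparable_sites_is_an_error(self):
        sm = build_supermatrix({"a": {"nad2": "AAA---"}, "b": {"nad2": "---GGG"}})
        with pytest.raises(ValueError, match="a / b"):
            distances(sm, model="p")

    def test_saturation_guard_in_closed_form(self):
        with pytest.raises(ValueError, match="saturated"):
            k2p_distance(0.5, 0.2)


class TestNeighborJoining:
    def test_additive_four_taxon_case_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) in path-distance form
        taxa = ("A", "B", "C", "D")
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(taxa=taxa, matrix=D, model="p"))
        assert same_topology(tree, "((A:1,B:2):1,(C:3,D:4):0);")
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxon_closed_form(self):
        taxa = ("A", "B", "C")
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(taxa=taxa, matrix=D, model="p"))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_five_taxon_topology_matches_exhaustive_least_squares(self):
        rng = np.random.default_rng(11)
        taxa = ["A", "B", "C", "D", "E"]
        for _ in range(10):
            newick, dist = random_additive_tree(rng, 5)
            # relabel to A..E
            mapping = dict(zip([f"T{i}" for i in range(5)], taxa))
            dist = {frozenset(mapping[x] for x in k): v for k, v in dist.items()}
            for old, new in mapping.items():
                newick = newick.replace(old + ":", new + ":")
            n = len(taxa)
            D = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                D[i, j] = D[j, i] = dist[frozenset((taxa[i], taxa[j]))]
            tree = nj_tree(DistanceMatrix(taxa=tuple(taxa), matrix=D, model="p"))
            assert same_topology(tree, newick)
            # agreement with brute-force least squares over all 15 topologies
            best = best_ls_topology(taxa, dist)
            for split in best:
                outgroup = next(t for t in taxa if t not in split)
                assert is_monophyletic(tree, split, outgroup).monophyletic

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 12))
    def test_recovers_generating_topology_from_additive_distances(self, seed, n):
        rng = np.random.default_rng(seed)
        newick, dist = random_additive_tree(rng, n)
        labels = [f"T{i}" for i in range(n)]
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            D[i, j] = D[j, i] = dist[frozenset((labels[i], labels[j]))]
        tree = nj_tree(DistanceMatrix(taxa=tuple(labels), matrix=D, model="p"))
        assert same_topology(tree, newick)

    def test_matches_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        newick, dist = random_additive_tree(rng, 8)
        labels = [f"T{i}" for i in range(8)]
        D = np.zeros((8, 8))
        for i, j in itertools.combinations(range(8), 2):
            D[i, j] = D[j, i] = dist[frozenset((labels[i], labels[j]))]
        # jitter so the comparison is not the pure-additive special case
        noise = rng.uniform(0, 0.02, size=D.shape)
        D += noise + noise.T
        np.fill_diagonal(D, 0.0)
        ours = nj_tree(DistanceMatrix(taxa=tuple(labels), matrix=D, model="p"))
        theirs = skbio_nj(SkbioDM(D, ids=labels))
        import io

        buf = io.StringIO()
        theirs.write(buf)
        assert same_topology(ours, buf.getvalue().strip())

    def test_fewer_than_three_taxa_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(taxa=("a", "b"), matrix=D, model="p"))

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(DistanceMatrix(taxa=("a", "b", "c"), matrix=D, model="p"))


class TestMonophyly:
    @pytest.fixture()
    def tree(self):
        taxa = ("A", "B", "C", "D", "E")
        D = np.array(
            [
                [0, 2, 6, 6, 8],
                [2, 0, 6, 6, 8],
                [6, 6, 0, 4, 8],
                [6, 6, 4, 0, 8],
                [8, 8, 8, 8, 0],
            ],
            float,
        )
        return nj_tree(DistanceMatrix(taxa=taxa, matrix=D, model="p"))

    def test_single_taxon_is_trivially_monophyletic(self, tree):
        assert is_monophyletic(tree, ["A"], "E").monophyletic

    def test_full_ingroup_is_trivially_monophyletic(self, tree):
        assert is_monophyletic(tree, ["A", "B", "C", "D"], "E").monophyletic

    def test_cherry_and_non_clade(self, tree):
        assert is_monophyletic(tree, ["A", "B"], "E").monophyletic
        res = is_monophyletic(tree, ["A", "C"], "E")
        assert not res.monophyletic and res.clade is None

    def test_unknown_label_and_outgroup_in_query_rejected(self, tree):
        with pytest.raises(ValueError, match="not in tree"):
            is_monophyletic(tree, ["A", "Z"], "E")
        with pytest.raises(ValueError, match="outgroup"):
            is_monophyletic(tree, ["A", "E"], "E")
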