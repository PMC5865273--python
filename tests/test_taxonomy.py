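import math
import random
from itertools import combinations

import pytest

from taxocover.taxonomy import (
    NewickParseError,
    TaxonomyError,
    TaxonomyFormatError,
    caterpillar,
    complete_binary_tree,
    parse_newick,
    random_binary_tree,
    read_greengenes,
    read_ncbi_dump,
    write_ncbi_dump,
    write_newick,
)

import oracle


def clade_label_sets(tree):
    """Frozensets of leaf labels per node — a topology fingerprint that is
    independent of node ids and child order."""
    return sorted(
        (frozenset(tree.label(v) for v in tree.clade_leaves(j))
         for j in tree.nodes),
        key=sorted,
    )


class TestNewick:
    def test_smallest_cherry(self):
        tree = parse_newick("(A,B);")
        assert tree.n_leaves == 2
        assert len(tree.internal_nodes) == 1

    def test_two_cherries(self):
        tree = parse_newick("((A,B),(C,D));")
        assert tree.n_leaves == 4
        assert len(tree.internal_nodes) == 3
        assert tree.depth(tree.node_for_label("A")) == 2

    @pytest.mark.parametrize("bad", ["((A,B);", "(A,(B,);", "(A,A);", "(A,B),(A,C));"])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_duplicate_leaf_label_named_in_error(self):
        with pytest.raises(NewickParseError, match="A"):
            parse_newick("((A,B),(A,C));")

    def test_round_trip_random_trees(self, rng):
        for n in range(2, 13):
            tree = random_binary_tree(n, rng)
            back = parse_newick(write_newick(tree))
            assert clade_label_sets(back) == clade_label_sets(tree)


class TestNcbiDump:
    def write(self, tmp_path, nodes_rows, names_rows):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text("".join(f"{r}\t|\n" for r in nodes_rows))
        names.write_text("".join(f"{r}\t|\n" for r in names_rows))
        return nodes, names

    def test_three_row_path(self, tmp_path):
        nodes, names = self.write(
            tmp_path,
            ["1\t|\t1\t|\tno rank", "2\t|\t1\t|\tphylum", "3\t|\t2\t|\tspecies"],
            ["1\t|\troot\t|\t\t|\tscientific name",
             "2\t|\tProteobacteria\t|\t\t|\tscientific name",
             "3\t|\tE. coli\t|\t\t|\tscientific name"],
        )
        tree = read_ncbi_dump(nodes, names)
        leaf = tree.node_for_label("E. coli")
        assert tree.depth(leaf) == 2
        assert tree.rank(leaf) == "species"

    def test_seven_taxon_complete_tree(self, tmp_path):
        nodes, names = self.write(
            tmp_path,
            ["1\t|\t1\t|\tno rank", "2\t|\t1\t|\tno rank", "3\t|\t1\t|\tno rank",
             "4\t|\t2\t|\tspecies", "5\t|\t2\t|\tspecies",
             "6\t|\t3\t|\tspecies", "7\t|\t3\t|\tspecies"],
            [f"{i}\t|\tt{i}\t|\t\t|\tscientific name" for i in range(1, 8)],
        )
        tree = read_ncbi_dump(nodes, names)
        sizes = sorted(len(tree.clade_leaves(v)) for v in tree.internal_nodes)
        assert sizes == [2, 2, 4]

    def test_round_trip(self, tmp_path, rng):
        tree = random_binary_tree(9, rng)
        write_ncbi_dump(tree, tmp_path / "n.dmp", tmp_path / "m.dmp")
        back = read_ncbi_dump(tmp_path / "n.dmp", tmp_path / "m.dmp")
        assert clade_label_sets(back) == clade_label_sets(tree)

    def test_orphan_taxid(self, tmp_path):
        nodes, names = self.write(
            tmp_path,
            ["1\t|\t1\t|\tno rank", "3\t|\t2\t|\tspecies"],
            ["1\t|\troot\t|\t\t|\tscientific name",
             "3\t|\tx\t|\t\t|\tscientific name"],
        )
        with pytest.raises(TaxonomyFormatError, match="orphan"):
            read_ncbi_dump(nodes, names)

    def test_multiple_roots(self, tmp_path):
        nodes, names = self.write(
            tmp_path,
            ["1\t|\t1\t|\tno rank", "2\t|\t2\t|\tno rank"],
            ["1\t|\ta\t|\t\t|\tscientific name",
             "2\t|\tb\t|\t\t|\tscientific name"],
        )
        with pytest.raises(TaxonomyFormatError, match="root"):
            read_ncbi_dump(nodes, names)


class TestGreengenes:
    def test_shared_phylum(self, tmp_path):
        path = tmp_path / "gg.tsv"
        path.write_text(
            "s1\tk__B; p__P; c__C1; o__O1; f__F1; g__G1; s__sp1\n"
            "s2\tk__B; p__P; c__C2; o__O2; f__F2; g__G2; s__sp2\n")
        tree = read_greengenes(path)
        lca = tree.lca([tree.node_for_label("s1"), tree.node_for_label("s2")])
        assert tree.label(lca) == "p__P"
        assert tree.rank(lca) == "phylum"

    def test_empty_species_attaches_at_genus(self, tmp_path):
        path = tmp_path / "gg.tsv"
        path.write_text("s1\tk__B; p__P; c__C; o__O; f__F; g__G; s__\n")
        tree = read_greengenes(path)
        parent = tree.parent(tree.node_for_label("s1"))
        assert tree.label(parent) == "g__G"
        assert tree.rank(parent) == "genus"

    def test_internal_count_equals_distinct_prefixes(self, tmp_path):
        lineages = [
            ("a", "k__B; p__P1; c__C1"),
            ("b", "k__B; p__P1; c__C2"),
            ("c", "k__B; p__P2"),
            ("d", "k__B; p__P2; c__C3; o__O1"),
            ("e", "k__A"),
        ]
        path = tmp_path / "gg.tsv"
        path.write_text("".join(f"{i}\t{l}\n" for i, l in lineages))
        prefixes = set()
        for _, lineage in lineages:
            parts = [p.strip() for p in lineage.split(";")]
            for i in range(1, len(parts) + 1):
                prefixes.add(tuple(parts[:i]))
        tree = read_greengenes(path)
        # internal nodes = implicit root + one node per distinct prefix
        assert len(tree.internal_nodes) == len(prefixes) + 1

    def test_conflicting_rank_order(self, tmp_path):
        path = tmp_path / "gg.tsv"
        path.write_text("s1\tp__P; k__B\n")
        with pytest.raises(TaxonomyFormatError, match="order"):
            read_greengenes(path)


class TestGenerators:
    def test_complete_clade_sizes_n4(self):
        tree = complete_binary_tree(4)
        assert sorted(len(tree.clade_leaves(v)) for v in tree.internal_nodes) == [2, 2, 4]

    def test_complete_n8_internal_count(self):
        assert len(complete_binary_tree(8).internal_nodes) == 7

    def test_complete_n3_shape(self):
        tree = complete_binary_tree(3)
        kids = tree.children(tree.root)
        kinds = sorted(len(tree.clade_leaves(c)) for c in kids)
        assert kinds == [1, 2]  # one cherry plus one leaf child of the root

    def test_power_of_two_splits_coincide(self):
        for n in (2, 4, 8, 16):
            balanced = complete_binary_tree(n)
            packed = complete_binary_tree(n, split="left_packed")
            assert clade_label_sets(balanced) == clade_label_sets(packed)

    def test_left_packed_root_split(self):
        tree = complete_binary_tree(6, split="left_packed")
        sizes = sorted(len(tree.clade_leaves(c)) for c in tree.children(tree.root))
        assert sizes == [2, 4]
        balanced = complete_binary_tree(6)
        sizes = sorted(len(balanced.clade_leaves(c)) for c in balanced.children(balanced.root))
        assert sizes == [3, 3]

    def test_caterpillar_n2_equals_complete(self):
        assert clade_label_sets(caterpillar(2)) == clade_label_sets(complete_binary_tree(2))

    def test_caterpillar_clade_sizes(self):
        tree = caterpillar(8)
        sizes = sorted(len(tree.clade_leaves(v)) for v in tree.internal_nodes)
        assert sizes == [2, 3, 4, 5, 6, 7, 8]
        assert sizes.count(2) == 1

    @pytest.mark.parametrize("fn", [complete_binary_tree, caterpillar])
    def test_too_few_leaves(self, fn):
        with pytest.raises(TaxonomyError):
            fn(1)

    @pytest.mark.parametrize("fn", [complete_binary_tree, caterpillar])
    @pytest.mark.parametrize("n", [2, 3, 5, 8, 11])
    def test_binary_internal_count(self, fn, n):
        assert len(fn(n).internal_nodes) == n - 1


class TestQueries:
    def test_lca_cherry(self):
        tree = caterpillar(8)
        pair = [tree.node_for_label("l1"), tree.node_for_label("l2")]
        assert tree.label(tree.lca(pair)) == "c2"

    def test_lca_spanning_pair_is_root(self):
        tree = caterpillar(8)
        pair = [tree.node_for_label("l3"), tree.node_for_label("l8")]
        assert tree.lca(pair) == tree.root

    def test_lca_matches_path_intersection(self, rng):
        for _ in range(20):
            tree = random_binary_tree(rng.randint(3, 10), rng)
            leaves = rng.sample(tree.leaves, rng.randint(1, tree.n_leaves))
            got = tree.lca(leaves)
            paths = [set(tree.ancestors(v)) for v in leaves]
            common = set.intersection(*paths)
            expected = max(common, key=tree.depth)
            assert got == expected

    def test_lca_of_empty_set(self):
        with pytest.raises(TaxonomyError):
            complete_binary_tree(4).lca([])

    def test_clade_queries(self):
        tree = complete_binary_tree(8)
        assert tree.clade_leaves(tree.root) == frozenset(tree.leaves)
        leaf = tree.node_for_label("l5")
        assert tree.clade_leaves(leaf) == frozenset({leaf})
        kids = tree.children(tree.root)
        assert [len(tree.clade_leaves(c)) for c in kids] == [4, 4]

    def test_unknown_node_raises(self):
        with pytest.raises(TaxonomyError):
            complete_binary_tree(4).clade_leaves(999)

    def test_relevant_singleton(self):
        tree = complete_binary_tree(4)
        leaf = tree.node_for_label("l1")
        assert tree.relevant_nodes([leaf]) == frozenset({leaf})

    def test_relevant_cherry(self):
        tree = complete_binary_tree(4)
        l1, l2 = tree.node_for_label("l1"), tree.node_for_label("l2")
        assert tree.relevant_nodes([l1, l2]) == frozenset({l1, l2, tree.parent(l1)})

    def test_relevant_matches_all_pairs_oracle(self, rng):
        for _ in range(25):
            tree = random_binary_tree(rng.randint(3, 10), rng)
            m = set(rng.sample(tree.leaves, rng.randint(2, tree.n_leaves)))
            got = tree.relevant_nodes(m)
            assert got == oracle.pairwise_lcas(tree, m)
            assert len(got) <= 2 * len(m) - 1
            anc = tree.lca(m)
            assert all(tree.is_ancestor_or_self(anc, v) for v in got)
            assert anc in got


class TestBalance:
    def test_complete_four(self):
        assert complete_binary_tree(4).total_cophenetic_index() == 2

    def test_caterpillar_four(self):
        assert caterpillar(4).total_cophenetic_index() == 4

    @pytest.mark.parametrize("n", range(2, 13))
    def test_caterpillar_closed_form(self, n):
        tree = caterpillar(n)
        assert tree.total_cophenetic_index() == n * (n - 1) * (n - 2) // 6
        # independent pair-depth sum
        brute = sum(tree.depth(tree.lca(p)) for p in combinations(tree.leaves, 2))
        assert brute == tree.total_cophenetic_index()

    @pytest.mark.parametrize("n", range(4, 11))
    def test_extremes_over_random_sample(self, n, rng):
        lo = complete_binary_tree(n).total_cophenetic_index()
        hi = caterpillar(n).total_cophenetic_index()
        for _ in range(30):
            tci = random_binary_tree(n, rng).total_cophenetic_index()
            assert lo <= tci <= hi
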