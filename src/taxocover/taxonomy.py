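"""Rooted reference taxonomies: data model, format readers, generators, queries.

A reference taxonomy is a rooted tree whose leaves are reference sequences
(species/strain level); internal nodes are higher taxonomic ranks.  Reads are
annotated at nodes of this tree, so everything downstream (confusion counts,
indicator maximisation, set cover) is phrased in terms of clades and lowest
common ancestors computed here.

Node identity is an internal integer, stable for the lifetime of a tree; leaf
labels are the external handle in all I/O.  Trees are immutable once built by
one of the constructors/readers.
"""

from __future__ import annotations

import itertools
import math
import random
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "TaxonomyTree",
    "TaxonomyError",
    "NewickParseError",
    "TaxonomyFormatError",
    "CANONICAL_RANKS",
    "parse_newick",
    "write_newick",
    "read_ncbi_dump",
    "write_ncbi_dump",
    "read_greengenes",
    "complete_binary_tree",
    "caterpillar",
    "random_binary_tree",
]

#: The seven standard ranks, root-most first.
CANONICAL_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class TaxonomyError(ValueError):
    """Structural or lookup error on a taxonomy tree."""


class NewickParseError(TaxonomyError):
    """Malformed Newick input."""


class TaxonomyFormatError(TaxonomyError):
    """Malformed NCBI dump or lineage table input."""


class TaxonomyTree:
    """Rooted tree with labelled leaves, optional ranks, and clade queries.

    Use the module-level constructors (:func:`parse_newick`,
    :func:`read_ncbi_dump`, :func:`read_greengenes`,
    :func:`complete_binary_tree`, :func:`caterpillar`,
    :func:`random_binary_tree`) rather than building instances by hand.
    """

    def __init__(self) -> None:
        self._parent: dict[int, int | None] = {}
        self._children: dict[int, list[int]] = {}
        self._label: dict[int, str] = {}
        self._rank: dict[int, str | None] = {}
        self._root: int | None = None
        # lazy caches
        self._depth: dict[int, int] | None = None
        self._clade: dict[int, frozenset[int]] | None = None
        self._leaves: tuple[int, ...] | None = None
        self._leaf_index: dict[int, int] | None = None
        self._node_by_label: dict[str, int] | None = None

    # -- construction (internal) ------------------------------------------

    def _add(self, parent: int | None, label: str | None = None,
             rank: str | None = None) -> int:
        node = len(self._parent)
        self._parent[node] = parent
        self._children[node] = []
        if parent is None:
            if self._root is not None:
                raise TaxonomyError("tree already has a root")
            self._root = node
        else:
            self._children[parent].append(node)
        if label is not None:
            self._label[node] = label
        self._rank[node] = rank
        return node

    def _validate(self) -> "TaxonomyTree":
        if self._root is None:
            raise TaxonomyError("empty tree")
        seen: list[str] = []
        for leaf in self.leaves:
            label = self._label.get(leaf)
            if not label:
                raise TaxonomyError(f"leaf node {leaf} has no label")
            seen.append(label)
        dupes = {x for x in seen if seen.count(x) > 1}
        if dupes:
            raise TaxonomyError(
                f"duplicate leaf labels: {', '.join(sorted(dupes))}")
        return self

    # -- basic structure ---------------------------------------------------

    @property
    def root(self) -> int:
        assert self._root is not None
        return self._root

    @property
    def nodes(self) -> Iterator[int]:
        return iter(self._parent)

    def __len__(self) -> int:
        return len(self._parent)

    def parent(self, node: int) -> int | None:
        self._check(node)
        return self._parent[node]

    def children(self, node: int) -> tuple[int, ...]:
        self._check(node)
        return tuple(self._children[node])

    def is_leaf(self, node: int) -> bool:
        self._check(node)
        return not self._children[node]

    def _check(self, node: int) -> None:
        if node not in self._parent:
            raise TaxonomyError(f"unknown node id: {node!r}")

    @property
    def leaves(self) -> tuple[int, ...]:
        """Leaves in depth-first (left-to-right) order."""
        if self._leaves is None:
            out: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                kids = self._children[v]
                if kids:
                    stack.extend(reversed(kids))
                else:
                    out.append(v)
            self._leaves = tuple(out)
            self._leaf_index = {v: i for i, v in enumerate(out)}
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def internal_nodes(self) -> tuple[int, ...]:
        return tuple(v for v in self._parent if self._children[v])

    def label(self, node: int) -> str | None:
        self._check(node)
        return self._label.get(node)

    def rank(self, node: int) -> str | None:
        self._check(node)
        return self._rank.get(node)

    def display_name(self, node: int) -> str:
        """Label if the node has one, else a stable synthetic name."""
        return self.label(node) or f"@{node}"

    def node_for_label(self, label: str) -> int:
        if self._node_by_label is None:
            by_label: dict[str, int] = {}
            for v, lab in self._label.items():
                by_label.setdefault(lab, v)
            self._node_by_label = by_label
        try:
            return self._node_by_label[label]
        except KeyError:
            raise TaxonomyError(f"no node labelled {label!r}") from None

    def depth(self, node: int) -> int:
        """Edge count from the root (0 for the root)."""
        if self._depth is None:
            depth = {self.root: 0}
            stack = [self.root]
            while stack:
                v = stack.pop()
                for c in self._children[v]:
                    depth[c] = depth[v] + 1
                    stack.append(c)
            self._depth = depth
        self._check(node)
        return self._depth[node]

    # -- clade queries ------------------------------------------------------

    def clade_leaves(self, node: int) -> frozenset[int]:
        """All leaf descendants of ``node`` (a leaf's clade is itself)."""
        self._check(node)
        if self._clade is None:
            clade: dict[int, frozenset[int]] = {}
            # postorder via an explicit stack
            stack: list[tuple[int, bool]] = [(self.root, False)]
            while stack:
                v, done = stack.pop()
                kids = self._children[v]
                if not kids:
                    clade[v] = frozenset((v,))
                elif done:
                    clade[v] = frozenset().union(*(clade[c] for c in kids))
                else:
                    stack.append((v, True))
                    stack.extend((c, False) for c in kids)
            self._clade = clade
        return self._clade[node]

    def ancestors(self, node: int) -> list[int]:
        """Path from ``node`` (inclusive) to the root."""
        self._check(node)
        path = [node]
        while (p := self._parent[path[-1]]) is not None:
            path.append(p)
        return path

    def is_ancestor_or_self(self, anc: int, node: int) -> bool:
        self._check(anc)
        v: int | None = node
        while v is not None:
            if v == anc:
                return True
            v = self._parent[v]
        return False

    def lca(self, nodes: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of nodes.

        For a singleton this is the node itself.  Computed by root-path
        intersection; instance sizes here are small.
        """
        it = iter(nodes)
        try:
            first = next(it)
        except StopIteration:
            raise TaxonomyError("lca of an empty set is undefined") from None
        path = self.ancestors(first)
        index = {v: i for i, v in enumerate(path)}
        best = 0  # index into path; larger index = shallower
        for v in it:
            self._check(v)
            while v not in index:
                parent = self._parent[v]
                assert parent is not None, "nodes of different trees?"
                v = parent
            best = max(best, index[v])
        return path[best]

    def relevant_nodes(self, m: Iterable[int]) -> frozenset[int]:
        """Candidate-set members plus all pairwise LCAs of members.

        These are the only nodes at which a classification-error indicator
        can attain its maximum over the subtree rooted at the LCA of ``m``
        (the LCA skeleton of the candidate set).  The pairwise LCAs of a
        leaf set equal the LCAs of consecutive leaves in depth-first order,
        so only ``|m| - 1`` LCA calls are needed.
        """
        members = set(m)
        if not members:
            raise TaxonomyError("relevant_nodes of an empty set is undefined")
        self.leaves  # ensure _leaf_index
        assert self._leaf_index is not None
        try:
            ordered = sorted(members, key=self._leaf_index.__getitem__)
        except KeyError as e:
            raise TaxonomyError(f"not a leaf of this tree: {e.args[0]!r}") from None
        rel = set(ordered)
        for a, b in itertools.pairwise(ordered):
            rel.add(self.lca((a, b)))
        return frozenset(rel)

    # -- balance ------------------------------------------------------------

    def total_cophenetic_index(self) -> int:
        """Sum over unordered leaf pairs of the depth of their LCA.

        Minimal for the complete binary tree and maximal for the rooted
        caterpillar among binary trees with the same number of leaves; used
        to place a taxonomy on the balance spectrum.
        """
        total = 0
        for v in self._parent:
            kids = self._children[v]
            if not kids:
                continue
            sizes = [len(self.clade_leaves(c)) for c in kids]
            whole = sum(sizes)
            pairs_here = math.comb(whole, 2) - sum(math.comb(s, 2) for s in sizes)
            total += pairs_here * self.depth(v)
        return total


# -- Newick -----------------------------------------------------------------


def parse_newick(text: str) -> TaxonomyTree:
    """Parse a Newick string into a :class:`TaxonomyTree`.

    Leaf labels are mandatory and must be unique; branch lengths are ignored.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if dtree.seed_node is None:
        raise NewickParseError("empty Newick input")

    tree = TaxonomyTree()

    def convert(dnode, parent: int | None) -> None:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if not label:
                raise NewickParseError("unlabeled leaf in Newick input")
            tree._add(parent, label=str(label))
        else:
            label = dnode.label
            v = tree._add(parent, label=str(label) if label else None)
            for child in dnode.child_nodes():
                convert(child, v)

    convert(dtree.seed_node, None)
    try:
        return tree._validate()
    except TaxonomyError as exc:
        raise NewickParseError(str(exc)) from None


def write_newick(tree: TaxonomyTree) -> str:
    """Serialise to Newick; ``parse_newick(write_newick(t))`` preserves
    topology and leaf labels."""

    def fmt(v: int) -> str:
        if tree.is_leaf(v):
            return tree.label(v) or ""
        inner = ",".join(fmt(c) for c in tree.children(v))
        return f"({inner}){tree.label(v) or ''}"

    return fmt(tree.root) + ";"


# -- NCBI taxonomy dump dialect ---------------------------------------------


def _split_dump_row(line: str) -> list[str]:
    # records end with "\t|"; fields are separated by "\t|\t"
    return line.rstrip("\n").rstrip("\t|").split("\t|\t")


def read_ncbi_dump(nodes_path, names_path) -> TaxonomyTree:
    """Read the NCBI taxonomy dump dialect (``nodes.dmp``/``names.dmp``).

    The root is the taxid that is its own parent.  Node labels are scientific
    names; ranks are preserved verbatim (``"no rank"`` becomes ``None``).
    """
    parent_of: dict[str, str] = {}
    rank_of: dict[str, str] = {}
    with open(nodes_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dump_row(line)
            if len(fields) < 3:
                raise TaxonomyFormatError(
                    f"{nodes_path}:{lineno}: expected at least 3 fields")
            taxid, parent, rank = fields[0], fields[1], fields[2]
            parent_of[taxid] = parent
            rank_of[taxid] = rank

    names: dict[str, str] = {}
    with open(names_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dump_row(line)
            if len(fields) < 2:
                raise TaxonomyFormatError(
                    f"{names_path}:{lineno}: expected at least 2 fields")
            taxid, name = fields[0], fields[1]
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class == "scientific name" or taxid not in names:
                names[taxid] = name

    roots = [t for t, p in parent_of.items() if p == t]
    if len(roots) != 1:
        raise TaxonomyFormatError(
            f"expected exactly one root taxid (own parent), found {len(roots)}")
    orphans = sorted(t for t, p in parent_of.items()
                     if p != t and p not in parent_of)
    if orphans:
        raise TaxonomyFormatError(
            f"orphan taxids (parent absent): {', '.join(orphans)}")

    children: dict[str, list[str]] = {t: [] for t in parent_of}
    for t, p in parent_of.items():
        if p != t:
            children[p].append(t)

    tree = TaxonomyTree()

    def norm_rank(r: str) -> str | None:
        return None if r in ("", "no rank") else r

    def build(taxid: str, parent: int | None) -> None:
        v = tree._add(parent, label=names.get(taxid, taxid),
                      rank=norm_rank(rank_of[taxid]))
        for c in children[taxid]:
            build(c, v)

    build(roots[0], None)
    return tree._validate()


def write_ncbi_dump(tree: TaxonomyTree, nodes_path, names_path) -> None:
    """Export in the dump dialect (taxids are node ids offset by 1)."""
    with open(nodes_path, "w", encoding="utf-8") as nodes_fh:
        for v in tree.nodes:
            p = tree.parent(v)
            taxid, ptaxid = v + 1, (v if p is None else p) + 1
            rank = tree.rank(v) or "no rank"
            nodes_fh.write(f"{taxid}\t|\t{ptaxid}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as names_fh:
        for v in tree.nodes:
            name = tree.display_name(v)
            names_fh.write(f"{v + 1}\t|\t{name}\t|\t\t|\tscientific name\t|\n")


# -- Greengenes-style lineage tables ----------------------------------------

_GG_RANK_OF_PREFIX = dict(zip("kpcofgs", CANONICAL_RANKS))
_GG_PREFIX_ORDER = {p: i for i, p in enumerate("kpcofgs")}


def read_greengenes(lineage_path) -> TaxonomyTree:
    """Read a lineage TSV: ``sequence_id <tab> k__X; p__Y; ...``.

    Builds the prefix tree over lineages; each sequence id becomes a leaf
    under its deepest named rank (empty tail ranks like ``s__`` are allowed
    and simply truncate the lineage).
    """
    tree = TaxonomyTree()
    root = tree._add(None, label=None)
    # map lineage prefix tuple -> node id
    index: dict[tuple[str, ...], int] = {(): root}
    seen_ids: set[str] = set()

    with open(lineage_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise TaxonomyFormatError(
                    f"{lineage_path}:{lineno}: expected 2 tab-separated fields")
            seq_id, lineage = parts[0].strip(), parts[1]
            if not seq_id:
                raise TaxonomyFormatError(
                    f"{lineage_path}:{lineno}: empty sequence id")
            if seq_id in seen_ids:
                raise TaxonomyFormatError(
                    f"{lineage_path}:{lineno}: duplicate sequence id {seq_id!r}")
            seen_ids.add(seq_id)

            named: list[str] = []
            last_order = -1
            truncated = False
            for token in (t.strip() for t in lineage.split(";")):
                if not token:
                    continue
                if len(token) < 3 or token[1:3] != "__" or token[0] not in _GG_PREFIX_ORDER:
                    raise TaxonomyFormatError(
                        f"{lineage_path}:{lineno}: bad rank token {token!r}")
                order = _GG_PREFIX_ORDER[token[0]]
                if order <= last_order:
                    raise TaxonomyFormatError(
                        f"{lineage_path}:{lineno}: rank prefix out of order at {token!r}")
                last_order = order
                if len(token) == 3:  # e.g. bare "s__": unnamed tail rank
                    truncated = True
                    continue
                if truncated:
                    raise TaxonomyFormatError(
                        f"{lineage_path}:{lineno}: named rank {token!r} after an empty one")
                named.append(token)

            node = root
            for i in range(1, len(named) + 1):
                key = tuple(named[:i])
                if key not in index:
                    token = named[i - 1]
                    index[key] = tree._add(
                        node, label=token, rank=_GG_RANK_OF_PREFIX[token[0]])
                node = index[key]
            tree._add(node, label=seq_id, rank="sequence")

    if not seen_ids:
        raise TaxonomyFormatError(f"{lineage_path}: no lineages found")
    return tree._validate()


# -- synthetic topologies ----------------------------------------------------


def _leaf_labels(n: int) -> list[str]:
    return [f"l{i}" for i in range(1, n + 1)]


def complete_binary_tree(n: int, split: str = "balanced") -> TaxonomyTree:
    """Complete binary tree on ``n`` leaves labelled l1..ln.

    For ``n`` a power of two this is the perfect tree (all leaves at depth
    log2 n) under either convention.  Otherwise ``split`` selects the build:

    * ``"balanced"`` (default): recursive ceil(n/2)/floor(n/2) split, the
      maximally balanced shape (minimum total cophenetic index);
    * ``"left_packed"``: the largest power of two below ``n`` on the left,
      equivalent to pruning the perfect tree on the next power of two down
      to its first ``n`` leaves.  This is the build the enumeration
      benchmarks use for their complete-tree series.
    """
    if n < 2:
        raise TaxonomyError(f"need at least 2 leaves, got {n}")
    if split not in ("balanced", "left_packed"):
        raise TaxonomyError(
            f"split must be 'balanced' or 'left_packed', got {split!r}")
    labels = _leaf_labels(n)
    tree = TaxonomyTree()

    def build(parent: int | None, lo: int, hi: int) -> None:
        if hi - lo == 1:
            tree._add(parent, label=labels[lo])
            return
        v = tree._add(parent)
        size = hi - lo
        if split == "balanced":
            half = (size + 1) // 2
        else:
            half = 1 << ((size - 1).bit_length() - 1)
        build(v, lo, lo + half)
        build(v, lo + half, hi)

    build(None, 0, n)
    return tree._validate()


def caterpillar(n: int) -> TaxonomyTree:
    """Rooted caterpillar on ``n`` leaves: internal nodes c2..cn with
    clade(ck) = {l1..lk}; cn is the root and l1, l2 are the deepest leaves."""
    if n < 2:
        raise TaxonomyError(f"need at least 2 leaves, got {n}")
    labels = _leaf_labels(n)
    tree = TaxonomyTree()
    chain = [tree._add(None, label=f"c{n}")]  # c_n .. c_2 top-down
    for k in range(n - 1, 1, -1):
        chain.append(tree._add(chain[-1], label=f"c{k}"))
    c2 = chain[-1]
    tree._add(c2, label=labels[0])
    tree._add(c2, label=labels[1])
    for k in range(3, n + 1):
        tree._add(chain[n - k], label=labels[k - 1])
    return tree._validate()


def random_binary_tree(n: int, rng: random.Random | int | None = None) -> TaxonomyTree:
    """Random binary topology on ``n`` leaves labelled l1..ln (random
    recursive splits; shapes vary, the distribution is not uniform)."""
    if n < 2:
        raise TaxonomyError(f"need at least 2 leaves, got {n}")
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    labels = _leaf_labels(n)
    rng.shuffle(labels)
    tree = TaxonomyTree()

    def build(parent: int | None, block: Sequence[str]) -> None:
        if len(block) == 1:
            tree._add(parent, label=block[0])
            return
        v = tree._add(parent)
        k = rng.randint(1, len(block) - 1)
        build(v, block[:k])
        build(v, block[k:])

    build(None, labels)
    return tree._validate()
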