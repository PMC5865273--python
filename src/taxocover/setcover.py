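"""Whole-sample disambiguation as set cover, and abundance profiling.

Reads are the elements X; each candidate node is the named subset of reads
for which it is indicator-optimal.  A cover with the least *total size* of
subsets has the least *overlap* (total size minus |X|), i.e. the least
residual ambiguity, so the default exact objective is minimum total size.
Minimum cardinality does not guarantee least overlap: the classic family
{1,2},{3,4},...,{n-1,n},{1..n-1},{2..n} has a size-2 cover with overlap n
while the perfect matching has overlap 0 (:func:`proposition1_instance`).

Exact solving is implicit enumeration (branch and bound) with
dominated-subset-free branching on the hardest element; instances arising
from real samples are tiny after argmax filtering, so exactness is cheap.
Reads with identical membership signatures are collapsed to weighted
elements internally, which changes no result.  Among optimal covers the
lexicographically smallest sorted name sequence is returned, so outputs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Iterable, Mapping, Sequence

from .annotation import ReadAnnotation
from .taxonomy import CANONICAL_RANKS, TaxonomyError, TaxonomyTree

__all__ = [
    "SetCoverInstance",
    "Cover",
    "SolverCapacityError",
    "build_instance",
    "greedy_cover",
    "min_cardinality_cover",
    "min_total_size_cover",
    "proposition1_instance",
    "assign_reads",
    "abundance_profile",
    "rollup_profile",
]

#: Largest family for which the exact solvers guarantee termination in
#: reasonable time; larger instances should use :func:`greedy_cover`.
EXACT_FAMILY_BOUND = 40


class SolverCapacityError(ValueError):
    """Instance too large for the exact solver; use the greedy solver."""


@dataclass(frozen=True)
class SetCoverInstance:
    """Elements (read ids) and a named family of subsets (candidate nodes)."""

    elements: frozenset
    family: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", frozenset(self.elements))
        fam = {str(k): frozenset(v) for k, v in dict(self.family).items()}
        object.__setattr__(self, "family", fam)
        for name, members in fam.items():
            if not members:
                raise ValueError(f"subset {name!r} is empty")
            extra = members - self.elements
            if extra:
                raise ValueError(
                    f"subset {name!r} contains non-elements: {sorted(map(str, extra))}")
        union = frozenset().union(*fam.values()) if fam else frozenset()
        if union != self.elements:
            missing = sorted(map(str, self.elements - union))
            raise ValueError(f"elements not covered by any subset: {missing}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self.family))

    def make_cover(self, chosen: Iterable[str], keep_order: bool = False) -> "Cover":
        """Validate that ``chosen`` covers all elements and compute metrics.

        ``keep_order=True`` preserves the given order of names (used by the
        greedy solver to report its pick order); the default sorts them.
        """
        if keep_order:
            names = tuple(dict.fromkeys(map(str, chosen)))
        else:
            names = tuple(sorted(set(map(str, chosen))))
        unknown = [n for n in names if n not in self.family]
        if unknown:
            raise ValueError(f"unknown subset names: {unknown}")
        covered = frozenset().union(*(self.family[n] for n in names)) if names else frozenset()
        if covered != self.elements:
            missing = sorted(map(str, self.elements - covered))
            raise ValueError(f"not a cover; uncovered elements: {missing}")
        total = sum(len(self.family[n]) for n in names)
        return Cover(chosen=names, size=len(names), total_size=total,
                     overlap=total - len(self.elements))


@dataclass(frozen=True)
class Cover:
    """A valid cover: chosen subset names plus size/total-size/overlap."""

    chosen: tuple[str, ...]
    size: int
    total_size: int
    overlap: int


def build_instance(annotations: Sequence[ReadAnnotation],
                   name_of_node=None) -> SetCoverInstance:
    """Instance from per-read argmax sets: one subset per candidate node,
    containing exactly the reads having it as an argmax.

    ``name_of_node`` maps node ids to subset names (default ``str``); pass
    ``tree.display_name`` to get taxon labels.
    """
    if not annotations:
        raise ValueError("no annotations given")
    name_of_node = name_of_node or str
    family: dict[str, set] = {}
    elements: set = set()
    for ann in annotations:
        elements.add(ann.read_id)
        for node in ann.argmax_nodes:
            family.setdefault(str(name_of_node(node)), set()).add(ann.read_id)
    return SetCoverInstance(elements=frozenset(elements),
                            family={k: frozenset(v) for k, v in family.items()})


def greedy_cover(inst: SetCoverInstance, tie_break: str = "lex") -> Cover:
    """Johnson's greedy algorithm: repeatedly pick the subset covering the
    most still-uncovered elements.  Ties broken by lexicographic name
    (``tie_break="lex"``, default) or reverse-lexicographic (``"revlex"``).
    Logarithmic approximation of the minimum-cardinality cover."""
    if tie_break not in ("lex", "revlex"):
        raise ValueError(f"tie_break must be 'lex' or 'revlex', got {tie_break!r}")
    uncovered = set(inst.elements)
    chosen: list[str] = []
    names = inst.names if tie_break == "lex" else tuple(reversed(inst.names))
    while uncovered:
        best_name = max(names, key=lambda n: len(inst.family[n] & uncovered))
        # max() keeps the first of equals, i.e. the tie_break order's winner
        gain = inst.family[best_name] & uncovered
        assert gain, "instance invariants guarantee progress"
        chosen.append(best_name)
        uncovered -= gain
    return inst.make_cover(chosen, keep_order=True)


# -- exact solvers -----------------------------------------------------------


def _collapse(inst: SetCoverInstance):
    """Group elements by membership signature; return (signatures, weights,
    covering-name lists).  Weighted totals equal the uncollapsed ones."""
    sig_of_elem: dict[Hashable, frozenset[str]] = {e: frozenset() for e in inst.elements}
    for name, members in inst.family.items():
        for e in members:
            sig_of_elem[e] |= {name}
    weights: dict[frozenset[str], int] = {}
    for sig in sig_of_elem.values():
        weights[sig] = weights.get(sig, 0) + 1
    sigs = sorted(weights, key=sorted)
    return sigs, weights


def _exact_cover(inst: SetCoverInstance, cost: Mapping[str, int]) -> Cover:
    if len(inst.family) > EXACT_FAMILY_BOUND:
        raise SolverCapacityError(
            f"{len(inst.family)} subsets exceeds the exact-solver bound of "
            f"{EXACT_FAMILY_BOUND}; use greedy_cover")
    sigs, weights = _collapse(inst)
    covers_sig = {sig: tuple(sorted(sig)) for sig in sigs}

    best: list[tuple[int, tuple[str, ...]] | None] = [None]

    def search(uncovered: list[frozenset[str]], chosen: tuple[str, ...],
               cost_so_far: int) -> None:
        if best[0] is not None:
            # every uncovered element costs at least its weight in total size
            # (and at least "something" in cardinality mode, where cost is 1
            # per subset: the bound below is valid for both since cost >= 1).
            if cost_so_far > best[0][0]:
                return
        if not uncovered:
            key = (cost_so_far, tuple(sorted(chosen)))
            if best[0] is None or key < best[0]:
                best[0] = key
            return
        # branch on the element with the fewest covering subsets
        target = min(uncovered, key=lambda s: (len(s), sorted(s)))
        for name in covers_sig[target]:
            still = [s for s in uncovered if name not in s]
            search(still, chosen + (name,), cost_so_far + cost[name])

    search(sigs, (), 0)
    assert best[0] is not None, "instance invariants guarantee a cover"
    return inst.make_cover(best[0][1])


def min_cardinality_cover(inst: SetCoverInstance) -> Cover:
    """Provably minimum number of chosen subsets; lexicographic tie-break."""
    return _exact_cover(inst, {n: 1 for n in inst.family})


def min_total_size_cover(inst: SetCoverInstance) -> Cover:
    """Provably minimum total subset size, hence minimum overlap;
    lexicographic tie-break."""
    return _exact_cover(inst, {n: len(inst.family[n]) for n in inst.family})


def proposition1_instance(k: int) -> SetCoverInstance:
    """The family {1,2},{3,4},...,{n-1,n},{1..n-1},{2..n} over X = {1..n},
    n = 2k: its minimum-cardinality covers have overlap >= 1 while the
    perfect matching (size n/2) has overlap 0."""
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    n = 2 * k
    elements = frozenset(range(1, n + 1))
    family: dict[str, frozenset] = {}
    for i in range(k):
        family[f"p{i + 1}"] = frozenset({2 * i + 1, 2 * i + 2})
    family["q1"] = frozenset(range(1, n))
    family["q2"] = frozenset(range(2, n + 1))
    return SetCoverInstance(elements=elements, family=family)


# -- abundance ---------------------------------------------------------------


def assign_reads(inst: SetCoverInstance, cover: Cover) -> dict[Hashable, dict[str, Fraction]]:
    """Split each read's unit weight uniformly over the chosen subsets that
    contain it (still-ambiguous reads are shared; weights sum to 1 per read)."""
    out: dict[Hashable, dict[str, Fraction]] = {}
    for e in inst.elements:
        holders = [n for n in cover.chosen if e in inst.family[n]]
        if not holders:
            raise ValueError(f"cover does not cover element {e!r}")
        share = Fraction(1, len(holders))
        out[e] = {n: share for n in holders}
    return out


def abundance_profile(assignments: Mapping[Hashable, Mapping[str, Fraction]]) -> dict[str, Fraction]:
    """Relative abundance per node: summed read weights over read count,
    as exact percentages summing to 100."""
    if not assignments:
        raise ValueError("no assignments given")
    n_reads = len(assignments)
    totals: dict[str, Fraction] = {}
    for shares in assignments.values():
        for name, w in shares.items():
            totals[name] = totals.get(name, Fraction(0)) + w
    return {name: w * 100 / n_reads for name, w in sorted(totals.items())}


def rollup_profile(tree: TaxonomyTree, profile: Mapping[str, Fraction],
                   rank: str) -> dict[str, Fraction]:
    """Aggregate a node-level profile at a taxonomic rank.

    Each node's abundance is added to its nearest ancestor (or itself) with
    the requested rank; nodes with no such ancestor go to an ``"Other"``
    bucket.  The total is preserved exactly.
    """
    rank = rank.lower()
    known = set(CANONICAL_RANKS) | {
        (tree.rank(v) or "").lower() for v in tree.nodes if tree.rank(v)}
    if rank not in known:
        raise TaxonomyError(f"unknown rank name: {rank!r}")
    out: dict[str, Fraction] = {}
    for name, value in profile.items():
        node = tree.node_for_label(name)
        bucket = "Other"
        for v in tree.ancestors(node):
            if (tree.rank(v) or "").lower() == rank:
                bucket = tree.display_name(v)
                break
        out[bucket] = out.get(bucket, Fraction(0)) + value
    return dict(sorted(out.items()))
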