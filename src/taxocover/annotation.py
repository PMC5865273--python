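"""Per-read taxonomic annotation by indicator maximisation over the LCA skeleton.

A read's candidate sequences define a classification problem inside the
subtree rooted at their LCA.  The indicator maximum over that whole subtree
is always attained at a *relevant* node (a candidate sequence or an LCA of
two or more candidates), so only those are scored.  All maximising nodes
are returned: ties are deliberately NOT broken per read — whole-sample
disambiguation is the set-cover stage's job, and per-read tie-breaking is
exactly the bias it removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .confusion import (
    SCORE_KEY_FNS,
    ConfusionCounts,
    Indicator,
    indicator,
)
from .taxonomy import TaxonomyError, TaxonomyTree

__all__ = [
    "ReadCandidates",
    "ReadAnnotation",
    "annotate_read",
    "annotate_sample",
    "ambiguity_histogram",
]


@dataclass(frozen=True)
class ReadCandidates:
    """A read id and its non-empty set of candidate leaves."""

    read_id: str
    m: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "m", frozenset(self.m))
        if not self.m:
            raise TaxonomyError(f"read {self.read_id!r}: empty candidate set")


@dataclass(frozen=True)
class ReadAnnotation:
    """All indicator-maximising nodes for one read, with the achieved score."""

    read_id: str
    argmax_nodes: frozenset[int]
    score: Fraction | float
    indicator: Indicator

    def __post_init__(self) -> None:
        object.__setattr__(self, "argmax_nodes", frozenset(self.argmax_nodes))

    @property
    def is_ambiguous(self) -> bool:
        return len(self.argmax_nodes) > 1


def annotate_read(tree: TaxonomyTree, rc: ReadCandidates,
                  kind: Indicator = Indicator.RAND) -> ReadAnnotation:
    """Score every relevant node with LCA-relative confusion counts and
    return the full argmax set.

    The returned score equals the maximum over *every* node of the subtree
    rooted at the LCA of the candidates, not just the relevant ones.
    """
    kind = Indicator(kind)
    m = rc.m
    anc = tree.lca(m)
    within = len(tree.clade_leaves(anc))
    n_m = len(m)
    key_fn = SCORE_KEY_FNS[kind]

    best_num, best_den = None, 1
    best_nodes: list[int] = []
    best_counts: ConfusionCounts | None = None
    for j in sorted(tree.relevant_nodes(m)):
        clade = tree.clade_leaves(j)
        tp = len(m & clade)
        fp = len(clade) - tp
        fn = n_m - tp
        tn = within - tp - fp - fn
        num, den = key_fn(tp, fp, tn, fn)
        if best_num is None or num * best_den > best_num * den:
            best_num, best_den = num, den
            best_nodes = [j]
            best_counts = ConfusionCounts(tp, fp, tn, fn)
        elif num * best_den == best_num * den:
            best_nodes.append(j)
    assert best_counts is not None
    return ReadAnnotation(
        read_id=rc.read_id,
        argmax_nodes=frozenset(best_nodes),
        score=indicator(kind, best_counts),
        indicator=kind,
    )


def annotate_sample(tree: TaxonomyTree, reads: Sequence[ReadCandidates],
                    kind: Indicator = Indicator.RAND) -> list[ReadAnnotation]:
    """Order-preserving batch of :func:`annotate_read`; read ids must be unique."""
    ids = [rc.read_id for rc in reads]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise TaxonomyError(f"duplicate read ids: {', '.join(dupes)}")
    return [annotate_read(tree, rc, kind) for rc in reads]


def ambiguity_histogram(annotations: Iterable[ReadAnnotation]) -> dict[int, int]:
    """Bin reads by the number of candidate annotations (argmax-set size)."""
    hist: dict[int, int] = {}
    for ann in annotations:
        k = len(ann.argmax_nodes)
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))
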