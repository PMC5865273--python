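"""Confusion counts and classification-error indicators for read annotation.

Annotating a read at a node j of a reference taxonomy is a binary
classification of reference sequences: leaves in clade(j) are predicted
positive, the read's candidate sequences are the true positives.  Two
conventions are supported:

* **LCA-relative** (production annotation): counts restricted to the leaves
  under the LCA of the candidate set, so TN/FN exist only inside that
  subtree (:func:`confusion_lca_relative`).
* **whole-tree / global** (enumeration studies): counts over every leaf of
  the tree, candidate nodes ranging over every internal node
  (:func:`confusion_global`).

Six indicators are provided; when any denominator of an indicator's formula
is zero, the score is defined to be zero.  Scores are compared as exact
rationals: :func:`indicator_key` returns a `Fraction` whose ordering equals
the ordering of the real scores (for the Yule phi, whose value involves a
square root, the key is the signed square of the value — a strictly
monotone transform, so argmax sets and ties are exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Callable, Iterable

from .taxonomy import TaxonomyError, TaxonomyTree

__all__ = [
    "ConfusionCounts",
    "Indicator",
    "confusion_global",
    "confusion_lca_relative",
    "balance_ratio",
    "indicator",
    "indicator_key",
    "UndefinedRatioError",
]


class UndefinedRatioError(ZeroDivisionError):
    """Balance ratio requested for an all-positive problem (FP + TN = 0)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """The (TP, FP, TN, FN) quadruple of one (candidate set, node) pair."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


class Indicator(str, Enum):
    """The six classification-error indicators.

    ``yule_phi`` is the Matthews correlation coefficient; ``auc`` is the
    two-point area under the ROC curve (TPR - FPR + 1) / 2; ``youden_j`` is
    equivalent to AUC (J = 2 AUC - 1), and ``jaccard`` to the F-measure
    (C = F / (2 - F)).
    """

    YULE_PHI = "yule_phi"
    YOUDEN_J = "youden_j"
    AUC = "auc"
    F_MEASURE = "f_measure"
    JACCARD = "jaccard"
    RAND = "rand"


def confusion_global(tree: TaxonomyTree, m: Iterable[int], j: int) -> ConfusionCounts:
    """Whole-tree confusion counts for candidate set ``m`` at node ``j``.

    TN is counted over every leaf of the tree; ``j`` may be any node.
    """
    mset = _leaf_set(tree, m)
    clade = tree.clade_leaves(j)
    tp = len(mset & clade)
    fp = len(clade) - tp
    fn = len(mset) - tp
    tn = tree.n_leaves - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def confusion_lca_relative(tree: TaxonomyTree, m: Iterable[int], j: int) -> ConfusionCounts:
    """Confusion counts restricted to the subtree rooted at the LCA of ``m``.

    ``j`` must lie in that subtree; TN/FN are counted among its leaves only.
    At ``j`` = LCA there are no TN and no FN.
    """
    mset = _leaf_set(tree, m)
    anc = tree.lca(mset)
    if not tree.is_ancestor_or_self(anc, j):
        raise TaxonomyError(
            f"node {j} lies outside the subtree rooted at the LCA of the "
            f"candidate set (use confusion_global for whole-tree counts)")
    within = len(tree.clade_leaves(anc))
    clade = tree.clade_leaves(j)
    tp = len(mset & clade)
    fp = len(clade) - tp
    fn = len(mset) - tp
    tn = within - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _leaf_set(tree: TaxonomyTree, m: Iterable[int]) -> frozenset[int]:
    mset = frozenset(m)
    if not mset:
        raise TaxonomyError("candidate set must be non-empty")
    leaves = set(tree.leaves)
    bad = mset - leaves
    if bad:
        raise TaxonomyError(f"not leaves of this tree: {sorted(bad)}")
    return mset


def balance_ratio(c: ConfusionCounts) -> Fraction:
    """(TP + FN) / (FP + TN): positive-class size over negative-class size."""
    if c.fp + c.tn == 0:
        raise UndefinedRatioError("balance ratio undefined when FP + TN = 0")
    return Fraction(c.tp + c.fn, c.fp + c.tn)


# -- exact score keys --------------------------------------------------------
#
# Each function maps (tp, fp, tn, fn) to an integer pair (num, den), den > 0,
# such that num/den orders identically to the indicator's real value.  The
# zero-denominator convention maps to (0, 1).  For yule_phi the value is
# a / sqrt(d); the key is sign(a) * a^2 / d, order-isomorphic to it.

def _key_rand(tp: int, fp: int, tn: int, fn: int) -> tuple[int, int]:
    den = tp + fp + tn + fn
    return (tp + tn, den) if den else (0, 1)


def _key_f_measure(tp: int, fp: int, tn: int, fn: int) -> tuple[int, int]:
    den = 2 * tp + fp + fn
    return (2 * tp, den) if den else (0, 1)


def _key_jaccard(tp: int, fp: int, tn: int, fn: int) -> tuple[int, int]:
    den = tp + fp + fn
    return (tp, den) if den else (0, 1)


def _key_auc(tp: int, fp: int, tn: int, fn: int) -> tuple[int, int]:
    pos, neg = tp + fn, fp + tn
    if pos == 0 or neg == 0:
        return (0, 1)
    return (tp * neg + tn * pos, 2 * pos * neg)


def _key_youden(tp: int, fp: int, tn: int, fn: int) -> tuple[int, int]:
    pos, neg = tp + fn, fp + tn
    if pos == 0 or neg == 0:
        return (0, 1)
    return (tp * tn - fp * fn, pos * neg)


def _key_yule_phi(tp: int, fp: int, tn: int, fn: int) -> tuple[int, int]:
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if d == 0:
        return (0, 1)
    a = tp * tn - fp * fn
    return (a * abs(a), d)


SCORE_KEY_FNS: dict[Indicator, Callable[[int, int, int, int], tuple[int, int]]] = {
    Indicator.RAND: _key_rand,
    Indicator.F_MEASURE: _key_f_measure,
    Indicator.JACCARD: _key_jaccard,
    Indicator.AUC: _key_auc,
    Indicator.YOUDEN_J: _key_youden,
    Indicator.YULE_PHI: _key_yule_phi,
}


def indicator_key(kind: Indicator, c: ConfusionCounts) -> Fraction:
    """Exact, order-preserving score key (see module docstring)."""
    num, den = SCORE_KEY_FNS[Indicator(kind)](c.tp, c.fp, c.tn, c.fn)
    return Fraction(num, den)


def indicator(kind: Indicator, c: ConfusionCounts) -> Fraction | float:
    """The indicator's value; zero whenever a denominator of its formula is
    zero.  Exact :class:`Fraction` for the five rational indicators; float
    for the Yule phi (its value involves a square root)."""
    kind = Indicator(kind)
    if kind is Indicator.YULE_PHI:
        num, den = _key_yule_phi(c.tp, c.fp, c.tn, c.fn)
        if num == 0:
            return 0.0
        sign = 1.0 if num > 0 else -1.0
        return sign * math.sqrt(abs(num) / den)
    num, den = SCORE_KEY_FNS[kind](c.tp, c.fp, c.tn, c.fn)
    return Fraction(num, den)
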