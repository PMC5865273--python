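"""Exhaustive enumeration experiments on synthetic reference topologies.

For a tree with n leaves, every non-empty leaf subset M is a possible
candidate set and every internal node j of the *whole* tree is a possible
annotation (whole-leafset confusion counts: TN ranges over all n leaves).
Two summaries are computed:

* the distribution of (TP, FP, TN, FN) quadruples over all (M, j) pairs,
  together with its TP + FN marginal — the latter is C(n, k) times the
  internal-node count and therefore identical for any two topologies with
  the same number of leaves and internal nodes, which is why balanced and
  imbalanced taxonomies yield equally balanced classification problems;

* the number of correct annotations per indicator: an annotation of a read
  from source leaf s in M at an indicator-maximising internal node j is
  correct iff s lies in clade(j); every maximising node contributes for
  every source leaf, so each subset M adds the sum of TP over its argmax
  nodes.

For the correctness counts two candidate conventions are supported: the
default (``candidates="lca"``) maximises over the internal nodes at or
under the LCA of the subset, the nodes the annotation procedure actually
considers (a singleton subset is annotated at its leaf and always counts
as correct); ``candidates="global"`` maximises over every internal node of
the whole tree.  The two coincide for perfect trees.  The complete-tree
series of :func:`table3_report` uses the left-packed build of the complete
tree (see :func:`taxocover.taxonomy.complete_binary_tree`).

Scores are compared as exact rationals via int64 cross-multiplication — no
floating point is involved, so argmax ties are exact.  Leaves are not
annotation candidates here; only internal nodes are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .confusion import Indicator
from .taxonomy import TaxonomyTree, caterpillar, complete_binary_tree

__all__ = [
    "EnumerationReport",
    "EnumerationCapacityError",
    "confusion_distribution",
    "positives_distribution",
    "count_correct_annotations",
    "table3_report",
]

_DISTRIBUTION_MAX_N = 20
_CORRECTNESS_MAX_N = 16
_CHUNK = 1 << 16  # subsets processed per numpy block


class EnumerationCapacityError(ValueError):
    """Leaf count exceeds the enumeration bound."""


@dataclass(frozen=True)
class EnumerationReport:
    """All enumeration summaries for one topology."""

    shape: str
    n: int
    distribution: Mapping[tuple[int, int, int, int], int]
    positives_distribution: Mapping[int, int]
    correct_counts: Mapping[Indicator, int]


def _clade_matrix(tree: TaxonomyTree) -> tuple[np.ndarray, np.ndarray, int]:
    """Leaf-in-clade membership of internal nodes, as a 0/1 matrix
    (n_leaves x n_internal) and as int64 leaf-set bitmasks."""
    leaves = tree.leaves
    index = {v: i for i, v in enumerate(leaves)}
    internal = tree.internal_nodes
    mat = np.zeros((len(leaves), len(internal)), dtype=np.int64)
    ints = np.zeros(len(internal), dtype=np.int64)
    for j, v in enumerate(internal):
        for leaf in tree.clade_leaves(v):
            mat[index[leaf], j] = 1
            ints[j] |= np.int64(1) << np.int64(index[leaf])
    return mat, ints, len(leaves)


def _subset_counts(clades: np.ndarray, n: int, lo: int, hi: int):
    """TP/FP/TN/FN arrays for subset masks lo..hi-1 (rows) x internal (cols),
    plus the per-row subset masks and sizes."""
    masks = np.arange(lo, hi, dtype=np.int64)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(np.int64)  # rows x n
    tp = bits @ clades
    sizes = clades.sum(axis=0)  # clade sizes, per internal node
    m_count = bits.sum(axis=1)
    fp = sizes[None, :] - tp
    fn = m_count[:, None] - tp
    tn = n - tp - fp - fn
    return tp, fp, tn, fn, masks, m_count


def confusion_distribution(tree: TaxonomyTree) -> dict[tuple[int, int, int, int], int]:
    """Tally of whole-leafset (TP, FP, TN, FN) over every non-empty leaf
    subset and every internal node."""
    n = tree.n_leaves
    if n > _DISTRIBUTION_MAX_N:
        raise EnumerationCapacityError(
            f"{n} leaves exceeds the enumeration bound of {_DISTRIBUTION_MAX_N}")
    clades, _, _ = _clade_matrix(tree)
    out: dict[tuple[int, int, int, int], int] = {}
    for lo in range(1, 1 << n, _CHUNK):
        hi = min(lo + _CHUNK, 1 << n)
        tp, fp, tn, fn, _, _ = _subset_counts(clades, n, lo, hi)
        quads = np.stack([a.ravel() for a in (tp, fp, tn, fn)], axis=1)
        uniq, counts = np.unique(quads, axis=0, return_counts=True)
        for row, c in zip(uniq, counts):
            key = tuple(int(x) for x in row)
            out[key] = out.get(key, 0) + int(c)
    return out


def positives_distribution(distribution: Mapping[tuple[int, int, int, int], int]) -> dict[int, int]:
    """Marginal of a confusion distribution over TP + FN (candidate-set size)."""
    out: dict[int, int] = {}
    for (tp, _fp, _tn, fn), c in distribution.items():
        out[tp + fn] = out.get(tp + fn, 0) + c
    return dict(sorted(out.items()))


def _num_den(kind: Indicator, tp, fp, tn, fn, n: int):
    """Vectorised exact score keys (num, den), den >= 1; order equals the
    indicator's real order (signed square for the Yule phi).  Mirrors
    ``confusion.SCORE_KEY_FNS``."""
    one = np.ones_like(tp)
    if kind is Indicator.RAND:
        return tp + tn, np.full_like(tp, n)
    if kind is Indicator.F_MEASURE:
        den = 2 * tp + fp + fn
        return np.where(den > 0, 2 * tp, 0), np.where(den > 0, den, one)
    if kind is Indicator.JACCARD:
        den = tp + fp + fn
        return np.where(den > 0, tp, 0), np.where(den > 0, den, one)
    pos, neg = tp + fn, fp + tn
    ok = (pos > 0) & (neg > 0)
    if kind is Indicator.AUC:
        return (np.where(ok, tp * neg + tn * pos, 0),
                np.where(ok, 2 * pos * neg, one))
    if kind is Indicator.YOUDEN_J:
        return np.where(ok, tp * tn - fp * fn, 0), np.where(ok, pos * neg, one)
    if kind is Indicator.YULE_PHI:
        d = (tp + fp) * pos * (tn + fp) * (tn + fn)
        a = tp * tn - fp * fn
        return np.where(d > 0, a * np.abs(a), 0), np.where(d > 0, d, one)
    raise ValueError(f"unknown indicator: {kind!r}")


def count_correct_annotations(tree: TaxonomyTree, kind: Indicator,
                              candidates: str = "lca") -> int:
    """Total correct annotations over all non-empty candidate sets.

    For each subset M, the internal nodes maximising the indicator (with
    whole-leafset counts and the zero-denominator-to-zero rule) each
    contribute one correct annotation per source leaf of M inside their
    clade, i.e. their TP; ties contribute once per tied node.

    ``candidates="lca"`` (default) maximises over the internal nodes at or
    under the LCA of M, with singleton subsets annotated at their leaf
    (always correct); ``candidates="global"`` maximises over every internal
    node of the tree.
    """
    kind = Indicator(kind)
    if candidates not in ("lca", "global"):
        raise ValueError(
            f"candidates must be 'lca' or 'global', got {candidates!r}")
    n = tree.n_leaves
    if n > _CORRECTNESS_MAX_N:
        raise EnumerationCapacityError(
            f"{n} leaves exceeds the enumeration bound of {_CORRECTNESS_MAX_N}")
    clades, clade_ints, _ = _clade_matrix(tree)
    k = clades.shape[1]
    sizes = clades.sum(axis=0)
    total = 0
    for lo in range(1, 1 << n, _CHUNK):
        hi = min(lo + _CHUNK, 1 << n)
        tp, fp, tn, fn, masks, m_count = _subset_counts(clades, n, lo, hi)
        num, den = _num_den(kind, tp, fp, tn, fn, n)
        if candidates == "lca":
            # the clades containing M form a chain, so the smallest one is
            # the LCA's clade; nodes outside it get a sentinel score below
            # every indicator's range [-1, 1]
            contains = (masks[:, None] & clade_ints[None, :]) == masks[:, None]
            size_or_inf = np.where(contains, sizes[None, :], np.iinfo(np.int64).max)
            lca_mask = clade_ints[np.argmin(size_or_inf, axis=1)]
            in_subtree = (lca_mask[:, None] & clade_ints[None, :]) == clade_ints[None, :]
            num = np.where(in_subtree, num, -3)
            den = np.where(in_subtree, den, 1)
        # running argmax by exact cross-multiplication (int64 products stay
        # far below 2**63 for n <= 16)
        best_num = num[:, 0].copy()
        best_den = den[:, 0].copy()
        for j in range(1, k):
            better = num[:, j] * best_den > best_num * den[:, j]
            best_num = np.where(better, num[:, j], best_num)
            best_den = np.where(better, den[:, j], best_den)
        correct = np.zeros(tp.shape[0], dtype=np.int64)
        for j in range(k):
            tied = num[:, j] * best_den == best_num * den[:, j]
            correct += np.where(tied, tp[:, j], 0)
        if candidates == "lca":
            correct = np.where(m_count == 1, 1, correct)
        total += int(correct.sum())
    return total


_SHAPES = {
    # the complete-tree series uses the left-packed build (see module docstring)
    "complete": lambda n: complete_binary_tree(n, split="left_packed"),
    "caterpillar": caterpillar,
}


def table3_report(max_n: int, shape: str = "complete",
                  kinds: Iterable[Indicator] = tuple(Indicator),
                  candidates: str = "lca") -> list[EnumerationReport]:
    """Per-n enumeration reports for n = 2..max_n on a generated shape."""
    if shape not in _SHAPES:
        raise ValueError(f"shape must be one of {sorted(_SHAPES)}, got {shape!r}")
    if not 2 <= max_n <= _CORRECTNESS_MAX_N:
        raise EnumerationCapacityError(
            f"max_n must be in 2..{_CORRECTNESS_MAX_N}, got {max_n}")
    kinds = [Indicator(k) for k in kinds]
    reports = []
    for n in range(2, max_n + 1):
        tree = _SHAPES[shape](n)
        dist = confusion_distribution(tree)
        reports.append(EnumerationReport(
            shape=shape,
            n=n,
            distribution=dist,
            positives_distribution=positives_distribution(dist),
            correct_counts={
                k: count_correct_annotations(tree, k, candidates) for k in kinds},
        ))
    return reports


def report_to_tsv(reports: list[EnumerationReport]) -> str:
    """Correct-annotation totals as TSV, indicators as rows and n as columns."""
    if not reports:
        return ""
    kinds = list(reports[0].correct_counts)
    lines = ["n\t" + "\t".join(str(r.n) for r in reports)]
    for k in kinds:
        lines.append(k.value + "\t" +
                     "\t".join(str(r.correct_counts[k]) for r in reports))
    return "\n".join(lines) + "\n"
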