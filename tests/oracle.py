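"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained: confusion counts
from explicit leaf-set algebra, indicator ordering via exact rational
comparison, maxima by scanning every node, and set covers by enumerating
every subfamily.  Nothing is shared with the library's implementation paths.
"""

from fractions import Fraction
from itertools import combinations


def quadruple(tree, m, j, scope_leaves):
    """(tp, fp, tn, fn) of candidate set ``m`` at node ``j``, with negatives
    counted over ``scope_leaves``."""
    clade = set(tree.clade_leaves(j))
    m = set(m)
    tp = len(m & clade)
    fp = len(clade - m)
    fn = len(m - clade)
    tn = len(set(scope_leaves)) - tp - fp - fn
    return tp, fp, tn, fn


def order_key(kind, tp, fp, tn, fn):
    """Exact ordering key of an indicator score; zero denominator -> 0.

    Rational indicators map to their value; the Yule phi maps to the signed
    square of its value (sign(a) * a^2 / d for a / sqrt(d)), which is a
    strictly increasing transform and hence order-faithful.
    """
    kind = str(kind.value if hasattr(kind, "value") else kind)
    if kind == "rand":
        return Fraction(tp + tn, tp + fp + tn + fn)
    if kind == "f_measure":
        den = 2 * tp + fp + fn
        return Fraction(2 * tp, den) if den else Fraction(0)
    if kind == "jaccard":
        den = tp + fp + fn
        return Fraction(tp, den) if den else Fraction(0)
    pos, neg = tp + fn, fp + tn
    if kind == "auc":
        if pos == 0 or neg == 0:
            return Fraction(0)
        return Fraction(tp * neg + tn * pos, 2 * pos * neg)
    if kind == "youden_j":
        if pos == 0 or neg == 0:
            return Fraction(0)
        return Fraction(tp * tn - fp * fn, pos * neg)
    if kind == "yule_phi":
        d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if d == 0:
            return Fraction(0)
        a = tp * tn - fp * fn
        return Fraction(a * abs(a), d)
    raise ValueError(kind)


def subtree_nodes(tree, root):
    """Every node (internal and leaf) of the subtree rooted at ``root``."""
    out, stack = [], [root]
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(tree.children(v))
    return out


def best_over_subtree(tree, m, kind):
    """(max key, argmax nodes) scanning every node under the LCA of ``m``,
    with negatives counted among the LCA's leaves."""
    anc = tree.lca(m)
    scope = tree.clade_leaves(anc)
    best, arg = None, []
    for j in subtree_nodes(tree, anc):
        key = order_key(kind, *quadruple(tree, m, j, scope))
        if best is None or key > best:
            best, arg = key, [j]
        elif key == best:
            arg.append(j)
    return best, arg


def pairwise_lcas(tree, m):
    """Relevant nodes by definition: members plus all pairwise LCAs."""
    rel = set(m)
    for a, b in combinations(sorted(m), 2):
        rel.add(tree.lca((a, b)))
    return rel


def count_correct(tree, kind, candidates="lca"):
    """Pure-python correct-annotation total over all non-empty leaf subsets."""
    leaves = list(tree.leaves)
    n = len(leaves)
    internal = list(tree.internal_nodes)
    total = 0
    for mask in range(1, 1 << n):
        m = {leaves[i] for i in range(n) if mask >> i & 1}
        if candidates == "lca":
            if len(m) == 1:
                total += 1
                continue
            anc = tree.lca(m)
            cand = [j for j in internal
                    if tree.clade_leaves(j) <= tree.clade_leaves(anc)]
        else:
            cand = internal
        best, tp_sum = None, 0
        for j in cand:
            tp, fp, tn, fn = quadruple(tree, m, j, leaves)
            key = order_key(kind, tp, fp, tn, fn)
            if best is None or key > best:
                best, tp_sum = key, tp
            elif key == best:
                tp_sum += tp
        total += tp_sum
    return total


def all_covers(family, elements):
    """Every valid cover, as sorted name tuples."""
    names = sorted(family)
    out = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            if set().union(*(family[c] for c in combo)) >= set(elements):
                out.append(combo)
    return out


def exhaustive_min_cover(family, elements, by="cardinality"):
    """Optimal cover by full enumeration; ties by sorted name sequence."""
    def cost(names):
        if by == "cardinality":
            return len(names)
        return sum(len(family[c]) for c in names)

    covers = all_covers(family, elements)
    return min(covers, key=lambda names: (cost(names), names))
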