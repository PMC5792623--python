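"""Independent oracles used by the unit and acceptance suites.

These deliberately avoid the package's own code paths: the TN93 oracle
inverts the substitution model numerically (matrix exponentials + root
finding) instead of using the closed form; the Fisher oracle enumerates the
hypergeometric distribution directly; tree helpers compare unrooted splits.
"""

import itertools
import math
from io import StringIO

import numpy as np
from scipy.linalg import expm
from scipy.optimize import root
from skbio import TreeNode


def pair_stats(a, b):
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    p1 = sum({x, y} == {"A", "G"} for x, y in pairs) / n
    p2 = sum({x, y} == {"C", "T"} for x, y in pairs) / n
    q = sum(x != y and {x, y} not in ({"A", "G"}, {"C", "T"}) for x, y in pairs) / n
    counts = np.zeros(4)
    for x, y in pairs:
        counts["ACGT".index(x)] += 1
        counts["ACGT".index(y)] += 1
    return p1, p2, q, counts / counts.sum()


def tn93_numeric_oracle(a, b):
    """Solve the TN93 moment equations for the expected substitution count."""
    p1_obs, p2_obs, q_obs, pi = pair_stats(a, b)

    def build_q(x):
        a1, a2, beta = x
        q = np.zeros((4, 4))
        for i, j in itertools.permutations(range(4), 2):
            pair = {i, j}
            rate = a1 if pair == {0, 2} else a2 if pair == {1, 3} else beta
            q[i, j] = rate * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def residual(x):
        p = expm(build_q(np.abs(x)))
        p1 = pi[0] * p[0, 2] + pi[2] * p[2, 0]
        p2 = pi[1] * p[1, 3] + pi[3] * p[3, 1]
        qq = sum(
            pi[i] * p[i, j]
            for i, j in itertools.permutations(range(4), 2)
            if {i, j} not in ({0, 2}, {1, 3})
        )
        return [p1 - p1_obs, p2 - p2_obs, qq - q_obs]

    x0 = [max(p1_obs, 1e-4), max(p2_obs, 1e-4), max(q_obs, 1e-4)]
    sol = root(residual, x0=x0, method="lm", tol=1e-15)
    assert max(abs(r) for r in residual(sol.x)) < 1e-12
    x = np.abs(sol.x)
    return -float(np.dot(pi, np.diag(build_q(x))))


def balanced_pair(length_blocks=100, c=8):
    """A pair with equal base composition and P1:P2:Q = 1:1:4 (the JC limit)."""
    s1 = list("ACGT" * length_blocks)
    s2 = s1.copy()
    pos = {b: [i for i, x in enumerate(s1) if x == b] for b in "ACGT"}
    half = c // 2
    for i in pos["A"][:half]:
        s2[i] = "G"
    for i in pos["G"][:half]:
        s2[i] = "A"
    for i in pos["C"][:half]:
        s2[i] = "T"
    for i in pos["T"][:half]:
        s2[i] = "C"
    for i in pos["A"][half: half + c]:
        s2[i] = "C"
    for i in pos["C"][half: half + c]:
        s2[i] = "A"
    for i in pos["G"][half: half + c]:
        s2[i] = "T"
    for i in pos["T"][half: half + c]:
        s2[i] = "G"
    return "".join(s1), "".join(s2)


def splits(newick):
    """Non-trivial unrooted splits (as frozensets of tip-name partitions)."""
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(tips) - 1:
            out.add(frozenset({clade, tips - clade}))
    return out


def random_additive_tree(names, rng):
    """Random unrooted binary topology with positive branch lengths."""
    root_node = TreeNode()
    for name in names[:3]:
        root_node.append(TreeNode(name=name))
    for name in names[3:]:
        candidates = [n for n in root_node.traverse() if n.parent is not None]
        chosen = candidates[rng.integers(len(candidates))]
        parent = chosen.parent
        parent.remove(chosen)
        inner = TreeNode()
        inner.append(chosen)
        inner.append(TreeNode(name=name))
        parent.append(inner)
    for node in root_node.traverse():
        if node.parent is not None:
            node.length = float(rng.uniform(0.05, 0.4))
    return root_node


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by direct hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def ranksum_two_sided(values, n1):
    """Two-sided rank-sum p by enumerating every group assignment."""
    from scipy.stats import rankdata

    values = np.asarray(values, float)
    n = values.size
    ranks = rankdata(values)
    expect = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - expect)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        hits += abs(w - expect) >= obs - 1e-12
        total += 1
    return hits / total
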