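"""Independent oracles shared by tests and the acceptance checks.

Everything here is deliberately naive (enumeration, textbook formulas) so it
stays independent of the implementation paths it verifies.
"""

import itertools

import numpy as np
from scipy.stats import entropy


def jsd_oracle(p, q):
    """Textbook Jensen-Shannon divergence: 0.5 KL(p||m) + 0.5 KL(q||m), bits."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = 0.5 * (p + q)
    return 0.5 * entropy(p, m, base=2) + 0.5 * entropy(q, m, base=2)


def flip_consistent_orders(node):
    """All leaf orders reachable by flipping subtrees (2^(N-1) for N leaves)."""
    if node.is_leaf:
        return [(node.label,)]
    lefts = flip_consistent_orders(node.left)
    rights = flip_consistent_orders(node.right)
    out = []
    for a, b in itertools.product(lefts, rights):
        out.append(a + b)
        out.append(b + a)
    return out


def best_flip_order(tree, matrix):
    """Exhaustive minimum of the adjacent-pair objective over all flip orders."""
    best_cost, best_order = None, None
    for order in flip_consistent_orders(tree.root):
        cost = sum(matrix.value(a, b) for a, b in zip(order, order[1:]))
        if best_cost is None or cost < best_cost:
            best_cost, best_order = cost, order
    return best_cost, best_order


def brute_force_agglomerate(values, labels, linkage="complete"):
    """Naive agglomerative clustering; returns merge heights and merged label sets."""
    dist = {
        (a, b): values[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i != j
    }
    clusters = [frozenset([lab]) for lab in labels]

    def cluster_dist(c1, c2):
        ds = [dist[(a, b)] for a in c1 for b in c2]
        if linkage == "complete":
            return max(ds)
        if linkage == "single":
            return min(ds)
        return sum(ds) / len(ds)

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cluster_dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((d, merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def random_dissimilarity(rng, n):
    """A random symmetric non-negative matrix with zero diagonal."""
    vals = rng.uniform(0.1, 2.0, size=(n, n))
    vals = np.triu(vals, 1)
    vals = vals + vals.T
    return vals
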