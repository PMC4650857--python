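"""Multi-motif comparison: dissimilarity matrix, clustering, leaf ordering, grid.

Comparing N >= 3 motifs uses all pairwise scalar dissimilarities D.  Motifs
are clustered hierarchically on D, the dendrogram's leaves are reordered by
subtree flips so adjacent motifs are as similar as possible (optimal leaf
ordering), and the difference logos of all ordered pairs are arranged in an
N x N grid with an empty diagonal, a shared ordinate, and cell backgrounds
on a green (most similar) to red (most dissimilar) gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .errors import MotifError
from .geometry import LogoColumns, build_difference_logo, build_sequence_logo, common_ordinate
from .measures import DEFAULT_MEASURES, MeasurePair, motif_dissimilarity
from .model import ProbabilityMotif, pad_motifs

LINKAGES = ("complete", "average", "single")

#: default background gradient endpoints: similar -> dissimilar
DEFAULT_PALETTE = ("#00B000", "#D00000")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric N x N matrix of pairwise motif dissimilarities with labels."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        values = np.asarray(self.values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise MotifError(f"motif labels must be unique, got {labels}")
        if values.shape != (n, n):
            raise MotifError(f"matrix shape {values.shape} does not match {n} labels")
        if np.isnan(values).any():
            raise MotifError("NaN in dissimilarity matrix")
        if np.any(values < 0):
            raise MotifError("dissimilarities must be non-negative")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0):
            raise MotifError("dissimilarity matrix must be symmetric (within 1e-12)")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise MotifError("dissimilarity matrix must have a zero diagonal")
        values = 0.5 * (values + values.T)  # exact symmetry for downstream code
        np.fill_diagonal(values, 0.0)
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def off_diagonal_range(self):
        mask = ~np.eye(self.n, dtype=bool)
        off = self.values[mask]
        return float(off.min()), float(off.max())


@dataclass(frozen=True)
class ClusterNode:
    """Node of a binary merge tree; leaves carry a label and height 0."""

    height: float
    leaves: tuple
    label: str | None = None
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass(frozen=True)
class ClusterTree:
    """Binary agglomerative clustering tree over motif labels.

    Wraps the merge structure (N leaves, N-1 internal nodes with
    non-decreasing merge heights along root paths) plus the raw linkage
    matrix for interop.
    """

    root: ClusterNode
    labels: tuple
    linkage_matrix: np.ndarray
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def pairwise_matrix(
    motifs,
    measures: MeasurePair = DEFAULT_MEASURES,
    pad: bool = False,
) -> DissimilarityMatrix:
    """All pairwise dissimilarities D of a motif list."""
    motifs = list(motifs)
    if len(motifs) < 2:
        raise MotifError("need at least 2 motifs")
    n = len(motifs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = motif_dissimilarity(motifs[i], motifs[j], measures, pad=pad)
            values[i, j] = values[j, i] = d
    return DissimilarityMatrix(labels=tuple(m.label for m in motifs), values=values)


def cluster(matrix: DissimilarityMatrix, linkage: str = "complete") -> ClusterTree:
    """Agglomerative hierarchical clustering of the dissimilarity matrix."""
    if linkage not in LINKAGES:
        raise MotifError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if matrix.n < 2:
        raise MotifError("need at least 2 motifs to cluster")
    condensed = squareform(matrix.values, checks=False)
    Z = _scipy_linkage(condensed, method=linkage)
    nodes = [
        ClusterNode(height=0.0, leaves=(lab,), label=lab) for lab in matrix.labels
    ]
    for a, b, h, _ in Z:
        left, right = nodes[int(a)], nodes[int(b)]
        nodes.append(
            ClusterNode(
                height=float(h),
                leaves=left.leaves + right.leaves,
                left=left,
                right=right,
            )
        )
    return ClusterTree(root=nodes[-1], labels=matrix.labels, linkage_matrix=Z, method=linkage)


@dataclass(frozen=True)
class LeafOrdering:
    """A permutation of motif labels realizable by flipping dendrogram subtrees."""

    labels: tuple

    def __iter__(self):
        return iter(self.labels)

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]


def adjacent_sum(order, matrix: DissimilarityMatrix) -> float:
    """Objective of leaf ordering: sum of D over adjacent label pairs."""
    order = list(order)
    return float(sum(matrix.value(a, b) for a, b in zip(order, order[1:])))


def is_flip_consistent(tree: ClusterTree, order) -> bool:
    """True if ``order`` places every subtree's leaves contiguously."""
    pos = {lab: i for i, lab in enumerate(order)}
    if set(pos) != set(tree.labels) or len(pos) != len(tree.labels):
        return False

    def check(node: ClusterNode) -> bool:
        idx = sorted(pos[lab] for lab in node.leaves)
        if idx != list(range(idx[0], idx[0] + len(idx))):
            return False
        return node.is_leaf or (check(node.left) and check(node.right))

    return check(tree.root)


def optimal_leaf_order(tree: ClusterTree, matrix: DissimilarityMatrix) -> LeafOrdering:
    """Optimal leaf ordering by the exact dynamic program over subtree flips.

    Among all 2^(N-1) orderings obtainable by flipping subtrees, returns one
    minimizing the sum of dissimilarities over adjacent leaves.  The DP
    tabulates, for every node and every (leftmost, rightmost) leaf pair of
    its subtree, the cheapest internal arrangement; ties break
    lexicographically by label, so the result is deterministic and
    independent of input order.
    """
    if set(tree.labels) != set(matrix.labels):
        raise MotifError("tree leaves do not match matrix labels")
    dist = {
        (a, b): matrix.value(a, b) for a in matrix.labels for b in matrix.labels
    }
    tables = {}  # id(node) -> {(u, w): (cost, choice)}

    def solve(node: ClusterNode):
        key = id(node)
        if key in tables:
            return tables[key]
        if node.is_leaf:
            tables[key] = {(node.label, node.label): (0.0, None)}
            return tables[key]
        table = {}
        for first, second in ((node.left, node.right), (node.right, node.left)):
            tf, ts = solve(first), solve(second)
            f_leaves = sorted(first.leaves)
            s_leaves = sorted(second.leaves)
            for u in f_leaves:
                for w in s_leaves:
                    best = None
                    for m in f_leaves:
                        if (u, m) not in tf:
                            continue
                        for k in s_leaves:
                            if (k, w) not in ts:
                                continue
                            c = tf[(u, m)][0] + dist[(m, k)] + ts[(k, w)][0]
                            if best is None or c < best[0] - 1e-15 or (
                                abs(c - best[0]) <= 1e-15 and (m, k) < best[1][2:]
                            ):
                                best = (c, (first, second, m, k))
                    if best is not None:
                        prev = table.get((u, w))
                        if prev is None or best[0] < prev[0] - 1e-15:
                            table[(u, w)] = best
        tables[key] = table
        return table

    root_table = solve(tree.root)
    (u, w), _ = min(root_table.items(), key=lambda item: (item[1][0], item[0]))

    def reconstruct(node: ClusterNode, u: str, w: str):
        if node.is_leaf:
            return [node.label]
        _, (first, second, m, k) = tables[id(node)][(u, w)]
        return reconstruct(first, u, m) + reconstruct(second, k, w)

    order = tuple(reconstruct(tree.root, u, w))
    return LeafOrdering(labels=order)


def _hex_to_rgb(color: str):
    c = color.lstrip("#")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))


def interpolate_color(c0: str, c1: str, t: float) -> str:
    """Linear RGB interpolation between two hex colors, t in [0, 1]."""
    t = min(max(float(t), 0.0), 1.0)
    r0, r1 = _hex_to_rgb(c0), _hex_to_rgb(c1)
    mixed = tuple(int(round(a + t * (b - a))) for a, b in zip(r0, r1))
    return "#{:02X}{:02X}{:02X}".format(*mixed)


@dataclass(frozen=True)
class GridCell:
    """One off-diagonal cell: difference logo of (row motif, column motif)."""

    row: str
    col: str
    geometry: LogoColumns
    dissimilarity: float
    color: str


@dataclass(frozen=True)
class ComparisonGrid:
    """Everything needed to draw the N x N comparison figure."""

    ordering: LeafOrdering
    tree: ClusterTree
    matrix: DissimilarityMatrix
    cells: dict = field(default_factory=dict)  # (i, j) 0-based -> GridCell
    shared_ordinate: float = 1.0
    header_logos: tuple = ()
    palette: tuple = DEFAULT_PALETTE

    @property
    def n(self) -> int:
        return len(self.ordering)


def build_grid(
    motifs,
    measures: MeasurePair = DEFAULT_MEASURES,
    linkage: str = "complete",
    palette=DEFAULT_PALETTE,
    pad: bool = False,
) -> ComparisonGrid:
    """Assemble the ordered, clustered, color-coded comparison grid.

    Rows/columns follow the optimal leaf ordering; cell (i, j) holds the
    difference logo of row motif i against column motif j (so cells mirror
    across the diagonal), with background color interpolated between the
    palette endpoints by D.  If all off-diagonal D coincide (e.g. identical
    motifs) every cell gets the "similar" endpoint.
    """
    motifs = list(motifs)
    if len(motifs) < 2:
        raise MotifError("need at least 2 motifs for a comparison grid")
    if pad:
        target = max(m.length for m in motifs)
        reference = next(m for m in motifs if m.length == target)
        motifs = [pad_motifs(m, reference)[0] for m in motifs]
    matrix = pairwise_matrix(motifs, measures)
    tree = cluster(matrix, linkage)
    ordering = optimal_leaf_order(tree, matrix)
    by_label = {m.label: m for m in motifs}
    ordered = [by_label[lab] for lab in ordering]

    dmin, dmax = matrix.off_diagonal_range()
    span = dmax - dmin
    cells = {}
    for i, mi in enumerate(ordered):
        for j, mj in enumerate(ordered):
            if i == j:
                continue
            geom = build_difference_logo(mi, mj, measures)
            d = matrix.value(mi.label, mj.label)
            t = 0.0 if span <= 0 else (d - dmin) / span
            cells[(i, j)] = GridCell(
                row=mi.label,
                col=mj.label,
                geometry=geom,
                dissimilarity=d,
                color=interpolate_color(palette[0], palette[1], t),
            )
    shared = common_ordinate(cell.geometry for cell in cells.values())
    header = tuple(build_sequence_logo(m) for m in ordered)
    return ComparisonGrid(
        ordering=ordering,
        tree=tree,
        matrix=matrix,
        cells=cells,
        shared_ordinate=shared,
        header_logos=header,
        palette=tuple(palette),
    )
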