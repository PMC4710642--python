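"""Distance-based phylogenetics: p/JC69/Poisson distances, Saitou-Nei
neighbor joining, bootstrap supports and Newick import/export.

Trees are held unrooted, as a trifurcating "root" node; supports are
percentages attached to internal edges of the point-estimate tree.
Negative branch-length estimates (a known NJ artefact on non-additive
matrices) are clamped to zero and flagged on the tree.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

GAP = "-"


class PhyloError(Exception):
    pass


class SaturationError(PhyloError):
    pass


class NewickParseError(PhyloError):
    pass


# ------------------------------------------------------------------ #
# distance matrices                                                  #
# ------------------------------------------------------------------ #

@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise PhyloError("matrix shape does not match label count")
        finite = np.isfinite(self.matrix)
        if not np.allclose(
            np.where(finite, self.matrix, 0.0),
            np.where(finite.T, self.matrix.T, 0.0),
        ):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if np.any(np.where(finite, self.matrix, 0.0) < 0):
            raise PhyloError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)


_NT_MODELS = ("p-distance", "JC69")
_PROT_MODELS = ("p-distance", "Poisson")


def _pairwise_p(rows: list[str], i: int, j: int, use_cols: list[int] | None) -> float | None:
    a, b = rows[i], rows[j]
    compared = mismatches = 0
    cols = use_cols if use_cols is not None else range(len(a))
    for c in cols:
        x, y = a[c], b[c]
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        return None
    return mismatches / compared


def distance_matrix(
    aln, model: str = "p-distance", pairwise_deletion: bool = True
) -> DistanceMatrix:
    """Pairwise evolutionary distances from an alignment.

    Nucleotide/codon alignments support ``p-distance`` and ``JC69``
    (d = -3/4 ln(1 - 4p/3)); protein alignments support ``p-distance``
    and ``Poisson`` (d = -ln(1 - p)).  Under pairwise deletion each pair
    skips only its own gap columns; otherwise columns containing any gap
    are excluded globally.  Entries past the model's saturation point
    (p >= 0.75 for JC69, p >= 1 for Poisson) become +inf and are flagged.
    """
    valid = _PROT_MODELS if aln.kind == "protein" else _NT_MODELS
    if model not in valid:
        raise PhyloError(f"model {model!r} not valid for {aln.kind} alignments")
    if len(aln.rows) < 3:
        raise PhyloError("need at least three rows for a distance matrix")
    labels = [rid for rid, _ in aln.rows]
    rows = [seq for _, seq in aln.rows]
    use_cols = None
    if not pairwise_deletion:
        use_cols = [
            c for c in range(len(rows[0])) if all(r[c] != GAP for r in rows)
        ]
    n = len(rows)
    mat = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p(rows, i, j, use_cols)
            if p is None:
                raise PhyloError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            if model == "p-distance":
                d = p
            elif model == "JC69":
                if p >= 0.75:
                    d = math.inf
                else:
                    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            else:  # Poisson
                if p >= 1.0:
                    d = math.inf
                else:
                    d = -math.log(1.0 - p)
            if math.isinf(d):
                saturated.append((labels[i], labels[j]))
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, matrix=mat, saturated=saturated)


# ------------------------------------------------------------------ #
# trees                                                              #
# ------------------------------------------------------------------ #

class TreeNode:
    """Tree node; ``children`` is a list of (child, branch_length)."""

    __slots__ = ("label", "children", "support")

    def __init__(self, label=None, children=None, support=None):
        self.label = label
        self.children: list[tuple["TreeNode", float]] = children or []
        self.support: float | None = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset:
        if self.is_leaf():
            return frozenset([self.label])
        out = frozenset()
        for child, _ in self.children:
            out |= child.leaf_labels()
        return out


@dataclass
class PhyloTree:
    root: TreeNode
    negative_clamped: list[str] = field(default_factory=list)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.root.leaf_labels())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the side excluding a reference leaf."""
        all_leaves = self.root.leaf_labels()
        ref = min(all_leaves)
        out = set()

        def visit(node: TreeNode):
            for child, _ in node.children:
                if not child.is_leaf():
                    side = child.leaf_labels()
                    canon = side if ref not in side else all_leaves - side
                    if 2 <= len(canon) <= len(all_leaves) - 2:
                        out.add(canon)
                    visit(child)

        visit(self.root)
        return out

    def bipartition_lengths(self) -> dict[frozenset, float]:
        all_leaves = self.root.leaf_labels()
        ref = min(all_leaves)
        out: dict[frozenset, float] = {}

        def visit(node: TreeNode):
            for child, length in node.children:
                if not child.is_leaf():
                    side = child.leaf_labels()
                    canon = side if ref not in side else all_leaves - side
                    if 2 <= len(canon) <= len(all_leaves) - 2:
                        out[canon] = length
                    visit(child)

        visit(self.root)
        return out

    def pendant_lengths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def visit(node: TreeNode):
            for child, length in node.children:
                if child.is_leaf():
                    out[child.label] = length
                else:
                    visit(child)

        visit(self.root)
        return out

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf distances along the tree (the induced metric)."""
        labels = self.leaves
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        mat = np.zeros((n, n))

        def visit(node: TreeNode) -> dict[int, float]:
            if node.is_leaf():
                return {index[node.label]: 0.0}
            below: dict[int, float] = {}
            groups = []
            for child, length in node.children:
                sub = {k: v + length for k, v in visit(child).items()}
                groups.append(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for li, di in groups[gi].items():
                        for lj, dj in groups[gj].items():
                            mat[li, lj] = mat[lj, li] = di + dj
            for g in groups:
                below.update(g)
            return below

        visit(self.root)
        return DistanceMatrix(labels=labels, matrix=mat)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance (symmetric bipartition difference)."""
    if set(t1.leaves) != set(t2.leaves):
        raise PhyloError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


# ------------------------------------------------------------------ #
# neighbor joining                                                   #
# ------------------------------------------------------------------ #

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Q criterion.

    Ties on Q are broken toward the smallest (i, j) pair in the current
    working order (joined clusters are appended at the end).  Negative
    branch-length estimates are clamped to zero and recorded on the tree.
    """
    if dm.n < 3:
        raise PhyloError("neighbor joining needs at least three taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise SaturationError(
            f"distance matrix contains saturated entries: {dm.saturated}"
        )
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    d = dm.matrix.astype(float).copy()
    clamped: list[str] = []

    def clamp(x: float, node: TreeNode) -> float:
        if x < 0:
            clamped.append(_node_desc(node))
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li = clamp(li, nodes[i])
        lj = clamp(lj, nodes[j])
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_next = np.zeros((n - 1, n - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = new_d[keep]
        d_next[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d_next

    # final three-way join (star resolution of the last three clusters)
    a = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    c = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(
        children=[
            (nodes[0], clamp(a, nodes[0])),
            (nodes[1], clamp(b, nodes[1])),
            (nodes[2], clamp(c, nodes[2])),
        ]
    )
    return PhyloTree(root=root, negative_clamped=clamped)


def _node_desc(node: TreeNode) -> str:
    labels = sorted(node.leaf_labels())
    return labels[0] if len(labels) == 1 else "{" + ",".join(labels) + "}"


# ------------------------------------------------------------------ #
# bootstrap                                                          #
# ------------------------------------------------------------------ #

def bootstrap_support(
    aln,
    n_reps: int,
    model: str = "p-distance",
    seed: int | None = None,
    pairwise_deletion: bool = True,
) -> PhyloTree:
    """NJ tree with bootstrap supports on its internal edges.

    Alignment columns are resampled with replacement (codon alignments
    resample whole codon triples); one NJ tree is built per replicate and
    each internal bipartition of the point-estimate tree receives the
    percentage of replicates containing it.  Replicates with saturated
    distances are dropped and the denominator adjusted.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    if seed is None:
        raise PhyloError("bootstrap requires an explicit seed")
    point_dm = distance_matrix(aln, model=model, pairwise_deletion=pairwise_deletion)
    point = nj_tree(point_dm)
    rng = np.random.default_rng(seed)
    ncol = aln.column_count
    codon = aln.kind == "codon"
    nunits = ncol // 3 if codon else ncol
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    valid = 0
    for _ in range(n_reps):
        units = rng.integers(0, nunits, size=nunits)
        if codon:
            cols = [3 * u + k for u in units for k in range(3)]
        else:
            cols = list(units)
        rows = [
            (rid, "".join(seq[c] for c in cols)) for rid, seq in aln.rows
        ]
        rep_aln = _RowsView(rows=rows, kind=aln.kind)
        try:
            rep_dm = distance_matrix(
                rep_aln, model=model, pairwise_deletion=pairwise_deletion
            )
            rep_tree = nj_tree(rep_dm)
        except (SaturationError, PhyloError):
            continue
        valid += 1
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    if valid == 0:
        raise SaturationError("every bootstrap replicate was saturated")
    all_leaves = point.root.leaf_labels()
    ref = min(all_leaves)

    def annotate(node: TreeNode):
        for child, _ in node.children:
            if not child.is_leaf():
                side = child.leaf_labels()
                canon = side if ref not in side else all_leaves - side
                if canon in counts:
                    child.support = 100.0 * counts[canon] / valid
                annotate(child)

    annotate(point.root)
    return point


@dataclass
class _RowsView:
    """Duck-typed minimal alignment (rows + kind) for bootstrap replicates."""

    rows: list[tuple[str, str]]
    kind: str

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])


# ------------------------------------------------------------------ #
# Newick I/O                                                         #
# ------------------------------------------------------------------ #

_SAFE_LABEL = re.compile(r"^[^\s()\[\]{}:;,']+$")


def _format_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(x: float) -> str:
    return format(x, ".10g")


def to_newick(tree: PhyloTree, include_support: bool = True) -> str:
    """Serialize with branch lengths; supports become internal node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return _format_label(str(node.label))
        inner = ",".join(
            f"{fmt(child)}:{_format_length(length)}" for child, length in node.children
        )
        sup = ""
        if include_support and node.support is not None:
            sup = _format_label(_format_length(node.support))
        return f"({inner}){sup}"

    return fmt(tree.root) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse Newick; numeric internal labels are read as bootstrap supports."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at position {pos}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open at end of input"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(str(exc)) from exc

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return TreeNode(label=label)
        node = TreeNode(
            children=[
                (convert(ch), ch.edge.length if ch.edge.length is not None else 0.0)
                for ch in dnode.child_nodes()
            ]
        )
        if dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                pass
        return node

    return PhyloTree(root=convert(dtree.seed_node))


def write_newick(tree: PhyloTree, path, include_support: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, include_support=include_support) + "\n")


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())
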