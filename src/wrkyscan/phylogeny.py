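"""Distance phylogenetics for WRKY-domain placement.

The pipeline aligns short (~60 aa) WRKY domains by pinning the invariant
heptapeptide anchor to a common column, computes Poisson-corrected
p-distances with pairwise deletion, and builds neighbor-joining trees with
optional column-resampling bootstrap.  Everything here is implemented
in-repo; newick text is the only exchange format.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .scanner import CANONICAL_VARIANTS, EXTENDED_VARIANTS, find_heptapeptides
from .seq_io import ProteinRecord

logger = logging.getLogger(__name__)

GAP = "-"


class AlignmentError(ValueError):
    pass


class DistanceError(ValueError):
    pass


class NewickError(ValueError):
    pass


# ---------------------------------------------------------------------------
# anchored alignment
# ---------------------------------------------------------------------------

@dataclass
class DomainAlignment:
    """Equal-length gapped rows sharing the heptapeptide anchor column."""

    ids: list[str]
    rows: list[str]
    anchor_col: int

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise AlignmentError("rows have unequal lengths")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def align_domains(
    records: Sequence[ProteinRecord],
    variants: Sequence[str] = EXTENDED_VARIANTS,
    trim: bool = False,
) -> DomainAlignment:
    """Anchor-pinned alignment of WRKY-domain records.

    Each record must contain exactly one heptapeptide anchor; rows are
    shifted so all anchors share one column, with terminal gaps padding the
    flanks.  With ``trim=True`` columns outside the span covered by every
    row are removed.
    """
    offsets: list[int] = []
    for rec in records:
        anchors = find_heptapeptides(rec, variants)
        if len(anchors) == 0:
            raise AlignmentError(f"record {rec.id!r} has no WRKY anchor")
        if len(anchors) > 1:
            raise AlignmentError(
                f"record {rec.id!r} has {len(anchors)} anchors; "
                "split multi-domain proteins first"
            )
        offsets.append(anchors[0].start)
    anchor_col = max(offsets, default=0)
    padded: list[str] = []
    for rec, off in zip(records, offsets):
        row = GAP * (anchor_col - off) + rec.sequence
        padded.append(row)
    width = max((len(r) for r in padded), default=0)
    rows = [r + GAP * (width - len(r)) for r in padded]
    aln = DomainAlignment([r.id for r in records], rows, anchor_col)
    if trim and len(aln):
        arr = np.array([list(r) for r in aln.rows])
        covered = (arr != GAP).all(axis=0)
        if covered.any():
            idx = np.where(covered)[0]
            lo, hi = idx[0], idx[-1] + 1
            aln = DomainAlignment(
                aln.ids, ["".join(r) for r in arr[:, lo:hi]], anchor_col - lo
            )
    return aln


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites under pairwise deletion.

    Only columns where both rows are non-gap count; zero overlapping columns
    is an error (undefined distance).
    """
    both = [(a, b) for a, b in zip(row_a, row_b) if a != GAP and b != GAP]
    if not both:
        raise DistanceError("no overlapping non-gap columns")
    diff = sum(a != b for a, b in both)
    return diff / len(both)


def poisson_correct(p):
    """Poisson-corrected distance d = -ln(1 - p), elementwise.

    Valid for 0 <= p < 1; p >= 1 is a saturation error (all sites differ,
    infinite estimated distance).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise DistanceError("p must satisfy 0 <= p < 1 (saturated distance)")
    out = -np.log1p(-arr)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise DistanceError("matrix shape does not match labels")
        if np.abs(m - m.T).max(initial=0.0) > 1e-12:
            raise DistanceError("matrix not symmetric")
        if np.abs(np.diag(m)).max(initial=0.0) > 0:
            raise DistanceError("nonzero diagonal")
        if (m < 0).any():
            raise DistanceError("negative distances")
        self.matrix = m

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


def distance_matrix(
    aln: DomainAlignment, correction: str = "poisson"
) -> DistanceMatrix:
    """All-pairs distances from an alignment (pairwise deletion).

    ``correction`` is ``"poisson"`` (default) or ``"p"`` for the raw
    proportion of differing sites.
    """
    if correction not in ("poisson", "p"):
        raise ValueError(f"unknown correction {correction!r}")
    arr = np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype="S1"
    ).reshape(len(aln), aln.n_cols)
    nongap = arr != GAP.encode()
    # pairwise overlap and mismatch counts via broadcasting
    both = nongap[:, None, :] & nongap[None, :, :]
    overlap = both.sum(axis=2)
    if (overlap == 0).any():
        i, j = np.argwhere(overlap == 0)[0]
        raise DistanceError(
            f"rows {aln.ids[i]!r} and {aln.ids[j]!r} share no non-gap columns"
        )
    mism = ((arr[:, None, :] != arr[None, :, :]) & both).sum(axis=2)
    p = mism / overlap
    d = poisson_correct(p) if correction == "poisson" else p
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(aln.ids), d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at an arbitrary (usually trifurcating) node."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Nontrivial bipartitions induced by internal edges."""
        all_leaves = self.leaf_set()
        n = len(all_leaves)
        parts: set[frozenset[frozenset[str]]] = set()
        sides = self._clade_sets()
        for node, side in sides.items():
            if node is self.root:
                continue
            if 1 < len(side) < n - 1:
                parts.add(frozenset({side, all_leaves - side}))
        return parts

    def _clade_sets(self) -> dict["TreeNode", frozenset[str]]:
        """Map node -> leaf set below it."""
        out: dict[TreeNode, frozenset[str]] = {}

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                s = frozenset({node.name})
            else:
                s = frozenset().union(*(walk(ch) for ch in node.children))
            out[node] = s
            return s

        walk(self.root)
        return out

    def clade_leafsets(self) -> dict["TreeNode", frozenset[str]]:
        return self._clade_sets()

    def to_newick(self, *, decimals: int = 10) -> str:
        return write_newick(self, decimals=decimals)


def is_monophyletic(tree: PhyloTree, labels: Iterable[str]) -> bool:
    """Whether ``labels`` form a connected subtree of the unrooted tree.

    True iff some edge separates exactly that leaf set, or the set is
    trivial (empty, singleton, or all leaves).
    """
    want = frozenset(labels)
    all_leaves = tree.leaf_set()
    if not want <= all_leaves:
        raise ValueError("labels not all present in tree")
    if len(want) <= 1 or want == all_leaves:
        return True
    if len(want) == len(all_leaves) - 1:
        return True  # complement is a single leaf: always an edge
    target = frozenset({want, all_leaves - want})
    return target in tree.bipartitions()


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined; exact Q ties
    are broken by the lexicographically lowest (sorted) label pair.  Negative
    branch-length estimates are clamped to zero (deficit logged at DEBUG).
    The returned tree is rooted at the final trifurcation.
    """
    n = len(dm.labels)
    if n < 3:
        raise DistanceError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name=lb) for lb in dm.labels]
    # sort key for tie-breaks: the smallest leaf label under each node
    keys: list[str] = list(dm.labels)

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamped negative branch length %.6g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        pairs = {tuple(sorted((int(i), int(j)))) for i, j in ties}
        i, j = min(pairs, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = clamp(li), clamp(lj)
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # resolve the final three around a central node
    (a, b, c) = nodes
    da = clamp(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    db = clamp(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    dc = clamp(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    a.length, b.length, c.length = da, db, dc
    order = sorted(range(3), key=lambda k: keys[k])
    root = TreeNode(children=[nodes[k] for k in order])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: DomainAlignment,
    n_reps: int = 1000,
    seed: int | None = None,
    correction: str = "poisson",
) -> PhyloTree:
    """Point-estimate NJ tree with column-resampling bootstrap supports.

    Columns are resampled with replacement (equal weights); the support of
    each internal edge of the point tree is the percentage of replicate
    trees containing the same bipartition.  ``seed`` is mandatory for
    reproducibility.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap")
    rng = np.random.default_rng(seed)
    point = neighbor_joining(distance_matrix(aln, correction))
    target = point.bipartitions()
    if not target:
        return point
    counts = {bp: 0 for bp in target}
    cols = np.array([list(r) for r in aln.rows])
    n_cols = cols.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row) for row in cols[:, idx]]
        rep = DomainAlignment(list(aln.ids), rep_rows, 0)
        try:
            rep_tree = neighbor_joining(distance_matrix(rep, correction))
        except DistanceError:
            continue  # saturated or gap-only resample
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    clades = point.clade_leafsets()
    all_leaves = point.leaf_set()
    for node, side in clades.items():
        if node is point.root or node.is_leaf:
            continue
        bp = frozenset({side, all_leaves - side})
        if bp in supports:
            node.support = supports[bp]
    return point


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def _fmt_len(x: float, decimals: int) -> str:
    s = f"{x:.{decimals}f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_newick(tree: PhyloTree, *, decimals: int = 10) -> str:
    """Serialize; bootstrap supports become internal node labels."""

    def render(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(render(ch, False) for ch in node.children)
            label = "" if node.support is None else _fmt_len(node.support, 4)
            body = f"({inner}){label}"
        if top:
            return body
        return f"{body}:{_fmt_len(node.length, decimals)}"

    return render(tree.root, True) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse newick text; internal node labels are read as supports when
    numeric.  Malformed input raises :class:`NewickError` with the offset."""
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError(f"missing terminal ';' at offset {len(s)}")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} at offset {pos}")

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            name = parse_label()
            if not name:
                raise error("empty leaf label")
            node.name = name
        if pos < len(s) and s[pos] == ":":
            pos += 1
            tok = parse_label()
            try:
                node.length = float(tok)
            except ValueError:
                raise error(f"bad branch length {tok!r}")
        return node

    root = parse_node()
    if pos != len(s):
        raise NewickError(f"trailing characters at offset {pos}")
    return PhyloTree(root)
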