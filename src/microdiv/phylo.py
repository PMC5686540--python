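"""Phylogenetic tree container with jplace-style edge numbering.

The reference trees used for read placement need three things the standard
containers do not provide together: stable integer edge numbers serialized
inside the Newick string (``...{17}`` as in the jplace exchange format),
deterministic canonical child ordering, and direct access to per-edge
conditional likelihood workspaces.  The container here is deliberately
minimal; scikit-bio / dendropy remain the cross-check in the test suite.

The substitution model used throughout (distances, placement likelihoods) is
the 20-state Poisson model with equal exchangeabilities and uniform
stationary frequencies; branch lengths are expected substitutions per site.
"""

from __future__ import annotations

import io
from typing import Iterator

import numpy as np

__all__ = [
    "Node",
    "parse_newick",
    "neighbor_joining",
    "p_same",
    "p_diff",
    "poisson_correct",
]

N_STATES = 20


# ---------------------------------------------------------------------------
# substitution model (Poisson / "proteinogenic Jukes-Cantor")
# ---------------------------------------------------------------------------

def p_same(t, k: int = N_STATES):
    """Probability a site shows the same residue after branch length ``t``."""
    t = np.asarray(t, dtype=float)
    return 1.0 / k + (k - 1.0) / k * np.exp(-k / (k - 1.0) * t)


def p_diff(t, k: int = N_STATES):
    """Probability of one specific different residue after branch length ``t``."""
    t = np.asarray(t, dtype=float)
    return 1.0 / k * (1.0 - np.exp(-k / (k - 1.0) * t))


def poisson_correct(p, k: int = N_STATES, max_dist: float = 10.0):
    """Maximum-likelihood distance from observed proportion of differences ``p``.

    d = -(k-1)/k * log(1 - p*k/(k-1)); saturated comparisons are capped at
    ``max_dist``.
    """
    p = np.asarray(p, dtype=float)
    arg = 1.0 - p * k / (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -(k - 1.0) / k * np.log(arg)
    d = np.where(arg <= 0, max_dist, d)
    return np.minimum(np.maximum(d, 0.0), max_dist)


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------

class Node:
    """A rooted tree node.  Unrooted trees are held rooted at a trifurcation."""

    __slots__ = ("name", "length", "children", "parent", "edge_num")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)  # length of the edge to the parent
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.edge_num: int | None = None

    # -- construction -----------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    # -- traversal --------------------------------------------------------
    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if not n.children]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    # -- canonical form and edge numbering --------------------------------
    def _min_leaf(self) -> str:
        if self.is_leaf:
            return self.name or ""
        return min(c._min_leaf() for c in self.children)

    def canonicalize(self) -> "Node":
        """Sort children everywhere by smallest descendant leaf name."""
        for node in self.postorder():
            node.children.sort(key=lambda c: c._min_leaf())
        return self

    def number_edges(self) -> "Node":
        """Assign consecutive edge numbers 0..E-1 by preorder over the
        canonical child ordering.  The root carries no edge (``None``)."""
        self.canonicalize()
        counter = 0
        for node in self.preorder():
            if node.parent is None:
                node.edge_num = None
            else:
                node.edge_num = counter
                counter += 1
        return self

    def edges(self) -> list["Node"]:
        """Non-root nodes, i.e. one per edge, ordered by edge number when set."""
        out = [n for n in self.preorder() if n.parent is not None]
        if all(n.edge_num is not None for n in out):
            out.sort(key=lambda n: n.edge_num)
        return out

    def n_edges(self) -> int:
        return sum(1 for n in self.preorder() if n.parent is not None)

    # -- copy --------------------------------------------------------------
    def copy(self) -> "Node":
        new = Node(self.name, self.length)
        new.edge_num = self.edge_num
        for c in self.children:
            new.add_child(c.copy())
        return new

    # -- serialization -----------------------------------------------------
    def to_newick(self, edge_numbers: bool = False) -> str:
        buf = io.StringIO()
        self._write(buf, edge_numbers)
        buf.write(";")
        return buf.getvalue()

    def _write(self, buf, edge_numbers: bool) -> None:
        if self.children:
            buf.write("(")
            for i, c in enumerate(self.children):
                if i:
                    buf.write(",")
                c._write(buf, edge_numbers)
            buf.write(")")
            if self.name:
                buf.write(self.name)
        else:
            buf.write(self.name or "")
        if self.parent is not None:
            buf.write(":" + format(self.length, ".12g"))
            if edge_numbers and self.edge_num is not None:
                buf.write("{%d}" % self.edge_num)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or '*'} len={self.length:.4g} edge={self.edge_num}>"


def parse_newick(text: str) -> Node:
    """Parse a Newick string, including jplace-style ``{edge}`` annotations."""
    text = text.strip()
    if text.endswith(";"):
        text = text[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        # name
        start = pos
        while pos < len(text) and text[pos] not in ":,(){};":
            pos += 1
        if pos > start:
            node.name = text[start:pos]
        # branch length
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",(){};":
                pos += 1
            node.length = float(text[start:pos])
        # edge number
        if pos < len(text) and text[pos] == "{":
            end = text.index("}", pos)
            node.edge_num = int(text[pos + 1 : end])
            pos = end + 1
        return node

    root = parse_node()
    if pos != len(text):
        raise ValueError(f"trailing characters in newick at offset {pos}")
    return root


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: np.ndarray, labels: list[str]) -> Node:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break to the smallest ``(i, j)`` index pair
    (row-major argmin).  Negative branch-length estimates are clamped to
    zero with the deficit moved to the sister branch so the joined pair
    keeps its observed distance.  Returns an unrooted tree represented as a
    trifurcating root, with edge numbers assigned.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise ValueError("distance matrix is not symmetric (tolerance 1e-9)")
    D = 0.5 * (D + D.T)

    nodes = [Node(name=l) for l in labels]
    active = list(range(n))
    D = D.copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major => smallest (i, j) on ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes at a trifurcating root (three-point formulas)
    a, b, c = active
    root = Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.add_child(nodes[idx])
    root.number_edges()
    return root


# ---------------------------------------------------------------------------
# generic distances on trees
# ---------------------------------------------------------------------------

def leaf_distance_matrix(root: Node) -> tuple[np.ndarray, list[str]]:
    """Patristic (path-length) distances between all leaves."""
    leaves = root.leaves()
    names = [l.name for l in leaves]
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    def collect(node: Node) -> dict[int, float]:
        if node.is_leaf:
            return {index[id(node)]: 0.0}
        merged: dict[int, float] = {}
        child_maps = []
        for c in node.children:
            cm = {k: v + c.length for k, v in collect(c).items()}
            child_maps.append(cm)
        for x in range(len(child_maps)):
            for y in range(x + 1, len(child_maps)):
                for ki, di in child_maps[x].items():
                    for kj, dj in child_maps[y].items():
                        D[ki, kj] = D[kj, ki] = di + dj
        for cm in child_maps:
            merged.update(cm)
        return merged

    collect(root)
    return D, names
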