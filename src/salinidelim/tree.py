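"""Minimal rooted/unrooted phylogenetic tree with Newick I/O.

Support values are stored (and serialized) as internal-node labels, the most
portable Newick dialect.  Unrooted trees are represented with a trifurcating
(or higher-degree) root placeholder.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional


class TreeError(ValueError):
    pass


class Node:
    """A tree node. Leaves carry a ``name``; internal nodes may carry a
    bootstrap ``support`` in [0, 100]."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.support: Optional[float] = None
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or '*'} len={self.length}>"


class PhyloTree:
    """Tree rooted at ``root``; branch lengths live on child edges."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ walk
    def traverse(self, order: str = "preorder") -> Iterator[Node]:
        def _pre(n: Node) -> Iterator[Node]:
            yield n
            for c in n.children:
                yield from _pre(c)

        def _post(n: Node) -> Iterator[Node]:
            for c in n.children:
                yield from _post(c)
            yield n

        yield from (_pre if order == "preorder" else _post)(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.traverse() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        names = [n.name for n in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise TreeError("tree has unnamed leaves")
        return names  # type: ignore[return-value]

    def copy(self) -> "PhyloTree":
        def _cp(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support = n.support
            for c in n.children:
                m.add(_cp(c))
            return m

        return PhyloTree(_cp(self.root))

    # ------------------------------------------------------------- distances
    def leaf_distances(self) -> tuple[list[str], dict[tuple[str, str], float]]:
        """All pairwise leaf-to-leaf path lengths (unordered pairs)."""
        names = sorted(self.leaf_names())
        # distance from every node down to each descendant leaf
        down: dict[int, dict[str, float]] = {}
        for n in self.traverse("postorder"):
            if n.is_leaf:
                down[id(n)] = {n.name: 0.0}  # type: ignore[dict-item]
            else:
                d: dict[str, float] = {}
                for c in n.children:
                    bl = c.length or 0.0
                    for leaf, dist in down[id(c)].items():
                        d[leaf] = dist + bl
                down[id(n)] = d
        dist: dict[tuple[str, str], float] = {}
        for n in self.traverse("postorder"):
            kids = n.children
            for c1, c2 in itertools.combinations(kids, 2):
                for l1, d1 in down[id(c1)].items():
                    for l2, d2 in down[id(c2)].items():
                        key = (l1, l2) if l1 < l2 else (l2, l1)
                        dist[key] = d1 + (c1.length or 0.0) + d2 + (c2.length or 0.0)
        return names, dist

    # ---------------------------------------------------------------- splits
    def bipartitions(self, trivial: bool = False) -> set[frozenset[str]]:
        """Non-trivial bipartitions as canonical frozensets of leaf names.

        Canonical side = the side NOT containing the lexicographically
        smallest leaf, so rootings do not change the set.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.traverse("postorder"):
            if n.is_leaf:
                below[id(n)] = frozenset([n.name])  # type: ignore[list-item]
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
        for n in self.traverse("postorder"):
            if n is self.root:
                continue
            side = below[id(n)]
            if not trivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            if anchor in side:
                side = all_leaves - side
            splits.add(side)
        return splits

    def robinson_foulds(self, other: "PhyloTree") -> int:
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise TreeError("leaf sets differ; RF undefined")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    # --------------------------------------------------------------- rooting
    def midpoint_root(self) -> "PhyloTree":
        """Root at the midpoint of the longest leaf-leaf path.

        Ties on path length are broken by the lexicographically smallest
        (leaf, leaf) pair.  Zero-length trees are rooted at the first
        internal node.
        """
        t = self.copy()
        names, dist = t.leaf_distances()
        if len(names) < 2:
            return t
        # deterministic tie-break: among max-distance pairs, smallest pair
        dmax = max(dist.values())
        pair = min(k for k, v in dist.items() if v == dmax)
        if dmax <= 0:
            return t
        a, _b = pair
        # walk from leaf a toward b, placing root at dmax/2 from a
        leafmap = {n.name: n for n in t.leaves()}
        path = _path_nodes(leafmap[pair[0]], leafmap[pair[1]])
        target = dmax / 2.0
        acc = 0.0
        for child, _par, direction in path:
            bl = child.length or 0.0
            if acc + bl >= target - 1e-12:
                along = target - acc  # distance into the edge, in walk order
                dist_from_child = along if direction == "up" else bl - along
                return _reroot_on_edge(t, child, dist_from_child)
            acc += bl
        return t  # pragma: no cover - numeric guard

    def __str__(self) -> str:
        return to_newick(self)


def _path_nodes(a: Node, b: Node) -> list[tuple[Node, Node, str]]:
    """Edges (child, parent, direction) along the a→b path in walk order;
    direction is 'up' (child → parent) before the LCA, 'down' after."""
    anc_a = []
    n: Optional[Node] = a
    while n is not None:
        anc_a.append(n)
        n = n.parent
    anc_set = {id(x) for x in anc_a}
    up_b = []
    n = b
    while id(n) not in anc_set:
        up_b.append(n)
        n = n.parent  # type: ignore[assignment]
    lca = n
    edges: list[tuple[Node, Node, str]] = []
    for x in anc_a:
        if x is lca:
            break
        edges.append((x, x.parent, "up"))  # type: ignore[arg-type]
    for x in reversed(up_b):
        edges.append((x, x.parent, "down"))  # type: ignore[arg-type]
    return edges


def _reroot_on_edge(t: PhyloTree, child: Node, dist_from_child: float) -> PhyloTree:
    """New root on the edge above ``child``, ``dist_from_child`` up from it."""
    bl = child.length or 0.0
    dist_from_child = min(max(dist_from_child, 0.0), bl)
    old_parent = child.parent
    assert old_parent is not None
    new_root = Node()
    old_parent.children.remove(child)
    child.parent = None
    # flip parent pointers from old_parent up to old root
    chain: list[Node] = []
    n: Optional[Node] = old_parent
    while n is not None:
        chain.append(n)
        n = n.parent
    lengths = [x.length for x in chain]
    for i in range(len(chain) - 1):
        lower, upper = chain[i], chain[i + 1]
        upper.children.remove(lower)
        lower.add(upper)
        upper.length = lengths[i]
    new_root.add(child)
    child.length = dist_from_child
    new_root.add(old_parent)
    old_parent.length = bl - dist_from_child
    # suppress single-child internal nodes left along the flipped chain
    for node in chain:
        if len(node.children) == 1 and node.parent is not None:
            only = node.children[0]
            gp = node.parent
            gp.children.remove(node)
            only.length = (only.length or 0.0) + (node.length or 0.0)
            only.parent = None
            gp.add(only)
    return PhyloTree(new_root)


# ---------------------------------------------------------------- Newick I/O

def to_newick(tree: PhyloTree, decimals: int = 6) -> str:
    def fmt_len(x: Optional[float]) -> str:
        if x is None:
            return ""
        return f":{round(x, decimals):g}"

    def rec(n: Node) -> str:
        if n.is_leaf:
            if not n.name:
                raise TreeError("unnamed leaf cannot be serialized")
            return f"{n.name}{fmt_len(n.length)}"
        inner = ",".join(rec(c) for c in n.children)
        label = ""
        if n.support is not None:
            label = f"{n.support:g}"
        elif n.name:
            label = n.name
        return f"({inner}){label}{fmt_len(n.length)}"

    return rec(tree.root) + ";"


def from_newick(text: str) -> PhyloTree:
    """Parse a Newick string; bare internal labels are read as supports when
    numeric, otherwise kept as names."""
    s = text.strip()
    if not s.endswith(";"):
        raise TreeError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.add(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.add(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise TreeError("unbalanced parentheses in newick")
            pos += 1
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise TreeError(f"trailing characters in newick at offset {pos}")
    return PhyloTree(root)


def is_ultrametric(tree: PhyloTree, tol: float = 1e-9) -> bool:
    depths = []

    def rec(n: Node, d: float) -> None:
        d += n.length or 0.0
        if n.is_leaf:
            depths.append(d)
        for c in n.children:
            rec(c, d)

    rec(tree.root, 0.0)
    return max(depths) - min(depths) <= tol * max(1.0, max(depths)) + 1e-12


def cherry(a: str, b: str, la: float = 1.0, lb: float = 1.0) -> PhyloTree:
    r = Node()
    r.add(Node(a, la))
    r.add(Node(b, lb))
    return PhyloTree(r)
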