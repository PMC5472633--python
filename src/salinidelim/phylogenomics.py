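"""Distance-based tree inference and gene-tree/species-tree congruence.

JC69 distances + neighbor joining with column bootstrap stand in for
likelihood inference; all congruence operations are engine-agnostic and also
accept externally computed Newick trees.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_core import AlignmentBlock, SequenceRecord
from .tree import Node, PhyloTree

D_MAX = 5.0


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise PhyloError("distance matrix diagonal not zero")
        if (self.d < 0).any():
            raise PhyloError("negative distances")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass
class CongruenceResult:
    gene_id: str
    monophyly: dict[str, bool]
    incongruent: bool
    offending_strains: list[str]


# ------------------------------------------------------------------ distances

def _comparable(arr: np.ndarray) -> np.ndarray:
    return (arr != b"-") & (arr != b"N")


def jc69_distances(aln: AlignmentBlock) -> DistanceMatrix:
    """Pairwise-deletion p-distances mapped through the JC69 correction;
    saturated pairs (p >= 0.75) are capped at D_MAX with a warning."""
    arr = aln.to_array()
    ok = _comparable(arr)
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            m = int(shared.sum())
            if m == 0:
                raise PhyloError(
                    f"no comparable sites between {aln.records[i].id} and {aln.records[j].id}")
            p = float((arr[i, shared] != arr[j, shared]).sum()) / m
            if p >= 0.75:
                warnings.warn("saturated pair capped at d=5.0", stacklevel=2)
                dist = D_MAX
            else:
                dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(aln.ids), d)


def strip_unclean_columns(aln: AlignmentBlock) -> AlignmentBlock:
    """Drop columns containing any gap or N (simple quality trimming)."""
    arr = aln.to_array()
    keep = _comparable(arr).all(axis=0)
    return AlignmentBlock(tuple(
        SequenceRecord(r.id, arr[i, keep].tobytes().decode("ascii"))
        for i, r in enumerate(aln.records)
    ))


# ------------------------------------------------------------ neighbor joining

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Q-criterion ties break on the lexicographically smallest (label, label)
    pair (cluster label = smallest leaf inside); negative branch lengths are
    clamped to zero with the excess moved to the sister branch.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise PhyloError("need >= 2 taxa")
    nodes: list[Node] = [Node(lbl) for lbl in labels]
    reps = list(labels)  # smallest leaf label under each active node
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: Optional[tuple[float, str, str, int, int]] = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                pa, pb = reps[active[ai]], reps[active[aj]]
                key_pair = (pa, pb) if pa < pb else (pb, pa)
                cand = (q, key_pair[0], key_pair[1], ai, aj)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, ai, aj = best  # type: ignore[misc]
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        new = Node()
        a_node, b_node = nodes[i], nodes[j]
        a_node.length, b_node.length = float(li), float(lj)
        new.add(a_node)
        new.add(b_node)
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        # distances to the new node
        newrow = np.zeros(len(nodes))
        for bk in range(m):
            kidx = active[bk]
            if kidx in (i, j):
                continue
            newrow[kidx] = 0.5 * (d[i, kidx] + d[j, kidx] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(newrow)] = newrow
        d[: len(newrow), -1] = newrow
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    root = Node()
    if len(active) == 2:
        i, j = active
        dij = float(d[i, j])
        a_node, b_node = nodes[i], nodes[j]
        if a_node.is_leaf and not b_node.is_leaf:
            # hang the leaf off the internal node's root (trifurcation)
            a_node.length = dij
            b_node.add(a_node)
            return PhyloTree(b_node)
        if b_node.is_leaf and not a_node.is_leaf:
            b_node.length = dij
            a_node.add(b_node)
            return PhyloTree(a_node)
        a_node.length = dij / 2
        b_node.length = dij / 2
        root.add(a_node)
        root.add(b_node)
        return PhyloTree(root)
    root.add(nodes[active[0]])
    return PhyloTree(root)


def tree_from_alignment(aln: AlignmentBlock) -> PhyloTree:
    return nj_tree(jc69_distances(aln))


# ------------------------------------------------------------------- bootstrap

def bootstrap_support(aln: AlignmentBlock, n_boot: int = 100, seed: int = 0) -> PhyloTree:
    """NJ tree from the full alignment, internal edges annotated with the
    percentage of column-resampled replicates containing the same
    bipartition."""
    if n_boot < 1:
        raise PhyloError("n_boot must be >= 1")
    ref = tree_from_alignment(aln)
    rng = np.random.default_rng(seed)
    arr = aln.to_array()
    ncol = arr.shape[1]
    counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        cols = rng.integers(0, ncol, size=ncol)
        rep = AlignmentBlock(tuple(
            SequenceRecord(r.id, arr[i, cols].tobytes().decode("ascii"))
            for i, r in enumerate(aln.records)
        ))
        for split in tree_from_alignment(rep).bipartitions():
            counts[split] = counts.get(split, 0) + 1
    below: dict[int, frozenset] = {}
    all_leaves = frozenset(ref.leaf_names())
    anchor = min(all_leaves)
    for node in ref.traverse("postorder"):
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is ref.root:
                continue
            side = below[id(node)]
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            canon = (all_leaves - side) if anchor in side else side
            node.support = 100.0 * counts.get(canon, 0) / n_boot
    return ref


# --------------------------------------------------------------- concatenation

def concatenate(
    alignments: Mapping[str, AlignmentBlock],
    gene_subset: Optional[Sequence[str]] = None,
) -> tuple[AlignmentBlock, dict[str, tuple[int, int]]]:
    """Column-wise concatenation in sorted gene-id order; returns the block
    and a gene → [start, end) column-range partition map."""
    genes = sorted(gene_subset) if gene_subset is not None else sorted(alignments)
    if not genes:
        raise PhyloError("empty gene subset")
    missing = [g for g in genes if g not in alignments]
    if missing:
        raise PhyloError(f"genes not found: {missing[:5]}")
    strain_sets = {g: frozenset(alignments[g].ids) for g in genes}
    ref = strain_sets[genes[0]]
    for g in genes:
        if strain_sets[g] != ref:
            raise PhyloError(
                f"strain-set mismatch in {g}: "
                f"missing {sorted(ref - strain_sets[g])}, extra {sorted(strain_sets[g] - ref)}")
    strains = sorted(ref)
    parts = {s: [] for s in strains}
    partition: dict[str, tuple[int, int]] = {}
    offset = 0
    for g in genes:
        by_id = {r.id: r.seq for r in alignments[g].records}
        for s in strains:
            parts[s].append(by_id[s])
        partition[g] = (offset, offset + alignments[g].length)
        offset += alignments[g].length
    block = AlignmentBlock(tuple(SequenceRecord(s, "".join(parts[s])) for s in strains))
    return block, partition


# ------------------------------------------------------------------ congruence

def species_monophyly(
    tree: PhyloTree,
    assignment: Mapping[str, str],
    gene_id: str = "",
) -> CongruenceResult:
    """Species-level congruence: a species is monophyletic iff its leaves form
    a bipartition of the unrooted tree (singletons and all-but-trivial sets by
    convention)."""
    leaves = set(tree.leaf_names())
    unassigned = leaves - set(assignment)
    if unassigned:
        raise PhyloError(f"strains without species assignment: {sorted(unassigned)[:5]}")
    anchor = min(leaves)
    splits = tree.bipartitions()
    species: dict[str, set[str]] = {}
    for s in leaves:
        species.setdefault(assignment[s], set()).add(s)
    mono: dict[str, bool] = {}
    offenders: list[str] = []
    for sp, members in sorted(species.items()):
        if len(members) <= 1 or len(members) >= len(leaves) - 1:
            mono[sp] = True
            continue
        canon = frozenset(leaves - members) if anchor in members else frozenset(members)
        mono[sp] = canon in splits
        if not mono[sp]:
            offenders.extend(_offending(tree, members))
    incongruent = not all(mono.values())
    return CongruenceResult(gene_id, mono, incongruent, sorted(set(offenders)))


def _offending(tree: PhyloTree, members: set[str]) -> list[str]:
    """Foreign strains inside the smallest rooted clade containing ``members``
    (computed on the midpoint-rooted tree)."""
    rooted = tree.midpoint_root()
    best: Optional[set[str]] = None
    below: dict[int, set[str]] = {}
    for n in rooted.traverse("postorder"):
        if n.is_leaf:
            below[id(n)] = {n.name}
        else:
            below[id(n)] = set().union(*(below[id(c)] for c in n.children))
        cl = below[id(n)]
        if members <= cl and (best is None or len(cl) < len(best)):
            best = cl
    assert best is not None
    return sorted(best - members)


def partition_tree_comparison(
    scc_tree: PhyloTree,
    recomb_tree: PhyloTree,
    mincore_tree: PhyloTree,
    assignment: Mapping[str, str],
) -> dict:
    """Per-tree species monophyly plus pairwise Robinson–Foulds distances."""
    trees = {"scc": scc_tree, "recombinant": recomb_tree, "minimum_core": mincore_tree}
    leafsets = {k: set(t.leaf_names()) for k, t in trees.items()}
    if len({frozenset(v) for v in leafsets.values()}) != 1:
        raise PhyloError("trees have different leaf sets")
    mono = {k: species_monophyly(t, assignment, k) for k, t in trees.items()}
    rf = {}
    for (ka, ta), (kb, tb) in itertools.combinations(trees.items(), 2):
        rf[f"{ka}__{kb}"] = ta.robinson_foulds(tb)
    return {
        "monophyly": {k: v.monophyly for k, v in mono.items()},
        "species_level_congruent": all(not v.incongruent for v in mono.values()),
        "rf": rf,
    }
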