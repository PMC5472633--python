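"""16S-like marker analysis and binary-trait clustering.

Covers SNP counting between marker sequences, the SNP-vs-ANI regression
(including the SNP count at which the fitted line crosses 95% ANI), Jaccard
average-linkage clustering of presence/absence trait tables, and adjusted-
Rand agreement between strain partitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .ani import ANIResult, upgma
from .phylogenomics import DistanceMatrix
from .tree import PhyloTree

AMBIGUOUS = frozenset("N-")


class MarkerError(ValueError):
    pass


@dataclass
class MarkerSet:
    sequences: dict[str, str]   # strain -> one representative marker

    @classmethod
    def from_copies(cls, copies: Mapping[str, Sequence[str]]) -> "MarkerSet":
        """One representative per strain; heterogeneous copies are an error."""
        reps = {}
        for strain, seqs in copies.items():
            if not seqs:
                raise MarkerError(f"strain {strain} has no marker copies")
            if len(set(seqs)) != 1:
                raise MarkerError(f"strain {strain} has heterogeneous marker copies")
            reps[strain] = seqs[0]
        return cls(reps)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    x_at_ani95: float


def snp_count(seq_a: str, seq_b: str) -> int:
    """Differing unambiguous positions; gaps and Ns are skipped."""
    if len(seq_a) != len(seq_b):
        raise MarkerError("marker sequences have different lengths")
    return sum(
        1 for a, b in zip(seq_a, seq_b)
        if a != b and a not in AMBIGUOUS and b not in AMBIGUOUS
    )


def snp_vs_ani(markers: MarkerSet, ani: ANIResult) -> tuple[pd.DataFrame, RegressionFit]:
    """One row per unordered strain pair (snps, ani); OLS of ANI on SNPs."""
    strains = sorted(set(markers.sequences) & set(ani.labels))
    idx = {s: ani.labels.index(s) for s in strains}
    rows = []
    for a, b in itertools.combinations(strains, 2):
        v = ani.ani[idx[a], idx[b]]
        if np.isnan(v):
            continue
        rows.append((a, b, snp_count(markers.sequences[a], markers.sequences[b]), float(v)))
    if len(rows) < 3:
        raise MarkerError("need >= 3 strain pairs for a regression")
    df = pd.DataFrame(rows, columns=["strain_a", "strain_b", "snps", "ani"])
    if df["snps"].nunique() < 2:
        raise MarkerError("zero variance in SNP counts; fit refused")
    fit = stats.linregress(df["snps"], df["ani"])
    x95 = (95.0 - fit.intercept) / fit.slope if fit.slope != 0 else float("nan")
    return df, RegressionFit(float(fit.slope), float(fit.intercept),
                             float(fit.rvalue) ** 2, float(x95))


def jaccard_distances(presence: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distance between strain presence/absence rows.

    All-zero rows are at distance 1 from everything (warning emitted)."""
    import warnings

    labels = list(presence.index)
    x = presence.values.astype(bool)
    if (~x.any(axis=1)).any():
        warnings.warn("all-zero trait rows: distance 1 to everything", stacklevel=2)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = (x[i] | x[j]).sum()
            inter = (x[i] & x[j]).sum()
            d[i, j] = d[j, i] = 1.0 - (inter / union if union else 0.0)
    return DistanceMatrix(labels, d)


def trait_cluster(presence: pd.DataFrame, linkage: str = "average") -> PhyloTree:
    """Average-linkage dendrogram on Jaccard distances between strains."""
    if linkage != "average":
        raise MarkerError("only average linkage is supported")
    if presence.shape[0] < 2 or presence.shape[1] < 1:
        raise MarkerError("need >= 2 strains and >= 1 trait")
    return upgma(jaccard_distances(presence))


def cut_dendrogram(tree: PhyloTree, k: int) -> dict[str, str]:
    """k-group partition from the dendrogram: remove the k-1 highest-placed
    merges (the standard hclust cut)."""
    # node height = max root distance to a leaf below
    heights: dict[int, float] = {}
    members: dict[int, list[str]] = {}

    def rec(node) -> tuple[float, list[str]]:
        if node.is_leaf:
            heights[id(node)] = 0.0
            members[id(node)] = [node.name]
            return 0.0, [node.name]
        hs, ms = [], []
        for c in node.children:
            h, m = rec(c)
            hs.append(h + (c.length or 0.0))
            ms.append(m)
        h = max(hs)
        flat = [x for m in ms for x in m]
        heights[id(node)] = h
        members[id(node)] = flat
        return h, flat

    rec(tree.root)
    internals = sorted(
        (n for n in tree.traverse() if not n.is_leaf),
        key=lambda n: -heights[id(n)],
    )
    cut = {id(tree.root)}
    for n in internals:
        if len(cut) >= k:
            break
        if id(n) in cut:
            cut.discard(id(n))
            for c in n.children:
                cut.add(id(c))
    id_map = {id(n): n for n in tree.traverse()}
    out = {}
    for gi, nid in enumerate(sorted(cut, key=lambda i: min(members[i])), 1):
        for leaf in members[nid]:
            out[leaf] = f"cluster{gi:02d}"
    return out


def partition_agreement(partition_a: Mapping[str, str], partition_b: Mapping[str, str]) -> float:
    """Adjusted Rand index between two strain partitions (1 = identical)."""
    if set(partition_a) != set(partition_b):
        raise MarkerError("partitions cover different strain sets")
    keys = sorted(partition_a)
    return float(adjusted_rand_score([partition_a[k] for k in keys],
                                     [partition_b[k] for k in keys]))
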