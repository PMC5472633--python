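"""Orthologous-group inference: all-vs-all nucleotide similarity (seed-and-
extend over shared 16-mers), Markov clustering at a configurable inflation
index, paralog flagging, and single-copy-core extraction.

The similarity search replaces a translated-BLAST bidirectional analysis:
percent identity over aligned columns stands in for the percent-match cutoff,
and a minimum-coverage filter stands in for the e-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SEED_K = 16


class OrthologyError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityHit:
    query_gene: str
    subject_gene: str
    identity: float   # percent over aligned columns
    coverage: float   # aligned columns / shorter gene length
    score: float

    def __post_init__(self):
        if not 0 <= self.identity <= 100:
            raise OrthologyError("identity out of range")
        if not 0 < self.coverage <= 1:
            raise OrthologyError("coverage out of range")


@dataclass
class OrthoMatrix:
    strains: list[str]
    families: list[str]                  # OG ids, ordered
    counts: np.ndarray                   # strains x families, int
    members: dict[str, list[str]]        # OG id -> gene ids
    singletons: list[str]                # genes in no multi-member OG

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.strains, columns=self.families)

    @property
    def presence(self) -> np.ndarray:
        return (self.counts > 0).astype(int)


@dataclass(frozen=True)
class CorePartition:
    core_ogs: tuple[str, ...]   # OGs present in every strain
    scc_ogs: tuple[str, ...]    # core OGs single-copy in every strain

    def __post_init__(self):
        if not set(self.scc_ogs) <= set(self.core_ogs):
            raise OrthologyError("scc_ogs must be a subset of core_ogs")


# ------------------------------------------------------------ similarity

def _kmer_set(seq: str, k: int = SEED_K) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def _ungapped_identity(a: str, b: str, offset: int) -> tuple[float, int]:
    """Identity of the ungapped alignment placing b[j] against a[j + offset].

    Returns (percent identity, aligned columns)."""
    a_start = max(0, offset)
    b_start = max(0, -offset)
    n = min(len(a) - a_start, len(b) - b_start)
    if n <= 0:
        return 0.0, 0
    av = np.frombuffer(a[a_start : a_start + n].encode(), dtype="S1")
    bv = np.frombuffer(b[b_start : b_start + n].encode(), dtype="S1")
    matches = int((av == bv).sum())
    return 100.0 * matches / n, n


def _best_offset(a: str, b: str, kmers_a: dict[str, list[int]], seq_b: str,
                 k: int = SEED_K) -> Optional[int]:
    """Most-voted diagonal offset (a_pos - b_pos) over shared k-mers."""
    votes: dict[int, int] = {}
    for j in range(0, len(seq_b) - k + 1):
        kmer = seq_b[j : j + k]
        for i in kmers_a.get(kmer, ()):
            off = i - j
            votes[off] = votes.get(off, 0) + 1
    if not votes:
        return None
    return min(votes, key=lambda o: (-votes[o], o))


def all_vs_all_similarity(
    gene_seqs: Mapping[str, str],
    cutoff: float = 70.0,
    min_coverage: float = 0.5,
) -> list[SimilarityHit]:
    """Directed hits for every ordered gene pair sharing a 16-mer and passing
    the identity/coverage filters; self-hits excluded, symmetry guaranteed."""
    if len(gene_seqs) < 2:
        raise OrthologyError("need at least two genes")
    for g, s in gene_seqs.items():
        if not s:
            raise OrthologyError(f"empty sequence for gene {g!r}")
    genes = sorted(gene_seqs)
    index: dict[str, dict[str, list[int]]] = {}
    buckets: dict[str, list[str]] = {}
    for g in genes:
        seq = gene_seqs[g]
        kmap: dict[str, list[int]] = {}
        for i in range(0, len(seq) - SEED_K + 1):
            kmap.setdefault(seq[i : i + SEED_K], []).append(i)
        index[g] = kmap
        for kmer in kmap:
            buckets.setdefault(kmer, []).append(g)
    candidate_pairs: set[tuple[str, str]] = set()
    for bucket in buckets.values():
        if len(bucket) < 2:
            continue
        for x in range(len(bucket)):
            for y in range(x + 1, len(bucket)):
                candidate_pairs.add((bucket[x], bucket[y]))
    hits: list[SimilarityHit] = []
    for ga, gb in sorted(candidate_pairs):
        sa, sb = gene_seqs[ga], gene_seqs[gb]
        off = _best_offset(sa, sb, index[ga], sb)
        if off is None:
            continue
        ident, ncols = _ungapped_identity(sa, sb, off)
        if ncols == 0:
            continue
        coverage = ncols / min(len(sa), len(sb))
        if ident < cutoff or coverage < min_coverage:
            continue
        score = (ident / 100.0) * coverage
        hits.append(SimilarityHit(ga, gb, ident, coverage, score))
        hits.append(SimilarityHit(gb, ga, ident, coverage, score))
    return hits


# ----------------------------------------------------------------------- MCL

def mcl_fixed_point(
    adjacency: np.ndarray,
    inflation: float,
    prune: float = 1e-9,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Iterate expansion (matrix square) and inflation (element-wise power,
    column renormalization) to convergence; self-loops are added with the
    column-maximum weight beforehand."""
    m = adjacency.astype(float).copy()
    n = m.shape[0]
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated
    return m


def _clusters_from_matrix(m: np.ndarray, eps: float = 1e-6) -> list[list[int]]:
    """Connected components of the converged flow matrix."""
    n = m.shape[0]
    adj = (m + m.T) > eps
    seen = np.zeros(n, dtype=bool)
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        clusters.append(sorted(comp))
    return clusters


def strain_of_gene(gene_id: str) -> str:
    """Gene ids are '<strain>|<rest>'; the strain is the first field."""
    return gene_id.split("|")[0]


def mcl_cluster(
    hits: Sequence[SimilarityHit],
    inflation: float = 1.5,
    all_genes: Optional[Sequence[str]] = None,
) -> OrthoMatrix:
    """Markov clustering of the similarity graph into orthologous groups.

    Genes in no multi-member cluster are singletons. ``all_genes`` lists every
    input gene so hit-less genes are still accounted for.
    """
    genes = sorted(set(all_genes or [])
                   | {h.query_gene for h in hits} | {h.subject_gene for h in hits})
    gidx = {g: i for i, g in enumerate(genes)}
    # cluster each connected component separately (identical result, faster)
    weight: dict[tuple[int, int], float] = {}
    for h in hits:
        weight[(gidx[h.query_gene], gidx[h.subject_gene])] = h.score
    parent = list(range(len(genes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j) in weight:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    comps: dict[int, list[int]] = {}
    for i in range(len(genes)):
        comps.setdefault(find(i), []).append(i)

    clusters: list[list[str]] = []
    for comp in comps.values():
        if len(comp) == 1:
            clusters.append([genes[comp[0]]])
            continue
        sub = sorted(comp)
        pos = {g: i for i, g in enumerate(sub)}
        adj = np.zeros((len(sub), len(sub)))
        for (i, j), w in weight.items():
            if i in pos and j in pos:
                adj[pos[i], pos[j]] = w
        converged = mcl_fixed_point(adj, inflation)
        for idxs in _clusters_from_matrix(converged):
            clusters.append(sorted(genes[sub[i]] for i in idxs))

    clusters.sort(key=lambda c: c[0])
    og_clusters = [c for c in clusters if len(c) > 1]
    singletons = sorted(g for c in clusters if len(c) == 1 for g in c)
    strains = sorted({strain_of_gene(g) for g in genes})
    sidx = {s: i for i, s in enumerate(strains)}
    families = [f"OG{i + 1:05d}" for i in range(len(og_clusters))]
    counts = np.zeros((len(strains), len(families)), dtype=int)
    members: dict[str, list[str]] = {}
    for fi, cluster in enumerate(og_clusters):
        members[families[fi]] = cluster
        for g in cluster:
            counts[sidx[strain_of_gene(g)], fi] += 1
    return OrthoMatrix(strains, families, counts, members, singletons)


# ----------------------------------------------------------- core extraction

def extract_core(matrix: OrthoMatrix) -> CorePartition:
    """Core = OGs present in every strain; SCC = core OGs with exactly one
    copy per strain (paralog-containing OGs removed)."""
    if len(matrix.strains) < 2:
        raise OrthologyError("core extraction needs >= 2 strains")
    core, scc = [], []
    for fi, fam in enumerate(matrix.families):
        col = matrix.counts[:, fi]
        if col.min() >= 1:
            core.append(fam)
            if (col == 1).all():
                scc.append(fam)
    return CorePartition(tuple(core), tuple(scc))


def og_stats(matrix: OrthoMatrix, core: CorePartition,
             mean_gene_count: Optional[float] = None) -> dict[str, float]:
    """Headline pan/core arithmetic: pan size (OGs + singletons), core size,
    core as integer % of pan and of the average per-strain gene count.

    ``mean_gene_count`` overrides the matrix-derived average (e.g. when the
    per-genome annotation totals are known independently)."""
    n_genes = int(matrix.counts.sum()) + len(matrix.singletons)
    if n_genes == 0:
        raise OrthologyError("matrix contains no genes")
    pan = len(matrix.families) + len(matrix.singletons)
    core_n = len(core.core_ogs)
    if mean_gene_count is None:
        mean_gene_count = n_genes / len(matrix.strains)
    return {
        "n_ogs": len(matrix.families),
        "n_singletons": len(matrix.singletons),
        "pan_size": pan,
        "core_size": core_n,
        "scc_size": len(core.scc_ogs),
        "core_pct_of_pan": pct_of(core_n, pan),
        "core_pct_of_avg_gene_count": pct_of(core_n, mean_gene_count),
    }


def pct_of(part: float, whole: float) -> int:
    """Integer percentage, round-half-even."""
    import decimal

    d = decimal.Decimal(100 * part) / decimal.Decimal(whole)
    return int(d.quantize(decimal.Decimal("1"), rounding=decimal.ROUND_HALF_EVEN))
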