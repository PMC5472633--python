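"""Whole-genome relatedness: fragment-based ANI, gene-based gANI with
alignment fraction, the 100−ANI distance matrix, a UPGMA dendrogram, and
threshold species delineation.

Fragment best-hit search uses exact 15-mer seeding with ungapped diagonal
scoring (a deterministic stand-in for a BLASTN search). Reciprocal values are
averaged into symmetric matrices; both directions are retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phylogenomics import DistanceMatrix
from .tree import Node, PhyloTree

ANI_SEED_K = 15
MIN_HIT_IDENTITY = 30.0    # percent
MIN_HIT_COVERAGE = 0.7     # of fragment length
SEED_STRIDE = 10


class ANIError(ValueError):
    pass


@dataclass
class ANIResult:
    labels: list[str]
    ani: np.ndarray           # percent; nan = undefined
    gani: np.ndarray
    af: np.ndarray
    n_fragments_used: np.ndarray

    def frame(self, which: str = "ani") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.labels, columns=self.labels)


@dataclass
class SpeciesPartition:
    assignment: dict[str, str]
    method: str
    thresholds: dict[str, float]
    clique_purity: dict[str, float]

    def as_sets(self) -> list[set[str]]:
        out: dict[str, set[str]] = {}
        for s, c in self.assignment.items():
            out.setdefault(c, set()).add(s)
        return [out[k] for k in sorted(out)]


# ------------------------------------------------------------------ fragments

def fragment_genome(genome_seq: str, fragment_len: int = 1020) -> list[str]:
    """Consecutive non-overlapping windows; trailing remainder discarded."""
    if len(genome_seq) < fragment_len:
        raise ANIError("genome shorter than fragment length")
    n = len(genome_seq) // fragment_len
    return [genome_seq[i * fragment_len : (i + 1) * fragment_len] for i in range(n)]


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


class _SubjectIndex:
    """15-mer position index over a subject sequence and its reverse
    complement (concatenated with a separator to keep diagonals distinct)."""

    def __init__(self, seq: str, k: int = ANI_SEED_K):
        self.k = k
        self.seq = seq + "N" * k + _revcomp(seq)
        self.arr = np.frombuffer(self.seq.encode(), dtype="S1")
        self.kmers: dict[str, list[int]] = {}
        for i in range(0, len(self.seq) - k + 1):
            kmer = self.seq[i : i + k]
            if "N" in kmer:
                continue
            self.kmers.setdefault(kmer, []).append(i)

    def best_hit(self, fragment: str) -> Optional[tuple[float, int]]:
        """(percent identity, aligned columns) of the highest-scoring local
        segment (match +1 / mismatch −1, the HSP analog) over the three
        most-voted diagonals."""
        k = self.k
        votes: dict[int, int] = {}
        for j in range(0, len(fragment) - k + 1, SEED_STRIDE):
            for i in self.kmers.get(fragment[j : j + k], ()):
                off = i - j
                votes[off] = votes.get(off, 0) + 1
        if not votes:
            return None
        frag = np.frombuffer(fragment.encode(), dtype="S1")
        best: Optional[tuple[float, float, int]] = None
        for off in sorted(votes, key=lambda o: (-votes[o], o))[:3]:
            s_start = max(0, off)
            f_start = max(0, -off)
            n = min(len(self.arr) - s_start, len(frag) - f_start)
            if n <= 0:
                continue
            sub = self.arr[s_start : s_start + n]
            fr = frag[f_start : f_start + n]
            valid = sub != b"N"
            match = (sub == fr) & valid
            vals = np.where(match, 1.0, np.where(valid, -1.0, 0.0))
            cs = np.cumsum(vals)
            prefix_min = np.minimum.accumulate(np.concatenate([[0.0], cs]))[:-1]
            gains = cs - prefix_min
            end = int(np.argmax(gains))
            if gains[end] <= 0:
                continue
            start = int(np.argmin(np.concatenate([[0.0], cs])[: end + 1]))
            seg_valid = valid[start : end + 1]
            ncols = int(seg_valid.sum())
            if ncols == 0:
                continue
            ident = 100.0 * int(match[start : end + 1].sum()) / ncols
            cand = (gains[end], ident, ncols)
            if best is None or cand > best:
                best = cand
        if best is None:
            return None
        return best[1], best[2]


def ani_pair(
    query_genome: str,
    subject_genome: str,
    fragment_len: int = 1020,
    min_identity: float = MIN_HIT_IDENTITY,
    min_coverage: float = MIN_HIT_COVERAGE,
    subject_index: Optional["_SubjectIndex"] = None,
) -> tuple[float, int]:
    """One-directional ANI: mean identity of query fragments whose best
    subject hit passes the 30%-identity / 70%-coverage filters.

    Returns (ani percent, fragments used); ani is nan when nothing survives.
    """
    fragments = fragment_genome(query_genome, fragment_len)
    index = subject_index or _SubjectIndex(subject_genome)
    idents = []
    for frag in fragments:
        hit = index.best_hit(frag)
        if hit is None:
            continue
        ident, ncols = hit
        if ident >= min_identity and ncols >= min_coverage * fragment_len:
            idents.append(ident)
    if not idents:
        return float("nan"), 0
    return float(np.mean(idents)), len(idents)


# ----------------------------------------------------------------- gANI / AF

def _gene_best_hits(genes_a: Mapping[str, str], genes_b: Mapping[str, str]
                    ) -> dict[str, tuple[str, float, int]]:
    """Best hit in B for each gene of A: gene_a -> (gene_b, identity, cols)."""
    from .orthology import _best_offset, _ungapped_identity

    index_b: dict[str, dict[str, list[int]]] = {}
    buckets: dict[str, list[str]] = {}
    k = 16
    for g, seq in genes_b.items():
        kmap: dict[str, list[int]] = {}
        for i in range(0, len(seq) - k + 1):
            kmap.setdefault(seq[i : i + k], []).append(i)
        index_b[g] = kmap
        for kmer in kmap:
            buckets.setdefault(kmer, []).append(g)
    out: dict[str, tuple[str, float, int]] = {}
    for ga in sorted(genes_a):
        sa = genes_a[ga]
        cands: set[str] = set()
        for i in range(0, len(sa) - k + 1, SEED_STRIDE):
            cands.update(buckets.get(sa[i : i + k], ()))
        best: Optional[tuple[float, int, str]] = None
        for gb in sorted(cands):
            off = _best_offset(genes_b[gb], sa, index_b[gb], sa)
            if off is None:
                continue
            ident, ncols = _ungapped_identity(genes_b[gb], sa, off)
            if ncols == 0:
                continue
            cand = (ident, ncols, gb)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]) \
                    or ((cand[0], cand[1]) == (best[0], best[1]) and gb == ga):
                best = cand
        if best is not None:
            out[ga] = (best[2], best[0], best[1])
    return out


def gani_af_pair(
    genes_a: Mapping[str, str],
    genes_b: Mapping[str, str],
) -> tuple[float, float]:
    """Directional gANI/AF from bidirectional best hits (A → B direction).

    gANI = length-weighted mean identity of BBH pairs; AF = aligned length of
    BBH genes in A over total gene length of A.
    """
    if not genes_a or not genes_b:
        raise ANIError("empty gene set")
    fwd = _gene_best_hits(genes_a, genes_b)
    rev = _gene_best_hits(genes_b, genes_a)
    total_len_a = sum(len(s) for s in genes_a.values())
    aligned = 0
    wsum = 0.0
    wtot = 0
    for ga, (gb, ident, ncols) in fwd.items():
        back = rev.get(gb)
        if back is None or back[0] != ga:
            continue
        aligned += ncols
        wsum += ident * ncols
        wtot += ncols
    if wtot == 0:
        return float("nan"), 0.0
    return wsum / wtot, aligned / total_len_a


# ------------------------------------------------------------------- matrices

def ani_matrix(
    genomes: Mapping[str, str],
    fragment_len: int = 1020,
) -> ANIResult:
    """Symmetric (direction-averaged) ANI over all genome pairs. gANI/AF
    matrices are left as nan; fill via :func:`gani_af_matrix`."""
    labels = sorted(genomes)
    n = len(labels)
    ani = np.full((n, n), np.nan)
    nfrag = np.zeros((n, n), dtype=int)
    np.fill_diagonal(ani, 100.0)
    indexes = {lbl: _SubjectIndex(genomes[lbl]) for lbl in labels}
    for i, j in itertools.combinations(range(n), 2):
        aij, nij = ani_pair(genomes[labels[i]], genomes[labels[j]], fragment_len,
                            subject_index=indexes[labels[j]])
        aji, nji = ani_pair(genomes[labels[j]], genomes[labels[i]], fragment_len,
                            subject_index=indexes[labels[i]])
        vals = [v for v in (aij, aji) if not np.isnan(v)]
        ani[i, j] = ani[j, i] = float(np.mean(vals)) if vals else np.nan
        nfrag[i, j], nfrag[j, i] = nij, nji
    gani = np.full((n, n), np.nan)
    af = np.full((n, n), np.nan)
    np.fill_diagonal(gani, 100.0)
    np.fill_diagonal(af, 1.0)
    return ANIResult(labels, ani, gani, af, nfrag)


def gani_af_matrix(
    gene_sets: Mapping[str, Mapping[str, str]],
    result: Optional[ANIResult] = None,
) -> ANIResult:
    """Symmetric gANI/AF over all strains' gene sets; merged into ``result``
    when given."""
    labels = sorted(gene_sets)
    n = len(labels)
    if result is None:
        result = ANIResult(labels, np.full((n, n), np.nan), np.full((n, n), np.nan),
                           np.full((n, n), np.nan), np.zeros((n, n), dtype=int))
        np.fill_diagonal(result.ani, 100.0)
    elif result.labels != labels:
        raise ANIError("strain labels differ between ANI result and gene sets")
    np.fill_diagonal(result.gani, 100.0)
    np.fill_diagonal(result.af, 1.0)
    for i, j in itertools.combinations(range(n), 2):
        gij, aij = gani_af_pair(gene_sets[labels[i]], gene_sets[labels[j]])
        gji, aji = gani_af_pair(gene_sets[labels[j]], gene_sets[labels[i]])
        gvals = [v for v in (gij, gji) if not np.isnan(v)]
        result.gani[i, j] = result.gani[j, i] = float(np.mean(gvals)) if gvals else np.nan
        result.af[i, j] = result.af[j, i] = float(np.mean([aij, aji]))
    return result


def ani_distance_matrix(result: ANIResult) -> DistanceMatrix:
    """ANI divergence 100 − ANI; missing values become maximal divergence."""
    d = 100.0 - result.ani
    d[np.isnan(d)] = 100.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(result.labels), d)


# ---------------------------------------------------------------------- UPGMA

def upgma(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration into a rooted ultrametric dendrogram;
    merge ties break on the smallest (label, label) pair."""
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ANIError("need >= 2 taxa")
    clusters: dict[str, tuple[Node, float, int]] = {
        lbl: (Node(lbl), 0.0, 1) for lbl in labels
    }
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            key = (a, b) if a < b else (b, a)
            dist[key] = dm.get(a, b)
    while len(clusters) > 1:
        best_key = min(dist, key=lambda k: (dist[k], k))
        a, b = best_key
        h = dist[best_key] / 2.0
        na, ha, sa = clusters.pop(a)
        nb, hb, sb = clusters.pop(b)
        parent = Node()
        na.length = h - ha
        nb.length = h - hb
        parent.add(na)
        parent.add(nb)
        rep = min(a, b)
        newsize = sa + sb
        newdist: dict[str, float] = {}
        for c in clusters:
            ka = (a, c) if a < c else (c, a)
            kb = (b, c) if b < c else (c, b)
            newdist[c] = (sa * dist[ka] + sb * dist[kb]) / newsize
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, v in newdist.items():
            key = (rep, c) if rep < c else (c, rep)
            dist[key] = v
        clusters[rep] = (parent, h, newsize)
    (root, _, _), = clusters.values()
    return PhyloTree(root)


# ----------------------------------------------------------------- delineation

def delineate_species(
    result: ANIResult,
    method: str = "ani95",
    ani_threshold: float = 95.0,
    gani_threshold: float = 96.5,
    af_threshold: float = 0.6,
) -> SpeciesPartition:
    """Single-linkage species delineation.

    Edge (i,j) when the pair meets the criterion (ani >= 95, or gANI > 96.5
    AND AF > 0.6; missing values fail); candidate species = connected
    components. Clique purity = fraction of within-component pairs meeting
    the criterion.
    """
    labels = result.labels
    n = len(labels)
    if method == "ani95":
        crit = np.nan_to_num(result.ani, nan=-1.0) >= ani_threshold
        thresholds = {"ani": ani_threshold}
    elif method == "gani_af":
        crit = (np.nan_to_num(result.gani, nan=-1.0) > gani_threshold) \
            & (np.nan_to_num(result.af, nan=-1.0) > af_threshold)
        thresholds = {"gani": gani_threshold, "af": af_threshold}
    else:
        raise ANIError(f"unknown method {method!r}")
    crit = crit | crit.T
    np.fill_diagonal(crit, True)
    comp = -np.ones(n, dtype=int)
    cid = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = cid
        while stack:
            u = stack.pop()
            for v in np.nonzero(crit[u])[0]:
                if comp[v] < 0:
                    comp[v] = cid
                    stack.append(int(v))
        cid += 1
    assignment = {}
    order = {}
    for i, lbl in enumerate(labels):
        c = int(comp[i])
        if c not in order:
            order[c] = f"cand{len(order) + 1:02d}"
        assignment[lbl] = order[c]
    purity = {}
    for c, name in order.items():
        idx = np.nonzero(comp == c)[0]
        if len(idx) < 2:
            purity[name] = 1.0
        else:
            sub = crit[np.ix_(idx, idx)]
            npairs = len(idx) * (len(idx) - 1) // 2
            purity[name] = float(np.triu(sub, 1).sum()) / npairs
    return SpeciesPartition(assignment, method, thresholds, purity)
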