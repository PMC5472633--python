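"""Recombination screening of single-copy core genes.

Implements three alignment-based tests with permutation p-values:

* PHI — mean refined incompatibility over nearby pairs of parsimony-
  informative sites (window measured as original alignment-position distance,
  default 100 nt); recombination depresses the statistic, so the permutation
  test is lower-tailed.
* MaxChi — maximum 2x2 chi-square contrast of match/mismatch counts across a
  candidate breakpoint for any sequence pair (upper tail).
* NSS — clustering of compatibility patterns between neighbouring sites
  (upper tail).

The decision rule flagging a gene as recombinant defaults to PHI alone;
``any``/``all`` combinations of the three tests are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .io_core import AlignmentBlock

GAPLIKE = (b"-", b"N")


class RecombinationError(ValueError):
    pass


@dataclass
class InformativeSites:
    positions: np.ndarray          # original column indices, ascending
    columns: np.ndarray            # n_sites x n_seqs uint8 state codes
    n_states: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class GeneTestResult:
    gene_id: str
    phi_stat: float = float("nan")
    phi_p: float = 1.0
    maxchi_stat: float = float("nan")
    maxchi_p: float = 1.0
    nss_stat: float = float("nan")
    nss_p: float = 1.0
    testable: bool = True
    recombinant: bool = False


@dataclass
class RecombReport:
    results: list[GeneTestResult]
    recombinant_set: set[str]
    minimum_core_set: set[str]
    alpha: float
    decision: str

    def __post_init__(self):
        tested = {r.gene_id for r in self.results}
        if self.recombinant_set & self.minimum_core_set:
            raise RecombinationError("partition sets overlap")
        if self.recombinant_set | self.minimum_core_set != tested:
            raise RecombinationError("partition does not cover tested genes")

    @property
    def pct_recombinant(self) -> float:
        from .summary import pct1
        return pct1(len(self.recombinant_set), len(self.results))


# --------------------------------------------------------- informative sites

def informative_sites(aln: AlignmentBlock) -> InformativeSites:
    """Parsimony-informative, gap-free columns with original indices.

    A column qualifies when at least two states are each carried by at least
    two sequences; columns containing '-' or 'N' are removed first.
    """
    if len(aln) < 4:
        raise RecombinationError("tests require >= 4 sequences")
    arr = aln.to_array()
    clean = ~np.any((arr == b"-") | (arr == b"N"), axis=0)
    positions, columns, n_states = [], [], []
    for j in np.nonzero(clean)[0]:
        col = arr[:, j]
        states, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            # recode to small ints, keeping only states seen in the column
            code = np.searchsorted(states, col).astype(np.uint8)
            positions.append(j)
            columns.append(code)
            n_states.append(len(states))
    return InformativeSites(
        positions=np.array(positions, dtype=int),
        columns=np.array(columns, dtype=np.uint8) if columns else np.empty((0, len(aln)), np.uint8),
        n_states=np.array(n_states, dtype=int),
    )


def pair_incompatibility(site_i: np.ndarray, site_j: np.ndarray) -> int:
    """Refined incompatibility: cyclomatic number E - V + C of the bipartite
    graph of observed joint states; 0 iff the pair is compatible."""
    pairs = set(zip(site_i.tolist(), site_j.tolist()))
    left = {a for a, _ in pairs}
    right = {b for _, b in pairs}
    v = len(left) + len(right)
    e = len(pairs)
    # connected components via union-find over the bipartite vertices
    verts = [("L", a) for a in left] + [("R", b) for b in right]
    idx = {u: i for i, u in enumerate(verts)}
    parent = list(range(len(verts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(idx[("L", a)]), find(idx[("R", b)])
        if ra != rb:
            parent[ra] = rb
    c = len({find(i) for i in range(len(verts))})
    return e - v + c


def incompatibility_matrix(sites: InformativeSites) -> np.ndarray:
    k = sites.n_sites
    m = np.zeros((k, k), dtype=np.int16)
    for i in range(k):
        for j in range(i + 1, k):
            s = pair_incompatibility(sites.columns[i], sites.columns[j])
            m[i, j] = m[j, i] = s
    return m


# ------------------------------------------------------------------ statistics

def phi_statistic(
    sites: InformativeSites,
    window: int = 100,
    incompat: Optional[np.ndarray] = None,
    order: Optional[np.ndarray] = None,
) -> float:
    """Mean pairwise incompatibility over informative-site pairs whose
    original positions are within ``window`` nt of each other.

    ``order`` permutes which site columns occupy the (fixed) positions, the
    permutation-null device used by the p-value machinery.
    """
    k = sites.n_sites
    if k < 2:
        raise RecombinationError("PHI needs >= 2 informative sites")
    if incompat is None:
        incompat = incompatibility_matrix(sites)
    pos = sites.positions
    mask = np.abs(pos[:, None] - pos[None, :]) <= window
    np.fill_diagonal(mask, False)
    if not mask.any():
        raise RecombinationError("no informative-site pairs within window")
    m = incompat if order is None else incompat[np.ix_(order, order)]
    return float(m[mask].sum() / mask.sum())


def nss_statistic(
    sites: InformativeSites,
    incompat: Optional[np.ndarray] = None,
    order: Optional[np.ndarray] = None,
) -> float:
    """Mean fraction of matching entries between adjacent rows of the binary
    incompatibility matrix."""
    k = sites.n_sites
    if k < 3:
        raise RecombinationError("NSS needs >= 3 informative sites")
    if incompat is None:
        incompat = incompatibility_matrix(sites)
    b = (incompat > 0)
    if order is not None:
        b = b[np.ix_(order, order)]
    eq = (b[:-1] == b[1:])
    return float(eq.mean())


def maxchi_statistic(
    sites: InformativeSites,
    window_fraction: float = 2.0 / 3.0,
    order: Optional[np.ndarray] = None,
) -> float:
    """Maximum 2x2 chi-square (no continuity correction) of match/mismatch x
    left/right over all sequence pairs and breakpoints between informative
    sites, within a centered window of ceil(window_fraction * k) sites per
    side (clipped at the alignment ends)."""
    cols = sites.columns
    k = sites.n_sites
    if k < 2:
        raise RecombinationError("MaxChi needs >= 2 informative sites")
    if order is not None:
        cols = cols[order]
    n_seq = cols.shape[1]
    h = max(1, ceil(window_fraction * k))
    bs = np.arange(1, k)
    los = np.maximum(0, bs - h)
    his = np.minimum(k, bs + h)
    nl = (bs - los).astype(float)[:, None]       # breakpoints x 1
    nr = (his - bs).astype(float)[:, None]
    best = 0.0
    for a in range(n_seq - 1):
        diff = (cols[:, a + 1 :] != cols[:, a : a + 1]).astype(np.int64)  # k x rest
        cum = np.concatenate([np.zeros((1, diff.shape[1]), dtype=np.int64),
                              np.cumsum(diff, axis=0)])
        mis_l = (cum[bs] - cum[los]).astype(float)   # breakpoints x rest
        mis_r = (cum[his] - cum[bs]).astype(float)
        mat_l = nl - mis_l
        mat_r = nr - mis_r
        n = nl + nr
        num = n * (mis_l * mat_r - mat_l * mis_r) ** 2
        den = nl * nr * (mis_l + mis_r) * (mat_l + mat_r)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi = np.where(den > 0, num / den, 0.0)
        m = float(chi.max())
        if m > best:
            best = m
    return best


# ------------------------------------------------------------ permutation test

def permutation_pvalue(
    observed: float,
    perm_stats: Sequence[float],
    tail: str,
) -> float:
    perm = np.asarray(perm_stats, dtype=float)
    if tail == "lower":
        extreme = int((perm <= observed + 1e-12).sum())
    elif tail == "upper":
        extreme = int((perm >= observed - 1e-12).sum())
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (1 + extreme) / (len(perm) + 1)


def permutation_test(
    statistic_fn: Callable[[Optional[np.ndarray]], float],
    n_sites: int,
    n_perm: int,
    rng: np.random.Generator,
    tail: str,
) -> tuple[float, float]:
    """Generic site-order permutation test.

    ``statistic_fn(order)`` evaluates the statistic under a site permutation
    (``None`` = observed order). Add-one p-value: min attainable is
    1/(n_perm+1).
    """
    observed = statistic_fn(None)
    perms = [statistic_fn(rng.permutation(n_sites)) for _ in range(n_perm)]
    return observed, permutation_pvalue(observed, perms, tail)


# ------------------------------------------------------------------ screening

def evaluate_gene(
    gene_id: str,
    aln: AlignmentBlock,
    window: int = 100,
    window_fraction: float = 2.0 / 3.0,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    run_maxchi: bool = True,
    run_nss: bool = True,
) -> GeneTestResult:
    rng = rng or np.random.default_rng(0)
    res = GeneTestResult(gene_id)
    try:
        sites = informative_sites(aln)
    except RecombinationError:
        res.testable = False
        return res
    k = sites.n_sites
    if k < 2:
        res.testable = False
        return res
    incompat = incompatibility_matrix(sites)
    try:
        res.phi_stat, res.phi_p = permutation_test(
            lambda order: phi_statistic(sites, window, incompat, order),
            k, n_perm, rng, tail="lower",
        )
    except RecombinationError:
        res.testable = False
        return res
    if run_maxchi:
        res.maxchi_stat, res.maxchi_p = permutation_test(
            lambda order: maxchi_statistic(sites, window_fraction, order),
            k, n_perm, rng, tail="upper",
        )
    if run_nss and k >= 3:
        res.nss_stat, res.nss_p = permutation_test(
            lambda order: nss_statistic(sites, incompat, order),
            k, n_perm, rng, tail="upper",
        )
    return res


def _decide(res: GeneTestResult, alpha: float, decision: str) -> bool:
    if not res.testable:
        return False
    ps = {"phi": res.phi_p, "maxchi": res.maxchi_p, "nss": res.nss_p}
    if decision == "phi":
        return ps["phi"] < alpha
    avail = [p for s, p in ps.items() if not np.isnan(getattr(res, f"{s}_stat"))]
    if decision == "any":
        return any(p < alpha for p in avail)
    if decision == "all":
        return bool(avail) and all(p < alpha for p in avail)
    raise ValueError(f"unknown decision rule {decision!r}")


def screen_genes(
    alignments: Mapping[str, AlignmentBlock],
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    window: int = 100,
    decision: str = "phi",
    run_maxchi: bool = True,
    run_nss: bool = True,
) -> RecombReport:
    """Screen SCC gene alignments; partition into recombinant vs minimum core.

    Untestable genes (too few informative sites) are assigned to the minimum
    core with ``testable=False``.
    """
    ss = np.random.SeedSequence(seed)
    results: list[GeneTestResult] = []
    recomb: set[str] = set()
    mincore: set[str] = set()
    gene_ids = sorted(alignments)
    for gene_id, child in zip(gene_ids, ss.spawn(len(gene_ids))):
        rng = np.random.default_rng(child)
        res = evaluate_gene(gene_id, alignments[gene_id], window=window,
                        n_perm=n_perm, rng=rng,
                        run_maxchi=run_maxchi, run_nss=run_nss)
        res.recombinant = _decide(res, alpha, decision)
        results.append(res)
        (recomb if res.recombinant else mincore).add(gene_id)
    return RecombReport(results, recomb, mincore, alpha, decision)
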