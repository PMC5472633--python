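"""Pan/core rarefaction and incidence-based richness estimation.

Chao1 and ACE are computed on the incidence spectrum (number of genomes an
orthologous group occurs in), treating genomes as samples — the same reading
vegan's ``specpool`` applies to site × species matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .orthology import OrthoMatrix


class PangenomeError(ValueError):
    pass


@dataclass
class RarefactionResult:
    k: np.ndarray
    pan_mean: np.ndarray
    pan_se: np.ndarray
    core_mean: np.ndarray
    core_se: np.ndarray
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k, "pan_mean": self.pan_mean, "pan_se": self.pan_se,
            "core_mean": self.core_mean, "core_se": self.core_se,
        })


@dataclass
class RichnessEstimate:
    s_obs: int
    chao: float
    ace: float
    q: dict[int, int]


def _presence(matrix: Union[OrthoMatrix, np.ndarray],
              collapse_paralogs: bool = True) -> np.ndarray:
    """Strains × OGs 0/1 matrix. "Recent paralogs" (extra copies within one
    strain) are collapsed to presence, matching occupancy-histogram usage."""
    counts = matrix.counts if isinstance(matrix, OrthoMatrix) else np.asarray(matrix)
    if counts.size == 0:
        raise PangenomeError("empty matrix")
    return (counts > 0).astype(np.int8) if collapse_paralogs else counts.astype(np.int8)


def occupancy_spectrum(
    matrix: Union[OrthoMatrix, np.ndarray],
    exclude_singletons: bool = True,
    collapse_paralogs: bool = True,
    extra_singletons: int = 0,
) -> dict[int, int]:
    """Q_j = number of OGs present in exactly j strains (j >= 1).

    ``extra_singletons`` adds file-level singleton genes (clusters of size 1,
    not represented as matrix columns) to Q_1 when singletons are included.
    """
    pres = _presence(matrix, collapse_paralogs)
    occ = pres.sum(axis=0)
    n = pres.shape[0]
    q = {j: int((occ == j).sum()) for j in range(1, n + 1)}
    if exclude_singletons:
        q[1] = 0
    else:
        q[1] += extra_singletons
    return {j: c for j, c in q.items() if c > 0} or {1: 0}


def rarefy(
    matrix: Union[OrthoMatrix, np.ndarray],
    n_perm: int = 100,
    seed: int = 0,
) -> RarefactionResult:
    """Cumulative pan (union) and core (intersection) sizes as genomes are
    added in random order.

    Means are the exact expectations over all orderings (hypergeometric
    form, equal to the average over exhaustively enumerated orders); the
    standard error of the cumulative sizes is estimated from ``n_perm``
    random orderings.
    """
    import math

    if n_perm < 1:
        raise PangenomeError("n_perm must be >= 1")
    pres = _presence(matrix).astype(bool)
    n, _m = pres.shape
    occ = pres.sum(axis=0).astype(int)
    ks = np.arange(1, n + 1)
    pan_mean = np.empty(n)
    core_mean = np.empty(n)
    for i, k in enumerate(ks):
        denom = math.comb(n, k)
        # P(OG with occupancy o missed by all k draws) = C(n-o, k)/C(n, k)
        pan_mean[i] = sum(1.0 - math.comb(n - o, k) / denom for o in occ)
        # P(OG present in every one of the k draws) = C(o, k)/C(n, k)
        core_mean[i] = sum(math.comb(o, k) / denom for o in occ if o >= k)
    rng = np.random.default_rng(seed)
    pan = np.empty((n_perm, n))
    core = np.empty((n_perm, n))
    for p in range(n_perm):
        order = rng.permutation(n)
        cum_union = np.zeros(pres.shape[1], dtype=bool)
        cum_inter = np.ones(pres.shape[1], dtype=bool)
        for i, s in enumerate(order):
            cum_union |= pres[s]
            cum_inter &= pres[s]
            pan[p, i] = cum_union.sum()
            core[p, i] = cum_inter.sum()
    return RarefactionResult(
        k=ks,
        pan_mean=pan_mean,
        pan_se=pan.std(axis=0, ddof=0) / np.sqrt(n_perm),
        core_mean=core_mean,
        core_se=core.std(axis=0, ddof=0) / np.sqrt(n_perm),
        n_perm=n_perm, seed=seed,
    )


def chao_estimate(spectrum: dict[int, int]) -> float:
    """Incidence Chao1: S_obs + Q1^2/(2 Q2), with the bias-form fallback
    Q1(Q1-1)/2 when Q2 = 0."""
    s_obs = sum(spectrum.values())
    if s_obs < 1:
        raise PangenomeError("empty spectrum")
    q1 = spectrum.get(1, 0)
    q2 = spectrum.get(2, 0)
    if q2 > 0:
        return s_obs + q1 * q1 / (2.0 * q2)
    return s_obs + q1 * (q1 - 1) / 2.0


def ace_estimate(spectrum: dict[int, int], rare_cutoff: int = 10) -> float:
    """Incidence-based coverage estimator with rare-class cutoff 10."""
    s_obs = sum(spectrum.values())
    if s_obs < 1:
        raise PangenomeError("empty spectrum")
    rare = {j: c for j, c in spectrum.items() if j <= rare_cutoff}
    s_rare = sum(rare.values())
    s_abund = s_obs - s_rare
    n_rare = sum(j * c for j, c in rare.items())
    q1 = spectrum.get(1, 0)
    if n_rare <= 1:
        return float(s_obs)
    c_ace = 1.0 - q1 / n_rare
    if c_ace == 0.0:
        return chao_estimate(spectrum)
    ssum = sum(j * (j - 1) * c for j, c in rare.items())
    gamma2 = max(s_rare * ssum / (c_ace * n_rare * (n_rare - 1)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + q1 * gamma2 / c_ace


def richness(matrix: Union[OrthoMatrix, np.ndarray],
             exclude_singletons: bool = False,
             extra_singletons: int = 0) -> RichnessEstimate:
    spec = occupancy_spectrum(matrix, exclude_singletons=exclude_singletons,
                              extra_singletons=extra_singletons)
    return RichnessEstimate(
        s_obs=sum(spec.values()),
        chao=chao_estimate(spec),
        ace=ace_estimate(spec),
        q=spec,
    )
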