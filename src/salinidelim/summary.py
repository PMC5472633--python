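"""Headline-count arithmetic and the end-of-run summary record.

Percentages are recomputed from counts (never copied) with one-decimal
round-half-even formatting.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field, asdict
from typing import Optional


class SummaryError(ValueError):
    pass


def pct1(part: float, whole: float) -> float:
    """100*part/whole to one decimal, round-half-even; exact for int inputs."""
    if whole == 0:
        raise SummaryError("percentage of zero total")
    num = decimal.Decimal(part) * 100
    d = num / decimal.Decimal(whole)
    return float(d.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_EVEN))


@dataclass
class RunSummary:
    n_strains: int
    n_ogs: int
    n_singletons: int
    core_size: int
    scc_size: int
    n_recombinant: int
    n_minimum_core: int
    n_incongruent: int
    n_candidate_species_ani: int
    n_candidate_species_gani_af: int
    chao: float
    ace: float
    pan_size: int = 0
    pct_recombinant: float = 0.0
    pct_incongruent_of_recombinant: float = 0.0
    pct_incongruent_of_scc: float = 0.0

    def __post_init__(self):
        if self.n_recombinant + self.n_minimum_core != self.scc_size:
            raise SummaryError(
                "recombinant + minimum core must partition the tested SCC "
                f"({self.n_recombinant} + {self.n_minimum_core} != {self.scc_size})")
        self.pan_size = self.n_ogs + self.n_singletons
        self.pct_recombinant = pct1(self.n_recombinant, self.scc_size) if self.scc_size else 0.0
        self.pct_incongruent_of_recombinant = (
            pct1(self.n_incongruent, self.n_recombinant) if self.n_recombinant else 0.0)
        self.pct_incongruent_of_scc = (
            pct1(self.n_incongruent, self.scc_size) if self.scc_size else 0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    def format_text(self) -> str:
        d = self.to_dict()
        width = max(len(k) for k in d)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in d.items())


def summarize_counts(
    n_recombinant: int,
    scc_size: int,
    n_incongruent: Optional[int] = None,
) -> dict[str, float]:
    """The recomputable percentage ledger from raw counts."""
    if not 0 <= n_recombinant <= scc_size:
        raise SummaryError("inconsistent counts")
    out = {
        "n_recombinant": n_recombinant,
        "scc_size": scc_size,
        "n_minimum_core": scc_size - n_recombinant,
        "pct_recombinant": pct1(n_recombinant, scc_size),
    }
    if n_incongruent is not None:
        if n_incongruent > n_recombinant:
            raise SummaryError("incongruent genes exceed recombinant genes")
        out["n_incongruent"] = n_incongruent
        out["pct_incongruent_of_recombinant"] = (
            pct1(n_incongruent, n_recombinant) if n_recombinant else 0.0)
        out["pct_incongruent_of_scc"] = pct1(n_incongruent, scc_size)
    return out
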