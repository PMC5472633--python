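"""Readers/writers for the formats every stage touches, plus config/logging.

Conventions
-----------
* Sequences are stored upper-case; ``U`` is mapped to ``T`` and any character
  outside ``{A,C,G,T,N,-}`` becomes ``N``.
* All coordinates in internal tables are 0-based, half-open.
* All randomness flows from a single seed in :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .tree import PhyloTree, from_newick, to_newick

logger = logging.getLogger("salinidelim")

ALPHABET = frozenset("ACGTN-")

_CANON = {c: c for c in "ACGTN-"}
_CANON["U"] = "T"


class FormatError(ValueError):
    """Malformed input file."""


def _canonicalize(seq: str) -> str:
    s = seq.upper()
    return "".join(_CANON.get(c, "N") for c in s)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} with empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentBlock:
    """A set of equal-length sequences (an aligned gene family)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise FormatError(f"alignment records have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def to_array(self) -> np.ndarray:
        """Rows = records, cells = single-byte characters."""
        return np.frombuffer(
            "".join(r.seq for r in self.records).encode("ascii"), dtype="S1"
        ).reshape(len(self.records), self.length)

    def subset(self, ids: Sequence[str]) -> "AlignmentBlock":
        by_id = {r.id: r for r in self.records}
        return AlignmentBlock(tuple(by_id[i] for i in ids))


@dataclass
class PipelineConfig:
    """Tuning knobs shared by all pipeline stages."""

    similarity_cutoff: float = 70.0       # percent identity for ortholog hits
    evalue_analog_min_coverage: float = 0.5
    inflation: float = 1.5                # MCL inflation index
    phi_window: int = 100                 # nt, original-position distance
    alpha: float = 0.01
    n_permutations: int = 1000
    fragment_len: int = 1020              # ANI fragment size
    ani_species_threshold: float = 95.0
    gani_threshold: float = 96.5
    af_threshold: float = 0.6
    bootstrap_gene: int = 100
    bootstrap_concat: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.similarity_cutoff <= 100:
            raise ValueError("similarity_cutoff must be in (0, 100]")
        if not 0 < self.evalue_analog_min_coverage <= 1:
            raise ValueError("min coverage must be in (0, 1]")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 19:
            raise ValueError("n_permutations must be >= 19")
        if not (0 < self.ani_species_threshold <= 100 and 0 < self.gani_threshold <= 100):
            raise ValueError("ANI thresholds must be percentages")
        if not 0 < self.af_threshold <= 1:
            raise ValueError("af_threshold must be a fraction")
        if self.fragment_len < 100:
            raise ValueError("fragment_len too small")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


# --------------------------------------------------------------------- FASTA

def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a multi-FASTA file; order preserved, sequences canonicalized."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _canonicalize(str(rec.seq))))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


def read_alignment(path: Union[str, Path]) -> AlignmentBlock:
    return AlignmentBlock(tuple(read_fasta(path)))


# -------------------------------------------------------------------- Newick

def write_newick(tree: PhyloTree, path: Union[str, Path]) -> None:
    """Branch lengths to 6 decimals, supports as internal-node labels."""
    if len(tree.leaves()) < 2:
        raise ValueError("refusing to write a tree with <2 leaves")
    Path(path).write_text(to_newick(tree) + "\n")


def read_newick(path: Union[str, Path]) -> PhyloTree:
    return from_newick(Path(path).read_text())


# --------------------------------------------------------------- TSV matrix

def read_matrix_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Labeled rectangular numeric matrix: first row/column are labels."""
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            if line.strip() == "":
                continue
            rows.append(line.rstrip("\n").split("\t"))
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(f"{path}: ragged row {i} ({len(r)} fields, expected {width})")
    header = rows[0][1:]
    index = [r[0] for r in rows[1:]]
    try:
        values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    df = pd.DataFrame(values, index=index, columns=header)
    if np.allclose(df.values, np.round(df.values)):
        df = df.astype(int)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index_label="")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
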