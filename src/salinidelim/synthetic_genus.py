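"""Synthetic bacterial genus with known species structure.

Simulates a genus of genomes under an ultrametric species tree: single-copy
core gene families, clade-biased accessory families, sporadic within-genome
paralogs, tract-level homologous recombination between species, and a
slow-evolving multi-copy 16S-like marker (copies identical within a strain).
Substitutions follow JC69 with no indels, so per-family records are aligned
by construction.

Every stage downstream of the simulator can therefore be tested against the
truth tables this module emits (species labels, family memberships, and a
recombination-event ledger).
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .io_core import AlignmentBlock, SequenceRecord, write_fasta
from .tree import Node, PhyloTree

MARKER_FAMILY = "rrn16S"
MARKER_RATE = 1.0 / 20.0     # marker evolves at 1/20 the core-gene rate
PARALOG_DIVERGENCE = 0.005   # extra divergence of a duplicated copy

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    n_species: int
    strains_per_species: tuple[int, ...]
    n_core_genes: int
    n_accessory_genes: int
    within_species_div: float
    between_species_div: float
    gene_len: int = 900
    marker_len: int = 1500
    marker_copies_range: tuple[int, int] = (2, 5)
    recomb_gene_fraction: float = 0.0
    recomb_tract_fraction: float = 1.0
    paralog_rate: float = 0.0
    accessory_clade_bias: float = 0.7
    spacer_len_range: tuple[int, int] = (50, 200)
    max_contigs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise SimulationError("n_species must be >= 1")
        if len(self.strains_per_species) != self.n_species:
            raise SimulationError("strains_per_species must have n_species entries")
        if any(s < 1 for s in self.strains_per_species):
            raise SimulationError("every species needs at least one strain")
        if not (self.between_species_div > self.within_species_div > 0):
            raise SimulationError("require between_species_div > within_species_div > 0")
        for name in ("recomb_gene_fraction", "recomb_tract_fraction",
                     "paralog_rate", "accessory_clade_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.recomb_gene_fraction > 0 and self.recomb_tract_fraction <= 0:
            raise SimulationError("recomb_tract_fraction must be in (0, 1]")


@dataclass(frozen=True)
class RecombEvent:
    family_id: str
    donor_strain: str
    recipient_strain: str
    tract: tuple[int, int]  # 0-based half-open, gene coordinates

    def __post_init__(self):
        if self.tract[1] <= self.tract[0]:
            raise SimulationError("empty recombination tract")


@dataclass
class GeneRow:
    gene_id: str
    family_id: str
    contig: str
    start: int  # 0-based half-open within contig
    end: int
    strand: str


@dataclass
class SyntheticGenus:
    params: SimParams
    strains: list[str]
    truth_species: dict[str, str]
    species_tree: PhyloTree
    # family -> strain -> allele (the single-copy allele carried by the strain)
    alleles: dict[str, dict[str, str]]
    core_families: list[str]
    accessory_families: list[str]
    # strain -> list of (gene_id, family_id, seq) for duplicated extra copies
    paralogs: dict[str, list[tuple[str, str, str]]]
    marker_seqs: dict[str, list[str]]
    truth_events: list[RecombEvent] = field(default_factory=list)
    genomes: dict[str, dict[str, str]] = field(default_factory=dict)   # strain -> contig -> seq
    gene_tables: dict[str, list[GeneRow]] = field(default_factory=dict)
    # shared (syntenic) genome layout: ordered (family_id, strand); spacer
    # sequences between layout slots are themselves evolved on the tree
    layout: list[tuple[str, str]] = field(default_factory=list)
    spacer_alleles: list[dict[str, str]] = field(default_factory=list)

    @property
    def per_family_alignments(self) -> dict[str, AlignmentBlock]:
        out = {}
        for fam, by_strain in self.alleles.items():
            recs = tuple(SequenceRecord(s, by_strain[s]) for s in sorted(by_strain))
            out[fam] = AlignmentBlock(recs)
        return out

    def gene_records(self, strain: str) -> list[SequenceRecord]:
        """All genes carried by a strain (core, accessory, paralogs, markers)."""
        recs = []
        for fam in self.core_families + self.accessory_families:
            if strain in self.alleles[fam]:
                recs.append(SequenceRecord(f"{strain}|{fam}", self.alleles[fam][strain]))
        for gene_id, _fam, seq in self.paralogs.get(strain, []):
            recs.append(SequenceRecord(gene_id, seq))
        for i, seq in enumerate(self.marker_seqs.get(strain, []), 1):
            recs.append(SequenceRecord(f"{strain}|{MARKER_FAMILY}|{i}", seq))
        return recs

    def truth_family_of(self, gene_id: str) -> str:
        return gene_id.split("|")[1]


# ------------------------------------------------------------- species tree

def _random_ultrametric(names: Sequence[str], height: float, rng: np.random.Generator) -> Node:
    """Random binary ultrametric subtree; crown node sits exactly at ``height``."""
    if len(names) == 1:
        n = Node(names[0], height)
        return n
    node = Node()
    idx = rng.permutation(len(names))
    cut = int(rng.integers(1, len(names)))
    groups = ([names[i] for i in sorted(idx[:cut])], [names[i] for i in sorted(idx[cut:])])
    for grp in groups:
        if len(grp) == 1:
            node.add(Node(grp[0], height))
        else:
            hc = float(height * rng.uniform(0.3, 0.9))
            sub = _random_ultrametric(grp, hc, rng)
            sub.length = height - hc
            node.add(sub)
    return node


def strain_names(n_species: int, strains_per_species: Sequence[int]) -> tuple[list[str], dict[str, str]]:
    strains, species_of = [], {}
    for si in range(n_species):
        sp = f"species{si + 1:02d}"
        for j in range(strains_per_species[si]):
            name = f"sp{si + 1:02d}s{j + 1:02d}"
            strains.append(name)
            species_of[name] = sp
    return strains, species_of


def simulate_species_tree(
    n_species: int,
    strains_per_species: Sequence[int],
    within_species_div: float,
    between_species_div: float,
    seed: Union[int, np.random.Generator] = 0,
) -> PhyloTree:
    """Ultrametric strain tree: conspecific leaf pairs are ≤ 2×within deep,
    heterospecific pairs exactly 2×between deep."""
    if n_species < 1:
        raise SimulationError("n_species must be >= 1")
    if any(s < 1 for s in strains_per_species):
        raise SimulationError("every species needs at least one strain")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strains, species_of = strain_names(n_species, strains_per_species)
    by_species: dict[str, list[str]] = {}
    for s in strains:
        by_species.setdefault(species_of[s], []).append(s)
    if n_species == 1:
        only = list(by_species.values())[0]
        if len(only) == 1:
            raise SimulationError("a single species with one strain is not a tree")
        return PhyloTree(_random_ultrametric(only, within_species_div, rng))
    root = Node()
    for sp in sorted(by_species):
        members = by_species[sp]
        if len(members) == 1:
            root.add(Node(members[0], between_species_div))
        else:
            crown = _random_ultrametric(members, within_species_div, rng)
            crown.length = between_species_div - within_species_div
            crown.name = None
            root.add(crown)
    return PhyloTree(root)


# ------------------------------------------------------------ JC69 evolution

def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _seq_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    codes = np.searchsorted(_BASES, arr)
    return codes


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def mutate_jc69(codes: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """One JC69 draw over ``distance`` expected substitutions/site."""
    if distance < 0:
        raise SimulationError("negative branch length")
    if distance == 0:
        return codes.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    hit = rng.random(codes.size) < p_change
    out = codes.copy()
    if hit.any():
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def evolve_family(
    tree: PhyloTree,
    ancestral_seq: str,
    rate_multiplier: float = 1.0,
    seed: Union[int, np.random.Generator] = 0,
) -> AlignmentBlock:
    """Evolve ``ancestral_seq`` down ``tree`` under JC69; one record per leaf."""
    if len(ancestral_seq) < 1:
        raise SimulationError("ancestral sequence must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = _seq_to_codes(ancestral_seq)
    leaves: dict[str, np.ndarray] = {}

    def rec(node: Node, codes: np.ndarray) -> None:
        d = (node.length or 0.0) * rate_multiplier
        if (node.length or 0.0) < 0:
            raise SimulationError("negative branch length")
        here = mutate_jc69(codes, d, rng)
        if node.is_leaf:
            leaves[node.name] = here  # type: ignore[index]
        for c in node.children:
            rec(c, here)

    rec(tree.root, anc)
    recs = tuple(SequenceRecord(name, _codes_to_seq(leaves[name])) for name in sorted(leaves))
    return AlignmentBlock(recs)


# --------------------------------------------------------------- genus build

def simulate_genus(params: SimParams) -> SyntheticGenus:
    """Full simulation: tree, families, paralogs, markers, recombination,
    genome assembly. Deterministic in ``params.seed``."""
    ss = np.random.SeedSequence(params.seed)
    (tree_seed, fam_seed, acc_seed, par_seed, mark_seed,
     layout_seed, rec_seed, asm_seed) = ss.spawn(8)
    tree = simulate_species_tree(
        params.n_species, params.strains_per_species,
        params.within_species_div, params.between_species_div,
        np.random.default_rng(tree_seed),
    )
    strains, species_of = strain_names(params.n_species, params.strains_per_species)

    fam_rng = np.random.default_rng(fam_seed)
    alleles: dict[str, dict[str, str]] = {}
    core, accessory = [], []
    for k in range(params.n_core_genes):
        fam = f"fam{k + 1:05d}"
        core.append(fam)
        anc = random_sequence(params.gene_len, fam_rng)
        aln = evolve_family(tree, anc, 1.0, fam_rng)
        alleles[fam] = {r.id: r.seq for r in aln.records}

    acc_rng = np.random.default_rng(acc_seed)
    species_list = sorted(set(species_of.values()))
    for k in range(params.n_accessory_genes):
        fam = f"acc{k + 1:05d}"
        anc = random_sequence(params.gene_len, acc_rng)
        aln = evolve_family(tree, anc, 1.0, acc_rng)
        full = {r.id: r.seq for r in aln.records}
        if acc_rng.random() < params.accessory_clade_bias:
            sp = species_list[int(acc_rng.integers(len(species_list)))]
            present = [s for s in strains if species_of[s] == sp]
        else:
            # U-shaped occupancy: most accessory genes rare or near-universal
            f = float(acc_rng.beta(0.3, 0.3))
            mask = acc_rng.random(len(strains)) < f
            present = [s for s, m in zip(strains, mask) if m]
            if not present:
                present = [strains[int(acc_rng.integers(len(strains)))]]
        accessory.append(fam)
        alleles[fam] = {s: full[s] for s in present}

    par_rng = np.random.default_rng(par_seed)
    paralogs: dict[str, list[tuple[str, str, str]]] = {s: [] for s in strains}
    if params.paralog_rate > 0 and core:
        for s in strains:
            if par_rng.random() < params.paralog_rate:
                fam = core[int(par_rng.integers(len(core)))]
                src = _seq_to_codes(alleles[fam][s])
                dup = _codes_to_seq(mutate_jc69(src, PARALOG_DIVERGENCE, par_rng))
                paralogs[s].append((f"{s}|{fam}|p1", fam, dup))

    mark_rng = np.random.default_rng(mark_seed)
    anc_marker = random_sequence(params.marker_len, mark_rng)
    marker_aln = evolve_family(tree, anc_marker, MARKER_RATE, mark_rng)
    marker_by_strain = {r.id: r.seq for r in marker_aln.records}
    lo, hi = params.marker_copies_range
    marker_seqs = {
        s: [marker_by_strain[s]] * int(mark_rng.integers(lo, hi + 1)) for s in strains
    }

    genus = SyntheticGenus(
        params=params, strains=strains, truth_species=species_of, species_tree=tree,
        alleles=alleles, core_families=core, accessory_families=accessory,
        paralogs=paralogs, marker_seqs=marker_seqs,
    )
    _build_layout(genus, np.random.default_rng(layout_seed))
    apply_recombination(genus, params, np.random.default_rng(rec_seed))
    assemble_genomes(genus, np.random.default_rng(asm_seed))
    return genus


def _build_layout(genus: SyntheticGenus, rng: np.random.Generator) -> None:
    """One syntenic gene order + strand per genus, with homologous intergenic
    spacers evolved down the species tree (so genomes align end-to-end)."""
    p = genus.params
    fams = list(genus.core_families) + list(genus.accessory_families) + [MARKER_FAMILY]
    order = rng.permutation(len(fams))
    genus.layout = [
        (fams[int(i)], "+" if rng.random() < 0.5 else "-") for i in order
    ]
    lo, hi = p.spacer_len_range
    genus.spacer_alleles = []
    for _ in range(len(genus.layout) + 1):
        anc = random_sequence(int(rng.integers(lo, hi + 1)), rng)
        aln = evolve_family(genus.species_tree, anc, 1.0, rng)
        genus.spacer_alleles.append({r.id: r.seq for r in aln.records})


def apply_recombination(
    genus: SyntheticGenus,
    params: SimParams,
    seed: Union[int, np.random.Generator] = 0,
) -> list[RecombEvent]:
    """Overwrite a tract of the recipient's allele with the donor's, for a
    ``recomb_gene_fraction`` share of core families; ledger every event."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frac = params.recomb_gene_fraction
    if frac == 0:
        return []
    if params.n_species < 2:
        raise SimulationError("cross-species recombination requires >= 2 species")
    n_events = int(round(frac * len(genus.core_families)))
    chosen = rng.choice(len(genus.core_families), size=n_events, replace=False)
    events = []
    for idx in sorted(int(i) for i in chosen):
        fam = genus.core_families[idx]
        recipient = genus.strains[int(rng.integers(len(genus.strains)))]
        others = [s for s in genus.strains
                  if genus.truth_species[s] != genus.truth_species[recipient]]
        donor = others[int(rng.integers(len(others)))]
        gene_len = len(genus.alleles[fam][recipient])
        tract_len = max(1, int(round(params.recomb_tract_fraction * gene_len)))
        start = int(rng.integers(0, gene_len - tract_len + 1))
        end = start + tract_len
        old = genus.alleles[fam][recipient]
        new = old[:start] + genus.alleles[fam][donor][start:end] + old[end:]
        genus.alleles[fam][recipient] = new
        if genus.genomes:
            _patch_genome(genus, recipient, fam, new)
        ev = RecombEvent(fam, donor, recipient, (start, end))
        genus.truth_events.append(ev)
        events.append(ev)
    return events


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _patch_genome(genus: SyntheticGenus, strain: str, family: str, new_seq: str) -> None:
    for row in genus.gene_tables[strain]:
        if row.family_id == family and row.gene_id == f"{strain}|{family}":
            contig = genus.genomes[strain][row.contig]
            insert = new_seq if row.strand == "+" else revcomp(new_seq)
            genus.genomes[strain][row.contig] = (
                contig[: row.start] + insert + contig[row.end :]
            )
            return
    raise SimulationError(f"gene {family} not found in {strain} gene table")


def assemble_genomes(genus: SyntheticGenus, seed: Union[int, np.random.Generator] = 0) -> None:
    """Realize each strain's genome from the shared syntenic layout.

    Genes present in the strain are laid down in layout order with their
    homologous evolved spacers; extra marker copies and paralog duplicates
    are inserted at strain-specific positions. The result is split into 1–5
    contigs; coordinates are 0-based half-open per contig.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not genus.layout:
        _build_layout(genus, rng)
    lo, hi = genus.params.spacer_len_range
    genus.genomes.clear()
    genus.gene_tables.clear()
    for strain in genus.strains:
        # each slot = (spacer_seq, optional (gene_id, family, seq, strand))
        slots: list[tuple[str, Optional[tuple[str, str, str, str]]]] = []
        for idx, (fam, strand) in enumerate(genus.layout):
            spacer = genus.spacer_alleles[idx][strain]
            if fam == MARKER_FAMILY:
                gene = (f"{strain}|{MARKER_FAMILY}|1", fam,
                        genus.marker_seqs[strain][0], strand)
            elif strain in genus.alleles[fam]:
                gene = (f"{strain}|{fam}", fam, genus.alleles[fam][strain], strand)
            else:
                gene = None
            slots.append((spacer, gene))
        slots.append((genus.spacer_alleles[len(genus.layout)][strain], None))
        # strain-specific insertions: extra marker copies, then paralogs
        extras: list[tuple[str, str, str]] = []
        for i, seq in enumerate(genus.marker_seqs[strain][1:], 2):
            extras.append((f"{strain}|{MARKER_FAMILY}|{i}", MARKER_FAMILY, seq))
        for gene_id, fam, seq in genus.paralogs.get(strain, []):
            extras.append((gene_id, fam, seq))
        for gene_id, fam, seq in extras:
            pos = int(rng.integers(0, len(slots) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            spacer = random_sequence(int(rng.integers(lo, hi + 1)), rng)
            slots.insert(pos, (spacer, (gene_id, fam, seq, strand)))
        n_contigs = int(rng.integers(1, genus.params.max_contigs + 1))
        n_contigs = min(n_contigs, len(slots))
        cuts = sorted(rng.choice(np.arange(1, len(slots)), size=n_contigs - 1,
                                 replace=False).tolist()) if n_contigs > 1 else []
        groups = np.split(np.arange(len(slots)), cuts)
        contigs: dict[str, str] = {}
        rows: list[GeneRow] = []
        for ci, grp in enumerate(groups, 1):
            contig_name = f"{strain}_c{ci}"
            parts: list[str] = []
            pos = 0
            for si in grp:
                spacer, gene = slots[int(si)]
                parts.append(spacer)
                pos += len(spacer)
                if gene is not None:
                    gene_id, fam, seq, strand = gene
                    oriented = seq if strand == "+" else revcomp(seq)
                    rows.append(GeneRow(gene_id, fam, contig_name, pos,
                                        pos + len(oriented), strand))
                    parts.append(oriented)
                    pos += len(oriented)
            contigs[contig_name] = "".join(parts)
        genus.genomes[strain] = contigs
        genus.gene_tables[strain] = rows


# -------------------------------------------------------------------- output

def emit_genus(genus: SyntheticGenus, out_dir: Union[str, Path]) -> Path:
    """Write genome FASTAs, per-strain gene FASTAs + tables, per-family
    alignments, markers and truth tables under ``out_dir``."""
    out = Path(out_dir)
    for sub in ("genomes", "genes", "gene_tables", "alignments"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for strain in genus.strains:
        write_fasta(
            [SequenceRecord(c, s) for c, s in genus.genomes[strain].items()],
            out / "genomes" / f"{strain}.fna",
        )
        write_fasta(genus.gene_records(strain), out / "genes" / f"{strain}.ffn")
        with open(out / "gene_tables" / f"{strain}.tsv", "w") as fh:
            fh.write("gene_id\tfamily_id\tcontig\tstart\tend\tstrand\n")
            for r in genus.gene_tables[strain]:
                fh.write(f"{r.gene_id}\t{r.family_id}\t{r.contig}\t{r.start}\t{r.end}\t{r.strand}\n")
    for fam, aln in genus.per_family_alignments.items():
        write_fasta(list(aln.records), out / "alignments" / f"{fam}.fasta")
    markers = []
    for strain in genus.strains:
        for i, seq in enumerate(genus.marker_seqs[strain], 1):
            markers.append(SequenceRecord(f"{strain}|{MARKER_FAMILY}|{i}", seq))
    write_fasta(markers, out / "markers.fasta")
    with open(out / "truth_species.tsv", "w") as fh:
        fh.write("strain\tspecies\n")
        for s in genus.strains:
            fh.write(f"{s}\t{genus.truth_species[s]}\n")
    with open(out / "truth_events.tsv", "w") as fh:
        fh.write("family_id\tdonor\trecipient\ttract_start\ttract_end\n")
        for ev in genus.truth_events:
            fh.write(f"{ev.family_id}\t{ev.donor_strain}\t{ev.recipient_strain}"
                     f"\t{ev.tract[0]}\t{ev.tract[1]}\n")
    return out
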