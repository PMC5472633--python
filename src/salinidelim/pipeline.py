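"""End-to-end orchestration: simulate → orthologs → pangenome → recombination
screen → partitioned trees → ANI/gANI-AF delineation → markers/traits →
summary. One config, one seed, deterministic artifacts."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import ani as ani_mod
from . import markers_traits as mk
from . import pangenome as pg
from . import phylogenomics as ph
from . import recombination as rc
from .io_core import AlignmentBlock, PipelineConfig, SequenceRecord, write_matrix_tsv, write_newick
from .orthology import OrthoMatrix, all_vs_all_similarity, extract_core, mcl_cluster, og_stats
from .summary import RunSummary
from .synthetic_genus import SimParams, SyntheticGenus, emit_genus, simulate_genus

logger = logging.getLogger("salinidelim.pipeline")

DEFAULT_SIM = dict(
    n_species=3,
    strains_per_species=(4, 4, 4),
    n_core_genes=60,
    n_accessory_genes=40,
    within_species_div=0.01,
    between_species_div=0.06,
    recomb_gene_fraction=0.3,
    recomb_tract_fraction=0.5,
    paralog_rate=0.1,
)


class PipelineError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s ...", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("orthologs")
def ortholog_stage(genus: SyntheticGenus, cfg: PipelineConfig) -> OrthoMatrix:
    gene_seqs = {}
    for strain in genus.strains:
        for rec in genus.gene_records(strain):
            gene_seqs[rec.id] = rec.seq
    hits = all_vs_all_similarity(gene_seqs, cutoff=cfg.similarity_cutoff,
                                 min_coverage=cfg.evalue_analog_min_coverage)
    return mcl_cluster(hits, inflation=cfg.inflation, all_genes=list(gene_seqs))


def scc_alignments(genus_or_members, matrix: OrthoMatrix, scc_ogs) -> dict[str, AlignmentBlock]:
    """Per-SCC-OG alignment with strain ids as record labels."""
    from .orthology import strain_of_gene

    gene_seqs = {}
    if isinstance(genus_or_members, SyntheticGenus):
        for strain in genus_or_members.strains:
            for rec in genus_or_members.gene_records(strain):
                gene_seqs[rec.id] = rec.seq
    else:
        gene_seqs = dict(genus_or_members)
    out = {}
    for og in scc_ogs:
        recs = tuple(
            SequenceRecord(strain_of_gene(g), gene_seqs[g])
            for g in sorted(matrix.members[og], key=strain_of_gene)
        )
        out[og] = AlignmentBlock(recs)
    return out


def run_pipeline(
    out_dir: Union[str, Path],
    sim_params: Optional[SimParams] = None,
    config: Optional[PipelineConfig] = None,
    n_perm_recomb: Optional[int] = None,
    gene_trees: bool = True,
) -> RunSummary:
    """Run every stage on a simulated genus; write artifacts under
    ``out_dir`` and return the internally consistent RunSummary."""
    cfg = config or PipelineConfig()
    params = sim_params or SimParams(seed=cfg.rng_seed, **DEFAULT_SIM)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genus = simulate_genus(params)
    emit_genus(genus, out / "data")

    matrix = ortholog_stage(genus, cfg)
    core = extract_core(matrix)
    stats = og_stats(matrix, core)
    write_matrix_tsv(matrix.to_frame(), out / "og_counts.tsv")

    spectrum = pg.occupancy_spectrum(matrix, exclude_singletons=True)
    rich = pg.richness(matrix, extra_singletons=len(matrix.singletons))
    rare = pg.rarefy(matrix, n_perm=100, seed=cfg.rng_seed)
    rare.to_frame().to_csv(out / "rarefaction.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(spectrum.items()), columns=["occupancy", "n_ogs"]).to_csv(
        out / "occupancy_spectrum.tsv", sep="\t", index=False)

    alns = scc_alignments(genus, matrix, core.scc_ogs)
    report = rc.screen_genes(
        alns, alpha=cfg.alpha,
        n_perm=n_perm_recomb or cfg.n_permutations,
        seed=cfg.rng_seed, window=cfg.phi_window,
    )
    _write_recomb(report, out)

    genomes = {s: "".join(genus.genomes[s][c] for c in sorted(genus.genomes[s]))
               for s in genus.strains}
    ani_res = ani_mod.ani_matrix(genomes, fragment_len=cfg.fragment_len)
    gene_sets = {s: {r.id: r.seq for r in genus.gene_records(s)} for s in genus.strains}
    ani_res = ani_mod.gani_af_matrix(gene_sets, ani_res)
    for name in ("ani", "gani", "af"):
        write_matrix_tsv(ani_res.frame(name), out / f"{name}.tsv")
    part_ani = ani_mod.delineate_species(ani_res, "ani95", cfg.ani_species_threshold)
    part_gani = ani_mod.delineate_species(
        ani_res, "gani_af", gani_threshold=cfg.gani_threshold, af_threshold=cfg.af_threshold)
    pd.DataFrame({
        "strain": list(part_ani.assignment),
        "ani95": list(part_ani.assignment.values()),
        "gani_af": [part_gani.assignment[s] for s in part_ani.assignment],
    }).to_csv(out / "species_partition.tsv", sep="\t", index=False)
    dend = ani_mod.upgma(ani_mod.ani_distance_matrix(ani_res))
    write_newick(dend, out / "ani_dendrogram.nwk")

    trees = {}
    subsets = {
        "scc": sorted(alns),
        "recomb": sorted(report.recombinant_set),
        "mincore": sorted(report.minimum_core_set),
    }
    for name, subset in subsets.items():
        if not subset:
            continue
        block, _parts = ph.concatenate(alns, subset)
        trees[name] = ph.tree_from_alignment(block)
        write_newick(trees[name].midpoint_root(), out / f"{name}.nwk")

    assignment = part_ani.assignment
    n_incongruent = 0
    congruence_rows = []
    if gene_trees:
        for og in sorted(report.recombinant_set):
            gt = ph.tree_from_alignment(alns[og])
            res = ph.species_monophyly(gt, assignment, og)
            congruence_rows.append((og, res.incongruent, ";".join(res.offending_strains)))
            n_incongruent += int(res.incongruent)
        pd.DataFrame(congruence_rows, columns=["gene", "incongruent", "offending"]).to_csv(
            out / "congruence.tsv", sep="\t", index=False)

    markers = mk.MarkerSet.from_copies(genus.marker_seqs)
    try:
        pairs, fit = mk.snp_vs_ani(markers, ani_res)
        pairs.to_csv(out / "snp_vs_ani.tsv", sep="\t", index=False)
        (out / "snp_ani_fit.json").write_text(json.dumps(asdict(fit), indent=1))
    except mk.MarkerError as exc:
        logger.warning("marker regression skipped: %s", exc)

    presence = matrix.to_frame().astype(bool).astype(int)
    if presence.shape[1] >= 1:
        dendro = mk.trait_cluster(presence)
        write_newick(dendro, out / "trait_dendrogram.nwk")

    summary = RunSummary(
        n_strains=len(genus.strains),
        n_ogs=stats["n_ogs"],
        n_singletons=stats["n_singletons"],
        core_size=stats["core_size"],
        scc_size=len(report.results),
        n_recombinant=len(report.recombinant_set),
        n_minimum_core=len(report.minimum_core_set),
        n_incongruent=n_incongruent,
        n_candidate_species_ani=len(set(part_ani.assignment.values())),
        n_candidate_species_gani_af=len(set(part_gani.assignment.values())),
        chao=rich.chao,
        ace=rich.ace,
    )
    (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=1))
    (out / "summary.txt").write_text(summary.format_text() + "\n")
    return summary


def _write_recomb(report: rc.RecombReport, out: Path) -> None:
    rows = [(r.gene_id, r.phi_stat, r.phi_p, r.maxchi_stat, r.maxchi_p,
             r.nss_stat, r.nss_p, r.testable, r.recombinant) for r in report.results]
    pd.DataFrame(rows, columns=["gene", "phi", "phi_p", "maxchi", "maxchi_p",
                                "nss", "nss_p", "testable", "recombinant"]).to_csv(
        out / "recombination.tsv", sep="\t", index=False)
    (out / "recombinant.txt").write_text("\n".join(sorted(report.recombinant_set)) + "\n")
    (out / "minimum_core.txt").write_text("\n".join(sorted(report.minimum_core_set)) + "\n")
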