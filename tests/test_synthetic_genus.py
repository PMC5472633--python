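import math
from pathlib import Path

import numpy as np
import pytest

from salinidelim.io_core import read_fasta
from salinidelim.synthetic_genus import (
    MARKER_FAMILY,
    RecombEvent,
    SimParams,
    SimulationError,
    apply_recombination,
    emit_genus,
    evolve_family,
    revcomp,
    simulate_genus,
    simulate_species_tree,
)
from salinidelim.tree import is_ultrametric


def base_params(**kw):
    defaults = dict(
        n_species=3, strains_per_species=(2, 2, 2),
        n_core_genes=8, n_accessory_genes=4,
        within_species_div=0.01, between_species_div=0.06,
        gene_len=300, marker_len=600, seed=5,
    )
    defaults.update(kw)
    return SimParams(**defaults)


class TestParams:
    def test_divergence_ordering_enforced(self):
        with pytest.raises(SimulationError):
            base_params(within_species_div=0.1, between_species_div=0.05)

    def test_zero_strains_rejected(self):
        with pytest.raises(SimulationError):
            base_params(strains_per_species=(2, 0, 2))


class TestSpeciesTree:
    def test_single_species_cherry(self):
        t = simulate_species_tree(1, [2], 0.01, 0.05, seed=1)
        assert sorted(t.leaf_names()) == ["sp01s01", "sp01s02"]
        assert len(t.leaves()) == 2

    def test_species_monophyletic_by_construction(self):
        t = simulate_species_tree(3, [2, 2, 2], 0.01, 0.05, seed=1)
        splits = t.bipartitions(trivial=False)
        leaves = frozenset(t.leaf_names())
        anchor = min(leaves)
        for sp in ("sp02", "sp03"):  # sp01 contains the anchor
            members = frozenset(l for l in leaves if l.startswith(sp))
            assert members in splits

    def test_ultrametric(self):
        t = simulate_species_tree(4, [3, 2, 2, 1], 0.01, 0.07, seed=2)
        assert is_ultrametric(t)

    def test_between_paths_exceed_within(self):
        # [DERIVED] oracle: compute path lengths on the emitted tree
        t = simulate_species_tree(3, [3, 3, 3], 0.01, 0.06, seed=3)
        _, dist = t.leaf_distances()
        within = [v for (a, b), v in dist.items() if a[:4] == b[:4]]
        between = [v for (a, b), v in dist.items() if a[:4] != b[:4]]
        assert max(within) < min(between)
        assert all(abs(v - 0.12) < 1e-9 for v in between)
        assert all(v <= 0.02 + 1e-9 for v in within)


class TestEvolveFamily:
    def test_zero_rate_identical(self):
        t = simulate_species_tree(2, [2, 2], 0.01, 0.05, seed=4)
        aln = evolve_family(t, "ACGT" * 50, rate_multiplier=0.0, seed=1)
        assert {r.seq for r in aln.records} == {"ACGT" * 50}

    def test_jc_expected_p_distance(self):
        # [DERIVED] closed-form JC: E[p] = 3/4 (1 - exp(-4 d / 3)), d = total path
        from salinidelim.tree import cherry

        d = 0.1
        t = cherry("x", "y", d / 2, d / 2)
        expect = 0.75 * (1 - math.exp(-4 * d / 3))
        rng = np.random.default_rng(0)
        ps = []
        L = 10_000
        for rep in range(200):
            aln = evolve_family(t, "ACGT" * (L // 4), 1.0, rng)
            a, b = aln.records
            ps.append(sum(1 for x, y in zip(a.seq, b.seq) if x != y) / L)
        se = np.std(ps, ddof=1) / math.sqrt(len(ps))
        assert abs(np.mean(ps) - expect) < 3 * max(se, 1e-4)

    def test_deeper_pair_more_divergent(self):
        from salinidelim.tree import cherry

        rng = np.random.default_rng(1)
        shallow, deep = [], []
        for _ in range(100):
            a1 = evolve_family(cherry("x", "y", 0.01, 0.01), "ACGT" * 250, 1.0, rng)
            a2 = evolve_family(cherry("x", "y", 0.05, 0.05), "ACGT" * 250, 1.0, rng)
            for aln, acc in ((a1, shallow), (a2, deep)):
                x, y = aln.records
                acc.append(sum(1 for p, q in zip(x.seq, y.seq) if p != q))
        assert np.mean(deep) > np.mean(shallow)

    def test_negative_branch_rejected(self):
        from salinidelim.tree import cherry

        t = cherry("x", "y", -0.1, 0.1)
        with pytest.raises(SimulationError):
            evolve_family(t, "ACGT", 1.0, 1)


class TestRecombination:
    def test_zero_fraction_no_events(self):
        g1 = simulate_genus(base_params(recomb_gene_fraction=0.0))
        assert g1.truth_events == []

    def test_whole_allele_replacement(self):
        g = simulate_genus(base_params(recomb_gene_fraction=0.25,
                                       recomb_tract_fraction=1.0, seed=9))
        assert g.truth_events
        for ev in g.truth_events:
            assert g.alleles[ev.family_id][ev.recipient_strain] == \
                g.alleles[ev.family_id][ev.donor_strain]
            assert g.truth_species[ev.donor_strain] != g.truth_species[ev.recipient_strain]

    def test_partial_tract(self):
        params = base_params(recomb_gene_fraction=0.0)
        g = simulate_genus(params)
        pre = {f: dict(g.alleles[f]) for f in g.core_families}
        tract_params = base_params(recomb_gene_fraction=0.25, recomb_tract_fraction=0.5)
        events = apply_recombination(g, tract_params, seed=3)
        assert events
        for ev in events:
            s, e = ev.tract
            donor = pre[ev.family_id][ev.donor_strain]
            old = pre[ev.family_id][ev.recipient_strain]
            new = g.alleles[ev.family_id][ev.recipient_strain]
            assert new[s:e] == donor[s:e]
            assert new[:s] == old[:s] and new[e:] == old[e:]

    def test_genome_patched_after_assembly(self):
        params = base_params(recomb_gene_fraction=0.0)
        g = simulate_genus(params)
        tract_params = base_params(recomb_gene_fraction=0.2, recomb_tract_fraction=1.0)
        events = apply_recombination(g, tract_params, seed=4)
        for ev in events:
            row = next(r for r in g.gene_tables[ev.recipient_strain]
                       if r.family_id == ev.family_id and "|p" not in r.gene_id)
            sl = g.genomes[ev.recipient_strain][row.contig][row.start:row.end]
            if row.strand == "-":
                sl = revcomp(sl)
            assert sl == g.alleles[ev.family_id][ev.recipient_strain]

    def test_single_species_rejected(self):
        with pytest.raises(SimulationError):
            simulate_genus(SimParams(
                n_species=1, strains_per_species=(4,), n_core_genes=4,
                n_accessory_genes=0, within_species_div=0.01,
                between_species_div=0.05, gene_len=200,
                recomb_gene_fraction=0.5, seed=1))


class TestGenusInvariants:
    def test_marker_copies_identical_and_in_range(self, small_genus):
        lo, hi = small_genus.params.marker_copies_range
        for strain, copies in small_genus.marker_seqs.items():
            assert lo <= len(copies) <= hi
            assert len(set(copies)) == 1

    def test_gene_intervals_within_bounds(self, small_genus):
        for strain, rows in small_genus.gene_tables.items():
            for r in rows:
                contig = small_genus.genomes[strain][r.contig]
                assert 0 <= r.start < r.end <= len(contig)

    def test_clean_genus_family_trees_match_species(self):
        # clean sim, long genes: every family tree keeps species monophyletic
        from salinidelim.phylogenomics import species_monophyly, tree_from_alignment

        g = simulate_genus(base_params(
            n_core_genes=5, n_accessory_genes=0, gene_len=5000,
            between_species_div=0.06, seed=21))
        for fam, aln in g.per_family_alignments.items():
            t = tree_from_alignment(aln)
            res = species_monophyly(t, g.truth_species, fam)
            assert not res.incongruent, fam

    def test_accessory_occupancy_u_shape(self):
        from salinidelim.orthology import OrthoMatrix

        g = simulate_genus(base_params(
            n_species=3, strains_per_species=(4, 4, 4),
            n_core_genes=30, n_accessory_genes=60,
            accessory_clade_bias=0.3, seed=8))
        n = len(g.strains)
        occ = [len(g.alleles[f]) for f in g.accessory_families + g.core_families]
        counts = np.bincount(occ, minlength=n + 1)
        mid = counts[3 : n - 2]
        # mass concentrates at the extremes (rare or universal)
        assert counts[1] + counts[2] > mid.mean() * 2
        assert counts[n] > mid.mean() * 2


class TestEmission:
    def test_file_counts_and_roundtrip(self, small_genus, tmp_path):
        out = emit_genus(small_genus, tmp_path / "genus")
        strains = small_genus.strains
        assert len(list((out / "genomes").glob("*.fna"))) == len(strains)
        assert len(list((out / "gene_tables").glob("*.tsv"))) == len(strains)
        assert (out / "truth_species.tsv").exists()
        # re-slice genomes by emitted coordinates and compare to gene records
        for strain in strains:
            contigs = {r.id: r.seq for r in read_fasta(out / "genomes" / f"{strain}.fna")}
            genes = {r.id: r.seq for r in read_fasta(out / "genes" / f"{strain}.ffn")}
            table = (out / "gene_tables" / f"{strain}.tsv").read_text().splitlines()[1:]
            assert table
            for line in table:
                gene_id, fam, contig, start, end, strand = line.split("\t")
                sl = contigs[contig][int(start):int(end)]
                if strand == "-":
                    sl = revcomp(sl)
                assert sl == genes[gene_id]

    def test_determinism(self, tmp_path):
        p = base_params(recomb_gene_fraction=0.2, paralog_rate=0.3, seed=13)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        emit_genus(simulate_genus(p), d1)
        emit_genus(simulate_genus(p), d2)
        files1 = sorted(f.relative_to(d1) for f in d1.rglob("*") if f.is_file())
        files2 = sorted(f.relative_to(d2) for f in d2.rglob("*") if f.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
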