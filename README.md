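# salinidelim

Phylogenomic species delineation for a genus of closely related bacteria, as a
reusable desk-scale pipeline:

1. **synthetic_genus** — simulates a genus with known species structure:
   ultrametric species tree, single-copy core families, clade-biased accessory
   families, sporadic paralogs, tract-level cross-species homologous
   recombination, and a slow-evolving multi-copy 16S-like marker. Emits
   genomes, gene tables, per-family alignments and truth tables, so every
   downstream stage is testable without downloads.
2. **orthology** — all-vs-all nucleotide similarity (exact 16-mer seeding +
   ungapped extension; identity cutoff 70%, coverage ≥ 0.5), Markov clustering
   (inflation 1.5), paralog flagging, core / single-copy-core extraction.
3. **pangenome** — pan/core rarefaction (exact means + permutation SE),
   occupancy spectra, incidence-based Chao1 and ACE richness.
4. **recombination** — PHI, MaxChi and NSS with seeded permutation p-values
   (add-one formula); genes partitioned into a recombinant set and the
   "minimum core" (default decision rule: PHI p < 0.01).
5. **phylogenomics** — JC69 distances, neighbor joining, column bootstrap,
   midpoint rooting, concatenated trees for the SCC / recombinant /
   minimum-core partitions, species-monophyly congruence scoring and
   Robinson–Foulds comparison. Externally computed Newick trees are accepted
   for all congruence operations.
6. **ani** — fragment-based ANI (1020-nt windows, 30%-identity / 70%-coverage
   hit filters), gene-based gANI + alignment fraction from bidirectional best
   hits, the 100−ANI distance matrix, UPGMA dendrogram, and threshold species
   delineation (ANI ≥ 95, or gANI > 96.5 & AF > 0.6; single-linkage components
   with per-component clique purity).
7. **markers_traits** — 16S SNP counting, the SNP-vs-ANI regression (reports
   the SNP count at the fitted 95% ANI crossing), Jaccard average-linkage
   clustering of binary trait tables, adjusted-Rand partition agreement.
8. **cli / pipeline** — one config, one seed, end-to-end deterministic run
   with a consistency-checked summary.

## CLI

```bash
salinidelim run --seed 7 --out runs/demo          # full simulated pipeline
salinidelim simulate --config sim.yaml --out data # synthetic genus + truth
salinidelim orthologs --genes data/genes --out ogs
salinidelim pangenome --matrix ogs/og_counts.tsv --perms 100 --out pan
salinidelim recomb --alignments data/alignments --alpha 0.01 --perms 1000 --out rec
salinidelim trees --alignments data/alignments --boot 100 --out scc.nwk
salinidelim congruence --tree scc.nwk --assignment data/truth_species.tsv
salinidelim ani --genomes data/genomes --fragment-len 1020 --out ani
salinidelim markers --markers data/markers.fasta --ani ani/ani.tsv --out mk
salinidelim traits --table traits.tsv --out traits.nwk
```

Every subcommand also runs standalone on user-supplied data (genome FASTAs,
per-strain gene FASTAs/tables, aligned per-gene FASTAs, binary trait TSVs).

## Conventions

* Sequences upper-case over `{A,C,G,T,N,-}`; `U` → `T`, anything else → `N`.
* All coordinates are 0-based half-open (gene tables, recombination tracts).
* Newick support values are written as internal-node labels; branch lengths
  to 6 decimals.
* Reciprocal ANI/gANI/AF values are averaged into symmetric matrices.
* All randomness flows from one seed; equal config + seed ⇒ byte-identical
  outputs.
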