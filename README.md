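# phagetax

Genome-based taxonomy for bacteriophage populations.

Sequencing has outpaced phage taxonomy: collections such as the
*Acinetobacter* phages grew from a few dozen to well over a hundred genomes
(31–378 kb) in a few years, and assigning new isolates to genera and
subfamilies now rests on whole-genome metrics rather than morphology.
`phagetax` implements that workflow as a reusable pipeline for anyone
classifying a set of phage genomes:

1. **Intergenomic nucleotide similarity** — reciprocal, length-normalised
   local alignment of every genome pair,

   `sim% = 100 · (id_ab + id_ba) / (len_a + len_b)`,

   with identities aggregated over merged, non-overlapping HSPs (word size
   7, match +2, mismatch −3; built-in seed-and-extend aligner or an external
   `blastn` backend).
2. **Protein groups ("phams")** — single-linkage clustering of all
   translated CDSs with BLOSUM62 local alignment at ≥35% identity and ≥50%
   coverage of both sequences; single-member groups are orphams.
3. **Two-tier taxonomy** — sub-clusters (genera) as connected components at
   ≥65% nucleotide similarity, species at ≥95%; clusters (subfamilies) by
   complete-linkage clustering of shared protein content cut at 30%, with
   sub-clusters kept atomic; genomes related to nothing are singletons.
4. **Pangenome partition** — per-cluster core / accessory / unique protein
   groups, with exclusive-core counts and `N/A` handling for single-genome
   clusters.
5. **Network export** — binary gene presence/absence matrix, Jaccard-style
   genome-content distances, NEXUS output for splits-network software, and
   a leaf-ordered heatmap table.
6. **Synthetic populations** — a seeded generator that plants clusters,
   genera, species, gene families and singletons with controlled divergence
   and gene sharing, so every stage is testable against known truth without
   downloading anything.

## Worked example

Simulate the demo population (3 planted clusters × 2 genera × 3 genomes
plus 2 singletons, ~8 kb genomes) and run the full pipeline on it:

```bash
phagetax simulate --seed 42 --out demo_fixture
phagetax init-config --out run.yaml        # then set input_paths/out_dir
```

or from Python:

```python
from phagetax import PopulationConfig, simulate_population, similarity_matrix
from phagetax.pipeline import RunConfig, run_all

genomes, truth = simulate_population(PopulationConfig(rng_seed=42))
manifest = run_all(RunConfig(out_dir="demo_out"), genomes=genomes)
```

`demo_out/` then contains `similarity.tsv`, `groups.tsv`,
`shared_content.tsv`, `taxonomy.tsv`, `pangenome.tsv`,
`content_distance.nex`, `heatmap.tsv` and a `manifest.json` with checksums.
The taxonomy table assigns each genome a cluster letter and sub-cluster
number (`A1`, `B2`, …) and flags singletons; with the demo conditions the
planted structure is recovered exactly — e.g. the similarity matrix shows
≈88% within genera, ≈33% between genera of the same cluster and 100.0 on
the diagonal, and `pangenome.tsv` reports for every multi-genome cluster

```
cluster_id  n_genomes  n_core  n_accessory  n_unique  n_core_exclusive  n_shared
A           6          6       10           6         5                 N/A
```

exactly the planted design (6 core families of which 1 is shared with other
clusters, 5 accessory per genus, 1 private gene per genome), while the two
singleton rows show `N/A` core/accessory counts.

To compare real records (e.g. reproduce published pairwise similarities for
named phage pairs), download the GenBank files and run:

```bash
python scripts/pairwise_compare.py AM24.gb R2096.gb
```

which prints the nucleotide similarity and shared-protein percentage for
the pair.

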