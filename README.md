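# taxoforce

Taxogenomic genus delineation and environmental-forcing analysis for
bacterial genome collections.

## What it does

Modern prokaryotic taxonomy above the species rank leans on whole-genome
relatedness indices rather than 16S rRNA identity. Given a set of genomes
(e.g. a family like *Stappiaceae* whose genera are tangled), `taxoforce`
answers two questions:

1. **Where is the genus boundary?** Average amino-acid identity (AAI) is
   computed for every genome pair from reciprocal best protein hits. The
   symmetric AAI matrix is then clustered by single linkage at *every*
   observed threshold: the partition of genomes into connected components of
   the graph with edges S ≥ t only changes when t crosses an observed value,
   so the threshold axis decomposes into **stable intervals** `[lo–hi]`,
   each carrying one candidate genus partition. Candidates are ranked
   against a reference phylogenomic grouping by adjusted Rand index (then
   fewest forbidden merges, fewest singletons, widest interval); the
   top-ranked interval is the proposed genus threshold. Species-level calls
   use OrthoANI-style average nucleotide identity (same species at ANI ≥ 96,
   different below 95, the 95–96 band ambiguous) together with digital DDH
   at its 70 % boundary, and the percentage of conserved proteins (POCP,
   `100·(C1+C2)/(T1+T2)`) is available as the classical genus index.

2. **How much of the gene content is environmental?** The pangenome's
   binary genome × CDS-cluster matrix Y is analysed by canonical
   correspondence analysis (CCA) constrained on habitat categories: the
   chi-square residual matrix `Q = (P − rcᵀ)/√(rcᵀ)` is projected onto the
   weighted-centred habitat indicators and decomposed by SVD. The ratio of
   constrained to total inertia is the fraction of gene-content variation
   forced by the **environment**; its complement is attributed to
   **phylogeny**. A label-permutation test calibrates the constrained
   fraction, and habitat-specific CDS are called both from ordination
   scores (|score| > 0.15 toward a habitat's centroid direction) and from
   strict/relaxed habitat exclusivity, with a KEGG-module completeness rule
   (at most one missing component) for metabolic interpretation.

A seeded synthetic-data module generates ground-truthed inputs for both
analyses — planted genus blocks with a known threshold gap, and pangenomes
with core, clade-driven and habitat-driven genes — so the whole pipeline is
testable without downloads.

## Worked example

```python
from taxoforce import (GenusDelineation, PangenomeCCA,
                       simulate_similarity_matrix, simulate_pangenome)
from taxoforce.simulate import study_matrix_config, study_pangenome_config

# 38 genomes in 17 planted genus blocks, intra-genus AAI ≥ 78.5, inter ≤ 71.9
S, truth = simulate_similarity_matrix(study_matrix_config(seed=1))
res = GenusDelineation(S, reference=truth.partition).fit()
best = res.optimal
print(best.interval, "ARI:", best.ari_vs_reference)

# 16 genomes over six habitats, ~4 600 CDS clusters
pa, design, _ = simulate_pangenome(study_pangenome_config(seed=1))
cca = PangenomeCCA(pa, design).fit()
print(f"axes: {cca.n_axes}, environmental: {100*cca.env_fraction:.1f}%, "
      f"phylogenetic: {100*cca.phylo_fraction:.1f}%")
```

prints

```
StableInterval([78.90–79.00], 17 clusters) ARI: 1.0
axes: 5, environmental: 58.8%, phylogenetic: 41.2%
```

The first line is the top-ranked stable run: thresholds from just above the
largest inter-genus value up to 79.00 all yield the planted 17-genus
partition (78.90 is the smallest intra-genus AAI drawn; above 79.00 a genus
starts to fragment), and it matches the reference exactly (ARI 1). The second
says six habitat categories span five constrained ordination axes and that
habitat explains 58.8 % of the chi-square inertia of this synthetic
pangenome — high because its planted habitat effects and the clade/habitat
overlap are both counted as habitat-explained.

The same stages are scriptable from the shell:

```sh
taxoforce simulate matrix --out sim --seed 1
taxoforce delineate --matrix sim/matrix.tsv --reference groups.tsv \
    --out candidates.tsv --dendrogram tree.nwk
taxoforce cca --pa gene_presence_absence.csv --habitats habitats.tsv --out cca_dir/
taxoforce habitat-genes --cca cca_dir/ --pa matrix.tsv --habitats habitats.tsv \
    --cutoff 0.15 --out calls/
```

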