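# cazymeta

Genome-resolved analysis of carbohydrate-active enzymes (CAZymes) in
microbial communities. The package takes the standard annotation artifacts
produced for a set of metagenome-assembled genomes (MAGs) — HMMER
`domtblout` searches against CAZyme HMM databases, DIAMOND/BLAST tabular
hits against protein databases, gene tables, per-contig coverage and
gene × sample read-pair counts — and turns them into per-gene CAZy family,
EC-number and substrate annotations, CAZyme-gene-cluster (CGC/PUL) calls,
and MAG-level presence/expression summaries suitable for community ecology.

It is aimed at microbiome researchers who already have MAGs and mapped
metagenome/metatranscriptome reads and want a tested, reproducible
implementation of the downstream CAZyme analysis.

## What it computes

**Family annotation.** Domain hits are filtered (independent-domain
E-value < 1 × 10⁻¹⁸, profile coverage ≥ 35%) and reduced per gene to a
non-overlapping set: a pair of matches may share at most 50% of the
shorter alignment. Surviving hits define the gene's CAZy families (a gene
can carry several, e.g. GH13 + CBM48).

**EC assignment.** A four-rule cascade, stopping at the first rule that
yields an EC: (1) curated subfamily (dbCAN-sub-style) metadata on
surviving subfamily hits; (2) DRAM-derived KO ECs that agree with the
family's curated EC list; (3) same-family hits to characterised CAZy
proteins (E < 1 × 10⁻¹⁰², identity ≥ 35%, query coverage ≥ 70%);
(4) BLAST-derived KEGG KO ECs with the rule-2 agreement check.

**Substrates.** A gene maps to a substrate category only when one of its
(family, EC) pairs is a curated key of the substrate table.

**CGC detection.** Signature genes (CAZyme, transcription factor,
signal-transduction protein, transporter) chain into a cluster when at
most two non-signature genes separate consecutive signature genes; a
cluster needs ≥ 1 CAZyme and ≥ 1 other signature gene. Cluster substrates
come from PUL-database homology ranked by summed bitscores (method B) and
from majority voting over member-gene substrates (method C).

**Quantification.** A MAG is present in a sample when reads cover ≥ 10% of
its genome (contig-length-weighted breadth); gene counts below five read
pairs are zeroed before TPM normalisation (TPM_g = 10⁶ · r_g / Σr, with
r_g = count_g/(length_g/1000)); per-capita expression divides a genome's
summed TPM by its mean fold-coverage.

**Ecology.** Richness partitions, inverse Simpson diversity (1/Σp²),
Bray–Curtis dissimilarity (Σ|x−y|/Σ(x+y)), Spearman correlations,
Mann–Whitney habitat comparisons, and the per-substrate expressing
fraction (populations expressing / populations encoding, classified
against a slope-0.5 line).

Because real studies hinge on external databases, the package ships a
seeded synthetic-community generator (`cazymeta.simulate`) that emits the
full fixture file set with a ground-truth ledger, so every stage is
testable end to end without downloads.

## Worked example

```bash
cazymeta simulate --seed 3 --out fx --genomes-per-habitat 4 --noise-free
cazymeta run-all --in-dir fx --out-dir out
```

writes `annotations.tsv`, `cgcs.tsv`, `tpm.tsv`, `presence.tsv`,
`substrate_activity.tsv` and a checksum manifest under `out/`. The same
chain drives the numbered analysis scripts; for example

```bash
python analysis/02_annotate_cazymes.py
```

prints (seed 1, 25 genomes per habitat, noise-free):

```
470 CAZyme genes annotated (100.0% family agreement with planted truth, 100.0% EC agreement)
EC evidence routes: {'RULE1': 276, 'RULE4': 41, 'NONE': 48, 'RULE2': 64, 'RULE3': 41}
substrate census covers 8 categories; tables in results/ec_sources.tsv and results/substrate_census.tsv
```

i.e. all 470 planted CAZyme genes are recovered with exactly their planted
families and ECs; the route counts show which cascade rule fired for each
gene, and 48 genes were planted without EC evidence and correctly left
unassigned. `analysis/03_detect_cgcs.py` reports precision = recall = 1.0
for 200 planted clusters against 200 decoy loci, with both substrate
methods agreeing with the planted substrate on every cluster.

## Layout

- `src/cazymeta/` — library: `io_formats`, `annotation`, `ec`,
  `substrates`, `cgc`, `quant`, `ecology`, `simulate`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `tests/` — pytest suite, including property tests with exhaustive
  oracles for the combinatorial kernels
- `docs/methods.md` — model, parameters and design notes
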