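# Methods

## Scope and data model

The package implements the computational stages that sit *after* the heavy
bioinformatics of a genome-resolved CAZyme study: assembly, binning,
quality control, read mapping and fragment counting are upstream tools
whose outputs (gene tables, HMMER per-domain tables, DIAMOND tabular hits,
per-contig coverage, count matrices) are consumed as plain-text tables.
All parsing lives in `io_formats`; downstream modules operate on typed
records (`DomainHit`, `AlignmentHit`, `GeneRecord`, `CazymeAnnotation`,
`CGC`) only. Coordinates are 1-based inclusive throughout, matching both
HMMER and GFF conventions. The `domtblout` reader defaults to the
`hmmsearch` orientation (profile = query, protein = target) with a flag
for the `hmmscan` transpose; a trailing `.hmm` on profile names is
stripped and subfamily labels such as `GH16_3` are kept distinct from
their parent family.

## Family annotation

Hits are filtered on the independent-domain E-value (strictly below
1 × 10⁻¹⁸) and profile coverage ((hmm_to − hmm_from + 1)/hmm_length,
at least 0.35). Coverage is measured on the HMM profile, not the query,
which is what "domain coverage" means in the dbCAN tool lineage, and the
independent-domain E-value is the filtered statistic rather than the
full-sequence one.

Overlap resolution reduces each gene's surviving hits to a set in which no
pair overlaps by more than 50% of the shorter alignment. The published
parser scripts in this lineage do not document a tie-break, so the
procedure here is fully deterministic: candidates are ranked by
(i-E-value ascending, alignment length descending, family label,
alignment start) and accepted greedily against all previously accepted
hits. Filtering precedes overlap resolution; a regression test pins a case
where the reverse order changes the outcome (a high-scoring,
low-coverage hit evicting a legitimate neighbour before being filtered
away itself). The greedy selection is verified against exhaustive subset
enumeration on thousands of random instances. Whether the original
tooling compared the overlap against the shorter hit or either hit is not
knowable from its description; the shorter-alignment convention used here
is the one its ancestor script implements.

## EC cascade

Four evidence routes are consulted strictly in order, stopping at the
first that yields at least one EC; the firing rule is recorded as
provenance. Rule 2 and rule 4 "agreement" is implemented as set
intersection between the KO's EC metadata and the union of curated EC
lists of the gene's assigned families. When a rule yields several ECs all
are kept — downstream substrate matching unions over them. Partial EC
strings ("3.2.1.-") are legal and compared literally; no EC-hierarchy
reasoning is attempted. The cascade provably never emits an EC absent
from its evidence inputs, and an exhaustive test covers all 16
presence/absence patterns of the four evidence types.

## Substrate matching

A substrate is assigned only when (family, EC) co-occur as a curated key:
this is the stricter reading of matching both identifiers against a
curated table, and it prevents an EC shared across families from dragging
in a substrate the family does not act on. Family-only (EC-less) curated
rows are deliberately unsupported. The curated map is an input file; the
repository generates a synthetic map for tests rather than shipping a
frozen copy of any public database.

## CGC detection and substrates

"At most two genes apart" is read as ≤ 2 intervening non-signature genes
between consecutive signature genes, the CGC-Finder semantics this
definition paraphrases. A maximal chain qualifies as a cluster iff it
contains ≥ 1 CAZyme and ≥ 1 other signature gene; the span runs from
first to last signature member, so interior nulls are members but
flanking nulls are not, and contig boundaries terminate chains. Genes with
multiple evidence types take the role precedence CAZyme > transporter >
transcription factor > signal-transduction protein, CAZyme membership
being the cluster-defining property. Signature-evidence thresholds
(TF/STP HMM: E < 1e-4, coverage ≥ 0.35; TCDB: E ≤ 1e-10, query coverage
≥ 35%; tcDoms: E < 1e-4) follow the defaults of the annotation suite this
pipeline models and are exposed in `RunConfig`.

Method B (homology) keeps PUL hits with E < 1 × 10⁻¹⁰², sums the best
bitscore per (member gene, PUL) pair — best-per-pair prevents multi-HSP
double counting — and ranks candidate PULs, requiring the matched subject
proteins to include a CAZyme and another signature role; ties break on
PUL identifier. Method C (voting) gives each member gene one vote per
distinct substrate it carries and requires the winning tally to reach 2:
a one-vote "majority" is uninformative. Both knobs are config-exposed.
The generalised adjacent-pair counter (`count_gene_pairs`) implements the
susCD-style tally; strict adjacency (indices differing by 1) is required.

## Quantification

Genome quality filtering keeps completeness ≥ 50% and contamination ≤ 5%
(both inclusive). Genome breadth and depth are contig-length-weighted
means; presence requires breadth ≥ 0.10. The five-read-pair floor is
applied per gene *per sample* (cell-wise): the per-sample framing of TPM
makes the cell-wise reading the coherent one, and the alternative
(per gene across samples) is a one-line config change. TPM is computed
per sample with the denominator over *all* genes in the table, not
CAZyme genes only — TPM is defined against the full transcriptome and
subsetting happens after normalisation. Per-capita expression is the
genome's summed TPM divided by its mean fold-coverage; zero depth yields
a missing value, never zero. Multi-EC genes contribute their full TPM to
each of their ECs in the aggregation tables (the grouped quantities are
per-activity, not a partition of reads).

## Ecology statistics

Inverse Simpson (1/Σp²) and Bray–Curtis (Σ|x−y|/Σ(x+y)) are computed
directly from their definitions and cross-checked in tests against
scipy's distance implementation and closed-form identities. Spearman and
Mann–Whitney go through scipy: Spearman uses average ranks and the
t-approximation for the p-value; the rank-sum comparison uses exact
enumeration when both groups have ≤ 8 tie-free observations and the
normal approximation with tie and continuity corrections otherwise,
matching R's `wilcox.test` behaviour. No multiple-testing correction is
applied to habitat comparisons because the machinery reproduces
per-comparison statistics only. The expressing fraction counts, per
substrate and habitat, MAGs present in ≥ 1 habitat sample that encode
≥ 1 gene for the substrate, and of those the MAGs with ≥ 1 such gene
expressed (≥ 5 read pairs) in ≥ 1 habitat sample; fractions are
classified against the 0.5 line and undefined (not zero) when nothing
encodes the substrate.

## Synthetic community generator

The generator emulates the statistical structure the analysis assumes:
two habitats (water, sediment) with per-habitat sample sets, genomes of
2–4 contigs with 8–20 genes of 300–2400 nt, habitat-dependent CAZyme
density and family pools, planted clusters and decoy loci, and
habitat-dependent expression states with overdispersed counts. The
estuary scenario plants the qualitative contrast the analysis is meant to
resolve: sediment genomes encode CAZymes more densely (p = 0.30 vs 0.15)
over a GH-richer family pool, while water genomes express a larger
fraction of what they encode (expression probability 0.85 vs 0.45).

Margins are engineered, not sampled: true domain hits draw E-values in
[10⁻⁴⁰, 10⁻¹⁹] with coverage ≥ 0.40, decoys in [10⁻¹⁷, 10⁻⁵] or with
coverage ≤ 0.30 — at least a decade / 0.05 away from the thresholds — so
threshold unit tests are non-flaky by construction. Multi-domain genes
place their matches in disjoint protein windows so planted families are
never lost to overlap resolution. Counts are negative binomial
(mean 80 expressed, 0.2 silent, dispersion 10; Poisson would understate
metatranscriptome overdispersion); `noise_free` mode replaces draws with
their rounded means (≥ 5 expressed, 0 silent), making end-to-end ledger
recovery exact. Expression state is drawn once per (genome, substrate) at
habitat level rather than per sample, so the measured expressing fraction
is exactly a binomial proportion of the configured probability — this is
what the binomial-CI checks exercise. One RNG stream per fixture type,
all spawned from the master seed, keeps fixtures stable when new types
are added.

What the generator does *not* emulate: nucleotide/protein sequences (only
identifiers, coordinates and hit statistics are emitted), phylogenetic
structure, strain heterogeneity, compositional coupling between coverage
and counts, and database incompleteness. Passing tests therefore
demonstrate the correctness of the decision rules and arithmetic under
the stated statistical assumptions, not robustness to real-data
pathologies such as chimeric bins or homology-detection ambiguity.

## Problem sizes and determinism

The shipped analyses use 25 genomes per habitat (~2,500 genes) for the
estuary runs, 200 planted + 200 decoy clusters for cluster recovery, and
200 genomes for the noisy expressing-fraction estimate; these sizes give
stable statistics while keeping every script interactive. All entry
points are seeded, and identical seeds reproduce identical files
(checksummed in each run manifest).

## Known limitations

Subfamily labels are not reconciled with parent families (a gene hit by
both `GH16` and `GH16_3` counts both labels); the EC cascade trusts its
evidence tables and does no hierarchy-aware conflict resolution;
cross-genome cluster families and synteny visualisation are out of scope;
and differential-expression modelling is deliberately left to dedicated
tools operating on the exported count/TPM tables.
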