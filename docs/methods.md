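# Methods

This note documents the models, conventions and design choices behind
`microdiv`, in the spirit of the methods documentation of simulation and
statistics packages: what each stage assumes, which knobs matter, and what
the synthetic data does and does not establish about real genomes.

## The analysis in one paragraph

Given a set of conspecific strain genomes (FASTA + GFF3 gene features),
genes are clustered into families; families present in every genome form
the core genome. Core genes are aligned per family, concatenated, and
scanned for SNP sites under an occurrence filter. Per-gene SNP loads
against a reference strain give a variability distribution whose upper
Tukey outliers are the highly variable genes (HVGs) and whose lower
quartile is the conserved backbone. Nucleotide p-distances on the
concatenation drive neighbor-joining trees with bootstrap support.
Families unique to one strain supply marker genes for deconvolving mixed
cultures from shotgun reads by perfect-match counting and RPKM.

## Gene-family clustering

Pairs of genes are compared by exact global dynamic-programming alignment
(Biopython's pairwise aligner; match 2, mismatch −3, gap open −5, extend
−2, end gaps free). Identity is matching columns over aligned columns with
end gaps excluded; coverage is the aligned span over the **longer**
sequence — the stricter denominator, which prevents gene fragments from
bridging unrelated families. An edge requires identity ≥ 0.50 and coverage
≥ 0.80; families are connected components of the edge graph, with the
lexicographically smallest member gene ID as family ID, so the clustering
is invariant to input order.

Two deliberate simplifications relative to common pangenome pipelines:

- No E-value pre-filter. E-values depend on database size; the
  identity/coverage pair is the binding constraint and is applied
  directly.
- Connected components instead of Markov (MCL) clustering. On
  well-separated families the two agree; components are deterministic and
  parameter-free. Chaining through intermediate sequences is possible in
  principle and is the price of this choice.

A shared-15-mer prefilter bounds the all-vs-all cost. At ≥50% identity
over ≥80% of a ≥100 bp gene, a passing pair shares a 15-mer in all but
adversarial cases; the test suite asserts prefiltered and exhaustive
clustering agree on simulated data.

Paralogs stay in their family (the presence/absence matrix records
counts); alignment-based steps use the best-scoring member pair.

## ANI and dereplication

ANI between two genomes is the mean best-pair identity over families
carried by both, in percent. Dereplication single-links genomes at
ANI > 99% and keeps one representative per cluster (most genes, ties
lexicographic). Marker selection separately warns when retained strains
share ANI ≥ 98%, the regime where read assignment becomes unreliable.

## Core SNP calling

Per-family alignments are positional when all members have equal length
(the default, indel-free simulation regime) and otherwise each member is
globally aligned to the reference member and projected onto reference
coordinates (reference rows are gap-free; insertions relative to the
reference are dropped). This replaces an external multiple aligner: the
downstream statistics are column counts, which at within-species identity
levels do not depend on the aligner's choice among near-identical
alignments.

A column is a SNP site iff, after excluding gap-containing columns
(a SNP is a substitution, not an indel), at least two bases occur and the
summed count of all non-majority bases is ≥ `min_occurrence` × (number of
genomes), default 20%. The boundary is inclusive: exactly 20% is kept,
anything below is treated as possible sequencing error. A site kept at the
boundary with 10 genomes therefore needs ≥ 2 minority observations.
Majority ties are broken A<C<G<T; this affects only which allele is
labelled majority, never whether the site is called. SNPs/Mbp is
`count × 10⁶ / length`; both the alignment-length and mean-genome-length
denominators are exposed because either normalisation is defensible and
they differ by the core-to-genome length ratio.

Pairwise cgSNP counts against the reference skip any column with a gap or
ambiguous base in either row. Synonymous/non-synonymous classification
takes each differing position independently: the reference codon is
mutated at that position alone and translated under bacterial code
table 11; stop gain/loss counts as non-synonymous; ambiguous bases are
unclassifiable. (Full Ka/Ks estimation is out of scope.) The per-genome
summary reports the exact non-synonymous percentage together with its
integer part, the form such percentages are conventionally printed in.

## Per-gene variability and HVG detection

For each core family, the variability statistic is the mean pairwise SNP
count of every non-reference genome against the reference (an all-vs-all
option exists but the reference-based mean is the default). The reference
strain is the most divergent genome — maximal mean p-distance to all
others, the strain at the deepest split of the tree — so that
within-collection diversity projects onto a common outgroup-like axis.

Quartiles of the per-family means use linear interpolation of order
statistics (the numpy default); the convention must be pinned for the
Tukey rule to be reproducible. HVGs satisfy mean > Q3 + 1.5·IQR strictly;
boundary-equal values are not outliers. Conserved genes satisfy
mean < Q1. With fewer than four families quartiles are not meaningful and
both operations refuse to run.

## Trees

Distances are nucleotide p-distances (differing over comparable ungapped
columns) on the core concatenation. Trees are classical neighbor joining:
minimal Q-criterion pair joined at each step, ties broken by
lexicographic taxon label so results are order-independent; negative limb
lengths are clamped to zero with the deficit shifted to the sister branch
(standard practice, noted in the output). The tree is unrooted and
rendered with a trifurcating root. Bootstrap resamples alignment columns
with replacement, rebuilds the tree, and reports each original split's
replicate frequency ×100; all splits are emitted and display filtering
(e.g. at 50) is left to the consumer. The HVG tree concatenates only HVG
families — comparing it with the full-core tree shows whether
fast-evolving genes record a different history (e.g. recent niche
adaptation) than the genome-wide consensus.

A documented divergence: trees are built from nucleotide distances rather
than aligned protein concatenations. This keeps one distance pipeline
shared with the SNP machinery; an amino-acid p-distance variant would slot
in behind the same interface.

## Marker genes and mixture deconvolution

Candidates are families unique to one strain. A candidate is rejected if
(reasons in the audit trail, first matching wins): its annotation matches
the blacklist (transposase, phage, integrase — mobile elements recombine
across strains); it lies within 500 bp of a contig end (assembly-edge
artefacts); or any other strain's genome contains an alignment ≥ 100 bp at
≥ 90% identity (21-mer seeded, greedy ungapped extension on both strands).
The longest ten survivors per strain are kept — longer genes offer more
mappable positions.

Reads count for a marker only on full-length exact identity on either
strand (the "perfect mode" of short-read mappers). Reads matching markers
of more than one strain are discarded and tallied, not fractionally
assigned. Marker abundance is RPKM; strain abundance is the **mean** RPKM
over the strain's markers (median available), making the estimate
invariant to marker duplication; proportions normalise strain RPKMs to
sum to one per time point. With equal-length error-free reads the
expected strain RPKM is proportional to its mixture weight up to the
(length − read length + 1)/length edge factor, which averages out over
markers; empirically a 4-strain 0.5/0.3/0.15/0.05 mixture at 5×10⁵ reads
is recovered within ~0.01 absolute.

## The synthetic-data generator

The generator is first-class, tested code; it emulates the statistical
structure the analyses assume:

- **Phylogeny**: Kingman-coalescent random binary tree (exponential
  waiting times, uniform pair merges), rescaled to unit root-to-tip depth;
  user-supplied Newick trees are accepted.
- **Substitution**: Jukes–Cantor along the tree. `base_subst_rate` is the
  expected substitutions per site over the full depth (default 0.02 —
  within-species scale, two tips differ by ≤ 4% of sites before multiple
  hits). Events are Poisson per branch (`L × rate × branch length`) at
  uniform positions; repeated hits at a site are applied sequentially, so
  the process is the exact JC event process and matches the JC closed form
  (verified to within binomial error at 2×10⁵ sites). A fraction of core
  genes (default 5%) forms a fast class at `fast_rate_multiplier` (default
  10×) — the planted HVG signal. No indels by default, keeping orthologs
  positionally aligned; the paper trail of every variant site is recorded.
- **Gene content**: accessory families arise by gain on internal branches
  and loss of sub-clades (rate split evenly; losses that would leave a
  single carrier are skipped, and post-hoc singleton accessory families do
  not occur, so each strain's unique-gene count is exactly
  `n_unique_genes_per_strain`, default 12 — a desk-scale stand-in for the
  ~157 singletons per genome seen in real strain collections, sized with a
  small buffer above the ten-marker target so contig-end rejections cannot
  starve a strain of markers).
- **Layout**: genes are shuffled per genome onto (default) two contigs
  with random intergenic spacers (default 100 bp), all forward-strand;
  GFF3 is emitted 1-based inclusive from 0-based half-open internals.
- **Reads**: strain chosen per read from the mixture weights
  (multinomial), start uniform over positions where the read fits a
  contig, reverse-complemented with probability 0.5, per-base substitution
  errors at `error_rate` (default 10⁻³), constant PHRED 35 qualities
  (carried, never used — profiling is exact-match). Time series default to
  the 10/24/48 h sampling pattern of a bioreactor co-culture.

Everything is driven by one `numpy` generator per seed: identical configs
give byte-identical FASTA/GFF3/FASTQ.

**What the simulations do not show**: real sequencing error profiles,
paired-end structure, recombination, codon-aware selection, annotation
noise, or assembly fragmentation. Passing tests demonstrate the
*operations* are correct against ground truth and closed forms — not that
a particular biological dataset would yield any particular SNP rate or
HVG count, which depend on the genomes analysed.

## Problem sizes and numerical choices

Tests and the acceptance computations run the heavy experiments at the
scale where their statistics are stable: HVG recovery at 22 strains × 500
core genes over 20 seeds (recall and false-positive rate are medians);
topology recovery on 6-taxon trees with the gene count chosen so the
shortest branch expects ≥ 50 substitutions; mixture recovery at 5×10⁵
reads. Tolerances follow the source of noise: closed-form checks use 3
standard deviations of the binomial/multinomial sampling error; exact
algorithmic contracts (NJ on additive matrices, oracle equivalences,
determinism) are asserted to 10⁻⁹ or exactly.

Degenerate inputs are defined rather than left to chance: empty sequences,
non-symmetric distance matrices, zero-length normalisation, families
missing the reference, empty HVG sets and zero mapped reads all raise (or
warn, where the quantity has a natural zero).

## Known limitations

- Connected-component clustering can chain families through intermediate
  sequences in dense similarity landscapes.
- Reference-projected alignment discards insertions relative to the
  reference; SNP columns exist only at reference positions.
- Perfect-match profiling loses reads at sequencing error rates ≥ ~1/read
  length; it never creates cross-strain false positives while marker
  uniqueness holds at read length, but abundance estimates degrade with
  error rate.
- Neighbor joining is distance-based; no likelihood or Bayesian
  alternative is provided, and bootstrap supports inherit p-distance
  saturation at high divergence.
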