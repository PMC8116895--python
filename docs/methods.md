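# Methods

`gliamp` analyzes a targeted amplicon of the wheat α-gliadin gene family — the
fragment that harbors the main celiac-disease (CD) immunogenic region: the
33-mer peptide (six overlapping copies of the DQ2.5-glia-α1a/α1b/α2 T-cell
epitopes), the flanking DQ2.5-glia-α3 epitope, and the innate-response
peptide p31-43. The package recovers amplicon sequence variants from
paired-end reads, annotates their epitope content and pseudogene status, and
quantifies their expression across a genotype × nitrogen × developmental
design with a qPCR-anchored normalization. All stages run against a synthetic
ground truth generated in-package, so every claim the analysis makes is
checkable against a known answer.

## The synthetic ground-truth family

`synthetic_data.bw208_like()` defines a 45-variant α-gliadin-like amplicon
family over the three bread-wheat subgenomes (A/B/D) whose marginal
composition encodes the study background it emulates:

* 45 variants, 20 pseudogenes (in-frame premature stop), 25 putative genes;
* exactly one putative gene (genome D) carrying the full six-copy 33-mer
  complement, at 2.4% of the family (`variant_13`);
* six genome-B putative genes, none with a 33-mer constituent epitope, two
  carrying DQ2.5-glia-α3;
* p31-43 (LG- or LP- form) in 38 of 45 variants and 20 of 25 putative genes;
* six variants (four putative genes) without any DQ2.5-class epitope — the
  most abundant variant (`variant_19`, genome B, 12% of the family) is one of
  them, carrying p31-43 only;
* among putative genes, five with exactly one constituent copy and four with
  exactly four (plus three two-copy genes so all four type-1 subtypes,
  1.1-1 / 1.1-2 / 1.2-4 / 1.3-6, are represented).

Sequences are realized from a synthetic α-gliadin-like template: a
signal-peptide-like leader followed by an amplicon window built from a
P/Q-rich repeat scaffold. Three design choices matter:

1. **Epitope copy number is varied by point-breaking repeat units**
   (`PQPQLPY → PQPQLQY`), not by deleting blocks. This mirrors how natural
   variants lose epitopes through SNPs, keeps all variants ~equal length
   (372–402 nt, all above the 160 nt pipeline filter and below the 2×300
   read span), and keeps every variant >90% identical to its genome
   exemplar — necessary for nearest-exemplar genome assignment with a 90%
   identity floor.
2. **Genome of origin is a synonymous codon signature**: Ser/Thr/Val residues
   are encoded with fixed genome-diagnostic codons, giving ~20+ diagnostic
   positions per variant and a ≥3-point identity margin between the correct
   and the next-best exemplar (the assignment tie margin is 0.5 points).
3. **Variant-to-variant divergence comes from seeded synonymous codon edits**
   (8 per variant), verified at build time: realized epitope counts must
   equal the design exactly (checked with the package's own scanner), the
   pseudogene flag must be realized, and every variant pair must differ by
   ≥6 nt so that 99%-identity clustering cannot merge two designs and the
   UNOISE skew rule cannot absorb one true variant into another.

Pseudogene stops are placed in a filler region downstream of every epitope
block, so stop placement never changes designed epitope counts. Frequencies
follow a fixed decreasing series (0.120 for the most abundant variant, 0.024
for the six-copy variant, remainder 0.030–0.010), chosen so the rarest
variant still receives ≥500 expected reads per sample at the default
sequencing depth.

What the generator does *not* emulate: indel sequencing errors,
quality-by-cycle decay, PCR stochasticity beyond multinomial sampling,
length polymorphism beyond ±30 nt, and real α-gliadin haplotype structure.
Passing tests therefore demonstrate the pipeline's correctness under
substitution-dominated MiSeq-like noise, not its robustness to indel-heavy
chemistry.

## Read simulation

2×300 paired reads are drawn multinomially from variant frequencies; forward
reads cover the amplicon 5′ end, reverse reads the 3′ end. Substitution
errors are i.i.d. at `per_base_error` (default 0.001) with flat Phred
qualities Q = −10·log₁₀(p), which keeps the expected-error filter
analytically checkable. A fraction `chimera_rate` (default 0.005) of pairs
derive from single-crossover two-parent templates — the simplest chimera
model the pipeline's detection step can catch. Default depth is 52,000 pairs
per sample: the smallest designed frequency (0.995%) then yields ≥500
expected reads per variant per sample, and total throughput is near the
~100,000 reads/sample scale typical for this assay.

## Variant recovery pipeline

Stages and defaults (all exposed in `PipelineParams`):

* **Merging** — best ungapped overlap (≥16 nt) between the forward read and
  the reverse-complemented mate, maximizing matches − mismatches; rejected
  if the best overlap's mismatch fraction exceeds 10%. Agreements get
  posterior quality min(q₁+q₂, 45); mismatches keep the higher-quality base
  with quality |q₁−q₂| (floor 2). With equal mate qualities a mismatch is
  resolved arbitrarily, so merging detects but cannot correct such errors;
  error reads are instead absorbed during denoising.
* **Filtering** — keep merged reads with length ≥160 nt and expected errors
  ≤1.0 (inclusive boundaries; EE = Σ 10^(−Q/10), N bases scored at Q2).
* **Dereplication** — exact grouping with per-sample sizes; descending size,
  ties lexicographic.
* **Denoising** — greedy UNOISE-style pass: a unique of size s joins a
  centroid of size c at Levenshtein distance d when s/c ≤ β(d) = 1/2^(αd+1)
  (α = 2); singletons are discarded. Centroids exactly reconstructable as a
  single crossover of two larger centroids are removed as chimeras.
* **Clustering** — greedy centroid clustering at 99% identity. Identity is
  matching columns over global-alignment columns with terminal-gap runs
  trimmed (end-gap-free); internal gaps count as non-matching columns.
* **Quantification** — uniques are assigned to the best-identity reference
  (the recovered set, or a database FASTA in cDNA mode) at ≥99% identity;
  ties keep the earlier entry and are logged.
* **High-confidence filter** — keep variants with ≥75 reads in ≥3 samples
  (inclusive).
* **Normalization** — normalized(v,s) = raw(v,s) × (min sample total /
  sample total) × dilution(s) / NF(s). The dilution factor undoes the
  pre-sequencing Cq-equalization dilution; NF is the geNorm normalization
  factor. The factors commute; provenance records each step applied.

At the default study scale (4 DNA samples × 52,000 pairs, error 0.001) the
pipeline recovers exactly the 45 ground-truth sequences byte-for-byte — no
splits, merges or losses — of which 20 are flagged pseudogenes.

## Annotation

Reading frame comes from infix alignment of the variant against the
reference CDS (frame = alignment start mod 3), falling back to the frame
maximizing the ungapped ORF when aligned identity is below 70%. A variant is
a pseudogene iff its in-frame translation contains a stop codon anywhere in
the amplicon window (the amplicon truncates the gene, so a stop at the final
codon is still premature). Epitope scanning counts overlapping exact
occurrences of each motif on the native (Q-encoded) translation; deamidation
(Q→E) is deliberately not modeled because genomic and transcript sequences
encode Q. Stops partition the protein: a match never spans a stop. Type
labels follow the 33-mer constituent copy number (1 → 1.1-1, 2 → 1.1-2,
4 → 1.2-4, 6 → 1.3-6, other positive → type1_other); with zero copies, the
flanking DQ2.5-glia-α3 makes a variant non_type1, otherwise it has no CD
epitope (p31-43, an innate-response peptide, never counts toward CD-epitope
status). The packaged epitope table (`data/epitopes.tsv`) is configuration,
not code, and can be overridden.

## qPCR quantification

Per-well efficiency is estimated from raw fluorescence: the additive
baseline is chosen by grid search (including zero) to maximize the r² of the
best 4–6-cycle log-linear window, restricted to the rising phase between 1%
and 85% of the curve span; E = 10^slope. This window-of-linearity approach
recovers a pure exponential exactly and a true baseline offset to ~10%.
Estimates with r² < 0.99 or E outside (1, 2.2] are flagged, never silently
altered. One common threshold per target (geometric middle of the pooled
exponential windows) gives comparable N0 = threshold/E^Cq within a target;
Cq is log-interpolated between bracketing cycles. The per-target E used for
N0 is the mean of per-well estimates.

geNorm stability is M_j = mean over k≠j of SD across samples of
log₂(expr_j/expr_k), with iterative exclusion of the least stable gene and
pairwise variation V(n/n+1) = SD of log₂(NF_n/NF_{n+1}). With only three
reference genes only V(2/3) is computable; it is reported, not thresholded.
NF is the geometric mean of the stable references, rescaled so NF has
geometric mean 1 across samples (the geNorm convention); normalized
expression divides by NF. NF is computed per sample (the design pools cDNA
replicates before qPCR, so wells and samples coincide).

The curve simulator uses F(c) = baseline + min(N0·E^c, plateau) + Gaussian
noise: exactly exponential until saturation, which keeps the closed-form
checks (log-slope = log E; ΔCq = 1 per doubling of N0) exact.

## Expression design and statistics

The expression generator applies, multiplicatively on a per-variant
baseline (∝ DNA frequency): an RNAi silencing factor on putative genes
(wild type 1.0, D-hordein-promoter line 0.35, γ-gliadin-promoter line 0.08),
a nitrogen response on putative genes of the A and D subgenomes (high/low
ratios 2.5, 4.0 and 1.0 respectively — the γ-gliadin-promoter line is
designed non-responsive), a grain-filling trajectory over days post anthesis
(10/18/26 DPA → 0.4/1.0/0.7, peaking at 18 DPA), and lognormal noise with
CV 0.25. These factors are the study conditions the generator encodes, not
fitted quantities; with the noise off, aggregate fold changes recover them
exactly (including the fourfold response of the hordein-promoter line on
the A and D genomes).

Group comparisons run one-way ANOVA followed by two-tailed Dunnett
comparisons against a control, with Shapiro–Wilk and Levene checks always
reported alongside. Dunnett familywise adjustment uses the multivariate-t
distribution (scipy, seeded); it reduces to the two-sample t-test at k = 1
and holds the simulated familywise type-I error at ≈0.05 under the global
null. Because the developmental trajectory dominates within-group variance,
the nitrogen contrast in the analysis scripts is computed on sample totals
divided by the known DPA profile; this is a generator-calibration check, not
an analysis recipe for real data (which would test within stage or model the
stage effect). No correction beyond Dunnett's own familywise control is
applied.

PCA standardizes active variables (population SD) and projects supplementary
quantitative variables by correlation with the scores; supplementary
variables never influence the axes, and constant columns are dropped with a
warning. Heatmap ordering uses 1 − Spearman correlation (average ranks for
ties; zero-variance rows get correlation 0 with a warning), average linkage,
deterministic leaf order, and per-row z-scoring for display.

## Numerical conventions and edge cases

* Phred offset +33 everywhere; posterior merge quality capped at Q45.
* The expected-error boundary is inclusive with a 1e-9 relative tolerance so
  a read at exactly the limit passes despite floating-point summation.
* All thresholds (≥75 reads, ≥3 samples, ≥160 nt, ≤1.0 EE) are inclusive.
* Reported coordinates are 1-based inclusive; translation table 1.
* Every stochastic operation takes one seed and draws all randomness from a
  single generator; pipeline stages derive their seeds from one
  SeedSequence, making full runs bit-for-bit reproducible.

## Problem sizes

The analysis scripts and acceptance run use 4 DNA samples × 52,000 read
pairs (per-variant per-sample depth ≥500) for variant recovery, 36 cDNA
samples × 3,000 pairs for expression quantification, 144 qPCR wells × 40
cycles, and 800 simulated null datasets for the familywise-error check.
These sizes give stable results (recovery is exact and deterministic in
practice across seeds) while keeping a full run in minutes on one CPU.

## Known limitations

* Genome assignment by nearest exemplar is a stand-in for the published
  subgenome-addressing approach, which is not fully specified in this
  context; with real data, exemplars should be genome-annotated reference
  sequences.
* The p31-43 LG-/LP- peptide strings and DQ2.5 epitope cores ship as
  literature-derived defaults in a config table and should be reviewed
  against the current epitope registry before use on real data.
* Merging cannot correct equal-quality overlap mismatches (see above), so
  per-read exactness is bounded by (1−p)^L; denoising, not merging, is the
  error-correction stage.
* The read simulator draws errors uniformly; real MiSeq error profiles are
  position- and context-dependent.
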