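# gliamp

Analysis of a wheat α-gliadin amplicon harboring the main celiac-disease
(CD) immunogenic region — the 33-mer peptide with its six overlapping
DQ2.5-restricted T-cell epitope copies, the flanking DQ2.5-glia-α3 epitope,
and the innate-response peptide p31-43.

The package is aimed at cereal genomics / gluten immunology work where one
needs to (a) recover high-confidence amplicon sequence variants from
paired-end Illumina reads, (b) annotate each variant for pseudogene status,
CD-epitope content, 33-mer copy number, type-1 subtype and subgenome of
origin, and (c) quantify variant expression across genotype × nitrogen ×
developmental-stage designs with an RT-qPCR-anchored normalization. A
first-class synthetic-data module generates ground-truth gene families,
reads, qPCR fluorescence curves and expression designs, so the entire
pipeline is verifiable end-to-end without any external data.

## The core methods

**Variant recovery.** Read pairs are merged (best ungapped overlap,
posterior qualities), filtered by length ≥ 160 nt and expected errors
EE = Σᵢ 10^(−Qᵢ/10) ≤ 1, dereplicated, denoised UNOISE-style — a unique of
size *s* is absorbed by a centroid of size *c* at edit distance *d* when
s/c ≤ β(d) = 1/2^(αd+1), α = 2, with two-parent chimera removal — then
clustered at 99% identity, and kept when supported by ≥ 75 reads in ≥ 3
samples.

**Annotation.** Variants are frame-aligned to a reference CDS, translated,
flagged as pseudogenes on any in-frame stop, scanned for overlapping epitope
motif occurrences (matches never span a stop), typed by 33-mer constituent
copy number (1 → 1.1-1, 2 → 1.1-2, 4 → 1.2-4, 6 → 1.3-6), and assigned to
the A/B/D subgenome by nearest exemplar.

**qPCR stack.** Per-well efficiency from raw fluorescence via the window of
linearity (E = 10^slope of the best 4–6-cycle log-linear fit after baseline
search); starting quantities N₀ = threshold / E^Cq; reference-gene
stability by geNorm (M = mean SD of pairwise log₂ ratios, iterative
exclusion, V(n/n+1)); per-sample normalization factor NF = geometric mean of
the stable references. Normalized counts = raw × (smallest sample total /
sample total) × dilution factor / NF.

**Statistics.** One-way ANOVA with two-tailed Dunnett comparisons against a
control (Shapiro–Wilk and Levene reported alongside), PCA with supplementary
prolamin-content variables projected by correlation, and heatmap ordering by
average-linkage clustering on 1 − Spearman correlation.

## Worked example

```python
from gliamp import synthetic_data as sd, amplicon as amp, epitope as ep
from gliamp.pipeline import recover_variants

family = sd.build_family(sd.bw208_like(seed=42))   # 45-variant ground truth
res = recover_variants(family, amp.PipelineParams(), n_samples=4,
                       depth=52_000, error=0.001, chimera=0.005, seed=42)
print(len(res.matrix))                              # 45
ann = ep.annotate_database(
    [(v, s) for v, s in zip(res.matrix.index, res.variants.seqs)],
    ep.load_epitope_table(), family.reference_cds, family.exemplars)
print(int(ann.is_pseudogene.sum()))                 # 20
print(int((ann.n33mer_copies == 6).sum()))          # 1
print(int(ann.p31_43_present.sum()))                # 38
```

The pipeline recovers all 45 designed variants byte-for-byte from 208,000
simulated read pairs: 20 carry an in-frame premature stop (pseudogenes),
exactly one putative gene carries the full six-copy 33-mer complement, and
the p31-43 innate peptide is detected in 38 of the 45 variants.

The same flow is available stepwise as numbered drivers under `analysis/`
(family construction, variant recovery, annotation, qPCR normalization,
cDNA quantification, expression statistics), each writing its tables under
`results/`. Running `analysis/06_expression_analysis.py` after 01–05 prints,
among other things, the high/low-nitrogen fold change of putative-gene
expression by subgenome:

```
genome                    A     B     D
rnai_gliadin_promoter  0.82  0.92  0.93
rnai_hordein_promoter  4.23  1.00  3.93
wild_type              2.63  0.94  2.48
```

i.e. the designed fourfold nitrogen response of the D-hordein-promoter RNAi
line on the A and D subgenomes, the ~2.5-fold wild-type response, and the
flat γ-gliadin-promoter line, recovered through the full read-level +
qPCR-normalization stack (designed ratios 4.0 / 2.5 / 1.0; the residual
deviation is sampling and normalization noise).

A thin CLI mirrors the library: `gliamp simulate family`, `gliamp denoise`,
`gliamp annotate`, `gliamp qpcr quantify|genorm`, `gliamp run`.

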