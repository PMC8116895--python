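#!/usr/bin/env python
"""Build the BW208-like ground-truth amplicon family and write the database.

The default design realizes 45 alpha-gliadin amplicon variants over the A/B/D
subgenomes: 20 pseudogenes, one genome-D putative gene carrying the full
six-copy 33-mer complement at 2.4% frequency, six genome-B putative genes
without any 33-mer constituent epitope, and the p31-43 innate peptide in 38
variants. Outputs: database FASTA, truth TSV, genome exemplars and the
reference CDS under results/family/.
"""

from pathlib import Path

from gliamp import synthetic_data as sd

OUT = Path("results/family")


def main() -> None:
    build = sd.build_family(sd.bw208_like(seed=42))
    build.write(OUT)
    t = build.truth
    print(f"built {len(t)} variants -> {OUT}")
    print(f"  pseudogenes:            {int(t.is_pseudogene.sum())}")
    print(f"  putative genes:         {int((~t.is_pseudogene).sum())}")
    print(f"  p31-43 carriers:        {int(t.p31_43_present.sum())}")
    six = t[t.n33mer_copies == 6]
    print(
        f"  six-copy 33-mer variant: {six.index[0]} "
        f"(genome {six.genome.iloc[0]}, frequency {six.dna_frequency.iloc[0]:.3f})"
    )
    top = t.dna_frequency.idxmax()
    print(f"  most abundant variant:  {top} (genome {t.loc[top, 'genome']}, "
          f"frequency {t.loc[top, 'dna_frequency']:.3f})")


if __name__ == "__main__":
    main()
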