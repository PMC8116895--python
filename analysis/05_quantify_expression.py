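#!/usr/bin/env python
"""Quantify variant transcript abundance in the 36 cDNA samples.

Simulates paired-end cDNA reads from the expression design (samples are
sequenced at equal depth, emulating the pre-sequencing Cq-based dilution),
maps merged/filtered reads against the amplicon database at 99% identity,
and normalizes counts to the smallest sample with the dilution factor and the
qPCR normalization factor from analysis 04. Writes results/expression/.

Requires: results/qpcr/sample_factors.tsv (run 04 first).
"""

from pathlib import Path

import pandas as pd

from gliamp import amplicon as amp
from gliamp import synthetic_data as sd

OUT = Path("results/expression")
FACTORS = Path("results/qpcr/sample_factors.tsv")
DEPTH_CDNA = 3000


def main() -> None:
    if not FACTORS.exists():
        raise SystemExit("run analysis/04_qpcr_normalization.py first (needs sample_factors.tsv)")
    factors = pd.read_csv(FACTORS, sep="\t", index_col=0)
    family = sd.build_family(sd.bw208_like(seed=42))
    design = sd.default_expression_design(family.truth, seed=2024, noise_cv=0.25)
    truth, meta = sd.simulate_expression(design)

    cfg = sd.ReadSimConfig(
        depth_per_sample=DEPTH_CDNA, per_base_error=0.001, chimera_rate=0.005, seed=99
    )
    reads = sd.simulate_reads(family.records, {s: truth[s].to_dict() for s in truth.columns}, cfg)
    res = amp.run_read_pipeline(reads, amp.PipelineParams(), database=family.records)
    normalized, provenance = amp.normalize_counts(
        res.raw_matrix, dilution=factors["dilution_factor"], nf=factors["nf"]
    )
    OUT.mkdir(parents=True, exist_ok=True)
    res.raw_matrix.to_csv(OUT / "raw_matrix.tsv", sep="\t")
    normalized.to_csv(OUT / "normalized_matrix.tsv", sep="\t")
    meta.assign(dilution_factor=factors["dilution_factor"], nf=factors["nf"]).to_csv(
        OUT / "sample_sheet.tsv", sep="\t"
    )

    # how well do normalized counts track the designed expression?
    shared = normalized.mul(truth.sum(axis=0) / normalized.sum(axis=0), axis=1)
    corr = shared.stack().corr(truth.stack())
    print(f"mapped cDNA reads for {normalized.shape[1]} samples "
          f"({res.log.counts.get('unassigned_reads', 0)} reads unassigned)")
    print(f"normalization provenance: {provenance}")
    print(f"correlation of normalized counts with designed abundance: r = {corr:.3f}")


if __name__ == "__main__":
    main()
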