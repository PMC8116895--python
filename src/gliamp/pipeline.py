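"""End-to-end orchestration: synthetic truth -> qPCR -> read pipeline ->
annotation -> expression analysis, with every stage logged to a manifest and
all tables written as TSV.

The run is fully deterministic given the config seed: stage seeds are derived
from one SeedSequence so stages can be re-run bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import amplicon as amp
from . import epitope as ep
from . import expression as ex
from . import qpcr as qp
from . import synthetic_data as sd
from .config import RunConfig
from .io import SeqRecord, write_fasta


class StageError(RuntimeError):
    pass


@dataclass
class PipelineBundle:
    family: sd.FamilyBuild
    recovery: amp.PipelineResult
    annotation: pd.DataFrame
    quantification: pd.DataFrame
    nf: pd.Series
    stability: qp.StabilityResult
    normalized: pd.DataFrame
    sample_meta: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def dna_sample_reads(
    family: sd.FamilyBuild, n_samples: int, depth: int, error: float, chimera: float, seed: int
) -> dict[str, list[sd.ReadPair]]:
    """Paired reads for the DNA (genomic) samples at the designed frequencies."""
    freqs = family.truth["dna_frequency"].to_dict()
    abund = {f"dna_{i + 1}": freqs for i in range(n_samples)}
    cfg = sd.ReadSimConfig(
        depth_per_sample=depth, per_base_error=error, chimera_rate=chimera, seed=seed
    )
    return sd.simulate_reads(family.records, abund, cfg)


def recover_variants(
    family: sd.FamilyBuild,
    params: amp.PipelineParams,
    n_samples: int = 4,
    depth: int = 52_000,
    error: float = 0.001,
    chimera: float = 0.005,
    seed: int = 42,
) -> amp.PipelineResult:
    """The DNA discovery run: simulate reads off the family and recover the
    high-confidence variant set (no database; the reads define it)."""
    reads = dna_sample_reads(family, n_samples, depth, error, chimera, seed)
    return amp.run_read_pipeline(reads, params)


def qpcr_normalization(
    expr_totals: pd.Series, noise_sd: float, seed: int
) -> tuple[pd.DataFrame, qp.StabilityResult, pd.Series, pd.Series]:
    """Simulate reference-gene and target wells, quantify, run geNorm.

    Returns (well table, stability, NF per sample, dilution factor per
    sample). Reference genes are stable across samples; the target well's
    starting quantity tracks the sample's true aggregate expression. The
    dilution factor mirrors the pre-sequencing Cq-equalization dilution:
    samples are diluted down to the least-concentrated one.
    """
    rng = np.random.default_rng(seed)
    samples = list(expr_totals.index)
    eff = {"CDC": 1.92, "ADP-RF": 1.88, "RLI": 1.95, "agli_amplicon": 1.85}
    scale = 1e-3 / max(expr_totals.max(), 1e-12)
    wells = []
    for s in samples:
        for gene, base in (("CDC", 2e-4), ("ADP-RF", 5e-4), ("RLI", 1e-4)):
            n0 = base * rng.lognormal(0.0, 0.05)
            wells.append({"well": f"{s}:{gene}", "target": gene, "sample": s, "n0": n0})
        wells.append(
            {
                "well": f"{s}:agli",
                "target": "agli_amplicon",
                "sample": s,
                "n0": max(expr_totals[s] * scale, 1e-12),
            }
        )
    cfg = sd.QpcrSimConfig(efficiencies=eff, noise_sd=noise_sd, seed=int(rng.integers(2**31)))
    curves = sd.simulate_qpcr(cfg, pd.DataFrame(wells))
    quant = qp.quantify_wells(curves)
    ref = quant[quant["target"] != "agli_amplicon"].pivot_table(
        index="target", columns="sample", values="N0"
    )
    stability = qp.genorm_stability(ref)
    genes_used = [g for g in ref.index if g not in stability.exclusion_order]
    nfs = qp.normalization_factors(ref, genes_used)
    target_n0 = quant[quant["target"] == "agli_amplicon"].set_index("sample")["N0"]
    dilution = (target_n0 / target_n0.min()).reindex(samples).rename("dilution_factor")
    return quant, stability, nfs.nf.reindex(samples), dilution


def run_pipeline(config: RunConfig, depth_cdna: int = 4000) -> PipelineBundle:
    """Execute the full analysis on synthetic truth and write all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def stage(name, fn, *args, **kw):
        try:
            res = fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"ok": True}
        return res

    if config.family != "bw208_like":
        raise StageError(f"unknown family design {config.family!r}")
    family = stage("family", sd.build_family, sd.bw208_like(seed=seeds[0]))
    family.write(out / "family")

    epitopes = ep.load_epitope_table(config.epitope_table)
    recovery = stage(
        "recovery",
        recover_variants,
        family,
        config.params,
        n_samples=config.n_dna_samples,
        depth=config.depth_per_sample,
        error=config.per_base_error,
        chimera=config.chimera_rate,
        seed=seeds[1],
    )
    manifest["stages"]["recovery"].update(recovery.log.counts)
    rec_records = [(vid, seq) for vid, seq in zip(recovery.matrix.index, recovery.variants.seqs)]
    write_fasta(
        [
            SeqRecord(id=vid, seq=seq, size=int(n))
            for (vid, seq), n in zip(rec_records, recovery.matrix.sum(axis=1))
        ],
        out / "recovered_variants.fasta",
    )
    recovery.raw_matrix.to_csv(out / "dna_raw_matrix.tsv", sep="\t")

    annotation = stage(
        "annotation", ep.annotate_database, rec_records, epitopes, family.reference_cds, family.exemplars
    )
    annotation.to_csv(out / "annotation.tsv", sep="\t")

    design = sd.default_expression_design(family.truth, seed=seeds[2], noise_cv=config.noise_cv)
    truth_expr, meta = stage("expression_truth", sd.simulate_expression, design)
    quant, stability, nf, dilution = stage(
        "qpcr", qpcr_normalization, truth_expr.sum(axis=0), config.qpcr_noise_sd, seeds[3]
    )
    quant.to_csv(out / "qpcr_wells.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"M": stability.m_values, **{k: v for k, v in stability.v_values.items()}}
    ).to_csv(out / "qpcr_stability.tsv", sep="\t")

    cdna_abund = {s: truth_expr[s].to_dict() for s in truth_expr.columns}
    # pre-sequencing dilution equalizes template amounts; the multinomial draw
    # at equal depth emulates it, the dilution factor undoes it afterwards
    cfg_reads = sd.ReadSimConfig(
        depth_per_sample=depth_cdna,
        per_base_error=config.per_base_error,
        chimera_rate=config.chimera_rate,
        seed=seeds[4],
    )
    cdna_reads = stage("cdna_reads", sd.simulate_reads, family.records, cdna_abund, cfg_reads)
    cdna = stage("cdna_quant", amp.run_read_pipeline, cdna_reads, config.params, rec_records)
    normalized, provenance = amp.normalize_counts(
        cdna.raw_matrix, dilution=dilution, nf=nf
    )
    manifest["stages"]["cdna_quant"].update(cdna.log.counts)
    manifest["provenance"] = provenance
    normalized.to_csv(out / "normalized_matrix.tsv", sep="\t")
    meta = meta.assign(dilution_factor=dilution, nf=nf)
    meta.to_csv(out / "sample_sheet.tsv", sep="\t")

    agg = stage(
        "aggregate", ex.aggregate, normalized, annotation, meta, ["genome"], ["genotype", "n_level"]
    )
    agg.to_csv(out / "aggregate_genome.tsv", sep="\t", index=False)
    ex.fold_change(agg).to_csv(out / "fold_change_genome.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineBundle(
        family=family,
        recovery=recovery,
        annotation=annotation,
        quantification=quant,
        nf=nf,
        stability=stability,
        normalized=normalized,
        sample_meta=meta,
        manifest=manifest,
    )
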