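#!/usr/bin/env python
"""Genome/type aggregation, nitrogen response, statistics, PCA and heatmap.

Consumes the normalized cDNA matrix from analysis 05: aggregates expression
per subgenome and per type-1 subtype, computes high/low-nitrogen fold
changes per genotype, tests the high-vs-low N contrast per genotype (ANOVA +
two-tailed Dunnett with assumption checks, on stage-adjusted totals), runs a
PCA of genotype x N aggregates (summed over DPA) with synthetic grain
prolamin contents as supplementary variables, and orders the variant heatmap
by average-linkage clustering on 1 - Spearman correlation. Writes
results/stats/.

Requires: results/expression/ and results/annotation/ (run 03-05 first).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gliamp import expression as ex
from gliamp import synthetic_data as sd

EXPR = Path("results/expression")
ANN = Path("results/annotation/annotation.tsv")
OUT = Path("results/stats")


def main() -> None:
    if not (EXPR / "normalized_matrix.tsv").exists() or not ANN.exists():
        raise SystemExit("run analyses 03-05 first")
    normalized = pd.read_csv(EXPR / "normalized_matrix.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(EXPR / "sample_sheet.tsv", sep="\t", index_col=0)
    ann = pd.read_csv(ANN, sep="\t", index_col=0)
    OUT.mkdir(parents=True, exist_ok=True)

    # per-genome aggregation and nitrogen fold change (putative genes)
    putative = ann.index[~ann.is_pseudogene]
    agg = ex.aggregate(
        normalized.loc[putative], ann, meta, ["genome"], ["genotype", "n_level"]
    )
    agg.to_csv(OUT / "aggregate_genome.tsv", sep="\t", index=False)
    fc = ex.fold_change(agg)
    fc.to_csv(OUT / "fold_change_genome.tsv", sep="\t", index=False)
    print("high/low nitrogen fold change of putative-gene expression by genome:")
    print(fc.pivot(index="genotype", columns="genome", values="fold_change").round(2).to_string())

    # type-1 subtype aggregation
    type1 = ann.index[(ann.n33mer_copies > 0) & (~ann.is_pseudogene)]
    agg_t = ex.aggregate(normalized.loc[type1], ann, meta, ["type_label"], ["genotype", "n_level"])
    agg_t.to_csv(OUT / "aggregate_type1.tsv", sep="\t", index=False)

    # nitrogen contrast per genotype on sample totals adjusted for the known
    # grain-filling trajectory (the generator's DPA profile)
    dpa_profile = sd.ExpressionDesign.__dataclass_fields__["dpa_profile"].default_factory()
    stage = meta["dpa"].map(dpa_profile)
    adj = normalized.sum(axis=0) / stage
    rows = []
    for gt in meta["genotype"].unique():
        groups = {
            nl: adj[meta[(meta.genotype == gt) & (meta.n_level == nl)].index].to_numpy()
            for nl in ("low", "high")
        }
        rep = ex.compare_groups(groups, control="low", seed=7)
        rows.append(
            {
                "genotype": gt,
                "anova_F": rep.anova_f,
                "anova_p": rep.anova_p,
                "dunnett_p": rep.comparisons["p_adjusted"].iloc[0],
                "shapiro_p_low": rep.shapiro["low"][1],
                "shapiro_p_high": rep.shapiro["high"][1],
                "levene_p": rep.levene[1],
            }
        )
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(OUT / "nitrogen_contrasts.tsv", sep="\t", index=False)
    print("\nhigh-vs-low nitrogen contrast (Dunnett, stage-adjusted totals):")
    print(stats_df[["genotype", "anova_F", "dunnett_p"]].round(4).to_string(index=False))

    # PCA of genotype x N aggregates (sum over DPA) + synthetic prolamin contents
    long = normalized.T.join(meta[["genotype", "n_level"]])
    cells = long.groupby(["genotype", "n_level"]).sum(numeric_only=True)
    rng = np.random.default_rng(31)
    put_tot = cells[list(putative)].sum(axis=1)
    prolamin = pd.DataFrame(
        {
            "alpha_gliadins": put_tot * rng.lognormal(0, 0.05, len(cells)),
            "gamma_gliadins": 0.6 * put_tot * rng.lognormal(0, 0.08, len(cells)),
            "total_prolamin": 1.9 * put_tot * rng.lognormal(0, 0.05, len(cells)),
        },
        index=cells.index,
    )
    prolamin.to_csv(OUT / "prolamin_supplementary_synthetic.tsv", sep="\t")
    pca = ex.pca_with_supplementary(cells, supplementary=prolamin, n_components=3)
    pca.scores.to_csv(OUT / "pca_scores.tsv", sep="\t")
    pca.supplementary.to_csv(OUT / "pca_supplementary.tsv", sep="\t")
    print(f"\nPCA: PC1+PC2 explain {100 * pca.explained[:2].sum():.1f}% of variance")
    print("supplementary prolamin projections on PC1:",
          pca.supplementary["PC1"].round(3).to_dict())

    # heatmap ordering of variants across samples
    order = ex.heatmap_order(normalized)
    pd.Series(order.row_order, name="variant_id").to_csv(OUT / "heatmap_row_order.tsv", sep="\t", index=False)
    pd.Series(order.col_order, name="sample_id").to_csv(OUT / "heatmap_col_order.tsv", sep="\t", index=False)
    print(f"heatmap row order computed; first rows: {order.row_order[:5]}")


if __name__ == "__main__":
    main()
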