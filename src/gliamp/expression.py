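"""Expression aggregation and statistics for normalized amplicon abundances.

Aggregates normalized variant abundances by subgenome, type label or
gene/pseudogene class across the genotype x nitrogen x DPA design, computes
high/low-nitrogen fold changes, runs one-way ANOVA with two-tailed Dunnett
comparisons against a control (with Shapiro-Wilk and Levene assumption
checks), performs PCA with supplementary quantitative variables projected by
correlation, and orders heatmap rows/columns by average-linkage hierarchical
clustering on 1 - Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# aggregation and ratios


def aggregate(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    sample_meta: pd.DataFrame,
    variant_keys: list[str] | None = None,
    sample_keys: list[str] | None = None,
) -> pd.DataFrame:
    """Group-and-sum normalized abundances.

    ``variant_keys`` select annotation columns (genome, type_label,
    is_pseudogene, ...); ``sample_keys`` select sample-sheet columns
    (genotype, n_level, dpa, ...). Sums are conservative: re-summing any
    partition reproduces the grand total.
    """
    missing = [v for v in matrix.index if v not in annotations.index]
    if missing:
        raise DesignError(f"unannotated variants: {missing}")
    long = matrix.stack().rename("abundance").reset_index()
    long.columns = ["variant_id", "sample_id", "abundance"]
    for key in variant_keys or []:
        long[key] = long["variant_id"].map(annotations[key])
    for key in sample_keys or []:
        long[key] = long["sample_id"].map(sample_meta[key])
    keys = (variant_keys or []) + (sample_keys or [])
    if not keys:
        return pd.DataFrame({"abundance": [long["abundance"].sum()]})
    return long.groupby(keys, observed=True)["abundance"].sum().reset_index()


def fold_change(
    aggregates: pd.DataFrame,
    ratio_key: str = "n_level",
    numerator: str = "high",
    denominator: str = "low",
) -> pd.DataFrame:
    """Elementwise numerator/denominator ratio per group after pivoting on
    ``ratio_key``."""
    keys = [c for c in aggregates.columns if c not in (ratio_key, "abundance")]
    wide = aggregates.pivot_table(index=keys, columns=ratio_key, values="abundance", aggfunc="sum")
    if (wide[denominator] <= 0).any():
        raise DesignError("non-positive denominator group in fold change")
    out = (wide[numerator] / wide[denominator]).rename("fold_change").reset_index()
    return out


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class StatReport:
    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    shapiro: dict[str, tuple[float, float]]  # group -> (W, p)
    levene: tuple[float, float]
    comparisons: pd.DataFrame  # group, statistic, p_adjusted, significant
    control: str = ""


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    control: str,
    alpha: float = 0.05,
    seed: int = 0,
) -> StatReport:
    """One-way ANOVA plus two-tailed Dunnett comparisons against a control.

    Assumption checks (Shapiro-Wilk per group, Levene across groups) are
    always computed and reported alongside; Dunnett familywise-adjusted
    p-values come from the multivariate-t distribution (seeded).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if control not in groups:
        raise DesignError(f"control group {control!r} not present")
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise DesignError("each group needs >= 2 observations and >= 2 groups")
    names = [g for g in groups if g != control]
    shapiro = {}
    for g, v in groups.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro[g] = tuple(map(float, stats.shapiro(v))) if len(set(v)) > 1 else (1.0, 1.0)
    lev = stats.levene(*groups.values())
    f, p = stats.f_oneway(*groups.values())
    n_total = sum(len(v) for v in groups.values())
    if not np.isfinite(f):  # identical groups
        f, p = 0.0, 1.0
    res = stats.dunnett(
        *[groups[g] for g in names],
        control=groups[control],
        alternative="two-sided",
        rng=np.random.default_rng(seed),
    )
    comp = pd.DataFrame(
        {
            "group": names,
            "statistic": res.statistic,
            "p_adjusted": res.pvalue,
            "significant": res.pvalue <= alpha,
        }
    )
    return StatReport(
        anova_f=float(f),
        anova_p=float(p),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        shapiro=shapiro,
        levene=(float(lev.statistic), float(lev.pvalue)),
        comparisons=comp,
        control=control,
    )


# ---------------------------------------------------------------------------
# PCA with supplementary variables


@dataclass
class PcaResult:
    scores: pd.DataFrame  # individuals x components
    loadings: pd.DataFrame  # active variables x components (correlation-scaled)
    explained: pd.Series  # variance fraction per component
    supplementary: pd.DataFrame  # supplementary variables x components
    dropped: list[str] = field(default_factory=list)


def pca_with_supplementary(
    active: pd.DataFrame,
    supplementary: pd.DataFrame | None = None,
    n_components: int | None = None,
) -> PcaResult:
    """Centered, unit-variance PCA of active variables; supplementary
    quantitative variables are projected by their correlation with the
    component scores and never influence the axes. Constant active columns
    are dropped with a warning."""
    if active.shape[0] < 2 or active.shape[1] < 2:
        raise DesignError("PCA needs >= 2 individuals and >= 2 variables")
    sd = active.std(axis=0, ddof=0)
    dropped = list(active.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
        active = active.drop(columns=dropped)
        sd = sd.drop(labels=dropped)
    X = (active - active.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
    k = n_components or len(s)
    k = min(k, len(s))
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=active.index, columns=comps)
    explained = pd.Series(s**2 / np.sum(s**2), index=[f"PC{i + 1}" for i in range(len(s))])[:k]
    # variable loadings as correlations with scores (FactoMineR-style circle)
    load = np.zeros((active.shape[1], k))
    for j in range(k):
        denom = np.std(scores.iloc[:, j], ddof=0)
        if denom > 0:
            load[:, j] = [
                np.corrcoef(active.iloc[:, v], scores.iloc[:, j])[0, 1]
                for v in range(active.shape[1])
            ]
    loadings = pd.DataFrame(load, index=active.columns, columns=comps)
    if supplementary is not None and supplementary.shape[1] > 0:
        sup = np.zeros((supplementary.shape[1], k))
        for v in range(supplementary.shape[1]):
            col = supplementary.iloc[:, v].to_numpy(dtype=float)
            for j in range(k):
                if np.std(col) > 0:
                    sup[v, j] = np.corrcoef(col, scores.iloc[:, j])[0, 1]
        sup_df = pd.DataFrame(sup, index=supplementary.columns, columns=comps)
    else:
        sup_df = pd.DataFrame(columns=comps)
    return PcaResult(
        scores=scores, loadings=loadings, explained=explained, supplementary=sup_df, dropped=dropped
    )


# ---------------------------------------------------------------------------
# heatmap ordering


@dataclass
class HeatmapOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    scaled: pd.DataFrame  # row z-scores for divergent-scale display


def _spearman_distance(matrix: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between rows; zero-variance rows get
    correlation 0 (distance 1) with a warning."""
    n = matrix.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)  # average ranks for ties
    sds = ranks.std(axis=1)
    if (sds == 0).any():
        warnings.warn("zero-variance rows: Spearman correlation set to 0", stacklevel=2)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    corr = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if sds[i] == 0 or sds[j] == 0:
                c = 1.0 if i == j else 0.0
            else:
                c = float(np.dot(centered[i], centered[j]) / (len(ranks[i]) * sds[i] * sds[j]))
            corr[i, j] = corr[j, i] = c
    d = np.maximum(1.0 - corr, 0.0)  # guard fp overshoot of perfect correlation
    np.fill_diagonal(d, 0.0)
    return d


def heatmap_order(matrix: pd.DataFrame, cluster_columns: bool = True) -> HeatmapOrder:
    """Row (and optionally column) dendrogram orderings.

    Distance is 1 - Spearman correlation; linkage is average (UPGMA); leaf
    order is deterministic with ties broken by input order; rows are z-scored
    per row for display.
    """
    if matrix.shape[0] < 2:
        raise DesignError("need >= 2 rows to cluster")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d_rows = _spearman_distance(matrix.to_numpy(dtype=float))
        row_link = linkage(squareform(d_rows, checks=False), method="average")
        row_order = [matrix.index[i] for i in leaves_list(row_link)]
        col_link, col_order = None, list(matrix.columns)
        if cluster_columns and matrix.shape[1] >= 2:
            d_cols = _spearman_distance(matrix.to_numpy(dtype=float).T)
            col_link = linkage(squareform(d_cols, checks=False), method="average")
            col_order = [matrix.columns[i] for i in leaves_list(col_link)]
        mu = matrix.mean(axis=1)
        sd = matrix.std(axis=1, ddof=0).replace(0, 1.0)
        scaled = matrix.sub(mu, axis=0).div(sd, axis=0)
    return HeatmapOrder(
        row_order=row_order, col_order=col_order, row_linkage=row_link,
        col_linkage=col_link, scaled=scaled,
    )
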