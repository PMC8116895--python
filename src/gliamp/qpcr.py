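"""RT-qPCR quantification: efficiency, Cq, N0, geNorm stability and NF.

Per-well amplification efficiency is estimated from raw fluorescence in the
LinRegPCR spirit: after subtracting an estimated baseline, the window of 4-6
consecutive cycles in the log-linear phase maximizing the r^2 of
log10(F) ~ cycle gives E = 10^slope. Starting quantities follow
N0 = threshold / E^Cq, with Cq the fractional cycle at which fluorescence
crosses the threshold. Reference-gene stability uses the geNorm measure
M_j = mean over k != j of SD_samples(log2(expr_j / expr_k)); normalization
factors are geometric means of the stable reference genes, rescaled so their
geometric mean over samples is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class NoAmplificationError(ValueError):
    pass


@dataclass
class EfficiencyEstimate:
    E: float
    window: tuple[int, int]  # first and last cycle of the fit window (1-based, inclusive)
    r_squared: float
    baseline: float
    warnings: list[str] = field(default_factory=list)


def _window_regressions(logf: np.ndarray, cycles: np.ndarray, lengths: tuple[int, ...]):
    """(slope, r2, start_index, length) for every window of the given lengths
    over the finite entries of logf; yields only all-finite windows."""
    out = []
    n = len(logf)
    for w in lengths:
        for s in range(0, n - w + 1):
            y = logf[s : s + w]
            if not np.all(np.isfinite(y)):
                continue
            x = cycles[s : s + w].astype(float)
            xm, ym = x.mean(), y.mean()
            sxx = np.sum((x - xm) ** 2)
            sxy = np.sum((x - xm) * (y - ym))
            syy = np.sum((y - ym) ** 2)
            if sxx == 0 or syy == 0:
                r2 = 1.0 if syy == 0 else 0.0
                slope = 0.0 if sxx == 0 else sxy / sxx
            else:
                slope = sxy / sxx
                r2 = (sxy * sxy) / (sxx * syy)
            out.append((slope, r2, s, w))
    return out


def estimate_efficiency(
    fluorescence: np.ndarray | list[float],
    min_window: int = 4,
    max_window: int = 6,
    r2_floor: float = 0.99,
    n_baseline_candidates: int = 60,
) -> EfficiencyEstimate:
    """LinRegPCR-style per-well efficiency from a raw fluorescence curve.

    The baseline is chosen by grid search (including zero) to maximize the
    best log-linear-window r^2; the window is restricted to the rising phase
    below 85% of the plateau. E outside (1, 2.2] is reported with a warning,
    never silently clamped.
    """
    f = np.asarray(fluorescence, dtype=float)
    if len(f) < 10:
        raise NoAmplificationError("curve shorter than 10 cycles")
    if not np.all(np.isfinite(f)):
        raise NoAmplificationError("non-finite fluorescence values")
    cycles = np.arange(1, len(f) + 1)
    plateau = float(f.max())
    span = plateau - float(f.min())
    if span <= 0 or plateau <= 0:
        raise NoAmplificationError("flat curve: no amplification signal")

    early = f[: max(8, len(f) // 4)]
    b_hi = float(np.percentile(early, 90))
    candidates = np.unique(np.concatenate([[0.0], np.linspace(0.0, b_hi, n_baseline_candidates)]))
    rise_cap = float(f.min()) + 0.85 * span
    signal_floor = 0.01 * span  # keep the fit window clear of baseline noise

    best = None  # (r2, window_len, slope, start, baseline)
    lengths = tuple(range(max_window, min_window - 1, -1))
    for b in candidates:
        g = f - b
        with np.errstate(divide="ignore", invalid="ignore"):
            logf = np.where(
                (g > signal_floor) & (f <= rise_cap), np.log10(np.maximum(g, 1e-300)), np.nan
            )
        for slope, r2, s, w in _window_regressions(logf, cycles, lengths):
            if slope <= 0:
                continue
            # strict improvement only: candidates are scanned from b=0 upward,
            # so ties on fit quality keep the smallest baseline
            key = (round(r2, 12), w)
            if best is None or key > (round(best[0], 12), best[1]):
                best = (r2, w, slope, s, b)
    if best is None:
        raise NoAmplificationError("no rising log-linear window found")
    r2, w, slope, s, b = best
    e = float(10.0**slope)
    warnings = []
    if r2 < r2_floor:
        warnings.append(f"low_fit_quality:r2={r2:.4f}")
    if not 1.0 < e <= 2.2:
        warnings.append(f"efficiency_out_of_range:{e:.3f}")
    return EfficiencyEstimate(
        E=e, window=(int(cycles[s]), int(cycles[s + w - 1])), r_squared=float(r2),
        baseline=float(b), warnings=warnings,
    )


def call_cq(fluorescence: np.ndarray | list[float], threshold: float) -> float:
    """Fractional cycle at which fluorescence first crosses the threshold.

    Linear interpolation in log-fluorescence between the bracketing cycles;
    NaN when the curve never reaches the threshold.
    """
    f = np.asarray(fluorescence, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = np.nonzero(f >= threshold)[0]
    if len(above) == 0:
        return float("nan")
    i = int(above[0])
    if i == 0:
        return 1.0
    f0, f1 = f[i - 1], f[i]
    if f0 <= 0:
        return float(i + 1)
    return float(i + (np.log(threshold) - np.log(f0)) / (np.log(f1) - np.log(f0)))


def compute_n0(threshold: float, efficiency: float, cq: float) -> float:
    """Starting quantity N0 = threshold / E^Cq."""
    if efficiency <= 1.0:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(threshold / efficiency**cq)


def common_threshold(curves: list[np.ndarray], baselines: list[float] | None = None) -> float:
    """One shared threshold per target: the geometric middle of the pooled
    exponential windows (between 10% and 50% of each curve's span)."""
    lows, highs = [], []
    for i, c in enumerate(curves):
        f = np.asarray(c, dtype=float)
        b = baselines[i] if baselines else float(np.percentile(f[:8], 50))
        g = f - b
        top = g.max()
        if top <= 0:
            continue
        lows.append(0.10 * top)
        highs.append(0.50 * top)
    if not lows:
        raise NoAmplificationError("no usable curves for threshold selection")
    return float(np.sqrt(np.median(lows) * np.median(highs)))


# ---------------------------------------------------------------------------
# geNorm


@dataclass
class StabilityResult:
    m_values: pd.Series  # initial M per gene
    exclusion_order: list[str]  # least stable first
    final_pair: tuple[str, str]
    v_values: dict[str, float]  # e.g. {"V2/3": ...}


def _m_values(expr: pd.DataFrame) -> pd.Series:
    log = np.log2(expr)
    genes = list(expr.index)
    m = {}
    for j in genes:
        sds = [np.std(log.loc[j] - log.loc[k], ddof=1) for k in genes if k != j]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_stability(expr: pd.DataFrame) -> StabilityResult:
    """geNorm reference-gene stability with iterative least-stable exclusion.

    ``expr`` is a genes x samples table of positive quantities (N0). Pairwise
    variations V(n/n+1) compare normalization factors built from the n and
    n+1 most stable genes.
    """
    if expr.shape[0] < 3 or expr.shape[1] < 2:
        raise ValueError("geNorm needs >= 3 genes and >= 2 samples")
    if (expr <= 0).any().any():
        raise ValueError("expression values must be positive")
    initial_m = _m_values(expr)
    remaining = expr.copy()
    exclusion: list[str] = []
    ranked_sets: dict[int, list[str]] = {}
    while remaining.shape[0] > 2:
        ranked_sets[remaining.shape[0]] = list(remaining.index)
        m = _m_values(remaining)
        worst = m.idxmax()
        exclusion.append(str(worst))
        remaining = remaining.drop(index=worst)
    ranked_sets[2] = list(remaining.index)
    final_pair = tuple(remaining.index)

    v_values = {}
    log = np.log2(expr)
    for n in range(2, expr.shape[0]):
        nf_n = log.loc[ranked_sets[n]].mean(axis=0)  # log2 geometric mean
        nf_n1 = log.loc[ranked_sets[n + 1]].mean(axis=0)
        v_values[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return StabilityResult(
        m_values=initial_m, exclusion_order=exclusion, final_pair=final_pair, v_values=v_values
    )


@dataclass
class NormalizationFactorSet:
    nf: pd.Series  # per sample, geometric mean over samples == 1
    genes_used: list[str]


def normalization_factors(expr: pd.DataFrame, genes_used: list[str]) -> NormalizationFactorSet:
    """Per-sample NF: geometric mean of the stable reference genes, rescaled
    so the geometric mean of NF across samples is 1."""
    if not genes_used:
        raise ValueError("genes_used must be non-empty")
    sub = expr.loc[genes_used]
    if (sub <= 0).any().any():
        raise ValueError("expression values must be positive")
    log_nf = np.log2(sub).mean(axis=0)
    log_nf = log_nf - log_nf.mean()  # geometric-mean-1 convention
    return NormalizationFactorSet(nf=np.power(2.0, log_nf).rename("NF"), genes_used=list(genes_used))


# ---------------------------------------------------------------------------
# curve-table driver


def quantify_wells(curves: pd.DataFrame, min_window: int = 4, max_window: int = 6) -> pd.DataFrame:
    """Per-well E/Cq/N0 from a long curve table (well, target, sample, cycle,
    fluorescence). One common threshold per target; per-target efficiency is
    the mean of the per-well estimates (the usual LinRegPCR practice)."""
    out = []
    for target, group in curves.groupby("target", sort=False):
        wells = []
        for (well, sample), g in group.groupby(["well", "sample"], sort=False):
            f = g.sort_values("cycle")["fluorescence"].to_numpy()
            wells.append((well, sample, f))
        ests = {w: estimate_efficiency(f, min_window, max_window) for w, _, f in wells}
        e_target = float(np.mean([est.E for est in ests.values()]))
        thr = common_threshold([f for _, _, f in wells], [ests[w].baseline for w, _, _ in wells])
        for well, sample, f in wells:
            est = ests[well]
            cq = call_cq(f - est.baseline, thr)
            n0 = compute_n0(thr, e_target, cq) if np.isfinite(cq) else float("nan")
            out.append(
                {
                    "well": well,
                    "target": target,
                    "sample": sample,
                    "E_well": est.E,
                    "E_target": e_target,
                    "r_squared": est.r_squared,
                    "threshold": thr,
                    "Cq": cq,
                    "N0": n0,
                    "warnings": ";".join(est.warnings),
                }
            )
    return pd.DataFrame(out)
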