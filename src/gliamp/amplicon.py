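"""Amplicon variant recovery from paired-end reads.

Implements the read-level pipeline used for the wheat alpha-gliadin amplicon:
pair merging with posterior qualities, expected-error filtering, exact
dereplication, UNOISE-style abundance-skew denoising with two-parent chimera
removal, greedy 99%-identity centroid clustering, database mapping, the
high-confidence (>=75 reads in >=3 samples) filter, and count normalization
(rarefaction factor to the smallest sample x dilution factor / qPCR
normalization factor).

Default parameters follow the study conditions: minimum merged length 160 nt,
maximum expected errors 1.0, UNOISE alpha 2, 99% clustering identity,
high-confidence threshold of 75 reads in 3 samples.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import identity, levenshtein
from .synthetic_data import ReadPair, revcomp

MAX_POSTERIOR_Q = 45
N_QUALITY = 2  # Phred assigned to N calls before expected-error filtering


@dataclass
class PipelineParams:
    min_merged_len: int = 160
    max_expected_errors: float = 1.0
    unoise_alpha: float = 2.0
    cluster_identity: float = 0.99
    min_reads: int = 75
    min_samples: int = 3
    min_overlap: int = 16
    max_mismatch_frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0.5 < self.cluster_identity <= 1.0:
            raise ValueError("cluster_identity outside (0.5, 1]")
        for name in ("min_merged_len", "max_expected_errors", "unoise_alpha", "min_reads", "min_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MergedRead:
    seq: str
    quals: np.ndarray  # per-base Phred


@dataclass
class StageLog:
    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + n


# ---------------------------------------------------------------------------
# merging

_BASE2IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE2IDX[_b] = _i
_BASE2IDX[ord("N")] = 4


def _seq_array(seqs: list[str], length: int) -> np.ndarray:
    buf = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return buf.reshape(len(seqs), length)


def _qual_array(quals: list[str], length: int) -> np.ndarray:
    buf = np.frombuffer("".join(quals).encode(), dtype=np.uint8)
    return buf.reshape(len(quals), length).astype(np.int16) - 33


def merge_pairs_batch(
    pairs: list[ReadPair],
    min_overlap: int = 16,
    max_mismatch_frac: float = 0.1,
) -> list[MergedRead | str]:
    """Merge a batch of equal-length read pairs.

    Returns one entry per pair: a MergedRead, or a rejection-reason string.
    The best ungapped overlap maximizes (matches - mismatches) over all
    overlaps >= ``min_overlap``; the merge is rejected when the best overlap's
    mismatch fraction exceeds ``max_mismatch_frac``. In the overlap,
    agreements keep the base with posterior quality min(q1+q2, 45); at
    mismatches the higher-quality base wins with quality |q1-q2| (floor 2).
    """
    if not pairs:
        return []
    lf = len(pairs[0].fwd)
    lr = len(pairs[0].rev)
    if any(len(p.fwd) != lf or len(p.rev) != lr for p in pairs):
        # mixed lengths: fall back to per-pair batches
        return [merge_pairs(p, min_overlap, max_mismatch_frac) for p in pairs]
    n = len(pairs)
    F = _seq_array([p.fwd for p in pairs], lf)
    FQ = _qual_array([p.fwd_qual for p in pairs], lf)
    R = _seq_array([revcomp(p.rev) for p in pairs], lr)
    RQ = _qual_array([p.rev_qual for p in pairs], lr)[:, ::-1]

    max_o = min(lf, lr)
    if max_o < min_overlap:
        return ["no_overlap"] * n
    best_score = np.full(n, -(10**9), dtype=np.int32)
    best_o = np.zeros(n, dtype=np.int32)
    best_m = np.zeros(n, dtype=np.int32)
    for o in range(min_overlap, max_o + 1):
        m = np.count_nonzero(F[:, lf - o :] == R[:, :o], axis=1).astype(np.int32)
        score = 2 * m - o
        upd = score > best_score
        best_score[upd] = score[upd]
        best_o[upd] = o
        best_m[upd] = m[upd]

    out: list[MergedRead | str] = []
    for i in range(n):
        o = int(best_o[i])
        mism = o - int(best_m[i])
        if o < min_overlap or mism > max_mismatch_frac * o:
            out.append("no_overlap" if o < min_overlap else "overlap_mismatch")
            continue
        fseq, rseq = F[i], R[i]
        fq, rq = FQ[i], RQ[i]
        ov_f, ov_r = fseq[lf - o :], rseq[:o]
        ovq_f, ovq_r = fq[lf - o :], rq[:o]
        agree = ov_f == ov_r
        cons = np.where(ovq_f >= ovq_r, ov_f, ov_r)
        cons[agree] = ov_f[agree]
        consq = np.where(
            agree,
            np.minimum(ovq_f + ovq_r, MAX_POSTERIOR_Q),
            np.maximum(np.abs(ovq_f - ovq_r), 2),
        )
        seq = bytes(fseq[: lf - o]).decode() + bytes(cons).decode() + bytes(rseq[o:]).decode()
        quals = np.concatenate([fq[: lf - o], consq, rq[o:]])
        out.append(MergedRead(seq=seq, quals=quals))
    return out


def merge_pairs(pair: ReadPair, min_overlap: int = 16, max_mismatch_frac: float = 0.1):
    """Merge a single read pair (see merge_pairs_batch)."""
    if not pair.fwd or not pair.rev:
        raise ValueError("empty mate sequence")
    return merge_pairs_batch([pair], min_overlap, max_mismatch_frac)[0]


# ---------------------------------------------------------------------------
# quality filtering


def expected_errors(quals) -> float:
    """Sum over bases of the Phred-implied error probability 10^(-Q/10)."""
    q = np.asarray(quals, dtype=float)
    if q.size == 0:
        return 0.0
    if (q < 0).any():
        raise ValueError("negative Phred score")
    return float(np.sum(np.power(10.0, -q / 10.0)))


def filter_reads(
    merged: list[MergedRead], params: PipelineParams, log: StageLog | None = None
) -> list[MergedRead]:
    """Keep reads with length >= min_merged_len and EE <= max_expected_errors.

    N bases are assigned Phred 2 for the expected-error computation, so any N
    content pushes a read toward rejection. Input order is preserved.
    """
    kept = []
    for r in merged:
        if len(r.seq) < params.min_merged_len:
            if log:
                log.add("too_short")
            continue
        quals = r.quals
        if "N" in r.seq:
            quals = quals.copy()
            quals[np.frombuffer(r.seq.encode(), dtype=np.uint8) == ord("N")] = N_QUALITY
        # inclusive boundary with fp-tie tolerance: EE exactly at the limit passes
        if expected_errors(quals) > params.max_expected_errors * (1.0 + 1e-9):
            if log:
                log.add("max_ee")
            continue
        kept.append(r)
    if log:
        log.add("retained", len(kept))
    return kept


# ---------------------------------------------------------------------------
# dereplication


@dataclass
class Uniques:
    seqs: list[str]
    sizes: np.ndarray  # total size, descending
    sample_counts: pd.DataFrame  # uniques x samples

    def __len__(self) -> int:
        return len(self.seqs)


def dereplicate(reads_per_sample: dict[str, list[str]]) -> Uniques:
    """Exact-sequence dereplication with per-sample sizes.

    Uniques are sorted by total size descending, ties lexicographic by
    sequence; total sizes conserve the input read count.
    """
    samples = list(reads_per_sample)
    counts: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(len(samples), dtype=np.int64))
    for j, sample in enumerate(samples):
        for seq in reads_per_sample[sample]:
            counts[seq][j] += 1
    items = sorted(counts.items(), key=lambda kv: (-int(kv[1].sum()), kv[0]))
    seqs = [s for s, _ in items]
    mat = np.array([c for _, c in items], dtype=np.int64).reshape(len(items), len(samples))
    sizes = mat.sum(axis=1)
    sc = pd.DataFrame(mat, index=pd.RangeIndex(len(seqs)), columns=samples)
    return Uniques(seqs=seqs, sizes=sizes, sample_counts=sc)


# ---------------------------------------------------------------------------
# UNOISE-style denoising


def _beta(d: int, alpha: float) -> float:
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def _max_skew_distance(ratio: float, alpha: float) -> int:
    """Largest d with ratio <= beta(d); -1 if even d=1 fails."""
    if ratio <= 0:
        return 10**6
    d = int(np.floor((np.log2(1.0 / ratio) - 1.0) / alpha))
    return d


def is_chimera(seq: str, parents: list[str]) -> bool:
    """True if seq is exactly a single-crossover product of two parents.

    Checks whether a prefix copied from one parent and a suffix copied from
    another (both larger) cover the full candidate, excluding trivial
    reconstructions from a single parent.
    """
    L = len(seq)
    pref = []
    suff = []
    for p in parents:
        k = 0
        m = min(L, len(p))
        while k < m and seq[k] == p[k]:
            k += 1
        pref.append(k)
        k = 0
        while k < m and seq[L - 1 - k] == p[len(p) - 1 - k]:
            k += 1
        suff.append(k)
    for i in range(len(parents)):
        if pref[i] >= L:  # identical to a parent: not a chimera
            return False
    for i in range(len(parents)):
        for j in range(len(parents)):
            if i != j and pref[i] + suff[j] >= L:
                return True
    return False


def denoise(
    uniques: Uniques,
    alpha: float = 2.0,
    discard_singletons: bool = True,
    log: StageLog | None = None,
) -> Uniques:
    """UNOISE-style greedy denoising plus two-parent chimera removal.

    Passing over uniques in decreasing size order, a unique is absorbed by an
    existing centroid when its Levenshtein distance d satisfies
    size_u / size_c <= beta(d) = 1 / 2^(alpha*d + 1); otherwise it founds a
    new centroid. Centroids exactly reconstructable as a single crossover of
    two larger centroids are then removed as chimeras; singletons are
    discarded by default.
    """
    cen_seqs: list[str] = []
    cen_sizes: list[int] = []
    cen_counts: list[np.ndarray] = []
    for i in range(len(uniques)):
        size = int(uniques.sizes[i])
        if discard_singletons and size < 2:
            if log:
                log.add("singletons_discarded")
            continue
        seq = uniques.seqs[i]
        row = uniques.sample_counts.iloc[i].to_numpy()
        best_j, best_d = -1, -1
        for j, (cseq, csize) in enumerate(zip(cen_seqs, cen_sizes)):
            kmax = _max_skew_distance(size / csize, alpha)
            if kmax < 1:
                continue
            d = levenshtein(seq, cseq, k=min(kmax, 10**6))
            if d >= 1 and (best_d < 0 or d < best_d):
                best_j, best_d = j, d
            elif d == 0:
                best_j, best_d = j, 0
                break
        if best_j >= 0:
            cen_sizes[best_j] += size
            cen_counts[best_j] = cen_counts[best_j] + row
        else:
            cen_seqs.append(seq)
            cen_sizes.append(size)
            cen_counts.append(row.copy())

    order = np.argsort(-np.array(cen_sizes), kind="stable")
    keep: list[int] = []
    for idx in order:
        parents = [cen_seqs[k] for k in keep if cen_sizes[k] > cen_sizes[idx]]
        if parents and is_chimera(cen_seqs[idx], parents):
            if log:
                log.add("chimeras_removed")
            continue
        keep.append(int(idx))
    seqs = [cen_seqs[k] for k in keep]
    sizes = np.array([cen_sizes[k] for k in keep], dtype=np.int64)
    mat = np.array([cen_counts[k] for k in keep], dtype=np.int64).reshape(
        len(keep), uniques.sample_counts.shape[1]
    )
    if log:
        log.add("centroids", len(seqs))
    return Uniques(
        seqs=seqs,
        sizes=sizes,
        sample_counts=pd.DataFrame(mat, columns=uniques.sample_counts.columns),
    )


# ---------------------------------------------------------------------------
# clustering and mapping


def cluster_centroids(uniques: Uniques, identity_threshold: float = 0.99) -> Uniques:
    """Greedy centroid clustering in decreasing-size order.

    A sequence joins the first centroid whose global-alignment identity
    (matching columns over alignment columns) reaches the threshold, else it
    founds a new cluster.
    """
    cen: list[int] = []
    sizes: list[int] = []
    counts: list[np.ndarray] = []
    for i in range(len(uniques)):
        row = uniques.sample_counts.iloc[i].to_numpy()
        joined = False
        for j, c in enumerate(cen):
            if identity(uniques.seqs[i], uniques.seqs[c]) >= identity_threshold:
                sizes[j] += int(uniques.sizes[i])
                counts[j] = counts[j] + row
                joined = True
                break
        if not joined:
            cen.append(i)
            sizes.append(int(uniques.sizes[i]))
            counts.append(row.copy())
    mat = np.array(counts, dtype=np.int64).reshape(len(cen), uniques.sample_counts.shape[1])
    return Uniques(
        seqs=[uniques.seqs[c] for c in cen],
        sizes=np.array(sizes, dtype=np.int64),
        sample_counts=pd.DataFrame(mat, columns=uniques.sample_counts.columns),
    )


def map_to_database(
    uniques: Uniques,
    database: list[tuple[str, str]],
    identity_threshold: float = 0.99,
    log: StageLog | None = None,
) -> pd.DataFrame:
    """Assign uniques (weighted by size) to best-identity database variants.

    Ties keep the earlier database entry; uniques below the identity
    threshold are counted as unassigned in the log. Returns a variants x
    samples raw count matrix over the full database.
    """
    if not database:
        raise ValueError("empty database")
    vids = [vid for vid, _ in database]
    refs = [seq for _, seq in database]
    exact = {seq: k for k, seq in reversed(list(enumerate(refs)))}
    samples = list(uniques.sample_counts.columns)
    mat = np.zeros((len(vids), len(samples)), dtype=np.int64)
    n_unassigned = 0
    max_len = max(len(r) for r in refs)
    kmax = int(np.ceil((1.0 - identity_threshold) * 2 * max_len)) + 2
    for i in range(len(uniques)):
        seq = uniques.seqs[i]
        row = uniques.sample_counts.iloc[i].to_numpy()
        j = exact.get(seq, -1)
        if j < 0:
            # prefilter by banded edit distance, then exact identity ranking
            cand = [k for k, ref in enumerate(refs) if levenshtein(seq, ref, k=kmax) >= 0]
            best_id, j = -1.0, -1
            for k in cand:
                ident = identity(seq, refs[k])
                if ident > best_id + 1e-12:
                    best_id, j = ident, k
                elif abs(ident - best_id) <= 1e-12 and log:
                    log.add("ties")
            if j < 0 or best_id < identity_threshold:
                n_unassigned += int(row.sum())
                j = -1
        if j >= 0:
            mat[j] += row
    if log:
        log.add("unassigned_reads", n_unassigned)
    return pd.DataFrame(mat, index=pd.Index(vids, name="variant_id"), columns=samples)


# ---------------------------------------------------------------------------
# abundance-matrix operations


def high_confidence_filter(
    matrix: pd.DataFrame, min_reads: int = 75, min_samples: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Keep variants with >= min_reads in each of >= min_samples samples.

    Thresholds are inclusive. Returns the filtered matrix and the dropped
    variant ids.
    """
    ok = (matrix >= min_reads).sum(axis=1) >= min_samples
    dropped = list(matrix.index[~ok])
    return matrix.loc[ok], dropped


def normalize_counts(
    matrix: pd.DataFrame,
    dilution: pd.Series | None = None,
    nf: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Rarefaction-factor normalization with dilution and qPCR NF adjustment.

    normalized(v, s) = raw(v, s) * (min sample total / sample-s total)
    * dilution(s) / NF(s). Returns the normalized matrix and the provenance
    trail (one entry per transformation applied, in order).
    """
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total reads in sample(s): {bad}")
    provenance = ["raw"]
    out = matrix * (totals.min() / totals)
    provenance.append("rarefied_to_smallest_sample")
    if dilution is not None:
        d = dilution.reindex(matrix.columns)
        if d.isna().any() or (d <= 0).any():
            raise ValueError("dilution factors must be positive for every sample")
        out = out * d
        provenance.append("dilution_adjusted")
    if nf is not None:
        f = nf.reindex(matrix.columns)
        if f.isna().any() or (f <= 0).any():
            raise ValueError("normalization factors must be positive for every sample")
        out = out / f
        provenance.append("nf_adjusted")
    return out, provenance


# ---------------------------------------------------------------------------
# end-to-end read pipeline


@dataclass
class PipelineResult:
    variants: Uniques  # recovered variant sequences with per-sample sizes
    raw_matrix: pd.DataFrame  # variants x samples counts after mapping
    matrix: pd.DataFrame  # after the high-confidence filter
    dropped: list[str]
    log: StageLog


def run_read_pipeline(
    readset: dict[str, list[ReadPair]],
    params: PipelineParams | None = None,
    database: list[tuple[str, str]] | None = None,
) -> PipelineResult:
    """merge -> EE/length filter -> dereplicate -> denoise -> cluster ->
    quantify -> high-confidence filter.

    With ``database`` given, per-sample counts come from mapping against it
    (the cDNA quantification mode); otherwise the recovered denoised/clustered
    variants themselves are the reference (the DNA discovery mode).
    """
    params = params or PipelineParams()
    log = StageLog()
    per_sample: dict[str, list[str]] = {}
    for sample, pairs in readset.items():
        log.add("input_pairs", len(pairs))
        merged = merge_pairs_batch(pairs, params.min_overlap, params.max_mismatch_frac)
        ok = [m for m in merged if isinstance(m, MergedRead)]
        log.add("merge_rejected", len(merged) - len(ok))
        kept = filter_reads(ok, params, log)
        per_sample[sample] = [r.seq for r in kept]
    uniques = dereplicate(per_sample)
    log.add("uniques", len(uniques))
    den = denoise(uniques, alpha=params.unoise_alpha, log=log)
    recovered = cluster_centroids(den, params.cluster_identity)
    log.add("clusters", len(recovered))
    ref = database if database is not None else [
        (f"zotu_{i + 1}", s) for i, s in enumerate(recovered.seqs)
    ]
    raw = map_to_database(uniques, ref, params.cluster_identity, log)
    filtered, dropped = high_confidence_filter(raw, params.min_reads, params.min_samples)
    if database is None:
        # keep only recovered sequences surviving the filter as the variant set
        keep_idx = [i for i, (vid, _) in enumerate(ref) if vid in set(filtered.index)]
        recovered = Uniques(
            seqs=[ref[i][1] for i in keep_idx],
            sizes=recovered.sizes[keep_idx],
            sample_counts=recovered.sample_counts.iloc[keep_idx].reset_index(drop=True),
        )
    return PipelineResult(variants=recovered, raw_matrix=raw, matrix=filtered, dropped=dropped, log=log)
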