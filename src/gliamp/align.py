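"""Pairwise alignment primitives shared by the denoising, clustering and
annotation stages.

edlib provides the edit-distance / alignment-path kernel; the identity
definition used throughout the package (matching columns over global-alignment
columns, terminal gaps excluded) lives here so every stage agrees on it.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def levenshtein(a: str, b: str, k: int = -1) -> int:
    """Edit distance between two sequences.

    ``k`` bounds the search (edlib early-exit); a return value of -1 means the
    distance exceeds ``k``.
    """
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def identity(a: str, b: str) -> float:
    """Fraction of matching columns in a global alignment of ``a`` and ``b``.

    Columns are counted over the alignment path with terminal-gap runs
    trimmed, so a sequence that is a pure prefix/suffix extension of another
    is not penalized for the overhang; internal gaps count as non-matching
    columns.
    """
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    ops = _CIGAR_RE.findall(res["cigar"])
    # trim terminal indel runs (end-gap-free convention)
    while ops and ops[0][1] in "ID":
        ops = ops[1:]
    while ops and ops[-1][1] in "ID":
        ops = ops[:-1]
    matches = 0
    columns = 0
    for n, op in ops:
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    if columns == 0:
        return 0.0
    return matches / columns


def best_hit(query: str, references: list[str], min_identity: float) -> tuple[int, float, bool]:
    """Best-identity reference for ``query``.

    Returns ``(index, identity, tied)`` where ``index`` is -1 if no reference
    reaches ``min_identity``. Ties on identity keep the earliest reference and
    set the ``tied`` flag.
    """
    best_i, best_id, tied = -1, -1.0, False
    for i, ref in enumerate(references):
        ident = identity(query, ref)
        if ident > best_id + 1e-12:
            best_i, best_id, tied = i, ident, False
        elif abs(ident - best_id) <= 1e-12:
            tied = True
    if best_id < min_identity:
        return -1, best_id, tied
    return best_i, best_id, tied
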