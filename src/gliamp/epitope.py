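"""Annotation of alpha-gliadin amplicon variants.

Reading frame, translation, pseudogene status (internal stop codons),
overlapping CD-epitope counts, 33-mer copy number, type-1 subtype labels and
genome-of-origin assignment by nearest exemplar.

Epitope matching is exact on the native (Q-encoded) peptide: the scan runs on
translated genomic/transcript sequence, where deamidation has not occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import edlib
import pandas as pd
from Bio.Seq import Seq

from .align import identity

CAT_33MER = "33mer_constituent"
CAT_FLANKING = "flanking_dq2"
CAT_INNATE = "innate_peptide"

TYPE_LABELS = ("1.1-1", "1.1-2", "1.2-4", "1.3-6", "type1_other", "non_type1", "no_cd_epitope")

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class EpitopeDef:
    name: str
    peptide: str
    category: str

    def __post_init__(self) -> None:
        if len(self.peptide) < 5 or not set(self.peptide) <= AA20:
            raise ValueError(f"epitope {self.name}: invalid peptide {self.peptide!r}")
        if self.category not in (CAT_33MER, CAT_FLANKING, CAT_INNATE):
            raise ValueError(f"epitope {self.name}: unknown category {self.category!r}")


def load_epitope_table(path: str | Path | None = None) -> list[EpitopeDef]:
    """Load an epitope TSV (name, peptide, category); default is the packaged table."""
    if path is None:
        src = resources.files("gliamp").joinpath("data/epitopes.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    defs = [EpitopeDef(r["name"], r["peptide"], r["category"]) for _, r in df.iterrows()]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate epitope names in table")
    return defs


def count_overlapping(text: str, motif: str) -> int:
    """Number of possibly-overlapping exact occurrences of ``motif`` in ``text``."""
    n, start = 0, 0
    while True:
        i = text.find(motif, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def scan_epitopes(protein: str, epitopes: list[EpitopeDef]) -> dict[str, int]:
    """Overlapping occurrence counts per epitope.

    Stop codons ('*') partition the protein; segments between stops are
    scanned independently so a match never spans a stop.
    """
    segments = protein.split("*")
    counts = {}
    for ep in epitopes:
        counts[ep.name] = sum(count_overlapping(seg, ep.peptide) for seg in segments)
    return counts


def count_33mer_copies(counts: dict[str, int], epitopes: list[EpitopeDef]) -> int:
    return sum(counts.get(ep.name, 0) for ep in epitopes if ep.category == CAT_33MER)


def has_innate_peptide(counts: dict[str, int], epitopes: list[EpitopeDef]) -> bool:
    return any(counts.get(ep.name, 0) > 0 for ep in epitopes if ep.category == CAT_INNATE)


def classify_type(counts: dict[str, int], epitopes: list[EpitopeDef]) -> str:
    """Type-1 subtype from the 33-mer constituent copy number.

    1/2/4/6 copies map to subtypes 1.1-1, 1.1-2, 1.2-4 and 1.3-6; other
    positive counts are type1_other. With zero copies, any other DQ2.5-class
    epitope (the flanking one) makes the variant non_type1; otherwise it has
    no CD epitope at all. The innate p31-43 peptide never counts toward
    CD-epitope status.
    """
    n = count_33mer_copies(counts, epitopes)
    named = {1: "1.1-1", 2: "1.1-2", 4: "1.2-4", 6: "1.3-6"}
    if n > 0:
        return named.get(n, "type1_other")
    flanking = sum(counts.get(ep.name, 0) for ep in epitopes if ep.category == CAT_FLANKING)
    return "non_type1" if flanking > 0 else "no_cd_epitope"


def translate_frame(seq: str, frame: int) -> str:
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=1))


def _longest_orf(protein: str) -> int:
    return max((len(s) for s in protein.split("*")), default=0)


def determine_frame(seq: str, reference_cds: str, min_identity: float = 0.70) -> tuple[int, str]:
    """Reading-frame offset of an amplicon within a reference CDS.

    Local (infix) alignment of the variant against the reference; the frame is
    the alignment start modulo 3. If the aligned identity falls below
    ``min_identity`` the frame maximizing the ungapped ORF length is used
    instead. Returns ``(frame_offset, method)``.
    """
    if not reference_cds.startswith("ATG"):
        raise AnnotationError("reference CDS must begin at a start codon")
    res = edlib.align(seq, reference_cds, mode="HW", task="locations")
    if res["editDistance"] >= 0 and res["locations"]:
        start = res["locations"][0][0]
        ident = 1.0 - res["editDistance"] / max(1, len(seq))
        if ident >= min_identity:
            return start % 3, "alignment"
    orf_lens = [_longest_orf(translate_frame(seq, f)) for f in range(3)]
    best = max(orf_lens)
    if best == 0:
        raise AnnotationError("no open reading frame in any frame and no alignment")
    return orf_lens.index(best), "orf_fallback"


def detect_pseudogene(seq: str, frame: int) -> tuple[bool, list[int]]:
    """Pseudogene flag plus 1-based amino-acid stop positions.

    Any stop codon in the amplicon translation counts as premature (the
    amplicon truncates the gene, so its final codon is still internal to the
    full protein).
    """
    if len(seq) < 3:
        raise AnnotationError("sequence shorter than one codon")
    protein = translate_frame(seq, frame)
    stops = [i + 1 for i, aa in enumerate(protein) if aa == "*"]
    return len(stops) > 0, stops


def assign_genome(
    seq: str,
    exemplars: dict[str, str],
    min_identity: float = 0.90,
    tie_margin: float = 0.005,
) -> tuple[str, float]:
    """Nearest-exemplar genome call (A/B/D/...), 'unassigned' below the
    identity floor or when the top two genomes tie within ``tie_margin``."""
    if not exemplars:
        raise AnnotationError("empty genome exemplar set")
    idents = sorted(
        ((identity(seq, ex), g) for g, ex in exemplars.items()),
        key=lambda t: (-t[0], t[1]),
    )
    best_id, best_g = idents[0]
    if best_id < min_identity:
        return "unassigned", best_id
    if len(idents) > 1 and best_id - idents[1][0] < tie_margin:
        return "unassigned", best_id
    return best_g, best_id


@dataclass
class AnnotatedVariant:
    variant_id: str
    seq: str
    frame_offset: int
    protein: str
    is_pseudogene: bool
    stop_positions: list[int]
    epitope_counts: dict[str, int]
    n33mer_copies: int
    type_label: str
    genome: str
    genome_identity: float = 0.0
    frame_method: str = "alignment"


def annotate_variant(
    variant_id: str,
    seq: str,
    epitopes: list[EpitopeDef],
    reference_cds: str,
    exemplars: dict[str, str] | None = None,
) -> AnnotatedVariant:
    frame, method = determine_frame(seq, reference_cds)
    protein = translate_frame(seq, frame)
    is_pseudo, stops = detect_pseudogene(seq, frame)
    counts = scan_epitopes(protein, epitopes)
    n33 = count_33mer_copies(counts, epitopes)
    label = classify_type(counts, epitopes)
    genome, gid = ("unassigned", 0.0)
    if exemplars:
        genome, gid = assign_genome(seq, exemplars)
    return AnnotatedVariant(
        variant_id=variant_id,
        seq=seq,
        frame_offset=frame,
        protein=protein,
        is_pseudogene=is_pseudo,
        stop_positions=stops,
        epitope_counts=counts,
        n33mer_copies=n33,
        type_label=label,
        genome=genome,
        genome_identity=gid,
        frame_method=method,
    )


def annotate_database(
    records: list[tuple[str, str]],
    epitopes: list[EpitopeDef],
    reference_cds: str,
    exemplars: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate a (variant_id, sequence) database into a tidy table."""
    rows = []
    for vid, seq in records:
        ann = annotate_variant(vid, seq, epitopes, reference_cds, exemplars)
        row = {
            "variant_id": vid,
            "length_bp": len(seq),
            "frame_offset": ann.frame_offset,
            "is_pseudogene": ann.is_pseudogene,
            "n33mer_copies": ann.n33mer_copies,
            "type_label": ann.type_label,
            "genome": ann.genome,
            "p31_43_present": has_innate_peptide(ann.epitope_counts, epitopes),
        }
        row.update(ann.epitope_counts)
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant_id")
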