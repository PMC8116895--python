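"""Ground-truth synthetic data for the alpha-gliadin amplicon analysis.

This module generates the four kinds of inputs the pipeline consumes, with
known truth so every downstream stage is verifiable without external data:

* an amplicon variant family (``build_family``) emulating the structure of the
  wheat cv. Bobwhite (BW208-like) alpha-gliadin amplicon: 45 variants across
  the A/B/D subgenomes, 20 of them pseudogenes, with a designed celiac-epitope
  composition (33-mer constituent copies, the flanking DQ2.5 epitope, and the
  p31-43 innate peptide in its LG-/LP- forms);
* paired-end 2x300 reads with substitution errors and optional two-parent
  chimeras (``simulate_reads``);
* a genotype x nitrogen x developmental-stage expression design with RNAi
  silencing and nitrogen-response factors (``simulate_expression``);
* raw qPCR fluorescence curves following F(c) = F0 * E^c with baseline,
  plateau saturation and Gaussian noise (``simulate_qpcr``).

The family is built on a synthetic alpha-gliadin-like template: a repetitive
P/Q-rich repeat scaffold flanked by unique ends. Epitope copy number is varied
by point-breaking repeat units (PQPQLPY -> PQPQLQY) rather than deleting them,
which mirrors how natural variants lose epitopes through SNPs and keeps every
variant within striking distance of its genome exemplar. Genome of origin is
encoded as fixed genome-diagnostic synonymous codon choices at Ser/Thr/Val
residues; variant-to-variant divergence comes from seeded synonymous codon
edits, verified to keep all pairs below the pipeline's 99% clustering
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import epitope as ep
from .align import levenshtein
from .io import SeqRecord, write_fasta, write_fastq


class ConstraintError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# protein-level building blocks (see module docstring)

PREFIX_AA = "VRVPVPQLQ"
SUFFIX_AA = "QVSQSQQQA"
FILLER_CYCLE = "QQSNQATQVQ"  # no P/F/Y/L/R: can never take part in a motif hit

UNIT = "PQPQLPY"  # the 33-mer repeat unit
UNIT_BROKEN = "PQPQLQY"  # single P->Q substitution breaks all constituent motifs
CORE_HEAD = "LQLQPF"
CORE_TAIL = "PQPQPF"

P31_BLOCK = {"LG": "LGQQQPFPPQQPY", "LP": "LPQQQPFPPQQPY", None: "LGQQQPSPPQQPY"}
A3_BLOCK = {True: "FRPQQPYPQ", False: "SRPQQPYPQ"}

# intact (U) / broken (u) unit patterns per designed 33-mer copy number
K33_PATTERN = {6: "UUU", 4: "UUu", 3: "UuU", 2: "Uuu", 1: "uuU", 0: "uuu"}

PRESEQ_AA = "MKTFLILALLAIVATTATTAVGSNQEQQVA"  # signal-peptide-like leader, 30 codons

CANON_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}
# genome-diagnostic synonymous codons (the subgenome signature)
SIGNATURE_CODON = {
    "S": {"A": "TCT", "B": "TCC", "D": "AGT"},
    "V": {"A": "GTT", "B": "GTC", "D": "GTA"},
    "T": {"A": "ACT", "B": "ACC", "D": "ACA"},
}
# synonymous alternatives used for seeded variant-to-variant divergence
SYN_ALTERNATIVES = {
    "Q": ["CAG"],
    "P": ["CCT", "CCC", "CCG"],
    "L": ["CTC", "CTA", "CTG", "TTA", "TTG"],
    "A": ["GCC", "GCA"],
}

MIN_PAIR_DIST = 6  # nucleotide edits between any two variants (> 1% of length)


def _filler(n: int) -> str:
    reps = (n // len(FILLER_CYCLE)) + 1
    return (FILLER_CYCLE * reps)[:n]


# ---------------------------------------------------------------------------
# designs


@dataclass
class VariantDesign:
    variant_id: str
    genome: str  # A | B | D
    is_pseudogene: bool
    epitope_spec: dict[str, int]
    length_bp: int
    dna_frequency: float
    k33: int = 0
    a3: bool = False
    p31_form: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.dna_frequency <= 1.0:
            raise ConstraintError(f"{self.variant_id}: dna_frequency outside (0, 1]")
        if self.length_bp < 160:
            raise ConstraintError(f"{self.variant_id}: shorter than the 160 bp length filter")
        if self.length_bp % 3:
            raise ConstraintError(f"{self.variant_id}: length must be a codon multiple")


@dataclass
class FamilyDesign:
    variants: list[VariantDesign]
    snp_rate: float = 0.02  # synonymous edits per site, approximate
    seed: int = 42
    name: str = "family"

    def __post_init__(self) -> None:
        total = sum(v.dna_frequency for v in self.variants)
        if abs(total - 1.0) > 1e-9:
            raise ConstraintError(f"family frequencies sum to {total}, not 1")


def _epitope_spec(k33: int, a3: bool, p31_form: str | None) -> dict[str, int]:
    pat = K33_PATTERN[k33]
    spec = {
        "DQ2.5-glia-a1a": int(pat[0] == "U"),
        "DQ2.5-glia-a1b": sum(pat[i] == "U" and pat[i + 1] == "U" for i in range(2)),
        "DQ2.5-glia-a2": pat.count("U"),
        "DQ2.5-glia-a3": int(a3),
        "p31-43-LG": int(p31_form == "LG"),
        "p31-43-LP": int(p31_form == "LP"),
    }
    assert sum(spec[n] for n in ("DQ2.5-glia-a1a", "DQ2.5-glia-a1b", "DQ2.5-glia-a2")) == k33
    return spec


# (genome, is_pseudogene, 33mer copies, flanking a3, p31-43 form) for the 45
# variants of the default BW208-like family. The marginals encode the study
# background: 20 pseudogenes; one six-copy genome-D putative gene (variant 13,
# 2.4% of the family); six genome-B putative genes without 33-mer constituents,
# two of them with the flanking DQ2.5 epitope; p31-43 in 38/45 variants and
# 20/25 putative genes; six variants (four putative genes) with no DQ2.5-class
# epitope; 5 putative genes with one constituent copy and 4 with four; the most
# abundant variant (19) a genome-B putative gene carrying p31-43 only.
_BW208_TABLE: list[tuple[str, bool, int, bool, str | None]] = [
    ("D", False, 1, True, "LG"),
    ("B", True, 0, False, "LG"),
    ("D", False, 4, True, "LG"),
    ("B", False, 0, True, "LG"),
    ("D", True, 4, True, "LG"),
    ("D", False, 2, True, "LG"),
    ("B", True, 0, True, "LG"),
    ("A", False, 0, True, "LG"),
    ("D", True, 2, True, None),
    ("D", False, 1, True, "LG"),
    ("D", True, 3, True, "LG"),
    ("D", False, 0, True, "LG"),
    ("D", False, 6, True, "LG"),
    ("D", True, 1, True, "LG"),
    ("A", False, 4, True, "LP"),
    ("A", True, 1, True, "LG"),
    ("B", False, 0, True, "LP"),
    ("B", True, 0, True, "LP"),
    ("B", False, 0, False, "LG"),
    ("A", True, 0, False, "LP"),
    ("D", False, 4, True, None),
    ("D", True, 2, True, "LG"),
    ("A", False, 1, True, "LG"),
    ("A", True, 0, True, "LP"),
    ("B", False, 0, False, "LG"),
    ("D", True, 0, True, "LG"),
    ("D", False, 2, True, None),
    ("A", True, 2, False, "LG"),
    ("D", False, 0, True, "LG"),
    ("B", True, 0, True, "LG"),
    ("D", False, 4, True, None),
    ("D", True, 1, False, "LP"),
    ("A", False, 0, True, "LG"),
    ("A", True, 2, True, None),
    ("B", False, 0, False, "LP"),
    ("A", True, 1, False, "LG"),
    ("D", False, 1, False, "LP"),
    ("A", True, 0, True, "LG"),
    ("A", False, 2, True, None),
    ("B", True, 0, True, "LG"),
    ("A", False, 0, True, "LP"),
    ("B", True, 0, True, "LP"),
    ("A", False, 1, False, None),
    ("B", False, 0, False, "LG"),
    ("D", False, 0, True, "LP"),
]

SIX_COPY_INDEX = 12  # variant_13
MOST_ABUNDANT_INDEX = 18  # variant_19, genome B, p31-43 only


def bw208_like(seed: int = 42) -> FamilyDesign:
    """The default 45-variant BW208-like family design."""
    n = len(_BW208_TABLE)
    freqs = np.zeros(n)
    freqs[SIX_COPY_INDEX] = 0.024
    freqs[MOST_ABUNDANT_INDEX] = 0.120
    others = [i for i in range(n) if i not in (SIX_COPY_INDEX, MOST_ABUNDANT_INDEX)]
    weights = np.array([3.0 - 2.0 * j / (len(others) - 1) for j in range(len(others))])
    freqs[others] = (1.0 - 0.024 - 0.120) * weights / weights.sum()

    lengths = [3 * (124 + (7 * i) % 11) for i in range(n)]
    variants = []
    for i, (genome, pseudo, k33, a3, p31) in enumerate(_BW208_TABLE):
        variants.append(
            VariantDesign(
                variant_id=f"variant_{i + 1:02d}",
                genome=genome,
                is_pseudogene=pseudo,
                epitope_spec=_epitope_spec(k33, a3, p31),
                length_bp=lengths[i],
                dna_frequency=float(freqs[i]),
                k33=k33,
                a3=a3,
                p31_form=p31,
            )
        )
    return FamilyDesign(variants=variants, seed=seed, name="bw208_like")


# ---------------------------------------------------------------------------
# realization


def _design_protein(vd: VariantDesign) -> str:
    """Amino-acid sequence of the amplicon window for one design."""
    pat = K33_PATTERN[vd.k33]
    core = CORE_HEAD + "".join(UNIT if c == "U" else UNIT_BROKEN for c in pat) + CORE_TAIL
    fixed = (
        PREFIX_AA
        + P31_BLOCK[vd.p31_form]
        + _filler(4)
        + core
        + _filler(4)
        + A3_BLOCK[vd.a3]
    )
    n_aa = vd.length_bp // 3
    pad = n_aa - len(fixed) - len(SUFFIX_AA)
    if pad < 5:
        raise ConstraintError(f"{vd.variant_id}: length {vd.length_bp} cannot hold epitope blocks")
    f3 = list(_filler(pad))
    if vd.is_pseudogene:
        f3[pad // 2] = "*"  # premature stop downstream of every epitope block
    return fixed + "".join(f3) + SUFFIX_AA


def _encode(protein: str, genome: str, rng: np.random.Generator | None, n_edits: int = 8) -> str:
    """Reverse-translate with the genome codon signature plus seeded synonymous edits."""
    codons = []
    for aa in protein:
        if aa in SIGNATURE_CODON and genome in SIGNATURE_CODON[aa]:
            codons.append(SIGNATURE_CODON[aa][genome])
        else:
            codons.append(CANON_CODON[aa])
    if rng is not None and n_edits > 0:
        editable = [i for i, aa in enumerate(protein) if aa in SYN_ALTERNATIVES]
        picks = rng.choice(len(editable), size=min(n_edits, len(editable)), replace=False)
        for j in picks:
            pos = editable[j]
            alts = SYN_ALTERNATIVES[protein[pos]]
            codons[pos] = alts[rng.integers(len(alts))]
    return "".join(codons)


def _template_window_protein(length_codons: int = 129) -> str:
    tmpl = VariantDesign(
        variant_id="template",
        genome="D",
        is_pseudogene=False,
        epitope_spec=_epitope_spec(6, True, "LG"),
        length_bp=3 * length_codons,
        dna_frequency=1.0,
        k33=6,
        a3=True,
        p31_form="LG",
    )
    return _design_protein(tmpl)


@dataclass
class FamilyBuild:
    design: FamilyDesign
    records: list[tuple[str, str]]  # (variant_id, nucleotide sequence)
    truth: pd.DataFrame
    reference_cds: str
    exemplars: dict[str, str]

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.records)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [SeqRecord(id=vid, seq=seq) for vid, seq in self.records],
            out_dir / "database.fasta",
        )
        self.truth.to_csv(out_dir / "truth.tsv", sep="\t")
        write_fasta(
            [SeqRecord(id=f"exemplar_{g}", seq=s) for g, s in sorted(self.exemplars.items())],
            out_dir / "genome_exemplars.fasta",
        )
        write_fasta(
            [SeqRecord(id="reference_cds", seq=self.reference_cds)],
            out_dir / "reference_cds.fasta",
        )


def build_family(design: FamilyDesign, epitopes: list[ep.EpitopeDef] | None = None) -> FamilyBuild:
    """Realize a family design into verified nucleotide sequences plus truth.

    Every realized sequence is checked against the epitope scanner (counts
    must equal the design exactly), for pseudogene status (in-frame stop iff
    designed), and for pairwise divergence (Levenshtein distance of at least
    ``MIN_PAIR_DIST`` so 99%-identity clustering cannot merge two designs).
    """
    if epitopes is None:
        epitopes = ep.load_epitope_table()
    master = np.random.default_rng(design.seed)

    def realize(vd: VariantDesign, subseed: int) -> str:
        protein = _design_protein(vd)
        seq = _encode(protein, vd.genome, np.random.default_rng(subseed))
        counts = ep.scan_epitopes(protein, epitopes)
        expected = dict(vd.epitope_spec)
        for name in counts:
            if counts.get(name, 0) != expected.get(name, 0):
                raise ConstraintError(
                    f"{vd.variant_id}: designed {expected.get(name, 0)} x {name}, "
                    f"realized {counts.get(name, 0)}"
                )
        translated = ep.translate_frame(seq, 0)
        if ("*" in translated) != vd.is_pseudogene:
            raise ConstraintError(f"{vd.variant_id}: pseudogene flag not realized")
        return seq

    seqs: list[str] = []
    for vd in design.variants:
        seq = realize(vd, int(master.integers(2**31)))
        for attempt in range(50):
            if all(levenshtein(seq, s, k=MIN_PAIR_DIST - 1) == -1 for s in seqs):
                break
            seq = realize(vd, int(master.integers(2**31)))
        else:
            raise GenerationError(f"{vd.variant_id}: identity collision after max retries")
        seqs.append(seq)

    records = [(vd.variant_id, s) for vd, s in zip(design.variants, seqs)]
    window = _template_window_protein()
    reference_cds = _encode(PRESEQ_AA, "D", None) + _encode(window, "D", None) + "TAA"
    exemplars = {g: _encode(window, g, None) for g in "ABD"}

    rows = []
    for vd, seq in zip(design.variants, seqs):
        row = {
            "variant_id": vd.variant_id,
            "genome": vd.genome,
            "is_pseudogene": vd.is_pseudogene,
            "length_bp": len(seq),
            "dna_frequency": vd.dna_frequency,
            "n33mer_copies": vd.k33,
            "p31_43_present": vd.p31_form is not None,
        }
        row.update(vd.epitope_spec)
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("variant_id")
    return FamilyBuild(design, records, truth, reference_cds, exemplars)


# ---------------------------------------------------------------------------
# paired-end read simulation


@dataclass
class ReadSimConfig:
    depth_per_sample: int = 52_000
    read_length: int = 300
    per_base_error: float = 0.001
    chimera_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error <= 0.05:
            raise ConfigurationError("per_base_error outside [0, 0.05]")
        if self.depth_per_sample <= 0:
            raise ConfigurationError("depth_per_sample must be positive")


@dataclass
class ReadPair:
    id: str
    fwd: str
    fwd_qual: str
    rev: str
    rev_qual: str
    truth: str = ""


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _error_quality(p: float) -> int:
    if p <= 0:
        return 40
    return int(round(-10.0 * np.log10(p)))


def _inject_errors(template: str, n: int, p: float, rng: np.random.Generator) -> list[str]:
    """n copies of template with iid substitution errors at rate p."""
    arr = np.frombuffer(template.encode(), dtype=np.uint8)
    idx = np.searchsorted(_BASES, arr)  # template is ACGT-only
    tiled = np.tile(idx, (n, 1))
    if p > 0:
        mask = rng.random(tiled.shape) < p
        shift = rng.integers(1, 4, size=int(mask.sum()))
        tiled[mask] = (tiled[mask] + shift) % 4
    chars = _BASES[tiled]
    return [bytes(row).decode() for row in chars]


def simulate_reads(
    database: list[tuple[str, str]],
    per_sample_abundances: dict[str, dict[str, float]],
    config: ReadSimConfig,
) -> dict[str, list[ReadPair]]:
    """Multinomial paired-end read simulation.

    Forward reads cover the amplicon 5' end, reverse reads the 3' end
    (reverse-complemented), each ``read_length`` long with substitution errors
    at ``per_base_error`` and flat Phred qualities matching that rate.
    A fraction ``chimera_rate`` of pairs derive from single-crossover
    two-parent chimera templates. Deterministic given ``config.seed``.
    """
    if not database:
        raise ConfigurationError("empty database")
    seqs = dict(database)
    min_len = min(len(s) for s in seqs.values())
    if config.read_length > min_len:
        raise ConfigurationError(
            f"read_length {config.read_length} exceeds shortest amplicon ({min_len} bp)"
        )
    rng = np.random.default_rng(config.seed)
    qual_char = chr(_error_quality(config.per_base_error) + 33)
    out: dict[str, list[ReadPair]] = {}
    for sample, abund in per_sample_abundances.items():
        vids = [vid for vid, _ in database if abund.get(vid, 0.0) > 0]
        weights = np.array([abund[v] for v in vids], dtype=float)
        if (weights < 0).any():
            raise ConfigurationError(f"negative abundance in sample {sample}")
        probs = weights / weights.sum()
        n_chim = rng.binomial(config.depth_per_sample, config.chimera_rate)
        counts = rng.multinomial(config.depth_per_sample - n_chim, probs)
        pairs: list[ReadPair] = []
        for vid, n in zip(vids, counts):
            if n == 0:
                continue
            pairs.extend(_simulate_from_template(sample, vid, seqs[vid], n, config, qual_char, rng))
        for j in range(n_chim):
            a, b = rng.choice(len(vids), size=2, replace=False, p=probs)
            sa, sb = seqs[vids[a]], seqs[vids[b]]
            k = int(rng.integers(50, min(len(sa), len(sb)) - 50))
            template = sa[:k] + sb[k:]
            pairs.extend(
                _simulate_from_template(
                    sample, f"chimera:{vids[a]}:{vids[b]}:{k}", template, 1, config, qual_char, rng
                )
            )
        for i, pr in enumerate(pairs):
            pr.id = f"{sample}:{i} truth={pr.truth}"
        out[sample] = pairs
    return out


def _simulate_from_template(sample, truth, template, n, config, qual_char, rng) -> list[ReadPair]:
    L = config.read_length
    fwd_t = template[:L]
    rev_t = revcomp(template[-L:])
    fwds = _inject_errors(fwd_t, n, config.per_base_error, rng)
    revs = _inject_errors(rev_t, n, config.per_base_error, rng)
    qual = qual_char * L
    return [
        ReadPair(id="", fwd=f, fwd_qual=qual, rev=r, rev_qual=qual, truth=truth)
        for f, r in zip(fwds, revs)
    ]


def write_paired_fastq(readset: dict[str, list[ReadPair]], out_dir: str | Path, gz: bool = True) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gz else ".fastq"
    for sample, pairs in readset.items():
        write_fastq(
            (SeqRecord(id=p.id, seq=p.fwd, qual=p.fwd_qual) for p in pairs),
            out_dir / f"{sample}_R1{ext}",
        )
        write_fastq(
            (SeqRecord(id=p.id, seq=p.rev, qual=p.rev_qual) for p in pairs),
            out_dir / f"{sample}_R2{ext}",
        )


# ---------------------------------------------------------------------------
# expression design


@dataclass
class ExpressionDesign:
    """Genotype x nitrogen x DPA expression truth for the amplicon family.

    ``silencing_factor`` multiplies putative-gene abundance (RNAi lines only);
    ``n_response_factor`` is the high-N/low-N ratio applied to nitrogen
    responsive variants (putative genes on the A and D subgenomes);
    ``dpa_profile`` is a grain-filling trajectory peaking at 18 days post
    anthesis; multiplicative lognormal noise has coefficient of variation
    ``noise_cv``.
    """

    baseline_abundance: dict[str, float]
    putative_variants: set[str]
    responsive_variants: set[str]
    genotypes: tuple[str, ...] = ("wild_type", "rnai_hordein_promoter", "rnai_gliadin_promoter")
    n_levels: tuple[str, ...] = ("low", "high")
    dpa: tuple[int, ...] = (10, 18, 26)
    blocks: int = 2
    silencing_factor: dict[str, float] = field(
        default_factory=lambda: {
            "wild_type": 1.0,
            "rnai_hordein_promoter": 0.35,
            "rnai_gliadin_promoter": 0.08,
        }
    )
    n_response_factor: dict[str, float] = field(
        default_factory=lambda: {
            "wild_type": 2.5,
            "rnai_hordein_promoter": 4.0,
            "rnai_gliadin_promoter": 1.0,
        }
    )
    dpa_profile: dict[int, float] = field(default_factory=lambda: {10: 0.4, 18: 1.0, 26: 0.7})
    noise_cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for g, f in self.silencing_factor.items():
            if g != "wild_type" and not f < 1.0:
                raise ConstraintError(f"RNAi silencing factor for {g} must be < 1")
        if self.silencing_factor.get("wild_type", 1.0) != 1.0:
            raise ConstraintError("wild_type silencing factor must be 1")


def default_expression_design(truth: pd.DataFrame, seed: int = 0, noise_cv: float = 0.25) -> ExpressionDesign:
    """Expression design derived from a family truth table."""
    baseline = (truth["dna_frequency"] * 1000.0).to_dict()
    putative = set(truth.index[~truth["is_pseudogene"]])
    responsive = set(truth.index[(~truth["is_pseudogene"]) & truth["genome"].isin(["A", "D"])])
    return ExpressionDesign(
        baseline_abundance=baseline,
        putative_variants=putative,
        responsive_variants=responsive,
        noise_cv=noise_cv,
        seed=seed,
    )


def simulate_expression(design: ExpressionDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True per-sample abundances plus the sample sheet.

    abundance(variant, sample) = baseline x silencing (putative genes) x
    nitrogen response (responsive variants at high N) x DPA profile x
    lognormal(noise_cv) noise with unit mean.
    """
    rng = np.random.default_rng(design.seed)
    sigma = float(np.sqrt(np.log(1.0 + design.noise_cv**2)))
    variants = list(design.baseline_abundance)
    samples, meta = [], []
    values = {}
    for gt in design.genotypes:
        for nl in design.n_levels:
            for d in design.dpa:
                for b in range(1, design.blocks + 1):
                    sid = f"{gt}.{nl}N.{d}dpa.b{b}"
                    samples.append(sid)
                    meta.append(
                        {"sample_id": sid, "genotype": gt, "n_level": nl, "dpa": d, "block": b}
                    )
                    col = np.empty(len(variants))
                    for i, v in enumerate(variants):
                        x = design.baseline_abundance[v]
                        if v in design.putative_variants:
                            x *= design.silencing_factor[gt]
                        if v in design.responsive_variants and nl == "high":
                            x *= design.n_response_factor[gt]
                        x *= design.dpa_profile[d]
                        if design.noise_cv > 0:
                            x *= rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                        col[i] = x
                    values[sid] = col
    table = pd.DataFrame(values, index=pd.Index(variants, name="variant_id"))
    return table, pd.DataFrame(meta).set_index("sample_id")


# ---------------------------------------------------------------------------
# qPCR fluorescence simulation


@dataclass
class QpcrSimConfig:
    efficiencies: dict[str, float]  # true per-target amplification efficiency E in (1, 2]
    cycles: int = 40
    baseline: float = 50.0
    plateau: float = 4000.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ConfigurationError(f"target {t}: efficiency {e} outside (1, 2]")


def simulate_qpcr(config: QpcrSimConfig, wells: pd.DataFrame) -> pd.DataFrame:
    """Raw fluorescence curves for a well table (well, target, sample, n0).

    F(c) = baseline + min(n0 * E^c, plateau) plus Gaussian noise: exact
    exponential growth until the signal saturates at the plateau. Expected
    fluorescence is non-decreasing until the plateau.
    """
    rng = np.random.default_rng(config.seed)
    cyc = np.arange(1, config.cycles + 1)
    rows = []
    for _, w in wells.iterrows():
        e = config.efficiencies[w["target"]]
        x = w["n0"] * np.power(e, cyc)
        f = config.baseline + np.minimum(x, config.plateau)
        if config.noise_sd > 0:
            f = f + rng.normal(0.0, config.noise_sd, size=len(cyc))
        for c, v in zip(cyc, f):
            rows.append(
                {
                    "well": w["well"],
                    "target": w["target"],
                    "sample": w["sample"],
                    "cycle": int(c),
                    "fluorescence": float(v),
                }
            )
    return pd.DataFrame(rows)
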