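"""Core record types and coordinate conventions.

Coordinate conventions used throughout the package:

* Internal coordinates are **0-based, half-open**. Breakpoints of
  insertion/deletion variants are 0-based *between-base* offsets on the
  bait locus: position ``p`` sits between 1-based bases ``p`` and ``p+1``.
* Every human-facing report (RIP tables, candidate tables) is **1-based
  inclusive**; BED output is 0-based half-open. The two are therefore
  related by ``bed_start = report_start - 1`` for every emitted record.
* Gene models carry 1-based inclusive exon intervals on the locus frame,
  as they appear in exon tables.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DNA_ALPHABET",
    "revcomp",
    "LocusSequence",
    "GeneModel",
    "RepeatConsensus",
    "CandidateSV",
    "RipRecord",
    "GenotypeCounts",
    "PopGenResult",
    "label_feature",
]

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENOTYPES = ("+/+", "+/-", "-/-")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusSequence:
    """A named DNA sequence with an optional chromosomal anchor.

    ``offset`` is the 1-based chromosomal position of the first base
    (0 when the sequence is unplaced).
    """

    name: str
    seq: str
    breed: str = ""
    offset: int = 0
    chrom: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"locus {self.name!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"locus {self.name!r}: non-DNA symbol(s) {sorted(bad)!r}"
            )
        if self.offset < 0:
            raise ValueError(f"locus {self.name!r}: negative offset")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of a gene on the locus coordinate frame.

    Exons are 1-based inclusive ``(start, end)`` intervals in genomic
    order; introns are the gaps between consecutive exons. ``strand``
    orients exon/intron numbering: on '-', Exon1/Intron1 are adjacent to
    the transcription start at the genomic right end.
    """

    gene_name: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_name!r}: at least one exon required")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(
                    f"gene {self.gene_name!r}: bad exon interval ({start},{end})"
                )
            if start <= prev_end:
                raise ValueError(
                    f"gene {self.gene_name!r}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive genomic span of the gene."""
        return self.exons[0][0], self.exons[-1][1]

    def intron_interval(self, k: int) -> tuple[int, int]:
        """Genomic 1-based inclusive interval of intron ``k`` (transcription order)."""
        if not 1 <= k <= self.n_introns:
            raise ValueError(f"gene {self.gene_name!r} has no intron {k}")
        gi = k if self.strand == "+" else len(self.exons) - k
        return self.exons[gi - 1][1] + 1, self.exons[gi][0] - 1


@dataclass(frozen=True)
class RepeatConsensus:
    """A repeat-family consensus sequence (no ambiguous bases allowed)."""

    name: str
    repeat_class: str  # SINE, LINE, or ERV
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"consensus {self.name!r}: empty sequence")
        bad = set(self.seq) - (DNA_ALPHABET - {"N"})
        if bad:
            raise ValueError(
                f"consensus {self.name!r}: disallowed symbol(s) {sorted(bad)!r}"
            )
        if self.repeat_class not in ("SINE", "LINE", "ERV"):
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CandidateSV:
    """An insertion or deletion relative to the bait locus.

    ``bait_pos`` is the 0-based between-base breakpoint on the bait (the
    insertion point for INS; the start of the deleted bait segment for
    DEL). ``seq`` is the inserted (INS) or deleted (DEL) sequence.
    """

    sv_type: str  # "INS" or "DEL"
    bait_pos: int
    length: int
    seq: str
    sources: frozenset[str] = frozenset()
    members: tuple["CandidateSV", ...] = ()

    def __post_init__(self) -> None:
        if self.sv_type not in ("INS", "DEL"):
            raise ValueError(f"sv_type must be INS or DEL, got {self.sv_type!r}")
        if self.length < 1:
            raise ValueError("SV length must be >= 1")
        if len(self.seq) != self.length:
            raise ValueError("seq length does not match declared length")
        if self.bait_pos < 0:
            raise ValueError("negative breakpoint")
        self.sources = frozenset(self.sources)


@dataclass
class RipRecord:
    """An annotated polymorphic retrotransposon insertion (one report row)."""

    rip_name: str
    sv: CandidateSV
    family: str
    repeat_class: str  # SINE / LINE / ERV / "none"
    direction: str  # "+", "-", or "." when unclassified
    identity: float
    insertion_coverage: float
    tsd: str
    feature_label: str
    chrom_span: str

    def __post_init__(self) -> None:
        if (self.family == "unclassified") != (self.direction == "."):
            raise ValueError("direction '.' iff family is unclassified")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")
        if not 0.0 <= self.insertion_coverage <= 1.0:
            raise ValueError("insertion coverage outside [0,1]")

    @property
    def element_length(self) -> int:
        """Length of the element proper: detected SV length minus the TSD.

        A retrotransposition event duplicates its target site, so the raw
        inserted segment is element + one extra TSD copy; reports quote
        the element length.
        """
        return self.sv.length - len(self.tsd)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for a biallelic insertion locus in one breed."""

    breed: str
    n_ins_ins: int
    n_ins_del: int
    n_del_del: int

    def __post_init__(self) -> None:
        for n in (self.n_ins_ins, self.n_ins_del, self.n_del_del):
            if n < 0 or int(n) != n:
                raise ValueError("genotype counts must be non-negative integers")
        if self.total < 1:
            raise ValueError("at least one individual required")

    @property
    def total(self) -> int:
        return self.n_ins_ins + self.n_ins_del + self.n_del_del

    @property
    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_ins_ins, self.n_ins_del, self.n_del_del)


@dataclass(frozen=True)
class PopGenResult:
    """Per-breed population-genetic summary of one insertion locus."""

    breed: str
    n: int
    p_ins: float
    p_del: float
    geno_freq: tuple[float, float, float]
    hwe_chi2: float
    hwe_df: int
    hwe_p: float
    pic: float
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if abs(self.p_ins + self.p_del - 1.0) > 1e-12:
            raise ValueError("allele frequencies must sum to 1")
        if abs(sum(self.geno_freq) - 1.0) > 1e-12:
            raise ValueError("genotype frequencies must sum to 1")
        if self.pic > 0.375 + 1e-12:
            raise ValueError("biallelic PIC cannot exceed 0.375")


def label_feature(sv: "CandidateSV | int", model: GeneModel) -> str:
    """Place a breakpoint relative to a gene model.

    Returns ``"ExonK"`` / ``"IntronK"`` with K counted 1-based in
    transcription order (respecting ``model.strand``), or
    ``"upstream"`` / ``"downstream"`` outside the gene span. A breakpoint
    exactly at an exon boundary does not interrupt the exon and is
    assigned to the adjacent intron (or flank).
    """
    pos = sv.bait_pos if isinstance(sv, CandidateSV) else int(sv)
    exons = model.exons
    n = len(exons)

    # Classify in genomic order first.
    if pos <= exons[0][0] - 1:
        genomic = ("flank_left", 0)
    elif pos >= exons[-1][1]:
        genomic = ("flank_right", 0)
    else:
        genomic = None
        for i, (start, end) in enumerate(exons):
            if start <= pos <= end - 1:
                genomic = ("exon", i + 1)
                break
            if i + 1 < n and end <= pos <= exons[i + 1][0] - 1:
                genomic = ("intron", i + 1)
                break
        assert genomic is not None

    kind, k = genomic
    if model.strand == "+":
        if kind == "flank_left":
            return "upstream"
        if kind == "flank_right":
            return "downstream"
        return f"{'Exon' if kind == 'exon' else 'Intron'}{k}"
    # '-' strand: numbering mirrors, flanks swap.
    if kind == "flank_left":
        return "downstream"
    if kind == "flank_right":
        return "upstream"
    if kind == "exon":
        return f"Exon{n - k + 1}"
    return f"Intron{n - k}"
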