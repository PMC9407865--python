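"""Classification of candidate insertions against a repeat-consensus library.

Each insertion is locally aligned (Smith-Waterman, affine gaps) against
every consensus and its reverse complement; the best-scoring hit assigns
family, class, and orientation when it clears the identity and
insertion-coverage thresholds. Target-site duplications are searched in
a rotation-aware way around the (left-normalized) breakpoint, and the
results are assembled into report records named
``<gene>-<class>-RIP<serial>``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .model import (
    CandidateSV,
    GeneModel,
    LocusSequence,
    RepeatConsensus,
    RipRecord,
    label_feature,
    revcomp,
)

__all__ = [
    "AnnotationParams",
    "Classification",
    "classify_insertion",
    "detect_tsd",
    "build_rip_record",
    "annotate_insertions",
]


@dataclass(frozen=True)
class AnnotationParams:
    min_identity: float = 0.70
    min_insertion_coverage: float = 0.80
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -1
    tsd_min: int = 5
    tsd_max: int = 20
    tsd_max_mismatch: int = 1
    tsd_search_window: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")
        if self.tsd_min > self.tsd_max:
            raise ValueError("tsd_min must not exceed tsd_max")


@dataclass(frozen=True)
class Classification:
    family: str
    repeat_class: str
    direction: str
    identity: float
    insertion_coverage: float


def _local_aligner(params: AnnotationParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _identity_and_coverage(alignment, sv_seq: str) -> tuple[float, float]:
    """Identity over alignment columns; coverage over the insertion."""
    sv_blocks, cons_blocks = alignment.aligned
    matches = 0
    aligned_cols = 0
    aligned_sv = 0
    prev_s = prev_c = None
    for (ss, se), (cs, ce) in zip(sv_blocks, cons_blocks):
        if prev_s is not None:
            aligned_cols += (ss - prev_s) + (cs - prev_c)  # internal gap columns
        a = alignment.target[ss:se]
        b = alignment.query[cs:ce]
        matches += sum(x == y for x, y in zip(a, b))
        aligned_cols += se - ss
        aligned_sv += se - ss
        prev_s, prev_c = se, ce
    if aligned_cols == 0:
        return 0.0, 0.0
    return matches / aligned_cols, aligned_sv / len(sv_seq)


def classify_insertion(
    sv: CandidateSV,
    library: Sequence[RepeatConsensus],
    params: AnnotationParams | None = None,
) -> Classification:
    """Assign a repeat family and orientation to an insertion.

    The hit is accepted only when identity >= ``min_identity`` AND
    insertion coverage >= ``min_insertion_coverage``; otherwise the
    insertion is reported unclassified with the best identity/coverage
    observed. Orientation '+' means the forward consensus won; score
    ties prefer '+'.
    """
    if sv.sv_type != "INS":
        raise ValueError("only insertions are classified against the library")
    if not library:
        raise ValueError("empty consensus library")
    params = params or AnnotationParams()
    aligner = _local_aligner(params)
    best = None  # (score, name, class, direction, identity, coverage)
    for cons in library:
        for direction, cseq in (("+", cons.seq), ("-", revcomp(cons.seq))):
            alignments = aligner.align(sv.seq, cseq)
            if len(alignments) == 0:
                continue
            alignment = alignments[0]
            score = alignment.score
            if best is None or score > best[0]:
                ident, cov = _identity_and_coverage(alignment, sv.seq)
                best = (score, cons.name, cons.repeat_class, direction, ident, cov)
    assert best is not None
    _, name, rclass, direction, ident, cov = best
    if ident >= params.min_identity and cov >= params.min_insertion_coverage:
        return Classification(name, rclass, direction, ident, cov)
    return Classification("unclassified", "none", ".", ident, cov)


def detect_tsd(
    bait: LocusSequence, sv: CandidateSV, params: AnnotationParams | None = None
) -> str:
    """Find the target-site duplication of an insertion, if any.

    Returns the longest duplicated word of length in
    [``tsd_min``, ``tsd_max``] present both on the bait at the breakpoint
    and at the corresponding end(s) of the inserted sequence (any
    left-normalization rotation is accounted for). Exact duplications are
    preferred; only when none exists is a copy with up to
    ``tsd_max_mismatch`` mismatches accepted. Ties at equal length go to
    the smallest rotation (the configuration closest to the un-shifted
    one). Empty string when no duplication is found.
    """
    if sv.sv_type != "INS":
        raise ValueError("TSDs are only defined for insertions")
    params = params or AnnotationParams()
    ins = sv.seq
    bp = sv.bait_pos

    def scan(max_mm: int) -> str:
        for length in range(min(params.tsd_max, len(ins)), params.tsd_min - 1, -1):
            for s in range(0, length + 1):
                left = length - s
                if bp - left < 0 or bp + s > len(bait.seq):
                    continue
                bait_word = bait.seq[bp - left : bp + s]
                ins_word = (ins[-left:] if left else "") + (ins[:s] if s else "")
                if len(ins_word) != length:
                    continue
                mismatches = sum(a != b for a, b in zip(bait_word, ins_word))
                if mismatches <= max_mm:
                    return bait_word
        return ""

    exact = scan(0)
    if exact:
        return exact
    if params.tsd_max_mismatch > 0:
        return scan(params.tsd_max_mismatch)
    return ""


def _consensus_tsd(
    bait: LocusSequence, sv: CandidateSV, params: AnnotationParams
) -> str:
    """TSD call corroborated across a cluster's member genomes.

    Background SNPs can corrupt one genome's copy of the duplicated word;
    the per-member calls are therefore taken to a majority vote (the
    representative's own call breaks ties).
    """
    own = detect_tsd(bait, sv, params)
    if not sv.members or len(sv.members) == 1:
        return own
    calls = [detect_tsd(bait, m, params) for m in sv.members]
    counts = Counter(calls)
    top = max(counts.values())
    winners = [c for c, n in counts.items() if n == top]
    return own if own in winners else winners[0]


def build_rip_record(
    sv: CandidateSV,
    classification: Classification,
    tsd: str,
    model: GeneModel,
    locus: LocusSequence,
    rip_name: str | None = None,
) -> RipRecord:
    """Assemble one report row from its parts.

    The chromosome span uses the report dialect: a 2-bp interval flanking
    the breakpoint for insertions absent from the reference frame, the
    full span for deletions (element present in the reference).
    """
    contig = locus.chrom or locus.name
    base = locus.offset - 1 if locus.offset else 0  # chromosomal shift
    if sv.sv_type == "INS":
        # 2-bp interval flanking the breakpoint (bases bp and bp+1, 1-based)
        left = base + sv.bait_pos
        span = f"{contig}:{left}-{left + 1}"
    else:
        start = base + sv.bait_pos + 1
        span = f"{contig}:{start}-{start + sv.length - 1}"
    name = rip_name or f"{model.gene_name}-{classification.repeat_class}-RIP"
    return RipRecord(
        rip_name=name,
        sv=sv,
        family=classification.family,
        repeat_class=classification.repeat_class,
        direction=classification.direction,
        identity=classification.identity,
        insertion_coverage=classification.insertion_coverage,
        tsd=tsd,
        feature_label=label_feature(sv, model),
        chrom_span=span,
    )


def annotate_insertions(
    svs: Sequence[CandidateSV],
    library: Sequence[RepeatConsensus],
    model: GeneModel,
    bait: LocusSequence,
    params: AnnotationParams | None = None,
) -> list[RipRecord]:
    """Classify and name every candidate insertion of one locus.

    Serials are per (gene, class) in breakpoint order; a lone RIP keeps
    the bare ``-RIP`` suffix, multiple ones are numbered ``-RIP1``,
    ``-RIP2``, ...
    """
    params = params or AnnotationParams()
    records = []
    for sv in svs:
        if sv.sv_type != "INS":
            continue
        cls = classify_insertion(sv, library, params)
        tsd = _consensus_tsd(bait, sv, params) if cls.family != "unclassified" else ""
        records.append(build_rip_record(sv, cls, tsd, model, bait))
    # assign serials per repeat class
    by_class = Counter(r.repeat_class for r in records)
    seen: Counter = Counter()
    for r in records:
        if by_class[r.repeat_class] > 1:
            seen[r.repeat_class] += 1
            r.rip_name = f"{model.gene_name}-{r.repeat_class}-RIP{seen[r.repeat_class]}"
    return records
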