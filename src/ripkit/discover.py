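"""Large-indel discovery between a bait locus and assembly-derived sequences.

Strategy: seed the pairwise comparison with k-mers that are unique in
both sequences, chain the seeds collinearly (weighted
longest-increasing-subsequence on merged exact-match runs), resolve the
inter-anchor gap segments by global affine alignment when both sides
are small enough, and read insertions/deletions >= ``min_sv_len`` off
the resulting segment structure. Cross-genome recurrence is restored by
clustering near-identical calls over breeds and keeping clusters
supported by at least ``min_sources`` distinct breeds.

Insertion/deletion breakpoints are left-normalized (shifted to their
leftmost equivalent placement) so that calls from different genomes are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from Bio import Align

from .model import CandidateSV, LocusSequence, revcomp
from .simulate import left_normalize_insertion

__all__ = [
    "AlignmentError",
    "Anchor",
    "GapSegment",
    "AnchorChain",
    "DiscoveryParams",
    "align_locus",
    "extract_svs",
    "cluster_svs",
    "discover_svs",
    "insilico_pcr",
]


class AlignmentError(RuntimeError):
    """No collinear anchor chain could be built for a sequence pair."""


@dataclass(frozen=True)
class Anchor:
    """An aligned (not necessarily exact) collinear segment."""

    bait_pos: int
    query_pos: int
    length: int


@dataclass(frozen=True)
class GapSegment:
    """Unaligned space between consecutive anchors (0-based half-open)."""

    bait_start: int
    bait_end: int
    query_start: int
    query_end: int

    @property
    def bait_len(self) -> int:
        return self.bait_end - self.bait_start

    @property
    def query_len(self) -> int:
        return self.query_end - self.query_start


@dataclass
class AnchorChain:
    """Collinear decomposition of a bait/query pair into anchors and gaps."""

    bait: LocusSequence
    query: LocusSequence
    anchors: list[Anchor]
    gaps: list[GapSegment]


@dataclass(frozen=True)
class DiscoveryParams:
    k: int = 31
    min_sv_len: int = 50
    cluster_pos_tol: int = 20
    cluster_len_tol: float = 0.1
    min_sources: int = 2
    band: int = 64
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -1
    max_gap_align: int = 5000

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("anchor k-mer size must be >= 11")
        if self.min_sv_len < 1 or self.min_sources < 1:
            raise ValueError("min_sv_len and min_sources must be >= 1")


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in seen:
            dup.add(kmer)
        else:
            seen[kmer] = i
    for kmer in dup:
        del seen[kmer]
    return seen


def _merge_runs(pairs: list[tuple[int, int]], k: int) -> list[Anchor]:
    """Merge co-diagonal, consecutive k-mer hits into maximal runs."""
    runs: list[Anchor] = []
    pairs.sort()
    prev = None
    for bp, qp in pairs:
        if prev and bp == prev.bait_pos + prev.length - k + 1 and qp - bp == prev.query_pos - prev.bait_pos:
            prev = Anchor(prev.bait_pos, prev.query_pos, prev.length + 1)
            runs[-1] = prev
        else:
            prev = Anchor(bp, qp, k)
            runs.append(prev)
    return runs


def _chain(runs: list[Anchor]) -> list[Anchor]:
    """Heaviest collinear chain (strictly increasing, non-overlapping)."""
    runs = sorted(runs, key=lambda a: (a.bait_pos, a.query_pos))
    n = len(runs)
    best = [a.length for a in runs]
    back = [-1] * n
    for i in range(n):
        ai = runs[i]
        for j in range(i):
            aj = runs[j]
            if (
                aj.bait_pos + aj.length <= ai.bait_pos
                and aj.query_pos + aj.length <= ai.query_pos
                and best[j] + ai.length > best[i]
            ):
                best[i] = best[j] + ai.length
                back[i] = j
    i = max(range(n), key=best.__getitem__)
    chain = []
    while i != -1:
        chain.append(runs[i])
        i = back[i]
    return chain[::-1]


def _aligner(params: DiscoveryParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _resolve_gap(
    gap: GapSegment,
    bait_seq: str,
    query_seq: str,
    params: DiscoveryParams,
) -> tuple[list[Anchor], list[GapSegment]]:
    """Split a mixed gap into aligned sub-anchors and pure indel gaps."""
    if gap.bait_len == 0 or gap.query_len == 0:
        return [], [gap]
    if max(gap.bait_len, gap.query_len) > params.max_gap_align:
        return [], [gap]  # passed through as a raw length-difference segment
    b = bait_seq[gap.bait_start : gap.bait_end]
    q = query_seq[gap.query_start : gap.query_end]
    alignment = _aligner(params).align(b, q)[0]
    b_blocks, q_blocks = alignment.aligned
    anchors = []
    gaps = []
    prev_b, prev_q = gap.bait_start, gap.query_start
    for (bs, be), (qs, qe) in zip(b_blocks, q_blocks):
        bs, be = bs + gap.bait_start, be + gap.bait_start
        qs, qe = qs + gap.query_start, qe + gap.query_start
        if bs > prev_b or qs > prev_q:
            gaps.append(GapSegment(prev_b, bs, prev_q, qs))
        anchors.append(Anchor(bs, qs, be - bs))
        prev_b, prev_q = be, qe
    if prev_b < gap.bait_end or prev_q < gap.query_end:
        gaps.append(GapSegment(prev_b, gap.bait_end, prev_q, gap.query_end))
    return anchors, gaps


def align_locus(
    bait: LocusSequence, query: LocusSequence, params: DiscoveryParams | None = None
) -> AnchorChain:
    """Build the anchor chain between the bait and one query locus.

    Raises :class:`AlignmentError` when no forward collinear chain exists
    (e.g. the query is reverse-complemented); the caller may retry on the
    reverse complement.
    """
    params = params or DiscoveryParams()
    bk = _unique_kmers(bait.seq, params.k)
    qk = _unique_kmers(query.seq, params.k)
    pairs = [(bp, qk[kmer]) for kmer, bp in bk.items() if kmer in qk]
    if not pairs:
        raise AlignmentError(
            f"no shared unique {params.k}-mers between {bait.name!r} and {query.name!r}"
        )
    chain = _chain(_merge_runs(pairs, params.k))

    # gaps between consecutive chained anchors, plus the two ends
    raw_gaps = []
    prev_b, prev_q = 0, 0
    for a in chain:
        if a.bait_pos > prev_b or a.query_pos > prev_q:
            raw_gaps.append(GapSegment(prev_b, a.bait_pos, prev_q, a.query_pos))
        prev_b, prev_q = a.bait_pos + a.length, a.query_pos + a.length
    if prev_b < len(bait.seq) or prev_q < len(query.seq):
        raw_gaps.append(GapSegment(prev_b, len(bait.seq), prev_q, len(query.seq)))

    anchors = list(chain)
    gaps: list[GapSegment] = []
    for gap in raw_gaps:
        sub_anchors, sub_gaps = _resolve_gap(gap, bait.seq, query.seq, params)
        anchors.extend(sub_anchors)
        gaps.extend(sub_gaps)
    anchors.sort(key=lambda a: a.bait_pos)
    gaps.sort(key=lambda g: g.bait_start)
    return AnchorChain(bait=bait, query=query, anchors=anchors, gaps=gaps)


def _trim_common_flanks(b: str, q: str) -> tuple[int, str, str]:
    """Trim shared prefix/suffix; returns (prefix_len, bait_rest, query_rest)."""
    pre = 0
    while pre < len(b) and pre < len(q) and b[pre] == q[pre]:
        pre += 1
    suf = 0
    while (
        suf < len(b) - pre and suf < len(q) - pre and b[len(b) - 1 - suf] == q[len(q) - 1 - suf]
    ):
        suf += 1
    return pre, b[pre : len(b) - suf], q[pre : len(q) - suf]


def extract_svs(chain: AnchorChain, params: DiscoveryParams | None = None) -> list[CandidateSV]:
    """Read candidate insertions/deletions off a chain's gap segments.

    Each gap whose net length difference reaches ``min_sv_len`` yields one
    SV: INS when the query side is longer (sequence = the extra query
    bases), DEL otherwise. Smaller indels and substitution-only gaps are
    discarded. Breakpoints are left-normalized.
    """
    params = params or DiscoveryParams()
    bait_seq, query_seq = chain.bait.seq, chain.query.seq
    out = []
    for gap in chain.gaps:
        net = gap.query_len - gap.bait_len
        if abs(net) < params.min_sv_len:
            continue
        b = bait_seq[gap.bait_start : gap.bait_end]
        q = query_seq[gap.query_start : gap.query_end]
        pre, b_rest, q_rest = _trim_common_flanks(b, q)
        if net > 0:
            # insertion: extra query bases (any residual bait side is a
            # substitution remnant; keep the net-length inserted segment)
            seq = q_rest[: net] if len(q_rest) >= net else q
            pos = gap.bait_start + pre
            pos, seq = left_normalize_insertion(bait_seq, pos, seq)
            sv = CandidateSV("INS", pos, len(seq), seq, frozenset({chain.query.breed}))
        else:
            seq = b_rest[: -net] if len(b_rest) >= -net else b
            pos = gap.bait_start + pre
            pos, seq = left_normalize_insertion(bait_seq, pos, seq)
            sv = CandidateSV("DEL", pos, len(seq), seq, frozenset({chain.query.breed}))
        out.append(sv)
    out.sort(key=lambda sv: sv.bait_pos)
    return out


def _same_cluster(a: CandidateSV, b: CandidateSV, params: DiscoveryParams) -> bool:
    if a.sv_type != b.sv_type:
        return False
    if abs(a.bait_pos - b.bait_pos) > params.cluster_pos_tol:
        return False
    return abs(a.length - b.length) <= params.cluster_len_tol * max(a.length, b.length)


def cluster_svs(
    per_genome: Mapping[str, Sequence[CandidateSV]],
    params: DiscoveryParams | None = None,
) -> list[CandidateSV]:
    """Merge per-genome calls into recurrent candidate loci.

    Calls of identical type with breakpoints within ``cluster_pos_tol``
    and lengths within ``cluster_len_tol`` (relative) merge; clusters
    supported by fewer than ``min_sources`` distinct breeds are dropped.
    The representative is the member with the longest sequence (ties:
    lexicographically first source breed), its sources the breed union,
    and all members are retained for downstream corroboration.
    """
    params = params or DiscoveryParams()
    members = [sv for svs in per_genome.values() for sv in svs]
    n = len(members)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _same_cluster(members[i], members[j], params):
                parent[find(i)] = find(j)

    groups: dict[int, list[CandidateSV]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(members[i])

    out = []
    for grp in groups.values():
        sources = frozenset().union(*(sv.sources for sv in grp))
        if len(sources) < params.min_sources:
            continue
        rep = sorted(grp, key=lambda sv: (-sv.length, min(sv.sources)))[0]
        rep = replace(rep, sources=sources, members=tuple(grp))
        out.append(rep)
    out.sort(key=lambda sv: sv.bait_pos)
    return out


def discover_svs(
    bait: LocusSequence,
    queries: Sequence[LocusSequence],
    params: DiscoveryParams | None = None,
) -> list[CandidateSV]:
    """Convenience wrapper: align every query, extract, and cluster."""
    params = params or DiscoveryParams()
    per_genome = {}
    for query in queries:
        chain = align_locus(bait, query, params)
        per_genome[query.breed] = extract_svs(chain, params)
    return cluster_svs(per_genome, params)


def _find_hits(seq: str, primer: str, max_mismatch: int) -> list[int]:
    hits = []
    m = len(primer)
    for i in range(len(seq) - m + 1):
        mismatches = 0
        for a, b in zip(seq[i : i + m], primer):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def insilico_pcr(
    haplotype: LocusSequence,
    fwd: str,
    rev: str,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> list[int]:
    """Predicted amplicon lengths for a primer pair on one haplotype.

    Genotyping an insertion allele amounts to running both haplotypes:
    a heterozygote yields two products differing by the insertion length.
    An empty list means no product.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 bp")
    seq = haplotype.seq
    fwd_hits = _find_hits(seq, fwd, max_mismatch)
    rev_hits = _find_hits(seq, revcomp(rev), max_mismatch)
    products = []
    for f in fwd_hits:
        for r in rev_hits:
            length = r + len(rev) - f
            if f <= r and 0 < length <= max_product:
                products.append(length)
    return sorted(products)
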