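"""Anchor-chain alignment, SV extraction, clustering, and in-silico PCR."""

import numpy as np
import pytest

from ripkit import simulate as sim
from ripkit.discover import (
    AlignmentError,
    AnchorChain,
    DiscoveryParams,
    GapSegment,
    align_locus,
    cluster_svs,
    discover_svs,
    extract_svs,
    insilico_pcr,
)
from ripkit.model import CandidateSV, LocusSequence, revcomp


def _random_locus(rng, n, name="bait", breed="ref"):
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return LocusSequence(name, seq, breed=breed)


class TestAlignExtract:
    def test_identity_has_no_differing_gaps(self, rng):
        bait = _random_locus(rng, 4000)
        query = LocusSequence("q", bait.seq, breed="b")
        chain = align_locus(bait, query)
        assert all(g.bait_len == g.query_len for g in chain.gaps)
        assert extract_svs(chain) == []

    def test_single_block_insertion_recovered(self, rng):
        """Planted 286-bp block appears as one gap with +286 on the query side."""
        bait = _random_locus(rng, 5000)
        block = "".join(rng.choice(list("ACGT"), size=286))
        qseq = bait.seq[:2500] + block + bait.seq[2500:]
        query = LocusSequence("q", qseq, breed="b")
        chain = align_locus(bait, query)
        diff_gaps = [g for g in chain.gaps if g.query_len != g.bait_len]
        assert len(diff_gaps) == 1
        assert diff_gaps[0].query_len - diff_gaps[0].bait_len == 286
        (sv,) = extract_svs(chain)
        assert (sv.sv_type, sv.length) == ("INS", 286)
        assert abs(sv.bait_pos - 2500) <= 5  # left-normalization wiggle

    def test_reverse_complement_fails_forward_chain(self, rng):
        bait = _random_locus(rng, 3000)
        query = LocusSequence("q", revcomp(bait.seq), breed="b")
        with pytest.raises(AlignmentError, match="q"):
            align_locus(bait, query)

    def test_deletion_recovered(self, rng):
        bait = _random_locus(rng, 5000)
        qseq = bait.seq[:2000] + bait.seq[2100:]
        chain = align_locus(bait, LocusSequence("q", qseq, breed="b"))
        (sv,) = extract_svs(chain)
        assert (sv.sv_type, sv.length) == ("DEL", 100)
        assert sv.seq == bait.seq[sv.bait_pos : sv.bait_pos + 100]

    @pytest.mark.parametrize("extra,kept", [(49, False), (50, True)])
    def test_threshold_boundary(self, rng, extra, kept):
        """Net gap difference below min_sv_len is discarded; at it, kept."""
        bait = _random_locus(rng, 4000)
        block = "".join(rng.choice(list("ACGT"), size=extra))
        qseq = bait.seq[:1500] + block + bait.seq[1500:]
        chain = align_locus(bait, LocusSequence("q", qseq, breed="b"))
        svs = extract_svs(chain)
        assert bool(svs) is kept

    def test_mixed_gap_net_difference(self):
        """A gap with bait 10 bp vs query 59 bp nets 49 and is discarded."""
        bait = LocusSequence("bait", "A" * 200)
        query = LocusSequence("q", "C" * 260, breed="b")
        chain = AnchorChain(bait, query, anchors=[], gaps=[GapSegment(100, 110, 100, 159)])
        assert extract_svs(chain) == []
        chain.gaps = [GapSegment(100, 110, 100, 160)]  # net 50
        (sv,) = extract_svs(chain)
        assert sv.sv_type == "INS" and sv.length == 50

    def test_left_normalization_shifts_through_repeat(self):
        """An insertion planted right of an identical word slides left."""
        core = "ACGTACGGTTCACCGTAGGCTAAC"
        bait_seq = core * 3 + "GATTACAGATTACA" + core * 3
        bait = LocusSequence("bait", bait_seq)
        ins = "GATTACA"  # equal to the preceding 7-mer: fully ambiguous
        pos = len(core) * 3 + 14
        qseq = bait_seq[:pos] + ins + bait_seq[pos:]
        chain = AnchorChain(bait, LocusSequence("q", qseq, breed="b"), anchors=[],
                            gaps=[GapSegment(pos, pos, pos, pos + 7)])
        (sv,) = extract_svs(chain, DiscoveryParams(min_sv_len=5))
        assert sv.bait_pos == len(core) * 3  # leftmost equivalent placement
        assert sv.length == 7

    def test_swap_symmetry(self, rng):
        """Swapping bait and query turns the INS into a DEL at the same site."""
        bait = _random_locus(rng, 5000)
        block = "".join(rng.choice(list("ACGT"), size=120))
        qseq = bait.seq[:2500] + block + bait.seq[2500:]
        query = LocusSequence("q", qseq, breed="b")
        fwd = extract_svs(align_locus(bait, query))
        rev = extract_svs(align_locus(LocusSequence("bait2", qseq), LocusSequence("q2", bait.seq, breed="b")))
        assert [(s.sv_type, s.length) for s in fwd] == [("INS", 120)]
        assert [(s.sv_type, s.length) for s in rev] == [("DEL", 120)]
        assert fwd[0].bait_pos == rev[0].bait_pos
        assert fwd[0].seq == rev[0].seq

    def test_min_sv_len_monotonicity(self, fixture_loci):
        locus = fixture_loci[1]
        chain = align_locus(locus["bait"], locus["assemblies"][1])
        counts = [
            len(extract_svs(chain, DiscoveryParams(min_sv_len=m)))
            for m in (50, 100, 300, 310, 400)
        ]
        assert counts == sorted(counts, reverse=True)


def _brute_force_clusters(members, params):
    """Independent transitive-closure oracle for the clustering rule."""
    def linked(a, b):
        return (
            a.sv_type == b.sv_type
            and abs(a.bait_pos - b.bait_pos) <= params.cluster_pos_tol
            and abs(a.length - b.length) <= params.cluster_len_tol * max(a.length, b.length)
        )

    unassigned = list(members)
    clusters = []
    while unassigned:
        group = [unassigned.pop()]
        changed = True
        while changed:
            changed = False
            for sv in list(unassigned):
                if any(linked(sv, m) for m in group):
                    group.append(sv)
                    unassigned.remove(sv)
                    changed = True
        clusters.append(group)
    return clusters


class TestClustering:
    def test_recurrent_insertion_merges_across_breeds(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=286))
        per_genome = {
            f"breed{i}": [CandidateSV("INS", 1000 + d, 286, seq, frozenset({f"breed{i}"}))]
            for i, d in enumerate((-3, 0, 2, 3))
        }
        (cluster,) = cluster_svs(per_genome)
        assert len(cluster.sources) == 4
        assert len(cluster.members) == 4

    def test_singleton_dropped_by_min_sources(self):
        per_genome = {"only": [CandidateSV("INS", 10, 60, "A" * 60, frozenset({"only"}))]}
        assert cluster_svs(per_genome, DiscoveryParams(min_sources=2)) == []
        assert len(cluster_svs(per_genome, DiscoveryParams(min_sources=1))) == 1

    def test_length_tolerance_splits_clusters(self):
        per_genome = {
            "a": [CandidateSV("INS", 100, 286, "A" * 286, frozenset({"a"}))],
            "b": [CandidateSV("INS", 100, 800, "C" * 800, frozenset({"b"}))],
        }
        out = cluster_svs(per_genome, DiscoveryParams(min_sources=1))
        assert len(out) == 2

    def test_matches_brute_force_oracle(self, rng):
        params = DiscoveryParams(min_sources=1)
        for _ in range(20):
            members = []
            per_genome = {}
            for i in range(rng.integers(2, 7)):
                svs = []
                for _ in range(rng.integers(0, 4)):
                    pos = int(rng.integers(0, 300))
                    ln = int(rng.integers(50, 400))
                    sv = CandidateSV(
                        str(rng.choice(["INS", "DEL"])), pos, ln, "A" * ln,
                        frozenset({f"b{i}"}),
                    )
                    svs.append(sv)
                    members.append(sv)
                per_genome[f"b{i}"] = svs
            ours = cluster_svs(per_genome, params)
            oracle = _brute_force_clusters(members, params)
            assert len(ours) == len(oracle)
            ours_sig = sorted(
                tuple(sorted((m.bait_pos, m.length) for m in c.members)) for c in ours
            )
            oracle_sig = sorted(
                tuple(sorted((m.bait_pos, m.length) for m in c)) for c in oracle
            )
            assert ours_sig == oracle_sig


class TestPlantedRecovery:
    def test_every_planted_insertion_recovered(self, fixture_loci):
        """All >=50 bp planted insertions: exact length, breakpoint within 5 bp."""
        for locus in fixture_loci:
            clustered = discover_svs(locus["bait"], locus["assemblies"])
            truth = locus["truth"].drop_duplicates("insertion")
            assert len(clustered) == len(truth)
            for row in truth.itertuples():
                match = [
                    sv for sv in clustered
                    if sv.sv_type == "INS" and sv.length == row.sv_len
                    and abs(sv.bait_pos - row.bait_pos_norm) <= 5
                ]
                assert len(match) == 1, f"{row.insertion} not recovered exactly"

    def test_no_svs_between_identical_sequences(self, rng):
        bait = _random_locus(rng, 6000)
        same = LocusSequence("q", bait.seq, breed="b")
        assert discover_svs(bait, [same], DiscoveryParams(min_sources=1)) == []


class TestInsilicoPcr:
    @pytest.fixture()
    def site(self, rng):
        bait = _random_locus(rng, 3000)
        fwd = bait.seq[1000:1020]
        rev = revcomp(bait.seq[1480:1500])
        return bait, fwd, rev

    def test_reference_product_length(self, site):
        bait, fwd, rev = site
        assert insilico_pcr(bait, fwd, rev) == [500]

    def test_insertion_haplotype_shifts_product(self, site, rng):
        bait, fwd, rev = site
        block = "".join(rng.choice(list("ACGT"), size=286))
        hap = LocusSequence("h", bait.seq[:1250] + block + bait.seq[1250:])
        assert insilico_pcr(hap, fwd, rev) == [500 + 286]

    def test_heterozygote_two_products(self, site, rng):
        bait, fwd, rev = site
        block = "".join(rng.choice(list("ACGT"), size=286))
        hap2 = LocusSequence("h", bait.seq[:1250] + block + bait.seq[1250:])
        lengths = sorted(insilico_pcr(bait, fwd, rev) + insilico_pcr(hap2, fwd, rev))
        assert lengths[1] - lengths[0] == 286

    def test_absent_primer_gives_no_product(self, site):
        bait, _, rev = site
        assert insilico_pcr(bait, "T" * 20, rev) == []

    def test_short_primer_rejected(self, site):
        bait, fwd, rev = site
        with pytest.raises(ValueError):
            insilico_pcr(bait, "ACGTACGT", rev)
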