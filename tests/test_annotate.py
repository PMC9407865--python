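"""Repeat-family classification, TSD detection, and record assembly."""

import numpy as np
import pytest

from ripkit.annotate import (
    AnnotationParams,
    annotate_insertions,
    build_rip_record,
    classify_insertion,
    detect_tsd,
)
from ripkit.model import (
    CandidateSV,
    GeneModel,
    LocusSequence,
    RepeatConsensus,
    revcomp,
)


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def library():
    rng = np.random.default_rng(7)
    return [
        RepeatConsensus("SINEA1_286", "SINE", _dna(rng, 286)),
        RepeatConsensus("SINEA1_301", "SINE", _dna(rng, 301)),
        RepeatConsensus("L1_frag", "LINE", _dna(rng, 1000)),
    ]


def _ins(seq, pos=100):
    return CandidateSV("INS", pos, len(seq), seq)


class TestClassify:
    def test_perfect_copy_self_alignment(self, library):
        cls = classify_insertion(_ins(library[0].seq), library)
        assert (cls.family, cls.repeat_class, cls.direction) == ("SINEA1_286", "SINE", "+")
        assert cls.identity == 1.0 and cls.insertion_coverage == 1.0

    def test_reverse_complement_flips_direction(self, library):
        cls = classify_insertion(_ins(revcomp(library[0].seq)), library)
        assert cls.direction == "-" and cls.family == "SINEA1_286"
        assert cls.identity == 1.0

    def test_random_insertion_unclassified(self, library, rng):
        """Random 286-mers never reach 70% identity over 80% coverage."""
        for _ in range(10):
            cls = classify_insertion(_ins(_dna(rng, 286)), library)
            assert cls.family == "unclassified"
            assert cls.repeat_class == "none" and cls.direction == "."

    def test_strand_antisymmetry(self, library, rng):
        """Reverse-complementing the insertion flips direction only."""
        seq = library[0].seq
        arr = list(seq)
        for i in rng.choice(len(arr), size=6, replace=False):
            arr[i] = "ACGT"[(("ACGT".index(arr[i])) + 1) % 4]
        diverged = "".join(arr)
        fwd = classify_insertion(_ins(diverged), library)
        rev = classify_insertion(_ins(revcomp(diverged)), library)
        assert {fwd.direction, rev.direction} == {"+", "-"}
        assert fwd.identity == pytest.approx(rev.identity)
        assert fwd.insertion_coverage == pytest.approx(rev.insertion_coverage)

    def test_mutation_never_increases_identity(self, library, rng):
        seq = list(library[0].seq)
        base = classify_insertion(_ins("".join(seq)), library).identity
        for _ in range(15):
            i = int(rng.integers(len(seq)))
            mutated = seq.copy()
            mutated[i] = "ACGT"[("ACGT".index(seq[i]) + 2) % 4]
            ident = classify_insertion(_ins("".join(mutated)), library).identity
            assert ident <= base

    def test_diverged_copies_classified_accurately(self, library):
        """2%-diverged copies: right family, identity >= 0.95, >=99% of 200 runs."""
        ok = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            seq = list(library[1].seq)
            for i in range(len(seq)):
                if rng.random() < 0.02:
                    seq[i] = "ACGT"[("ACGT".index(seq[i]) + int(rng.integers(1, 4))) % 4]
            cls = classify_insertion(_ins("".join(seq)), library)
            if cls.family == "SINEA1_301" and cls.identity >= 0.95:
                ok += 1
        assert ok >= 198

    def test_contract_errors(self, library):
        with pytest.raises(ValueError):
            classify_insertion(CandidateSV("DEL", 0, 60, "A" * 60), library)
        with pytest.raises(ValueError):
            classify_insertion(_ins("A" * 60), [])


class TestTsd:
    def _planted_case(self, tsd, elem, rotate=0):
        """Bait with the target word; insertion = element + TSD copy.

        Flank bases are chosen so no chance homology extends the planted
        duplication; ``rotate`` mimics left-normalization shifting the
        breakpoint back through the duplicated word.
        """
        assert elem[0] != "T" and elem[-1] != "C"
        left = "C" * 60
        right = "T" * 60
        bait = LocusSequence("b", left + tsd + right)
        pos = len(left) + len(tsd)
        ins = elem + tsd
        for _ in range(rotate):
            ins = bait.seq[pos - 1] + ins[:-1]
            pos -= 1
        return bait, CandidateSV("INS", pos, len(ins), ins)

    def test_planted_word_returned(self):
        tsd = "TTCAGGACCTGA"  # 12-mer, distinct from the flanks
        elem = "GGCCATTGCGCGATCCGGATTACCCAGGTCAG"
        bait, sv = self._planted_case(tsd, elem)
        assert detect_tsd(bait, sv) == tsd

    def test_rotated_configuration_detected(self):
        """A fully left-normalized insertion still reveals its TSD."""
        tsd = "TTCAGGACCTGA"
        elem = "GGCCATTGCGCGATCCGGATTACCCAGGTCAG"
        bait, sv = self._planted_case(tsd, elem, rotate=len(tsd))
        assert detect_tsd(bait, sv) == tsd

    def test_no_duplication_gives_empty(self):
        rng = np.random.default_rng(3)
        bait = LocusSequence("b", _dna(rng, 200))
        sv = _ins(_dna(rng, 80), pos=100)
        assert detect_tsd(bait, sv) == ""

    def test_longest_duplication_wins(self):
        """With nested valid lengths the longest exact word is returned."""
        tsd = "ACCTGATTCAGG"  # contains shorter valid suffix words too
        elem = "GGCCATTGCGCGATCCGGATTACCCAGGTCAG"
        bait, sv = self._planted_case(tsd, elem)
        found = detect_tsd(bait, sv)
        assert found == tsd and len(found) == 12

    def test_cluster_voting_outweighs_one_corrupted_copy(self, library):
        tsd = "TTCAGGACCTGA"
        elem = "GGCCATTGCGCGATCCGGATTACCCAGGTCAG"
        bait, good = self._planted_case(tsd, elem)
        corrupted_ins = good.seq[:-1] + ("A" if good.seq[-1] != "A" else "C")
        bad = CandidateSV("INS", good.bait_pos, len(corrupted_ins), corrupted_ins)
        from ripkit.annotate import _consensus_tsd

        rep = CandidateSV(
            "INS", good.bait_pos, good.length, good.seq,
            frozenset({"a", "b", "c"}), members=(good, bad, good),
        )
        assert _consensus_tsd(bait, rep, AnnotationParams()) == tsd


class TestRecords:
    MODEL = GeneModel("LEPROT", "+", ((2001, 2150), (3001, 3150)))

    def test_chromosomal_span_arithmetic(self, library):
        locus = LocusSequence("L", "ACGT" * 2000, chrom="6", offset=146975573)
        sv = _ins(library[0].seq, pos=2500)
        cls = classify_insertion(sv, library)
        rec = build_rip_record(sv, cls, "", self.MODEL, locus)
        # breakpoint flanks chromosomal bases offset+2499 and offset+2500
        assert rec.chrom_span == "6:146978072-146978073"
        assert rec.feature_label == "Intron1"

    def test_serial_numbering(self, library, rng):
        svs = [_ins(library[0].seq, pos=2500), _ins(library[1].seq, pos=3500)]
        bait = LocusSequence("L", _dna(rng, 5000))
        records = annotate_insertions(svs, library, self.MODEL, bait)
        assert [r.rip_name for r in records] == ["LEPROT-SINE-RIP1", "LEPROT-SINE-RIP2"]

    def test_single_rip_keeps_bare_suffix(self, library, rng):
        bait = LocusSequence("L", _dna(rng, 5000))
        records = annotate_insertions([_ins(library[0].seq, pos=2500)], library, self.MODEL, bait)
        assert records[0].rip_name == "LEPROT-SINE-RIP"

    def test_unclassified_record(self, library, rng):
        sv = _ins(_dna(rng, 120), pos=2500)
        bait = LocusSequence("L", _dna(rng, 5000))
        (rec,) = annotate_insertions([sv], library, self.MODEL, bait)
        assert rec.family == "unclassified"
        assert rec.repeat_class == "none" and rec.direction == "."
        assert rec.tsd == ""

    def test_fixture_end_to_end_identity_floor(self, fixture_loci):
        """Fixture insertions classify to their own family with high identity."""
        from ripkit.discover import discover_svs

        locus = fixture_loci[0]
        clustered = discover_svs(locus["bait"], locus["assemblies"])
        records = annotate_insertions(
            clustered, locus["library"], locus["model"], locus["bait"]
        )
        assert len(records) == 1
        rec = records[0]
        assert rec.family == "SINEA1_286" and rec.direction == "-"
        assert rec.identity >= 0.95 and rec.insertion_coverage >= 0.9
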