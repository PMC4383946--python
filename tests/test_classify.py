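import pytest
from hypothesis import given, strategies as st

from tests.conftest import make_entry
from trfcall.classify import (
    REGION_FIVE,
    REGION_INTERNAL,
    REGION_THREE,
    REGION_TRAILER,
    RegistryError,
    TRFRecord,
    TRFRegistry,
    assign_ids,
    assign_region,
    assign_subclass,
    call_trfs,
    check_terminator,
    read_trfs,
    region_concentration,
    summarize_site,
    write_trfs,
)
from trfcall.mapping import ReadAlignment
from trfcall.reference import SEG_MATURE, SEG_TRAILER, TRFReference


@pytest.fixture
def entry():
    return make_entry(name="g1", mature="ACGTACGTACGTACGTACGT", trailer="TTTTGGGGCCCCAAAA")


@pytest.fixture
def ref(entry):
    return TRFReference("t", (entry,))


def aln(seq, count, gene="g1", segment=SEG_MATURE, offset=0):
    return ReadAlignment(sequence=seq, count=count, gene=gene, segment=segment, offset=offset)


class TestAssignRegion:
    def test_offset_zero_on_mature_is_five_prime(self, ref, entry):
        a = aln(entry.mature_plus_cca[:10], 1)
        assert assign_region(a, ref) == REGION_FIVE

    def test_reaching_segment_end_is_three_prime(self, ref, entry):
        seq = entry.mature_plus_cca[-10:]
        a = aln(seq, 1, offset=len(entry.mature_plus_cca) - 10)
        assert assign_region(a, ref) == REGION_THREE
        assert seq.endswith("CCA")

    def test_mid_mature_is_internal(self, ref, entry):
        a = aln(entry.mature_plus_cca[7:17], 1, offset=7)
        assert assign_region(a, ref) == REGION_INTERNAL

    def test_trailer_start_is_trailer(self, ref, entry):
        a = aln(entry.trailer[:10], 1, segment=SEG_TRAILER)
        assert assign_region(a, ref) == REGION_TRAILER

    def test_mid_trailer_is_internal(self, ref, entry):
        a = aln(entry.trailer[3:13], 1, segment=SEG_TRAILER, offset=3)
        assert assign_region(a, ref) == REGION_INTERNAL


class TestSummarizeSite:
    def alns(self, counts):
        return [aln(seq, n) for seq, n in counts.items()]

    def test_single_dominant_at_exactly_080(self):
        s = summarize_site("g", REGION_FIVE, self.alns({"A" * 20: 80, "C" * 20: 15, "G" * 20: 5}))
        assert s.dominant_reads == ("A" * 20,)
        assert s.dominant_fraction == pytest.approx(0.80)

    def test_top_two_dominant(self):
        s = summarize_site("g", REGION_FIVE, self.alns({"A" * 20: 50, "C" * 20: 40, "G" * 20: 10}))
        assert s.dominant_reads == ("A" * 20, "C" * 20)
        assert s.dominant_fraction == pytest.approx(0.90)

    def test_degraded_site_fails(self):
        s = summarize_site("g", REGION_FIVE, self.alns({"A" * 20: 40, "C" * 20: 35, "G" * 20: 25}))
        assert s.dominant_reads == ()

    def test_tie_broken_by_length_then_lexicographic(self):
        s = summarize_site("g", REGION_FIVE, self.alns({"AAAA": 50, "CCCCC": 50}))
        assert s.counts[0][0] == "CCCCC"  # longer first

    def test_counts_aggregated_across_alignments(self):
        s = summarize_site("g", REGION_FIVE, [aln("A" * 20, 30), aln("A" * 20, 30), aln("C" * 20, 10)])
        assert dict(s.counts)["A" * 20] == 60

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            summarize_site("g", REGION_FIVE, [])

    @given(counts=st.dictionaries(st.text("ACGT", min_size=14, max_size=20),
                                  st.integers(1, 500), min_size=1, max_size=8))
    def test_lower_threshold_keeps_top_read_and_passing_sites(self, counts):
        alns = [aln(s, c) for s, c in counts.items()]
        hi = summarize_site("g", REGION_FIVE, alns, threshold=0.8)
        lo = summarize_site("g", REGION_FIVE, alns, threshold=0.5)
        if hi.dominant_reads:
            assert lo.dominant_reads  # a passing site still passes
            assert hi.dominant_reads[0] in lo.dominant_reads  # top read never lost


class TestRegionConcentration:
    def test_all_on_region(self):
        assert region_concentration([(REGION_FIVE, 10)]) == 1.0

    def test_ninety_ten_split(self):
        assert region_concentration([(REGION_FIVE, 90), (REGION_INTERNAL, 10)]) == pytest.approx(0.90)

    def test_all_internal_is_zero(self):
        assert region_concentration([(REGION_INTERNAL, 10)]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            region_concentration([])


class TestAssignSubclass:
    @pytest.mark.parametrize("length,letter", [(15, "a"), (18, "a"), (22, "b"), (26, "b"), (31, "c")])
    def test_trf5_bins(self, length, letter):
        assert assign_subclass("tRF-5", length) == letter

    @pytest.mark.parametrize("length,letter", [(18, "a"), (20, "a"), (22, "b")])
    def test_trf3_bins(self, length, letter):
        assert assign_subclass("tRF-3", length) == letter

    def test_trf1_has_no_subclass(self):
        assert assign_subclass("tRF-1", 19) is None

    def test_bad_length(self):
        with pytest.raises(ValueError):
            assign_subclass("tRF-5", 0)


class TestCheckTerminator:
    def test_poly_t_overlapping_end(self):
        assert check_terminator("ACGTTTTTG", 7)

    def test_no_t_run(self):
        assert not check_terminator("ACGACGACG", 5)

    def test_run_of_exactly_four_ending_at_end_offset(self):
        assert check_terminator("ACTTTTGGGG", 6)

    def test_run_far_from_end(self):
        assert not check_terminator("TTTTTACGACGACGACGACG", 18)

    def test_run_of_three_insufficient(self):
        assert not check_terminator("ACGTTTGGG", 6)


class TestRegistry:
    def test_first_ids(self):
        reg = TRFRegistry()
        assert reg.assign("tRF-5", "A" * 15) == 5001
        assert reg.assign("tRF-3", "C" * 18) == 3001
        assert reg.assign("tRF-1", "G" * 19) == 1001

    def test_idempotent(self):
        reg = TRFRegistry()
        assert reg.assign("tRF-5", "A" * 15) == reg.assign("tRF-5", "A" * 15)

    def test_sequential(self):
        reg = TRFRegistry()
        assert reg.assign("tRF-1", "G" * 19) == 1001
        assert reg.assign("tRF-1", "T" * 20) == 1002

    def test_json_round_trip(self, tmp_path):
        reg = TRFRegistry()
        reg.assign("tRF-5", "A" * 15)
        p = tmp_path / "reg.json"
        reg.to_json(p)
        loaded = TRFRegistry.from_json(p)
        assert loaded.lookup("tRF-5", "A" * 15) == 5001
        assert loaded.assign("tRF-5", "C" * 15) == 5002

    def test_collision_detected(self, tmp_path):
        p = tmp_path / "reg.json"
        p.write_text('{"ids": {"tRF-5": {"AAAA": 5001, "CCCC": 5001}, "tRF-3": {}, "tRF-1": {}},'
                     ' "next": {"tRF-5": 5002, "tRF-3": 3001, "tRF-1": 1001}}')
        with pytest.raises(RegistryError):
            TRFRegistry.from_json(p)


class TestCallTrfs:
    def make_alignments(self, entry, five=(), three=(), trailer=(), internal=()):
        out = []
        for seq, n in five:
            out.append(aln(seq, n, gene=entry.name))
        for seq, n in three:
            out.append(aln(seq, n, gene=entry.name, offset=len(entry.mature_plus_cca) - len(seq)))
        for seq, n in trailer:
            out.append(aln(seq, n, gene=entry.name, segment=SEG_TRAILER))
        for seq, n in internal:
            out.append(aln(seq, n, gene=entry.name, offset=3))
        return out

    def test_basic_call_each_type(self, ref, entry):
        alns = self.make_alignments(
            entry,
            five=[(entry.mature_plus_cca[:15], 90), (entry.mature_plus_cca[:14], 5)],
            three=[(entry.mature_plus_cca[-18:], 80)],
            trailer=[(entry.trailer[:12], 70)],
        )
        trfs, conc = call_trfs(alns, ref)
        assert {(t.trf_type, t.trf_id) for t in trfs} == {
            ("tRF-5", "5001"), ("tRF-3", "3001"), ("tRF-1", "1001")
        }
        assert conc[entry.name] == 1.0

    def test_failed_site_yields_nothing(self, ref, entry):
        alns = self.make_alignments(
            entry,
            five=[(entry.mature_plus_cca[:15], 40), (entry.mature_plus_cca[:16], 35),
                  (entry.mature_plus_cca[:17], 25)],
        )
        trfs, _ = call_trfs(alns, ref)
        assert trfs == []

    def test_singleton_site_not_called(self, ref, entry):
        alns = self.make_alignments(entry, five=[(entry.mature_plus_cca[:15], 1)])
        assert call_trfs(alns, ref, min_site_count=2)[0] == []

    def test_internal_reads_never_called(self, ref, entry):
        alns = self.make_alignments(entry, internal=[(entry.mature_plus_cca[3:18], 500)])
        assert call_trfs(alns, ref)[0] == []

    def test_sibling_subclasses(self, ref, entry):
        alns = self.make_alignments(
            entry,
            five=[(entry.mature_plus_cca[:15], 50), (entry.mature_plus_cca[:22], 45)],
        )
        trfs, _ = call_trfs(alns, ref)
        assert {(t.length, t.subclass, t.trf_id) for t in trfs} == {
            (15, "a", "5001a"), (22, "b", "5002b")
        }

    def test_solitary_has_no_letter(self, ref, entry):
        alns = self.make_alignments(entry, five=[(entry.mature_plus_cca[:15], 50)])
        (t,) = call_trfs(alns, ref)[0]
        assert t.subclass is None and t.trf_id == "5001"

    def test_multi_parent_single_record(self):
        e1 = make_entry(name="g1", mature="ACGTACGTACGTACGTACGT")
        e2 = make_entry(name="g2", mature="ACGTACGTACGTACGTAAAA")  # same 15-nt prefix
        ref2 = TRFReference("t", (e1, e2))
        seq = e1.mature_plus_cca[:15]
        alns = [aln(seq, 40, gene="g1"), aln(seq, 40, gene="g2")]
        trfs, _ = call_trfs(alns, ref2)
        (t,) = trfs
        assert t.parents == ("g1", "g2")

    def test_registry_reuse_keeps_ids(self, ref, entry):
        reg = TRFRegistry()
        alns = self.make_alignments(entry, five=[(entry.mature_plus_cca[:15], 50)])
        first, _ = call_trfs(alns, ref, registry=reg)
        second, _ = call_trfs(alns, ref, registry=reg)
        assert [t.trf_id for t in first] == [t.trf_id for t in second] == ["5001"]

    def test_terminator_flag_set(self, ref, entry):
        # trailer "TTTTGGGGCCCCAAAA": a 4-long fragment ends inside the poly-T run
        alns = self.make_alignments(entry, trailer=[(entry.trailer[:14], 50)])
        (t,) = call_trfs(alns, ref, min_site_count=2)[0]
        assert t.trf_type == "tRF-1" and t.terminator is False
        alns = self.make_alignments(entry, trailer=[(entry.trailer[:5], 50)])
        (t,) = call_trfs(alns, ref)[0]
        assert t.terminator is True

    def test_trf3_always_ends_cca(self, ref, entry):
        alns = self.make_alignments(entry, three=[(entry.mature_plus_cca[-20:], 60)])
        (t,) = call_trfs(alns, ref)[0]
        assert t.sequence.endswith("CCA")


class TestAssignIds:
    def test_known_sequence_keeps_id(self):
        reg = TRFRegistry()
        reg.assign("tRF-5", "A" * 15)
        rec = TRFRecord("9999", "tRF-5", None, "A" * 15, ("g1",))
        (out,) = assign_ids([rec], reg)
        assert out.trf_id == "5001"

    def test_new_sequence_minted(self):
        reg = TRFRegistry()
        rec = TRFRecord("", "tRF-1", None, "G" * 19, ("g1",))
        (out,) = assign_ids([rec], reg)
        assert out.trf_id == "1001"


def test_trf_tsv_round_trip(tmp_path):
    records = [
        TRFRecord("5001a", "tRF-5", "a", "A" * 15, ("g1", "g2")),
        TRFRecord("1001", "tRF-1", None, "G" * 19, ("g3",), terminator=True),
    ]
    p = tmp_path / "trfs.tsv"
    write_trfs(records, p)
    assert read_trfs(p) == records
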