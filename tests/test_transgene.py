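"""T-DNA insertion mapping: matcher, orphans, clustering, local SVs."""

import numpy as np
import pytest

from somavar._util import random_dna, revcomp, stream_rng
from somavar.simulate import (InsertionTruth, simulate_construct_mixture_pairs,
                              simulate_insertion_reads)
from somavar.simulate.insertion import _draw_pairs
from somavar.transgene import (Alignment, ConstructModel, KmerIndex,
                               count_spanning_pairs, detect_local_deletion,
                               extract_orphans, filter_homologous_loci,
                               host_depth, locate_insertions,
                               match_reads_to_construct,
                               pair_alignments_from_sam)

RNG = stream_rng(42, "transgene-tests")
CONSTRUCT = random_dna(RNG, 3000)


class TestKmerMatcher:
    def test_verbatim_read_aligns(self):
        idx = KmerIndex(CONSTRUCT)
        aln = idx.align(CONSTRUCT[500:600])
        assert aln is not None and aln.pos == 500 and aln.strand == "+"
        assert aln.identity == 1.0

    def test_reverse_complement_aligns(self):
        idx = KmerIndex(CONSTRUCT)
        aln = idx.align(revcomp(CONSTRUCT[500:600]))
        assert aln is not None and aln.pos == 500 and aln.strand == "-"

    def test_random_read_unaligned(self):
        idx = KmerIndex(CONSTRUCT)
        assert idx.align(random_dna(stream_rng(1, "other"), 100)) is None

    def test_identity_threshold(self):
        idx = KmerIndex(CONSTRUCT)
        read = list(CONSTRUCT[500:600])
        for i in range(40, 56):  # 16 mismatches -> 84% identity
            read[i] = "A" if read[i] != "A" else "C"
        assert idx.align("".join(read)) is None

    def test_repeat_placement_gets_zero_mapq(self):
        target = CONSTRUCT[:400] + CONSTRUCT[:400]
        idx = KmerIndex(target)
        aln = idx.align(CONSTRUCT[100:200])
        assert aln is not None and aln.mapq == 0

    def test_match_reads_to_construct_wrapper(self):
        reads = [("a", CONSTRUCT[0:100]), ("b", random_dna(RNG, 100))]
        out = match_reads_to_construct(reads, CONSTRUCT)
        assert out["a"] is not None and out["b"] is None


class TestExtractOrphans:
    A = Alignment(0, "+", 1.0, 1.0, 60)

    def test_definitional_cases(self):
        pairs = {"p1": {1: self.A, 2: None},   # end2 orphan
                 "p2": {1: self.A, 2: self.A},  # both aligned
                 "p3": {1: None, 2: None}}      # neither
        orphans, skipped = extract_orphans(pairs)
        assert orphans == [("p1", 2)] and skipped == 0

    def test_unpaired_record_skipped(self):
        orphans, skipped = extract_orphans({"p1": {1: self.A}})
        assert orphans == [] and skipped == 1


class TestLocateInsertions:
    def run(self, **kw):
        defaults = dict(seed=1, coverage_depth=30,
                        host_sequence_length_bp=30_000, insertion_site=15_000)
        defaults.update(kw)
        truth = InsertionTruth(**defaults)
        data = simulate_insertion_reads(truth)
        res = locate_insertions(data.pairs, data.construct_seq,
                                data.host_seq, truth.host_name,
                                insert_size_mean=truth.insert_size_mean,
                                insert_size_sd=truth.insert_size_sd)
        return truth, data, res

    def test_plus_orientation_exact_coordinate(self):
        truth, _, res = self.run(orientation="+")
        assert len(res.calls) == 1
        call = res.calls[0]
        assert call.orientation == "+"
        assert call.lb_adjacent_coordinate == truth.lb_adjacent_coordinate
        assert call.refined

    def test_minus_orientation_exact_coordinate(self):
        truth, _, res = self.run(orientation="-")
        call = res.calls[0]
        assert call.orientation == "-"
        assert call.lb_adjacent_coordinate == truth.lb_adjacent_coordinate

    def test_support_below_min_yields_no_call(self):
        truth, data, _ = self.run()
        res = locate_insertions(data.pairs, data.construct_seq,
                                data.host_seq, truth.host_name,
                                min_support=10_000)
        assert res.calls == []

    def test_local_deletion_exact_with_junction_reads(self):
        truth, _, res = self.run(adjacent_deletion_bp=1_500)
        assert len(res.local_svs) == 1
        sv = res.local_svs[0]
        assert sv.size_bp == 1_500
        assert sv.start_bp == truth.insertion_site + 1
        assert "junction_read" in sv.evidence

    def test_local_deletion_within_50bp_by_depth_only(self):
        truth, data, _ = self.run(adjacent_deletion_bp=1_500)
        res = locate_insertions(data.pairs, data.construct_seq,
                                data.host_seq, truth.host_name,
                                insert_size_mean=truth.insert_size_mean,
                                insert_size_sd=truth.insert_size_sd,
                                refine=False)
        sv = res.local_svs[0]
        assert abs(sv.size_bp - 1_500) <= 50
        assert "coverage_gap" in sv.evidence

    def test_no_deletion_no_local_sv(self):
        truth, _, res = self.run(adjacent_deletion_bp=0, filler_sequence="",
                                 mh_left_bp=0, mh_right_bp=0)
        assert truth.adjacent_deletion_bp == 0
        assert res.local_svs == []


class TestDetectLocalDeletion:
    def _call(self, coord):
        from somavar.transgene import InsertionCall

        return InsertionCall("Gm13", coord, "+", 5, 5)

    def test_pure_deletion_pair_spacing_evidence(self):
        """A deletion without inserted sequence shows both a coverage gap
        and host-host pairs whose implied span exceeds the insert limit."""
        rng = stream_rng(3, "pure-del")
        host = random_dna(rng, 20_000)
        allele = host[:10_000] + host[11_000:]  # 1 kb deletion
        truth = InsertionTruth(host_sequence_length_bp=20_000,
                               insertion_site=10_000, coverage_depth=30,
                               seed=3)
        pairs = _draw_pairs(rng, allele, 3_000, truth, "d")
        idx = KmerIndex(host)
        host_full, host_pairs = [], {}
        for name, r1, r2 in pairs:
            spans = {}
            for end, seq in ((1, r1), (2, r2)):
                aln = idx.align(seq)
                if aln is not None:
                    host_full.append((aln, len(seq)))
                    spans[end] = (aln.pos + 1, aln.pos + len(seq))
            if len(spans) == 2:
                host_pairs[name] = (min(s[0] for s in spans.values()),
                                    max(s[1] for s in spans.values()))
        depth = host_depth(len(host), host_full)
        svs = detect_local_deletion(depth, self._call(10_000), 350.0, 35.0,
                                    host_pairs=list(host_pairs.values()))
        assert len(svs) == 1
        sv = svs[0]
        assert abs(sv.size_bp - 1_000) <= 50
        assert sv.evidence == {"coverage_gap", "pair_spacing"}

    def test_insufficient_flank_coverage_undetermined(self):
        depth = np.full(10_000, 2, dtype=np.int32)
        svs = detect_local_deletion(depth, self._call(5_000), 350.0, 35.0)
        assert svs[0].status == "undetermined"


class TestHomologyFilter:
    def _call(self, coord, mate_positions):
        from somavar.transgene import InsertionCall

        return InsertionCall("Gm05", coord, "+", 5, 5,
                             mate_construct_positions=mate_positions)

    MODEL = ConstructModel(CONSTRUCT,
                           elements=[("GmUbi", 1, 800), ("BAR", 1000, 1600)],
                           homologous_elements=["GmUbi"])

    def test_promoter_supported_call_in_paralog_region_flagged(self):
        call = self._call(500_000, [100, 200, 300, 700])
        out = filter_homologous_loci([call], self.MODEL,
                                     [("Gm05", 490_000, 510_000)])
        assert out[0].filtered_homologous

    def test_marker_supported_call_retained(self):
        call = self._call(500_000, [1100, 1200, 1300, 1500])
        out = filter_homologous_loci([call], self.MODEL,
                                     [("Gm05", 490_000, 510_000)])
        assert not out[0].filtered_homologous

    def test_empty_paralog_list_no_flags(self):
        call = self._call(500_000, [100, 200])
        out = filter_homologous_loci([call], self.MODEL, [])
        assert not out[0].filtered_homologous

    def test_call_outside_paralog_region_retained(self):
        call = self._call(900_000, [100, 200, 300])
        out = filter_homologous_loci([call], self.MODEL,
                                     [("Gm05", 490_000, 510_000)])
        assert not out[0].filtered_homologous


class TestSpanningPairs:
    ELEMENT = (1280, 1800)

    def _count(self, fraction):
        pairs = simulate_construct_mixture_pairs(
            CONSTRUCT, self.ELEMENT, excised_fraction=fraction, seed=5,
            coverage=30)
        idx = KmerIndex(CONSTRUCT)
        alns, lens = {}, {}
        for name, r1, r2 in pairs:
            alns[name] = {1: idx.align(r1), 2: idx.align(r2)}
            lens[(name, 1)], lens[(name, 2)] = len(r1), len(r2)
        return count_spanning_pairs(alns, lens, self.ELEMENT, 350.0, 35.0)

    def test_hemizygous_excision_detected(self):
        assert self._count(0.5) > 0

    def test_intact_construct_counts_zero(self):
        assert self._count(0.0) == 0

    def test_element_longer_than_any_span_counts_zero(self):
        pairs = simulate_construct_mixture_pairs(
            CONSTRUCT, self.ELEMENT, excised_fraction=0.0, seed=5)
        idx = KmerIndex(CONSTRUCT)
        alns, lens = {}, {}
        for name, r1, r2 in pairs:
            alns[name] = {1: idx.align(r1), 2: idx.align(r2)}
            lens[(name, 1)], lens[(name, 2)] = len(r1), len(r2)
        huge = (200, 2900)
        assert count_spanning_pairs(alns, lens, huge, 350.0, 35.0) == 0


class TestSamIngestion:
    def test_sam_records_map_to_alignments(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"LN": len(CONSTRUCT), "SN": "construct"}]}
        path = tmp_path / "aln.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = "p1"
            a.query_sequence = CONSTRUCT[100:200]
            a.flag = 0x1 | 0x40  # paired, first in pair
            a.reference_id = 0
            a.reference_start = 100
            a.mapping_quality = 60
            a.cigarstring = "100M"
            fh.write(a)
            b = pysam.AlignedSegment(fh.header)
            b.query_name = "p1"
            b.query_sequence = random_dna(RNG, 100)
            b.flag = 0x1 | 0x80 | 0x4  # paired, second, unmapped
            fh.write(b)
        alns, lengths = pair_alignments_from_sam(str(path))
        assert alns["p1"][1].pos == 100
        assert alns["p1"][1].mapq == 60
        assert alns["p1"][2] is None
        assert lengths[("p1", 1)] == 100
        orphans, _ = extract_orphans(alns)
        assert orphans == [("p1", 2)]
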