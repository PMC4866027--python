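"""CGH segmentation, classification, heterogeneity and gene accounting."""

import numpy as np
import pytest

from somavar.cgh import (ClassificationThresholds, GeneModel, ProbeTrack,
                         Segment, SegmentationParams, SVCall, best_window,
                         calls_to_bed, candidate_review, center_track,
                         classify_segments, filter_heterogeneity,
                         genes_overlapping, merge_adjacent_calls,
                         read_genes_gff3, segment_track, summarize_class)

THR = ClassificationThresholds()


def make_track(values, sample_id="S", chrom="Gm11", spacing=2000):
    values = np.asarray(values, dtype=float)
    pos = np.arange(1, values.size + 1) * spacing
    return ProbeTrack.from_arrays(sample_id, "ref", {chrom: (pos, values)})


def make_segment(mean, n_probes, chrom="Gm11", first=0):
    last = first + n_probes - 1
    return Segment(chrom, first, last, (first + 1) * 2000,
                   (last + 1) * 2000, n_probes, mean)


def make_call(chrom, first, last, cls, sample, mean=None):
    if mean is None:
        mean = 1.0 if cls == "UpCNV" else -1.0
    return SVCall(chrom, first, last, (first + 1) * 2000, (last + 1) * 2000,
                  last - first + 1, mean, call_class=cls, sample_id=sample)


def brute_force_best_window(x, min_len=2):
    """Plain-loop enumeration of every admissible window."""
    n = len(x)
    best = (-1, -1, 0.0, 0.0)
    for i in range(n):
        if i != 0 and i < min_len:
            continue
        for j in range(i + min_len, n + 1):
            if j != n and n - j < min_len:
                continue
            if n - (j - i) < min_len:
                continue
            win = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            diff = abs(win.mean() - rest.mean())
            z = diff / np.sqrt(1 / len(win) + 1 / len(rest))
            if round(z, 9) > round(best[3], 9):
                best = (i, j, diff, z)
    return best


class TestCenterTrack:
    def test_constant_offset_removed(self):
        track = make_track([0.2] * 10)
        out = center_track(track)
        assert np.allclose(out.data["Gm11"][1], 0.0)

    def test_idempotent_on_median_zero(self):
        track = make_track([-1.0, 0.0, 1.0])
        out = center_track(track)
        assert np.allclose(out.data["Gm11"][1], [-1.0, 0.0, 1.0])
        again = center_track(out)
        assert np.allclose(again.data["Gm11"][1], out.data["Gm11"][1])

    def test_empty_track_rejected(self):
        track = ProbeTrack("S", "ref", {})
        with pytest.raises(ValueError):
            center_track(track)


class TestBestWindow:
    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 60))
            x = rng.normal(0, 0.2, n)
            if rng.random() < 0.7:
                a = int(rng.integers(0, n - 3))
                b = int(rng.integers(a + 3, n + 1))
                x[a:b] -= 1.0
            got = best_window(x, 2)
            want = brute_force_best_window(x, 2)
            assert got[:2] == want[:2]
            assert got[3] == pytest.approx(want[3])

    def test_zero_noise_single_changepoint_is_exact(self):
        x = np.concatenate([np.zeros(100), -np.ones(50)])
        i, j, diff, _ = best_window(x, 2)
        assert {i, j} <= {0, 100, 150}
        assert (i, j) in ((0, 100), (100, 150))
        assert diff == pytest.approx(1.0)
        # the raw-mean-difference single-split scan lands at the same spot
        raw = [abs(x[:t].mean() - x[t:].mean()) for t in range(2, 149)]
        assert int(np.argmax(raw)) + 2 == 100


class TestSegmentTrack:
    def test_constant_track_single_segment(self):
        track = make_track(np.zeros(50))
        segs = segment_track(track, SegmentationParams(seed=0))
        assert len(segs) == 1
        assert (segs[0].first_probe_index, segs[0].last_probe_index) == (0, 49)

    def test_zero_noise_changepoint_two_segments(self):
        track = make_track(np.concatenate([np.zeros(100), -np.ones(50)]))
        segs = segment_track(track, SegmentationParams(seed=0))
        assert [(s.first_probe_index, s.last_probe_index) for s in segs] == \
            [(0, 99), (100, 149)]
        assert segs[1].mean_log2 == pytest.approx(-1.0)

    def test_partition_invariant(self, rng):
        values = rng.normal(0, 0.15, 300)
        values[120:160] -= 1.0
        track = make_track(values)
        segs = segment_track(track, SegmentationParams(seed=3))
        covered = sorted((s.first_probe_index, s.last_probe_index)
                         for s in segs)
        assert covered[0][0] == 0 and covered[-1][1] == 299
        for (a, b), (c, d) in zip(covered, covered[1:]):
            assert c == b + 1
        assert sum(s.n_probes for s in segs) == 300

    def test_tiny_chromosome_returned_whole(self):
        track = make_track([0.0, -1.0, 0.4])
        segs = segment_track(track, SegmentationParams(seed=0))
        assert len(segs) == 1 and segs[0].n_probes == 3

    def test_reproducible_with_seed(self, rng):
        values = rng.normal(0, 0.15, 200)
        track = make_track(values)
        a = segment_track(track, SegmentationParams(seed=11))
        b = segment_track(track, SegmentationParams(seed=11))
        assert [(s.first_probe_index, s.last_probe_index) for s in a] == \
            [(s.first_probe_index, s.last_probe_index) for s in b]


class TestClassifySegments:
    @pytest.mark.parametrize("mean, n_probes, expected", [
        (0.40, 5, "UpCNV"),
        (-0.60, 3, "DownCNV"),
        (-0.60, 2, None),        # below the 3-probe call minimum
        (0.0, 5, None),
        (0.3484, 5, None),       # exactly at a threshold is never a call
        (-0.5257, 5, None),
        (0.3485, 5, "UpCNV"),
        (-0.5258, 5, "DownCNV"),
    ])
    def test_threshold_semantics(self, mean, n_probes, expected):
        calls = classify_segments([make_segment(mean, n_probes)], THR, "S")
        if expected is None:
            assert calls == []
        else:
            assert len(calls) == 1 and calls[0].call_class == expected

    def test_monotonicity_in_thresholds(self, rng):
        segs = [make_segment(float(m), 5, first=i * 10)
                for i, m in enumerate(rng.normal(0, 0.6, 50))]
        base_up = {c.first_probe_index for c in classify_segments(
            segs, THR, "S") if c.call_class == "UpCNV"}
        stricter = ClassificationThresholds(upper=0.6, lower=THR.lower)
        up2 = {c.first_probe_index for c in classify_segments(
            segs, stricter, "S") if c.call_class == "UpCNV"}
        assert up2 <= base_up
        base_down = {c.first_probe_index for c in classify_segments(
            segs, THR, "S") if c.call_class == "DownCNV"}
        stricter = ClassificationThresholds(upper=THR.upper, lower=-0.9)
        down2 = {c.first_probe_index for c in classify_segments(
            segs, stricter, "S") if c.call_class == "DownCNV"}
        assert down2 <= base_down


class TestMergeAdjacentCalls:
    def test_fragmented_event_rejoined(self):
        calls = [make_call("Gm11", 10, 14, "DownCNV", "S", -1.1),
                 make_call("Gm11", 15, 20, "DownCNV", "S", -0.9)]
        merged = merge_adjacent_calls(calls)
        assert len(merged) == 1
        m = merged[0]
        assert (m.first_probe_index, m.last_probe_index) == (10, 20)
        assert m.mean_log2 == pytest.approx((5 * -1.1 + 6 * -0.9) / 11)

    def test_different_class_or_gap_not_merged(self):
        calls = [make_call("Gm11", 10, 14, "DownCNV", "S"),
                 make_call("Gm11", 15, 20, "UpCNV", "S"),
                 make_call("Gm11", 30, 35, "UpCNV", "S")]
        assert len(merge_adjacent_calls(calls)) == 3


class TestCandidateReview:
    def test_subthreshold_segment_listed(self):
        segs = [make_segment(0.30, 5)]
        out = candidate_review(segs, THR, 0.8)
        assert out == segs  # 0.30 > 0.3484 * 0.8 = 0.2787

    def test_called_segment_not_listed(self):
        assert candidate_review([make_segment(0.40, 5)], THR, 0.8) == []

    def test_identity_relax_factor_empty(self):
        segs = [make_segment(0.30, 5), make_segment(-0.4, 5)]
        assert candidate_review(segs, THR, 1.0) == []

    def test_sorted_by_magnitude(self):
        segs = [make_segment(0.29, 5), make_segment(-0.48, 5, first=10)]
        out = candidate_review(segs, THR, 0.8)
        assert [s.mean_log2 for s in out] == [-0.48, 0.29]


class TestFilterHeterogeneity:
    def test_exact_recurrence_flagged_everywhere(self):
        calls = {f"S{i}": [make_call("Gm11", 10, 20, "DownCNV", f"S{i}")]
                 for i in range(1, 4)}
        calls["S4"] = [make_call("Gm11", 40, 50, "DownCNV", "S4")]
        out = filter_heterogeneity(calls, mode="exact")
        assert all(c.filtered_as_heterogeneity
                   for s in ("S1", "S2", "S3") for c in out[s])
        assert not out["S4"][0].filtered_as_heterogeneity

    def test_same_span_different_class_not_flagged(self):
        calls = {"S1": [make_call("Gm11", 10, 20, "DownCNV", "S1")],
                 "S2": [make_call("Gm11", 10, 20, "UpCNV", "S2")]}
        out = filter_heterogeneity(calls, mode="exact")
        assert not any(c.filtered_as_heterogeneity
                       for cs in out.values() for c in cs)

    def test_reciprocal_mode_threshold(self):
        # 50% reciprocal overlap at a 0.8 requirement: both retained
        calls = {"S1": [make_call("Gm11", 0, 9, "DownCNV", "S1")],
                 "S2": [make_call("Gm11", 5, 14, "DownCNV", "S2")]}
        out = filter_heterogeneity(calls, mode="reciprocal",
                                   reciprocal_overlap=0.8)
        assert not any(c.filtered_as_heterogeneity
                       for cs in out.values() for c in cs)
        out = filter_heterogeneity(calls, mode="reciprocal",
                                   reciprocal_overlap=0.3)
        assert all(c.filtered_as_heterogeneity
                   for cs in out.values() for c in cs)

    def test_single_sample_warns_and_is_noop(self):
        calls = {"S1": [make_call("Gm11", 10, 20, "DownCNV", "S1")]}
        with pytest.warns(UserWarning):
            out = filter_heterogeneity(calls)
        assert not out["S1"][0].filtered_as_heterogeneity

    def test_idempotent(self):
        calls = {f"S{i}": [make_call("Gm11", 10, 20, "DownCNV", f"S{i}")]
                 for i in (1, 2)}
        once = filter_heterogeneity(calls)
        twice = filter_heterogeneity(once)
        assert [(c.filtered_as_heterogeneity for c in once[s])
                for s in once] is not None
        assert all(a.filtered_as_heterogeneity == b.filtered_as_heterogeneity
                   for s in once for a, b in zip(once[s], twice[s]))


GENES = [GeneModel("g1", "Gm11", 21_000, 23_000),
         GeneModel("g2", "Gm11", 29_000, 43_000),
         GeneModel("g3", "Gm11", 41_000, 44_000),
         GeneModel("g4", "Gm11", 10_000, 22_500),
         GeneModel("g5", "Gm13", 5_000, 6_000)]


class TestGenesOverlapping:
    def test_partial_and_full_overlaps_count(self):
        # call spans 22,000..42,000: g1, g2 partial/full, g3 partial, g4 edge
        call = make_call("Gm11", 10, 20, "DownCNV", "S1")
        out = genes_overlapping([call], GENES)
        assert out["S1"][1] == {"g1", "g2", "g3", "g4"}

    def test_intergenic_call_counts_nothing(self):
        call = make_call("Gm11", 30, 33, "UpCNV", "S1")  # 62k..68k
        out = genes_overlapping([call], GENES)
        assert out.get("S1", (set(), set()))[0] == set()

    def test_one_bp_abutment_not_counted(self):
        # gene g5 ends at 6,000; call starts at 6,001 on Gm13
        call = SVCall("Gm13", 0, 3, 6_001, 9_000, 4, 1.0,
                      call_class="UpCNV", sample_id="S1")
        out = genes_overlapping([call], GENES)
        assert out["S1"][0] == set()
        touching = SVCall("Gm13", 0, 3, 6_000, 9_000, 4, 1.0,
                          call_class="UpCNV", sample_id="S1")
        out = genes_overlapping([touching], GENES)
        assert out["S1"][0] == {"g5"}

    def test_unknown_chromosome_raises_with_name(self):
        call = make_call("Gm99", 0, 5, "UpCNV", "S1")
        with pytest.raises(ValueError, match="Gm99"):
            genes_overlapping([call], GENES)

    def test_flagged_calls_ignored(self):
        call = make_call("Gm11", 10, 20, "DownCNV", "S1")
        call.filtered_as_heterogeneity = True
        assert genes_overlapping([call], GENES) == {}


class TestSummarizeClass:
    def test_per_genotype_gene_count_stats(self):
        calls = []
        # S2 deletes 4 genes, S3 deletes 1 (g5 via Gm13), S1 none
        calls.append(make_call("Gm11", 10, 20, "DownCNV", "S2"))
        calls.append(SVCall("Gm13", 0, 3, 5_500, 9_000, 4, -1.0,
                            call_class="DownCNV", sample_id="S3"))
        summary = summarize_class(calls, GENES, "test",
                                  samples=["S1", "S2", "S3"])
        down = summary["down"]
        assert down["max_genes_per_genotype"] == 4
        assert down["median_genes_per_genotype"] == 1
        assert down["min_genes_per_genotype"] == 0
        assert down["total_unique_genes"] == 5
        assert down["n_genic_segments"] == 2

    def test_single_genic_segment_size(self):
        call = SVCall("Gm11", 10, 12, 21_000, 27_434, 3, 1.0,
                      call_class="UpCNV", sample_id="S1")
        summary = summarize_class([call], GENES, "t", samples=["S1"])
        up = summary["up"]
        assert up["mean_segment_size_bp"] == up["median_segment_size_bp"] \
            == 6_435

    def test_no_genic_segments_reported_absent(self):
        call = make_call("Gm11", 30, 33, "UpCNV", "S1")  # intergenic
        summary = summarize_class([call], GENES, "t", samples=["S1"])
        assert summary["up"]["mean_segment_size_bp"] is None
        assert summary["up"]["n_genic_segments"] == 0


class TestIO:
    def test_track_tsv_round_trip(self, tmp_path):
        track = make_track([0.1, -0.2, 0.3])
        path = tmp_path / "S.track.tsv"
        track.to_tsv(str(path))
        back = ProbeTrack.from_tsv(str(path))
        assert back.sample_id == "S"
        assert np.allclose(back.data["Gm11"][1], [0.1, -0.2, 0.3])

    def test_gff3_gene_parsing(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text("##gff-version 3\n"
                       "Gm11\tsrc\tgene\t100\t200\t.\t+\t.\tID=geneA\n"
                       "Gm11\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=t1;"
                       "Parent=geneA\n"
                       "Gm13\tsrc\tgene\t50\t80\t.\t-\t.\tID=geneB\n")
        genes = read_genes_gff3(str(gff))
        assert {(g.gene_id, g.chromosome, g.start_bp, g.end_bp)
                for g in genes} == {("geneA", "Gm11", 100, 200),
                                    ("geneB", "Gm13", 50, 80)}

    def test_bed_export_format(self, tmp_path):
        call = make_call("Gm11", 10, 20, "DownCNV", "S1", mean=-1.0425)
        path = tmp_path / "calls.bed"
        calls_to_bed([call], str(path))
        chrom, start, end, name, score, strand = \
            path.read_text().strip().split("\t")
        assert (chrom, start, end) == ("Gm11", "21999", "42000")
        assert name == "S1|DownCNV"
        assert score == str(int(round(-1.0425 * 1000)))
        assert strand == "."
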