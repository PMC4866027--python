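"""Recovery benchmarks: run each pipeline stage on planted-truth fixtures.

Every function here generates fixtures with the synthetic-data module,
runs the corresponding analysis stage from scratch, and measures recovery
against the planted truth (or against an independent brute-force oracle).
The functions return plain metric dicts; the test suite asserts thresholds
on them and the acceptance script reports them.

The brute-force oracles in this module are deliberately written with
scalar loops over explicit definitions, independent of the vectorized
production code paths they check.
"""

from __future__ import annotations

import numpy as np

from . import cgh as cgh_mod
from .junctions import resolve_junction
from .simulate import (CghEvent, CghTruth, CohortTruth, InsertionTruth,
                       simulate_cgh, simulate_cohort, simulate_cohort_vcf,
                       simulate_insertion_reads, simulate_junction)
from .substitutions import (FilterCriteria, apply_site_filters,
                            per_sample_counts, read_vcf_sites)
from .transgene import locate_insertions

SPACING = 2000


# ---------------------------------------------------------------------------
# oracles


def oracle_best_window(x, min_len=2):
    """Exhaustive window scan by scalar loops over prefix sums."""
    n = len(x)
    csum = [0.0]
    for v in x:
        csum.append(csum[-1] + float(v))
    total = csum[n]
    best = (-1, -1, 0.0)
    for i in range(n):
        if i != 0 and i < min_len:
            continue
        for j in range(i + min_len, n + 1):
            if j != n and n - j < min_len:
                continue
            w = j - i
            out = n - w
            if out < min_len:
                continue
            s = csum[j] - csum[i]
            diff = abs(s / w - (total - s) / out)
            z = diff / (1.0 / w + 1.0 / out) ** 0.5
            if round(z, 9) > round(best[2], 9):
                best = (i, j, z)
    return best


def oracle_junction_decomposition(junction, left_ref, right_ref):
    """Canonical decomposition by enumerating every split.

    Among all (left block, right block, filler) decompositions with exact
    flank matches, the minimal-filler ones are selected and the leftmost
    breakpoint chosen; returns (left block length, right block length,
    filler).
    """
    n = len(junction)
    decomps = []
    for p in range(0, min(n, len(left_ref)) + 1):
        if junction[:p] != left_ref[:p]:
            break
        pmax = p
    for p in range(0, pmax + 1):
        for s in range(0, min(n - p, len(right_ref)) + 1):
            if s and junction[n - s:] != right_ref[len(right_ref) - s:]:
                continue
            decomps.append((p, s, junction[p:n - s]))
    min_filler = min(len(f) for _, _, f in decomps)
    candidates = [(p, s, f) for p, s, f in decomps if len(f) == min_filler]
    # leftmost breakpoint: smallest left block; break ties by largest s
    return min(candidates, key=lambda t: (t[0], -t[1]))


# ---------------------------------------------------------------------------
# benchmarks


def segmentation_oracle_benchmark(seed: int = 1, n_tracks: int = 20,
                                  n_probes: int = 400) -> dict:
    """Single-changepoint tracks: production window search vs brute force.

    Each track steps from 0 to -1 at a random changepoint (noise sd 0.15);
    the production search must return the same window as the exhaustive
    scalar scan, and the final segmentation must place a boundary exactly
    at the scan's optimum.
    """
    rng = np.random.default_rng(seed)
    n_agree_search = 0
    n_agree_boundary = 0
    for _ in range(n_tracks):
        c = int(rng.integers(50, n_probes - 50))
        x = rng.normal(0.0, 0.15, n_probes)
        x[c:] -= 1.0
        i, j, _, _ = cgh_mod.best_window(x, 2)
        oi, oj, _ = oracle_best_window(x, 2)
        if (i, j) == (oi, oj):
            n_agree_search += 1
        pos = np.arange(1, n_probes + 1) * SPACING
        track = cgh_mod.ProbeTrack.from_arrays("S", "ref",
                                               {"c": (pos, x)})
        segs = cgh_mod.segment_track(track,
                                     cgh_mod.SegmentationParams(seed=seed))
        boundaries = {s.first_probe_index for s in segs} - {0}
        oracle_edges = {e for e in (oi, oj) if 0 < e < n_probes}
        if oracle_edges <= boundaries:
            n_agree_boundary += 1
    return {
        "n_tracks": n_tracks,
        "search_agreement_pct": 100.0 * n_agree_search / n_tracks,
        "boundary_agreement_pct": 100.0 * n_agree_boundary / n_tracks,
    }


def _planted_multi_sample_truth(seed: int, n_samples: int, noise_sd: float,
                                shared: bool) -> CghTruth:
    rng = np.random.default_rng(seed)
    chrom_len = 1_000_000
    samples = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    planted = []
    for si, s in enumerate(samples):
        for chrom, cls, shift in (("Gm11", "del", -1.0),
                                  ("Gm13", "dup", 1.0)):
            n_ev = int(rng.integers(5, 26))          # probes in event
            # keep clear of the fixed shared-event region near 880-940 kb
            start_idx = int(rng.integers(30, 400 - n_ev))
            start = (start_idx + 1) * SPACING
            end = (start_idx + n_ev) * SPACING
            planted.append(CghEvent(s, chrom, start, end, cls, shift))
    shared_events = []
    if shared:
        shared_events = [CghEvent(None, "Gm11", 900_000, 940_000, "del",
                                  -1.0),
                         CghEvent(None, "Gm13", 880_000, 912_000, "dup",
                                  1.0)]
    return CghTruth(planted_events=planted, shared_events=shared_events,
                    chromosome_lengths={"Gm11": chrom_len,
                                        "Gm13": chrom_len},
                    noise_sd=noise_sd, probe_spacing_bp=SPACING, seed=seed,
                    sample_ids=samples)


def _call_events(tracks, seed: int):
    params = cgh_mod.SegmentationParams(seed=seed)
    thr = cgh_mod.ClassificationThresholds()
    calls_by = {}
    for s, track in tracks.items():
        segs = cgh_mod.segment_track(track, params)
        calls_by[s] = cgh_mod.call_and_merge(segs, thr, sample_id=s)
    return calls_by


def sv_recovery_benchmark(seed: int = 1, n_samples: int = 20) -> dict:
    """Planted-event recovery on noisy multi-sample fixtures.

    Events are +-1.0 log2 shifts of 5-25 probes (noise sd 0.15); an event
    counts as recovered when a same-class call matches both boundaries
    within 2 probes, and any overlapping opposite-class call is a swap.
    """
    truth = _planted_multi_sample_truth(seed, n_samples, noise_sd=0.15,
                                        shared=False)
    tracks, _ = simulate_cgh(truth)
    calls_by = _call_events(tracks, seed)
    class_of = {"del": cgh_mod.DOWN_LABEL, "dup": cgh_mod.UP_LABEL}
    n_events = 0
    n_recovered = 0
    n_swaps = 0
    boundary_errors = []
    for ev in truth.planted_events:
        n_events += 1
        a = ev.start_bp // SPACING - 1
        b = ev.end_bp // SPACING - 1
        hit = False
        for call in calls_by[ev.sample_id]:
            if call.chromosome != ev.chromosome:
                continue
            overlaps = call.first_probe_index <= b \
                and call.last_probe_index >= a
            if not overlaps:
                continue
            if call.call_class != class_of[ev.sv_class]:
                n_swaps += 1
                continue
            err = max(abs(call.first_probe_index - a),
                      abs(call.last_probe_index - b))
            if err <= 2:
                hit = True
                boundary_errors.append(err)
        if hit:
            n_recovered += 1
    return {
        "n_events": n_events,
        "sensitivity_pct": 100.0 * n_recovered / n_events,
        "max_boundary_error_probes": max(boundary_errors, default=0),
        "class_swaps": n_swaps,
    }


def heterogeneity_benchmark(seed: int = 1, n_samples: int = 6) -> dict:
    """Shared vs private flagging on noise-free fixtures (exact mode)."""
    truth = _planted_multi_sample_truth(seed, n_samples, noise_sd=0.0,
                                        shared=True)
    tracks, _ = simulate_cgh(truth)
    calls_by = cgh_mod.filter_heterogeneity(_call_events(tracks, seed),
                                            mode="exact")
    shared_spans = {(ev.chromosome, ev.start_bp, ev.end_bp)
                    for ev in truth.shared_events}
    n_shared = n_shared_flagged = 0
    n_private = n_private_flagged = 0
    for s, calls in calls_by.items():
        for call in calls:
            key = (call.chromosome, call.start_bp, call.end_bp)
            if key in shared_spans:
                n_shared += 1
                n_shared_flagged += call.filtered_as_heterogeneity
            else:
                n_private += 1
                n_private_flagged += call.filtered_as_heterogeneity
    return {
        "n_samples": n_samples,
        "n_shared_calls": n_shared,
        "expected_shared_calls": len(truth.shared_events) * n_samples,
        "shared_flagged_pct": (100.0 * n_shared_flagged / n_shared
                               if n_shared else 0.0),
        "private_flagged_pct": (100.0 * n_private_flagged / n_private
                                if n_private else 0.0),
    }


def substitution_recovery_benchmark(seed: int = 1, n_cohorts: int = 50,
                                    n_sites: int = 10_000,
                                    n_samples: int = 5,
                                    vcf_every: int = 10,
                                    tmp_dir: str | None = None) -> dict:
    """Planted private-count recovery across random cohorts.

    Every ``vcf_every``-th cohort goes through the full VCF write/read
    round trip; the rest run on the in-memory sites (identical content).
    """
    import os
    import tempfile

    n_exact = 0
    total_sites = 0
    for i in range(n_cohorts):
        cseed = seed + i
        rng = np.random.default_rng(cseed)
        counts = tuple(int(c) for c in rng.integers(0, 80, n_samples))
        truth = CohortTruth(n_samples=n_samples, n_sites=n_sites,
                            private_counts=counts, depth_mean=20.0,
                            seed=cseed)
        if i % vcf_every == 0:
            with tempfile.TemporaryDirectory(dir=tmp_dir) as d:
                vcf = os.path.join(d, "cohort.vcf")
                data = simulate_cohort_vcf(truth, vcf)
                sites, samples, _ = read_vcf_sites(vcf)
        else:
            data = simulate_cohort(truth)
            sites, samples = data.sites, data.sample_ids
        subs, _ = apply_site_filters(sites, samples, FilterCriteria())
        table = per_sample_counts(subs, samples)
        got = tuple(table.n_private.tolist())
        total_sites += n_sites
        n_exact += got == counts
    return {
        "n_cohorts": n_cohorts,
        "n_sites_total": total_sites,
        "exact_recovery_pct": 100.0 * n_exact / n_cohorts,
    }


def insertion_recovery_benchmark(seed: int = 1, n_seeds: int = 5,
                                 coverages: tuple = (10, 30)) -> dict:
    """Insertion locus recovery over orientations x coverages x seeds."""
    n_runs = 0
    n_chrom = n_orient = n_exact_coord = 0
    deletion_err_junction = []
    deletion_err_depth = []
    for orientation in ("+", "-"):
        for coverage in coverages:
            for k in range(n_seeds):
                truth = InsertionTruth(
                    orientation=orientation, coverage_depth=coverage,
                    host_sequence_length_bp=30_000, insertion_site=15_000,
                    seed=seed + k)
                data = simulate_insertion_reads(truth)
                res = locate_insertions(
                    data.pairs, data.construct_seq, data.host_seq,
                    truth.host_name,
                    insert_size_mean=truth.insert_size_mean,
                    insert_size_sd=truth.insert_size_sd)
                n_runs += 1
                if not res.calls:
                    continue
                call = max(res.calls, key=lambda c: c.total_support)
                n_chrom += call.chromosome == truth.host_name
                n_orient += call.orientation == truth.orientation
                n_exact_coord += (call.lb_adjacent_coordinate
                                  == truth.lb_adjacent_coordinate)
                if res.local_svs:
                    deletion_err_junction.append(abs(
                        res.local_svs[0].size_bp
                        - truth.adjacent_deletion_bp))
                res_d = locate_insertions(
                    data.pairs, data.construct_seq, data.host_seq,
                    truth.host_name,
                    insert_size_mean=truth.insert_size_mean,
                    insert_size_sd=truth.insert_size_sd, refine=False)
                if res_d.local_svs:
                    deletion_err_depth.append(abs(
                        res_d.local_svs[0].size_bp
                        - truth.adjacent_deletion_bp))
    return {
        "n_runs": n_runs,
        "chromosome_recovery_pct": 100.0 * n_chrom / n_runs,
        "orientation_recovery_pct": 100.0 * n_orient / n_runs,
        "exact_coordinate_pct": 100.0 * n_exact_coord / n_runs,
        "n_deletions_sized": len(deletion_err_junction),
        "max_deletion_error_junction_bp": max(deletion_err_junction,
                                              default=-1),
        "max_deletion_error_depth_bp": max(deletion_err_depth, default=-1),
    }


def junction_oracle_benchmark(seed: int = 1, n_cases: int = 1000) -> dict:
    """resolve_junction vs exhaustive decomposition on random junctions."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    n_agree = 0
    n_round_trip = 0
    for i in range(n_cases):
        filler_len = int(rng.integers(0, 11))
        filler = "".join(bases[rng.integers(0, 4, filler_len)])
        if filler_len == 0:
            mh_l = mh_r = int(rng.integers(0, 11))
        else:
            mh_l, mh_r = int(rng.integers(0, 11)), int(rng.integers(0, 11))
        obs, truth = simulate_junction(mh_l, mh_r, filler,
                                       seed=seed * 100_000 + i)
        res = resolve_junction(obs)
        p, s, f = oracle_junction_decomposition(
            obs.junction_sequence, obs.left_flank_ref, obs.right_flank_ref)
        left_len = res.breakpoint_left - obs.left_anchor + 1
        right_len = obs.right_anchor - res.breakpoint_right + 1
        n_agree += (left_len, right_len,
                    res.filler_sequence) == (p, s, f)
        n_round_trip += (res.mh_left_bp, res.mh_right_bp,
                         res.filler_sequence, res.event_size_bp) == \
            (truth.mh_left_bp, truth.mh_right_bp, truth.filler_sequence,
             truth.event_size_bp)
    return {
        "n_cases": n_cases,
        "oracle_agreement_pct": 100.0 * n_agree / n_cases,
        "round_trip_pct": 100.0 * n_round_trip / n_cases,
    }


def threshold_boundary_benchmark() -> dict:
    """Segments at exactly the calibrated thresholds are never called."""
    thr = cgh_mod.ClassificationThresholds()
    segs = [
        cgh_mod.Segment("c", 0, 4, 1, 5, 5, thr.upper),
        cgh_mod.Segment("c", 0, 4, 1, 5, 5, thr.lower),
        cgh_mod.Segment("c", 0, 1, 1, 2, 2, 1.5),    # 2 probes, huge shift
        cgh_mod.Segment("c", 0, 1, 1, 2, 2, -1.5),
    ]
    calls = cgh_mod.classify_segments(segs, thr, "S")
    nudged = [
        cgh_mod.Segment("c", 0, 4, 1, 5, 5, thr.upper + 1e-4),
        cgh_mod.Segment("c", 0, 4, 1, 5, 5, thr.lower - 1e-4),
    ]
    control = cgh_mod.classify_segments(nudged, thr, "S")
    return {
        "n_boundary_segments": len(segs),
        "boundary_violations": len(calls),
        "nudged_called": len(control),
    }
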