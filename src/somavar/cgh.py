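"""Copy-number segmentation and structural-variant calling from CGH tracks.

A tiling-array comparison of a test genotype against its reference produces
one log2 intensity ratio per probe.  Contiguous runs of shifted probes mark
deletions (negative shift) or duplications (positive shift).  The pipeline:

1. optional median-centering of each track;
2. recursive binary segmentation with a permutation acceptance test
   (minimum segment mean difference 0.1 log2 units, minimum segment length
   2 probes, acceptance percentile 0.99, 10 permutations);
3. classification of segment means against empirically calibrated
   thresholds (upper 0.3484 for copy gain "UpCNV", lower -0.5257 for copy
   loss "DownCNV", 3-probe minimum per call);
4. subtraction of intra-cultivar heterogeneity: same-class calls at the
   exact same probe location in multiple plants of one background are
   segregating background variation, not induced events, and are flagged;
5. gene-overlap accounting against a GFF3 annotation and per-class
   summaries (unique genes hit, genic-segment size statistics).

Hemizygous and homozygous deletions are not distinguished; a hemizygous
loss shows an intermediate negative shift but both fall below the lower
threshold when calibrated as here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import stream_rng

UP_LABEL = "UpCNV"
DOWN_LABEL = "DownCNV"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ProbeTrack:
    """Ordered per-probe (chromosome, position, log2 ratio) measurements."""

    sample_id: str
    reference_id: str
    # chromosome -> (positions 1-based strictly increasing, log2 ratios)
    data: dict[str, tuple[np.ndarray, np.ndarray]]

    @classmethod
    def from_arrays(cls, sample_id: str, reference_id: str,
                    data: dict[str, tuple[np.ndarray, np.ndarray]]
                    ) -> "ProbeTrack":
        clean = {}
        for chrom, (pos, log2) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            log2 = np.asarray(log2, dtype=np.float64)
            if pos.size != log2.size:
                raise ValueError(f"{chrom}: position/ratio length mismatch")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions not strictly increasing")
            if not np.all(np.isfinite(log2)):
                raise ValueError(f"{chrom}: non-finite log2 ratios")
            clean[chrom] = (pos, log2)
        return cls(sample_id, reference_id, clean)

    @classmethod
    def from_tsv(cls, path: str, sample_id: Optional[str] = None,
                 reference_id: str = "reference") -> "ProbeTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "pos", "log2"], comment="#")
        if sample_id is None:
            sample_id = str(path).rsplit("/", 1)[-1].split(".")[0]
        df = df.sort_values(["chrom", "pos"], kind="mergesort")
        data = {str(c): (g["pos"].to_numpy(np.int64),
                         g["log2"].to_numpy(np.float64))
                for c, g in df.groupby("chrom", sort=True)}
        return cls.from_arrays(sample_id, reference_id, data)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                pos, log2 = self.data[chrom]
                for p, v in zip(pos, log2):
                    fh.write(f"{chrom}\t{p}\t{v:.4f}\n")

    @property
    def n_probes(self) -> int:
        return sum(p.size for p, _ in self.data.values())


@dataclass
class SegmentationParams:
    min_segment_difference: float = 0.1   # log2 units
    min_probes_segment: int = 2
    acceptance_percentile: float = 0.99
    n_permutations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.acceptance_percentile < 1:
            raise ValueError("acceptance_percentile must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ClassificationThresholds:
    upper: float = 0.3484    # calibrated on duplications in FN plants
    lower: float = -0.5257   # calibrated on hemizygous deletions
    min_probes_call: int = 3

    def __post_init__(self) -> None:
        if not self.lower < 0 < self.upper:
            raise ValueError("need lower < 0 < upper")


@dataclass
class Segment:
    chromosome: str
    first_probe_index: int  # 0-based index within the chromosome's probes
    last_probe_index: int   # inclusive
    start_bp: int           # position of first probe (1-based)
    end_bp: int             # position of last probe (1-based)
    n_probes: int
    mean_log2: float

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SVCall(Segment):
    call_class: str = UP_LABEL
    sample_id: str = ""
    filtered_as_heterogeneity: bool = False


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# operations


def center_track(track: ProbeTrack) -> ProbeTrack:
    """Subtract the genome-wide median log2 ratio from every probe.

    A cheap per-track re-centering so that the unchanged majority of the
    genome sits at 0; idempotent.
    """
    if track.n_probes == 0:
        raise ValueError("empty track")
    allv = np.concatenate([v for _, v in track.data.values()])
    med = float(np.median(allv))
    data = {c: (p, v - med) for c, (p, v) in track.data.items()}
    return ProbeTrack(track.sample_id, track.reference_id, data)


def best_window(x: np.ndarray, min_len: int
                ) -> tuple[int, int, float, float]:
    """Best sub-window of ``x`` against its complement, leftmost on ties.

    The statistic is the two-sample mean difference normalized by its
    combinatorial scale, z(i, j) = |mean(x[i:j]) - mean(rest)| /
    sqrt(1/n_in + 1/n_out); normalization makes windows of very unequal
    sizes comparable, so a few extreme probes cannot dominate the
    permutation null through tiny windows.  An edge-anchored window is an
    ordinary binary split; an interior window captures an event in the
    middle of a flat interval with one step.  Both the window and its
    complement need ``min_len`` probes, and a window edge may not leave a
    flank shorter than ``min_len``.  Returns (i, j, raw mean difference,
    z); i == -1 when no admissible window exists.
    """
    n = x.size
    if n < 2 * min_len:
        return -1, -1, 0.0, 0.0
    csum = np.concatenate([[0.0], np.cumsum(x)])
    total = csum[n]
    best = (-1, -1, 0.0, 0.0)
    for i in range(0, n - min_len + 1):
        if i != 0 and i < min_len:
            continue
        j_lo = i + min_len
        j_hi = n if i > 0 else n - min_len  # whole interval is not a window
        if j_lo > j_hi:
            continue
        j = np.arange(j_lo, j_hi + 1)
        # a right flank, when present, must hold min_len probes
        j = j[(j == n) | (n - j >= min_len)]
        if j.size == 0:
            continue
        win = j - i
        out = n - win
        win_sum = csum[j] - csum[i]
        diff = np.abs(win_sum / win - (total - win_sum) / out)
        z = diff / np.sqrt(1.0 / win + 1.0 / out)
        # a window and its complement have mathematically equal z; round
        # before comparing so the leftmost of such a tie wins regardless
        # of float noise
        zr = np.round(z, 9)
        k = int(np.argmax(zr))
        if zr[k] > round(best[3], 9):
            best = (i, int(j[k]), float(diff[k]), float(z[k]))
    return best


def _segment_values(x: np.ndarray, params: SegmentationParams,
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive permutation-accepted segmentation of one chromosome.

    At each step the best sub-window of the current interval is accepted
    iff its raw mean difference reaches ``min_segment_difference`` and its
    normalized statistic exceeds the ``acceptance_percentile`` quantile of
    the maximal statistic over ``n_permutations`` shufflings of the
    interval's probe values; the interval then splits at the accepted
    window edges and recursion continues until no window is accepted.
    """
    bounds: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        i, j, diff, z = best_window(seg, params.min_probes_segment)
        accept = False
        if i >= 0 and diff >= params.min_segment_difference:
            perm_stats = np.empty(params.n_permutations)
            for b in range(params.n_permutations):
                perm = rng.permutation(seg)
                _, _, _, pz = best_window(perm, params.min_probes_segment)
                perm_stats[b] = pz
            threshold = float(np.quantile(perm_stats,
                                          params.acceptance_percentile))
            accept = z > threshold
        if accept:
            for a, b2 in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                if b2 > a:
                    recurse(a, b2)
        else:
            bounds.append((lo, hi))

    recurse(0, x.size)
    bounds.sort()
    return bounds


def segment_track(track: ProbeTrack, params: SegmentationParams
                  ) -> list[Segment]:
    """Partition each chromosome's probes into mean-homogeneous segments.

    At each step the split maximizing the absolute difference of side means
    is accepted iff the difference reaches ``min_segment_difference`` and
    exceeds the ``acceptance_percentile`` quantile of the same statistic on
    ``n_permutations`` shufflings of the interval; recursion stops when no
    split is accepted or a side would fall under ``min_probes_segment``
    probes.  The permutation stream is seeded per (sample, chromosome) so a
    fixed seed reproduces the segmentation.
    """
    segments: list[Segment] = []
    for chrom in sorted(track.data):
        pos, log2 = track.data[chrom]
        if pos.size == 0:
            continue
        if pos.size < 2 * params.min_probes_segment:
            bounds = [(0, pos.size)]
        else:
            rng = stream_rng(params.seed, "segment", track.sample_id, chrom)
            bounds = _segment_values(log2, params, rng)
        for lo, hi in bounds:
            segments.append(Segment(
                chromosome=chrom, first_probe_index=lo,
                last_probe_index=hi - 1, start_bp=int(pos[lo]),
                end_bp=int(pos[hi - 1]), n_probes=hi - lo,
                mean_log2=float(np.mean(log2[lo:hi]))))
    return segments


def classify_segments(segments: Iterable[Segment],
                      thresholds: ClassificationThresholds,
                      sample_id: str = "") -> list[SVCall]:
    """Turn segments into UpCNV/DownCNV calls.

    "Exceeded" and "less than" are strict: a mean exactly equal to a
    threshold is not a call, and calls need ``min_probes_call`` probes.
    """
    calls: list[SVCall] = []
    for seg in segments:
        if seg.n_probes < thresholds.min_probes_call:
            continue
        if seg.mean_log2 > thresholds.upper:
            cls = UP_LABEL
        elif seg.mean_log2 < thresholds.lower:
            cls = DOWN_LABEL
        else:
            continue
        calls.append(SVCall(
            chromosome=seg.chromosome,
            first_probe_index=seg.first_probe_index,
            last_probe_index=seg.last_probe_index,
            start_bp=seg.start_bp, end_bp=seg.end_bp,
            n_probes=seg.n_probes, mean_log2=seg.mean_log2,
            call_class=cls, sample_id=sample_id or "",
        ))
    return calls


def merge_adjacent_calls(calls: Iterable[SVCall]) -> list[SVCall]:
    """Merge same-class calls on directly adjacent probe runs.

    With an acceptance threshold taken from only 10 permutations, a true
    event is occasionally fragmented by a spurious internal split; the
    fragments are adjacent calls of the same class and are rejoined here
    (probe-count-weighted mean).  Calls from different samples, classes or
    chromosomes never merge.
    """
    out: list[SVCall] = []
    for c in sorted(calls, key=lambda c: (c.sample_id, c.chromosome,
                                          c.first_probe_index)):
        prev = out[-1] if out else None
        if prev is not None and prev.sample_id == c.sample_id \
                and prev.chromosome == c.chromosome \
                and prev.call_class == c.call_class \
                and prev.last_probe_index + 1 == c.first_probe_index:
            total = prev.n_probes + c.n_probes
            prev.mean_log2 = (prev.mean_log2 * prev.n_probes
                              + c.mean_log2 * c.n_probes) / total
            prev.last_probe_index = c.last_probe_index
            prev.end_bp = c.end_bp
            prev.n_probes = total
        else:
            out.append(replace(c))
    return out


def call_and_merge(segments: Iterable[Segment],
                   thresholds: ClassificationThresholds,
                   sample_id: str = "") -> list[SVCall]:
    """Classify, rejoin fragments, then apply the probe-count minimum.

    Segmentation occasionally fragments one event into adjacent pieces, and
    a piece may fall under the per-call probe minimum even though the event
    as a whole clears it; thresholding the mean first, merging adjacent
    same-class pieces, and applying ``min_probes_call`` to the merged call
    keeps the probe minimum a property of the event.  A lone sub-minimum
    segment is still dropped exactly as in ``classify_segments``.
    """
    permissive = ClassificationThresholds(
        upper=thresholds.upper, lower=thresholds.lower, min_probes_call=1)
    merged = merge_adjacent_calls(
        classify_segments(segments, permissive, sample_id=sample_id))
    return [c for c in merged if c.n_probes >= thresholds.min_probes_call]


def candidate_review(segments: Iterable[Segment],
                     thresholds: ClassificationThresholds,
                     relax_factor: float) -> list[Segment]:
    """Sub-threshold segments worth a human look.

    Mechanizes the visual-inspection step: segments that fail the strict
    call but would pass thresholds relaxed by ``relax_factor`` are returned
    sorted by |mean| descending.  Never mutates calls.
    """
    if not 0 < relax_factor <= 1:
        raise ValueError("relax_factor must be in (0, 1]")
    rel_up = thresholds.upper * relax_factor
    rel_down = thresholds.lower * relax_factor
    out = []
    for seg in segments:
        if seg.n_probes < thresholds.min_probes_call:
            continue
        strict = seg.mean_log2 > thresholds.upper or \
            seg.mean_log2 < thresholds.lower
        relaxed = seg.mean_log2 > rel_up or seg.mean_log2 < rel_down
        if relaxed and not strict:
            out.append(seg)
    out.sort(key=lambda s: -abs(s.mean_log2))
    return out


def _reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    inter = min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.size_bp, inter / b.size_bp)


def filter_heterogeneity(calls_by_sample: dict[str, list[SVCall]],
                         mode: str = "exact", min_recurrence: int = 2,
                         reciprocal_overlap: float = 1.0
                         ) -> dict[str, list[SVCall]]:
    """Flag calls shared across plants of one background as heterogeneity.

    A call recurring at the same location with the same class in at least
    ``min_recurrence`` samples is standing intra-cultivar variation, not an
    induced event.  "exact" mode requires identical chromosome and start/end
    probe indices; "reciprocal" mode requires pairwise reciprocal overlap of
    at least ``reciprocal_overlap``.  Flagged calls stay in the output (for
    audit) but are excluded from downstream counts.  Idempotent.
    """
    if mode not in ("exact", "reciprocal"):
        raise ValueError(f"unknown mode {mode!r}")
    out = {s: [replace(c) for c in calls]
           for s, calls in calls_by_sample.items()}
    if len(out) < 2:
        warnings.warn("heterogeneity filtering needs >= 2 samples sharing a "
                      "background; returning calls unchanged", stacklevel=2)
        return out

    flat = [(s, c) for s, calls in out.items() for c in calls]
    if mode == "exact":
        groups: dict[tuple, list[tuple[str, SVCall]]] = {}
        for s, c in flat:
            key = (c.chromosome, c.first_probe_index, c.last_probe_index,
                   c.call_class)
            groups.setdefault(key, []).append((s, c))
        for members in groups.values():
            if len({s for s, _ in members}) >= min_recurrence:
                for _, c in members:
                    c.filtered_as_heterogeneity = True
    else:
        for s, c in flat:
            carriers = {s}
            for s2, c2 in flat:
                if s2 == s or c2.call_class != c.call_class \
                        or c2.chromosome != c.chromosome:
                    continue
                if _reciprocal_overlap(c, c2) >= reciprocal_overlap:
                    carriers.add(s2)
            if len(carriers) >= min_recurrence:
                c.filtered_as_heterogeneity = True
    return out


def unfiltered_calls(calls_by_sample: dict[str, list[SVCall]]
                     ) -> dict[str, list[SVCall]]:
    """Calls surviving the heterogeneity filter."""
    return {s: [c for c in calls if not c.filtered_as_heterogeneity]
            for s, calls in calls_by_sample.items()}


def _gene_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(
            g.start_bp, g.end_bp + 1, g.gene_id)  # half-open interval
    return trees


def genes_overlapping(calls: Iterable[SVCall], genes: Sequence[GeneModel]
                      ) -> dict[str, tuple[set[str], set[str]]]:
    """Per-sample sets of (duplicated, deleted) gene ids.

    A gene counts when its interval overlaps a call by at least 1 bp; a
    gene hit by several calls of one class counts once per sample.  Calls
    flagged as heterogeneity are ignored.  A call on a chromosome absent
    from the annotation raises, naming the chromosome.
    """
    trees = _gene_trees(genes)
    out: dict[str, tuple[set[str], set[str]]] = {}
    for call in calls:
        if call.filtered_as_heterogeneity:
            continue
        if call.chromosome not in trees:
            raise ValueError(
                f"chromosome {call.chromosome!r} in calls but not in the "
                "gene annotation")
        dup, dele = out.setdefault(call.sample_id, (set(), set()))
        hits = {iv.data for iv in
                trees[call.chromosome].overlap(call.start_bp,
                                               call.end_bp + 1)}
        (dup if call.call_class == UP_LABEL else dele).update(hits)
    return out


def summarize_class(calls: Iterable[SVCall], genes: Sequence[GeneModel],
                    class_label: str,
                    samples: Optional[Sequence[str]] = None) -> dict:
    """Class-level summary of genic SV burden and segment sizes.

    For Up and Down calls separately: total unique genes affected in the
    class, max/median/min per-genotype gene counts, number of genic
    segments (calls overlapping at least one gene), and mean/median segment
    size over genic segments only (absent, not zero, when there are none).
    """
    calls = [c for c in calls if not c.filtered_as_heterogeneity]
    per_sample = genes_overlapping(calls, genes) if calls else {}
    if samples is None:
        samples = sorted({c.sample_id for c in calls})
    summary: dict = {"class_label": class_label, "samples": list(samples)}
    trees = _gene_trees(genes)
    for direction, label in ((UP_LABEL, "up"), (DOWN_LABEL, "down")):
        idx = 0 if direction == UP_LABEL else 1
        gene_sets = {s: per_sample.get(s, (set(), set()))[idx]
                     for s in samples}
        counts = [len(gene_sets[s]) for s in samples]
        genic_sizes = []
        for c in calls:
            if c.call_class != direction:
                continue
            tree = trees.get(c.chromosome)
            if tree is not None and tree.overlap(c.start_bp, c.end_bp + 1):
                genic_sizes.append(c.size_bp)
        summary[label] = {
            "total_unique_genes": len(set().union(*gene_sets.values())
                                      if gene_sets else set()),
            "max_genes_per_genotype": max(counts) if counts else 0,
            "median_genes_per_genotype": median(counts) if counts else 0,
            "min_genes_per_genotype": min(counts) if counts else 0,
            "n_genic_segments": len(genic_sizes),
            "mean_segment_size_bp": (float(np.mean(genic_sizes))
                                     if genic_sizes else None),
            "median_segment_size_bp": (float(np.median(genic_sizes))
                                       if genic_sizes else None),
        }
    return summary


# ---------------------------------------------------------------------------
# annotation input and BED output


def read_genes_gff3(path: str) -> list[GeneModel]:
    """Gene models (type == gene) from a GFF3 annotation."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end))
    return genes


def calls_to_bed(calls: Iterable[SVCall], path: str) -> None:
    """BED: chrom, start-1, end, name=sample|class, score=mean*1000, '.'."""
    rows = sorted(calls, key=lambda c: (c.chromosome, c.start_bp))
    with open(path, "w") as fh:
        for c in rows:
            score = int(round(c.mean_log2 * 1000))
            fh.write(f"{c.chromosome}\t{c.start_bp - 1}\t{c.end_bp}\t"
                     f"{c.sample_id}|{c.call_class}\t{score}\t.\n")
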