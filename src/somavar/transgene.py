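"""T-DNA insertion-site mapping from paired-end reads.

The strategy follows the orphaned-mate approach: reads are first matched
against the transgene sequence between the left border (LB) and right
border (RB); the mates of construct-matched reads that themselves fail to
match the construct ("orphans") are then placed on the host genome.  Orphans
pile up on both flanks of the integration site with convergent strands; the
innermost host base on the LB side is the reported coordinate, and the
orientation follows the convention that "+" means the construct runs LB to
RB on the host forward strand.  Candidate loci whose support derives from
construct elements with known genomic paralogs are flagged, not deleted.
Read depth and pair spacing around a located insertion expose adjacent
deletions too small for array detection, and junction-spanning reads refine
both the insertion coordinate and the deletion bounds to base-pair
exactness.

A built-in matcher (exact 21-mer seeds with ungapped extension, >= 90%
identity over >= 90% of the read on either strand) handles fixture-scale
data; externally produced SAM alignments are ingested equivalently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._util import revcomp

DEFAULT_K = 21
MIN_IDENTITY = 0.9
MIN_COVERED = 0.9


# ---------------------------------------------------------------------------
# alignment primitives


@dataclass
class Alignment:
    pos: int        # 0-based leftmost position of the read on the target
    strand: str     # '+' or '-'
    identity: float
    covered: float  # fraction of the read inside the target
    mapq: int       # 60 unique best placement, 0 ambiguous


class KmerIndex:
    """Exact k-mer seed index with ungapped extension over one sequence."""

    def __init__(self, target: str, k: int = DEFAULT_K):
        if k < 1:
            raise ValueError("k must be >= 1")
        if not target:
            raise ValueError("empty target sequence")
        self.target = target
        self.k = k
        self.index: dict[str, list[int]] = {}
        for i in range(len(target) - k + 1):
            self.index.setdefault(target[i:i + k], []).append(i)

    def _candidates(self, read: str) -> set[int]:
        k = self.k
        offsets = list(range(0, max(1, len(read) - k + 1), k))
        if len(read) >= k and (len(read) - k) not in offsets:
            offsets.append(len(read) - k)
        diags: set[int] = set()
        for off in offsets:
            for hit in self.index.get(read[off:off + k], ()):
                diags.add(hit - off)
        return diags

    def _score(self, read: str, diag: int) -> tuple[float, float]:
        t = self.target
        lo = max(0, -diag)
        hi = min(len(read), len(t) - diag)
        if hi <= lo:
            return 0.0, 0.0
        matches = sum(1 for i in range(lo, hi) if read[i] == t[diag + i])
        covered = (hi - lo) / len(read)
        return matches / (hi - lo), covered

    def align(self, read: str) -> Optional[Alignment]:
        """Best ungapped placement of the read on either strand, or None.

        A placement qualifies when identity >= 90% over >= 90% of the read
        length; mapq is 0 when several placements tie for best.
        """
        if self.k > len(read):
            raise ValueError("k exceeds read length")
        best: Optional[Alignment] = None
        n_best = 0
        for strand, seq in (("+", read), ("-", revcomp(read))):
            for diag in self._candidates(seq):
                ident, cov = self._score(seq, diag)
                if ident < MIN_IDENTITY or cov < MIN_COVERED:
                    continue
                score = ident * cov
                if best is None or score > best.identity * best.covered + 1e-12:
                    best = Alignment(max(diag, 0), strand, ident, cov, 60)
                    n_best = 1
                elif abs(score - best.identity * best.covered) <= 1e-12 \
                        and (diag != best.pos or strand != best.strand):
                    n_best += 1
        if best is not None and n_best > 1:
            best.mapq = 0
        return best


def match_reads_to_construct(reads: Iterable[tuple[str, str]],
                             construct: str, k: int = DEFAULT_K
                             ) -> dict[str, Optional[Alignment]]:
    """Align each (read_key, sequence) to the LB-RB construct interval.

    Returns the alignment per read key (None when unmatched); a read is
    construct-aligned iff its value is not None.
    """
    idx = KmerIndex(construct, k)
    return {key: idx.align(seq) for key, seq in reads}


def extract_orphans(pair_alignments: dict[str, dict[int, Optional[Alignment]]]
                    ) -> tuple[list[tuple[str, int]], int]:
    """Read ends whose mate is construct-aligned but which are not.

    ``pair_alignments`` maps read name -> {1: aln|None, 2: aln|None}.
    Returns (orphans, n_skipped_unpaired).
    """
    orphans: list[tuple[str, int]] = []
    skipped = 0
    for name, ends in pair_alignments.items():
        if set(ends) != {1, 2}:
            skipped += 1
            continue
        for end in (1, 2):
            mate = 2 if end == 1 else 1
            if ends[mate] is not None and ends[end] is None:
                orphans.append((name, end))
    return orphans, skipped


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ConstructModel:
    """The transgene sequence between LB and RB plus element annotations."""

    sequence: str
    elements: list[tuple[str, int, int]] = field(default_factory=list)
    homologous_elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, start, end in self.elements:
            if not 1 <= start <= end <= len(self.sequence):
                raise ValueError(f"element {name} outside construct bounds")

    def element_interval(self, name: str) -> tuple[int, int]:
        for n, s, e in self.elements:
            if n == name:
                return s, e
        raise KeyError(name)


@dataclass
class OrphanPlacement:
    read_name: str
    end: int
    host_pos: int            # 0-based leftmost on host
    strand: str
    mapq: int
    read_len: int
    mate_construct_pos: int  # 0-based leftmost of the construct-aligned mate
    mate_construct_strand: str


@dataclass
class InsertionCall:
    chromosome: str
    lb_adjacent_coordinate: int  # 1-based host base adjacent to LB
    orientation: str
    n_supporting_pairs_left: int
    n_supporting_pairs_right: int
    filtered_homologous: bool = False
    refined: bool = False
    left_inner_bp: int = 0   # innermost host base of the left-flank pile-up
    right_inner_bp: int = 0  # innermost host base of the right-flank pile-up
    mate_construct_positions: list[int] = field(default_factory=list)

    @property
    def total_support(self) -> int:
        return self.n_supporting_pairs_left + self.n_supporting_pairs_right


@dataclass
class LocalSVCall:
    chromosome: str
    start_bp: int
    end_bp: int
    evidence: set[str] = field(default_factory=set)
    status: str = "ok"  # ok | undetermined

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


# ---------------------------------------------------------------------------
# clustering and filtering


def _strand_clusters(placements: list[OrphanPlacement],
                     max_gap: float) -> list[list[OrphanPlacement]]:
    clusters: list[list[OrphanPlacement]] = []
    for p in sorted(placements, key=lambda p: p.host_pos):
        if clusters and p.host_pos - clusters[-1][-1].host_pos <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def cluster_insertions(placements: Sequence[OrphanPlacement],
                       insert_size_mean: float, chromosome: str,
                       min_support: int = 3, min_mapq: int = 20,
                       max_adjacent_gap: int = 20_000
                       ) -> list[InsertionCall]:
    """Group orphan placements into insertion calls.

    Orphans within twice the mean insert size form a flank cluster; a call
    pairs a forward-strand (upstream) cluster with the nearest downstream
    reverse-strand cluster, each with at least ``min_support`` pairs.  The
    flank clusters may sit up to ``max_adjacent_gap`` apart, since an
    insertion-adjacent deletion widens the gap between the pile-ups well
    beyond the insert size.  The reported coordinate is the innermost host
    base on the LB side, and the orientation comes from which construct end
    the flank mates hit: left-flank mates on the construct reverse strand
    mean the LB faces the left flank, i.e. LB-to-RB on the forward strand
    ("+").
    """
    usable = [p for p in placements if p.mapq >= min_mapq]
    gap = 2 * insert_size_mean
    plus = [c for c in _strand_clusters(
        [p for p in usable if p.strand == "+"], gap)
        if len(c) >= min_support]
    minus = [c for c in _strand_clusters(
        [p for p in usable if p.strand == "-"], gap)
        if len(c) >= min_support]
    calls: list[InsertionCall] = []
    used_minus: set[int] = set()
    for left in plus:
        left_inner = max(p.host_pos + p.read_len for p in left)  # 1-based
        candidates = [
            (mi, right) for mi, right in enumerate(minus)
            if mi not in used_minus
            and -gap <= (min(p.host_pos for p in right) + 1 - left_inner)
            <= gap + max_adjacent_gap]
        if not candidates:
            continue
        mi, right = min(candidates, key=lambda t: abs(
            min(p.host_pos for p in t[1]) + 1 - left_inner))
        used_minus.add(mi)
        right_inner = min(p.host_pos for p in right) + 1
        lb_left_votes = sum(1 for p in left
                            if p.mate_construct_strand == "-")
        orientation = "+" if lb_left_votes >= len(left) / 2 else "-"
        coord = left_inner if orientation == "+" else right_inner
        calls.append(InsertionCall(
            chromosome=chromosome, lb_adjacent_coordinate=coord,
            orientation=orientation, n_supporting_pairs_left=len(left),
            n_supporting_pairs_right=len(right), left_inner_bp=left_inner,
            right_inner_bp=right_inner,
            mate_construct_positions=[p.mate_construct_pos
                                      for p in left + right]))
    return calls


def filter_homologous_loci(calls: Sequence[InsertionCall],
                           construct: ConstructModel,
                           paralog_regions: Sequence[tuple[str, int, int]]
                           ) -> list[InsertionCall]:
    """Flag calls explained by construct-genome homology.

    A call is flagged (not deleted) when more than half of its supporting
    mates aligned within construct elements known to have genomic paralogs
    and its coordinate falls inside a listed paralog region.
    """
    homologous_spans = [construct.element_interval(n)
                        for n in construct.homologous_elements]
    out = []
    for call in calls:
        flagged = False
        if homologous_spans and paralog_regions \
                and call.mate_construct_positions:
            inside = sum(
                1 for pos in call.mate_construct_positions
                if any(s - 1 <= pos <= e - 1 for s, e in homologous_spans))
            frac = inside / len(call.mate_construct_positions)
            in_paralog = any(
                chrom == call.chromosome and s <= call.lb_adjacent_coordinate <= e
                for chrom, s, e in paralog_regions)
            flagged = frac > 0.5 and in_paralog
        out.append(InsertionCall(**{**call.__dict__,
                                    "filtered_homologous": flagged}))
    return out


# ---------------------------------------------------------------------------
# junction refinement and local SV detection


def _max_prefix_at(read: str, target: str, diag: int) -> int:
    n = 0
    while n < len(read) and 0 <= diag + n < len(target) \
            and read[n] == target[diag + n]:
        n += 1
    return n


def _max_suffix_at(read: str, target: str, diag: int) -> int:
    n = 0
    L = len(read)
    while n < L and 0 <= diag + L - 1 - n < len(target) \
            and read[L - 1 - n] == target[diag + L - 1 - n]:
        n += 1
    return n


def partial_host_placement(seq: str, host: str, idx: KmerIndex,
                           min_anchor: int = 30
                           ) -> Optional[tuple[int, int, str]]:
    """Anchored placement of a read that only partially matches the host.

    Junction-spanning orphans (part host, part construct or filler) fail
    the full-length matcher but still carry an exact host anchor; the
    longest exact prefix or suffix match of at least ``min_anchor`` bases,
    on either strand, places them.  Returns (host_pos of the matched
    block, matched length, strand) with the forward strand meaning the
    read itself matched forward.
    """
    best: Optional[tuple[int, int, str]] = None
    best_len = min_anchor - 1
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for diag in idx._candidates(s):
            p = _max_prefix_at(s, host, diag)
            sfx = _max_suffix_at(s, host, diag)
            if max(p, sfx) <= best_len or max(p, sfx) == len(s):
                continue
            if p >= sfx:
                best = (diag, p, strand)
            else:
                best = (diag + len(s) - sfx, sfx, strand)
            best_len = max(p, sfx)
    return best


def _touches_construct(segment: str, construct: str, construct_rc: str
                       ) -> bool:
    if len(segment) < DEFAULT_K:
        return True  # too short to verify; accept
    for probe in (segment[:DEFAULT_K], segment[-DEFAULT_K:]):
        if probe in construct or probe in construct_rc:
            return True
    return False


def refine_insertion(call: InsertionCall, reads: Iterable[tuple[str, str]],
                     host: str, construct: str, host_index: KmerIndex,
                     window: int = 5000
                     ) -> tuple[InsertionCall, Optional[int]]:
    """Refine the insertion breakpoints with junction-spanning reads.

    A read whose prefix matches the host exactly up to a point and whose
    remainder matches the construct pins the left junction to the base; a
    read whose suffix matches the host past the construct/filler pins the
    host resumption point after any adjacent deletion.  Returns the refined
    call and the resumption coordinate (1-based first retained host base
    right of the insertion) when observed.
    """
    construct_rc = revcomp(construct)
    centre = (call.left_inner_bp + call.right_inner_bp) // 2
    left_votes: Counter[int] = Counter()
    right_votes: Counter[int] = Counter()
    for _, seq in reads:
        for read in (seq, revcomp(seq)):
            for diag in host_index._candidates(read):
                if abs(diag - centre) > window:
                    continue
                p = _max_prefix_at(read, host, diag)
                if 15 <= p < len(read) \
                        and _touches_construct(read[p:], construct,
                                               construct_rc):
                    left_votes[diag + p] += 1  # 1-based last host base
                s = _max_suffix_at(read, host, diag)
                if 15 <= s < len(read) \
                        and _touches_construct(read[:len(read) - s],
                                               construct, construct_rc):
                    right_votes[diag + len(read) - s + 1] += 1

    refined = InsertionCall(**call.__dict__)
    resumption = None
    if left_votes:
        site = max(sorted(left_votes), key=lambda c: (left_votes[c], -c))
        refined.left_inner_bp = site
        refined.refined = True
    if right_votes:
        resumption = max(sorted(right_votes),
                         key=lambda c: (right_votes[c], c))
        refined.right_inner_bp = resumption
    if refined.refined or resumption is not None:
        if call.orientation == "+":
            refined.lb_adjacent_coordinate = refined.left_inner_bp
        else:
            refined.lb_adjacent_coordinate = (
                resumption if resumption is not None
                else refined.right_inner_bp)
    return refined, resumption


def host_depth(host_len: int, alignments: Iterable[tuple[Alignment, int]]
               ) -> np.ndarray:
    """Per-base depth from full-length host alignments (aln, read_len)."""
    depth = np.zeros(host_len + 1, dtype=np.int32)
    for aln, read_len in alignments:
        lo = max(aln.pos, 0)
        hi = min(aln.pos + read_len, host_len)
        depth[lo] += 1
        depth[hi] -= 1
    return np.cumsum(depth[:-1])


def detect_local_deletion(depth: np.ndarray, call: InsertionCall,
                          insert_size_mean: float, insert_size_sd: float,
                          host_pairs: Sequence[tuple[int, int]] = (),
                          junction_bounds: Optional[tuple[int, int]] = None,
                          min_gap_bp: int = 200, depth_ratio: float = 0.2,
                          search_window: int = 20000, read_length: int = 100
                          ) -> list[LocalSVCall]:
    """Insertion-adjacent deletions from coverage gaps and pair spacing.

    A window of at least ``min_gap_bp`` adjacent to the insertion with
    normalized depth below ``depth_ratio`` times the flank median is a
    homozygous deletion candidate; host-host pairs whose implied span
    exceeds mean + 3 sd corroborate it.  Junction-read bounds, when given as
    (last retained base left, first retained base right), override the
    depth-derived bounds exactly.  Flank coverage below 5x yields an
    "undetermined" call.
    """
    centre = call.lb_adjacent_coordinate
    lo = max(0, centre - search_window)
    hi = min(depth.size, centre + search_window)
    flank = np.concatenate([depth[lo:max(lo, centre - 2000)],
                            depth[min(hi, centre + 2000):hi]])
    flank_median = float(np.median(flank)) if flank.size else 0.0
    if flank_median < 5:
        return [LocalSVCall(call.chromosome, centre, centre,
                            status="undetermined")]

    if junction_bounds is not None:
        left_last, right_first = junction_bounds
        if right_first - left_last <= 1:
            return []
        return [LocalSVCall(call.chromosome, left_last + 1, right_first - 1,
                            evidence={"junction_read"})]

    low = depth[lo:hi] < depth_ratio * flank_median
    calls: list[LocalSVCall] = []
    i = 0
    while i < low.size:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < low.size and low[j]:
            j += 1
        start_bp, end_bp = lo + i + 1, lo + j  # 1-based inclusive
        run_len = end_bp - start_bp + 1
        near = min(abs(start_bp - centre), abs(end_bp - centre))
        if run_len >= min_gap_bp and (near <= insert_size_mean
                                      or start_bp <= centre <= end_bp):
            # refine to the longest zero-depth run inside the candidate: a
            # homozygous deletion is strictly uncovered, and its zero run
            # overshoots each true edge by only ~read_length/coverage bases
            seg = depth[start_bp - 1:end_bp]
            zs = ze = best_len = 0
            cur = -1
            for k, v in enumerate(seg):
                if v == 0:
                    if cur < 0:
                        cur = k
                    if k - cur + 1 > best_len:
                        best_len, zs, ze = k - cur + 1, cur, k
                else:
                    cur = -1
            if best_len >= min_gap_bp // 2:
                start_bp, end_bp = start_bp + zs, start_bp - 1 + ze + 1
            else:
                # hemizygous or noisy gap: pull the threshold-run edges
                # back by their expected overshoot
                bias = int(round(read_length * depth_ratio)) - 1
                if end_bp - start_bp + 1 > 2 * bias:
                    start_bp += bias
                    end_bp -= bias
            ev = {"coverage_gap"}
            thr = insert_size_mean + 3 * insert_size_sd
            for p_start, p_end in host_pairs:
                if p_end - p_start + 1 > thr and p_start < start_bp \
                        and p_end > end_bp:
                    ev.add("pair_spacing")
                    break
            calls.append(LocalSVCall(call.chromosome, start_bp, end_bp,
                                     evidence=ev))
        i = j
    return calls


def count_spanning_pairs(pair_alignments: dict[str, dict[int,
                                                         Optional[Alignment]]],
                         read_lengths: dict[tuple[str, int], int],
                         element: tuple[int, int], insert_size_mean: float,
                         insert_size_sd: float) -> int:
    """Pairs spanning a construct element consistent with its excision.

    Both ends must align to the construct on opposite sides of the element
    (1-based interval); the outer span must exceed mean + 3 sd (incompatible
    with an intact construct at that insert size) while span minus element
    length stays within mean + 3 sd (exactly what excision of the element
    predicts).  An intact-only locus with a tight insert distribution
    yields 0.
    """
    e_start0, e_end0 = element[0] - 1, element[1] - 1
    e_len = element[1] - element[0] + 1
    thr = insert_size_mean + 3 * insert_size_sd
    n = 0
    for name, ends in pair_alignments.items():
        a1, a2 = ends.get(1), ends.get(2)
        if a1 is None or a2 is None:
            continue
        l1 = read_lengths.get((name, 1), 0)
        l2 = read_lengths.get((name, 2), 0)
        spans = sorted([(a1.pos, a1.pos + l1), (a2.pos, a2.pos + l2)])
        (ls, le), (rs, re) = spans
        if le - 1 <= e_start0 and rs > e_end0:
            outer = re - ls
            if outer > thr and outer - e_len <= thr:
                n += 1
    return n


# ---------------------------------------------------------------------------
# end-to-end convenience and SAM ingestion


@dataclass
class LocateResult:
    calls: list[InsertionCall]
    local_svs: list[LocalSVCall]
    resumption_bp: Optional[int]
    n_orphans: int
    n_construct_aligned: int


def locate_insertions(pairs: Sequence[tuple[str, str, str]], construct: str,
                      host: str, host_name: str,
                      insert_size_mean: float = 350.0,
                      insert_size_sd: float = 35.0,
                      min_support: int = 3, min_mapq: int = 20,
                      k: int = DEFAULT_K, refine: bool = True,
                      detect_deletion: bool = True) -> LocateResult:
    """Run the full insertion-mapping pipeline on raw read pairs.

    ``pairs`` holds (name, read1, read2) sequences.  Orphan extraction,
    host placement, clustering, junction refinement and local deletion
    detection are chained with shared indexes.
    """
    construct_idx = KmerIndex(construct, k)
    host_idx = KmerIndex(host, k)
    pair_alns: dict[str, dict[int, Optional[Alignment]]] = {}
    seqs: dict[tuple[str, int], str] = {}
    for name, r1, r2 in pairs:
        pair_alns[name] = {1: construct_idx.align(r1),
                           2: construct_idx.align(r2)}
        seqs[(name, 1)] = r1
        seqs[(name, 2)] = r2
    n_con = sum(1 for ends in pair_alns.values()
                for a in ends.values() if a is not None)
    orphans, _ = extract_orphans(pair_alns)

    placements: list[OrphanPlacement] = []
    host_full: list[tuple[Alignment, int]] = []
    host_ends: dict[str, dict[int, tuple[int, int]]] = {}
    host_alns: dict[tuple[str, int], Optional[Alignment]] = {}
    for name, r1, r2 in pairs:
        for end, seq in ((1, r1), (2, r2)):
            if pair_alns[name][end] is not None:
                continue
            aln = host_idx.align(seq)
            host_alns[(name, end)] = aln
            if aln is None:
                continue
            host_full.append((aln, len(seq)))
            host_ends.setdefault(name, {})[end] = (aln.pos + 1,
                                                   aln.pos + len(seq))
    for name, end in orphans:
        seq = seqs[(name, end)]
        mate = pair_alns[name][2 if end == 1 else 1]
        aln = host_alns.get((name, end))
        if aln is not None:
            pos, span, strand, mapq = aln.pos, len(seq), aln.strand, aln.mapq
        else:
            # junction-spanning orphan: place by its exact host anchor
            part = partial_host_placement(seq, host, host_idx)
            if part is None:
                continue
            pos, span, strand = part[0], part[1], part[2]
            mapq = 60
        placements.append(OrphanPlacement(
            read_name=name, end=end, host_pos=pos, strand=strand,
            mapq=mapq, read_len=span,
            mate_construct_pos=mate.pos, mate_construct_strand=mate.strand))

    calls = cluster_insertions(placements, insert_size_mean, host_name,
                               min_support=min_support, min_mapq=min_mapq)
    resumption = None
    local_svs: list[LocalSVCall] = []
    if calls:
        best = max(calls, key=lambda c: c.total_support)
        if refine:
            junction_candidates = [
                (key, v) for key, v in seqs.items()
                if pair_alns[key[0]][key[1]] is None
                and host_alns.get(key) is None]
            refined, resumption = refine_insertion(
                best, junction_candidates, host, construct, host_idx)
            calls = [refined if c is best else c for c in calls]
            best = refined
        if detect_deletion:
            depth = host_depth(len(host), host_full)
            host_pairs = [
                (min(ends[1][0], ends[2][0]), max(ends[1][1], ends[2][1]))
                for ends in host_ends.values() if set(ends) == {1, 2}]
            jb = None
            if resumption is not None and best.refined:
                jb = (best.left_inner_bp, resumption)
            local_svs = detect_local_deletion(
                depth, best, insert_size_mean, insert_size_sd,
                host_pairs=host_pairs, junction_bounds=jb)
    return LocateResult(calls, local_svs, resumption, len(orphans), n_con)


def pair_alignments_from_sam(sam_path: str
                             ) -> tuple[dict[str, dict[int,
                                                       Optional[Alignment]]],
                                        dict[tuple[str, int], int]]:
    """Ingest externally produced alignments (SAM) into the matcher's shape.

    Primary alignments only; an unmapped record maps to None.  Returns the
    per-pair alignment dict and the read lengths.
    """
    import pysam

    alns: dict[str, dict[int, Optional[Alignment]]] = {}
    lengths: dict[tuple[str, int], int] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            end = 2 if rec.is_read2 else 1
            name = rec.query_name
            lengths[(name, end)] = rec.query_length or \
                len(rec.query_sequence or "")
            if rec.is_unmapped:
                alns.setdefault(name, {})[end] = None
            else:
                alns.setdefault(name, {})[end] = Alignment(
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    identity=1.0, covered=1.0,
                    mapq=rec.mapping_quality)
    for ends in alns.values():
        ends.setdefault(1, None)
        ends.setdefault(2, None)
    return alns, lengths
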