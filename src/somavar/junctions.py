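"""Breakpoint junction resolution.

A junction sequence (from a Sanger product or the consensus of
junction-spanning reads) is decomposed against the two reference flanks it
joins.  The decomposition yields the exact breakpoint coordinates, the event
size, the per-side microhomology lengths, and any filler sequence (junction
bases matching neither flank continuation), the signatures used to recognise
microhomology-mediated end joining.

Conventions
-----------
``left_flank_ref`` is reference sequence read in junction orientation whose
first base sits at 1-based genomic coordinate ``left_anchor``; it must extend
*past* the candidate breakpoint (i.e. include deleted bases).
``right_flank_ref`` ends at 1-based coordinate ``right_anchor`` and extends
*before* the breakpoint.  Matching is exact (no mismatches): junctions here
come from Sanger products or read consensus, and homology is treated as exact
sequence identity.

When the maximal prefix and suffix matches overlap inside the junction the
breakpoint is ambiguous within a single homology window; that window is the
microhomology tract shared by both breakpoint ends, and breakpoints are
reported left-aligned (leftmost consistent position).  When filler separates
the two matched blocks, the per-side homologies are independent: the left
block's end is compared against the reference immediately upstream of the
right breakpoint, and the right block's start against the reference
continuation past the left breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

MIN_FLANK_MATCH = 15  # bp of exact flank match required on each side
DEFAULT_K_MAX = 25    # largest microhomology length searched


@dataclass
class JunctionObservation:
    """One junction sequence plus its two anchored reference flanks."""

    junction_sequence: str
    left_flank_ref: str
    right_flank_ref: str
    left_anchor: int   # 1-based genomic coordinate of left_flank_ref[0]
    right_anchor: int  # 1-based genomic coordinate of right_flank_ref[-1]
    event_type: str = "deletion"  # deletion | duplication | insertion_junction
    chromosome: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.left_flank_ref or not self.right_flank_ref:
            raise ValueError("flank references must be non-empty")
        if len(self.junction_sequence) < 20:
            raise ValueError("junction sequence must be at least 20 bp")
        if self.event_type not in ("deletion", "duplication", "insertion_junction"):
            raise ValueError(f"unknown event_type {self.event_type!r}")


@dataclass
class JunctionResolution:
    """A resolved breakpoint."""

    breakpoint_left: int   # 1-based last retained base of the left flank
    breakpoint_right: int  # 1-based first retained base of the right flank
    event_size_bp: Optional[int]
    mh_left_bp: int
    mh_right_bp: int
    filler_sequence: str
    # [start, end] 1-based window within which the left breakpoint may slide
    # without changing the event; collapses to a point when unambiguous.
    mh_window: tuple[int, int] = field(default=(0, 0))
    status: str = "resolved"  # resolved | unresolved | no_event


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def microhomology_length(seq_a_end: str, seq_b_ref_upstream: str,
                         k_max: int = DEFAULT_K_MAX) -> int:
    """Largest k <= k_max with the last k bases of both sequences identical.

    ``seq_a_end`` is the sequence ending at a junction point; the comparison
    against ``seq_b_ref_upstream`` (reference ending just upstream of the
    partner breakpoint) measures how far the junction point could slide.
    """
    if len(seq_a_end) < k_max or len(seq_b_ref_upstream) < k_max:
        raise ValueError("both sequences must be at least k_max long")
    return min(_common_suffix(seq_a_end, seq_b_ref_upstream), k_max)


def resolve_junction(obs: JunctionObservation,
                     k_max: int = DEFAULT_K_MAX) -> JunctionResolution:
    """Decompose a junction sequence into breakpoints, microhomology, filler.

    Finds the maximal exact prefix match of the junction against the left
    flank and the maximal exact suffix match against the right flank.  The
    bases between the matched blocks are filler; overlapping blocks define
    the microhomology window and the breakpoint is reported at its leftmost
    consistent position.
    """
    j = obs.junction_sequence
    n = len(j)
    p = _common_prefix(j, obs.left_flank_ref)
    s = _common_suffix(j, obs.right_flank_ref)
    if p < MIN_FLANK_MATCH or s < MIN_FLANK_MATCH:
        return JunctionResolution(0, 0, None, 0, 0, "", (0, 0), "unresolved")

    lref, rref = obs.left_flank_ref, obs.right_flank_ref
    if p + s >= n:
        # Ambiguous breakpoint: matched blocks overlap by w bases.  The
        # window sequence is present in the reference on both sides of the
        # junction, i.e. homology "on either end" of the breakpoint.
        w = p + s - n
        left_len = n - s          # leftmost consistent position
        filler = ""
        mh_left = mh_right = w
    else:
        left_len = p
        filler = j[p:n - s]
        # Independent per-side homology relative to the (unambiguous)
        # breakpoints: end of the left block vs reference immediately
        # upstream of the right breakpoint, and start of the right block vs
        # the reference continuation past the left breakpoint.
        w = 0
        mh_right = min(_common_suffix(j[:p], rref[:len(rref) - s]), k_max)
        mh_left = min(_common_prefix(j[n - s:], lref[p:]), k_max)

    breakpoint_left = obs.left_anchor + left_len - 1
    breakpoint_right = obs.right_anchor - s + 1
    res = JunctionResolution(
        breakpoint_left=breakpoint_left,
        breakpoint_right=breakpoint_right,
        event_size_bp=None,
        mh_left_bp=mh_left,
        mh_right_bp=mh_right,
        filler_sequence=filler,
        mh_window=(breakpoint_left, breakpoint_left + w),
        status="resolved",
    )
    if obs.event_type in ("deletion", "duplication"):
        res.event_size_bp = size_from_breakpoints(res, obs.event_type)
        if res.event_size_bp == 0:
            res.status = "no_event"
    return res


def size_from_breakpoints(resolution: JunctionResolution,
                          event_type: str = "deletion") -> int:
    """Event size implied by the two breakpoint coordinates.

    Deletion size is the number of reference bases absent between the
    retained flanks; duplication size is the length of the duplicated span
    (right anchor upstream of left anchor in a tandem-duplication junction).
    """
    bl, br = resolution.breakpoint_left, resolution.breakpoint_right
    if event_type == "deletion":
        size = br - bl - 1
        if size < 0:
            raise ValueError(
                f"inconsistent anchors for deletion: left={bl} right={br}")
        return size
    if event_type == "duplication":
        size = bl - br + 1
        if size <= 0:
            raise ValueError(
                f"inconsistent anchors for duplication: left={bl} right={br}")
        return size
    raise ValueError(f"no size defined for event_type {event_type!r}")
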