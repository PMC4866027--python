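"""Synthetic breakpoint junctions with planted microhomology and filler.

Flank references are i.i.d. uniform DNA; microhomology and filler are then
imposed by local edits, with explicit mismatch guards at every block
boundary so the planted decomposition is the unique maximal one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .._util import BASES, other_base, random_dna, stream_rng
from ..junctions import JunctionObservation


def _base_not(rng, *exclude: str) -> str:
    choices = [b for b in BASES if b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


@dataclass
class JunctionTruth:
    mh_left_bp: int
    mh_right_bp: int
    filler_sequence: str
    breakpoint_left: int
    breakpoint_right: int
    event_size_bp: int


def simulate_junction(mh_left_bp: int, mh_right_bp: int, filler: str,
                      flank_len: int = 60, seed: int = 0,
                      deleted_bp: int = 500, left_anchor: int = 1001,
                      ) -> tuple[JunctionObservation, JunctionTruth]:
    """Build a deletion junction whose resolution returns the planted values.

    Without filler the junction carries a single homology tract shared by
    both breakpoint ends, so ``mh_left_bp == mh_right_bp`` is required; with
    filler, per-side homologies are independent and any combination may be
    planted.
    """
    if mh_left_bp < 0 or mh_right_bp < 0:
        raise ValueError("microhomology lengths must be >= 0")
    if flank_len // 2 <= max(mh_left_bp, mh_right_bp) + len(filler) + 1:
        raise ValueError("flank_len must exceed 2*(mh + filler length + 1)")
    if not filler and mh_left_bp != mh_right_bp:
        raise ValueError(
            "without filler the junction has one shared homology tract; "
            "mh_left_bp and mh_right_bp must be equal")
    if any(c not in "ACGT" for c in filler):
        raise ValueError("filler must be over {A,C,G,T}")

    rng = stream_rng(seed, "junction", mh_left_bp, mh_right_bp, filler)
    block = flank_len // 2  # retained bases on each side of the junction
    left = list(random_dna(rng, flank_len))
    right = list(random_dna(rng, flank_len))
    a = left[:block]          # retained left block
    b = right[-block:]        # retained right block

    if filler:
        # plant mh_right: reference upstream of the right breakpoint ends
        # with the same bases as the retained left block
        if mh_right_bp:
            right[-block - mh_right_bp:-block] = a[-mh_right_bp:]
        right[-block - mh_right_bp - 1] = other_base(
            rng, a[-mh_right_bp - 1])
        # plant mh_left: deleted continuation past the left breakpoint
        # begins with the same bases as the retained right block
        if mh_left_bp:
            left[block:block + mh_left_bp] = b[:mh_left_bp]
        left[block + mh_left_bp] = other_base(rng, b[mh_left_bp])
        # filler must match neither continuation; edits to the retained
        # blocks are written back into the flank references they came from
        if filler[0] == left[block]:
            if mh_left_bp:
                b[0] = other_base(rng, filler[0])
                right[-block] = b[0]
                left[block:block + mh_left_bp] = b[:mh_left_bp]
                left[block + mh_left_bp] = other_base(rng, b[mh_left_bp])
            else:
                # stay distinct from b[0] too, so measured mh_left stays 0
                left[block] = _base_not(rng, filler[0], b[0])
        if filler[-1] == right[-block - 1]:
            if mh_right_bp:
                a[-1] = other_base(rng, filler[-1])
                left[block - 1] = a[-1]
                right[-block - mh_right_bp:-block] = a[-mh_right_bp:]
                right[-block - mh_right_bp - 1] = other_base(
                    rng, a[-mh_right_bp - 1])
            else:
                right[-block - 1] = _base_not(rng, filler[-1], a[-1])
    else:
        # single shared tract: deleted continuation past the left breakpoint
        # repeats the first mh bases of the retained right block
        m = mh_left_bp
        if m:
            left[block:block + m] = b[:m]
        left[block + m] = other_base(rng, b[m])
        right[-block - 1] = other_base(rng, a[-1])

    junction = "".join(a) + filler + "".join(b)
    breakpoint_left = left_anchor + block - 1
    breakpoint_right = breakpoint_left + deleted_bp + 1
    right_anchor = breakpoint_right + block - 1
    obs = JunctionObservation(
        junction_sequence=junction,
        left_flank_ref="".join(left),
        right_flank_ref="".join(right),
        left_anchor=left_anchor,
        right_anchor=right_anchor,
        event_type="deletion",
    )
    truth = JunctionTruth(mh_left_bp, mh_right_bp, filler,
                          breakpoint_left, breakpoint_right, deleted_bp)
    return obs, truth
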