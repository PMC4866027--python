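"""Small shared helpers: DNA strings and reproducible per-stream RNGs."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def other_base(rng: np.random.Generator, base: str) -> str:
    """A uniformly chosen base different from ``base``."""
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(0, len(choices)))]


def stream_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic generator for a named substream of a run seed.

    Labels (sample ids, chromosome names, stage names) are hashed with CRC32
    so the stream depends only on the run seed and the labels, never on
    iteration order.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        keys.append(zlib.crc32(str(lab).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(keys)
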