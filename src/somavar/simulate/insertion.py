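"""Synthetic T-DNA insertion loci sampled as paired-end reads.

The post-insertion (variant) allele is the host sequence with an adjacent
deletion, the construct (left border to right border) inserted at the
insertion site in the stated orientation, and filler bases at the
construct-host junction.  Microhomology is imposed by local edits: the
construct's left-border start repeats the retained host bases at the
insertion point, and the deleted host tail repeats the construct's
right-border end.  Error-free 100 bp read pairs are drawn uniformly from
the variant allele (homozygous case) or 50:50 from variant and reference
alleles (hemizygous), with Gaussian insert sizes truncated above twice the
read length.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._util import other_base, random_dna, revcomp, stream_rng


@dataclass
class InsertionTruth:
    host_sequence_length_bp: int = 60_000
    insertion_site: int = 30_000      # 1-based host base adjacent to LB ("+")
    orientation: str = "+"
    construct_length_bp: int = 4_000
    adjacent_deletion_bp: int = 1_500
    filler_sequence: str = "ACGTAC"   # 6 bp, as at a characterized locus
    mh_left_bp: int = 3
    mh_right_bp: int = 3
    read_length: int = 100
    insert_size_mean: float = 350.0
    insert_size_sd: float = 35.0
    coverage_depth: float = 30.0
    zygosity: str = "homozygous"      # homozygous | hemizygous
    seed: int = 0
    host_name: str = "Gm13"

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")
        if self.insertion_site + self.adjacent_deletion_bp > \
                self.host_sequence_length_bp:
            raise ValueError("insertion site + deletion exceeds host length")
        if self.construct_length_bp < self.read_length:
            raise ValueError("construct shorter than read length")
        if self.coverage_depth <= 0:
            raise ValueError("coverage_depth must be positive")
        if self.zygosity not in ("homozygous", "hemizygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.adjacent_deletion_bp < 0 or self.mh_left_bp < 0 \
                or self.mh_right_bp < 0:
            raise ValueError("lengths must be >= 0")

    @property
    def lb_adjacent_coordinate(self) -> int:
        """Host base adjacent to the construct's left border."""
        if self.orientation == "+":
            return self.insertion_site
        return self.insertion_site + self.adjacent_deletion_bp + 1


# element layout imposed on the synthetic construct, as fractions of its
# length: a transposon pair, a transposase and a selectable marker
_ELEMENT_LAYOUT = (("Pong", 0.05, 0.30), ("mPing", 0.32, 0.45),
                   ("Tpase", 0.50, 0.70), ("BAR", 0.75, 0.90))


@dataclass
class InsertionData:
    truth: InsertionTruth
    host_seq: str
    construct_seq: str
    variant_allele: str
    pairs: list[tuple[str, str, str]]  # (name, read1, read2)
    elements: list[tuple[str, int, int]]  # 1-based inclusive on construct
    manifest: pd.DataFrame = field(repr=False, default=None)


def _variant_allele(truth: InsertionTruth, host: str, construct: str) -> str:
    site, dele = truth.insertion_site, truth.adjacent_deletion_bp
    ins = construct if truth.orientation == "+" else revcomp(construct)
    return host[:site] + ins + truth.filler_sequence + host[site + dele:]


def _draw_pairs(rng: np.random.Generator, allele: str, n_pairs: int,
                truth: InsertionTruth, name_prefix: str
                ) -> list[tuple[str, str, str]]:
    rl = truth.read_length
    pairs = []
    for i in range(n_pairs):
        frag = 0
        while frag <= 2 * rl or frag > len(allele):
            frag = int(round(rng.normal(truth.insert_size_mean,
                                        truth.insert_size_sd)))
        start = int(rng.integers(0, len(allele) - frag + 1))
        r1 = allele[start:start + rl]
        r2 = revcomp(allele[start + frag - rl:start + frag])
        pairs.append((f"{name_prefix}{i:06d}", r1, r2))
    return pairs


def simulate_insertion_reads(truth: InsertionTruth,
                             out_dir: str | None = None) -> InsertionData:
    """Generate host/construct FASTA, paired FASTQ and the truth manifest."""
    rng = stream_rng(truth.seed, "insertion")
    host = list(random_dna(rng, truth.host_sequence_length_bp))
    construct = list(random_dna(rng, truth.construct_length_bp))

    site, dele = truth.insertion_site, truth.adjacent_deletion_bp
    # left-border microhomology: the construct begins with a copy of the
    # retained host bases at the insertion point
    if truth.mh_left_bp:
        construct[:truth.mh_left_bp] = host[site - truth.mh_left_bp:site]
    # right-side microhomology: the deleted host tail ends like the
    # construct's right border (only visible to junction resolution)
    if truth.mh_right_bp and dele >= truth.mh_right_bp:
        host[site + dele - truth.mh_right_bp:site + dele] = \
            construct[-truth.mh_right_bp:]
    # Accidental-ambiguity guards: the breakpoint read out of junction-
    # spanning reads is only well defined when the reference continuation
    # differs from the inserted sequence at each junction.  The first
    # deleted base must differ from the first inserted base, and the last
    # deleted base from the base preceding the host resumption (filler end,
    # or the inserted block's end when there is no filler).  A planted
    # right-side homology with no filler leaves the resumption coordinate
    # genuinely ambiguous within the homology tract and is not guarded.
    ins = construct if truth.orientation == "+" else \
        list(revcomp("".join(construct)))
    if dele > truth.mh_right_bp and host[site] == ins[0]:
        host[site] = other_base(rng, ins[0])
    if dele > 0:
        last_before_res = truth.filler_sequence[-1] \
            if truth.filler_sequence else ins[-1]
        if truth.filler_sequence or truth.mh_right_bp == 0:
            if host[site + dele - 1] == last_before_res:
                host[site + dele - 1] = other_base(rng, last_before_res)
    host = "".join(host)
    construct = "".join(construct)

    allele = _variant_allele(truth, host, construct)
    n_pairs = int(round(truth.coverage_depth * len(allele)
                        / (2 * truth.read_length)))
    if truth.zygosity == "homozygous":
        pairs = _draw_pairs(rng, allele, n_pairs, truth, "var")
    else:
        half = n_pairs // 2
        pairs = _draw_pairs(rng, allele, half, truth, "var") + \
            _draw_pairs(rng, host, n_pairs - half, truth, "ref")

    scale = truth.construct_length_bp
    elements = [(name, int(a * scale) + 1, int(b * scale))
                for name, a, b in _ELEMENT_LAYOUT]
    manifest = pd.DataFrame([{
        "chromosome": truth.host_name,
        "insertion_site": truth.insertion_site,
        "lb_adjacent_coordinate": truth.lb_adjacent_coordinate,
        "orientation": truth.orientation,
        "adjacent_deletion_bp": truth.adjacent_deletion_bp,
        "filler_sequence": truth.filler_sequence,
        "mh_left_bp": truth.mh_left_bp,
        "mh_right_bp": truth.mh_right_bp,
        "zygosity": truth.zygosity,
        "n_pairs": len(pairs),
    }])
    data = InsertionData(truth, host, construct, allele, pairs, elements,
                         manifest)
    if out_dir is not None:
        _write_insertion_files(data, out_dir)
    return data


def _write_fasta(path: str, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def _write_insertion_files(data: InsertionData, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    truth = data.truth
    _write_fasta(os.path.join(out_dir, "host.fa"), truth.host_name,
                 data.host_seq)
    _write_fasta(os.path.join(out_dir, "construct.fa"), "construct",
                 data.construct_seq)
    qual = "I" * truth.read_length
    with open(os.path.join(out_dir, "reads_1.fastq"), "w") as f1, \
            open(os.path.join(out_dir, "reads_2.fastq"), "w") as f2:
        for name, r1, r2 in data.pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{qual[:len(r1)]}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{qual[:len(r2)]}\n")
    data.manifest.to_csv(os.path.join(out_dir, "truth_manifest.tsv"),
                         sep="\t", index=False)
    pd.DataFrame(data.elements, columns=["name", "start", "end"]).to_csv(
        os.path.join(out_dir, "construct_elements.tsv"), sep="\t",
        index=False)


def simulate_construct_mixture_pairs(construct: str,
                                     element: tuple[int, int],
                                     excised_fraction: float = 0.5,
                                     coverage: float = 30.0,
                                     read_length: int = 100,
                                     insert_size_mean: float = 350.0,
                                     insert_size_sd: float = 35.0,
                                     seed: int = 0
                                     ) -> list[tuple[str, str, str]]:
    """Read pairs from a mixture of intact and element-excised construct
    copies, emulating a locus where one homologous chromosome carries a
    transgene whose internal element has excised."""
    if not 0 <= excised_fraction <= 1:
        raise ValueError("excised_fraction must be in [0, 1]")
    rng = stream_rng(seed, "mixture")
    start, end = element
    excised = construct[:start - 1] + construct[end:]
    truth = InsertionTruth(
        host_sequence_length_bp=len(construct) * 2,
        insertion_site=len(construct), construct_length_bp=len(construct),
        adjacent_deletion_bp=0, filler_sequence="", mh_left_bp=0,
        mh_right_bp=0, read_length=read_length,
        insert_size_mean=insert_size_mean, insert_size_sd=insert_size_sd,
        coverage_depth=coverage, seed=seed)
    n_pairs = int(round(coverage * len(construct) / (2 * read_length)))
    n_exc = int(round(excised_fraction * n_pairs))
    pairs = _draw_pairs(rng, construct, n_pairs - n_exc, truth, "intact")
    if n_exc and len(excised) > 2 * read_length:
        pairs += _draw_pairs(rng, excised, n_exc, truth, "excised")
    return pairs
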