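"""Private homozygous substitution filtering from multi-sample genotype calls.

A de novo single-base mutation in one plant of a jointly genotyped cohort
appears as a site that is homozygous for the alternate base in exactly one
individual and confidently homozygous reference in every other.  The filter
keeps exactly those sites: every sample covered by at least ``min_depth``
reads, no heterozygous or missing calls, not monomorphic, and at most one
homozygous-alternate carrier.  Region exclusions subtract stretches known to
be heterogeneous in the background cultivar rather than induced (e.g. a
13 Mb stretch of one chromosome segregating in the mutagenesis parent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

HOM_REF, HET, MISSING, HOM_ALT = 0, 1, 2, 3
_CLASS_NAMES = {HOM_REF: "hom_ref", HET: "het", MISSING: "missing",
                HOM_ALT: "hom_alt"}
_TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass
class SiteGenotypes:
    """One biallelic SNV site's per-sample genotype class and read depth."""

    chromosome: str
    position: int  # 1-based
    ref_base: str
    alt_base: str
    genotype_classes: np.ndarray  # int codes, one per sample
    depths: np.ndarray            # reads, one per sample

    def __post_init__(self) -> None:
        self.genotype_classes = np.asarray(self.genotype_classes,
                                           dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        if self.genotype_classes.size != self.depths.size:
            raise ValueError("genotype/depth length mismatch")
        if self.ref_base not in "ACGT":
            raise ValueError(f"bad ref base {self.ref_base!r}")
        if np.any(self.depths < 0):
            raise ValueError("negative depth")


@dataclass
class FilterCriteria:
    min_depth: int = 5        # reads per sample at the site
    max_alt_carriers: int = 1
    require_homozygous: bool = True
    # (chromosome, start_bp, end_bp, sample_id or None for all samples)
    exclusion_regions: list[tuple] = field(default_factory=list)
    # "site": any under-covered sample drops the site (conservative reading
    # of a site-level filter); "carrier": only the carrier's depth counts
    depth_scope: str = "site"

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.max_alt_carriers < 1:
            raise ValueError("min_depth and max_alt_carriers must be >= 1")
        if self.depth_scope not in ("site", "carrier"):
            raise ValueError(f"unknown depth_scope {self.depth_scope!r}")


@dataclass
class PrivateSubstitution:
    sample_id: str
    chromosome: str
    position: int
    ref_base: str
    alt_base: str

    @property
    def is_transition(self) -> bool:
        return {self.ref_base, self.alt_base} in _TRANSITIONS


@dataclass
class FilterStats:
    n_sites_in: int = 0
    n_failed_depth: int = 0
    n_monomorphic: int = 0
    n_het_or_missing: int = 0
    n_multi_carrier: int = 0
    n_kept: int = 0
    n_skipped_non_snv: int = 0


def apply_site_filters(sites: Iterable[SiteGenotypes], sample_ids:
                       Sequence[str], criteria: FilterCriteria
                       ) -> tuple[list[PrivateSubstitution], FilterStats]:
    """Extract substitutions private to one individual.

    A site yields exactly one PrivateSubstitution iff every sample's depth
    meets ``min_depth`` (site scope), no sample is heterozygous or missing,
    and exactly one sample is homozygous-alternate with all others
    homozygous-reference.  Order of the clauses matches a hierarchy of
    confidence: coverage first, call quality second, privacy last.
    """
    if len(sample_ids) == 0:
        raise ValueError("zero samples")
    stats = FilterStats()
    subs: list[PrivateSubstitution] = []
    for site in sites:
        if site.genotype_classes.size != len(sample_ids):
            raise ValueError(
                f"{site.chromosome}:{site.position}: sample count differs "
                "from the cohort")
        stats.n_sites_in += 1
        gts = site.genotype_classes
        alt_mask = gts == HOM_ALT
        if criteria.depth_scope == "site":
            depth_ok = bool(np.all(site.depths >= criteria.min_depth))
        else:
            depth_ok = bool(np.all(site.depths[alt_mask]
                                   >= criteria.min_depth)) \
                and bool(alt_mask.any())
        if not depth_ok:
            stats.n_failed_depth += 1
            continue
        if np.any((gts == HET) | (gts == MISSING)):
            stats.n_het_or_missing += 1
            continue
        n_alt = int(alt_mask.sum())
        if n_alt == 0:
            stats.n_monomorphic += 1
            continue
        if n_alt > criteria.max_alt_carriers or n_alt == len(sample_ids):
            # shared alternate calls, or monomorphic for a non-reference
            # base: neither can be private to one plant
            stats.n_multi_carrier += 1
            continue
        carrier = sample_ids[int(np.flatnonzero(alt_mask)[0])]
        subs.append(PrivateSubstitution(
            sample_id=carrier, chromosome=site.chromosome,
            position=site.position, ref_base=site.ref_base,
            alt_base=site.alt_base))
        stats.n_kept += 1
    return subs, stats


def apply_region_exclusion(subs: Sequence[PrivateSubstitution],
                           regions: Sequence[tuple]
                           ) -> tuple[list[PrivateSubstitution], int]:
    """Drop substitutions inside exclusion regions (1-based inclusive).

    A region is (chromosome, start_bp, end_bp) or
    (chromosome, start_bp, end_bp, sample_id) to restrict the exclusion to
    one individual.  Returns the surviving list and the number removed.
    """
    kept: list[PrivateSubstitution] = []
    removed = 0
    for sub in subs:
        hit = False
        for region in regions:
            chrom, start, end = region[:3]
            sample = region[3] if len(region) > 3 else None
            if sub.chromosome == chrom and start <= sub.position <= end \
                    and (sample is None or sub.sample_id == sample):
                hit = True
                break
        if hit:
            removed += 1
        else:
            kept.append(sub)
    return kept, removed


def per_sample_counts(subs: Sequence[PrivateSubstitution],
                      sample_ids: Sequence[str]) -> pd.DataFrame:
    """Counts per sample; cohort members without substitutions appear as 0."""
    counts = {s: 0 for s in sample_ids}
    for sub in subs:
        counts[sub.sample_id] = counts.get(sub.sample_id, 0) + 1
    return pd.DataFrame({"sample_id": list(counts),
                         "n_private": list(counts.values())})


def titv_ratio(subs: Sequence[PrivateSubstitution]) -> Optional[float]:
    """Transition/transversion ratio; None when transversions are zero."""
    ti = sum(1 for s in subs if s.is_transition)
    tv = len(subs) - ti
    return ti / tv if tv else None


# ---------------------------------------------------------------------------
# VCF input


def read_vcf_sites(path: str) -> tuple[list[SiteGenotypes], list[str],
                                       FilterStats]:
    """Biallelic SNV sites from a multi-sample VCF.

    Genotype classes come from GT; depth from FORMAT/DP, falling back to the
    AD sum; a sample with no usable depth gets 0 and so fails the depth
    rule.  Indels and multiallelic records are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    sites: list[SiteGenotypes] = []
    stats = FilterStats()
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1 \
                or var.ALT[0] not in "ACGT" or var.REF not in "ACGT":
            stats.n_skipped_non_snv += 1
            continue
        gts = np.asarray(var.gt_types, dtype=np.int8)
        # cyvcf2 gts012: 0=hom_ref 1=het 2=hom_alt 3=unknown
        classes = np.select([gts == 0, gts == 1, gts == 2],
                            [HOM_REF, HET, HOM_ALT], default=MISSING)
        depth = None
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            depth = dp.reshape(-1).astype(np.int64)
        else:
            try:
                ad = var.format("AD")
            except KeyError:
                ad = None
            if ad is not None:
                depth = ad.astype(np.int64).clip(min=0).sum(axis=1)
        if depth is None:
            depth = np.zeros(len(samples), dtype=np.int64)
        depth = np.clip(depth, 0, None)
        sites.append(SiteGenotypes(var.CHROM, var.POS, var.REF, var.ALT[0],
                                   classes.astype(np.int8), depth))
    return sites, samples, stats


def read_exclusion_bed(path: str) -> list[tuple]:
    """Exclusion regions from BED (0-based half-open -> 1-based inclusive).

    An optional 4th column restricts the exclusion to one sample id.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    regions = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]) + 1, int(row[2])
        sample = str(row[3]) if len(row) > 3 and not pd.isna(row[3]) else None
        regions.append((chrom, start, end, sample))
    return regions


def subs_to_vcf(subs: Sequence[PrivateSubstitution], sample_ids:
                Sequence[str], path: str) -> None:
    """Minimal single-sample-per-record VCF of the private substitutions."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,'
                 'Description="Carrier of the private substitution">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(subs, key=lambda s: (s.chromosome, s.position)):
            fh.write(f"{s.chromosome}\t{s.position}\t.\t{s.ref_base}\t"
                     f"{s.alt_base}\t.\tPASS\tSAMPLE={s.sample_id}\n")
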