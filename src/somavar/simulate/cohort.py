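"""Synthetic multi-sample genotype cohorts with planted private substitutions.

Emulates the jointly genotyped call set the substitution filter consumes:
each planted private site is homozygous-alternate in exactly one sample and
confidently homozygous-reference elsewhere; distractor sites realize the
patterns the filter must reject (shared alternate calls, heterozygous calls,
missing calls, under-covered would-be privates, monomorphic background).

Depths are Poisson around ``depth_mean``.  When ``depth_mean`` is at least
the usable minimum of 5 reads, planted private sites are clamped to >= 5 in
every sample so the planted truth is recoverable; a ``depth_mean`` below 5
emulates a uniformly under-covered run (all depths capped at 4), in which
every site fails the depth rule downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._util import BASES, stream_rng
from ..substitutions import HET, HOM_ALT, HOM_REF, MISSING, SiteGenotypes

_USABLE_DEPTH = 5


@dataclass
class CohortTruth:
    n_samples: int
    n_sites: int
    private_counts: tuple[int, ...]  # one per sample
    shared_poly_fraction: float = 0.1
    het_fraction: float = 0.1
    missing_fraction: float = 0.05
    depth_mean: float = 20.0
    seed: int = 0
    lowdepth_private_fraction: float = 0.05

    def __post_init__(self) -> None:
        if len(self.private_counts) != self.n_samples:
            raise ValueError("private_counts must have one entry per sample")
        if sum(self.private_counts) > self.n_sites:
            raise ValueError("sum of private_counts exceeds n_sites")
        for f in (self.shared_poly_fraction, self.het_fraction,
                  self.missing_fraction, self.lowdepth_private_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_samples < 2 and self.shared_poly_fraction > 0:
            raise ValueError(
                "shared polymorphisms need at least 2 samples")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class CohortData:
    sites: list[SiteGenotypes]
    sample_ids: list[str]
    manifest: pd.DataFrame  # planted private sites


def simulate_cohort(truth: CohortTruth, chromosome: str = "Gm01"
                    ) -> CohortData:
    """Generate the cohort in memory; see module docstring for semantics."""
    rng = stream_rng(truth.seed, "cohort")
    n, m = truth.n_sites, truth.n_samples
    positions = np.sort(rng.choice(np.arange(1, n * 50), size=n,
                                   replace=False))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    refs = np.array(list(BASES))[ref_idx]
    alts = np.array(list(BASES))[alt_idx]

    # site category assignment
    CAT_BG, CAT_PRIV, CAT_SHARED, CAT_HET, CAT_MISS, CAT_LOWDEPTH = range(6)
    cats = np.full(n, CAT_BG, dtype=np.int8)
    order = rng.permutation(n)
    k = 0
    owner = np.full(n, -1, dtype=np.int64)
    for si, cnt in enumerate(truth.private_counts):
        for _ in range(cnt):
            cats[order[k]] = CAT_PRIV
            owner[order[k]] = si
            k += 1
    n_rest = n - k
    for cat, frac in ((CAT_SHARED, truth.shared_poly_fraction),
                      (CAT_HET, truth.het_fraction),
                      (CAT_MISS, truth.missing_fraction),
                      (CAT_LOWDEPTH, truth.lowdepth_private_fraction)):
        cnt = int(round(frac * n_rest))
        cats[order[k:k + cnt]] = cat
        if cat == CAT_LOWDEPTH:
            owner[order[k:k + cnt]] = rng.integers(0, m, size=cnt)
        k += cnt
        if k > n:
            raise ValueError("distractor fractions exceed available sites")

    gts = np.full((n, m), HOM_REF, dtype=np.int8)
    depths = rng.poisson(truth.depth_mean, size=(n, m)).astype(np.int32)
    shallow_run = truth.depth_mean < _USABLE_DEPTH
    if shallow_run:
        np.clip(depths, 0, _USABLE_DEPTH - 1, out=depths)

    rows = []
    for i in range(n):
        cat = cats[i]
        if cat == CAT_PRIV:
            gts[i, owner[i]] = HOM_ALT
            if not shallow_run:
                np.clip(depths[i], _USABLE_DEPTH, None, out=depths[i])
            rows.append((truth.sample_ids[owner[i]], chromosome,
                         int(positions[i]), refs[i], alts[i]))
        elif cat == CAT_SHARED:
            carriers = rng.choice(m, size=int(rng.integers(2, m + 1)),
                                  replace=False)
            gts[i, carriers] = HOM_ALT
        elif cat == CAT_HET:
            gts[i, rng.integers(0, m)] = HET
        elif cat == CAT_MISS:
            gts[i, rng.integers(0, m)] = MISSING
        elif cat == CAT_LOWDEPTH:
            # a would-be private call spoiled by one under-covered sample
            gts[i, owner[i]] = HOM_ALT
            if not shallow_run:
                np.clip(depths[i], _USABLE_DEPTH, None, out=depths[i])
                others = [j for j in range(m) if j != owner[i]]
                spoiled = others[int(rng.integers(0, len(others)))] \
                    if others else owner[i]
                depths[i, spoiled] = int(rng.integers(0, _USABLE_DEPTH))

    sites = [SiteGenotypes(chromosome, int(positions[i]), refs[i], alts[i],
                           gts[i], depths[i]) for i in range(n)]
    manifest = pd.DataFrame(rows, columns=["sample_id", "chromosome",
                                           "position", "ref", "alt"])
    if not manifest.empty:
        manifest = manifest.sort_values(
            ["chromosome", "position"]).reset_index(drop=True)
    return CohortData(sites, truth.sample_ids, manifest)


def write_cohort_vcf(data: CohortData, path: str,
                     chromosome_length: int | None = None) -> None:
    """Plain-text VCF v4.2 with GT and DP per sample."""
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    chroms = sorted({s.chromosome for s in data.sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=somavar-simulate\n")
        for c in chroms:
            ln = chromosome_length or (max(
                s.position for s in data.sites if s.chromosome == c) + 1000)
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description='
                 '"Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(data.sample_ids) + "\n")
        for s in sorted(data.sites, key=lambda s: (s.chromosome, s.position)):
            cols = [s.chromosome, str(s.position), ".", s.ref_base,
                    s.alt_base, ".", "PASS", ".", "GT:DP"]
            cols += [f"{gt_str[int(g)]}:{int(d)}"
                     for g, d in zip(s.genotype_classes, s.depths)]
            fh.write("\t".join(cols) + "\n")


def simulate_cohort_vcf(truth: CohortTruth, vcf_path: str,
                        manifest_path: str | None = None,
                        chromosome: str = "Gm01") -> CohortData:
    """Generate the cohort and write the VCF plus its truth manifest."""
    data = simulate_cohort(truth, chromosome=chromosome)
    write_cohort_vcf(data, vcf_path)
    if manifest_path:
        data.manifest.to_csv(manifest_path, sep="\t", index=False)
    return data
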