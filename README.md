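# somavar

Genomic variation analysis for mutagenized and transgenic plant genomes.

Plant breeding introduces variation three ways: standing differences
between cultivars, random mutagenesis (e.g. fast-neutron irradiation), and
genetic transformation with its associated tissue culture.  Assessing how
much *unintended* genomic change each route carries requires the same
measurements on all three classes: structural variants (large deletions
and duplications), single-base substitutions private to one plant, and —
for transgenics — the exact structure of the T-DNA integration locus.
`somavar` implements that pipeline for array-CGH and short-read data, for
researchers comparing induced against standing variation in crop genomes.

## What it computes

* **CGH structural variants** — per-probe log2 ratio tracks are segmented
  by recursive permutation-accepted search (best sub-window vs complement
  under z = |Δmean| / √(1/n₁ + 1/n₂); raw-difference gate 0.1, minimum
  segment 2 probes, 0.99 acceptance percentile over 10 permutations).
  Segment means beyond calibrated thresholds (upper 0.3484 → "UpCNV",
  lower −0.5257 → "DownCNV", ≥ 3 probes) become calls; same-class calls at
  the exact same location in multiple plants of one background are flagged
  as intra-cultivar heterogeneity; gene overlaps and per-class size
  summaries are tabulated.
* **Private homozygous substitutions** — from a multi-sample VCF, keep
  biallelic SNV sites where every sample has ≥ 5 reads, no call is
  heterozygous or missing, and exactly one individual is homozygous for
  the alternate base; apply region exclusions; report per-sample counts
  and Ti/Tv.
* **T-DNA insertion loci** — reads matching the construct between the left
  and right borders identify "orphaned" mates, which are clustered on the
  host genome; strand geometry gives the orientation, junction-spanning
  reads refine the LB-adjacent coordinate to the base, and coverage gaps
  plus pair spacing expose insertion-adjacent deletions.
* **Breakpoint junctions** — a junction sequence is decomposed against its
  reference flanks into breakpoints, per-side microhomology and filler
  sequence, the signatures of microhomology-mediated end joining.
* **Synthetic data** — generators for all of the above with tab-separated
  truth manifests, so recovery is testable end-to-end with no downloads.

See `docs/methods.md` for the models, assumptions and parameter table.

## Worked example

Generate a 4-sample cohort with planted private substitutions (18, 2, 1, 0
per sample) and run the filter:

```sh
somavar simulate cohort --seed 42 --out sim   # or the Python API below
somavar snp-filter --vcf sim/cohort.vcf --out snp_out
cat snp_out/private_counts.tsv
```

```
sample_id       n_private
S01     18
S02     2
S03     1
S04     0
```

The planted counts come back exactly: distractor sites (shared
polymorphisms, heterozygous and missing calls, under-covered would-be
privates) are all rejected by the filter rules.  With the Python API the
same cohort is built with
`CohortTruth(n_samples=4, n_sites=5000, private_counts=(18, 2, 1, 0),
seed=42)`.

Simulate a homozygous T-DNA insertion at Gm13:15,000 ("+", 20×, with a
1,500 bp deletion and 6 bp filler adjacent to the right border) and map
it back:

```sh
somavar tdna-locate --reads1 tdna/reads_1.fastq --reads2 tdna/reads_2.fastq \
    --construct tdna/construct.fa --host tdna/host.fa --out tdna_out
cat tdna_out/insertion_calls.tsv tdna_out/local_sv.bed
```

```
chromosome  lb_adjacent_coordinate  orientation  support_left  support_right  refined  filtered_homologous
Gm13        15000                   +            22            14             True     False
Gm13        15000   16500   junction_read   1500    .
```

The call lands on the correct chromosome with the planted orientation; the
LB-adjacent coordinate (15,000) is exact because junction-spanning reads
pin it, with 22 and 14 supporting pairs on the two flanks.  The BED line is
the adjacent deletion, sized exactly (1,500 bp) from the junction reads.
The run log records every filter's in/out counts
(`770 construct-matched read ends, 38 orphans, 1 insertion call(s)`).

A full multi-stage run (CGH + substitutions + T-DNA + junctions) is
configured in one YAML file and driven by `somavar run --config run.yaml`;
each stage writes TSV/BED/VCF artifacts plus a run log into the output
directory, and stages with missing inputs are skipped with a notice.

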