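"""Pipeline orchestration: run the stages and emit the comparative report.

Each stage reads its inputs, runs the corresponding module, and writes
tab-separated artifacts into the output directory; the report layer only
collates stage outputs, it never computes numbers of its own.  A stage with
missing inputs is skipped with an explicit notice in the run log.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from glob import glob
from typing import Optional

import pandas as pd
import yaml

from . import cgh as cgh_mod
from . import junctions as junc_mod
from . import substitutions as subs_mod
from . import transgene as tg_mod

CALIBRATED_THRESHOLDS = dict(upper=0.3484, lower=-0.5257,
                                min_probes_call=3)


@dataclass
class RunConfig:
    """Parsed run configuration; defaults follow the calibrated pipeline."""

    seed: int = 0
    out_dir: str = "somavar_out"
    # sample -> germplasm class (inter-cultivar / FN-phenotype /
    # FN-no-phenotype / transgenic / control)
    classes: dict[str, str] = field(default_factory=dict)
    # sample -> background group name for heterogeneity filtering
    background_groups: dict[str, str] = field(default_factory=dict)
    cgh: Optional[dict] = None
    snp: Optional[dict] = None
    tdna: Optional[dict] = None
    junction: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for sample in cfg.background_groups:
            if cfg.classes and sample not in cfg.classes:
                raise ValueError(f"sample {sample!r} has a background group "
                                 "but no class assignment")
        return cfg


def _log(messages: list[str], msg: str) -> None:
    messages.append(msg)


def run_cgh_stage(cfg: RunConfig, log: list[str]) -> Optional[dict]:
    opts = cfg.cgh or {}
    tracks_dir = opts.get("tracks_dir")
    genes_path = opts.get("genes_gff3")
    if not tracks_dir or not os.path.isdir(tracks_dir):
        _log(log, "cgh: stage skipped (no tracks directory)")
        return None
    paths = sorted(glob(os.path.join(tracks_dir, "*.tsv")))
    paths = [p for p in paths if not p.endswith("truth_manifest.tsv")]
    if not paths:
        _log(log, "cgh: stage skipped (no track files)")
        return None
    params = cgh_mod.SegmentationParams(
        seed=cfg.seed, **{k: v for k, v in opts.items()
                          if k in ("min_segment_difference",
                                   "min_probes_segment",
                                   "acceptance_percentile",
                                   "n_permutations")})
    thr = cgh_mod.ClassificationThresholds(
        **{k: opts.get(k, CALIBRATED_THRESHOLDS[k])
           for k in CALIBRATED_THRESHOLDS})
    calls_by_sample: dict[str, list[cgh_mod.SVCall]] = {}
    for path in paths:
        track = cgh_mod.ProbeTrack.from_tsv(path)
        if opts.get("center", True):
            track = cgh_mod.center_track(track)
        segs = cgh_mod.segment_track(track, params)
        calls_by_sample[track.sample_id] = cgh_mod.call_and_merge(
            segs, thr, sample_id=track.sample_id)
        _log(log, f"cgh: {track.sample_id}: {track.n_probes} probes -> "
                  f"{len(segs)} segments -> "
                  f"{len(calls_by_sample[track.sample_id])} calls")

    # heterogeneity filtering within each background group
    groups: dict[str, list[str]] = {}
    for sample in calls_by_sample:
        groups.setdefault(cfg.background_groups.get(sample, "all"),
                          []).append(sample)
    for group, samples in sorted(groups.items()):
        if len(samples) < 2:
            _log(log, f"cgh: group {group}: single sample, heterogeneity "
                      "filter not applicable")
            continue
        sub = {s: calls_by_sample[s] for s in samples}
        filtered = cgh_mod.filter_heterogeneity(
            sub, mode=opts.get("heterogeneity_mode", "exact"),
            min_recurrence=opts.get("min_recurrence", 2),
            reciprocal_overlap=opts.get("reciprocal_overlap", 1.0))
        n_flagged = sum(c.filtered_as_heterogeneity
                        for calls in filtered.values() for c in calls)
        calls_by_sample.update(filtered)
        _log(log, f"cgh: group {group}: {n_flagged} calls flagged as "
                  "intra-cultivar heterogeneity")

    result = {"calls_by_sample": calls_by_sample}
    if genes_path and os.path.exists(genes_path):
        genes = cgh_mod.read_genes_gff3(genes_path)
        flat = [c for calls in calls_by_sample.values() for c in calls]
        by_class: dict[str, list] = {}
        for c in flat:
            label = cfg.classes.get(c.sample_id, "unassigned")
            by_class.setdefault(label, []).append(c)
        summaries = {}
        for label in sorted(by_class):
            samples = sorted({c.sample_id for c in by_class[label]})
            summaries[label] = cgh_mod.summarize_class(
                by_class[label], genes, label, samples=samples)
        result["genes"] = genes
        result["summaries"] = summaries
        result["gene_overlaps"] = cgh_mod.genes_overlapping(
            [c for c in flat if not c.filtered_as_heterogeneity], genes)
    else:
        _log(log, "cgh: no gene annotation; gene-overlap accounting skipped")
    return result


def run_snp_stage(cfg: RunConfig, log: list[str]) -> Optional[dict]:
    opts = cfg.snp or {}
    vcf_path = opts.get("vcf")
    if not vcf_path or not os.path.exists(vcf_path):
        _log(log, "snp: stage skipped (no VCF)")
        return None
    sites, samples, read_stats = subs_mod.read_vcf_sites(vcf_path)
    criteria = subs_mod.FilterCriteria(
        min_depth=opts.get("min_depth", 5),
        depth_scope=opts.get("depth_scope", "site"))
    subs, stats = subs_mod.apply_site_filters(sites, samples, criteria)
    stats.n_skipped_non_snv = read_stats.n_skipped_non_snv
    _log(log, f"snp: {stats.n_sites_in} sites in, "
              f"{stats.n_skipped_non_snv} non-SNV skipped, "
              f"{stats.n_failed_depth} failed depth, "
              f"{stats.n_het_or_missing} het/missing, "
              f"{stats.n_monomorphic} monomorphic, "
              f"{stats.n_multi_carrier} multi-carrier, "
              f"{stats.n_kept} private substitutions kept")
    removed = 0
    bed = opts.get("exclude_bed")
    if bed and os.path.exists(bed):
        regions = subs_mod.read_exclusion_bed(bed)
        subs, removed = subs_mod.apply_region_exclusion(subs, regions)
        _log(log, f"snp: {removed} substitutions removed by region "
                  "exclusion")
    counts = subs_mod.per_sample_counts(subs, samples)
    titv = subs_mod.titv_ratio(subs)
    return {"substitutions": subs, "samples": samples, "counts": counts,
            "titv": titv, "stats": stats, "n_excluded_by_region": removed}


def run_tdna_stage(cfg: RunConfig, log: list[str]) -> Optional[dict]:
    opts = cfg.tdna or {}
    needed = ("reads1", "reads2", "construct_fasta", "host_fasta")
    if not all(opts.get(kk) and os.path.exists(opts[kk]) for kk in needed):
        _log(log, "tdna: stage skipped (reads or references missing)")
        return None
    from Bio import SeqIO

    host_rec = next(SeqIO.parse(opts["host_fasta"], "fasta"))
    construct = str(next(
        SeqIO.parse(opts["construct_fasta"], "fasta")).seq).upper()
    r1 = {rec.id.rsplit("/", 1)[0]: str(rec.seq).upper()
          for rec in SeqIO.parse(opts["reads1"], "fastq")}
    r2 = {rec.id.rsplit("/", 1)[0]: str(rec.seq).upper()
          for rec in SeqIO.parse(opts["reads2"], "fastq")}
    pairs = [(name, r1[name], r2[name]) for name in sorted(r1)
             if name in r2]
    result = tg_mod.locate_insertions(
        pairs, construct, str(host_rec.seq).upper(), host_rec.id,
        insert_size_mean=opts.get("insert_size_mean", 350.0),
        insert_size_sd=opts.get("insert_size_sd", 35.0),
        min_support=opts.get("min_support", 3),
        min_mapq=opts.get("min_mapq", 20))
    paralog_bed = opts.get("paralog_bed")
    elements_tsv = opts.get("elements_tsv")
    if paralog_bed and elements_tsv and os.path.exists(paralog_bed) \
            and os.path.exists(elements_tsv):
        elements = [tuple(r) for r in pd.read_csv(
            elements_tsv, sep="\t").itertuples(index=False)]
        bed = pd.read_csv(paralog_bed, sep="\t", header=None)
        regions = [(str(r[0]), int(r[1]) + 1, int(r[2]))
                   for r in bed.itertuples(index=False)]
        model = tg_mod.ConstructModel(
            construct, elements,
            homologous_elements=opts.get("homologous_elements", []))
        result.calls = tg_mod.filter_homologous_loci(result.calls, model,
                                                     regions)
    _log(log, f"tdna: {result.n_construct_aligned} construct-matched read "
              f"ends, {result.n_orphans} orphans, {len(result.calls)} "
              f"insertion call(s), {len(result.local_svs)} local SV(s)")
    return {"result": result}


def run_junction_stage(cfg: RunConfig, log: list[str]) -> Optional[dict]:
    opts = cfg.junction or {}
    needed = ("junctions_fasta", "ref_fasta", "anchors_tsv")
    if not all(opts.get(kk) and os.path.exists(opts[kk]) for kk in needed):
        _log(log, "junction: stage skipped (inputs missing)")
        return None
    from Bio import SeqIO

    refs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(opts["ref_fasta"], "fasta")}
    anchors = pd.read_csv(opts["anchors_tsv"], sep="\t")
    resolutions = {}
    for rec in SeqIO.parse(opts["junctions_fasta"], "fasta"):
        rows = anchors[anchors["junction_id"] == rec.id]
        if rows.empty:
            _log(log, f"junction: {rec.id}: no anchors; skipped")
            continue
        sides = {r.side: r for r in rows.itertuples(index=False)}
        left, right = sides.get("left"), sides.get("right")
        if left is None or right is None:
            _log(log, f"junction: {rec.id}: needs a left and a right "
                      "anchor; skipped")
            continue
        flank_len = int(getattr(left, "flank_len", 60) or 60)
        ref = refs[left.chromosome]
        lf = ref[left.anchor_pos - 1:left.anchor_pos - 1 + flank_len]
        ref_r = refs[right.chromosome]
        rf = ref_r[max(0, right.anchor_pos - flank_len):right.anchor_pos]
        obs = junc_mod.JunctionObservation(
            junction_sequence=str(rec.seq).upper(), left_flank_ref=lf,
            right_flank_ref=rf, left_anchor=int(left.anchor_pos),
            right_anchor=int(right.anchor_pos),
            event_type=str(getattr(left, "event_type", "deletion")),
            chromosome=str(left.chromosome))
        resolutions[rec.id] = junc_mod.resolve_junction(obs)
    _log(log, f"junction: {len(resolutions)} junction(s) resolved")
    return {"resolutions": resolutions}


# ---------------------------------------------------------------------------
# report writing


def _write_cgh_outputs(out: str, cgh_res: dict) -> None:
    flat = [c for calls in cgh_res["calls_by_sample"].values()
            for c in calls]
    cgh_mod.calls_to_bed([c for c in flat if not c.filtered_as_heterogeneity],
                         os.path.join(out, "sv_calls.bed"))
    rows = [{
        "sample_id": c.sample_id, "chromosome": c.chromosome,
        "start_bp": c.start_bp, "end_bp": c.end_bp, "n_probes": c.n_probes,
        "mean_log2": round(c.mean_log2, 4), "call_class": c.call_class,
        "filtered_as_heterogeneity": c.filtered_as_heterogeneity,
    } for c in sorted(flat, key=lambda c: (c.sample_id, c.chromosome,
                                           c.start_bp))]
    pd.DataFrame(rows).to_csv(os.path.join(out, "sv_calls.tsv"), sep="\t",
                              index=False)
    if "summaries" in cgh_res:
        srows = []
        for label, summary in sorted(cgh_res["summaries"].items()):
            for direction in ("up", "down"):
                srows.append({"class": label, "direction": direction,
                              **summary[direction]})
        pd.DataFrame(srows).to_csv(os.path.join(out, "class_summary.tsv"),
                                   sep="\t", index=False)
    if "gene_overlaps" in cgh_res:
        grows = []
        for sample, (dup, dele) in sorted(cgh_res["gene_overlaps"].items()):
            for gid in sorted(dup):
                grows.append({"sample_id": sample, "gene_id": gid,
                              "sv_class": "duplicated"})
            for gid in sorted(dele):
                grows.append({"sample_id": sample, "gene_id": gid,
                              "sv_class": "deleted"})
        pd.DataFrame(grows, columns=["sample_id", "gene_id", "sv_class"]
                     ).to_csv(os.path.join(out, "gene_overlaps.tsv"),
                              sep="\t", index=False)


def _write_snp_outputs(out: str, snp_res: dict) -> None:
    snp_res["counts"].to_csv(os.path.join(out, "private_counts.tsv"),
                             sep="\t", index=False)
    subs_mod.subs_to_vcf(snp_res["substitutions"], snp_res["samples"],
                         os.path.join(out, "private_substitutions.vcf"))
    titv = snp_res["titv"]
    with open(os.path.join(out, "titv.tsv"), "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"titv_ratio\t{'' if titv is None else round(titv, 4)}\n")


def _write_tdna_outputs(out: str, tdna_res: dict) -> None:
    result: tg_mod.LocateResult = tdna_res["result"]
    rows = [{
        "chromosome": c.chromosome,
        "lb_adjacent_coordinate": c.lb_adjacent_coordinate,
        "orientation": c.orientation,
        "support_left": c.n_supporting_pairs_left,
        "support_right": c.n_supporting_pairs_right,
        "refined": c.refined,
        "filtered_homologous": c.filtered_homologous,
    } for c in result.calls]
    pd.DataFrame(rows).to_csv(os.path.join(out, "insertion_calls.tsv"),
                              sep="\t", index=False)
    with open(os.path.join(out, "local_sv.bed"), "w") as fh:
        for sv in result.local_svs:
            ev = ",".join(sorted(sv.evidence)) or sv.status
            fh.write(f"{sv.chromosome}\t{sv.start_bp - 1}\t{sv.end_bp}\t"
                     f"{ev}\t{sv.size_bp}\t.\n")


def _write_junction_outputs(out: str, junc_res: dict) -> None:
    rows = [{
        "junction_id": jid, "status": r.status,
        "breakpoint_left": r.breakpoint_left,
        "breakpoint_right": r.breakpoint_right,
        "event_size_bp": r.event_size_bp,
        "mh_left_bp": r.mh_left_bp, "mh_right_bp": r.mh_right_bp,
        "filler_sequence": r.filler_sequence,
    } for jid, r in sorted(junc_res["resolutions"].items())]
    pd.DataFrame(rows).to_csv(os.path.join(out, "junction_resolutions.tsv"),
                              sep="\t", index=False)


def run_all(config: RunConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns a dict of in-memory stage results; artifacts and a run log with
    per-filter record counts go to ``config.out_dir``.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    log: list[str] = [f"seed: {config.seed}"]
    results: dict = {}

    cgh_res = run_cgh_stage(config, log)
    if cgh_res is not None:
        _write_cgh_outputs(out, cgh_res)
        results["cgh"] = cgh_res
    snp_res = run_snp_stage(config, log)
    if snp_res is not None:
        _write_snp_outputs(out, snp_res)
        results["snp"] = snp_res
    tdna_res = run_tdna_stage(config, log)
    if tdna_res is not None:
        _write_tdna_outputs(out, tdna_res)
        results["tdna"] = tdna_res
    junc_res = run_junction_stage(config, log)
    if junc_res is not None:
        _write_junction_outputs(out, junc_res)
        results["junction"] = junc_res

    with open(os.path.join(out, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    manifest = {"seed": config.seed,
                "stages_run": sorted(results),
                "outputs": sorted(os.listdir(out))}
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["log"] = log
    return results
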