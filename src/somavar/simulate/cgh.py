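"""Synthetic tiling-array probe tracks with planted copy-number events.

Each sample-vs-reference hybridization is emulated as evenly spaced probes
whose log2 ratios are Gaussian around 0; probes inside a planted deletion or
duplication are shifted by the event's mean log2 shift.  "Shared" events are
realized at identical probe boundaries in every sample, emulating residual
intra-cultivar heterogeneity in the common background that the downstream
heterogeneity filter must subtract.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._util import stream_rng
from ..cgh import ProbeTrack


@dataclass
class CghEvent:
    sample_id: str | None  # None for events shared by every sample
    chromosome: str
    start_bp: int
    end_bp: int
    sv_class: str       # "dup" | "del"
    mean_shift: float   # log2 units


@dataclass
class CghTruth:
    planted_events: list[CghEvent]
    shared_events: list[CghEvent]
    chromosome_lengths: dict[str, int]
    noise_sd: float = 0.15
    probe_spacing_bp: int = 2000
    seed: int = 0
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be positive")
        for ev in self.planted_events + self.shared_events:
            if ev.sv_class not in ("dup", "del"):
                raise ValueError(f"bad sv_class {ev.sv_class!r}")
            if ev.chromosome not in self.chromosome_lengths:
                raise ValueError(f"unknown chromosome {ev.chromosome!r}")


def _probe_positions(length_bp: int, spacing: int) -> np.ndarray:
    return np.arange(spacing, length_bp + 1, spacing)


def _event_probe_span(ev: CghEvent, positions: np.ndarray) -> np.ndarray:
    return np.flatnonzero((positions >= ev.start_bp) & (positions <= ev.end_bp))


def simulate_cgh(truth: CghTruth, out_dir: str | None = None,
                 ) -> tuple[dict[str, ProbeTrack], pd.DataFrame]:
    """Generate one ProbeTrack per sample plus the truth manifest.

    Returns ``(tracks, manifest)``; if ``out_dir`` is given, also writes one
    tab-separated track per sample (columns chrom, pos, log2) and
    ``truth_manifest.tsv``.  Same seed and parameters give byte-identical
    files.  An event spanning fewer than 3 probes is rejected.
    """
    samples = list(truth.sample_ids)
    if not samples:
        samples = sorted({e.sample_id for e in truth.planted_events
                          if e.sample_id is not None})
    if not samples:
        raise ValueError("no sample ids given or derivable from events")
    for ev in truth.planted_events:
        if ev.sample_id not in samples:
            raise ValueError(f"event sample {ev.sample_id!r} not in samples")

    for sample in samples:
        evs = truth.shared_events + [
            e for e in truth.planted_events if e.sample_id == sample]
        by_chrom: dict[str, list[CghEvent]] = {}
        for e in evs:
            by_chrom.setdefault(e.chromosome, []).append(e)
        for chrom_evs in by_chrom.values():
            chrom_evs.sort(key=lambda e: e.start_bp)
            for prev, nxt in zip(chrom_evs, chrom_evs[1:]):
                if nxt.start_bp <= prev.end_bp:
                    raise ValueError(
                        f"overlapping events in sample {sample}: "
                        f"{prev.chromosome}:{prev.start_bp}-{prev.end_bp} and "
                        f"{nxt.start_bp}-{nxt.end_bp}")

    positions = {c: _probe_positions(l, truth.probe_spacing_bp)
                 for c, l in truth.chromosome_lengths.items()}
    for ev in truth.planted_events + truth.shared_events:
        if len(_event_probe_span(ev, positions[ev.chromosome])) < 3:
            raise ValueError(
                f"event {ev.chromosome}:{ev.start_bp}-{ev.end_bp} spans "
                "fewer than 3 probes")

    tracks: dict[str, ProbeTrack] = {}
    rows = []
    for sample in samples:
        rng = stream_rng(truth.seed, "cgh", sample)
        chrom_arrays = {}
        for chrom in sorted(truth.chromosome_lengths):
            pos = positions[chrom]
            log2 = rng.normal(0.0, truth.noise_sd, size=pos.size) \
                if truth.noise_sd > 0 else np.zeros(pos.size)
            for ev in truth.shared_events + [
                    e for e in truth.planted_events if e.sample_id == sample]:
                if ev.chromosome != chrom:
                    continue
                idx = _event_probe_span(ev, pos)
                log2[idx] += ev.mean_shift
            chrom_arrays[chrom] = (pos, log2)
        tracks[sample] = ProbeTrack.from_arrays(sample, "reference",
                                                chrom_arrays)
    for ev in truth.shared_events:
        for sample in samples:
            rows.append((sample, ev.chromosome, ev.start_bp, ev.end_bp,
                         ev.sv_class, ev.mean_shift, True))
    for ev in truth.planted_events:
        rows.append((ev.sample_id, ev.chromosome, ev.start_bp, ev.end_bp,
                     ev.sv_class, ev.mean_shift, False))
    manifest = pd.DataFrame(rows, columns=[
        "sample_id", "chromosome", "start_bp", "end_bp", "sv_class",
        "mean_shift", "shared"])

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for sample, track in tracks.items():
            track.to_tsv(os.path.join(out_dir, f"{sample}.track.tsv"))
        manifest.to_csv(os.path.join(out_dir, "truth_manifest.tsv"),
                        sep="\t", index=False)
    return tracks, manifest
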