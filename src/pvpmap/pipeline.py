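"""End-to-end orchestration: scan -> map assembly -> candidate ranking.

Library-level functions behind the command-line subcommands, so the whole
pipeline is drivable from Python (tests, notebooks) without touching the
shell interface.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from pvpmap import __version__ as _version
from pvpmap.core import (
    GenomeTable,
    GenomicInterval,
    ReadTrack,
    write_intervals,
)
from pvpmap.mapbuild import (
    EnhancerRecord,
    TssAnnotation,
    filter_by_broad_peaks,
    merge_with_pvp,
    remove_tss_proximal,
    union_tf_regions,
)
from pvpmap.pvp import GeometryGrid, ValleyCall, scan_genome, select_pvp_enhancers

__all__ = ["MapBuildResult", "build_enhancer_map", "write_map_outputs",
           "write_scan_outputs", "run_metadata"]


@dataclass
class MapBuildResult:
    """Final map plus per-stage record counts and the PVP calls behind it."""

    records: list[EnhancerRecord]
    stage_counts: dict[str, int]
    pvp_calls: list[ValleyCall]
    pvp_records: list[EnhancerRecord]
    parameters: dict


def build_enhancer_map(
    tf_peak_sets: Mapping[str, Sequence[GenomicInterval]],
    broad_peaks: Sequence[GenomicInterval],
    read_track: ReadTrack,
    tss: TssAnnotation,
    genome: GenomeTable | None = None,
    grid: GeometryGrid | None = None,
    step: int = 50,
    max_pvalue: float | None = 1e-6,
    top_n: int | None = None,
    tss_radius: int = 1000,
) -> MapBuildResult:
    """Assemble the genome-wide putative promoter-distal enhancer map.

    Stages, in order: (1) union of TF-bound regions; (2) filter by H3K27ac
    broad peaks; (3) PVP scan of the broad peaks and selection of confident
    valleys; (4) merge of the two evidence streams; (5) removal of
    TSS-proximal records.
    """
    tf_records = union_tf_regions(tf_peak_sets)
    filtered = filter_by_broad_peaks(tf_records, broad_peaks)
    calls = scan_genome(read_track, broad_peaks, grid=grid, step=step, genome=genome)
    pvp_records = select_pvp_enhancers(calls, max_pvalue=max_pvalue, top_n=top_n)
    pvp_records = filter_by_broad_peaks(pvp_records, broad_peaks)
    merged = merge_with_pvp(filtered, pvp_records)
    final, n_removed = remove_tss_proximal(merged, tss, radius=tss_radius)
    counts = {
        "tf_union": len(tf_records),
        "after_broad_peak_filter": len(filtered),
        "valley_calls": len(calls),
        "pvp_enhancers": len(pvp_records),
        "merged": len(merged),
        "tss_proximal_removed": n_removed,
        "final_map": len(final),
    }
    params = {
        "step": step,
        "max_pvalue": max_pvalue,
        "top_n": top_n,
        "tss_radius": tss_radius,
        "grid": {
            "valley_sizes": list((grid or GeometryGrid()).valley_sizes),
            "shoulder_sizes": list((grid or GeometryGrid()).shoulder_sizes),
        },
    }
    return MapBuildResult(final, counts, calls, pvp_records, params)


def _bed_score(rec: EnhancerRecord) -> float:
    # -log10 of the PVP score, capped at 300; 0 for records without a call.
    if rec.pvp_score is None or rec.pvp_score <= 0:
        return 300.0 if rec.pvp else 0.0
    return round(min(300.0, -math.log10(rec.pvp_score)), 4)


def write_map_outputs(result: MapBuildResult, prefix: str | Path) -> dict[str, Path]:
    """BED6 map + TSV evidence sidecar + JSON run metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed = prefix.with_suffix(".bed")
    ivs = [
        GenomicInterval(
            r.interval.chrom, r.interval.start, r.interval.end,
            name=f"E{i + 1:05d}", score=_bed_score(r), strand=".",
        )
        for i, r in enumerate(sorted(result.records, key=lambda r: r.interval))
    ]
    write_intervals(ivs, bed, dialect="bed6")
    tsv = prefix.with_suffix(".evidence.tsv")
    with open(tsv, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tpvp\ttf_sets\th3k27ac_signal\t"
                 "pvp_score\textent_bp\tprovenance\n")
        for i, r in enumerate(sorted(result.records, key=lambda r: r.interval)):
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"E{i + 1:05d}\t{int(r.pvp)}\t"
                f"{','.join(sorted(r.supporting_tf_sets)) or '.'}\t"
                f"{r.h3k27ac_signal:g}\t"
                f"{'' if r.pvp_score is None else repr(r.pvp_score)}\t"
                f"{'' if r.extent_bp is None else r.extent_bp}\t{r.provenance}\n"
            )
    return {"bed": bed, "evidence": tsv}


def write_scan_outputs(
    calls: Sequence[ValleyCall], prefix: str | Path
) -> dict[str, Path]:
    """BED6 of accepted valleys plus a TSV with counts and side p-values."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed = prefix.with_suffix(".bed")
    ivs = [
        GenomicInterval(
            c.chrom, c.valley_interval.start, c.valley_interval.end,
            name=f"V{i + 1:05d}",
            score=round(min(300.0, -math.log10(c.final_score)), 4)
            if c.final_score > 0 else 300.0,
            strand=".",
        )
        for i, c in enumerate(calls)
    ]
    write_intervals(ivs, bed, dialect="bed6")
    tsv = prefix.with_suffix(".valleys.tsv")
    with open(tsv, "w") as fh:
        fh.write(
            "chrom\tanchor\tvalley_start\tvalley_end\tfinal_score\t"
            "left_VS\tleft_SS\tleft_VR\tleft_SR\tleft_p\t"
            "right_VS\tright_SS\tright_VR\tright_SR\tright_p\n"
        )
        for c in calls:
            L, R = c.best_left, c.best_right
            fh.write(
                f"{c.chrom}\t{c.anchor}\t{c.valley_interval.start}\t"
                f"{c.valley_interval.end}\t{c.final_score!r}\t"
                f"{L.valley_size}\t{L.shoulder_size}\t{L.valley_reads}\t"
                f"{L.shoulder_reads}\t{L.p_value!r}\t"
                f"{R.valley_size}\t{R.shoulder_size}\t{R.valley_reads}\t"
                f"{R.shoulder_reads}\t{R.p_value!r}\n"
            )
    return {"bed": bed, "valleys": tsv}


def load_map_evidence(path: str | Path) -> list[EnhancerRecord]:
    """Read an ``*.evidence.tsv`` sidecar back into enhancer records."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tf = parts[idx["tf_sets"]]
            records.append(
                EnhancerRecord(
                    interval=GenomicInterval(
                        parts[idx["chrom"]],
                        int(parts[idx["start"]]),
                        int(parts[idx["end"]]),
                        name=parts[idx["name"]],
                    ),
                    pvp=bool(int(parts[idx["pvp"]])),
                    supporting_tf_sets=frozenset(
                        tf.split(",") if tf and tf != "." else ()
                    ),
                    h3k27ac_signal=float(parts[idx["h3k27ac_signal"]]),
                    pvp_score=float(parts[idx["pvp_score"]])
                    if parts[idx["pvp_score"]] else None,
                    extent_bp=int(parts[idx["extent_bp"]])
                    if parts[idx["extent_bp"]] else None,
                    provenance=parts[idx["provenance"]],
                )
            )
    return records


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_metadata(
    parameters: Mapping,
    inputs: Mapping[str, str | Path] | None = None,
    stage_counts: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> dict:
    """Metadata sufficient to reproduce a run: version, parameters, digests.

    The timestamp records when the run happened; everything else is
    deterministic, so reproducibility comparisons should hash the data
    outputs, not this file.
    """
    return {
        "tool": "pvpmap",
        "version": _version,
        "parameters": dict(parameters),
        "inputs": {
            k: {"path": str(p), "sha256": _sha256(p)}
            for k, p in (inputs or {}).items()
        },
        "stage_counts": dict(stage_counts or {}),
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_run_metadata(meta: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
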