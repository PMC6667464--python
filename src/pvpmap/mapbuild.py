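"""Assembly of the genome-wide putative-enhancer map.

The map is built in four stages: (1) union of transcription-factor peak
sets; (2) filtering by H3K27ac broad peaks, since acetylation marks active
enhancers; (3) merging in the peak-valley-peak calls, which need no TF
ChIP-seq at all; (4) removal of everything within 1 kb of a transcription
start site, leaving promoter-distal records only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from pvpmap.core import (
    CoverageTrack,
    GenomicInterval,
    interval_point_distance,
    merge_intervals,
)

__all__ = [
    "EnhancerRecord",
    "TssAnnotation",
    "union_tf_regions",
    "filter_by_broad_peaks",
    "merge_with_pvp",
    "remove_tss_proximal",
    "enhancer_extent",
    "canonical_interval",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnhancerRecord:
    """One putative-enhancer map entry with its evidence provenance."""

    interval: GenomicInterval
    pvp: bool
    supporting_tf_sets: frozenset[str]
    h3k27ac_signal: float = 0.0
    extent_bp: int | None = None
    provenance: str = "tf_union"
    pvp_score: float | None = None

    def __post_init__(self) -> None:
        if not self.pvp and not self.supporting_tf_sets:
            raise ValueError("record needs at least one evidence source")
        if self.extent_bp is not None and self.extent_bp <= 0:
            raise ValueError("extent must be positive when present")


@dataclass(frozen=True)
class Tss:
    chrom: str
    position: int
    gene: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene name must be non-empty")


class TssAnnotation:
    """Transcription start sites, indexed per chromosome for distance queries."""

    def __init__(self, tss: Iterable[Tss]):
        self.records = sorted(tss, key=lambda t: (t.chrom, t.position, t.gene))
        self._by_chrom: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[int]] = {}
        for t in self.records:
            by_chrom.setdefault(t.chrom, []).append(t.position)
        for chrom, pos in by_chrom.items():
            self._by_chrom[chrom] = np.asarray(sorted(pos), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_bed(cls, path) -> "TssAnnotation":
        from pvpmap.core import read_intervals

        recs = []
        for iv in read_intervals(path, dialect="bed6"):
            # TSS position: start of the feature on + strand, end-1 on -.
            pos = iv.end - 1 if iv.strand == "-" else iv.start
            recs.append(Tss(iv.chrom, pos, iv.name or f"{iv.chrom}:{pos}", iv.strand or "."))
        return cls(recs)

    def min_distance(self, iv: GenomicInterval) -> int | None:
        """Base distance from ``iv`` to the nearest TSS on its chromosome."""
        pos = self._by_chrom.get(iv.chrom)
        if pos is None or len(pos) == 0:
            return None
        i = int(np.searchsorted(pos, iv.start))
        best = None
        for j in (i - 1, i, int(np.searchsorted(pos, iv.end))):
            if 0 <= j < len(pos):
                d = interval_point_distance(iv, int(pos[j]))
                if best is None or d < best:
                    best = d
        return best

    def gene_tss(self, gene: str) -> Tss:
        for t in self.records:
            if t.gene == gene:
                return t
        raise KeyError(f"gene not in TSS annotation: {gene}")


def union_tf_regions(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> list[EnhancerRecord]:
    """Merge all TF peak sets into disjoint bound regions with label provenance.

    Every merged region lists each dataset label contributing >= 1 bp of
    overlapping peak.
    """
    pooled = [iv for peaks in peak_sets.values() for iv in peaks]
    if not pooled:
        logger.warning("no TF peaks supplied; empty map")
        return []
    merged = merge_intervals(pooled)
    by_label_sorted = {
        label: sorted(peaks) for label, peaks in peak_sets.items()
    }
    records = []
    for region in merged:
        labels = frozenset(
            label
            for label, peaks in by_label_sorted.items()
            if any(region.overlaps(p) for p in peaks)
        )
        records.append(
            EnhancerRecord(
                interval=region,
                pvp=False,
                supporting_tf_sets=labels,
                provenance="tf_union",
            )
        )
    return records


def filter_by_broad_peaks(
    records: Sequence[EnhancerRecord],
    broad_peaks: Sequence[GenomicInterval],
) -> list[EnhancerRecord]:
    """Keep records overlapping (>= 1 bp) any H3K27ac broad peak.

    Survivors carry the maximum signalValue of their overlapping peaks.
    """
    peaks_sorted = sorted(broad_peaks)
    out = []
    for rec in records:
        overlapping = [p for p in peaks_sorted if rec.interval.overlaps(p)]
        if overlapping:
            signal = max((p.score or 0.0) for p in overlapping)
            out.append(replace(rec, h3k27ac_signal=float(signal)))
    return out


def merge_with_pvp(
    tf_records: Sequence[EnhancerRecord],
    pvp_records: Sequence[EnhancerRecord],
) -> list[EnhancerRecord]:
    """Interval union of the TF-supported and PVP-called record sets.

    A merged region's pvp flag is the OR of its constituents, its TF labels
    the union, and its H3K27ac signal the max.
    """
    constituents = list(tf_records) + list(pvp_records)
    if not constituents:
        return []
    merged = merge_intervals([r.interval for r in constituents])
    const_sorted = sorted(constituents, key=lambda r: r.interval)
    out = []
    for region in merged:
        inside = [r for r in const_sorted if region.overlaps(r.interval)]
        pvp = any(r.pvp for r in inside)
        labels = frozenset().union(*(r.supporting_tf_sets for r in inside))
        signal = max(r.h3k27ac_signal for r in inside)
        scores = [r.pvp_score for r in inside if r.pvp_score is not None]
        out.append(
            EnhancerRecord(
                interval=region,
                pvp=pvp,
                supporting_tf_sets=labels,
                h3k27ac_signal=signal,
                provenance="merged",
                pvp_score=min(scores) if scores else None,
            )
        )
    return out


def remove_tss_proximal(
    records: Sequence[EnhancerRecord],
    tss: TssAnnotation,
    radius: int = 1000,
) -> tuple[list[EnhancerRecord], int]:
    """Drop records whose distance to any TSS is < ``radius`` bp.

    A record at distance exactly ``radius`` is retained; a record that
    contains a TSS (distance 0) is always promoter-proximal and dropped,
    including at radius 0. Returns the promoter-distal survivors and the
    number removed.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    kept = []
    for rec in records:
        d = tss.min_distance(rec.interval)
        if d is None or (d > 0 and d >= radius):
            kept.append(rec)
    removed = len(records) - len(kept)
    logger.info("TSS filter: kept %d, removed %d", len(kept), removed)
    return kept, removed


def canonical_interval(rec: EnhancerRecord, length: int = 390) -> GenomicInterval:
    """Fixed-length span centered on the record midpoint (or its extent).

    Downstream validation treats each enhancer as a single canonical
    nucleosome-depleted span; when a per-record half-point extent exists it
    sets the length, otherwise the genome-wide canonical length is used.
    """
    L = rec.extent_bp if rec.extent_bp else length
    mid = rec.interval.midpoint
    start = max(0, mid - L // 2)
    return GenomicInterval(rec.interval.chrom, start, start + L)


def enhancer_extent(
    record: EnhancerRecord,
    coverage: CoverageTrack,
    search_bp: int = 1000,
) -> int | None:
    """Half-point extent of the nucleosome-depleted region, in bp.

    Finds the summit of each flanking H3K27ac peak within ``search_bp`` of
    the valley center, then walks inward: the left half-point is the first
    base at/after the left summit whose depth falls below half the summit
    depth; the right half-point mirrors it. The reported extent is the
    half-open span between the two crossings. None when either summit has
    zero depth (no flanking peak to measure from).
    """
    iv = record.interval
    center = iv.midpoint
    lo = max(0, iv.start - search_bp)
    hi = iv.end + search_bp
    depth = coverage.depth_array(iv.chrom, lo, hi)

    left = depth[: center - lo]
    right = depth[center - lo :]
    if left.size == 0 or right.size == 0:
        return None
    l_summit = int(np.argmax(left))  # first max: summit farthest from valley
    r_summit = int(np.argmax(right[::-1]))
    r_summit = len(right) - 1 - r_summit  # last max
    l_depth = int(left[l_summit])
    r_depth = int(right[r_summit])
    if l_depth == 0 or r_depth == 0:
        return None

    l_half = None
    for i in range(l_summit, len(left)):
        if left[i] < l_depth / 2:
            l_half = lo + i
            break
    r_half = None
    for i in range(r_summit, -1, -1):
        if right[i] < r_depth / 2:
            r_half = (center - lo) + i + lo
            break
    if l_half is None or r_half is None:
        return None
    # Half-open span [l_half, r_half + 1): both crossings are sub-half bases.
    extent = r_half + 1 - l_half
    return extent if extent > 0 else None
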