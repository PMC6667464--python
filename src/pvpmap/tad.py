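"""TAD intersection, candidate ranking, and map-validation statistics.

A gene and its enhancers tend to share one topologically associating domain
(TAD), so intersecting the genome-wide putative-enhancer map with the
gene's TAD yields a short, rankable candidate list (EC1, EC2, ...). Two
statistics validate the map itself: a binomial read-concentration test
(are independent TF ChIP-seq reads concentrated inside the canonical
enhancer spans?) and a rank-sum comparison of H3K27ac signal between broad
peaks with and without a PVP call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom, mannwhitneyu

from pvpmap.core import (
    GenomicInterval,
    ReadTrack,
    count_reads,
    interval_distance,
    merge_intervals,
)
from pvpmap.mapbuild import EnhancerRecord, TssAnnotation, canonical_interval

__all__ = [
    "TadDomain",
    "CandidateRanking",
    "candidates_in_tad",
    "rank_candidates",
    "read_concentration_test",
    "pvp_signal_comparison",
    "tad_for_gene",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TadDomain:
    """A topologically associating domain, consumed from an interval file."""

    interval: GenomicInterval
    label: str | None = None


@dataclass(frozen=True)
class RankedCandidate:
    record: EnhancerRecord
    evidence_score: tuple
    rank_name: str  # EC1, EC2, ...


@dataclass(frozen=True)
class CandidateRanking:
    gene: str
    tad: TadDomain
    candidates: tuple[RankedCandidate, ...]

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class ConcentrationResult:
    """Outcome of the binomial read-concentration test."""

    fraction: float  # share of selected-peak reads inside enhancer spans
    p_value: float  # upper-tail binomial
    reads_in_enhancers: int
    reads_total: int
    null_probability: float
    n_peaks_selected: int


def tad_for_gene(
    tads: Sequence[TadDomain], tss: TssAnnotation, gene: str
) -> TadDomain:
    """The TAD containing the gene's TSS; smallest when domains nest."""
    t = tss.gene_tss(gene)
    containing = [
        d
        for d in tads
        if d.interval.chrom == t.chrom
        and d.interval.start <= t.position < d.interval.end
    ]
    if not containing:
        raise ValueError(f"no TAD contains the TSS of {gene}")
    containing.sort(key=lambda d: (len(d.interval), d.interval))
    if len(containing) > 1:
        logger.info(
            "%d nested TADs contain %s; using smallest (%d bp)",
            len(containing),
            gene,
            len(containing[0].interval),
        )
    return containing[0]


def candidates_in_tad(
    records: Sequence[EnhancerRecord], tad: TadDomain
) -> list[EnhancerRecord]:
    """Map records overlapping (>= 1 bp) the TAD, coordinate-sorted."""
    out = [r for r in records if r.interval.overlaps(tad.interval)]
    out.sort(key=lambda r: r.interval)
    return out


def _enrichment_rpkm(rec: EnhancerRecord, track: ReadTrack) -> float:
    """Reads per kb per million mapped reads over the record interval."""
    if track.total_reads == 0:
        return 0.0
    k = count_reads(track, rec.interval)
    kb = len(rec.interval) / 1000.0
    return k / kb / (track.total_reads / 1e6)


def rank_candidates(
    cands: Sequence[EnhancerRecord],
    read_tracks: Mapping[str, ReadTrack] | None = None,
    gene: str = "",
    tad: TadDomain | None = None,
) -> CandidateRanking:
    """Order candidates by ChIP-seq evidence strength and name them EC1..ECk.

    Evidence is compared lexicographically: a PVP call outranks any number
    of TF sets, more supporting TF sets outranks higher read enrichment,
    and ties fall back to summed normalized enrichment (RPKM) over the
    supplied read tracks. The full breakdown stays attached to every
    candidate so users can re-rank under their own weighting.
    """
    if not cands:
        logger.warning("empty candidate list for %s", gene or "<gene>")
        return CandidateRanking(gene, tad, ())
    read_tracks = read_tracks or {}
    scored = []
    for rec in cands:
        enrich = sum(_enrichment_rpkm(rec, t) for t in read_tracks.values())
        score = (int(rec.pvp), len(rec.supporting_tf_sets), enrich)
        scored.append((score, rec))
    # Descending evidence; coordinate breaks exact ties deterministically.
    scored.sort(key=lambda x: (tuple(-v for v in x[0]), x[1].interval))
    ranked = tuple(
        RankedCandidate(record=rec, evidence_score=score, rank_name=f"EC{i + 1}")
        for i, (score, rec) in enumerate(scored)
    )
    return CandidateRanking(gene, tad, ranked)


def read_concentration_test(
    peaks: Sequence[GenomicInterval],
    track: ReadTrack,
    enhancers: Sequence[EnhancerRecord],
    window: int = 4000,
    enhancer_len: int = 390,
) -> ConcentrationResult | None:
    """Binomial test of read concentration inside canonical enhancer spans.

    Peaks within ``window`` bp of any enhancer are selected; reads are
    attributed to a peak by midpoint. With U the union of selected peaks and
    E the union of canonical enhancer spans, k of the n reads in U fall in
    U ∩ E; under a uniform null each read lands in E with probability
    p0 = |U ∩ E| / |U|, and the test reports the upper tail P(X >= k).
    Returns None when no peak is selected or the selected peaks hold no
    reads.
    """
    spans = [canonical_interval(r, enhancer_len) for r in enhancers]
    if not spans or not peaks:
        return None
    spans_by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in spans:
        spans_by_chrom.setdefault(s.chrom, []).append(s)
    selected = []
    for p in peaks:
        near = spans_by_chrom.get(p.chrom, ())
        if any(interval_distance(p, s) <= window for s in near):
            selected.append(p)
    if not selected:
        return None
    union = merge_intervals(selected)
    e_union = merge_intervals(spans)
    n = sum(count_reads(track, u) for u in union)
    if n == 0:
        return None
    overlap_bp = 0
    k = 0
    for u in union:
        for e in e_union:
            ov = u.overlap_bp(e)
            if ov:
                overlap_bp += ov
                a = max(u.start, e.start)
                b = min(u.end, e.end)
                k += track.count(u.chrom, a, b)
    union_bp = sum(len(u) for u in union)
    p0 = overlap_bp / union_bp
    # Upper tail P(X >= k); survival function gives P(X > k-1).
    p_value = float(binom.sf(k - 1, n, p0)) if p0 < 1.0 else 1.0
    return ConcentrationResult(
        fraction=k / n,
        p_value=p_value,
        reads_in_enhancers=k,
        reads_total=n,
        null_probability=p0,
        n_peaks_selected=len(selected),
    )


def pvp_signal_comparison(
    peaks_with_pvp: Sequence[GenomicInterval],
    peaks_without: Sequence[GenomicInterval],
) -> tuple[float, float, float, float] | None:
    """Rank-sum comparison of H3K27ac signal between broad-peak groups.

    Two-sided Mann-Whitney U on the signalValue distributions of broad
    peaks that do vs. do not contain a PVP call. Returns (statistic, p,
    median_with, median_without), or None when a group is empty.
    """
    a = [p.score or 0.0 for p in peaks_with_pvp]
    b = [p.score or 0.0 for p in peaks_without]
    if not a or not b:
        logger.warning("signal comparison undefined: a group is empty")
        return None
    res = mannwhitneyu(a, b, alternative="two-sided")
    return (
        float(res.statistic),
        float(res.pvalue),
        float(np.median(a)),
        float(np.median(b)),
    )
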