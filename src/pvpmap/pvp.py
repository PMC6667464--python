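"""The peak-valley-peak (PVP) binomial statistic and genome scan.

An active enhancer is nucleosome-depleted, so H3K27ac reads pile up on the
two flanking shoulders and drop out over the valley. Under a uniform null,
reads falling in a valley V versus one shoulder S are Bernoulli trials with
success probability VS/(VS + SS) (the valley's share of the combined span);
observing VR valley reads out of n = VR + SR total is then scored by the
binomial CDF P(X <= VR). Each side of the valley is tested separately over a
small grid of valley/shoulder sizes, keeping the lowest p per side, and the
final valley score is the *greater* of the two side p values — both
shoulders must be enriched for a call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.special import bdtr

from pvpmap.core import GenomeTable, GenomicInterval, ReadTrack

__all__ = [
    "GeometryGrid",
    "SideScore",
    "ValleyCall",
    "shoulder_pvalue",
    "score_valley",
    "scan_broad_peak",
    "select_pvp_enhancers",
]

logger = logging.getLogger(__name__)

DEFAULT_VALLEY_SIZES = (250, 300, 350, 400)
DEFAULT_SHOULDER_SIZES = (300, 400, 500)


@dataclass(frozen=True)
class GeometryGrid:
    """Candidate valley and shoulder sizes (bp) enumerated per side."""

    valley_sizes: tuple[int, ...] = DEFAULT_VALLEY_SIZES
    shoulder_sizes: tuple[int, ...] = DEFAULT_SHOULDER_SIZES

    def __post_init__(self) -> None:
        if not self.valley_sizes or not self.shoulder_sizes:
            raise ValueError("size lists must be non-empty")
        if any(s <= 0 for s in self.valley_sizes + self.shoulder_sizes):
            raise ValueError("all sizes must be positive")

    @property
    def n_combinations(self) -> int:
        return len(self.valley_sizes) * len(self.shoulder_sizes)


@dataclass(frozen=True)
class SideScore:
    """Best-scoring geometry for one side of a candidate valley."""

    side: str  # "left" | "right"
    valley_size: int
    shoulder_size: int
    valley_reads: int
    shoulder_reads: int
    p_value: float


@dataclass(frozen=True)
class ValleyCall:
    """One scored PVP candidate valley."""

    chrom: str
    anchor: int
    best_left: SideScore
    best_right: SideScore
    final_score: float
    valley_interval: GenomicInterval
    source_broad_peak: GenomicInterval | None = None

    @property
    def sort_key(self) -> tuple:
        return (self.final_score, self.chrom, self.anchor)


def shoulder_pvalue(VR: int, SR: int, VS: int, SS: int) -> float:
    """P(X <= VR) for X ~ Binomial(n = VR + SR, p = VS / (VS + SS)).

    The probability that a uniformly placed read lands in the valley rather
    than the shoulder is the valley's share of the combined length. n = 0
    (no reads at all) returns 1: no evidence of depletion. Evaluated through
    the regularized incomplete beta function, stable for n up to 1e6.
    """
    if VR < 0 or SR < 0:
        raise ValueError("read counts must be non-negative")
    if VS <= 0 or SS <= 0:
        raise ValueError("sizes must be positive")
    n = VR + SR
    if n == 0:
        return 1.0
    p = VS / (VS + SS)
    return float(bdtr(min(VR, n), n, p))


def _valley_span(anchor: int, vs: int) -> tuple[int, int]:
    # Centered on the anchor; odd sizes put the extra base on the left.
    half_right = vs // 2
    return anchor - (vs - half_right), anchor + half_right


def _score_side(
    track: ReadTrack,
    chrom: str,
    anchor: int,
    side: str,
    grid: GeometryGrid,
    chrom_len: int,
) -> SideScore | None:
    """Minimum-p geometry for one side, or None when nothing fits."""
    best: SideScore | None = None
    for vs in grid.valley_sizes:
        vstart, vend = _valley_span(anchor, vs)
        if vstart < 0 or vend > chrom_len:
            continue
        vr = track.count(chrom, vstart, vend)
        for ss in grid.shoulder_sizes:
            if side == "left":
                sstart, send = vstart - ss, vstart
            else:
                sstart, send = vend, vend + ss
            if sstart < 0 or send > chrom_len:
                continue
            sr = track.count(chrom, sstart, send)
            p = shoulder_pvalue(vr, sr, vs, ss)
            if best is None or p < best.p_value:
                best = SideScore(side, vs, ss, vr, sr, p)
    return best


def score_valley(
    track: ReadTrack,
    chrom: str,
    anchor: int,
    grid: GeometryGrid | None = None,
    genome: GenomeTable | None = None,
) -> ValleyCall | None:
    """Score one candidate valley anchored at ``anchor``.

    Each side independently enumerates every (valley size, shoulder size)
    pair of the grid, keeping the lowest p. The final score is the larger of
    the two side minima; the reported valley interval comes from the side
    whose best p equals the final score (ties break to the left side).
    Returns None (unscorable) when no geometry fits on one side, e.g. at a
    chromosome edge.
    """
    grid = grid or GeometryGrid()
    chrom_len = genome[chrom] if genome is not None else 2**62
    left = _score_side(track, chrom, anchor, "left", grid, chrom_len)
    right = _score_side(track, chrom, anchor, "right", grid, chrom_len)
    if left is None or right is None:
        return None
    final = max(left.p_value, right.p_value)
    chosen = left if left.p_value >= right.p_value else right
    vstart, vend = _valley_span(anchor, chosen.valley_size)
    return ValleyCall(
        chrom=chrom,
        anchor=anchor,
        best_left=left,
        best_right=right,
        final_score=final,
        valley_interval=GenomicInterval(chrom, vstart, vend),
    )


def scan_broad_peak(
    track: ReadTrack,
    peak: GenomicInterval,
    grid: GeometryGrid | None = None,
    step: int = 50,
    genome: GenomeTable | None = None,
) -> list[ValleyCall]:
    """Slide anchors across one H3K27ac broad peak and de-overlap the calls.

    Anchors are placed every ``step`` bp from ``peak.start``. Calls are
    de-overlapped by greedy best-first non-maximum suppression on their
    valley intervals; accepted calls are returned coordinate-sorted.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    calls = []
    for anchor in range(peak.start, peak.end, step):
        call = score_valley(track, peak.chrom, anchor, grid, genome)
        if call is not None:
            calls.append(
                ValleyCall(
                    chrom=call.chrom,
                    anchor=call.anchor,
                    best_left=call.best_left,
                    best_right=call.best_right,
                    final_score=call.final_score,
                    valley_interval=call.valley_interval,
                    source_broad_peak=peak,
                )
            )
    accepted: list[ValleyCall] = []
    for call in sorted(calls, key=lambda c: c.sort_key):
        if not any(call.valley_interval.overlaps(a.valley_interval) for a in accepted):
            accepted.append(call)
    accepted.sort(key=lambda c: (c.chrom, c.anchor))
    return accepted


def scan_genome(
    track: ReadTrack,
    broad_peaks: Iterable[GenomicInterval],
    grid: GeometryGrid | None = None,
    step: int = 50,
    genome: GenomeTable | None = None,
) -> list[ValleyCall]:
    """Scan every broad peak; concatenation of per-peak accepted calls."""
    out: list[ValleyCall] = []
    for peak in sorted(broad_peaks):
        out.extend(scan_broad_peak(track, peak, grid, step, genome))
    return out


def select_pvp_enhancers(
    calls: Sequence[ValleyCall],
    max_pvalue: float | None = None,
    top_n: int | None = None,
):
    """Rank valley calls by final score and keep the confident ones.

    Exactly one of ``max_pvalue`` / ``top_n`` selects the cut: either every
    call with final score <= max_pvalue, or the top_n best-scoring calls.
    Returns :class:`~pvpmap.mapbuild.EnhancerRecord` objects flagged pvp=True.
    """
    from pvpmap.mapbuild import EnhancerRecord  # deferred: avoid import cycle

    if (max_pvalue is None) == (top_n is None):
        raise ValueError("supply exactly one of max_pvalue / top_n")
    ranked = sorted(calls, key=lambda c: c.sort_key)
    if top_n is not None:
        if top_n > len(ranked):
            logger.warning(
                "top_n=%d exceeds number of scorable calls (%d); keeping all",
                top_n,
                len(ranked),
            )
        kept = ranked[:top_n]
    else:
        kept = [c for c in ranked if c.final_score <= max_pvalue]
    return [
        EnhancerRecord(
            interval=c.valley_interval,
            pvp=True,
            supporting_tf_sets=frozenset(),
            h3k27ac_signal=0.0,
            provenance="pvp",
            pvp_score=c.final_score,
        )
        for c in kept
    ]
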