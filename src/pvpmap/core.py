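"""Genomic interval model, interval algebra, and BED-family readers/writers.

Coordinates are 0-based half-open everywhere, matching the BED standard used
by every on-disk format this package consumes. Strand is carried through but
ignored by all pipeline logic (enhancer calling is strand-agnostic).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeTable",
    "ReadTrack",
    "CoverageTrack",
    "BedParseError",
    "read_intervals",
    "write_intervals",
    "read_genome_table",
    "write_genome_table",
    "merge_intervals",
    "interval_point_distance",
    "interval_distance",
    "count_reads",
]


class BedParseError(ValueError):
    """Raised when a BED-family file has a malformed line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named chromosome.

    Ordering is (chrom lexicographic, start, end) so that sorting a list of
    intervals is deterministic.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeTable(dict):
    """Mapping chromosome name -> chromosome length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for chrom, length in self.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}: {length}")

    def contains(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self and 0 <= iv.start and iv.end <= self[iv.chrom]

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        for iv in intervals:
            if not self.contains(iv):
                raise ValueError(f"interval {iv} outside genome bounds")


class ReadTrack:
    """Per-chromosome sorted read midpoints supporting fast region counts.

    A read is assigned to exactly one position — its midpoint
    ``(start + end) // 2`` — so a read straddling a valley/shoulder boundary
    is never double-counted, which would inflate the binomial trial count.
    """

    def __init__(self, midpoints: Mapping[str, Sequence[int] | np.ndarray]):
        self._mid: dict[str, np.ndarray] = {}
        for chrom, pos in midpoints.items():
            arr = np.asarray(pos, dtype=np.int64)
            arr = np.sort(arr)
            self._mid[chrom] = arr
        self.total_reads = int(sum(len(a) for a in self._mid.values()))

    @classmethod
    def from_reads(cls, reads: Iterable[GenomicInterval]) -> "ReadTrack":
        by_chrom: dict[str, list[int]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r.midpoint)
        return cls(by_chrom)

    @classmethod
    def from_bed(cls, path: str | Path) -> "ReadTrack":
        return cls.from_reads(read_intervals(path, dialect="bed3"))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._mid)

    def midpoints(self, chrom: str) -> np.ndarray:
        return self._mid.get(chrom, np.empty(0, dtype=np.int64))

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of midpoints m with ``start <= m < end`` (binary search)."""
        arr = self._mid.get(chrom)
        if arr is None:
            return 0
        return int(np.searchsorted(arr, end) - np.searchsorted(arr, start))

    def shifted(self, offset: int) -> "ReadTrack":
        """New track with every midpoint translated by ``offset``."""
        return ReadTrack({c: a + offset for c, a in self._mid.items()})


def count_reads(track: ReadTrack, region: GenomicInterval) -> int:
    """Reads (midpoints) of ``track`` that fall inside ``region``."""
    return track.count(region.chrom, region.start, region.end)


class CoverageTrack:
    """Per-chromosome non-negative step function: position -> read depth.

    Stored per chromosome as breakpoint arrays ``starts``/``ends``/``depths``
    of disjoint, sorted constant-depth runs; depth is 0 outside the runs.
    """

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, depths) in runs.items():
            s = np.asarray(starts, dtype=np.int64)
            e = np.asarray(ends, dtype=np.int64)
            d = np.asarray(depths, dtype=np.int64)
            if not (len(s) == len(e) == len(d)):
                raise ValueError("run arrays must have equal length")
            if np.any(d < 0):
                raise ValueError("negative depth")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping/unsorted runs on {chrom}")
            self._runs[chrom] = (s, e, d)

    @classmethod
    def from_reads(
        cls, reads: Iterable[GenomicInterval], genome: GenomeTable | None = None
    ) -> "CoverageTrack":
        """Pile up read intervals into per-base depth (difference array)."""
        events: dict[str, list[tuple[int, int]]] = {}
        for r in reads:
            events.setdefault(r.chrom, []).append((r.start, r.end))
        runs = {}
        for chrom, spans in events.items():
            arr = np.asarray(spans, dtype=np.int64)
            bounds = np.unique(np.concatenate([arr[:, 0], arr[:, 1]]))
            delta = np.zeros(len(bounds), dtype=np.int64)
            delta += np.bincount(
                np.searchsorted(bounds, arr[:, 0]), minlength=len(bounds)
            )
            delta -= np.bincount(
                np.searchsorted(bounds, arr[:, 1]), minlength=len(bounds)
            )
            depth = np.cumsum(delta)[:-1]
            keep = depth != 0
            runs[chrom] = (bounds[:-1][keep], bounds[1:][keep], depth[keep])
        return cls(runs)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise BedParseError(f"{path}:{lineno}: expected 4 columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                    depth = int(round(float(parts[3])))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: {exc}") from exc
                by_chrom.setdefault(parts[0], []).append((start, end, depth))
        runs = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.asarray(rows, dtype=np.int64)
            runs[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(runs)

    def depth_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Materialize per-base depth over ``[start, end)`` as an int array."""
        if end <= start:
            raise ValueError("empty window")
        out = np.zeros(end - start, dtype=np.int64)
        runs = self._runs.get(chrom)
        if runs is None:
            return out
        s, e, d = runs
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(int(s[i]), start)
            b = min(int(e[i]), end)
            if a < b:
                out[a - start : b - start] = d[i]
        return out

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._runs):
                s, e, d = self._runs[chrom]
                for i in range(len(s)):
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{d[i]}\n")


# ---------------------------------------------------------------------------
# BED-family I/O

_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 3, "narrowPeak": 10, "broadPeak": 9}


def _fmt_score(score: float) -> str:
    # Lossless round-trip: integers render bare, floats via repr.
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_intervals(
    path: str | Path, dialect: str = "bed6"
) -> list[GenomicInterval]:
    """Read a BED3/BED6/narrowPeak/broadPeak file into intervals.

    narrowPeak/broadPeak carry their signalValue (column 7) as the interval
    score. ``track``/``browser``/``#`` header lines are skipped.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect: {dialect}")
    min_cols = _DIALECT_MIN_COLS[dialect]
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise BedParseError(
                    f"{path}:{lineno}: {dialect} needs >= {min_cols} columns, "
                    f"got {len(parts)}"
                )
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = score = strand = None
            if len(parts) > 3 and parts[3] not in (".", ""):
                name = parts[3]
            if dialect in ("narrowPeak", "broadPeak"):
                # signalValue is the meaningful peak-strength column.
                score = float(parts[6])
            elif len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            if len(parts) > 5 and parts[5] in ("+", "-", "."):
                strand = parts[5]
            out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return out


def write_intervals(
    xs: Sequence[GenomicInterval], path: str | Path, dialect: str = "bed6"
) -> None:
    """Write intervals as BED, sorted by (chrom, start, end)."""
    if dialect not in ("bed3", "bed6"):
        raise ValueError(f"unsupported output dialect: {dialect}")
    with open(path, "w") as fh:
        for iv in sorted(xs):
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = _fmt_score(iv.score) if iv.score is not None else "."
                strand = iv.strand if iv.strand is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n"
                )


def read_genome_table(path: str | Path) -> GenomeTable:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return GenomeTable(sizes)


def write_genome_table(genome: GenomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f"{chrom}\t{genome[chrom]}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(xs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal disjoint set of intervals covering exactly the union of ``xs``.

    Overlapping and bookended (end == start) intervals are merged; output is
    sorted by (chrom, start). Names/scores/strands are dropped — the result
    represents bare genomic regions.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in xs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookend
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def interval_point_distance(x: GenomicInterval, p: int) -> int:
    """Base distance from interval ``x`` to position ``p`` on the same chrom.

    0 when ``p`` lies inside ``x``; otherwise the distance to the nearest
    covered base: ``start - p`` left of the interval, ``p - end + 1`` right
    of it (the last covered base is ``end - 1``).
    """
    if x.start <= p < x.end:
        return 0
    if p < x.start:
        return x.start - p
    return p - x.end + 1


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Nearest-edge base distance between two intervals on the same chrom.

    0 on overlap; for disjoint intervals, the distance between the two
    closest covered bases (adjacent/bookended intervals are at distance 1),
    consistent with :func:`interval_point_distance`.
    """
    if a.chrom != b.chrom:
        raise ValueError("intervals on different chromosomes")
    if a.overlaps(b):
        return 0
    if a.end <= b.start:
        return b.start - a.end + 1
    return a.start - b.end + 1


def total_length(xs: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of ``xs``."""
    return sum(len(iv) for iv in merge_intervals(xs))


def intersect_length(xs: Sequence[GenomicInterval], ys: Sequence[GenomicInterval]) -> int:
    """Total bp in union(xs) ∩ union(ys)."""
    a = merge_intervals(xs)
    b = merge_intervals(ys)
    total = 0
    for iv in a:
        for jv in b:
            total += iv.overlap_bp(jv)
    return total
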