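"""Ground-truthed synthetic ChIP-seq landscapes for every pipeline stage.

The generator emulates the statistical structure the detector assumes:
H3K27ac reads placed uniformly at a background rate, with planted enhancers
where the two flanking shoulders are enriched by a constant fold and the
nucleosome-depleted valley is depleted by a constant fold. Around each
planted enhancer it also emits transcription-factor peaks (with per-dataset
sensitivity, plus uniform decoys), a broad acetylation domain, and an
independent "validation" TF peak/read set whose reads concentrate inside
the canonical enhancer core — the structure the read-concentration test
measures. TSSs are placed away from enhancers so every planted enhancer is
promoter-distal, and TADs partition each chromosome at random breakpoints.

Everything is reproducible: one integer seed fixes the landscape, and
emitted fixture files are byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from pvpmap.core import (
    CoverageTrack,
    GenomeTable,
    GenomicInterval,
    merge_intervals,
    write_genome_table,
    write_intervals,
)
from pvpmap.mapbuild import EnhancerRecord, Tss, TssAnnotation
from pvpmap.tad import TadDomain

__all__ = [
    "SyntheticConfig",
    "PlantedEnhancer",
    "SyntheticLandscape",
    "simulate_landscape",
    "emit_fixture_files",
    "gaussian_pvp_coverage",
]


class PackingError(RuntimeError):
    """Requested enhancers cannot be packed under the spacing constraint."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic landscape.

    Defaults model a merged H3K27ac library at 0.05 reads/bp background on a
    10-Mb chromosome, a 390-bp nucleosome-depleted core (the canonical
    enhancer extent) flanked by 400-bp acetylated shoulders enriched
    30-fold, with 5-fold read depletion inside the valley.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    n_enhancers: int = 20
    valley_width: int = 390
    shoulder_width: int = 400
    background_rate: float = 0.05  # reads per bp
    shoulder_enrichment: float = 30.0  # fold over background
    valley_depletion: float = 5.0  # fold reduction vs background
    read_length: int = 100
    n_tss: int = 50
    tss_exclusion: int = 2000  # min distance enhancer <-> TSS, bp
    tf_labels: tuple[str, ...] = ("Olig2", "Sox10", "Brg1")
    tf_sensitivity: float = 0.9  # P(planted enhancer gets a peak) per label
    tf_peak_width: int = 300
    n_decoy_peaks: int = 50  # per TF label, uniform placement
    tad_breakpoints: int | tuple[int, ...] = 10  # count, or explicit positions
    # Broad-peak emission
    n_background_blocks: int = 80
    background_block_width: int = 2000
    broad_signal_baseline: float = 3.0
    broad_signal_pvp_shift: float = 2.0  # fold shift for enhancer-bearing peaks
    # Independent validation TF set (concentration test)
    validation_label: str = "Sox10_sc"
    validation_peak_width: int = 1000
    validation_reads_per_enhancer: float = 200.0
    validation_core_fraction: float = 0.85
    validation_sensitivity: float = 0.8
    n_validation_decoy_peaks: int = 30

    def __post_init__(self) -> None:
        if self.n_enhancers < 0 or self.n_tss < 0:
            raise ValueError("counts must be non-negative")
        for name in ("valley_width", "shoulder_width", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("shoulder_enrichment", "valley_depletion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for name in ("tf_sensitivity", "validation_core_fraction",
                     "validation_sensitivity"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def genome(self) -> GenomeTable:
        return GenomeTable(self.chrom_lengths)

    @property
    def footprint_halfwidth(self) -> int:
        """Half-width of one enhancer footprint (valley half + shoulder)."""
        return self.valley_width // 2 + self.shoulder_width

    def to_json(self) -> str:
        d = asdict(self)
        d["chrom_lengths"] = dict(self.chrom_lengths)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_mapping(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        for key in ("tf_labels",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("tad_breakpoints"), list):
            d["tad_breakpoints"] = tuple(d["tad_breakpoints"])
        return cls(**d)


@dataclass(frozen=True)
class PlantedEnhancer:
    """Ground-truth record of one planted enhancer."""

    chrom: str
    center: int
    core: GenomicInterval  # the valley / nucleosome-depleted span
    shoulder_enrichment: float
    has_validation_peak: bool
    tf_labels: frozenset[str]


@dataclass
class SyntheticLandscape:
    config: SyntheticConfig
    enhancers: list[PlantedEnhancer]
    tss: TssAnnotation
    tads: list[TadDomain]
    reads: dict[str, list[GenomicInterval]]  # label -> read intervals
    broad_peaks: list[GenomicInterval]  # signalValue in .score
    tf_peaks: dict[str, list[GenomicInterval]]

    @property
    def genome(self) -> GenomeTable:
        return self.config.genome


def _place_separated(
    rng: np.random.Generator, lo: int, hi: int, n: int, min_sep: int
) -> np.ndarray:
    """n sorted positions in [lo, hi) pairwise >= min_sep apart.

    Draws in the volume left after removing the separation gaps, then
    re-inflates — exact uniform sampling of the separated configuration.
    """
    span = hi - lo - (n - 1) * min_sep
    if n > 0 and span <= 0:
        raise PackingError(
            f"cannot place {n} positions with separation {min_sep} in "
            f"[{lo}, {hi}): need {n * min_sep} bp, have {hi - lo}"
        )
    if n == 0:
        return np.empty(0, dtype=np.int64)
    base = np.sort(rng.integers(0, span, size=n))
    return lo + base + min_sep * np.arange(n)


def _uniform_reads(
    rng: np.random.Generator,
    chrom: str,
    lo: int,
    hi: int,
    n: int,
    read_length: int,
    chrom_len: int,
) -> list[GenomicInterval]:
    """n fixed-length reads with midpoints uniform in [lo, hi)."""
    if n <= 0 or hi <= lo:
        return []
    mids = rng.integers(lo, hi, size=n)
    half = read_length // 2
    starts = np.clip(mids - half, 0, chrom_len - read_length)
    return [
        GenomicInterval(chrom, int(s), int(s) + read_length) for s in np.sort(starts)
    ]


def simulate_landscape(config: SyntheticConfig) -> SyntheticLandscape:
    """Draw one complete landscape from the configured study conditions.

    Background H3K27ac reads are Poisson-placed uniformly outside enhancer
    footprints; each planted enhancer adds Poisson shoulder reads at
    ``background_rate * shoulder_enrichment`` over both shoulders and valley
    reads at ``background_rate / valley_depletion``. Compartment counts are
    independent Poisson draws, so the whole profile is a single
    inhomogeneous Poisson process with a piecewise-constant rate.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    vw, sw = config.valley_width, config.shoulder_width
    half_fp = config.footprint_halfwidth
    margin = half_fp + 600  # keep the widest scan geometry inside bounds

    enhancers: list[PlantedEnhancer] = []
    tss_records: list[Tss] = []
    tads: list[TadDomain] = []
    h3k27ac: list[GenomicInterval] = []
    validation_reads: list[GenomicInterval] = []
    broad_peaks: list[GenomicInterval] = []
    tf_peaks: dict[str, list[GenomicInterval]] = {l: [] for l in config.tf_labels}
    tf_peaks[config.validation_label] = []

    n_chroms = len(genome)
    gene_counter = 0
    for chrom in sorted(genome):
        L = genome[chrom]
        n_enh = config.n_enhancers // n_chroms + (
            1 if sorted(genome).index(chrom) < config.n_enhancers % n_chroms else 0
        )
        centers = _place_separated(
            rng, margin, L - margin, n_enh, min_sep=2 * (vw + sw)
        )

        footprints = [
            GenomicInterval(chrom, int(c) - half_fp, int(c) + half_fp)
            for c in centers
        ]

        # --- H3K27ac reads ------------------------------------------------
        # Background: uniform midpoints, thinned out of enhancer footprints.
        n_bg = rng.poisson(config.background_rate * L)
        if n_bg > 0:
            mids = rng.integers(0, L, size=n_bg)
            if footprints:
                fp_starts = np.array([f.start for f in footprints])
                fp_ends = np.array([f.end for f in footprints])
                idx = np.searchsorted(fp_ends, mids, side="right")
                inside = (idx < len(fp_starts)) & (mids >= fp_starts[idx.clip(max=len(fp_starts) - 1)])
                mids = mids[~inside]
            half = config.read_length // 2
            starts = np.clip(np.sort(mids) - half, 0, L - config.read_length)
            h3k27ac.extend(
                GenomicInterval(chrom, int(s), int(s) + config.read_length)
                for s in starts
            )
        # Planted compartments.
        for c in centers:
            c = int(c)
            v_lo, v_hi = c - vw // 2, c - vw // 2 + vw
            sh_rate = config.background_rate * config.shoulder_enrichment
            va_rate = config.background_rate / config.valley_depletion
            h3k27ac.extend(
                _uniform_reads(rng, chrom, v_lo - sw, v_lo,
                               rng.poisson(sh_rate * sw), config.read_length, L)
            )
            h3k27ac.extend(
                _uniform_reads(rng, chrom, v_lo, v_hi,
                               rng.poisson(va_rate * vw), config.read_length, L)
            )
            h3k27ac.extend(
                _uniform_reads(rng, chrom, v_hi, v_hi + sw,
                               rng.poisson(sh_rate * sw), config.read_length, L)
            )

        # --- TF peaks (map evidence) --------------------------------------
        planted_labels: list[frozenset[str]] = []
        for c in centers:
            c = int(c)
            labels = set()
            for label in config.tf_labels:
                if rng.random() < config.tf_sensitivity:
                    labels.add(label)
                    w = config.tf_peak_width
                    tf_peaks[label].append(
                        GenomicInterval(
                            chrom, c - w // 2, c - w // 2 + w,
                            name=f"{label}_enh", score=10.0,
                        )
                    )
            planted_labels.append(frozenset(labels))
        for label in config.tf_labels:
            w = config.tf_peak_width
            pos = rng.integers(margin, genome[chrom] - margin,
                               size=config.n_decoy_peaks)
            tf_peaks[label].extend(
                GenomicInterval(chrom, int(p), int(p) + w,
                                name=f"{label}_decoy", score=2.0)
                for p in np.sort(pos)
            )

        # --- Broad acetylation peaks --------------------------------------
        for c in centers:
            c = int(c)
            signal = config.broad_signal_baseline * config.broad_signal_pvp_shift * (
                1.0 + 0.25 * rng.random()
            )
            broad_peaks.append(
                GenomicInterval(chrom, c - half_fp, c + half_fp,
                                name="enh_domain", score=round(signal, 3))
            )
        block_pos = rng.integers(
            margin, L - margin - config.background_block_width,
            size=config.n_background_blocks,
        )
        for p in np.sort(block_pos):
            p = int(p)
            block = GenomicInterval(
                chrom, p, p + config.background_block_width,
                name="bg_domain",
                score=round(config.broad_signal_baseline * (1.0 + 0.25 * rng.random()), 3),
            )
            # Background blocks must not graze a planted footprint, or the
            # "no PVP" truth label would be wrong.
            if footprints and any(block.overlaps(f) for f in footprints):
                continue
            broad_peaks.append(block)

        # --- Validation TF set (independent of map evidence) --------------
        has_val: list[bool] = []
        for c in centers:
            c = int(c)
            hit = rng.random() < config.validation_sensitivity
            has_val.append(hit)
            if not hit:
                continue
            w = config.validation_peak_width
            tf_peaks[config.validation_label].append(
                GenomicInterval(chrom, c - w // 2, c - w // 2 + w,
                                name="val_enh", score=8.0)
            )
            n_reads = rng.poisson(config.validation_reads_per_enhancer)
            core_lo, core_hi = c - vw // 2, c - vw // 2 + vw
            in_core = rng.random(size=n_reads) < config.validation_core_fraction
            n_core = int(in_core.sum())
            validation_reads.extend(
                _uniform_reads(rng, chrom, core_lo, core_hi, n_core,
                               config.read_length, L)
            )
            # Off-core reads spread over the peak flanks outside the core.
            n_off = n_reads - n_core
            peak_lo, peak_hi = c - w // 2, c - w // 2 + w
            left_w = max(core_lo - peak_lo, 0)
            right_w = max(peak_hi - core_hi, 0)
            flank_w = left_w + right_w
            if flank_w > 0 and n_off > 0:
                n_left = int(rng.binomial(n_off, left_w / flank_w))
                validation_reads.extend(
                    _uniform_reads(rng, chrom, peak_lo, core_lo, n_left,
                                   config.read_length, L)
                )
                validation_reads.extend(
                    _uniform_reads(rng, chrom, core_hi, peak_hi, n_off - n_left,
                                   config.read_length, L)
                )
        val_decoys = rng.integers(margin, L - margin,
                                  size=config.n_validation_decoy_peaks)
        for p in np.sort(val_decoys):
            p = int(p)
            peak = GenomicInterval(
                chrom, p, p + config.validation_peak_width,
                name="val_decoy", score=1.0,
            )
            # Decoys are placed clear of enhancers so the +-4 kb selection
            # has unambiguous truth.
            if footprints and any(
                peak.overlaps(GenomicInterval(chrom, f.start - 8000, f.end + 8000))
                for f in footprints
            ):
                continue
            tf_peaks[config.validation_label].append(peak)
            validation_reads.extend(
                _uniform_reads(rng, chrom, p, p + config.validation_peak_width,
                               rng.poisson(20.0), config.read_length, L)
            )

        # --- TSS, away from every enhancer --------------------------------
        placed = 0
        attempts = 0
        n_tss_chrom = config.n_tss // n_chroms + (
            1 if sorted(genome).index(chrom) < config.n_tss % n_chroms else 0
        )
        while placed < n_tss_chrom and attempts < 100 * max(n_tss_chrom, 1):
            attempts += 1
            p = int(rng.integers(0, L))
            if footprints and any(
                f.start - config.tss_exclusion <= p < f.end + config.tss_exclusion
                for f in footprints
            ):
                continue
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss_records.append(Tss(chrom, p, f"G{gene_counter:04d}", strand))
            placed += 1

        # --- TADs: partition the chromosome -------------------------------
        if isinstance(config.tad_breakpoints, int):
            n_bp = config.tad_breakpoints
            bps = np.sort(rng.integers(1, L, size=n_bp)) if n_bp > 0 else np.empty(0, int)
        else:
            bps = np.sort(np.asarray(config.tad_breakpoints, dtype=np.int64))
        bounds = [0, *[int(b) for b in np.unique(bps) if 0 < b < L], L]
        for i in range(len(bounds) - 1):
            tads.append(
                TadDomain(
                    GenomicInterval(chrom, bounds[i], bounds[i + 1]),
                    label=f"{chrom}_tad{i + 1}",
                )
            )

        for c, labels, hit in zip(centers, planted_labels, has_val):
            c = int(c)
            enhancers.append(
                PlantedEnhancer(
                    chrom=chrom,
                    center=c,
                    core=GenomicInterval(chrom, c - vw // 2, c - vw // 2 + vw),
                    shoulder_enrichment=config.shoulder_enrichment,
                    has_validation_peak=hit,
                    tf_labels=labels,
                )
            )

    reads = {
        "H3K27ac": sorted(h3k27ac),
        config.validation_label: sorted(validation_reads),
    }
    return SyntheticLandscape(
        config=config,
        enhancers=enhancers,
        tss=TssAnnotation(tss_records),
        tads=tads,
        reads=reads,
        broad_peaks=sorted(broad_peaks),
        tf_peaks={k: sorted(v) for k, v in tf_peaks.items()},
    )


def gaussian_pvp_coverage(
    chrom: str,
    center: int,
    gap: int = 390,
    amplitude: int = 200,
    sigma: float = 100.0,
    baseline: int = 2,
) -> CoverageTrack:
    """Smooth two-summit coverage profile with a designed half-point gap.

    Two Gaussian shoulders are positioned so the half-maximum crossings sit
    exactly ``gap`` bp apart around ``center`` — the continuous analogue of
    the piecewise-constant landscape, used to exercise half-point extent
    measurement on realistic smooth profiles.
    """
    hwhm = sigma * math.sqrt(2.0 * math.log(2.0))
    mu_l = center - gap // 2 - hwhm
    mu_r = center + gap // 2 + hwhm
    lo = int(mu_l - 5 * sigma)
    hi = int(mu_r + 5 * sigma) + 1
    x = np.arange(lo, hi)
    depth = baseline + amplitude * (
        np.exp(-0.5 * ((x - mu_l) / sigma) ** 2)
        + np.exp(-0.5 * ((x - mu_r) / sigma) ** 2)
    )
    depth = np.round(depth).astype(np.int64)
    # Compress the per-base array into constant-depth runs.
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate([[0], change]) + lo
    ends = np.concatenate([change, [len(depth)]]) + lo
    vals = depth[starts - lo]
    keep = vals > 0
    return CoverageTrack({chrom: (starts[keep], ends[keep], vals[keep])})


def emit_fixture_files(landscape: SyntheticLandscape, out_dir: str | Path) -> dict[str, Path]:
    """Write the landscape as plain-text fixture files readable by the core I/O.

    Emits reads (BED3), broad peaks (broadPeak), one narrowPeak per TF
    label, TSS (BED6), TADs (BED3), chrom.sizes, a truth table (TSV) and
    the config (JSON). Deterministic: same landscape, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for label, reads in landscape.reads.items():
        p = out / f"reads_{label}.bed"
        write_intervals(reads, p, dialect="bed3")
        paths[f"reads_{label}"] = p

    p = out / "h3k27ac_broad.broadPeak"
    with open(p, "w") as fh:
        for i, peak in enumerate(sorted(landscape.broad_peaks)):
            fh.write(
                f"{peak.chrom}\t{peak.start}\t{peak.end}\t"
                f"{peak.name or f'peak{i + 1}'}\t0\t.\t{peak.score or 0}\t-1\t-1\n"
            )
    paths["broad_peaks"] = p

    for label, peaks in landscape.tf_peaks.items():
        p = out / f"tf_{label}.narrowPeak"
        with open(p, "w") as fh:
            for i, peak in enumerate(sorted(peaks)):
                fh.write(
                    f"{peak.chrom}\t{peak.start}\t{peak.end}\t"
                    f"{peak.name or f'{label}_{i + 1}'}\t0\t.\t"
                    f"{peak.score or 0}\t-1\t-1\t{len(peak) // 2}\n"
                )
        paths[f"tf_{label}"] = p

    p = out / "tss.bed"
    with open(p, "w") as fh:
        for t in landscape.tss:
            fh.write(f"{t.chrom}\t{t.position}\t{t.position + 1}\t{t.gene}\t0\t{t.strand}\n")
    paths["tss"] = p

    p = out / "tads.bed"
    write_intervals([d.interval for d in landscape.tads], p, dialect="bed3")
    paths["tads"] = p

    p = out / "chrom.sizes"
    write_genome_table(landscape.genome, p)
    paths["chrom_sizes"] = p

    p = out / "truth_enhancers.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tcenter\tcore_start\tcore_end\tshoulder_enrichment\t"
                 "has_validation_peak\ttf_labels\n")
        for e in landscape.enhancers:
            fh.write(
                f"{e.chrom}\t{e.center}\t{e.core.start}\t{e.core.end}\t"
                f"{e.shoulder_enrichment}\t{int(e.has_validation_peak)}\t"
                f"{','.join(sorted(e.tf_labels))}\n"
            )
    paths["truth"] = p

    p = out / "config.json"
    p.write_text(landscape.config.to_json() + "\n")
    paths["config"] = p
    return paths
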