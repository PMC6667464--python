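# Methods

## Model

H3K27ac marks the nucleosomes flanking an active, factor-bound enhancer,
so in ChIP-seq coverage an enhancer shows a peak-valley-peak (PVP) shape:
two read-rich shoulders around a nucleosome-depleted, read-poor valley.
The null model is that reads are placed uniformly. Conditional on the
n = VR + SR reads that fall in a valley (size VS) plus one shoulder
(size SS), each read lands in the valley independently with probability
p = VS/(VS + SS); the side score is the binomial CDF P(X ≤ VR). The test
is one-sided by design — only depletion of the valley relative to the
shoulder is evidence.

Valley sizes are enumerated over {250, 300, 350, 400} bp and shoulder
sizes over {300, 400, 500} bp, 12 combinations per side; the minimum p per
side is the side score and the **maximum** of the two side scores is the
final valley score. Taking the max means a valley is only as good as its
weaker shoulder: a cliff (one enriched side) never scores well. The two
sides optimize their valley size independently; tying the valley size
across sides was the other defensible reading, and it would only make
scores (weakly) larger. The minimum-over-geometries construction makes the
score conservative as a p-value (it is a minimum of 12 dependent p-values
capped by the other side's maximum); we treat it as a ranking score, not a
calibrated tail probability, and the null-calibration test below checks
its practical behaviour empirically.

### Read-to-region assignment

A read is assigned to exactly one position, its midpoint
⌊(start + end)/2⌋. This prevents a read straddling a valley/shoulder
boundary from being counted in both regions, which would inflate the
binomial trial count. Reads are not extended to fragment length first;
with typical fragment sizes (~200 bp) and shoulder sizes ≥ 300 bp the
midpoint convention shifts counts by at most a few reads per boundary.

### Scan and de-overlap

Candidate anchors slide at a fixed step (default 50 bp) across each
H3K27ac broad peak; valleys are only expected inside broad acetylation
domains, and restricting the scan there bounds the work. Per broad peak,
calls are de-overlapped by greedy best-first non-maximum suppression on
the valley intervals: accept in ascending final-score order, reject any
call whose valley overlaps an accepted one. Anchors whose geometry does
not fit inside the chromosome are skipped (not clamped); geometries that
fall off an edge are excluded from the per-side minimum. An anchor with no
fitting geometry on either side is unscorable and never ranked. Valley
intervals are centered on the anchor; odd sizes put the extra base on the
left.

Selection of confident valleys is explicit: either a score threshold
(`--max-pvalue`, default 1e-6) or a rank cut (`--top-n`). A manual
rank-and-inspect cut cannot be automated, so both knobs are exposed and
the choice is recorded in the run metadata.

## Map assembly

1. **TF union** — all transcription-factor peak sets are merged
   (overlapping and bookended intervals fuse); each merged region records
   every contributing dataset label.
2. **Broad-peak filter** — regions overlapping any H3K27ac broad peak by
   ≥ 1 bp survive and inherit the maximum overlapping signalValue. The
   1-bp rule is the permissive reading; a fractional-overlap variant is a
   parameter away but is not the default.
3. **PVP merge** — the selected valleys are unioned in; a merged record's
   PVP flag is the OR, labels the union, signal the max.
4. **TSS filter** — records closer than 1 kb to any transcription start
   site are removed. Distance is interval-to-point with base-gap
   semantics (a TSS just past the end of a record, position = end, is at
   distance 1). Exactly 1 kb is retained; a record containing a TSS
   (distance 0) is always removed, even at radius 0.

Coordinates are 0-based half-open throughout; sorting ties break by
(chrom, start, end) for determinism.

### Half-point extent

The width of the nucleosome-depleted region is measured on coverage as the
span between the half-maximum crossings of the two flanking peaks: per
side, the summit is the maximum depth within 1 kb of the valley center
(left side takes the first maximum, right side the last, so plateau
summits resolve away from the valley); walking from each summit toward the
valley, the half-point is the first base whose depth falls below half the
summit depth, and the reported extent is the half-open span between the
two crossings. No smoothing is applied before summit detection — coverage
from merged replicates is treated as piecewise-constant; a worked
rectangle (shoulders of depth 20 around a valley of depth 2) yields
exactly the 400-bp span between its steps. Records whose flanking summits
have zero depth get no extent. Downstream validation uses a canonical
enhancer span: the per-record extent when available, otherwise a fixed
390-bp window (the genome-wide mean extent) centered on the record
midpoint.

## TAD candidates and validation statistics

TADs are consumed from a BED file; Hi-C processing and TAD calling are out
of scope. For a gene, the TAD containing its TSS is used (smallest if
domains nest). Map records overlapping the TAD by ≥ 1 bp are the
candidates, ranked by lexicographic evidence: PVP flag, then number of
distinct supporting TF sets, then summed read enrichment
(reads/kb/million) over the supplied tracks. The breakdown is always
written out so users can re-rank under their own weighting; "evidence
strength" has no canonical definition and the lexicographic order is this
package's explicit choice.

**Read-concentration test.** Peaks of an independent TF dataset within
±4 kb (nearest-edge base distance) of any canonical enhancer span are
selected. With U the union of selected peaks and E the union of canonical
spans, k of the n reads (midpoints) in U fall in U ∩ E; under uniform
placement each read lands there with p0 = |U ∩ E| / |U|, and the test
reports the fraction k/n and the upper tail P(X ≥ k | n, p0). The
length-proportional p0 is the natural uniform null within the selected
peaks.

**PVP signal comparison.** Broad peaks containing at least one selected
valley versus the rest, compared on signalValue by a two-sided
Mann-Whitney U test (statistic, p, group medians).

## Synthetic landscapes

The generator emulates exactly the structure the detector assumes, which
is what makes its tests sharp and also bounds what they show.

* **Reads** are fixed-length intervals with midpoints uniform in their
  compartment; compartment counts are independent Poisson draws, so the
  profile is an inhomogeneous Poisson process with a piecewise-constant
  rate: background 0.05 reads/bp (a deeply sequenced merged library on a
  10-Mb chromosome), shoulders enriched 30-fold over 400 bp each side,
  valleys depleted 5-fold over a 390-bp core (the canonical
  nucleosome-free width). Background reads are thinned out of enhancer
  footprints so compartment rates are exact, not additive.
* **Planted enhancers** (default 20) are spaced ≥ 2 × (valley + shoulder)
  apart and ≥ 2 kb from every TSS, so all planted enhancers are
  promoter-distal by construction.
* **TF peaks** cover each enhancer with probability 0.9 per label, plus 50
  uniformly placed decoys per label. Broad acetylation domains cover each
  enhancer ± shoulder; background broad domains (80 blocks of 2 kb, placed
  clear of enhancer footprints) carry baseline signalValue while
  enhancer domains carry a 2-fold shifted signal.
* **A validation TF set** (1-kb peaks over 80% of enhancers, decoys kept
  ≥ 8 kb away) emits reads of which 85% fall in the 390-bp core — the
  concentration structure the read-concentration test is designed to
  detect, with p0 = 390/1000 = 0.39 for a fully overlapping peak.
* **TADs** partition each chromosome at random breakpoints; **TSSs** are
  uniform outside exclusion zones.

What the generator does *not* model: fragment-length variation, mappability
and GC bias, copy-number variation, replicate structure, or smoothed
summit shapes (a separate two-Gaussian profile generator with a designed
half-point gap exists solely to exercise the extent measurement). Passing
tests therefore demonstrate correctness of the statistics and the pipeline
under the stated model, not robustness to real-data artifacts.

## Numerical choices

* The binomial CDF is evaluated through the regularized incomplete beta
  function (`scipy.special.bdtr`): stable for n up to 10^6 and beyond,
  and exact to < 1e-10 relative error against rational-arithmetic
  summation over the whole n ≤ 60 lattice (tested).
* n = 0 (no reads in valley + shoulder) returns p = 1: no evidence.
* Read ingestion for scanning accepts mapped-read BED (midpoints);
  bedGraph is supported for coverage (extent measurement) but not
  converted to pseudo-reads, since depth-to-read conversion would invent
  counts the binomial model treats as real trials.
* Reproducibility: one integer seed drives a single `numpy` Generator;
  identical config + seed give byte-identical fixture files and map
  outputs. Run-metadata JSON contains a wall-clock timestamp and is the
  one file excluded from byte-identity comparisons.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on simulated data:
a 10-Mb chromosome with 20 planted enhancers for the recovery and
concentration checks, 20 (suite) or 5 (script) null landscapes for
calibration, 100 random small tracks for oracle equivalence, and exact
rational arithmetic up to n = 60 for the statistic itself. These sizes
give stable pass/fail behaviour at comfortable margins while keeping a
full run in the low tens of seconds.

## Known limitations

* The valley score is a ranking score, not a calibrated p-value (minimum
  over a dependent geometry grid); no FDR is computed.
* The scan proposes anchors only inside broad peaks; enhancers outside
  called acetylation domains are invisible to the PVP stage (they can
  still enter the map through TF evidence).
* Replicates are expected pre-merged; there is no replicate-aware model.
* Candidate ranking is a heuristic ordering for experimental follow-up,
  not a posterior probability of enhancer function.
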