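# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention) internally; 1-based
inputs (cytosine reports, optional BED dialect) convert at the reader
boundary. "Overlap" means ≥ 1 shared base under half-open semantics unless a
`min_bp` parameter says otherwise; abutting intervals do not overlap. Sex
chromosomes stay in the data model and are excluded by a pipeline-level
filter (`autosomes_only=True` by default in `run_dynamics`/`run_ndr`),
since PRDM9's role on them differs from autosomes and the analysis is
defined on autosomes.

## Peak turnover classification

De novo status at a target stage means zero ≥ 1 bp overlaps with any peak of
the same mark at any configured prior stage. The pipeline's default prior
set for the mid-zygotene split is the premeiotic series (Undiff, A1, B,
mpL), not all strictly earlier stages: marks appearing at leptotene and
persisting into mid-zygotene are still PRDM9-derived de novo marks, and
the early-forming class would otherwise be empty by construction.

The presence matrix evaluates each hotspot-associated mid-zygotene peak
against the peak sets of L, mZ, lZ and e1P with the same overlap predicate.
Classification reads each row as a turnover history; leptotene presence
dominates (early-forming regardless of later columns), and the three
remaining classes are the strictly-nested disappearance patterns. A row
that disappears and reappears (0,1,0,1) fits no class and is reported as
`unclassified` rather than forced — only four patterns are defined, and the
count partition (four classes + unclassified = all labeled peaks) is
asserted in `DynamicsReport`.

## H3K9me2 dips

For a hotspot of width w, flanks are [start − 2w, start) and [end, end + 2w),
clipped at chromosome ends (the truncated span is used; a single surviving
flank is used alone). The hotspot is a dip when inside mean density ÷ mean
of flank means < 0.5. The published criterion — hotspot density "less than
twice" its flanks — is read literally almost always true; the 0.5 ratio
expresses the evident intent (flanks at least twice the hotspot) and the
threshold is an exposed parameter (`ratio_threshold`). Zero-signal flanks
make the ratio undefined and the hotspot is skipped, never silently passed.

## Spatial association test

`fisher_overlap_test` tiles the genome into non-overlapping bins (default
1 kb), scores each bin for ≥ 1 bp overlap with each set, and applies
Fisher's exact test (two-sided) to the 2×2 bin counts. The construction
assumes bin-level independence; features spanning several bins correlate
adjacent bins and make the test anticonservative, which is why the null
calibration check draws features inside distinct tiles. No multiple-testing
correction is applied anywhere in the package: significance decisions use
the fixed thresholds of the underlying definitions.

## NOMe-seq model

Context classification is strand-resolved: WCG = ACG/TCG (endogenous CpG
methylation), GCH = GCA/GCC/GCT (M.CviPI accessibility signal). GCG and CCG
are ambiguous between the two signals and are excluded entirely. Site level
is methylated reads ÷ all detected reads; the 3× depth cutoff applies per
site before any window or region statistic. Replicate tables merge by
summing counts per site.

The NDR caller slides a 100-bp window at a 20-bp step from coordinate 0 of
each chromosome (the trailing window is clipped). Each window's pooled
(meth, unmeth) GCH counts are tested against the pooled whole-genome
counts in a 2×2 χ² with df = 1 and no continuity correction. The published
criterion tests the *average level*, which is not directly a χ² quantity;
pooled counts are the standard realization, and the "higher than
background" direction is enforced by assigning p = 1 to any window whose
unweighted mean site level is at or below the genome mean (also to empty
windows and degenerate margins). Significant windows (p ≤ 10⁻¹⁰) merge when
overlapping or bookended; merged regions are kept iff they hold > 5 GCH
sites and span > 140 bp, both measured on the merged region. Every emitted
record re-satisfies all three criteria by construction, and tightening
`p_max` can only shrink calls (each tighter call lies inside a looser one).

TSS proximity is strand-agnostic and symmetric: an NDR is proximal iff its
coordinate gap to the nearest TSS is ≤ 1.5 kb (an NDR edge exactly 1.5 kb
away is proximal on either side). A hotspot is "within" an NDR iff its
center base lies inside the NDR interval. Region levels are unweighted
means of site levels and are undefined (NaN, never zero) below 3 sites;
accessibility ratios divide by the genome mean GCH level. The genome mean
uses sequential (cumsum-order) summation so that the whole genome queried
as a region returns a ratio of exactly 1.0.

## Signal tracks

Fragment records are single-end style (chrom, 5′ position, strand),
extended 150 bp 3′-ward — the average sonicated chromatin length — and
accumulated at base resolution before re-binning into 50-bp bins. Partial
bins therefore receive fractional mass and total track mass equals the sum
of clipped fragment lengths exactly. Spike-in factors use the
minimum-count sample as reference (factorₛ = min counts ÷ countsₛ), scaling
samples down rather than inflating sparse ones. Matrix columns falling even
partly off-chromosome are missing (NaN), not zero, so edge regions never
dilute profiles; profiles are per-column means over non-missing entries.
`region_mean_density` is the length-weighted mean of bin values over the
(clipped) interval.

## Simulator

The generator's defaults define the study conditions at desk scale:

- genome: 3 autosomes × 2 Mb;
- classes: 27 early-forming / 24 fast-turnover / 10 slow-turnover /
  40 persistent, a 100× scale-down of the study-scale class ratio
  (≈ 2700 : 2369 : 1036 : 4032);
- class width means 2000/800/1100/1400 bp (early > persistent > slow >
  fast, echoing the ~2 kb early-forming vs < 1 kb fast-turnover contrast),
  CV 0.15, per-stage edge jitter ± 40 bp;
- hotspots: 150 × 300 bp with gamma(0.8, 10) strengths (heavy-tailed);
- NOMe: GCH sites every 10 bp, WCG every 50 bp, depth 3 + Poisson(7),
  planted 400-bp NDRs at Beta-mean GCH 0.5 over 0.05 background
  (concentration 50), WCG background 0.75;
- signal: 40 000 fragments per stage, 10 % uniform background, peak
  fragments proportional to strength, spike counts Poisson(10 000).

All features draw their centers from one deterministic grid of slots spaced
wider than the widest possible feature, partitioned among hotspots, TSS,
distractor peaks and NDRs. Planted features therefore never collide, which
is what makes exact label recovery a meaningful structural check of the
analysis chain rather than a statistical accident. Each component (slots,
genome, hotspots, peaks, NOMe, signal) uses its own RNG stream derived from
the master seed by hashing the component name, so adding or reconfiguring
one component never perturbs the draws of another.

What the simulator does *not* emulate — and what passing tests therefore do
not show about real data: irregular CpG/GpC site density and mappability
gaps, bisulfite conversion error, fragment-length variation, peak-caller
boundary noise beyond the fixed jitter, overlapping or nested features
(real promoter peaks do overlap hotspots), replicate batch effects, and
inter-chromosomal heterogeneity. Planted NDRs sit on their own slots, so
the default bundle's hotspot-in-NDR fraction is ~0 by design; the
accessibility-ratio calibration plants accessibility directly on hotspot
intervals instead.

## Problem sizes and numerical choices

Analyses run comfortably at the default scale (6 Mb genome, ~600 k GCH
sites, 300 k scan windows, 500-replicate null simulations); the full test
suite and the acceptance script each finish in well under a minute of
compute. Window statistics are vectorized with cumulative sums over
position-sorted site arrays; the windowed χ² p-values match
`scipy.stats.chi2_contingency(correction=False)` on the same tables to
relative 1e-9 (asserted against a brute-force enumeration oracle).
Ranking ties in `matrix_around` keep input order (stable sort). Degenerate
inputs are explicit: empty hotspot sets warn and return empty associations,
zero-variance t-test groups report p = 1 (identical) or p = 0 (separated)
rather than dividing by zero, and undefined levels propagate as NaN.

## Known limitations

- The de novo definition is binary at ≥ 1 bp; a minimum-overlap-fraction
  option exists but defaults off since no fraction is published.
- The χ² window test can also be run on pooled counts only; a site-mean
  proportion variant is not implemented because pooled counts are the
  standard realization and the published choice is unstated.
- `overlap_summary` counts membership patterns of the first (reference)
  set only; three-way Venn counts therefore depend on the reference choice,
  which is documented rather than hidden.
- The CLI covers simulate/dynamics/ndr; matrix export and dip scans are
  library calls (see `examples/03`, `examples/04`).
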