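# Methods

## The measurement

A seed-typing experiment measures meiotic crossovers (COs) inside a short
interval (tens of kb) flanked by two seed-expressed fluorescent reporters
on the same chromosome.  Two quantities come out of it:

1. **Genetic length** of the interval, from F2 seed colors.  Single-color
   seeds (green-only, `G-/--`, or red-only, `--/-R`) derive from a
   recombinant gamete, so `RF = 100 × (N_G + N_R) / N_T` estimates the
   interval's genetic length in cM.  No map-function correction is applied:
   with r well below 0.01 the Haldane/Kosambi corrections are far smaller
   than sampling noise.
2. **CO positions**, from amplicon sequencing of selected single-color
   recombinants.  Each recombinant is heterozygous on one side of its CO
   and homozygous on the other, so the breakpoint is the transition in its
   per-marker genotype vector.

Note that the single-color seed probability is not r/2 per color: a seed is
green-only only if *neither* gamete carries the red reporter, giving
p = r²/4 + r(1−r)/2 per color and an expected single-color fraction of
r − r²/2.  The seed-count simulator and its calibration test use this exact
form (the distinction is a ~0.25% relative effect at r = 0.005, invisible
in practice but free to get right).

## Genotyping and filtering

Genotypes are called from the reference-read fraction f = ref/(ref+alt):

| condition           | call     |
|---------------------|----------|
| depth < 30          | NOCALL   |
| f ≥ 0.9             | HOM_REF  |
| f ≤ 0.1             | HOM_ALT  |
| 0.3 ≤ f ≤ 0.7       | HET      |
| otherwise           | NOCALL   |

The 30-read floor mirrors the coverage filter applied to the amplicon data;
the band edges are a design choice (the source analyses compared read
percentages without publishing exact bands) picked to be unambiguous at
~1500× and conservative at the 30× floor.  All five numbers are
configurable.  Marker-level quality control drops markers whose cohort
median depth is below the floor or whose NOCALL rate exceeds 20%
(`max_fraction_nocall`); upstream base-quality filtering is assumed to have
happened during variant calling and is out of scope.

Marker thinning keeps SNPs at a minimum spacing by a greedy left-to-right
scan (first SNP always kept).  The defaults follow the two interval styles:
100 bp for dense ~26-kb intervals, 400 bp for sparser ~50-kb ones.  InDels
never enter the CO topology; they count toward polymorphism density only.

## Breakpoint detection

The published analyses designated breakpoints manually; `seedtyper`
replaces that with a deterministic, auditable rule.  Per sample: drop
NOCALLs, run-length encode the remaining states, and absorb any run shorter
than `min_flank` (default 2) into its neighbors — merging a short run
flanked by two same-state runs (an error burst), or a short edge run into
its single neighbor.  Then:

* exactly two runs, both ≥ `min_flank`, one of them HET → **OK**; the
  breakpoint is the interval between the last marker of the first run and
  the first marker of the second, reported with its midpoint and direction
  (e.g. `HET->HOM_ALT`);
* one run → **NO_TRANSITION**;
* more than two runs, or a HOM_REF/HOM_ALT pair (which would require two
  COs between adjacent markers) → **MULTIPLE_TRANSITIONS**;
* fewer than `2 × min_flank` informative markers → **INSUFFICIENT_MARKERS**.

A short run lying between two *different* states is deliberately not
absorbed: collapsing it either way would silently pick one of two
conflicting breakpoints, so the sample fails QC instead.  Failed samples
stay in the output with their status, making success-rate accounting
(n_ok / n_attempted) reproducible from the result table alone.

## Landscapes, hotspots, sections

Raw CO counts are not comparable across cohorts, so landscapes are
normalized to the seed-scored genetic length: each OK call carries
`total_cM / n_ok`, spread uniformly over its bracketing marker interval
when binning (bins then respect mapping resolution), and the binned values
are divided by bin width in Mb.  The landscape integrates to `total_cM`
exactly by construction (the conservation test requires 1e-9).  Hotspot and
section membership instead uses the breakpoint midpoint — a single decision
per call — so shares are bin-width independent and sum to 1 over a tiling
partition.  Hotspot activity is `share × total_cM / length_Mb`.

Two-cohort section comparison (wild type vs a mismatch-repair mutant)
computes each cohort's per-section activity from its own normalized rate,
excludes sections with zero COs in either cohort, and correlates
polymorphism density (SNPs+InDels/kb by default; a flag switches to SNPs
only) with relative activity (mutant/wild type) using Spearman's rho.  The
two-sided p-value uses the t approximation
`t = ρ·√((n−2)/(1−ρ²))` on n−2 df; at n = 10 this reproduces published
section-analysis p-values to the printed digit, and the test suite bounds
its error against full permutation enumeration at small n.  Fewer than
three retained sections is an error rather than a meaningless correlation.

Percent heterozygosity of introgression lines is the summed length of
heterozygous blocks over a 125-Mb genome.

## The simulator

The generator emulates the study conditions: a 26.3-kb interval at 18.7
polymorphisms/kb (~10% InDels), three separated hotspots of 8.8/4.6/3.4 kb
carrying roughly 32/60/8% of COs over a weak uniform background, cohorts of
~250–300 single-CO recombinants, Poisson read depth with mean 1500,
symmetric per-read miscalls (default 0.5%), and seed populations of
3000–5000 seeds with r ≈ 0.005.  Marker positions are i.i.d. uniform by
default; an optional blockwise density profile emulates the
polymorphism-free patches of real intervals and drives the
density-coupling studies.  `density_coupled_weights` multiplies each
hotspot weight by `(1 + coupling × local density/kb)` and rescales to
preserve the summed hotspot weight, so coupling redistributes COs among
hotspots without changing the hotspot/background split.

Orientation of selected recombinants (HET→HOM vs HOM→HET) defaults to
50/50; the empirical split among selected seeds is not published, and the
parameter is exposed (`p_het_to_hom`) rather than guessed silently.  The
homozygous side is the non-reporter parent's genotype (HOM_ALT), matching
the selection scheme.  CO positions that would fall outside the marker span
(undetectable by construction) are redrawn, so every truth genotype vector
has exactly one transition; with study-like marker densities this affects
a negligible edge fraction of draws.

What the simulator does **not** model — PCR chimeras, gene-conversion
tracts, mapping artifacts at InDels, depth heterogeneity along amplicons,
double COs — bounds what passing tests show: they validate the estimators
and the detection logic under the stated noise model, not robustness to
every artifact of real libraries.  Double COs, if present in real data,
surface as MULTIPLE_TRANSITIONS QC failures rather than silently wrong
calls.

All randomness flows from one recorded seed; independent sub-streams per
operation are derived from (seed, operation-salt) pairs, so outputs are
bit-reproducible and adding an operation does not shift another's stream.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; VCF is 1-based and BED
  0-based at the file boundary.  Region membership is half-open.
* Group percentiles use linear interpolation between order statistics (the
  most common convention; the published figures do not state one).
* Welch's t-test (unequal variances, Welch–Satterthwaite df) is used for
  group comparisons; p-values are reported unadjusted, matching how
  pairwise comparisons are usually reported for these measurements.
* Outputs carry the tool version and a configuration hash; re-runs with the
  same inputs are byte-identical (no timestamps).
* Test and acceptance problem sizes (cohorts of 298–500, 2000 seed-count
  replicates, 100 landscape/section replicates) were chosen as the smallest
  sizes at which the checked properties are statistically sharp.

## Known limitations

* Genotyping is threshold-based, not likelihood-based; at depths near the
  30-read floor the HET band is wide by design and ambiguous calls become
  NOCALLs rather than soft calls.
* Breakpoints are only localized between informative markers; resolution
  degrades in polymorphism-free patches and after aggressive thinning.
* The section comparison assumes both cohorts share one marker map and
  interval; comparing across accessions with structural differences (e.g.
  deletions spanning a hotspot) requires mapping both to the same reference
  coordinates upstream.
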