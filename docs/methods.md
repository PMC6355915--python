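# Methods

This note records the models the package implements, the conventions
and defaults it fixes where the underlying methodology leaves choices
open, what the synthetic-data generator does and does not emulate, and
the numerical decisions that affect results.

## Coordinates and coverage model

All internal coordinates are 0-based, half-open (BED convention); GTF
input is converted at the parsing boundary. "Upstream" and
"downstream" are strand-aware relative to a gene's TSS/TES. Coverage
is run-length encoded per contig; window sums are computed from
segment integrals, so windowed means are exact regardless of how the
signal was split into intervals on disk, and bases outside any
interval read as 0. Writing and re-reading a bedGraph reproduces the
signal function exactly (zero-valued and uncovered bases are
equivalent). narrowPeak summit offsets of −1 map to the interval
midpoint; this is a dialect decision and can be tightened to an error.

Genes may carry several annotated transcript starts. Selection among
them — for the PRR and for the pausing-index bound call — maximizes
the mean control-condition signal over TSS ± 250 bp, with exact ties
going to the 5′-most candidate so the choice is deterministic.

## Spike-in calibration

The per-library normalization factor is spike-in reads per million
experimental-genome reads; `calibrate_track` divides signal by it, for
IP and input libraries alike. The factor itself is depth-invariant (a
ratio of two counts that scale together), so dividing a raw-count
track by it does not remove depth effects; `depth_normalize=True`
first converts to counts per million experimental reads, making the
combined scaling counts-per-spike-in-read, which is invariant to
sequencing depth at a fixed spike-in chromatin fraction. Use that
variant when comparing conditions; the plain variant is for tracks
already depth-normalized upstream. A zero experimental or spike-in
count leaves the factor undefined and raises rather than silently
producing 0 or infinity.

Enrichment tracks are log2((IP + p)/(input + p)) with a symmetric
pseudocount p = 0.01 signal units, which keeps enrichment finite and
exactly antisymmetric under swapping IP and input. Ratios are computed
exactly on the merged run-length segmentation by default; a
`bin_width` option averages both tracks over fixed-width bins first.
The binned mode is coarser but smaller; the exact mode is what the
oracle tests check against. `ratio_normalize` is the linear-ratio
variant (e.g. a histone mark over nucleosomal occupancy) used upstream
of window quantification; note that bases covered by neither track
remain uncovered (read 0), so its output is meaningful only where at
least one input has signal.

## PRR

Windows: TSS window = TSS ± 250 bp; body = TSS + 500 to TES − 500,
mirrored on the minus strand. A gene whose body window is empty is
marked ineligible rather than erroring, and genes at the signal floor
(0.01) in both windows are dropped as "no signal" — the floor avoids
±∞ log-ratios without reordering genes. The statistic is computed on
linear enrichment (or nascent coverage), never on log-scale tracks.
Because it is a log-ratio of means of one track, any uniform positive
rescaling — in particular the calibration factor — cancels exactly.

Condition comparisons use the two-sample KS test on the genes eligible
in both conditions (exact null below n = 30 per sample, asymptotic
otherwise; fewer than 10 shared genes flags the result low-power).
Quartile stratification splits genes at the 25/50/75 percentiles of
the reference values (control PRR, low to high); values exactly on a
boundary fall in the lower quartile, so the split is deterministic
under ties. Intron-size stratification bins genes by largest intron
(default breaks: quartiles of largest-intron size among the analysed
genes, since no canonical break set exists) and compares classes with
one-way ANOVA, excluding empty classes. The bound-vs-unbound window
change test uses Welch's (unequal-variance) t-test — the conservative
choice when only "two-sample t-test" is specified — with the
degenerate identical-tracks case reported as t = 0, p = 1 by
convention rather than NaN.

## Wave-front detection and elongation rates

Genes longer than 10 kb are binned at 100 bp over 20 kb downstream of
the TSS; bins extending past the gene end are masked invalid, and
profiles with fewer than 20 valid bins are flagged. The profile is
smoothed with a centered 5-bin rolling mean; the detector enumerates
local minima within 5% of the smoothed range above the global minimum
and takes the most upstream — the position where signal first bottoms
out at background. Two corrections matter:

1. A centered rolling mean of width w delays the floor onset of a
   falling edge by w//2 bins; that shift is subtracted in the
   `refine='none'` variant.
2. The floor onset itself sits systematically downstream of the
   midpoint of any non-vertical falling edge (for the logistic edges
   the generator produces, by ~300 bp at the default edge scale).
   The default `refine='halfmax'` therefore walks upstream from the
   floor onset to where the smoothed profile crosses halfway between
   the plateau level (90th percentile of pre-onset bins) and the
   floor, interpolating between bins. For a symmetric edge this
   midpoint is an unbiased front estimate; on a noiseless step both
   variants agree to within one bin.

Flat or monotone profiles have no defined front and are flagged, not
guessed. Rates are (front₈ − front₂)/6 min by default; other timepoint
pairs are accepted but 2→8 min is the headline estimate. A front that
moved upstream between timepoints is reported as a regressed-front
flag with a missing rate. Both the mean and the median across genes
are reported, since pooling versus per-gene averaging is a genuine
choice; on synthetic data they agree closely. Any constant bias in
front placement cancels in the two-timepoint difference, which is why
rate recovery is more robust than absolute front placement.

## Metagene profiles

Scaled profiles use fixed per-base flanks (600 bp default) and a body
rescaled to 100 bins by exact fractional-overlap mean pooling (via the
cumulative integral), making the profile linear in the track and
independent of how gene length divides the bin count. SEM is across
genes per position (ddof = 1; defined as 0 for a single gene); it is
not an across-replicate error. Flanks running past the covered contig
extent are zero-padded and tallied. Heatmap rows sort by decreasing
mean of the sort track over TSS ± 250 bp with gene-id tie-break.

## Target assignment and bound calls

Peak-to-gene distance is summit-to-TSS (promoter-centric binding), not
summit-to-gene-body; a summit exactly equidistant between two TSSs is
assigned to both genes rather than dropped, and peaks on contigs
without genes are warned and skipped. The 2.0-fold enrichment cutoff
is applied as a post-filter on the narrowPeak fold-enrichment column.
The pausing-index bound call is strict (mean TSS-window enrichment
> 1.3, not ≥), as is the expressed-gene rule (mean control RPKM > 1).
Inputs must share one gene-ID namespace; no ID conversion is
performed.

## Synthetic-data generator

The generator emulates, on one synthetic contig with Poisson count
noise on 10 bp bins: non-overlapping genes with log-normal lengths
(default ln-scale μ = 9, σ = 0.8; or a requested fraction over 10 kb)
and log-normal largest-intron sizes; IP tracks as a promoter Gaussian
(sd 100 bp) of per-gene log-normal strength over a gene-body plateau
and flat background, against an input that is flat at the IP's
genome-wide mean rate — i.e. an input library of the same total depth,
which is the realistic sequencing design and what makes TSS-window
input means well measured; spike-in read fractions in the library
stats; post-DRB waves advancing at a configurable rate with a logistic
front edge (scale 50 bp, ≈ 2 bins wide) rather than a degenerate hard
step; and narrowPeak calls over a planted bound subset plus sub-cutoff
decoys. Each simulated quantity's ground truth (expected PRR from the
expectation profile, front positions, the bound set) is recorded at
generation time. All randomness derives from one seed plus stable
per-condition offsets; identical configs produce byte-identical output
files.

One arithmetic consequence of the construction: with no promoter peak
the expected PRR is not exactly 0 but ≈ log2((bg + body)/(bg + body/2))
(+0.87 at the defaults), because half the TSS window lies upstream of
the gene at background level. The estimator matches the analytic truth
either way (median |error| ≈ 0.05 at the default depth), and condition
*differences* are unaffected.

What the generator does not emulate: read-level artefacts (duplicates,
mappability, GC bias), real gene-density and chromatin heterogeneity,
replicate structure, fragment-length effects, or DamID fragmentation.
Passing tests therefore demonstrate estimator correctness under the
assumed signal model, not robustness to every artefact of real
libraries.

## Problem sizes and tolerances

The test suite and the acceptance script run entirely on generated
data: PRR oracle checks on 50 genes at per-base exactness (1e-9); KS
sensitivity on 100 seeds × 500 genes (knockdown halves the promoter
peak; rejection at p < 0.01 expected in ≥ 95% of seeds); rate recovery
on 200 genes per true rate in {0.5, 1, 2} kb/min with a 50-counts/bin
plateau (mean within 10%); calibration depth-invariance at 3× depth
(median relative deviation a few percent, consistent with Poisson
counting); Fisher p enumeration over all 2×2 tables with N ≤ 20.
These sizes keep a full run around one minute while leaving the
statistical targets comfortably powered.
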