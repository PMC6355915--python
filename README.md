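# polpause

Analysis of RNA polymerase II promoter-proximal pausing from
spike-in-calibrated ChIP-seq and nascent-RNA (4sU/DRB) sequencing.

Metazoan Pol II frequently initiates and then stalls 20–60 nt
downstream of the transcription start site before being released into
productive elongation. `polpause` is a library for quantifying that
behaviour genome-wide, aimed at people analysing Pol II / CTD-phospho
ChIP-seq, MNase or histone-mark tracks, and DRB-synchronized nascent-RNA
time courses: it computes the Pol II release ratio, compares it across
conditions, estimates elongation rates from post-DRB wave fronts,
builds metagene profiles, and assigns factor peaks to target genes.

## The statistics at the core

**Pol II release ratio (PRR).** For a gene with transcription start
site TSS and end site TES (strand-aware), and a non-negative signal
track *s* (input-normalized ChIP enrichment or t0-normalized nascent
coverage),

```
PRR = log2( mean s over [TSS+500, TES−500) / mean s over [TSS−250, TSS+250) )
```

with both window means floored at a small pseudo-enrichment. Strongly
paused genes pile polymerase at the promoter and have low (negative)
PRR; release into the body raises it. Genes too short for a non-empty
body window are excluded. PRR distributions are compared across
conditions with a two-sample Kolmogorov–Smirnov test and stratified by
control-PRR quartile or largest-intron size class (one-way ANOVA).

**Spike-in calibration.** Each library is scaled by a normalization
factor, the number of reads mapped to the spike-in (reference) genome
per million reads mapped to the experimental genome; all libraries,
inputs included, are calibrated before enrichment is formed.

**Wave-front elongation rate.** After release from a DRB block, the
nascent-signal edge advances at the elongation rate. Per gene longer
than 10 kb, signal over the first 20 kb downstream of the TSS is
averaged into 100 bp bins, the wave front is located at each timepoint
(most upstream near-floor local minimum of the smoothed profile, refined
to the plateau/floor midpoint crossing), and

```
rate = (front at 8 min − front at 2 min) / 6 min        [bp/min]
```

**Target assignment.** Peaks below a 2.0-fold enrichment cutoff are
dropped; each surviving summit is assigned to the gene with the nearest
TSS; a factor complex's joint targets are the intersection of its
components' bound sets; class enrichment uses Fisher's exact test.

A synthetic-data generator (`polpause.simulate`) emulates all of these
signal structures with known ground truth, so every estimator is tested
end to end without external data.

## Worked example

`examples/01_release_ratio.py` simulates 500 genes in two conditions
where the knockdown halves the promoter peak, and runs the full PRR
comparison:

```
eligible genes in both conditions: 497
median PRR control: -1.181
median PRR knockdown: -0.481
two-sample KS: D = 0.398, p = 5.06e-36

PRR shift by control-PRR quartile (1 = most paused):
  Q1: median delta = +0.856 (n=125)
  Q2: median delta = +0.748 (n=124)
  Q3: median delta = +0.638 (n=124)
  Q4: median delta = +0.444 (n=124)
```

The knockdown raises the median PRR (less pausing, more release), the
KS test rejects distributional equality decisively, and the shift is
largest in the most strongly paused quartile — the expected signature
when a pausing factor is removed. The other scripts in `examples/`
cover elongation rates (`02`), metagene profiles and heatmaps (`03`),
peak-to-gene targets with Fisher enrichment (`04`), and spike-in
calibration across sequencing depths (`05`).

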