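# Methods

## Scope and model

The package implements the computational side of a transcription-inhibition
ChIP-seq study: given base-resolution coverage for IP/input pairs (RNAPII,
a histone acetyltransferase subunit, acetylation marks), stranded nascent
transcription, MNase nucleosome occupancy, and a gene/NDR/dyad annotation,
it (i) puts conditions on a common scale via transcriptionally silent
regions, (ii) classifies genes and nucleosomes by transcription, (iii) calls
sub-nucleosomal factor peaks in NDRs, (iv) stratifies genic nucleosomes into
nested RNAPII × predicted-occupancy quintiles, and (v) averages
feature-aligned profiles with PAS masking. All internal coordinates are
0-based half-open; 1-based conventions (fixed-step wiggle) exist only at
file boundaries.

## Normalization

RPGC scaling divides by the genome-wide mean over all non-excluded bases,
zeros included: "reads per genomic coverage" is a 1x normalization of the
whole genome, and which mean to use is the only genuinely open choice here —
including zero-coverage bases is the convention adopted (and documented)
throughout. Chromosome exclusion (an unstable chromosome in a truncation
strain, rDNA-bearing chrXII) is a config list applied at scaling time.

log2(IP/input) masks any base where the input — or the IP — is zero. The
zero-input rule avoids division by zero; the zero-IP rule is this package's
extension, because −∞ cannot participate in window means or averaged
profiles. Masked bases are NaN internally, are omitted from bedGraph output,
and windows more than half masked yield undefined scores.

Silent regions: 250 bp genome-wide bins; bins whose input mean falls outside
the closed interval [Q1, Q3] of the per-bin input distribution are dropped
(linear-interpolation quantiles; the closed interval keeps a degenerate
constant input fully usable); the 100 surviving bins with the lowest RNAPII
IP mean (raw-scale IP, not log ratio — the input filter already handles
coverage artifacts) are the silent set, ties broken by genomic position.
The per-bin statistic is the mean (sum and mean only differ at the trailing
partial bin). The silent set is computed once from the untreated
input/RNAPII pair and reused for every sample of the experiment; each
treated sample then gets factor = reference silent mean / sample silent
mean. Spike-in normalization is deliberately not implemented.

In the bundled pipeline, a treated track whose own silent mean is zero (the
simulated RNAPII IP is exactly zero there by construction) reuses the
factor derived from the acetylation pair: the generator applies one global
IP-efficiency distortion per condition, so one factor per condition is the
correct model.

## Classification

Windows are strand-oriented and half-open in transcription-direction
coordinates: offsets (0, 500) cover the 500 bases downstream of the TSS on
either strand. "Lowest quintile" uses a tie-inclusive cut: the cut value is
the round(n/5)-th smallest score and everything ≤ it is included. With
all-distinct scores this is exactly round(n/5) genes; with ties at the
boundary (e.g. many promoters with exactly zero upstream signal) the whole
tied group enters, which is what makes a planted all-or-nothing divergence
design exactly recoverable. The non-transcribed quintile is taken over all
genes; the unidirectional quintile over transcribed genes only — with ~5200
genes this arithmetic yields the ≈830 unidirectional promoters the field
works with. Upstream signal is antisense-strand only (divergent
transcription initiates antisense); the mouse variant uses a strict
above-median rule downstream (1 kb) and a configurable upstream window
(default 1000 bp, as no standard value exists).

Nucleosome change: ±50 bp dyad windows; only dyads with before-signal
strictly above the all-dyad median are classified ("transcribed"
nucleosomes); ratio r = after/before with 0.9 < r < 1.1 stable and
r ≤ 1/3 lost, both read literally, so r = 1.10 is not stable and r = 1/3 is
lost. Both tracks must already be on the shared silent-region scale.

## NDR peak calling

The per-NDR profile is raw per-base IP − input (RPGC). The smooth fit is a
least-squares cubic B-spline with one interior knot per 25 bp (effective
degrees of freedom ≈ width/25), evaluated at every base; the peak is the
leftmost argmax of the fitted curve. No smoothing parameter is standard for
this task; knots-per-width makes the fit scale-free across the ~120–300 bp
range of NDR widths, and 25 bp spacing recovers ≥ 80% of the height of any
Gaussian bump with sd ≥ 10 bp (a least-squares fit can also overshoot a
peak by ~1%, so exact-recovery tests allow [0.8a, 1.02a]). NDRs shorter
than 20 bp are skipped (a cubic spline needs support).

A peak is emitted when the tagged fitted amplitude exceeds 0.5 RPGC and the
untagged control's fitted amplitude (same smoothing) does not. The 0.5
threshold applies to the fitted value at the peak; the 0.1 RPGC
depleted-NDR threshold applies to the raw per-base maximum — the two rules
are intentionally different, and both raw and fitted amplitudes are
reported on every called peak. NDRs within 500 bp of a tRNA gene or
centromere are excluded before fitting (the factor binds these elements
promiscuously); the distance is configurable since no standard value
exists. Group comparisons (NDR width, owning-gene expression) use the
pooled-variance two-sided Student's t test, with t = 0, p = 1 by convention
for identical constant groups.

## Stratification

Dyad scores are means over the inclusive ±50 bp window (101 bases):
log2(Rpb3/input) for RNAPII, the window mean of the predicted-occupancy
track (window mean rather than the dyad-point value, so the score and the
RNAPII score summarize the same region), and log2(mark IP / MNase
occupancy) for occupancy-normalized marks. Quintile assignment is
rank-based with stable tie-breaking: group sizes differ by at most one even
when all scores tie, and label 1 is the lowest. RNAPII quintiles are
assigned over all included dyads, occupancy quintiles within each RNAPII
quintile separately; dyads with undefined scores are dropped (logged) before
assignment, and any RNAPII quintile with fewer than 5 dyads is an error.
"Genic" means the dyad lies in the body of a transcribed gene.

## Metaprofiles

TSS matrices are strand-oriented (downstream = increasing offset on both
strands) at single-base resolution; presentation binning would be applied
after averaging, never to the matrix. PAS masking invalidates offsets
strictly beyond the TSS→PAS distance and never touches upstream offsets;
chromosome-end and track-mask invalidity apply everywhere. The averaged
profile reports, per offset, the mean over valid entries, the valid count,
and the fraction of rows still valid — for PAS-masked TSS profiles that
fraction is non-increasing downstream by construction.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:
non-overlapping genes in sequential slots (upstream margin 650 bp to hold
the 100–600 bp divergent window, NDR of 120–300 bp abutting the TSS, body
800–1600 bp, dyads every 165 bp with a 100 bp body margin); a planted set
of grid-aligned 250 bp intergenic bins with exactly zero RNAPII signal;
constant-depth inputs (1.0); gene expression exp(N(0.5, 0.5)) on the
1x-coverage scale with exactly round(n/5) genes silenced; divergent
antisense upstream signal at 0.5× sense strength for a configurable
fraction of transcribed promoters; truncated-Gaussian factor peaks
(sd = NDR width/6) whose in-NDR maximum equals the planted amplitude
exactly; nucleosomal bumps (sd 30 bp, ±73 bp support) of constant height
for occupancy; a per-dyad predicted-occupancy score z ~ U(0.1, 1);
acetylation bump amplitude acetyl_coupling·e + mark_occ_coupling·z over a
0.05 background; and a treated condition multiplying RNAPII and its coupled
acetylation by 2^inhibition_log2fc (default −2, i.e. a "lost"-class change)
at half the transcribed genes, with every treated IP additionally scaled by
a global efficiency factor (0.7) that only silent-region normalization can
undo. Untagged-control artifact bumps are planted in both the tagged and
untagged IPs, so the control subtraction is load-bearing.

Noise is multiplicative: v ← max(0, v·(1 + N(0, noise_sd))), with
noise_sd = 0.1 by default. Variance scaling with signal mirrors sequencing
coverage (zero-coverage regions show no reads) and preserves exact zeros,
which is what keeps planted silent bins and non-divergent promoters
recoverable under noise. What the generator does **not** emulate:
read-level sampling (noise is per-base independent, not correlated over
fragment lengths — one visible consequence is that the raw-maximum
depleted-NDR rule, which tolerates correlated real-data noise, selects
nothing on noisy synthetic NDRs), mappability structure, copy-number
variation, replicate variability, or 5′-biased RNAPII profiles within gene
bodies. Passing tests therefore validate the arithmetic and the recovery
logic of each stage, not robustness to those real-data properties.

## Problem sizes and tolerances

The test and validation runs use: 2 × 250 kb chromosomes with 80 genes and
100 silent bins (silent recovery; exact set equality, halved-sample factor
2 ± 1e-6); 200 genes on 2 × 300 kb (classification; exact at zero noise,
≥ 95% mean class agreement over 20 seeds at 10% noise); 60 planted peaks
cycling amplitudes {0.2, 0.4, 0.8, 1.6} RPGC plus 10 control-only NDRs
(calling threshold 0.5 separates exactly {0.8, 1.6}; positions within ±2 bp;
100 randomized amplitude-monotonicity instances); ~2,500 genic dyads from
260 genes of 1.8–2.2 kb (25 cells balanced within ±1; occupancy-normalized
mark strictly increasing across occupancy quintiles in every RNAPII
quintile at coupling 4, mean |Spearman ρ| < 0.9 at coupling 0 over 3
seeds); and the default 200-gene genome with inhibition_log2fc = −1 and a
purely transcription-coupled mark for the fold-change contrast (medians
−1 ± 0.1 at lost and 0 ± 0.1 at stable dyads — the measured lost-dyad
median sits near −0.96 because the 0.05 RPGC acetylation background dilutes
the planted 2-fold drop, within the stated tolerance). Each brute-force
oracle comparison uses 50 random instances.

## Known limitations

- bedGraph/wiggle only; bigWig is out of scope.
- The pipeline orchestrator runs on simulated inputs; file-based inputs go
  through the individual CLI subcommands or the library functions.
- The treated-condition scale factor assumes one global IP efficiency per
  condition (see Normalization).
- Predicted nucleosome occupancy is an input score, never computed from
  sequence.
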