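# txnacetyl

Analysis pipeline for asking whether histone acetylation depends on
transcription: cross-condition ChIP-seq normalization against
transcriptionally silent regions, nascent-transcription-based classification
of genes and nucleosomes, smoothing-spline peak calling for sub-nucleosomal
factor binding inside nucleosome-depleted regions (NDRs), nested quintile
stratification of genic nucleosomes by RNAPII and predicted nucleosome
occupancy, and PAS-masked TSS metaprofiles. A synthetic-data generator plants
recoverable ground truth so every stage can be validated end to end.

## Who this is for

Computational epigenomics groups working with yeast (or mouse) ChIP-seq,
MNase ChIP-seq, NET-seq/PRO-seq coverage who need to compare a perturbed
condition (transcription inhibition, a truncation mutant) against an
untreated reference — a comparison that plain 1x depth scaling gets wrong
whenever the perturbation changes the total amount of immunoprecipitated
material.

## The methods in brief

**RPGC scaling and log2 ratios.** Coverage is scaled to reads-per-genomic-
coverage (genome-wide mean 1); per-base log2(IP/input) is masked wherever
the input is zero.

**Silent-region normalization.** The genome is cut into 250 bp bins, bins
outside the interquartile range of input coverage are discarded, and the 100
surviving bins with the lowest RNAPII (Rpb3) signal become the silent set.
For a treated sample *s* and untreated reference *r* the scale factor is

    f = mean_silent(r) / mean_silent(s)

so signal at silent regions — assumed invariant to the perturbation —
anchors the cross-condition scale.

**Gene classes.** Non-transcribed = lowest quintile of sense nascent signal
over TSS..TSS+500; unidirectional = transcribed genes in the lowest quintile
of antisense signal 100–600 bp upstream of the TSS (promoters lacking
divergent transcription). Nucleosomes with above-median Rpb3 are "stable"
when the between-condition ratio is within (0.9, 1.1) and "lost" when it
falls to ≤ 1/3.

**NDR factor peaks.** Within each NDR a least-squares cubic spline (one
interior knot per 25 bp) is fitted to IP − input (RPGC); a peak is called
when the fitted maximum exceeds 0.5 RPGC in the tagged sample but not in the
untagged control, excluding NDRs within 500 bp of tRNA genes or centromeres.
NDRs whose raw per-base maximum difference stays below 0.1 RPGC form the
factor-depleted comparison set (groups compared by pooled-variance two-sided
Student's t test).

**Nested stratification.** Genic dyads are split into quintiles of
log2(Rpb3/input) averaged over ±50 bp dyad windows, then each quintile is
split again by predicted nucleosome occupancy over the same window — 25
cells of nucleosomes with matched RNAPII but differing intrinsic occupancy,
profiled as dyad-aligned averages of occupancy-normalized mark signal.

**Metaprofiles.** TSS-aligned, strand-oriented signal matrices where each
gene stops contributing beyond its polyadenylation site; averaged profiles
carry the per-offset fraction of genes still plotted.

## Worked example

Run the whole pipeline on a small simulated genome (30 genes, one 120 kb
chromosome, 12 planted factor peaks cycling through amplitudes
0.2/0.4/0.8/1.6 RPGC, treatment halving RNAPII 4-fold at half of the
transcribed genes, treated IP efficiency 0.7):

```yaml
# example.yaml
simulation:
  n_chromosomes: 1
  chrom_length: 120000
  n_genes: 30
  n_planted_peaks: 12
  n_control_peaks: 3
  n_silent_bins: 20
  seed: 11
n_silent: 20
```

```bash
txnacetyl run --config example.yaml --outdir out/
```

prints the per-stage record counts:

```json
{
  "acetyl_fc_medians": {
    "lost": -1.376763871390723,
    "stable": 0.0010446501515053096
  },
  "depleted_ndrs": 0,
  "dyads": 190,
  "factor_peaks": 6,
  "gene_classes": {
    "non_transcribed": 6,
    "transcribed": 12,
    "unidirectional_transcribed": 12
  },
  "genes": 30,
  "ndrs": 30,
  "nucleosome_classes": {
    "lost": 62,
    "stable": 33,
    "unclassified": 95
  },
  "silent_bins": 20,
  "stratified_dyads": 149
}
```

Reading the numbers: exactly the 6 planted peaks above the 0.5 RPGC
threshold (amplitudes 0.8 and 1.6) are called; the planted class design
(1/5 non-transcribed, half of the transcribed divergent) is recovered; and
after silent-region normalization the median per-dyad acetylation log2 fold
change at RNAPII-lost nucleosomes is strongly negative while staying at
zero at stable nucleosomes — the transcription dependence of acetylation.
`out/scale_factors.tsv` shows the recovered cross-condition factor
(≈ 1.43 ≈ 1/0.7, undoing the simulated treated-IP efficiency):

```
sample             reference  factor             sample_silent_mean    reference_silent_mean
acetyl_ip_treated  acetyl_ip  1.428981467090176  0.045913451577720914  0.06560947139470538
```

Other outputs: `factor_peaks.bed`, `silent_regions.bed`, `gene_classes.tsv`,
`nucleosome_classes.tsv`, `strata_assignment.tsv`, `strata_profiles.tsv`,
`tss_profile_rnapii.tsv`, `acetyl_fold_change.tsv`, truth tables
(`truth_*.tsv`), all simulated tracks as bedGraph, and `run_log.json`.

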