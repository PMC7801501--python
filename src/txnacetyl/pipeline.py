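"""End-to-end pipeline on simulated data: scale → normalize → classify →
peaks → strata → profiles, with every table written to an output directory
and a machine-readable run log.

The stages mirror the analysis of a transcription-inhibition ChIP-seq
experiment: silent regions are found from the untreated input/RNAPII pair;
one scale factor per treated sample aligns it to its untreated counterpart
over those regions (the global IP-efficiency distortion of the treated
condition cancels there); genes and nucleosomes are classified from the
normalized signal; factor peaks are called in NDRs; genic nucleosomes are
stratified into nested RNAPII × predicted-occupancy quintiles; TSS
metaprofiles are averaged with PAS masking.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_nucleosome_change, classify_yeast_genes
from .normalize import apply_scale, find_silent_regions, silent_scale_factor
from .peaks import call_epl1_peaks, compare_ndr_groups, peaks_to_bed, select_depleted_ndrs
from .profiles import average_with_fraction, tss_matrix
from .strata import dyad_window_score, nested_strata, score_dyads, stratum_dyad_profiles
from .synthetic import SimulationConfig, make_genome, simulate_tracks
from .tracks import log2_ratio, write_bed, write_chrom_sizes, write_track

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "normalize", "classify", "peaks", "strata", "profiles")


def load_config(source) -> dict:
    """Accept a config dict or a YAML file path."""
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh) or {}


def acetylation_fold_change(acetyl_before, acetyl_after, dyads: pd.DataFrame,
                            halfwidth: int = 50) -> pd.DataFrame:
    """Per-dyad log2 change of acetylation window signal between conditions.

    Window means are ratioed (rather than averaging per-base log ratios) so
    a dyad's fold change is defined whenever both window means are positive.
    """
    rows = []
    for _, d in dyads.iterrows():
        chrom, pos = d["chrom"], int(d["pos"])
        b = dyad_window_score(acetyl_before, chrom, pos, halfwidth)
        a = dyad_window_score(acetyl_after, chrom, pos, halfwidth)
        fc = np.log2(a / b) if (b and b > 0 and a and a > 0) else np.nan
        rows.append((d["id"], chrom, pos, b, a, fc))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "before", "after",
                                       "log2fc"])


def run_pipeline(config, outdir) -> dict:
    """Run the requested stages in dependency order; return in-memory results.

    ``config`` is a dict (or YAML path) with optional keys ``simulation``
    (SimulationConfig fields), ``stages`` (subset of ``ALL_STAGES``), and
    stage parameters ``bin_width``, ``n_silent``, ``peak_threshold``,
    ``flank_up``, ``flank_down``, ``dyad_halfwidth``, ``dyad_flank``,
    ``write_tracks`` (set false to skip bedGraph serialization of the
    simulated tracks).
    Requesting a stage without its prerequisites is an error before any
    computation starts.
    """
    cfg = load_config(config)
    stages = list(cfg.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    for stage in stages:
        if stage != "simulate" and "simulate" not in stages:
            raise ValueError(f"stage {stage!r} requires the 'simulate' stage: "
                             "this pipeline runs on simulated inputs")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimulationConfig(**cfg.get("simulation", {}))
    bin_width = int(cfg.get("bin_width", sim_cfg.silent_bin_width))
    n_silent = int(cfg.get("n_silent", sim_cfg.n_silent_bins))
    peak_threshold = float(cfg.get("peak_threshold", 0.5))
    flank_up = int(cfg.get("flank_up", 500))
    flank_down = int(cfg.get("flank_down", 2000))
    halfwidth = int(cfg.get("dyad_halfwidth", 50))
    dyad_flank = int(cfg.get("dyad_flank", 200))

    results: dict = {}
    log: dict = {"package_version": __version__, "config": cfg,
                 "simulation": sim_cfg.__dict__.copy(), "stages": stages,
                 "counts": {}}
    for key in ("gene_length_range", "ndr_width_range", "peak_amplitude_range",
                "peak_amplitude_choices"):
        value = log["simulation"][key]
        log["simulation"][key] = list(value) if value is not None else None

    # --- simulate --------------------------------------------------------
    annotation = make_genome(sim_cfg)
    tracks, truth = simulate_tracks(annotation, sim_cfg)
    results["annotation"] = annotation
    results["tracks"] = tracks
    results["truth"] = truth
    log["counts"]["genes"] = len(annotation.genes)
    log["counts"]["ndrs"] = len(annotation.ndrs)
    log["counts"]["dyads"] = len(annotation.dyads)
    write_chrom_sizes(annotation.chrom_sizes, outdir / "chrom.sizes")
    annotation.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    gene_bed = annotation.genes.assign(
        start=annotation.genes[["tss", "pas"]].min(axis=1),
        end=annotation.genes[["tss", "pas"]].max(axis=1))
    write_bed(gene_bed, outdir / "genes.bed")
    write_bed(annotation.ndrs, outdir / "ndrs.bed")
    annotation.dyads.to_csv(outdir / "dyads.tsv", sep="\t", index=False)
    truth.write(str(outdir) + "/truth_")
    if cfg.get("write_tracks", True):
        for key, track in tracks.items():
            write_track(track, outdir / f"{key}.bedGraph")

    # --- normalize -------------------------------------------------------
    if "normalize" in stages:
        silent = find_silent_regions(tracks["rnapii_input"], tracks["rnapii_ip"],
                                     bin_width=bin_width, n_regions=n_silent)
        silent.to_bed(outdir / "silent_regions.bed")
        factors = {}
        normed = {}
        for treated, untreated in (("acetyl_ip_treated", "acetyl_ip"),
                                   ("rnapii_ip_treated", "rnapii_ip")):
            try:
                sf = silent_scale_factor(tracks[treated], tracks[untreated], silent)
            except ValueError:
                # zero silent mean (e.g. RNAPII, which is zero there by
                # construction): reuse the acetylation-derived factor, since
                # one global IP efficiency applies to the whole condition
                sf = factors["acetyl_ip_treated"]
            factors[treated] = sf
            normed[treated + "_norm"] = apply_scale(tracks[treated], sf)
        results["silent_regions"] = silent
        results["scale_factors"] = factors
        results["normalized"] = normed
        pd.DataFrame(
            [(k, f.reference, f.factor, f.sample_silent_mean, f.reference_silent_mean)
             for k, f in factors.items()],
            columns=["sample", "reference", "factor", "sample_silent_mean",
                     "reference_silent_mean"],
        ).to_csv(outdir / "scale_factors.tsv", sep="\t", index=False)
        log["counts"]["silent_bins"] = len(silent)

    # --- classify --------------------------------------------------------
    if "classify" in stages:
        gene_classes = classify_yeast_genes(tracks["netseq_plus"],
                                            tracks["netseq_minus"],
                                            annotation.genes)
        gene_classes.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
        results["gene_classes"] = gene_classes
        log["counts"]["gene_classes"] = gene_classes["class"].value_counts().to_dict()
        after = (results["normalized"]["rnapii_ip_treated_norm"]
                 if "normalize" in stages else tracks["rnapii_ip_treated"])
        nuc = classify_nucleosome_change(tracks["rnapii_ip"], after,
                                         annotation.dyads, halfwidth=halfwidth)
        nuc.to_csv(outdir / "nucleosome_classes.tsv", sep="\t", index=False)
        results["nucleosome_classes"] = nuc
        log["counts"]["nucleosome_classes"] = nuc["class"].value_counts().to_dict()

    # --- peaks -----------------------------------------------------------
    if "peaks" in stages:
        called = call_epl1_peaks(tracks["hat_ip"], tracks["hat_input"],
                                 tracks["untagged_ip"], tracks["untagged_input"],
                                 annotation, threshold=peak_threshold)
        peaks_to_bed(called, outdir / "factor_peaks.bed")
        depleted = select_depleted_ndrs(tracks["hat_ip"], tracks["hat_input"],
                                        annotation)
        results["peaks"] = called
        results["depleted_ndrs"] = depleted
        log["counts"]["factor_peaks"] = len(called)
        log["counts"]["depleted_ndrs"] = len(depleted)
        ndrs = annotation.ndrs.set_index("id")
        widths = ndrs["end"] - ndrs["start"]
        peak_ids = [p.ndr_id for p in called]
        if len(peak_ids) >= 2 and len(depleted) >= 2:
            ma, mb, t, p = compare_ndr_groups(widths.loc[peak_ids],
                                              widths.loc[depleted])
            results["ndr_width_comparison"] = {
                "mean_peak": ma, "mean_depleted": mb, "t": t, "p": p}
            pd.DataFrame([results["ndr_width_comparison"]]).to_csv(
                outdir / "ndr_width_comparison.tsv", sep="\t", index=False)

    # --- strata ----------------------------------------------------------
    if "strata" in stages:
        rpb3_log2 = log2_ratio(tracks["rnapii_ip"], tracks["rnapii_input"])
        mark_log2 = log2_ratio(tracks["acetyl_ip"], tracks["mnase_occ"])
        genic = annotation.dyads
        if "classify" in stages:
            transcribed = set(results["gene_classes"].loc[
                results["gene_classes"]["class"] != "non_transcribed", "id"])
            genic = genic[genic["gene_id"].isin(transcribed)]
        scores = score_dyads(rpb3_log2, tracks["pred_occ"], genic,
                             halfwidth=halfwidth, mark_log2={"mark": mark_log2})
        assignment = nested_strata(scores)
        assignment.to_csv(outdir / "strata_assignment.tsv", sep="\t", index=False)
        profiles = stratum_dyad_profiles(mark_log2, assignment, flank=dyad_flank)
        profiles.to_csv(outdir / "strata_profiles.tsv", sep="\t", index=False)
        results["strata"] = assignment
        results["strata_profiles"] = profiles
        log["counts"]["stratified_dyads"] = len(assignment)

    # --- profiles --------------------------------------------------------
    if "profiles" in stages:
        matrix = tss_matrix(tracks["rnapii_ip"], annotation.genes,
                            flank_up=flank_up, flank_down=flank_down,
                            pas_mask=True)
        profile = average_with_fraction(matrix)
        profile.to_frame().to_csv(outdir / "tss_profile_rnapii.tsv", sep="\t",
                                  index=False)
        results["tss_profile"] = profile
        if "normalize" in stages:
            fcs = acetylation_fold_change(
                tracks["acetyl_ip"],
                results["normalized"]["acetyl_ip_treated_norm"],
                annotation.dyads, halfwidth=halfwidth)
            fcs = fcs.merge(truth.dyad_truth[["id", "lost"]], on="id")
            fcs.to_csv(outdir / "acetyl_fold_change.tsv", sep="\t", index=False)
            results["acetyl_fold_change"] = fcs
            by_group = fcs.dropna(subset=["log2fc"]).groupby("lost")["log2fc"].median()
            results["acetyl_fc_medians"] = {
                "lost": float(by_group.get(True, np.nan)),
                "stable": float(by_group.get(False, np.nan))}
            log["counts"]["acetyl_fc_medians"] = results["acetyl_fc_medians"]

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["log"] = log
    return results
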