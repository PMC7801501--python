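"""Cross-condition normalization anchored on transcriptionally silent regions.

Treated or mutant ChIP-seq samples cannot be compared to an untreated
reference through read-depth scaling alone, because a global change in the
immunoprecipitated material changes the meaning of 1x coverage. The anchor
used here is a fixed set of genomic bins with minimal RNAPII occupancy:
signal there is assumed invariant to the perturbation, so the ratio of
silent-region means between reference and sample defines the scale factor.

Procedure: the genome is divided into fixed-width bins (250 bp), bins whose
input coverage falls outside the interquartile range are discarded (removing
mappability/copy-number artifacts), and the ``n_regions`` (100) surviving bins
with the lowest RNAPII (Rpb3) IP signal are kept as the silent set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import CoverageTrack, bin_track


@dataclass
class SilentRegionSet:
    """The bins used as the cross-condition normalization anchor."""

    bin_width: int
    bins: pd.DataFrame  # columns chrom, start, end, input_mean, rpb3_mean
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bins)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, row in self.bins.reset_index(drop=True).iterrows():
                fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                         f"silent_{i}\t0\t.\n")


@dataclass
class ScaleFactor:
    """Multiplier aligning a sample's silent-region mean to the reference's."""

    sample: str
    reference: str
    factor: float
    sample_silent_mean: float
    reference_silent_mean: float


def find_silent_regions(input_track: CoverageTrack, rpb3_track: CoverageTrack,
                        bin_width: int = 250, n_regions: int = 100) -> SilentRegionSet:
    """Select the ``n_regions`` lowest-RNAPII bins that pass the input IQR filter.

    The IQR filter keeps bins with input mean in the closed interval [Q1, Q3]
    (linear-interpolation quantiles), so a constant input keeps every bin.
    Ranking is by Rpb3 IP bin mean, ascending, ties broken by genomic order.
    """
    if bin_width < 1 or n_regions < 1:
        raise ValueError("bin_width and n_regions must be >= 1")
    if set(input_track.data) != set(rpb3_track.data):
        raise ValueError("input and Rpb3 tracks cover different chromosome sets")
    inp = bin_track(input_track, bin_width).bins.rename(columns={"value": "input_mean"})
    pol = bin_track(rpb3_track, bin_width).bins.rename(columns={"value": "rpb3_mean"})
    table = inp.merge(pol, on=["chrom", "start", "end"], validate="one_to_one")
    q1, q3 = np.quantile(table["input_mean"].to_numpy(), [0.25, 0.75])
    surviving = table[(table["input_mean"] >= q1) & (table["input_mean"] <= q3)]
    if len(surviving) < n_regions:
        raise ValueError(
            f"only {len(surviving)} bins survive the input IQR filter; "
            f"{n_regions} requested")
    ranked = surviving.sort_values(["rpb3_mean", "chrom", "start"],
                                   kind="mergesort").head(n_regions)
    ranked = ranked.sort_values(["chrom", "start"]).reset_index(drop=True)
    return SilentRegionSet(
        bin_width=bin_width,
        bins=ranked,
        provenance={"input": input_track.name, "rpb3": rpb3_track.name,
                    "iqr": (float(q1), float(q3)), "n_regions": n_regions},
    )


def _silent_mean(track: CoverageTrack, silent: SilentRegionSet) -> float:
    chunks = []
    for _, row in silent.bins.iterrows():
        chrom = row["chrom"]
        if chrom not in track.data:
            raise ValueError(f"silent bin on {chrom!r} absent from track {track.name!r}")
        chunks.append(track.data[chrom][int(row["start"]):int(row["end"])])
    return float(np.concatenate(chunks).mean())


def silent_scale_factor(sample: CoverageTrack, reference: CoverageTrack,
                        silent: SilentRegionSet) -> ScaleFactor:
    """factor = reference silent mean / sample silent mean."""
    ref_mean = _silent_mean(reference, silent)
    samp_mean = _silent_mean(sample, silent)
    if samp_mean == 0.0:
        raise ValueError(f"sample {sample.name!r} has zero silent-region mean; "
                         "scale factor undefined")
    return ScaleFactor(sample=sample.name, reference=reference.name,
                       factor=ref_mean / samp_mean,
                       sample_silent_mean=samp_mean, reference_silent_mean=ref_mean)


def apply_scale(track: CoverageTrack, factor: ScaleFactor) -> CoverageTrack:
    """Multiply every base by the factor; units preserved, provenance recorded."""
    if factor.factor <= 0:
        raise ValueError("scale factor must be positive")
    out = track.with_data({c: v * factor.factor for c, v in track.data.items()})
    out.provenance["silent_scale"] = {
        "reference": factor.reference, "factor": factor.factor}
    return out
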