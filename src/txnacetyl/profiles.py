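"""Feature-aligned signal matrices and averaged metaprofiles.

A :class:`ProfileMatrix` holds one row per feature and one column per base
offset from the anchor (TSS, peak center, or dyad). For TSS anchors rows are
strand-oriented (downstream = increasing offset on both strands) and, when
PAS masking is on, entries at offsets past the gene's TSS→PAS distance are
invalid — a gene stops contributing to the average at its polyadenylation
site. The averaged profile therefore carries, alongside the per-offset mean
over valid entries, the fraction of features still being plotted at each
offset (the gray fraction line of the average plots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import CoverageTrack


@dataclass
class ProfileMatrix:
    """feature × offset signal matrix with a validity mask."""

    feature_ids: list
    offsets: np.ndarray  # int offsets relative to anchor, ascending
    values: np.ndarray  # float, NaN where invalid
    valid: np.ndarray  # bool, same shape
    anchor: str = "TSS"  # TSS | feature | dyad

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")
        if self.values.shape != (len(self.feature_ids), len(self.offsets)):
            raise ValueError("matrix shape does not match ids × offsets")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.offsets)


@dataclass
class AverageProfile:
    """Per-offset mean over valid entries plus the fraction still plotted."""

    offsets: np.ndarray
    mean: np.ndarray  # NaN where no valid entries
    n_valid: np.ndarray
    fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "n": self.n_valid, "fraction": self.fraction})


def tss_matrix(track: CoverageTrack, genes: pd.DataFrame, flank_up: int,
               flank_down: int, pas_mask: bool = True) -> ProfileMatrix:
    """One strand-oriented row per gene, offsets [-flank_up, +flank_down].

    With ``pas_mask`` on, offsets strictly beyond the TSS→PAS distance are
    invalid (upstream offsets are never PAS-masked). Positions off the
    chromosome ends and track-undefined bases are invalid as well.
    """
    if flank_up < 0 or flank_down < 0:
        raise ValueError("flanks must be >= 0")
    offsets = np.arange(-flank_up, flank_down + 1)
    values = np.full((len(genes), len(offsets)), np.nan)
    for i, (_, g) in enumerate(genes.iterrows()):
        vals = track.data[g["chrom"]]
        n = len(vals)
        tss = int(g["tss"])
        if g["strand"] == "-":
            positions = tss - offsets
        else:
            positions = tss + offsets
        inb = (positions >= 0) & (positions < n)
        row = np.full(len(offsets), np.nan)
        row[inb] = vals[positions[inb]]
        if pas_mask:
            dist = abs(int(g["pas"]) - tss)
            row[offsets > dist] = np.nan
        values[i] = row
    valid = ~np.isnan(values)
    return ProfileMatrix(feature_ids=list(genes["id"]), offsets=offsets,
                         values=values, valid=valid, anchor="TSS")


def feature_matrix(track: CoverageTrack, anchors: pd.DataFrame,
                   flank: int) -> ProfileMatrix:
    """Unstranded rows centered on anchor positions, offsets [-flank, +flank].

    ``anchors`` needs columns chrom and pos (an ``id`` column is used for row
    ids when present). Only chromosome-end / track-undefined masking applies.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    offsets = np.arange(-flank, flank + 1)
    ids = list(anchors["id"]) if "id" in anchors.columns else list(range(len(anchors)))
    values = np.full((len(anchors), len(offsets)), np.nan)
    for i, (_, a) in enumerate(anchors.iterrows()):
        vals = track.data[a["chrom"]]
        positions = int(a["pos"]) + offsets
        inb = (positions >= 0) & (positions < len(vals))
        values[i, inb] = vals[positions[inb]]
    valid = ~np.isnan(values)
    return ProfileMatrix(feature_ids=ids, offsets=offsets, values=values,
                         valid=valid, anchor="feature")


def average_with_fraction(matrix: ProfileMatrix) -> AverageProfile:
    """Column means over valid entries, plus the fraction-plotted track."""
    n_rows = matrix.values.shape[0]
    if n_rows == 0:
        raise ValueError("empty profile matrix")
    n_valid = matrix.valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(np.where(matrix.valid, matrix.values, 0.0), axis=0)
        mean = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    return AverageProfile(offsets=matrix.offsets, mean=mean, n_valid=n_valid,
                          fraction=n_valid / n_rows)


def write_matrix(matrix: ProfileMatrix, path, mask_rule: str = "PAS") -> None:
    """Gzipped TSV with a one-line header comment describing the layout."""
    df = matrix.to_frame()
    with pd.io.common.get_handle(path, "w", compression="infer") as handle:
        handle.handle.write(
            f"# anchor={matrix.anchor} offsets={matrix.offsets[0]}..{matrix.offsets[-1]} "
            f"mask={mask_rule}\n")
        df.to_csv(handle.handle, sep="\t")
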