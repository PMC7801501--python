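"""Transcription-based classification of genes and nucleosomes.

Genes are classified from stranded nascent-transcription coverage (NET-seq in
yeast, PRO-seq in mouse):

* ``non_transcribed`` — lowest quintile of sense signal over the first window
  downstream of the TSS (yeast), or at/below the median (mouse).
* ``transcribed`` — the remainder.
* ``unidirectional_transcribed`` — transcribed genes in the lowest quintile of
  antisense signal upstream of the TSS, i.e. promoters lacking divergent
  transcription.

Nucleosome dyads are classified by the change in RNAPII (Rpb3) occupancy in a
±50 bp dyad window between two conditions: a change of less than 10% is
``stable``, a decrease of at least 3-fold is ``lost``, anything else ``other``;
only dyads with above-median occupancy in the first condition are classified.

"Lowest quintile" everywhere means: the cut value is the ``round(n/5)``-th
smallest score and every score less than or equal to the cut value is in the
quintile, so ties at the boundary are included (with all-distinct scores the
quintile has exactly round(n/5) members).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tracks import CoverageTrack

logger = logging.getLogger(__name__)

NON_TRANSCRIBED = "non_transcribed"
TRANSCRIBED = "transcribed"
UNIDIRECTIONAL = "unidirectional_transcribed"


def window_signal(track: CoverageTrack, chrom: str, anchor: int, strand: str,
                  offset_start: int, offset_end: int) -> float:
    """Mean signal over a strand-oriented half-open window around an anchor.

    Offsets are in transcription-direction coordinates: positive = downstream.
    On the + strand the window is ``[anchor+offset_start, anchor+offset_end)``;
    on the - strand it is mirrored so that, e.g., offsets (0, 500) cover the
    500 bases ``anchor-499 .. anchor``. Windows are clipped at chromosome
    ends; an empty window yields NaN.
    """
    if offset_end <= offset_start:
        raise ValueError("offset_end must exceed offset_start")
    vals = track.data[chrom]
    n = len(vals)
    if strand == "-":
        lo, hi = anchor - offset_end + 1, anchor - offset_start + 1
    else:
        lo, hi = anchor + offset_start, anchor + offset_end
    lo, hi = max(lo, 0), min(hi, n)
    if hi <= lo:
        return float("nan")
    window = vals[lo:hi]
    if np.isnan(window).all():
        return float("nan")
    return float(np.nanmean(window))


def lowest_quintile_mask(scores: np.ndarray) -> np.ndarray:
    """Boolean mask of the lowest quintile, ties at the cut value included."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 5:
        raise ValueError(f"quintiles undefined for {n} < 5 scores")
    k = int(round(n / 5))
    cut = np.partition(scores, k - 1)[k - 1]
    return scores <= cut


def _strand_windows(plus: CoverageTrack, minus: CoverageTrack, genes: pd.DataFrame,
                    offset_start: int, offset_end: int, antisense: bool) -> np.ndarray:
    out = np.empty(len(genes))
    for i, (_, g) in enumerate(genes.iterrows()):
        sense_is_plus = g["strand"] == "+"
        use_plus = sense_is_plus != antisense
        track = plus if use_plus else minus
        out[i] = window_signal(track, g["chrom"], int(g["tss"]), g["strand"],
                               offset_start, offset_end)
    return out


def classify_yeast_genes(netseq_plus: CoverageTrack, netseq_minus: CoverageTrack,
                         genes: pd.DataFrame,
                         downstream_window: tuple[int, int] = (0, 500),
                         upstream_window: tuple[int, int] = (-600, -100),
                         ) -> pd.DataFrame:
    """Quintile-based yeast gene classes from stranded NET-seq coverage.

    Downstream signal is sense-strand over the first 500 bp past the TSS;
    upstream signal is antisense-strand over 100-600 bp upstream of the TSS
    (divergent transcription runs antisense). Returns a table with columns
    id, class, downstream_signal, upstream_signal.
    """
    if len(genes) < 5:
        raise ValueError("need at least 5 genes for quintile classification")
    down = _strand_windows(netseq_plus, netseq_minus, genes,
                           *downstream_window, antisense=False)
    up = _strand_windows(netseq_plus, netseq_minus, genes,
                         *upstream_window, antisense=True)
    classes = np.full(len(genes), TRANSCRIBED, dtype=object)
    classes[lowest_quintile_mask(down)] = NON_TRANSCRIBED
    transcribed = classes == TRANSCRIBED
    if transcribed.sum() >= 5:
        uni = np.zeros(len(genes), dtype=bool)
        uni[transcribed] = lowest_quintile_mask(up[transcribed])
        classes[uni] = UNIDIRECTIONAL
    return pd.DataFrame({
        "id": genes["id"].to_numpy(),
        "class": classes,
        "downstream_signal": down,
        "upstream_signal": up,
    })


def classify_mouse_genes(proseq_plus: CoverageTrack, proseq_minus: CoverageTrack,
                         genes: pd.DataFrame,
                         downstream_window: tuple[int, int] = (0, 1000),
                         upstream_window_bases: int = 1000) -> pd.DataFrame:
    """Mouse gene classes from stranded PRO-seq coverage.

    Transcribed = sense signal over 1 kb downstream of the TSS strictly above
    the all-gene median; unidirectional = transcribed genes in the lowest
    quintile of antisense signal over the configured upstream window.
    """
    if len(genes) < 5:
        raise ValueError("need at least 5 genes for classification")
    down = _strand_windows(proseq_plus, proseq_minus, genes,
                           *downstream_window, antisense=False)
    up = _strand_windows(proseq_plus, proseq_minus, genes,
                         -upstream_window_bases, 0, antisense=True)
    classes = np.full(len(genes), NON_TRANSCRIBED, dtype=object)
    classes[down > np.median(down)] = TRANSCRIBED
    transcribed = classes == TRANSCRIBED
    if transcribed.sum() >= 5:
        uni = np.zeros(len(genes), dtype=bool)
        uni[transcribed] = lowest_quintile_mask(up[transcribed])
        classes[uni] = UNIDIRECTIONAL
    return pd.DataFrame({
        "id": genes["id"].to_numpy(),
        "class": classes,
        "downstream_signal": down,
        "upstream_signal": up,
    })


def classify_nucleosome_change(before: CoverageTrack, after: CoverageTrack,
                               dyads: pd.DataFrame, halfwidth: int = 50,
                               ) -> pd.DataFrame:
    """Classify dyads as Rpb3 ``stable`` / ``lost`` / ``other`` between conditions.

    Both tracks must already be on a common (silent-region) scale. Only dyads
    whose before-signal exceeds the median over all dyads are classified
    (these are the transcribed nucleosomes); the rest are ``unclassified``.
    With ratio r = after/before: 0.9 < r < 1.1 is stable, r <= 1/3 is lost.
    """
    sig_before = np.empty(len(dyads))
    sig_after = np.empty(len(dyads))
    for i, (_, d) in enumerate(dyads.iterrows()):
        chrom, pos = d["chrom"], int(d["pos"])
        sig_before[i] = window_signal(before, chrom, pos, "+", -halfwidth, halfwidth + 1)
        sig_after[i] = window_signal(after, chrom, pos, "+", -halfwidth, halfwidth + 1)
    med = np.median(sig_before)
    classes = np.full(len(dyads), "unclassified", dtype=object)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sig_after / sig_before
    eligible = sig_before > med
    zero_before = eligible & (sig_before == 0)
    if zero_before.any():
        logger.info("excluding %d dyads with zero before-signal", int(zero_before.sum()))
    classified = eligible & ~zero_before
    r = ratio[classified]
    cls = np.full(r.shape, "other", dtype=object)
    cls[(r > 0.9) & (r < 1.1)] = "stable"
    cls[r <= 1.0 / 3.0] = "lost"
    classes[classified] = cls
    return pd.DataFrame({
        "id": dyads["id"].to_numpy(),
        "class": classes,
        "before": sig_before,
        "after": sig_after,
        "ratio": ratio,
    })
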