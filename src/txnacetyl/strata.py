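"""Nested quintile stratification of genic nucleosomes.

To ask whether intrinsically stable nucleosomes are preferentially acetylated
while controlling for how much RNAPII traverses them, genic nucleosome dyads
are first split into quintiles of RNAPII occupancy — log2(Rpb3/input) averaged
over an inclusive ±50 bp dyad window — and each RNAPII quintile is then split
into quintiles of predicted nucleosome occupancy over the same window. The
resulting 25 cells hold nucleosomes with matched RNAPII levels but differing
predicted occupancy; dyad-aligned average profiles per cell expose any
residual dependence of (nucleosome-normalized) histone-mark signal on
predicted occupancy.

Quintile labels run 1 (lowest score) to 5 (highest); within any stratum the
five groups differ in size by at most one, with ties broken by dyad order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tracks import CoverageTrack

logger = logging.getLogger(__name__)

DEFAULT_HALFWIDTH = 50


def dyad_window_score(track: CoverageTrack, chrom: str, pos: int,
                      halfwidth: int = DEFAULT_HALFWIDTH) -> float:
    """Mean track value over the inclusive ±halfwidth window around a dyad.

    Only defined values enter the mean; the score is NaN (undefined) when
    more than half of the window is masked or off-chromosome.
    """
    vals = track.data[chrom]
    n = len(vals)
    lo, hi = pos - halfwidth, pos + halfwidth + 1
    full = hi - lo
    lo, hi = max(lo, 0), min(hi, n)
    if hi <= lo:
        return float("nan")
    window = vals[lo:hi]
    n_defined = int(np.sum(~np.isnan(window)))
    if n_defined <= full / 2:
        return float("nan")
    return float(np.nanmean(window))


def assign_quintiles(scores, ids=None) -> np.ndarray:
    """Rank-based split into 5 near-equal groups; label 1 = lowest scores.

    Group sizes differ by at most one. Ties are broken by the ``ids``
    ordering (or input order) so the assignment is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 5:
        raise ValueError(f"cannot form quintiles from {n} < 5 scores")
    if np.isnan(scores).any():
        raise ValueError("undefined scores must be excluded before quintile assignment")
    tiebreak = np.arange(n) if ids is None else np.asarray(ids)
    order = np.lexsort((tiebreak, scores))
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) * 5 // n + 1
    return labels


def nested_strata(dyad_scores: pd.DataFrame) -> pd.DataFrame:
    """Nested quintile assignment: RNAPII quintiles, then occupancy within each.

    ``dyad_scores`` needs columns id, rpb3_score, occ_score (rows with NaN in
    either score are dropped with a logged count). Returns the surviving rows
    with added integer columns q_rpb3 and q_occ.
    """
    required = {"id", "rpb3_score", "occ_score"}
    missing = required - set(dyad_scores.columns)
    if missing:
        raise ValueError(f"dyad_scores missing columns {sorted(missing)}")
    defined = dyad_scores.dropna(subset=["rpb3_score", "occ_score"]).reset_index(drop=True)
    n_dropped = len(dyad_scores) - len(defined)
    if n_dropped:
        logger.info("dropping %d dyads with undefined scores", n_dropped)
    out = defined.copy()
    out["q_rpb3"] = assign_quintiles(out["rpb3_score"].to_numpy())
    out["q_occ"] = 0
    for q in range(1, 6):
        members = out.index[out["q_rpb3"] == q]
        if len(members) < 5:
            raise ValueError(f"RNAPII quintile {q} has {len(members)} < 5 dyads")
        out.loc[members, "q_occ"] = assign_quintiles(
            out.loc[members, "occ_score"].to_numpy())
    return out


def stratum_dyad_profiles(track: CoverageTrack, assignment: pd.DataFrame,
                          flank: int = 500) -> pd.DataFrame:
    """Dyad-aligned average profile per (q_rpb3, q_occ) cell.

    ``assignment`` needs columns chrom, pos, q_rpb3, q_occ. Returns a
    long-format table (q_rpb3, q_occ, offset, mean, n) where ``mean``
    averages only defined in-bounds values at each offset; empty cells are
    omitted with a logged reason.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    offsets = np.arange(-flank, flank + 1)
    records = []
    for (qr, qo), cell in assignment.groupby(["q_rpb3", "q_occ"], sort=True):
        if len(cell) == 0:  # pragma: no cover - groupby never yields empty
            logger.info("cell (%s, %s) empty; omitted", qr, qo)
            continue
        mat = np.full((len(cell), len(offsets)), np.nan)
        for i, (_, d) in enumerate(cell.iterrows()):
            vals = track.data[d["chrom"]]
            pos = int(d["pos"])
            lo, hi = pos - flank, pos + flank + 1
            clo, chi = max(lo, 0), min(hi, len(vals))
            mat[i, clo - lo:chi - lo] = vals[clo:chi]
        n_valid = np.sum(~np.isnan(mat), axis=0)
        with np.errstate(invalid="ignore"):
            means = np.where(n_valid > 0, np.nanmean(mat, axis=0), np.nan)
        for off, m, nv in zip(offsets, means, n_valid):
            records.append((int(qr), int(qo), int(off), float(m), int(nv)))
    return pd.DataFrame(records, columns=["q_rpb3", "q_occ", "offset", "mean", "n"])


def score_dyads(rpb3_log2: CoverageTrack, predicted_occ: CoverageTrack,
                dyads: pd.DataFrame, halfwidth: int = DEFAULT_HALFWIDTH,
                mark_log2: dict[str, CoverageTrack] | None = None) -> pd.DataFrame:
    """Convenience: per-dyad window scores feeding :func:`nested_strata`.

    ``rpb3_log2`` is a log2(Rpb3/input) track; ``predicted_occ`` the
    sequence-predicted nucleosome occupancy; optional ``mark_log2`` maps mark
    names to occupancy-normalized log2 tracks, added as ``<name>_score``.
    """
    rows = []
    for _, d in dyads.iterrows():
        chrom, pos = d["chrom"], int(d["pos"])
        row = {
            "id": d["id"], "chrom": chrom, "pos": pos,
            "rpb3_score": dyad_window_score(rpb3_log2, chrom, pos, halfwidth),
            "occ_score": dyad_window_score(predicted_occ, chrom, pos, halfwidth),
        }
        for name, track in (mark_log2 or {}).items():
            row[f"{name}_score"] = dyad_window_score(track, chrom, pos, halfwidth)
        rows.append(row)
    return pd.DataFrame(rows)
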