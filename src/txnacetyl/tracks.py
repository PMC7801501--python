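"""Coverage tracks, genome annotations, and the file formats that carry them.

Coordinates are 0-based, half-open everywhere inside the package; conversion to
1-based conventions (fixed-step wiggle) happens only at the file boundary.

A :class:`CoverageTrack` stores dense per-base float64 signal per chromosome.
Raw and RPGC tracks are nonnegative with uncovered bases equal to 0; log2-ratio
tracks may be negative and use NaN to mark undefined bases (the explicit mask
the ratio step requires).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW = "raw"
RPGC = "RPGC"
LOG2RATIO = "log2ratio"


class TrackFormatError(ValueError):
    """A coverage file does not parse under the requested dialect."""


@dataclass
class CoverageTrack:
    """Per-base signal for a set of chromosomes plus sample metadata.

    Parameters
    ----------
    data
        Mapping of chromosome name to a float64 array of per-base values.
    name, role, condition, strand
        Sample metadata. ``role`` is one of ``IP``, ``input``, ``control``;
        ``strand`` is ``+``, ``-`` or ``.`` (unstranded).
    units
        ``raw``, ``RPGC`` or ``log2ratio``. Only log2ratio tracks may hold
        NaN (undefined) or negative values.
    """

    data: dict[str, np.ndarray]
    name: str = ""
    role: str = "IP"
    condition: str = ""
    strand: str = "."
    units: str = RAW
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=np.float64) for c, v in self.data.items()}
        if self.units in (RAW, RPGC):
            for chrom, vals in self.data.items():
                if not np.isfinite(vals).all():
                    raise ValueError(f"{self.units} track has non-finite values on {chrom}")
                if (vals < 0).any():
                    raise ValueError(f"{self.units} track has negative values on {chrom}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def defined_mask(self, chrom: str) -> np.ndarray:
        """Boolean array, True where the track value is defined."""
        return ~np.isnan(self.data[chrom])

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.data.values()))

    def mean(self) -> float:
        """Genome-wide mean over defined bases."""
        n = sum(int(self.defined_mask(c).sum()) for c in self.data)
        if n == 0:
            raise ValueError("track has no defined bases")
        return self.total() / n

    def copy(self) -> "CoverageTrack":
        return replace(self, data={c: v.copy() for c, v in self.data.items()},
                       provenance=dict(self.provenance))

    def with_data(self, data: dict[str, np.ndarray], **meta) -> "CoverageTrack":
        kwargs = dict(name=self.name, role=self.role, condition=self.condition,
                      strand=self.strand, units=self.units,
                      provenance=dict(self.provenance))
        kwargs.update(meta)
        return CoverageTrack(data=data, **kwargs)


@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment (or read to be extended), 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus the feature tables the pipeline anchors on.

    genes:      columns id, chrom, strand, tss, pas  (tss < pas on +, tss > pas on -)
    ndrs:       columns id, chrom, start, end, gene_id
    dyads:      columns id, chrom, pos, gene_id
    exclusions: columns kind (tRNA | centromere), chrom, start, end
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    ndrs: pd.DataFrame
    dyads: pd.DataFrame
    exclusions: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        if len(g):
            plus = g["strand"] == "+"
            bad = (plus & (g["tss"] >= g["pas"])) | (~plus & (g["tss"] <= g["pas"]))
            if bad.any():
                raise ValueError(f"{int(bad.sum())} genes violate TSS/PAS strand ordering")
        n = self.ndrs
        if len(n):
            if (n["start"] >= n["end"]).any():
                raise ValueError("empty NDR interval")
            for _, row in n.iterrows():
                if row["start"] < 0 or row["end"] > self.chrom_sizes[row["chrom"]]:
                    raise ValueError(f"NDR {row['id']} out of chromosome bounds")

    def gene_by_id(self, gene_id: str) -> pd.Series:
        return self.genes.set_index("id").loc[gene_id]


def empty_annotation(chrom_sizes: Mapping[str, int]) -> GenomeAnnotation:
    return GenomeAnnotation(
        chrom_sizes=dict(chrom_sizes),
        genes=pd.DataFrame(columns=["id", "chrom", "strand", "tss", "pas"]),
        ndrs=pd.DataFrame(columns=["id", "chrom", "start", "end", "gene_id"]),
        dyads=pd.DataFrame(columns=["id", "chrom", "pos", "gene_id"]),
        exclusions=pd.DataFrame(columns=["kind", "chrom", "start", "end"]),
    )


@dataclass
class BinTable:
    """Fixed-width genomic bins with one value column per track.

    Every bin is exactly ``width`` bases except possibly the last per
    chromosome. ``bins`` has columns chrom, start, end plus value columns.
    """

    width: int
    bins: pd.DataFrame

    def intervals(self) -> pd.DataFrame:
        return self.bins[["chrom", "start", "end"]]


# ---------------------------------------------------------------------------
# file formats


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column text: chromosome name, length in bases."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            out[name] = int(size)
    return out


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_track(path, chrom_sizes: Mapping[str, int], format: str = "bedGraph",
               **meta) -> CoverageTrack:
    """Expand an interval-valued coverage file to per-base values.

    Uncovered bases read as 0. Overlapping intervals with conflicting values
    are a format error; overlapping intervals with equal values are tolerated.
    """
    data = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(int(n), dtype=bool) for c, n in chrom_sizes.items()}
    if format == "bedGraph":
        _read_bedgraph(path, data, covered)
    elif format in ("wiggle", "wig", "fixedStep"):
        _read_fixedstep(path, data, covered)
    else:
        raise ValueError(f"unknown track format {format!r}")
    units = meta.pop("units", RAW)
    if units == LOG2RATIO:
        # bases never covered are undefined for ratio tracks
        for c in data:
            data[c][~covered[c]] = np.nan
    return CoverageTrack(data=data, units=units, **meta)


def _assign(data, covered, chrom, start, end, value, lineno):
    if chrom not in data:
        raise TrackFormatError(f"line {lineno}: unknown chromosome {chrom!r}")
    n = len(data[chrom])
    if start < 0 or end > n or start >= end:
        raise TrackFormatError(
            f"line {lineno}: interval {chrom}:{start}-{end} outside chromosome of length {n}")
    seg = data[chrom][start:end]
    cov = covered[chrom][start:end]
    if cov.any() and not np.all(seg[cov] == value):
        raise TrackFormatError(
            f"line {lineno}: overlapping intervals with conflicting values at {chrom}:{start}-{end}")
    seg[:] = value
    cov[:] = True


def _read_bedgraph(path, data, covered) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise TrackFormatError(f"line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            _assign(data, covered, chrom, start, end, value, lineno)


def _read_fixedstep(path, data, covered) -> None:
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                continue
            if chrom is None:
                raise TrackFormatError(f"line {lineno}: value before fixedStep header")
            _assign(data, covered, chrom, pos, pos + span, float(line), lineno)
            pos += step


def write_track(track: CoverageTrack, path, format: str = "bedGraph") -> None:
    """Write a track, run-length merging adjacent equal values.

    For bedGraph, zero-valued runs of raw/RPGC tracks and undefined (NaN)
    bases of log2ratio tracks are omitted; values keep >= 6 significant digits.
    """
    if format == "bedGraph":
        with open(path, "w") as fh:
            for chrom, vals in track.data.items():
                starts, ends, values = _run_arrays(vals)
                keep = ~np.isnan(values) & (values != 0.0)
                if not keep.any():
                    continue
                frame = pd.DataFrame({"chrom": chrom, "start": starts[keep],
                                      "end": ends[keep], "value": values[keep]})
                # default float formatting is the shortest exact repr, so a
                # write/read round-trip is the identity on per-base values
                frame.to_csv(fh, sep="\t", header=False, index=False)
    elif format in ("wiggle", "wig", "fixedStep"):
        with open(path, "w") as fh:
            for chrom, vals in track.data.items():
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                fh.writelines(f"{float(v)!r}\n" for v in vals)
    else:
        raise ValueError(f"unknown track format {format!r}")


def _run_arrays(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(starts, ends, values) of maximal equal-value runs (NaN-aware)."""
    n = len(vals)
    if n == 0:
        empty = np.array([], dtype=int)
        return empty, empty, np.array([])
    same = (vals[1:] == vals[:-1]) | (np.isnan(vals[1:]) & np.isnan(vals[:-1]))
    breaks = np.flatnonzero(~same) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    return starts, ends, vals[starts]


def write_bed(df: pd.DataFrame, path, name_col: str = "id", score_col=None) -> None:
    """Write intervals (chrom/start/end + name) as BED6."""
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            score = 0 if score_col is None else row[score_col]
            strand = row.get("strand", ".")
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                     f"{row[name_col]}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# core operations


def coverage_from_fragments(fragments: Sequence[Fragment],
                            chrom_sizes: Mapping[str, int],
                            extension: int | None = None) -> CoverageTrack:
    """Pile up fragments into raw coverage.

    With ``extension`` set (e.g. 146 or 350 bp), each fragment is extended
    from its 5' end in its strand direction to the stated length, clipped at
    chromosome ends; each covered base gains 1.
    """
    if extension is not None and extension < 1:
        raise ValueError("extension must be >= 1")
    data = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}
    for frag in fragments:
        if frag.chrom not in data:
            raise ValueError(f"fragment on unknown chromosome {frag.chrom!r}")
        n = len(data[frag.chrom])
        if frag.start < 0 or frag.end > n:
            raise ValueError(f"fragment {frag.chrom}:{frag.start}-{frag.end} outside chromosome")
        if extension is None:
            start, end = frag.start, frag.end
        elif frag.strand == "-":
            start, end = frag.end - extension, frag.end
        else:
            start, end = frag.start, frag.start + extension
        start, end = max(start, 0), min(end, n)
        data[frag.chrom][start:end] += 1.0
    return CoverageTrack(data=data, units=RAW)


def scale_rpgc(track: CoverageTrack,
               excluded_chromosomes: Iterable[str] = ()) -> CoverageTrack:
    """1x normalization: scale so the mean over non-excluded bases is 1.

    Excluded chromosomes (e.g. an unstable chromosome in a mutant strain) are
    dropped from the returned track. The mean includes zero-coverage bases.
    """
    if track.units == LOG2RATIO:
        raise ValueError("cannot RPGC-scale a log2ratio track")
    excluded = set(excluded_chromosomes)
    kept = {c: v for c, v in track.data.items() if c not in excluded}
    if not kept:
        raise ValueError("all chromosomes excluded")
    n = sum(len(v) for v in kept.values())
    mean = sum(float(v.sum()) for v in kept.values()) / n
    if mean == 0.0:
        raise ValueError("track is all-zero outside excluded chromosomes; RPGC undefined")
    data = {c: v / mean for c, v in kept.items()}
    out = track.with_data(data, units=RPGC)
    out.provenance["rpgc_scale"] = 1.0 / mean
    if excluded:
        out.provenance["excluded_chromosomes"] = sorted(excluded)
    return out


def log2_ratio(ip: CoverageTrack, input_track: CoverageTrack) -> CoverageTrack:
    """Per-base log2(IP/input); bases where input (or IP) is 0 are undefined.

    Masking rather than pseudocounting follows the zero-input removal rule;
    zero-IP bases are likewise masked because -inf cannot enter averages.
    """
    if set(ip.data) != set(input_track.data):
        raise ValueError("IP and input cover different chromosome sets")
    data = {}
    for chrom, ipv in ip.data.items():
        inv = input_track.data[chrom]
        if len(ipv) != len(inv):
            raise ValueError(f"chromosome {chrom} lengths differ between IP and input")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where((inv > 0) & (ipv > 0), np.log2(np.divide(ipv, inv, where=inv > 0,
                                                                  out=np.ones_like(ipv))), np.nan)
        data[chrom] = r
    return ip.with_data(data, units=LOG2RATIO,
                        name=f"log2({ip.name}/{input_track.name})" if ip.name else "log2ratio")


def bin_track(track: CoverageTrack, width: int) -> BinTable:
    """Mean per fixed-width bin; the trailing partial bin averages its own length."""
    if width < 1:
        raise ValueError("bin width must be >= 1")
    rows = []
    for chrom, vals in track.data.items():
        n = len(vals)
        starts = np.arange(0, n, width)
        ends = np.minimum(starts + width, n)
        sums = np.add.reduceat(vals, starts)
        means = sums / (ends - starts)
        for s, e, m in zip(starts, ends, means):
            rows.append((chrom, int(s), int(e), float(m)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return BinTable(width=width, bins=bins)
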