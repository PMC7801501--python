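"""Synthetic miniature genome and coverage tracks with planted ground truth.

The generator emulates, at desk scale, the statistical structure the pipeline
assumes in real data:

* a multi-chromosome genome of non-overlapping genes, each with an upstream
  NDR and regularly spaced nucleosome dyads in its body;
* stranded nascent-transcription coverage (sense over gene bodies, optional
  divergent antisense 100-600 bp upstream of a configurable fraction of
  transcribed promoters);
* RNAPII IP/input with a genome-wide background that is zero inside a set of
  planted silent bins (the normalization anchor);
* factor (HAT) MNase IP/input with sub-nucleosomal Gaussian peaks planted
  inside NDRs, plus an untagged control sharing artifact peaks with the IP;
* MNase nucleosome occupancy with positioned dyads, a per-dyad predicted
  nucleosome occupancy score, and acetylation IP whose per-nucleosome
  amplitude is coupled to local RNAPII signal (and optionally to predicted
  occupancy);
* a treated condition in which RNAPII and its coupled acetylation drop by
  ``inhibition_log2fc`` at designated "lost" genes and every treated IP is
  distorted by a global efficiency factor that silent-region normalization
  must undo.

Noise is multiplicative: each base becomes ``max(0, v * (1 + N(0, noise_sd)))``,
so zero-signal regions stay exactly zero, as in real coverage where sampling
variance scales with signal. All randomness flows from ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tracks import RPGC, CoverageTrack, GenomeAnnotation

_UPSTREAM_MARGIN = 650  # room for the 100-600 bp upstream antisense window
_DOWNSTREAM_MARGIN = 150
_DYAD_EDGE_MARGIN = 100  # keeps +-73 bp nucleosome footprints inside gene bodies
_NUC_FOOTPRINT = 73  # half-width of the nucleosomal bump support
_NUC_SD = 30.0  # sd of nucleosomal Gaussian bumps

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI"]


class SimulationSizingError(ValueError):
    """The requested genes/annotations cannot be placed on the genome."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome and its coverage tracks.

    Amplitudes are on the 1x-coverage (RPGC) scale; ``noise_sd`` is the
    relative (per-base, multiplicative) noise coefficient.
    """

    n_chromosomes: int = 2
    chrom_length: int = 400_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (800, 1600)
    ndr_width_range: tuple[int, int] = (120, 300)
    nucleosome_spacing: int = 165
    fraction_divergent: float = 0.5
    n_planted_peaks: int = 60
    peak_amplitude_range: tuple[float, float] = (0.2, 1.6)
    peak_amplitude_choices: tuple[float, ...] | None = (0.2, 0.4, 0.8, 1.6)
    n_control_peaks: int = 10
    control_amplitude: float = 1.0
    n_silent_bins: int = 100
    silent_bin_width: int = 250
    acetyl_coupling: float = 2.0
    mark_occ_coupling: float = 1.0
    inhibition_log2fc: float = -2.0
    fraction_lost: float = 0.5
    treated_efficiency: float = 0.7
    input_depth: float = 1.0
    rnapii_background: float = 0.1
    acetyl_background: float = 0.05
    divergent_strength: float = 0.5
    occupancy_amplitude: float = 2.0
    occupancy_background: float = 0.1
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes", "nucleosome_spacing",
                     "n_planted_peaks", "n_silent_bins", "silent_bin_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_control_peaks < 0:
            raise ValueError("n_control_peaks must be >= 0")
        for name in ("gene_length_range", "ndr_width_range", "peak_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"{name} must be an ordered positive range")
        for name in ("fraction_divergent", "fraction_lost"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.treated_efficiency <= 0 or self.input_depth <= 0:
            raise ValueError("treated_efficiency and input_depth must be positive")
        slot = (_UPSTREAM_MARGIN + self.ndr_width_range[1]
                + self.gene_length_range[1] + _DOWNSTREAM_MARGIN)
        per_chrom = -(-self.n_genes // self.n_chromosomes)
        if 1000 + per_chrom * slot > self.chrom_length:
            raise SimulationSizingError(
                f"{per_chrom} genes of slot size {slot} bp do not fit on a "
                f"{self.chrom_length} bp chromosome (need "
                f"{1000 + per_chrom * slot} bp)")


@dataclass
class TruthRecord:
    """Everything the generator planted, for recovery checks downstream."""

    planted_peaks: pd.DataFrame  # ndr_id, chrom, center, amplitude
    control_peaks: pd.DataFrame  # ndr_id, chrom, center, amplitude
    silent_bins: pd.DataFrame  # index, chrom, start, end
    gene_classes: pd.DataFrame  # id, class, divergent, lost, expression
    dyad_truth: pd.DataFrame  # id, chrom, pos, gene_id, rnapii, pred_occ, lost, acetyl_log2fc
    config: dict = field(default_factory=dict)

    def write(self, prefix) -> None:
        for name in ("planted_peaks", "control_peaks", "silent_bins",
                     "gene_classes", "dyad_truth"):
            getattr(self, name).to_csv(f"{prefix}{name}.tsv", sep="\t", index=False)


def _chrom_names(n: int) -> list[str]:
    return [f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}" for i in range(n)]


def make_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes, upstream NDRs, dyads and exclusions.

    Deterministic given ``config.seed``. Genes are laid out in sequential
    slots from the chromosome start; the remaining tail of each chromosome is
    intergenic space used by :func:`simulate_tracks` for silent bins, and
    hosts the tRNA/centromere exclusion features (placed at least 600 bp from
    any NDR so they never veto a planted peak).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    chroms = _chrom_names(config.n_chromosomes)
    chrom_sizes = {c: config.chrom_length for c in chroms}
    per_chrom = [config.n_genes // config.n_chromosomes
                 + (1 if i < config.n_genes % config.n_chromosomes else 0)
                 for i in range(config.n_chromosomes)]
    genes, ndrs, dyads = [], [], []
    gi = 0
    tails = {}
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = 500
        for _ in range(n_here):
            ndr_w = int(rng.integers(config.ndr_width_range[0],
                                     config.ndr_width_range[1] + 1))
            length = int(rng.integers(config.gene_length_range[0],
                                      config.gene_length_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            slot = _UPSTREAM_MARGIN + ndr_w + length + _DOWNSTREAM_MARGIN
            if cursor + slot > config.chrom_length - 500:
                raise SimulationSizingError(
                    f"gene {gi} does not fit on {chrom}: cursor {cursor} + slot "
                    f"{slot} exceeds usable length {config.chrom_length - 500}")
            gene_id = f"gene_{gi:04d}"
            if strand == "+":
                tss = cursor + _UPSTREAM_MARGIN + ndr_w
                pas = tss + length
                ndr_start, ndr_end = tss - ndr_w, tss
                body_lo, body_hi = tss, pas
                positions = np.arange(tss + _DYAD_EDGE_MARGIN,
                                      pas - _DYAD_EDGE_MARGIN + 1,
                                      config.nucleosome_spacing)
            else:
                pas = cursor + _DOWNSTREAM_MARGIN
                tss = pas + length
                ndr_start, ndr_end = tss, tss + ndr_w
                body_lo, body_hi = pas, tss
                positions = np.arange(tss - _DYAD_EDGE_MARGIN,
                                      pas + _DYAD_EDGE_MARGIN - 1,
                                      -config.nucleosome_spacing)
            genes.append((gene_id, chrom, strand, tss, pas))
            ndrs.append((f"ndr_{gi:04d}", chrom, ndr_start, ndr_end, gene_id))
            for k, pos in enumerate(positions):
                dyads.append((f"dyad_{gi:04d}_{k:02d}", chrom, int(pos), gene_id))
            cursor += slot
            gi += 1
        tails[chrom] = cursor + 600
    exclusions = []
    for chrom in chroms:
        # far end of the chromosome, clear of every NDR by construction
        base = config.chrom_length - 4000
        if base < tails[chrom]:
            continue
        exclusions.append(("tRNA", chrom, base, base + 80))
        exclusions.append(("tRNA", chrom, base + 1000, base + 1080))
        exclusions.append(("centromere", chrom, base + 2000, base + 2120))
    return GenomeAnnotation(
        chrom_sizes=chrom_sizes,
        genes=pd.DataFrame(genes, columns=["id", "chrom", "strand", "tss", "pas"]),
        ndrs=pd.DataFrame(ndrs, columns=["id", "chrom", "start", "end", "gene_id"]),
        dyads=pd.DataFrame(dyads, columns=["id", "chrom", "pos", "gene_id"]),
        exclusions=pd.DataFrame(exclusions, columns=["kind", "chrom", "start", "end"]),
    )


def _silent_bin_slots(annotation: GenomeAnnotation,
                      config: SimulationConfig) -> pd.DataFrame:
    """Grid-aligned intergenic bins eligible to be planted silent, with the
    global bin index they will have in a genome-wide binning of the same width."""
    width = config.silent_bin_width
    margin = 300
    rows = []
    offset = 0
    for chrom, size in annotation.chrom_sizes.items():
        busy = []
        for table, lo_col, hi_col in ((annotation.genes, "tss", "pas"),
                                      (annotation.ndrs, "start", "end"),
                                      (annotation.exclusions, "start", "end")):
            sub = table[table["chrom"] == chrom]
            for _, row in sub.iterrows():
                lo, hi = sorted((int(row[lo_col]), int(row[hi_col])))
                busy.append((lo - _UPSTREAM_MARGIN - margin,
                             hi + _UPSTREAM_MARGIN + margin))
        busy.sort()
        n_bins = -(-size // width)
        for k in range(n_bins):
            start, end = k * width, min((k + 1) * width, size)
            if end - start < width:
                continue
            if any(lo < end and hi > start for lo, hi in busy):
                continue
            rows.append((offset + k, chrom, start, end))
        offset += n_bins
    return pd.DataFrame(rows, columns=["index", "chrom", "start", "end"])


def _zeros(annotation: GenomeAnnotation) -> dict[str, np.ndarray]:
    return {c: np.zeros(n, dtype=np.float64) for c, n in annotation.chrom_sizes.items()}


def _constant(annotation: GenomeAnnotation, value: float) -> dict[str, np.ndarray]:
    return {c: np.full(n, value, dtype=np.float64)
            for c, n in annotation.chrom_sizes.items()}


def _add_bump(data: dict[str, np.ndarray], chrom: str, center: int,
              amplitude: float, sd: float, lo: int, hi: int) -> None:
    """Add a Gaussian bump truncated to [lo, hi) around ``center``."""
    lo = max(lo, 0)
    hi = min(hi, len(data[chrom]))
    x = np.arange(lo, hi)
    data[chrom][lo:hi] += amplitude * np.exp(-((x - center) ** 2) / (2.0 * sd * sd))


def _apply_noise(data: dict[str, np.ndarray], noise_sd: float,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    if noise_sd == 0:
        return data
    return {c: np.maximum(v * (1.0 + rng.normal(0.0, noise_sd, size=len(v))), 0.0)
            for c, v in data.items()}


def simulate_tracks(annotation: GenomeAnnotation, config: SimulationConfig,
                    ) -> tuple[dict[str, CoverageTrack], TruthRecord]:
    """Simulate every coverage track on the 1x (RPGC) scale, plus the truth.

    Returned track keys: rnapii_ip / rnapii_input (and ``_treated``),
    netseq_plus / netseq_minus, hat_ip / hat_input, untagged_ip /
    untagged_input, acetyl_ip / acetyl_input (and ``_treated``), mnase_occ,
    pred_occ.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    genes = annotation.genes
    n_genes = len(genes)

    # --- planted gene classes -------------------------------------------
    n_nt = int(round(n_genes / 5))
    order = rng.permutation(n_genes)
    nt_idx = set(order[:n_nt].tolist())
    expression = np.zeros(n_genes)
    tr_mask = np.array([i not in nt_idx for i in range(n_genes)])
    expression[tr_mask] = np.exp(rng.normal(0.5, 0.5, size=int(tr_mask.sum())))
    tr_indices = np.flatnonzero(tr_mask)
    n_div = int(round(config.fraction_divergent * len(tr_indices)))
    div_idx = set(rng.permutation(tr_indices)[:n_div].tolist())
    n_lost = int(round(config.fraction_lost * len(tr_indices)))
    lost_idx = set(rng.permutation(tr_indices)[:n_lost].tolist())
    classes = np.where(tr_mask, "transcribed", "non_transcribed").astype(object)
    uni = tr_mask & np.array([i not in div_idx for i in range(n_genes)])
    classes[uni] = "unidirectional_transcribed"
    gene_classes = pd.DataFrame({
        "id": genes["id"].to_numpy(),
        "class": classes,
        "divergent": [i in div_idx for i in range(n_genes)],
        "lost": [i in lost_idx for i in range(n_genes)],
        "expression": expression,
    })

    # --- silent bins -----------------------------------------------------
    slots = _silent_bin_slots(annotation, config)
    if len(slots) < config.n_silent_bins:
        raise SimulationSizingError(
            f"only {len(slots)} intergenic bins available for "
            f"{config.n_silent_bins} silent bins")
    silent = slots.iloc[:config.n_silent_bins].reset_index(drop=True)

    # --- RNAPII and nascent transcription -------------------------------
    fc = 2.0 ** config.inhibition_log2fc
    rnapii = _constant(annotation, config.rnapii_background)
    rnapii_tr = _constant(annotation, config.rnapii_background)
    net_plus = _zeros(annotation)
    net_minus = _zeros(annotation)
    for _, row in silent.iterrows():
        rnapii[row["chrom"]][row["start"]:row["end"]] = 0.0
        rnapii_tr[row["chrom"]][row["start"]:row["end"]] = 0.0
    for i, (_, g) in enumerate(genes.iterrows()):
        if expression[i] == 0:
            continue
        chrom, strand = g["chrom"], g["strand"]
        lo, hi = sorted((int(g["tss"]), int(g["pas"])))
        rnapii[chrom][lo:hi] += expression[i]
        rnapii_tr[chrom][lo:hi] += expression[i] * (fc if i in lost_idx else 1.0)
        sense = net_plus if strand == "+" else net_minus
        sense[chrom][lo:hi] += expression[i]
        if i in div_idx:
            anti = net_minus if strand == "+" else net_plus
            tss = int(g["tss"])
            if strand == "+":
                ulo, uhi = tss - 600, tss - 100
            else:
                ulo, uhi = tss + 101, tss + 601
            anti[chrom][max(ulo, 0):uhi] += config.divergent_strength * expression[i]

    # --- factor (HAT) peaks in NDRs --------------------------------------
    ndrs = annotation.ndrs.reset_index(drop=True)
    if config.n_planted_peaks + config.n_control_peaks > len(ndrs):
        raise SimulationSizingError(
            f"{config.n_planted_peaks}+{config.n_control_peaks} peak NDRs requested "
            f"but only {len(ndrs)} NDRs exist")
    ndr_order = rng.permutation(len(ndrs))
    peak_rows = ndr_order[:config.n_planted_peaks]
    control_rows = ndr_order[config.n_planted_peaks:
                             config.n_planted_peaks + config.n_control_peaks]
    hat = _constant(annotation, config.input_depth)
    untagged = _constant(annotation, config.input_depth)
    planted, control_planted = [], []
    for j, row_i in enumerate(peak_rows):
        ndr = ndrs.iloc[row_i]
        start, end = int(ndr["start"]), int(ndr["end"])
        width = end - start
        if config.peak_amplitude_choices:
            amp = float(config.peak_amplitude_choices[j % len(config.peak_amplitude_choices)])
        else:
            amp = float(rng.uniform(*config.peak_amplitude_range))
        center = int(rng.integers(start + width // 4, end - width // 4))
        _add_bump(hat, ndr["chrom"], center, amp, width / 6.0, start, end)
        planted.append((ndr["id"], ndr["chrom"], center, amp))
    for row_i in control_rows:
        ndr = ndrs.iloc[row_i]
        start, end = int(ndr["start"]), int(ndr["end"])
        width = end - start
        center = int(rng.integers(start + width // 4, end - width // 4))
        # artifact signal present in tagged and untagged IPs alike
        for data in (hat, untagged):
            _add_bump(data, ndr["chrom"], center, config.control_amplitude,
                      width / 6.0, start, end)
        control_planted.append((ndr["id"], ndr["chrom"], center, config.control_amplitude))

    # --- nucleosomes: occupancy, predicted occupancy, acetylation --------
    dyads = annotation.dyads.reset_index(drop=True)
    gene_index = {gid: i for i, gid in enumerate(genes["id"])}
    pred_scores = rng.uniform(0.1, 1.0, size=len(dyads))
    occ = _constant(annotation, config.occupancy_background)
    pred = _zeros(annotation)
    acetyl = _constant(annotation, config.acetyl_background)
    acetyl_tr = _constant(annotation, config.acetyl_background)
    dyad_rows = []
    for d_i, (_, d) in enumerate(dyads.iterrows()):
        chrom, pos = d["chrom"], int(d["pos"])
        gi = gene_index[d["gene_id"]]
        e = expression[gi]
        lost = gi in lost_idx
        z = pred_scores[d_i]
        lo, hi = pos - _NUC_FOOTPRINT, pos + _NUC_FOOTPRINT + 1
        _add_bump(occ, chrom, pos, config.occupancy_amplitude, _NUC_SD, lo, hi)
        pred[chrom][max(lo, 0):hi] = z
        amp = config.acetyl_coupling * e + config.mark_occ_coupling * z
        amp_tr = config.acetyl_coupling * e * (fc if lost else 1.0) \
            + config.mark_occ_coupling * z
        _add_bump(acetyl, chrom, pos, amp, _NUC_SD, lo, hi)
        _add_bump(acetyl_tr, chrom, pos, amp_tr, _NUC_SD, lo, hi)
        true_fc = float(np.log2(amp_tr / amp)) if amp > 0 else 0.0
        dyad_rows.append((d["id"], chrom, pos, d["gene_id"], e, z, lost, true_fc))
    dyad_truth = pd.DataFrame(dyad_rows, columns=[
        "id", "chrom", "pos", "gene_id", "rnapii", "pred_occ", "lost",
        "acetyl_log2fc"])

    # --- treated-condition efficiency distortion -------------------------
    eff = config.treated_efficiency
    rnapii_tr = {c: v * eff for c, v in rnapii_tr.items()}
    acetyl_tr = {c: v * eff for c, v in acetyl_tr.items()}

    def track(data, name, role="IP", condition="untreated", strand="."):
        noisy = _apply_noise(data, config.noise_sd, rng)
        return CoverageTrack(data=noisy, name=name, role=role,
                             condition=condition, strand=strand, units=RPGC)

    tracks = {
        "rnapii_ip": track(rnapii, "rnapii_ip"),
        "rnapii_input": track(_constant(annotation, config.input_depth),
                              "rnapii_input", role="input"),
        "rnapii_ip_treated": track(rnapii_tr, "rnapii_ip_treated",
                                   condition="treated"),
        "rnapii_input_treated": track(_constant(annotation, config.input_depth),
                                      "rnapii_input_treated", role="input",
                                      condition="treated"),
        "netseq_plus": track(net_plus, "netseq_plus", strand="+"),
        "netseq_minus": track(net_minus, "netseq_minus", strand="-"),
        "hat_ip": track(hat, "hat_ip"),
        "hat_input": track(_constant(annotation, config.input_depth),
                           "hat_input", role="input"),
        "untagged_ip": track(untagged, "untagged_ip", role="control"),
        "untagged_input": track(_constant(annotation, config.input_depth),
                                "untagged_input", role="control"),
        "acetyl_ip": track(acetyl, "acetyl_ip"),
        "acetyl_input": track(_constant(annotation, config.input_depth),
                              "acetyl_input", role="input"),
        "acetyl_ip_treated": track(acetyl_tr, "acetyl_ip_treated",
                                   condition="treated"),
        "acetyl_input_treated": track(_constant(annotation, config.input_depth),
                                      "acetyl_input_treated", role="input",
                                      condition="treated"),
        "mnase_occ": track(occ, "mnase_occ"),
        "pred_occ": track(pred, "pred_occ"),
    }
    truth = TruthRecord(
        planted_peaks=pd.DataFrame(planted, columns=["ndr_id", "chrom", "center",
                                                     "amplitude"]),
        control_peaks=pd.DataFrame(control_planted,
                                   columns=["ndr_id", "chrom", "center", "amplitude"]),
        silent_bins=silent,
        gene_classes=gene_classes,
        dyad_truth=dyad_truth,
        config=asdict(config),
    )
    return tracks, truth
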