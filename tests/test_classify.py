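"""Gene and nucleosome classification from nascent-transcription signal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from txnacetyl import (CoverageTrack, classify_mouse_genes,
                       classify_nucleosome_change, classify_yeast_genes,
                       window_signal)
from txnacetyl.classify import lowest_quintile_mask

SIZES = {"chrI": 20_000}


def _track(values):
    return CoverageTrack(data={"chrI": np.asarray(values, dtype=float)},
                         units="RPGC")


def test_window_signal_strand_orientation(rng):
    vals = rng.random(20_000)
    track = _track(vals)
    plus = window_signal(track, "chrI", 3000, "+", 0, 500)
    assert plus == pytest.approx(vals[3000:3500].mean())
    minus = window_signal(track, "chrI", 3000, "-", 0, 500)
    assert minus == pytest.approx(vals[2501:3001].mean())
    upstream = window_signal(track, "chrI", 3000, "+", -600, -100)
    assert upstream == pytest.approx(vals[2400:2900].mean())


def test_window_signal_constant_and_clipping():
    track = _track(np.full(20_000, 3.3))
    assert window_signal(track, "chrI", 100, "+", 0, 500) == pytest.approx(3.3)
    # entirely off-chromosome window is undefined
    assert np.isnan(window_signal(track, "chrI", 0, "+", -600, -100))


def _gene_frame(n, tss_spacing=1500):
    return pd.DataFrame({
        "id": [f"g{i:03d}" for i in range(n)],
        "chrom": "chrI",
        "strand": "+",
        "tss": 700 + tss_spacing * np.arange(n),
        "pas": 700 + tss_spacing * np.arange(n) + 900,
    })


def test_zero_downstream_genes_are_non_transcribed():
    genes = _gene_frame(10)
    sense = np.zeros(20_000)
    for i, tss in enumerate(genes["tss"]):
        if i not in (3, 7):
            sense[tss:tss + 500] = 1.0 + i
    result = classify_yeast_genes(_track(sense), _track(np.zeros(20_000)), genes)
    nt = set(result.loc[result["class"] == "non_transcribed", "id"])
    assert nt == {"g003", "g007"}


def test_all_tied_upstream_makes_all_transcribed_unidirectional():
    genes = _gene_frame(10)
    sense = np.zeros(20_000)
    for tss in genes["tss"][2:]:
        sense[tss:tss + 500] = 2.0
    result = classify_yeast_genes(_track(sense), _track(np.zeros(20_000)), genes)
    transcribed = result["class"] != "non_transcribed"
    assert (result.loc[transcribed, "class"] == "unidirectional_transcribed").all()


def test_planted_divergence_recovered_exactly(small_genome, small_sim):
    """Noise-free simulated promoters classify back to their planted classes."""
    tracks, truth = small_sim
    result = classify_yeast_genes(tracks["netseq_plus"], tracks["netseq_minus"],
                                  small_genome.genes)
    merged = result.merge(truth.gene_classes, on="id", suffixes=("_called", "_true"))
    assert (merged["class_called"] == merged["class_true"]).all()


def test_classification_invariant_under_monotone_transform():
    genes = _gene_frame(10)
    rng = np.random.default_rng(5)
    sense = np.zeros(20_000)
    anti = np.zeros(20_000)
    for tss in genes["tss"]:
        sense[tss:tss + 500] = rng.random() * 4
        anti[tss - 600:tss - 100] = rng.random() * 2
    a = classify_yeast_genes(_track(sense), _track(anti), genes)
    b = classify_yeast_genes(_track(np.expm1(sense)), _track(np.expm1(anti)), genes)
    assert a["class"].equals(b["class"])


def test_mouse_median_rule_is_strict():
    genes = _gene_frame(6)
    sense = np.zeros(20_000)
    for i, tss in enumerate(genes["tss"]):
        sense[tss:tss + 1000] = [1, 1, 1, 3, 3, 3][i]
    result = classify_mouse_genes(_track(sense), _track(np.zeros(20_000)), genes)
    transcribed = result["class"] != "non_transcribed"
    # median is 2; only the signal-3 genes exceed it strictly
    assert transcribed.sum() == 3
    assert set(result.loc[transcribed, "id"]) == {"g003", "g004", "g005"}


@given(st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=60))
def test_lowest_quintile_size_bounds(scores):
    scores = np.asarray(scores)
    mask = lowest_quintile_mask(scores)
    k = int(round(len(scores) / 5))
    cut = np.sort(scores)[k - 1]
    n_tied = int((scores == cut).sum())
    assert mask.sum() <= k + n_tied
    if len(np.unique(scores)) == len(scores):
        assert mask.sum() == k


def _change_tracks(befores, afters, spacing=200, halfwidth=50):
    n = spacing * (len(befores) + 2)
    before = np.zeros(n)
    after = np.zeros(n)
    dyads = []
    for i, (b, a) in enumerate(zip(befores, afters)):
        pos = spacing * (i + 1)
        before[pos - halfwidth:pos + halfwidth + 1] = b
        after[pos - halfwidth:pos + halfwidth + 1] = a
        dyads.append((f"d{i}", "chrI", pos, None))
    frame = pd.DataFrame(dyads, columns=["id", "chrom", "pos", "gene_id"])
    mk = lambda v: CoverageTrack(data={"chrI": v}, units="RPGC")
    return mk(before), mk(after), frame


@pytest.mark.parametrize("ratio,expected", [
    (1.0, "stable"),
    (1.0 / 3.0, "lost"),
    (0.34, "other"),
    (1.09, "stable"),
    (1.10, "other"),
    (0.9, "other"),
])
def test_nucleosome_change_thresholds(ratio, expected):
    # two low-occupancy dyads keep the median below the probed dyads
    befores = [0.1, 0.1, 3.0, 3.0]
    afters = [0.1, 0.1, 3.0 * ratio, 3.0 * ratio]
    before, after, dyads = _change_tracks(befores, afters)
    result = classify_nucleosome_change(before, after, dyads)
    assert (result.loc[2:, "class"] == expected).all()
    assert (result.loc[:1, "class"] == "unclassified").all()


def test_stable_and_lost_are_disjoint_over_ratio_grid():
    ratios = np.linspace(0.01, 2.0, 101)
    befores = np.concatenate([[0.1, 0.1], np.full(len(ratios), 3.0)])
    afters = np.concatenate([[0.1, 0.1], 3.0 * ratios])
    before, after, dyads = _change_tracks(befores.tolist(), afters.tolist())
    result = classify_nucleosome_change(before, after, dyads)
    assert not ((result["class"] == "stable") & (result["class"] == "lost")).any()
    classified = result["class"] != "unclassified"
    assert set(result.loc[classified, "class"]) <= {"stable", "lost", "other"}
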