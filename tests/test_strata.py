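"""Nested quintile stratification and dyad-aligned profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from txnacetyl import (CoverageTrack, SimulationConfig, assign_quintiles,
                       dyad_window_score, log2_ratio, make_genome,
                       nested_strata, score_dyads, simulate_tracks,
                       stratum_dyad_profiles)


def test_dyad_window_score_matches_bruteforce(rng):
    vals = rng.normal(size=5000)
    track = CoverageTrack(data={"chrI": vals}, units="log2ratio")
    for pos in rng.integers(60, 4940, size=20):
        score = dyad_window_score(track, "chrI", int(pos))
        assert score == pytest.approx(vals[pos - 50:pos + 51].mean())


def test_mostly_masked_window_is_undefined():
    vals = np.zeros(1000)
    vals[400:460] = np.nan  # 60 of 101 window bases masked
    track = CoverageTrack(data={"chrI": vals}, units="log2ratio")
    assert np.isnan(dyad_window_score(track, "chrI", 430))
    assert dyad_window_score(track, "chrI", 700) == 0.0


def test_quintiles_exact_split_and_tie_balance():
    labels = assign_quintiles(np.arange(1, 11))
    assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
    tied = assign_quintiles(np.zeros(12))
    sizes = np.bincount(tied)[1:]
    assert sizes.max() - sizes.min() <= 1


@given(st.integers(5, 200), st.integers(0, 10_000))
def test_quintile_sizes_match_rank_partition(n, seed):
    rng = np.random.default_rng(seed)
    scores = rng.random(n)
    labels = assign_quintiles(scores)
    # brute force: stable sort, then split ranks into 5 near-equal groups
    order = np.argsort(scores, kind="stable")
    expected = np.empty(n, dtype=int)
    expected[order] = np.arange(n) * 5 // n + 1
    assert (labels == expected).all()
    sizes = np.bincount(labels)[1:]
    assert sizes.max() - sizes.min() <= 1


def _scores(n, rng):
    return pd.DataFrame({
        "id": [f"d{i:04d}" for i in range(n)],
        "rpb3_score": rng.normal(size=n),
        "occ_score": rng.normal(size=n),
    })


def test_nested_partition_is_balanced(rng):
    assignment = nested_strata(_scores(250, rng))
    sizes = assignment.groupby(["q_rpb3", "q_occ"]).size()
    assert len(sizes) == 25
    assert sizes.between(9, 11).all()
    # every dyad in exactly one cell
    assert len(assignment) == 250


def test_constant_scores_still_balance(rng):
    scores = _scores(100, rng)
    scores["occ_score"] = 1.0
    sizes = nested_strata(scores).groupby(["q_rpb3", "q_occ"]).size()
    assert sizes.max() - sizes.min() <= 1
    scores["rpb3_score"] = 0.0
    flat = nested_strata(scores)
    # with constant RNAPII scores the nested split reduces to a flat
    # occupancy-only split within each tie-broken fifth
    assert flat.groupby("q_rpb3").size().tolist() == [20] * 5


def test_too_few_dyads_is_an_error(rng):
    with pytest.raises(ValueError):
        nested_strata(_scores(4, rng))


def test_undefined_scores_are_dropped(rng):
    scores = _scores(60, rng)
    scores.loc[5, "rpb3_score"] = np.nan
    assignment = nested_strata(scores)
    assert len(assignment) == 59
    assert "d0005" not in set(assignment["id"])


def test_stratum_profiles_match_bruteforce(rng):
    vals = rng.normal(size=20_000)
    track = CoverageTrack(data={"chrI": vals}, units="log2ratio")
    assignment = pd.DataFrame({
        "chrom": "chrI",
        "pos": rng.integers(300, 19_700, size=50),
        "q_rpb3": rng.integers(1, 6, size=50),
        "q_occ": rng.integers(1, 6, size=50),
    })
    profiles = stratum_dyad_profiles(track, assignment, flank=100)
    cell = assignment[(assignment["q_rpb3"] == assignment["q_rpb3"].iloc[0])
                      & (assignment["q_occ"] == assignment["q_occ"].iloc[0])]
    sub = profiles[(profiles["q_rpb3"] == assignment["q_rpb3"].iloc[0])
                   & (profiles["q_occ"] == assignment["q_occ"].iloc[0])]
    for offset in (-100, -3, 0, 57, 100):
        expected = np.mean([vals[p + offset] for p in cell["pos"]])
        got = sub.loc[sub["offset"] == offset, "mean"].iloc[0]
        assert got == pytest.approx(expected)
    assert (sub["n"] == len(cell)).all()


def test_constant_track_gives_constant_profiles(rng):
    track = CoverageTrack(data={"chrI": np.full(5000, 2.2)}, units="RPGC")
    assignment = pd.DataFrame({
        "chrom": "chrI", "pos": rng.integers(300, 4700, size=30),
        "q_rpb3": 1, "q_occ": rng.integers(1, 6, size=30)})
    profiles = stratum_dyad_profiles(track, assignment, flank=50)
    np.testing.assert_allclose(profiles["mean"], 2.2)


def _strata_run(mark_occ_coupling, seed):
    cfg = SimulationConfig(n_chromosomes=2, chrom_length=110_000, n_genes=60,
                           n_planted_peaks=5, n_control_peaks=0, n_silent_bins=10,
                           mark_occ_coupling=mark_occ_coupling, acetyl_coupling=1.0,
                           seed=seed)
    annotation = make_genome(cfg)
    tracks, truth = simulate_tracks(annotation, cfg)
    rpb3 = log2_ratio(tracks["rnapii_ip"], tracks["rnapii_input"])
    mark = log2_ratio(tracks["acetyl_ip"], tracks["mnase_occ"])
    transcribed = set(truth.gene_classes.loc[
        truth.gene_classes["class"] != "non_transcribed", "id"])
    dyads = annotation.dyads[annotation.dyads["gene_id"].isin(transcribed)]
    scores = score_dyads(rpb3, tracks["pred_occ"], dyads, mark_log2={"mark": mark})
    assignment = nested_strata(scores)
    return assignment.groupby(["q_rpb3", "q_occ"])["mark_score"].mean().unstack(), \
        assignment


def test_occupancy_coupled_mark_increases_across_occ_quintiles():
    cell_means, _ = _strata_run(mark_occ_coupling=4.0, seed=21)
    for q in range(1, 6):
        assert (np.diff(cell_means.loc[q]) > 0).all(), f"rpb3 quintile {q} not monotone"


def test_uncoupled_mark_shows_no_consistent_trend():
    rhos = []
    for seed in (21, 22, 23):
        cell_means, _ = _strata_run(mark_occ_coupling=0.0, seed=seed)
        for q in range(1, 6):
            rho, _ = stats.spearmanr(np.arange(5), cell_means.loc[q])
            rhos.append(abs(rho))
    assert np.mean(rhos) < 0.9


def test_rnapii_is_matched_within_quintiles():
    """Across occupancy quintiles the RNAPII level barely moves; across
    RNAPII quintiles it spans the full dynamic range."""
    _, assignment = _strata_run(mark_occ_coupling=4.0, seed=21)
    r = assignment.groupby(["q_rpb3", "q_occ"])["rpb3_score"].mean().unstack()
    within = (r.max(axis=1) - r.min(axis=1)).max()
    across = r.mean(axis=1).max() - r.mean(axis=1).min()
    assert within < across
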