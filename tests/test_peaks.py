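"""NDR difference profiles, spline peak fitting, and peak calling."""

import numpy as np
import pandas as pd
import pytest

from txnacetyl import (CoverageTrack, call_epl1_peaks, compare_ndr_groups,
                       fit_spline_peak, ndr_difference_profile,
                       select_depleted_ndrs)
from txnacetyl.peaks import NdrProfile
from txnacetyl.tracks import empty_annotation


def _bump(width, center, amplitude, sd):
    x = np.arange(width)
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sd * sd))


def _profile(diff):
    n = len(diff)
    return NdrProfile("ndr", "chrI", 0, n, ip=np.asarray(diff, float) + 1.0,
                      input=np.ones(n))


def test_difference_profile_extraction():
    ip = CoverageTrack(data={"chrI": np.full(1000, 1.0) + _bump(1000, 500, 1.0, 30)},
                       units="RPGC")
    inp = CoverageTrack(data={"chrI": np.ones(1000)}, units="RPGC")
    ndr = pd.Series({"id": "n0", "chrom": "chrI", "start": 400, "end": 650})
    profile = ndr_difference_profile(ip, inp, ndr)
    assert len(profile) == 250
    assert profile.difference.max() == pytest.approx(1.0)
    same = ndr_difference_profile(inp, inp, ndr)
    assert (same.difference == 0).all()


def test_short_ndr_rejected_by_fitter():
    with pytest.raises(ValueError, match="minimum fit length"):
        fit_spline_peak(_profile(np.zeros(5)))


def test_nonfinite_profile_rejected():
    diff = np.zeros(100)
    diff[3] = np.inf
    prof = NdrProfile("n", "chrI", 0, 100, ip=diff, input=np.zeros(100))
    with pytest.raises(ValueError, match="non-finite"):
        fit_spline_peak(prof)


@pytest.mark.parametrize("width,sd", [(200, 10), (200, 20), (120, 20), (300, 50)])
def test_symmetric_bump_position_and_amplitude(width, sd):
    center = width // 2
    pos, amp = fit_spline_peak(_profile(_bump(width, center, 1.0, sd)))
    assert abs(pos - center) <= 1
    assert 0.8 <= amp <= 1.02  # smoothing shrinks; LSQ may overshoot ~1%


def test_constant_profile_flat_fit_leftmost_tie():
    pos, amp = fit_spline_peak(_profile(np.full(80, 0.7)))
    assert pos == 0
    assert amp == pytest.approx(0.7)


def _peak_setup(amplitudes, control_amplitudes=None, width=200, sd=25):
    """One NDR per amplitude on a single chromosome; flat inputs."""
    n_ndrs = len(amplitudes)
    size = 1000 * (n_ndrs + 1)
    annotation = empty_annotation({"chrI": size})
    ip = np.ones(size)
    control = np.ones(size)
    rows = []
    for i, a in enumerate(amplitudes):
        start = 1000 * i + 400
        center = start + width // 2
        ip[start:start + width] += _bump(width, width // 2, a, sd)
        if control_amplitudes:
            control[start:start + width] += _bump(width, width // 2,
                                                  control_amplitudes[i], sd)
        rows.append((f"n{i}", "chrI", start, start + width, None))
    annotation.ndrs = pd.DataFrame(rows, columns=["id", "chrom", "start", "end",
                                                  "gene_id"])
    mk = lambda v: CoverageTrack(data={"chrI": v}, units="RPGC")
    flat = mk(np.ones(size))
    return mk(ip), flat, mk(control), annotation


def test_threshold_selects_expected_planted_amplitudes():
    ip, flat, control, annotation = _peak_setup([0.3, 0.6, 1.2])
    called = call_epl1_peaks(ip, flat, control, flat, annotation, threshold=0.5)
    assert {p.ndr_id for p in called} == {"n1", "n2"}


def test_control_bump_suppresses_call():
    ip, flat, control, annotation = _peak_setup([1.2, 1.2],
                                                control_amplitudes=[0.0, 1.2])
    called = call_epl1_peaks(ip, flat, control, flat, annotation)
    assert {p.ndr_id for p in called} == {"n0"}


def test_trna_proximity_excludes_ndr():
    ip, flat, control, annotation = _peak_setup([1.5, 1.5])
    annotation.exclusions = pd.DataFrame(
        [("tRNA", "chrI", 100, 180)], columns=["kind", "chrom", "start", "end"])
    called = call_epl1_peaks(ip, flat, control, flat, annotation)
    assert {p.ndr_id for p in called} == {"n1"}  # n0 is within 500 bp of the tRNA


def test_missing_control_is_an_error():
    ip, flat, control, annotation = _peak_setup([1.0])
    with pytest.raises(ValueError, match="untagged"):
        call_epl1_peaks(ip, flat, None, None, annotation)


def test_raising_amplitude_never_uncalls():
    rng = np.random.default_rng(11)
    for _ in range(20):
        width = int(rng.integers(120, 300))
        sd = width / 6
        a = float(rng.uniform(0.3, 1.2))
        ip, flat, control, annotation = _peak_setup([a], width=width, sd=sd)
        before = call_epl1_peaks(ip, flat, control, flat, annotation)
        ip2, _, _, _ = _peak_setup([a + float(rng.uniform(0.05, 1.0))],
                                   width=width, sd=sd)
        after = call_epl1_peaks(ip2, flat, control, flat, annotation)
        if before:
            assert after, f"raising amplitude {a} un-called the peak"


def test_depleted_selection_boundary():
    ip, flat, control, annotation = _peak_setup([0.0, 0.05])
    # identical IP and input: every NDR is depleted
    assert set(select_depleted_ndrs(flat, flat, annotation)) == {"n0", "n1"}
    # a single base exactly at the threshold is not depleted (strict <)
    spike = flat.copy()
    spike.data["chrI"][450] += 0.1
    assert set(select_depleted_ndrs(spike, flat, annotation)) == {"n1"}


def test_called_and_depleted_are_disjoint(small_sim, small_genome):
    tracks, truth = small_sim
    called = call_epl1_peaks(tracks["hat_ip"], tracks["hat_input"],
                             tracks["untagged_ip"], tracks["untagged_input"],
                             small_genome)
    depleted = select_depleted_ndrs(tracks["hat_ip"], tracks["hat_input"],
                                    small_genome)
    assert {p.ndr_id for p in called}.isdisjoint(depleted)


def test_pooled_t_test_against_closed_form():
    ma, mb, t, p = compare_ndr_groups([1, 2, 3], [4, 5, 6])
    # pooled variance = 1, se = sqrt(2/3): t = -3 / sqrt(2/3)
    assert (ma, mb) == (2.0, 5.0)
    assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
    assert p == pytest.approx(0.021312, abs=1e-5)
    mb2, ma2, t2, p2 = compare_ndr_groups([4, 5, 6], [1, 2, 3])
    assert t2 == pytest.approx(-t) and p2 == pytest.approx(p)


def test_identical_groups_give_p_one():
    assert compare_ndr_groups([2, 2, 2], [2, 2, 2])[2:] == (0.0, 1.0)
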