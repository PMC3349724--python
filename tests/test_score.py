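"""Pairing, distance, clustering, and ploidy metrics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairfish.errors import (
    EmptyWellError,
    GroupingError,
    InsufficientControlsError,
)
from pairfish.image import Channel
from pairfish.score import (
    DistancePool,
    ScoreParams,
    call_pairing,
    classify_count_bin,
    detect_colocalization,
    large_nucleus_cutoff,
    mean_intersignal_distance,
    pairwise_distances,
    score_nucleus,
    summarize_well,
    volume_proxy,
)
from pairfish.segment import NucleusRecord

from conftest import make_focus


# ---------------------------------------------------------------------------
# count bins

@pytest.mark.parametrize("count,expected", [
    (0, "0"), (1, "1"), (2, "2"), (3, "3"), (4, "4"), (5, "5+"), (7, "5+"),
    (100, "5+"),
])
def test_count_bins(count, expected):
    assert classify_count_bin(count) == expected


def test_negative_count_rejected():
    with pytest.raises(ValueError):
        classify_count_bin(-1)


# ---------------------------------------------------------------------------
# distances

def test_pairwise_distance_basics():
    assert pairwise_distances([make_focus(1, 1)]).size == 0
    d = pairwise_distances([make_focus(0, 0), make_focus(0.6, 0.8)])
    assert d == pytest.approx([1.0])


def test_pairwise_distances_mixed_nuclei_rejected():
    with pytest.raises(GroupingError):
        pairwise_distances([make_focus(0, 0, nucleus_label=1),
                            make_focus(1, 1, nucleus_label=2)])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_pairwise_distances_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 10, (4, 2))
    foci = [make_focus(x, y) for x, y in pts]
    got = sorted(pairwise_distances(foci))
    want = sorted(np.hypot(*(pts[i] - pts[j]))
                  for i in range(4) for j in range(i + 1, 4))
    assert np.allclose(got, want)


# ---------------------------------------------------------------------------
# pairing calls

def test_single_signal_is_paired():
    assert call_pairing([make_focus(2, 2)]) is True


def test_two_signals_beyond_threshold_are_unpaired():
    assert call_pairing([make_focus(0, 0), make_focus(1.2, 0)]) is False
    assert call_pairing([make_focus(0, 0), make_focus(0.99, 0)]) is True


def test_all_pairs_rule_requires_every_distance_below_threshold():
    # distances {0.5, 0.9, 1.1}: one failing pair unpairs the nucleus
    foci = [make_focus(0, 0), make_focus(0.5, 0),
            make_focus(-0.15, 0.8874)]
    d = sorted(pairwise_distances(foci))
    assert d[0] <= 1.0 and d[1] <= 1.0 < d[2]
    assert call_pairing(foci) is False


def test_zero_signals_not_paired():
    assert call_pairing([]) is False


def test_pairing_monotone_in_threshold():
    rng = np.random.default_rng(1)
    nuclei_foci = [
        [make_focus(*rng.uniform(0, 3, 2)) for _ in range(rng.integers(1, 4))]
        for _ in range(40)]
    fractions = []
    for thr in (0.25, 0.5, 1.0, 2.0, 5.0):
        p = ScoreParams(pairing_threshold_um=thr)
        fractions.append(np.mean([call_pairing(f, p) for f in nuclei_foci]))
    assert fractions == sorted(fractions)


# ---------------------------------------------------------------------------
# inter-signal distance and colocalization

def test_mean_intersignal_distance_examples():
    assert mean_intersignal_distance([make_focus(1, 1)], []) is None
    a = [make_focus(0, 0, channel=Channel.FISH_A)]
    b = [make_focus(2.0, 0, channel=Channel.FISH_B)]
    assert mean_intersignal_distance(a, b) == pytest.approx(2.0)
    tri_a = [make_focus(0, 0), make_focus(3, 0)]
    tri_b = [make_focus(0, 4)]
    assert mean_intersignal_distance(tri_a, tri_b) == pytest.approx(4.0)


def test_cross_channel_pool_ignores_same_channel_pairs():
    p = ScoreParams(distance_pool=DistancePool.CROSS_CHANNEL_ONLY)
    a = [make_focus(0, 0), make_focus(10, 0)]
    b = [make_focus(0, 3)]
    # cross pairs: 3 and sqrt(109); union pool would include the 10
    want = (3 + np.hypot(10, 3)) / 2
    assert mean_intersignal_distance(a, b, p) == pytest.approx(want)
    assert mean_intersignal_distance(a, [], p) is None


def test_colocalization_requires_shared_pixel_and_is_symmetric():
    f1 = make_focus(1, 1, pixels=[(5, 5), (5, 6)])
    f2 = make_focus(1.2, 1, pixels=[(5, 6), (5, 7)])
    f3 = make_focus(2, 2, pixels=[(5, 8), (5, 9)])  # adjacent, disjoint
    assert detect_colocalization([f1], [f2]) is True
    assert detect_colocalization([f2], [f1]) is True
    assert detect_colocalization([f1], [f3]) is False
    assert detect_colocalization([], [f1]) is False


# ---------------------------------------------------------------------------
# size metrics

def test_large_cutoff_uses_linear_interpolation():
    sizes = np.arange(1.0, 101.0)
    cutoff = large_nucleus_cutoff(sizes)
    assert cutoff == pytest.approx(95.05)
    assert 96.0 >= cutoff          # size 96 is flagged large
    assert not 95.0 >= cutoff      # size 95 is not


def test_large_cutoff_at_equality_counts_as_large():
    cutoff = large_nucleus_cutoff(np.full(30, 7.5))
    assert cutoff == pytest.approx(7.5)
    assert 7.5 >= cutoff


def test_large_cutoff_needs_enough_controls():
    with pytest.raises(InsufficientControlsError):
        large_nucleus_cutoff(np.arange(10.0))


@pytest.mark.parametrize("area,expected", [
    (0.0, 0.0),
    (np.pi, 4 * np.pi / 3),
    (4 * np.pi, 32 * np.pi / 3),
])
def test_volume_proxy_sphere_equivalents(area, expected):
    assert volume_proxy(area) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# well summaries

def _nucleus(label, area_um2=50.0):
    return NucleusRecord(label=label, pixel_count=int(area_um2 / 0.04),
                         area_um2=area_um2, centroid_um=(5, 5),
                         touches_border=False,
                         volume_proxy_um3=volume_proxy(area_um2),
                         rows=np.array([0]), cols=np.array([0]))


def test_summary_all_single_focus():
    scores = [score_nucleus(_nucleus(i), {
        "FISH_A": [make_focus(1, 1, nucleus_label=i)],
        "FISH_B": [make_focus(3, 3, nucleus_label=i,
                              pixels=[(15, 15), (15, 16)])],
    }) for i in range(1, 11)]
    s = summarize_well(scores)
    ch = s.channels["FISH_A"]
    assert ch.pct_single == pytest.approx(100.0)
    assert ch.fraction_by_bin == pytest.approx((0, 1, 0, 0, 0, 0))
    assert s.pct_1r1g == pytest.approx(100.0)
    assert s.pct_1r1g_touch <= s.pct_1r1g


def test_summary_pct_paired_and_bin_fractions():
    scores = []
    for i in range(1, 11):
        if i <= 7:  # paired: single focus
            foci = [make_focus(1, 1, nucleus_label=i)]
        else:       # unpaired: two distant foci
            foci = [make_focus(0, 0, nucleus_label=i),
                    make_focus(3, 0, nucleus_label=i, pixels=[(0, 15)])]
        scores.append(score_nucleus(_nucleus(i), {"FISH_A": foci}))
    s = summarize_well(scores)
    ch = s.channels["FISH_A"]
    assert ch.pct_paired == pytest.approx(70.0)
    assert ch.pct_single == pytest.approx(70.0)
    assert sum(ch.fraction_by_bin) == pytest.approx(1.0, abs=1e-9)
    assert ch.pct_single == pytest.approx(100 * ch.fraction_by_bin[1])


def test_far_fraction_uses_two_focus_nuclei_only():
    scores = []
    specs = [  # (n foci, separation um)
        (2, 5.0), (2, 2.0), (1, None), (3, None),
    ]
    for i, (n, sep) in enumerate(specs, start=1):
        if n == 1:
            foci = [make_focus(1, 1, nucleus_label=i)]
        elif n == 2:
            foci = [make_focus(0, 0, nucleus_label=i),
                    make_focus(sep, 0, nucleus_label=i, pixels=[(0, 25)])]
        else:
            foci = [make_focus(x, 0, nucleus_label=i, pixels=[(0, 30 + 5 * k)])
                    for k, x in enumerate((0, 2, 9))]
        scores.append(score_nucleus(_nucleus(i), {"FISH_A": foci}))
    s = summarize_well(scores)
    # of the two 2-focus nuclei, one exceeds 4 um
    assert s.channels["FISH_A"].pct_far == pytest.approx(50.0)


def test_empty_well_raises():
    with pytest.raises(EmptyWellError):
        summarize_well([])


def test_distance_histogram_open_terminal_bin():
    scores = [score_nucleus(_nucleus(1), {"FISH_A": [
        make_focus(0, 0, nucleus_label=1),
        make_focus(7.0, 0, nucleus_label=1, pixels=[(0, 35)]),
    ]})]
    s = summarize_well(scores)
    hist = s.channels["FISH_A"].distance_histogram
    assert hist.sum() == 1
    assert hist[-1] == 1  # the 7 um pair lands in the > 4 um bin
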