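"""Plate z-scores, dual-replicate hit calling, and validation tests."""
import numpy as np
import pytest
from scipy import stats

from pairfish.errors import (
    DegeneratePlateError,
    DegenerateVarianceError,
    ReplicateError,
    SampleSizeError,
)
from pairfish.score import WellSummary
from pairfish.screen import (
    HitCategory,
    ScreenParams,
    call_primary_hits,
    distance_shift_test,
    plate_zscores,
    validate_candidate,
    welch_t_test,
)


def _wells(values, channel="FISH_B"):
    return {w: WellSummary.from_metrics(v, channel=channel, well_id=w)
            for w, v in values.items()}


# ---------------------------------------------------------------------------
# z-scores

def test_zscore_of_plate_mean_is_zero():
    z = plate_zscores({"A": 60.0, "B": 70.0, "C": 80.0})
    assert z["B"] == pytest.approx(0.0)
    assert z["A"] == pytest.approx(-1.0)  # sample SD is 10


def test_zscores_match_direct_oracle_and_normalize():
    rng = np.random.default_rng(0)
    vals = {f"W{i:03d}": float(v)
            for i, v in enumerate(rng.normal(80, 3, 384))}
    z = plate_zscores(vals)
    x = np.array(list(vals.values()))
    want = (x - x.mean()) / x.std(ddof=1)
    assert np.allclose(list(z.values()), want, atol=1e-12)
    zx = np.array(list(z.values()))
    assert zx.mean() == pytest.approx(0.0, abs=1e-9)
    assert zx.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_degenerate_plates_raise():
    with pytest.raises(DegeneratePlateError):
        plate_zscores({"A": 1.0, "B": 2.0})
    with pytest.raises(DegeneratePlateError):
        plate_zscores({"A": 5.0, "B": 5.0, "C": 5.0})


def test_controls_excluded_from_plate_stats():
    vals = {"A": 70.0, "B": 80.0, "C": 90.0, "P": 10.0}
    roles = {"A": "library", "B": "library", "C": "library",
             "P": "pos_control"}
    z = plate_zscores(vals, roles=roles)
    assert z["B"] == pytest.approx(0.0)       # stats over A, B, C only
    assert z["P"] == pytest.approx(-7.0)      # but the control is scored
    z_all = plate_zscores(vals, ScreenParams(
        exclude_controls_from_plate_stats=False), roles=roles)
    assert z_all["B"] != pytest.approx(0.0)


# ---------------------------------------------------------------------------
# hit calling

def _reps_from_z(z1_map, z2_map, base=80.0, sd=3.0):
    """Build replicate WellSummaries whose pct_single z-scores equal the
    requested values (8 padding wells pin mean and SD)."""
    def build(zmap):
        # 32 padding wells with zero-mean spread keep one extreme well from
        # dominating the plate SD
        vals = {f"pad{i}": base + sd * v
                for i, v in enumerate([-1.5, -0.5, 0.5, 1.5] * 8)}
        for w, z in zmap.items():
            vals[w] = base + sd * z
        return vals
    return build(z1_map), build(z2_map)


def _call(z1_map, z2_map):
    v1, v2 = _reps_from_z(z1_map, z2_map)
    # normalise to the actual plate stats so requested z's are approximate;
    # use generous margins in the assertions instead
    hits = call_primary_hits(_wells(v1), _wells(v2))
    return {h.well_id: h for h in hits}


def test_hit_requires_both_replicates():
    hits = _call({"X": -3.5}, {"X": -0.5})
    assert hits["X"].category is HitCategory.NONE


def test_anti_pairer_from_dual_positive_z():
    hits = _call({"X": 3.2}, {"X": 3.7})
    assert hits["X"].category is HitCategory.ANTI_PAIRER


def test_pairing_promoter_from_dual_negative_z():
    hits = _call({"X": -3.5}, {"X": -4.0})
    assert hits["X"].category is HitCategory.PAIRING_PROMOTER


def test_promoter_via_multi_focus_bin_channel():
    # pct_single unremarkable, but the 3-focus bin fraction spikes in both
    def build(spike):
        vals = {}
        rng = np.random.default_rng(42 + int(spike * 100))
        for i in range(12):
            frac3 = 0.05 + 0.01 * rng.standard_normal()
            vals[f"W{i}"] = WellSummary.from_metrics(
                80.0 + rng.normal(0, 1),
                fraction_by_bin=(0.0, 0.8, 0.15 - frac3, frac3, 0.0, 0.05),
                well_id=f"W{i}")
        vals["X"] = WellSummary.from_metrics(
            80.0, fraction_by_bin=(0.0, 0.55, 0.10, 0.30, 0.0, 0.05),
            well_id="X")
        return vals
    hits = call_primary_hits(build(1), build(2))
    by_id = {h.well_id: h for h in hits}
    assert by_id["X"].category is HitCategory.PAIRING_PROMOTER
    assert by_id["X"].metric == "bin_fraction(3)"


def test_hit_calling_invariant_to_ordering_and_affine_rescaling():
    rng = np.random.default_rng(1)
    vals1 = {f"W{i}": float(v) for i, v in enumerate(rng.normal(80, 3, 40))}
    vals2 = {f"W{i}": float(v) for i, v in enumerate(rng.normal(80, 3, 40))}
    vals1["W0"] = vals2["W0"] = 55.0  # a clear hit
    base = call_primary_hits(_wells(vals1), _wells(vals2))
    shuffled = dict(sorted(vals1.items(), reverse=True))
    rescaled = {w: 3.0 * v + 11.0 for w, v in vals2.items()}
    alt = call_primary_hits(_wells(shuffled), _wells(rescaled))
    assert [(h.well_id, h.category) for h in base] == \
           [(h.well_id, h.category) for h in alt]


def test_mismatched_layouts_rejected():
    with pytest.raises(ReplicateError):
        call_primary_hits(_wells({"A": 1, "B": 2, "C": 3}),
                          _wells({"A": 1, "B": 2, "D": 3}))


# ---------------------------------------------------------------------------
# Welch t test

def test_identical_samples_give_t0_p1():
    t, df, p = welch_t_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_matches_scipy_unequal_variance():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = rng.normal(0, 1, rng.integers(3, 30))
        b = rng.normal(0.5, 3, rng.integers(3, 30))
        t, df, p = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_welch_symmetry_and_shift():
    a = [1, 2, 3, 4, 5]
    b = [11, 12, 13, 14, 15]
    t1, _, p1 = welch_t_test(a, b)
    t2, _, p2 = welch_t_test(b, a)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)
    assert t1 < 0 and p1 < 0.001


def test_welch_degenerate_inputs():
    with pytest.raises(SampleSizeError):
        welch_t_test([1.0], [1.0, 2.0])
    with pytest.raises(DegenerateVarianceError):
        welch_t_test([3.0, 3.0], [5.0, 5.0])
    t, _, p = welch_t_test([3.0, 3.0], [3.0, 3.0])
    assert t == 0.0 and p == 1.0


# ---------------------------------------------------------------------------
# validation and distance shift

def test_validation_requires_significance_and_direction():
    control = [80.0, 79.0, 81.0]
    # identical -> not validated
    p, ok = validate_candidate(control, control, HitCategory.PAIRING_PROMOTER)
    assert not ok
    # clear drop -> validated as promoter
    p, ok = validate_candidate([60.0, 62.0, 58.0], control,
                               HitCategory.PAIRING_PROMOTER)
    assert ok and p <= 0.05
    # same drop with an anti-pairer primary call: direction gate fails
    p, ok = validate_candidate([60.0, 62.0, 58.0], control,
                               HitCategory.ANTI_PAIRER)
    assert p <= 0.05 and not ok


def test_distance_shift_detects_planted_coalescence():
    rng = np.random.default_rng(4)
    control = rng.normal(1.8, 0.6, 300).clip(0.05)
    shifted = rng.normal(1.3, 0.6, 300).clip(0.05)
    p, smaller = distance_shift_test(shifted, control)
    assert smaller and p < 0.01
    p, smaller = distance_shift_test(control, control + 0.0)
    assert not smaller
    # significant but larger distances: flag stays false
    p, smaller = distance_shift_test(control + 0.5, control)
    assert p < 0.01 and not smaller


def test_distance_shift_needs_defined_distances():
    with pytest.raises(SampleSizeError):
        distance_shift_test([np.nan, np.nan], [1.0, 2.0])
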