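"""Plate-level statistics and screen hit calling.

Each well's summary metric (by default the percentage of single-signal
nuclei) is converted to a z-score against its own plate's mean and sample
SD.  A dsRNA is a candidate *pairing promoter* when, in both replicate
plates, it either drives pct_single to z <= -2 or drives one of the
2/3/4-focus bin fractions to z >= +2; it is a candidate *anti-pairer*
when pct_single reaches z >= +2 in both replicates.  Candidates are then
validated against untreated control wells with an unpaired t test (Welch,
unequal variances, by default), and inter-signal distance shifts are
tested per nucleus the same way.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegeneratePlateError,
    DegenerateVarianceError,
    ReplicateError,
    SampleSizeError,
)
from .score import WellSummary

#: plate-map roles whose wells enter plate mean/SD when controls are excluded
_STAT_ROLES = {"library", "neg_control"}


class HitCategory(str, Enum):
    PAIRING_PROMOTER = "pairing_promoter"
    ANTI_PAIRER = "anti_pairer"
    NONE = "none"


@dataclass
class ScreenParams:
    z_hit: float = 2.0
    validation_alpha: float = 0.05
    distance_alpha: float = 0.01
    metric_channel: str = "FISH_B"
    exclude_controls_from_plate_stats: bool = True
    sd_mode: str = "sample"  # "sample" (n-1) or "population"
    pooled_variance: bool = False  # validation t test: pooled instead of Welch

    def __post_init__(self) -> None:
        if self.z_hit <= 0:
            raise ValueError("z_hit must be positive")
        for a in (self.validation_alpha, self.distance_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError("sd_mode must be 'sample' or 'population'")


@dataclass
class HitCall:
    well_id: str
    target_id: str | None
    z_rep1: float
    z_rep2: float
    category: HitCategory
    metric: str = "pct_single"
    validation_p: float | None = None
    validated: bool = False


def plate_zscores(
    well_values: Mapping[str, float],
    p: ScreenParams | None = None,
    roles: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """z-score every well against its plate's mean and SD.

    When roles are given and control exclusion is configured, positive
    controls and blanks are left out of the plate mean/SD (they carry a
    known effect and would inflate the spread) but still receive z-scores.
    """
    p = p or ScreenParams()
    wells = list(well_values)
    if roles is not None and p.exclude_controls_from_plate_stats:
        included = [w for w in wells if roles.get(w, "library") in _STAT_ROLES]
    else:
        included = wells
    if len(included) < 3:
        raise DegeneratePlateError(
            f"need >= 3 wells for plate statistics, got {len(included)}")
    x = np.array([well_values[w] for w in included], dtype=np.float64)
    mean = float(x.mean())
    sd = float(x.std(ddof=1 if p.sd_mode == "sample" else 0))
    if sd == 0:
        raise DegeneratePlateError("plate SD is zero")
    return {w: (float(well_values[w]) - mean) / sd for w in wells}


def _bin_fraction(summary: WellSummary, channel: str, k: int) -> float | None:
    ch = summary.channels.get(channel)
    if ch is None or ch.fraction_by_bin is None:
        return None
    return ch.fraction_by_bin[k]


def call_primary_hits(
    rep1: Mapping[str, WellSummary],
    rep2: Mapping[str, WellSummary],
    p: ScreenParams | None = None,
    roles: Mapping[str, str] | None = None,
    targets: Mapping[str, str] | None = None,
) -> list[HitCall]:
    """Dual-replicate primary hit calling.

    pairing_promoter: pct_single z <= -z_hit in both replicates, or some
    bin k in {2,3,4} with z >= +z_hit in both replicates (same k).
    anti_pairer: pct_single z >= +z_hit in both replicates.  A well that
    satisfies both is reported as none with a warning.
    """
    p = p or ScreenParams()
    if set(rep1) != set(rep2):
        raise ReplicateError("replicate plates do not share a well layout")
    ch = p.metric_channel

    z1 = plate_zscores({w: rep1[w].pct_single(ch) for w in rep1}, p, roles)
    z2 = plate_zscores({w: rep2[w].pct_single(ch) for w in rep2}, p, roles)

    zbin1: dict[int, dict[str, float]] = {}
    zbin2: dict[int, dict[str, float]] = {}
    for k in (2, 3, 4):
        v1 = {w: _bin_fraction(rep1[w], ch, k) for w in rep1}
        v2 = {w: _bin_fraction(rep2[w], ch, k) for w in rep2}
        if all(v is not None for v in v1.values()) and all(
                v is not None for v in v2.values()):
            try:
                a = plate_zscores(v1, p, roles)  # type: ignore[arg-type]
                b = plate_zscores(v2, p, roles)  # type: ignore[arg-type]
            except DegeneratePlateError:
                continue  # a bin with zero spread carries no signal
            zbin1[k], zbin2[k] = a, b

    hits: list[HitCall] = []
    for w in sorted(rep1):
        promoter_single = z1[w] <= -p.z_hit and z2[w] <= -p.z_hit
        promoter_bin = None
        for k in zbin1:
            if zbin1[k][w] >= p.z_hit and zbin2[k][w] >= p.z_hit:
                promoter_bin = k
                break
        anti = z1[w] >= p.z_hit and z2[w] >= p.z_hit
        promoter = promoter_single or promoter_bin is not None

        if promoter and anti:
            warnings.warn(f"well {w}: conflicting promoter/anti-pairer "
                          "criteria; reporting none", stacklevel=2)
            category = HitCategory.NONE
        elif promoter:
            category = HitCategory.PAIRING_PROMOTER
        elif anti:
            category = HitCategory.ANTI_PAIRER
        else:
            category = HitCategory.NONE

        metric = "pct_single"
        if category is HitCategory.PAIRING_PROMOTER and not promoter_single:
            metric = f"bin_fraction({promoter_bin})"
        hits.append(HitCall(
            well_id=w,
            target_id=targets.get(w) if targets else None,
            z_rep1=z1[w],
            z_rep2=z2[w],
            category=category,
            metric=metric,
        ))
    return hits


def welch_t_test(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray
) -> tuple[float, float, float]:
    """Unpaired t test with unequal variances (Welch).

    Returns (t, Welch-Satterthwaite df, two-sided p).  Identical samples
    give t = 0, p = 1; two constant samples with different values have no
    variance to test against and raise.
    """
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise SampleSizeError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dm = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if dm == 0:
            return 0.0, float(x.size + y.size - 2), 1.0
        raise DegenerateVarianceError("both samples constant with unequal values")
    se2 = vx / x.size + vy / y.size
    t = dm / np.sqrt(se2)
    df = se2 ** 2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _pooled_t_test(a, b) -> tuple[float, float, float]:
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise SampleSizeError("each sample needs n >= 2")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, float(df), 1.0
        raise DegenerateVarianceError("both samples constant with unequal values")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    return float(t), float(df), float(2.0 * stats.t.sf(abs(t), df))


def validate_candidate(
    treatment_pct_single: Sequence[float],
    control_pct_single: Sequence[float],
    category: HitCategory,
    p: ScreenParams | None = None,
) -> tuple[float, bool]:
    """Validation test for one candidate dsRNA.

    Two-sided t test of replicate pct_single values against untreated
    control wells; validated iff p <= validation_alpha *and* the shift
    direction matches the primary category (promoters must decrease
    pct_single, anti-pairers must increase it).
    """
    p = p or ScreenParams()
    test = _pooled_t_test if p.pooled_variance else welch_t_test
    t, _, pval = test(treatment_pct_single, control_pct_single)
    if category is HitCategory.PAIRING_PROMOTER:
        direction_ok = t < 0
    elif category is HitCategory.ANTI_PAIRER:
        direction_ok = t > 0
    else:
        direction_ok = False
    return pval, bool(pval <= p.validation_alpha and direction_ok)


def validate_candidates(
    hits: Sequence[HitCall],
    treatment_pct_single: Mapping[str, Sequence[float]],
    control_pct_single: Sequence[float],
    p: ScreenParams | None = None,
) -> list[HitCall]:
    """Apply the validation test to every non-none hit, in place."""
    p = p or ScreenParams()
    for h in hits:
        if h.category is HitCategory.NONE:
            continue
        reps = treatment_pct_single.get(h.well_id)
        if reps is None:
            continue
        h.validation_p, h.validated = validate_candidate(
            reps, control_pct_single, h.category, p)
    return list(hits)


def distance_shift_test(
    treatment_per_nucleus_means: Sequence[float],
    control_per_nucleus_means: Sequence[float],
    p: ScreenParams | None = None,
) -> tuple[float, bool]:
    """Test for a shift of per-nucleus mean inter-signal distances.

    Welch test over nuclei; ``shifted_smaller`` is True iff
    p < distance_alpha and the treatment mean is below the control mean
    (i.e. heterochromatic signals have coalesced).
    """
    p = p or ScreenParams()
    t = [d for d in treatment_per_nucleus_means if d is not None and np.isfinite(d)]
    c = [d for d in control_per_nucleus_means if d is not None and np.isfinite(d)]
    if len(t) < 2 or len(c) < 2:
        raise SampleSizeError("need >= 2 defined per-nucleus distances per side")
    tstat, _, pval = welch_t_test(t, c)
    return pval, bool(pval < p.distance_alpha and tstat < 0)
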