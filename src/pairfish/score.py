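"""Per-nucleus pairing/clustering/ploidy metrics and per-well aggregation.

A nucleus is *paired* for a locus when it shows a single FISH signal, or
when the centre-to-centre distances between all pairs of its signals are
at most 1.0 um (the threshold used throughout the screen, selected on
control nuclei).  Cross-channel *clustering* is any pixel overlap between
foci of the two channels, reading out coalescence of nonhomologous
heterochromatin rather than homolog pairing.  Nuclear size is carried as
the raw 2-D area plus a sphere-equivalent volume proxy; nuclei at or above
the 95th percentile of control size are flagged *large* as a polyploidy
proxy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import (
    EmptyWellError,
    GroupingError,
    InsufficientControlsError,
)

if TYPE_CHECKING:  # only for annotations; avoids an import cycle
    from .foci import FocusRecord
    from .segment import NucleusRecord

COUNT_BINS: tuple[str, ...] = ("0", "1", "2", "3", "4", "5+")


class DistancePool(str, Enum):
    """Which focus pairs enter the inter-signal distance for clustering."""

    ALL_PAIRS_UNION = "all_pairs_union"
    CROSS_CHANNEL_ONLY = "cross_channel_only"


@dataclass
class ScoreParams:
    pairing_threshold_um: float = 1.0
    far_threshold_um: float = 4.0
    distance_bin_edges_um: tuple[float, ...] = (
        0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    large_percentile: float = 95.0
    distance_pool: DistancePool = DistancePool.ALL_PAIRS_UNION
    # zero-focus nuclei are excluded from the paired denominator by default:
    # a missing signal is a detection failure, not evidence of unpairing
    include_zero_focus_in_paired: bool = False

    def __post_init__(self) -> None:
        if self.pairing_threshold_um <= 0 or self.far_threshold_um <= 0:
            raise ValueError("distance thresholds must be positive")
        edges = tuple(float(e) for e in self.distance_bin_edges_um)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("distance_bin_edges_um must be strictly increasing")
        self.distance_bin_edges_um = edges
        if not 0 < self.large_percentile < 100:
            raise ValueError("large_percentile must be in (0, 100)")
        self.distance_pool = DistancePool(self.distance_pool)


@dataclass
class ChannelScore:
    focus_count: int
    count_bin: str
    paired: bool
    pairwise_um: np.ndarray  # all C(n,2) same-channel distances


@dataclass
class NucleusScore:
    nucleus_label: int
    area_um2: float
    volume_proxy_um3: float
    channels: dict[str, ChannelScore]
    mean_intersignal_distance_um: float | None
    clustered: bool
    is_large: bool | None = None


@dataclass
class ChannelSummary:
    fraction_by_bin: tuple[float, ...]  # over COUNT_BINS, sums to 1
    pct_single: float
    pct_paired: float
    pct_far: float
    distance_histogram: np.ndarray  # counts per bin, terminal bin open-ended


@dataclass
class WellSummary:
    """Per-well aggregate mirroring the screen's summary-table semantics."""

    n_nuclei: int
    channels: dict[str, ChannelSummary]
    pct_large: float
    mean_intersignal_distance_um: float | None
    pct_1r1g: float
    pct_1r1g_touch: float
    well_id: str | None = None

    def pct_single(self, channel: str) -> float:
        return self.channels[channel].pct_single

    @classmethod
    def from_metrics(
        cls,
        pct_single: float,
        channel: str = "FISH_B",
        fraction_by_bin: Sequence[float] | None = None,
        well_id: str | None = None,
    ) -> "WellSummary":
        """Build a minimal summary from well-level metrics alone.

        Used by the screen-level simulator, where wells are drawn at the
        summary level rather than rendered as images.
        """
        if fraction_by_bin is None:
            frac = (0.0, pct_single / 100.0, 1.0 - pct_single / 100.0,
                    0.0, 0.0, 0.0)
        else:
            frac = tuple(float(f) for f in fraction_by_bin)
        ch = ChannelSummary(
            fraction_by_bin=frac,
            pct_single=float(pct_single),
            pct_paired=float(pct_single),
            pct_far=0.0,
            distance_histogram=np.zeros(1),
        )
        return cls(n_nuclei=0, channels={channel: ch}, pct_large=0.0,
                   mean_intersignal_distance_um=None, pct_1r1g=0.0,
                   pct_1r1g_touch=0.0, well_id=well_id)


def classify_count_bin(focus_count: int) -> str:
    """Sort a focus count into the screen's six groups: 0,1,2,3,4,5+."""
    if focus_count < 0 or int(focus_count) != focus_count:
        raise ValueError(f"focus_count must be a non-negative integer, got {focus_count}")
    return COUNT_BINS[min(int(focus_count), 5)]


def _centroids(foci: Sequence["FocusRecord"]) -> np.ndarray:
    return np.array([f.centroid_um for f in foci], dtype=np.float64).reshape(-1, 2)


def _check_one_nucleus(foci: Sequence["FocusRecord"]) -> None:
    labels = {f.nucleus_label for f in foci}
    if len(labels) > 1:
        raise GroupingError(f"foci span nuclei {sorted(labels)}")


def pairwise_distances(foci: Sequence["FocusRecord"]) -> np.ndarray:
    """All C(n,2) Euclidean centroid distances (um) among one nucleus's foci."""
    _check_one_nucleus(foci)
    if len(foci) < 2:
        return np.empty(0, dtype=np.float64)
    return pdist(_centroids(foci))


def call_pairing(foci: Sequence["FocusRecord"], p: ScoreParams | None = None) -> bool:
    """True iff one signal, or all pairwise signal distances <= threshold.

    Zero signals is not paired (the caller tracks no-signal nuclei
    separately via the "0" count bin).
    """
    p = p or ScoreParams()
    _check_one_nucleus(foci)
    n = len(foci)
    if n == 0:
        return False
    if n == 1:
        return True
    return bool(pairwise_distances(foci).max() <= p.pairing_threshold_um)


def mean_intersignal_distance(
    fociA: Sequence["FocusRecord"],
    fociB: Sequence["FocusRecord"],
    p: ScoreParams | None = None,
) -> float | None:
    """Mean inter-signal distance (um) within one nucleus, or None.

    Pool is configurable: every unordered pair among the union of both
    channels' foci (default), or cross-channel pairs only.  Undefined
    (None) when the pool is empty.
    """
    p = p or ScoreParams()
    _check_one_nucleus(list(fociA) + list(fociB))
    if p.distance_pool is DistancePool.CROSS_CHANNEL_ONLY:
        if len(fociA) == 0 or len(fociB) == 0:
            return None
        d = cdist(_centroids(fociA), _centroids(fociB)).ravel()
    else:
        pts = _centroids(list(fociA) + list(fociB))
        if pts.shape[0] < 2:
            return None
        d = pdist(pts)
    return float(d.mean())


def detect_colocalization(
    fociA: Sequence["FocusRecord"], fociB: Sequence["FocusRecord"]
) -> bool:
    """True iff any focus of one channel shares a pixel with the other's."""
    if not fociA or not fociB:
        return False
    pixels_a: set[tuple[int, int]] = set()
    for f in fociA:
        pixels_a.update(f.pixel_set())
    return any(not pixels_a.isdisjoint(f.pixel_set()) for f in fociB)


def large_nucleus_cutoff(
    control_sizes: Sequence[float] | np.ndarray,
    p: ScoreParams | None = None,
    min_controls: int = 20,
) -> float:
    """Size cutoff: the large_percentile-th percentile of control nuclei.

    Linear interpolation between order statistics; a nucleus is flagged
    large iff its size is at or above the cutoff.
    """
    p = p or ScoreParams()
    sizes = np.asarray(control_sizes, dtype=np.float64)
    if sizes.size < min_controls:
        raise InsufficientControlsError(
            f"need >= {min_controls} control nuclei, got {sizes.size}")
    return float(np.percentile(sizes, p.large_percentile))


def volume_proxy(area_um2: float) -> float:
    """Sphere-equivalent volume (um^3) of a 2-D area: (4/3) pi (sqrt(A/pi))^3.

    A proxy only — the screen images single optical sections, so no true
    3-D volume is available.
    """
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    r = math.sqrt(area_um2 / math.pi)
    return 4.0 / 3.0 * math.pi * r ** 3


def score_nucleus(
    nucleus: "NucleusRecord",
    foci_by_channel: Mapping[str, Sequence["FocusRecord"]],
    p: ScoreParams | None = None,
) -> NucleusScore:
    """Assemble all per-nucleus metrics from its detected foci."""
    p = p or ScoreParams()
    channels: dict[str, ChannelScore] = {}
    for name, foci in foci_by_channel.items():
        channels[name] = ChannelScore(
            focus_count=len(foci),
            count_bin=classify_count_bin(len(foci)),
            paired=call_pairing(foci, p),
            pairwise_um=pairwise_distances(foci),
        )
    names = list(foci_by_channel)
    if len(names) >= 2:
        fa, fb = foci_by_channel[names[0]], foci_by_channel[names[1]]
        mean_d = mean_intersignal_distance(fa, fb, p)
        clustered = detect_colocalization(fa, fb)
    else:
        mean_d, clustered = None, False
    return NucleusScore(
        nucleus_label=nucleus.label,
        area_um2=nucleus.area_um2,
        volume_proxy_um3=nucleus.volume_proxy_um3,
        channels=channels,
        mean_intersignal_distance_um=mean_d,
        clustered=clustered,
    )


def set_large_flags(scores: Sequence[NucleusScore], cutoff: float) -> None:
    """Flag nuclei at or above the control-derived size cutoff (area um^2)."""
    for s in scores:
        s.is_large = bool(s.area_um2 >= cutoff)


def summarize_well(
    scores: Sequence[NucleusScore],
    p: ScoreParams | None = None,
    well_id: str | None = None,
) -> WellSummary:
    """Aggregate per-nucleus scores into the per-well summary."""
    p = p or ScoreParams()
    if len(scores) == 0:
        raise EmptyWellError("no scoreable nuclei in well")
    n = len(scores)
    channel_names = list(scores[0].channels)
    edges = np.asarray(p.distance_bin_edges_um + (np.inf,))

    summaries: dict[str, ChannelSummary] = {}
    for name in channel_names:
        counts = np.array([s.channels[name].focus_count for s in scores])
        bins = np.array([min(c, 5) for c in counts])
        frac = tuple(float((bins == k).sum()) / n for k in range(6))

        paired_flags = [s.channels[name].paired for s in scores]
        if p.include_zero_focus_in_paired:
            denom = n
            paired_n = sum(paired_flags)
        else:
            with_signal = counts > 0
            denom = int(with_signal.sum())
            paired_n = sum(f for f, w in zip(paired_flags, with_signal) if w)
        pct_paired = 100.0 * paired_n / denom if denom else 0.0

        two = [s for s in scores if s.channels[name].focus_count == 2]
        if two:
            far = sum(1 for s in two
                      if s.channels[name].pairwise_um.max() > p.far_threshold_um)
            pct_far = 100.0 * far / len(two)
        else:
            pct_far = 0.0

        all_d = np.concatenate(
            [s.channels[name].pairwise_um for s in scores]
            or [np.empty(0)])
        hist, _ = np.histogram(all_d, bins=edges)

        summaries[name] = ChannelSummary(
            fraction_by_bin=frac,
            pct_single=100.0 * frac[1],
            pct_paired=pct_paired,
            pct_far=pct_far,
            distance_histogram=hist,
        )

    large_flags = [s.is_large for s in scores if s.is_large is not None]
    pct_large = 100.0 * sum(large_flags) / n if large_flags else 0.0
    mean_ds = [s.mean_intersignal_distance_um for s in scores
               if s.mean_intersignal_distance_um is not None]
    mean_d = float(np.mean(mean_ds)) if mean_ds else None

    if len(channel_names) >= 2:
        a, b = channel_names[0], channel_names[1]
        one_one = [s for s in scores
                   if s.channels[a].focus_count == 1
                   and s.channels[b].focus_count == 1]
        pct_1r1g = 100.0 * len(one_one) / n
        pct_touch = 100.0 * sum(1 for s in one_one if s.clustered) / n
    else:
        pct_1r1g = pct_touch = 0.0

    return WellSummary(
        n_nuclei=n,
        channels=summaries,
        pct_large=pct_large,
        mean_intersignal_distance_um=mean_d,
        pct_1r1g=pct_1r1g,
        pct_1r1g_touch=pct_touch,
        well_id=well_id,
    )
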