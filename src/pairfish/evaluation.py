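"""Recovery benchmarks against planted ground truth.

These routines run the real pipeline (preprocess -> segment -> detect ->
score) over simulated wells and compare the results with the simulator's
truth tables: nucleus-count and centroid recovery, exact focus-count
recovery, pairing-fraction recovery, the size-vs-count independence check,
and the power/specificity of dual-replicate hit calling.  They back both
the test suite and the reproduction script.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .foci import FociParams, detect_foci_well
from .score import NucleusScore, ScoreParams, score_nucleus
from .screen import HitCategory, ScreenParams, call_primary_hits, welch_t_test
from .segment import NucleusRecord, SegParams, preprocess_dapi, segment_nuclei
from .simulate import SimParams, SimulatedWell, simulate_screen_plate, simulate_well


@dataclass
class WellEvaluation:
    """One simulated well analysed by the pipeline, plus its truth."""

    sim: SimulatedWell
    nuclei: list[NucleusRecord]
    scores: list[NucleusScore]
    #: (truth_row_idx, record_idx) matched one-to-one within the gate
    matches: list[tuple[int, int]]
    match_dist_um: list[float]


def analyze_simulated_wells(
    seeds: Sequence[int],
    params: SimParams,
    seg: SegParams | None = None,
    foci: FociParams | None = None,
    scoring: ScoreParams | None = None,
    match_gate_um: float = 1.0,
) -> list[WellEvaluation]:
    """Simulate and analyse wells; match recovered nuclei to planted ones.

    Matching is one-to-one (Hungarian assignment on centroid distance),
    gated at ``match_gate_um``.
    """
    seg = seg or SegParams()
    foci = foci or FociParams()
    scoring = scoring or ScoreParams()
    out: list[WellEvaluation] = []
    for seed in seeds:
        sim = simulate_well(dataclasses.replace(params, seed=int(seed)))
        pre = preprocess_dapi(sim.dapi, seg)
        _, nuclei = segment_nuclei(pre, seg)
        fa = detect_foci_well(sim.chan_a, nuclei, foci)
        fb = detect_foci_well(sim.chan_b, nuclei, foci)
        scores = [score_nucleus(n, {"FISH_A": fa[n.label],
                                    "FISH_B": fb[n.label]}, scoring)
                  for n in nuclei]
        matches: list[tuple[int, int]] = []
        dists: list[float] = []
        if nuclei:
            rec = np.array([n.centroid_um for n in nuclei])
            tru = sim.truth.nuclei[["x_um", "y_um"]].to_numpy()
            d = cdist(tru, rec)
            for i, j in zip(*linear_sum_assignment(d)):
                if d[i, j] <= match_gate_um:
                    matches.append((int(i), int(j)))
                    dists.append(float(d[i, j]))
        out.append(WellEvaluation(sim=sim, nuclei=nuclei, scores=scores,
                                  matches=matches, match_dist_um=dists))
    return out


def segmentation_recovery(evals: Sequence[WellEvaluation]) -> dict[str, float]:
    """Aggregate nucleus-count recovery and matched-centroid error."""
    planted = sum(len(e.sim.truth.nuclei) for e in evals)
    recovered = sum(len(e.nuclei) for e in evals)
    px = evals[0].sim.dapi.pixel_size_um
    dists = np.concatenate([e.match_dist_um for e in evals])
    return {
        "planted": float(planted),
        "recovered": float(recovered),
        "recovery_pct": 100.0 * recovered / planted,
        "mean_centroid_error_px": float(dists.mean() / px),
        "n_matched": float(dists.size),
    }


def foci_count_recovery(evals: Sequence[WellEvaluation]) -> dict[str, float]:
    """Fraction of matched nuclei whose detected focus count equals the
    planted count in both channels."""
    exact = total = 0
    for e in evals:
        tr = e.sim.truth.nuclei
        for i, j in e.matches:
            total += 1
            s = e.scores[j]
            ok = all(
                s.channels[ch].focus_count == tr.iloc[i][f"count_{ch}"]
                for ch in ("FISH_A", "FISH_B"))
            exact += ok
    return {"exact": float(exact), "total": float(total),
            "exact_pct": 100.0 * exact / total if total else float("nan")}


def pairing_recovery(evals: Sequence[WellEvaluation],
                     channel: str = "FISH_B") -> dict[str, float]:
    """Detected %-paired (nuclei with signal) vs the planted rate."""
    det_paired = det_sig = 0
    planted_paired = planted_n = 0
    for e in evals:
        planted_n += len(e.sim.truth.nuclei)
        planted_paired += int(e.sim.truth.nuclei[f"paired_{channel}"].sum())
        for s in e.scores:
            if s.channels[channel].focus_count > 0:
                det_sig += 1
                det_paired += s.channels[channel].paired
    return {
        "planted_pct": 100.0 * planted_paired / planted_n,
        "detected_pct": 100.0 * det_paired / det_sig,
        "n_detected": float(det_sig),
    }


def size_count_correlation(evals: Sequence[WellEvaluation],
                           channel: str = "FISH_B") -> float:
    """Pearson r between recovered nuclear area and detected focus count.

    With ploidy and pairing planted independently this should be ~0:
    signal count is not a ploidy readout when pairing accommodates the
    extra copies.
    """
    areas, counts = [], []
    for e in evals:
        for s in e.scores:
            areas.append(s.area_um2)
            counts.append(s.channels[channel].focus_count)
    return float(np.corrcoef(areas, counts)[0, 1])


def hit_calling_performance(
    n_runs: int = 100,
    seed: int = 0,
    n_wells: int = 384,
    n_hits: int = 8,
    effect: float = -20.0,
    baseline: float = 80.0,
    between_well_sd: float = 3.0,
    p: ScreenParams | None = None,
) -> dict[str, float]:
    """Power and specificity of dual-replicate hit calling.

    Each run draws two replicate 384-well plates at the summary level with
    ``n_hits`` planted pct_single offsets; power counts runs in which every
    planted well is called a pairing promoter with z <= -2 in both
    replicates, and the null rate counts calls of any category among
    unplanted wells.
    """
    p = p or ScreenParams()
    rng = np.random.default_rng(seed)
    wells = [f"W{i:03d}" for i in range(n_wells)]
    full_power_runs = 0
    null_calls = null_total = 0
    for _ in range(n_runs):
        hit_wells = set(rng.choice(wells, size=n_hits, replace=False))
        effects = {w: effect for w in hit_wells}
        rep1 = simulate_screen_plate(
            wells, int(rng.integers(2 ** 31)), baseline, between_well_sd,
            effects)
        rep2 = simulate_screen_plate(
            wells, int(rng.integers(2 ** 31)), baseline, between_well_sd,
            effects)
        hits = call_primary_hits(rep1, rep2, p)
        by_id = {h.well_id: h for h in hits}
        all_called = all(
            by_id[w].category is HitCategory.PAIRING_PROMOTER
            and by_id[w].z_rep1 <= -p.z_hit and by_id[w].z_rep2 <= -p.z_hit
            for w in hit_wells)
        full_power_runs += all_called
        for w in wells:
            if w not in hit_wells:
                null_total += 1
                null_calls += by_id[w].category is not HitCategory.NONE
    return {
        "power_pct": 100.0 * full_power_runs / n_runs,
        "null_call_rate_pct": 100.0 * null_calls / null_total,
    }


def welch_type1_rate(n_sims: int = 10_000, n: int = 10, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Empirical rejection rate of the Welch test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        _, _, pval = welch_t_test(a, b)
        rejections += pval <= alpha
    return rejections / n_sims
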