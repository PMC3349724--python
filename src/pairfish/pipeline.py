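"""End-to-end plate runner.

Ties the stages together for one or two replicate plates of well TIFFs:
segmentation -> per-nucleus focus detection -> scoring -> well summaries ->
(with two replicates) plate z-scores and hit calls.  The large-nucleus
cutoff is derived per plate from the pooled negative-control wells.  A
failing well is logged and skipped; it never aborts the run.  Outputs are
deterministic given inputs and config, and a manifest records the config
hash and package version.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import EmptyWellError, InsufficientControlsError, PairfishError
from .foci import detect_foci_well, smooth_channel
from .image import ImagePlane
from .io import (
    FOCI_COLUMNS,
    HITS_COLUMNS,
    PER_NUCLEUS_COLUMNS,
    PER_WELL_COLUMNS,
    read_platemap,
    read_well_images,
    write_table,
)
from .score import (
    NucleusScore,
    ScoreParams,
    WellSummary,
    large_nucleus_cutoff,
    score_nucleus,
    set_large_flags,
    summarize_well,
)
from .screen import HitCall, call_primary_hits
from .segment import NucleusRecord, preprocess_dapi, segment_nuclei

log = logging.getLogger("pairfish")

FISH_NAMES = ("FISH_A", "FISH_B")


@dataclass
class WellResult:
    plate: str
    well: str
    role: str
    target: str
    nuclei: list[NucleusRecord]
    scores: list[NucleusScore]
    foci_rows: list[dict]
    summary: WellSummary | None = None


def analyze_well(
    planes: Mapping[str, ImagePlane], config: PipelineConfig,
) -> tuple[list[NucleusRecord], list[NucleusScore], list[dict]]:
    """Segment, detect foci, and score a single well's planes."""
    pre = preprocess_dapi(planes["DAPI"], config.segmentation)
    _, nuclei = segment_nuclei(pre, config.segmentation)
    foci_by_nucleus: dict[str, dict[int, list]] = {}
    for name in FISH_NAMES:
        if name not in planes:
            continue
        smoothed = smooth_channel(planes[name], config.foci)
        foci_by_nucleus[name] = detect_foci_well(
            smoothed, nuclei, config.foci, presmoothed=True)
    scores: list[NucleusScore] = []
    foci_rows: list[dict] = []
    for nuc in nuclei:
        per_channel = {name: foci_by_nucleus[name][nuc.label]
                       for name in foci_by_nucleus}
        scores.append(score_nucleus(nuc, per_channel, config.scoring))
        for name, foci in per_channel.items():
            for f in foci:
                foci_rows.append({
                    "nucleus": nuc.label, "channel": name,
                    "x_um": f.centroid_um[0], "y_um": f.centroid_um[1],
                    "area_px": f.area_px, "peak": f.peak_intensity,
                })
    return nuclei, scores, foci_rows


def _flag_large(results: list[WellResult], scoring: ScoreParams) -> None:
    """Derive the large-nucleus cutoff from negative controls per plate."""
    by_plate: dict[str, list[WellResult]] = {}
    for r in results:
        by_plate.setdefault(r.plate, []).append(r)
    for plate, wells in by_plate.items():
        control_areas = [s.area_um2 for r in wells if r.role == "neg_control"
                         for s in r.scores]
        if not control_areas:  # fall back to the whole plate as baseline
            control_areas = [s.area_um2 for r in wells for s in r.scores]
        try:
            cutoff = large_nucleus_cutoff(control_areas, scoring)
        except InsufficientControlsError:
            log.warning("plate %s: too few control nuclei for a size cutoff; "
                        "large-nucleus flags unset", plate)
            continue
        for r in wells:
            set_large_flags(r.scores, cutoff)


def run_pipeline(
    plate_dirs: list[str | Path],
    platemap_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis over one or two replicate plate directories.

    Each plate directory holds one multi-page TIFF per well, named
    ``<well>.tif``, under ``<dir>/<plate_id>/`` or directly in the
    directory.  Hit calling requires exactly two replicates; with one,
    summaries are produced and hits are skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    platemap = read_platemap(platemap_path)
    plates = sorted(platemap["plate"].unique())

    rep_results: list[list[WellResult]] = []
    for rep_idx, plate_dir in enumerate(plate_dirs, start=1):
        plate_dir = Path(plate_dir)
        results: list[WellResult] = []
        for _, rec in platemap.sort_values(["plate", "well"]).iterrows():
            plate, well = str(rec["plate"]), str(rec["well"])
            tif = plate_dir / plate / f"{well}.tif"
            if not tif.exists():
                tif = plate_dir / f"{well}.tif"
            if rec["role"] == "blank" and not tif.exists():
                continue
            try:
                planes = read_well_images(tif, config.pixel_size_um,
                                          config.channel_order)
                nuclei, scores, foci_rows = analyze_well(planes, config)
                if not scores:
                    raise EmptyWellError(f"{plate}/{well}: no nuclei")
                results.append(WellResult(
                    plate=plate, well=well, role=str(rec["role"]),
                    target=str(rec.get("target", "")), nuclei=nuclei,
                    scores=scores, foci_rows=foci_rows))
            except PairfishError as exc:
                log.warning("replicate %d %s/%s skipped: %s",
                            rep_idx, plate, well, exc)
        _flag_large(results, config.scoring)
        for r in results:
            r.summary = summarize_well(r.scores, config.scoring, well_id=r.well)
        rep_results.append(results)

    tables = _build_tables(rep_results, config)
    write_table(tables["per_nucleus"], out_dir / "per_nucleus.tsv",
                PER_NUCLEUS_COLUMNS)
    write_table(tables["per_well"], out_dir / "per_well.tsv", PER_WELL_COLUMNS)
    write_table(tables["foci"], out_dir / "foci.tsv", FOCI_COLUMNS)
    if "hits" in tables:
        write_table(tables["hits"], out_dir / "hits.tsv", HITS_COLUMNS)
        write_table(tables["rank_order"], out_dir / "rank_order.tsv",
                    ["rank", "well", "target", "z_mean", "z_rep1", "z_rep2"])
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_replicates": len(plate_dirs),
        "plates": plates,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return tables


def _build_tables(
    rep_results: list[list[WellResult]], config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    nuc_rows, well_rows, foci_rows = [], [], []
    for rep_idx, results in enumerate(rep_results, start=1):
        prefix = f"r{rep_idx}-" if len(rep_results) > 1 else ""
        for r in results:
            plate_id = prefix + r.plate
            for nuc, s in zip(r.nuclei, r.scores):
                row = {
                    "plate": plate_id, "well": r.well, "nucleus": nuc.label,
                    "x_um": nuc.centroid_um[0], "y_um": nuc.centroid_um[1],
                    "area_px": nuc.pixel_count, "area_um2": nuc.area_um2,
                    "volume_proxy_um3": nuc.volume_proxy_um3,
                    "touches_border": nuc.touches_border,
                    "is_large": s.is_large,
                    "mean_intersignal_um": s.mean_intersignal_distance_um,
                    "clustered": s.clustered,
                }
                for name in FISH_NAMES:
                    ch = s.channels.get(name)
                    row[f"count_{name}"] = ch.focus_count if ch else None
                    row[f"paired_{name}"] = ch.paired if ch else None
                nuc_rows.append(row)
            for fr in r.foci_rows:
                foci_rows.append({"plate": plate_id, "well": r.well, **fr})
            smry = r.summary
            row = {
                "plate": plate_id, "well": r.well, "role": r.role,
                "target": r.target, "n_nuclei": smry.n_nuclei,
                "pct_large": smry.pct_large, "pct_1R1G": smry.pct_1r1g,
                "pct_1R1G_touch": smry.pct_1r1g_touch,
                "mean_intersignal_um": smry.mean_intersignal_distance_um,
            }
            for name in FISH_NAMES:
                ch = smry.channels.get(name)
                if ch is None:
                    continue
                row[f"pct_single_{name}"] = ch.pct_single
                row[f"pct_paired_{name}"] = ch.pct_paired
                row[f"pct_far_{name}"] = ch.pct_far
                labels = ["bin0", "bin1", "bin2", "bin3", "bin4", "bin5plus"]
                for lab, frac in zip(labels, ch.fraction_by_bin):
                    row[f"{lab}_{name}"] = frac
            well_rows.append(row)

    tables = {
        "per_nucleus": pd.DataFrame(nuc_rows),
        "per_well": pd.DataFrame(well_rows),
        "foci": pd.DataFrame(foci_rows, columns=FOCI_COLUMNS),
    }

    if len(rep_results) == 2:
        rep1 = {r.well: r.summary for r in rep_results[0]}
        rep2 = {r.well: r.summary for r in rep_results[1]}
        common = sorted(set(rep1) & set(rep2))
        roles = {r.well: r.role for r in rep_results[0]}
        targets = {r.well: r.target for r in rep_results[0]}
        hits = call_primary_hits(
            {w: rep1[w] for w in common}, {w: rep2[w] for w in common},
            config.screen, roles=roles, targets=targets)
        tables["hits"] = pd.DataFrame([{
            "well": h.well_id, "target": h.target_id or "",
            "category": h.category.value, "metric": h.metric,
            "z_rep1": h.z_rep1, "z_rep2": h.z_rep2,
            "validation_p": h.validation_p, "validated": h.validated,
        } for h in hits])
        rank = sorted(hits, key=lambda h: (h.z_rep1 + h.z_rep2) / 2)
        tables["rank_order"] = pd.DataFrame([{
            "rank": i + 1, "well": h.well_id, "target": h.target_id or "",
            "z_mean": (h.z_rep1 + h.z_rep2) / 2,
            "z_rep1": h.z_rep1, "z_rep2": h.z_rep2,
        } for i, h in enumerate(rank)])
    return tables
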