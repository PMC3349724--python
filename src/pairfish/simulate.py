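"""Synthetic FISH wells with full ground truth.

No raw screen images are deposited, so every downstream stage is exercised
against simulated fields that emulate the screen's acquisition: a single
optical section per field, ellipsoidal DAPI-stained nuclei (some touching,
some enlarged/polyploid), and per-nucleus FISH spots in two channels whose
number and geometry encode a planted pairing state:

* paired nucleus: one merged spot (most of the time) or two spots whose
  separation is drawn at <= 1.0 um;
* unpaired nucleus: two spots separated by > 1.0 um.

Spots are 2-D Gaussians truncated at 3 sigma over a flat autofluorescence
background with additive Gaussian noise; nuclei are filled ellipses with
Gaussian-blurred edges.  Polyploid nuclei double in area but, by default,
keep the same signal-count distribution — pairing accommodates extra
chromosome copies, so signal count is deliberately not a ploidy readout
(``polyploid_foci_factor`` restores a count increase if wanted).

Everything is driven by one numpy Generator per well, so a fixed
(params, seed) reproduces rasters and truth tables bit for bit.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LayoutError, PlacementError
from .image import Channel, ImagePlane
from .score import WellSummary

FISH_CHANNELS = (Channel.FISH_A, Channel.FISH_B)


@dataclass
class SimParams:
    """Study conditions for one simulated well.

    Geometry is in micrometres; the default pixel size (0.2 um/px) and
    nucleus radius (4.5 +/- 0.5 um projected) describe adhered Kc167-like
    cells under a high-NA 63x confocal.  Default pairing fractions mirror
    the screen averages for the two loci (80% and 70% single-signal
    nuclei); ``merged_fraction`` is the probability that a paired nucleus
    shows one merged signal rather than two resolved signals <= 1 um
    apart.
    """

    image_shape: tuple[int, int] = (768, 768)
    pixel_size_um: float = 0.2
    n_nuclei: int = 50
    nucleus_radius_um: tuple[float, float] = (4.5, 0.5)  # mean, SD
    min_radius_um: float = 3.0
    max_ellipticity: float = 1.2
    touching_fraction: float = 0.3
    polyploid_fraction: float = 0.05
    pairing_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: {"FISH_A": 0.8, "FISH_B": 0.7})
    merged_fraction: float = 0.95
    paired_sep_um: tuple[float, float] = (0.3, 0.95)
    unpaired_sep_um: tuple[float, float] = (1.5, 4.5)
    cluster_fraction: float = 0.4
    spot_amplitude: float = 150.0
    spot_sigma_um: float = 0.2
    background_level: float = 20.0
    noise_sd: float = 5.0
    dapi_amplitude: float = 110.0
    dapi_background: float = 10.0
    dapi_noise_sd: float = 11.0
    edge_sigma_px: float = 2.0
    polyploid_foci_factor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [self.touching_fraction, self.polyploid_fraction,
                 self.merged_fraction, self.cluster_fraction]
        fracs += [self.pairing_fraction_for(ch.value) for ch in FISH_CHANNELS]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.paired_sep_um
        if not 0 < lo <= hi <= 1.0:
            raise ValueError("paired_sep_um support must lie in (0, 1.0] um")
        lo, hi = self.unpaired_sep_um
        if not 1.0 < lo <= hi:
            raise ValueError("unpaired_sep_um support must exceed 1.0 um")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.polyploid_foci_factor not in (1, 2):
            raise ValueError("polyploid_foci_factor must be 1 or 2")

    def pairing_fraction_for(self, channel: str) -> float:
        if isinstance(self.pairing_fraction, Mapping):
            return float(self.pairing_fraction[channel])
        return float(self.pairing_fraction)


@dataclass
class GroundTruth:
    """Planted truth: one row per nucleus, one row per focus."""

    nuclei: pd.DataFrame
    foci: pd.DataFrame


@dataclass
class SimulatedWell:
    dapi: ImagePlane
    chan_a: ImagePlane
    chan_b: ImagePlane
    truth: GroundTruth

    @property
    def planes(self) -> dict[str, ImagePlane]:
        return {"DAPI": self.dapi, "FISH_A": self.chan_a, "FISH_B": self.chan_b}


# ---------------------------------------------------------------------------
# geometry helpers

@dataclass
class _Nucleus:
    idx: int
    center_px: np.ndarray  # (row, col), float
    radius_px: float
    a_px: float  # semi-major
    b_px: float  # semi-minor
    theta: float
    ploidy: int
    touching: bool
    area_px: int = 0


def _inside_ellipse(pt: np.ndarray, nuc: _Nucleus, margin_px: float) -> bool:
    d = pt - nuc.center_px
    ct, st = np.cos(nuc.theta), np.sin(nuc.theta)
    u = d[0] * ct + d[1] * st
    v = -d[0] * st + d[1] * ct
    a = nuc.a_px - margin_px
    b = nuc.b_px - margin_px
    if a <= 0 or b <= 0:
        return False
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_nuclei(params: SimParams, rng: np.random.Generator) -> list[_Nucleus]:
    h, w = params.image_shape
    px = params.pixel_size_um
    mean_r, sd_r = params.nucleus_radius_um
    nuclei: list[_Nucleus] = []
    for i in range(params.n_nuclei):
        ploidy = 2 if rng.random() < params.polyploid_fraction else 1
        r_um = max(rng.normal(mean_r, sd_r), params.min_radius_um)
        if ploidy == 2:
            r_um *= np.sqrt(2.0)  # double area
        e = rng.uniform(1.0, params.max_ellipticity)
        theta = rng.uniform(0.0, np.pi)
        r_px = r_um / px
        a_px, b_px = r_px * np.sqrt(e), r_px / np.sqrt(e)
        margin = a_px + 3 * params.edge_sigma_px + 2
        if 2 * margin >= min(h, w):
            raise PlacementError("image too small for the requested nuclei")
        touching = i > 0 and rng.random() < params.touching_fraction

        placed = False
        for attempt_mode in (("touch",) if touching else ()) + ("free",):
            for _ in range(300):
                if attempt_mode == "touch":
                    j = int(rng.integers(len(nuclei)))
                    partner = nuclei[j]
                    d = rng.uniform(1.4, 1.8) * 0.5 * (r_px + partner.radius_px)
                    ang = rng.uniform(0, 2 * np.pi)
                    center = partner.center_px + d * np.array(
                        [np.sin(ang), np.cos(ang)])
                    if not (margin <= center[0] <= h - margin
                            and margin <= center[1] <= w - margin):
                        continue
                    skip = {j}
                else:
                    center = np.array([
                        rng.uniform(margin, h - margin),
                        rng.uniform(margin, w - margin)])
                    skip = set()
                ok = True
                for k, other in enumerate(nuclei):
                    if k in skip:
                        continue
                    min_d = 1.05 * (a_px + other.a_px) + 6
                    if np.linalg.norm(center - other.center_px) < min_d:
                        ok = False
                        break
                if ok:
                    nuclei.append(_Nucleus(
                        idx=i, center_px=center, radius_px=r_px,
                        a_px=a_px, b_px=b_px, theta=theta, ploidy=ploidy,
                        touching=(attempt_mode == "touch")))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{params.n_nuclei}; "
                "image too crowded")
    return nuclei


def _ellipse_mask(nuc: _Nucleus, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    r0 = max(int(np.floor(nuc.center_px[0] - nuc.a_px - 1)), 0)
    r1 = min(int(np.ceil(nuc.center_px[0] + nuc.a_px + 2)), h)
    c0 = max(int(np.floor(nuc.center_px[1] - nuc.a_px - 1)), 0)
    c1 = min(int(np.ceil(nuc.center_px[1] + nuc.a_px + 2)), w)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dr = rows - nuc.center_px[0]
    dc = cols - nuc.center_px[1]
    ct, st = np.cos(nuc.theta), np.sin(nuc.theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    mask = (u / nuc.a_px) ** 2 + (v / nuc.b_px) ** 2 <= 1.0
    return mask, np.array([r0, c0])


def _in_territory(pt: np.ndarray, nuc: _Nucleus, margin_px: float,
                  neighbors: Sequence[_Nucleus]) -> bool:
    """Inside the nucleus's own (shrunken) ellipse and outside every
    neighbor's (expanded) ellipse — overlapping nuclei keep disjoint
    chromatin territories, so planted spots stay on their own side of
    any future watershed split."""
    if not _inside_ellipse(pt, nuc, margin_px):
        return False
    return all(not _inside_ellipse(pt, other, -margin_px)
               for other in neighbors)


def _sample_point(nuc: _Nucleus, margin_px: float, rng: np.random.Generator,
                  neighbors: Sequence[_Nucleus] = (),
                  tries: int = 400) -> np.ndarray:
    for _ in range(tries):
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.random())
        u = rad * (nuc.a_px - margin_px) * np.cos(ang)
        v = rad * (nuc.b_px - margin_px) * np.sin(ang)
        ct, st = np.cos(nuc.theta), np.sin(nuc.theta)
        pt = nuc.center_px + np.array([u * ct - v * st, u * st + v * ct])
        if _in_territory(pt, nuc, margin_px, neighbors):
            return pt
    return nuc.center_px.copy()


def _sample_pair(nuc: _Nucleus, sep_px: float, margin_px: float,
                 rng: np.random.Generator,
                 neighbors: Sequence[_Nucleus] = (),
                 tries: int = 400) -> tuple[np.ndarray, np.ndarray, float]:
    """Two points inside the (shrunken) nucleus at the requested separation.

    If the separation cannot fit (small nucleus), it is clamped to the
    longest chord that does; the clamped value is returned.
    """
    max_sep = 2.0 * (nuc.a_px - margin_px) * 0.98
    sep = min(sep_px, max_sep)
    half = sep / 2.0
    for _ in range(tries):
        c = _sample_point(nuc, margin_px, rng, neighbors)
        phi = rng.uniform(0, 2 * np.pi)
        offset = half * np.array([np.sin(phi), np.cos(phi)])
        p1, p2 = c + offset, c - offset
        if (_in_territory(p1, nuc, margin_px, neighbors)
                and _in_territory(p2, nuc, margin_px, neighbors)):
            return p1, p2, sep
    # fall back to the major axis through the centre
    ct, st = np.cos(nuc.theta), np.sin(nuc.theta)
    axis = np.array([ct, st])
    return nuc.center_px + half * axis, nuc.center_px - half * axis, sep


@dataclass
class _ChannelState:
    """Planted pairing state for one nucleus/channel, separate from the
    spot placement so collisions can be re-placed without re-drawing the
    state (which would bias the realised pairing fraction)."""

    paired: bool
    groups: list[float | None]  # per homolog group: None = merged, else sep um


def _draw_channel_state(params: SimParams, rng: np.random.Generator,
                        pair_frac: float, n_pairs: int) -> _ChannelState:
    """Draw the pairing state once per nucleus/channel; polyploid nuclei
    share the state across homolog groups (pairing accommodates ploidy)."""
    paired = bool(rng.random() < pair_frac)
    groups: list[float | None] = []
    for _ in range(n_pairs):
        if paired:
            if rng.random() < params.merged_fraction:
                groups.append(None)
            else:
                groups.append(float(rng.uniform(*params.paired_sep_um)))
        else:
            groups.append(float(rng.uniform(*params.unpaired_sep_um)))
    return _ChannelState(paired=paired, groups=groups)


def _place_channel_spots(
    nuc: _Nucleus, state: _ChannelState, params: SimParams,
    rng: np.random.Generator, margin_px: float,
    neighbors: Sequence[_Nucleus] = (),
) -> list[np.ndarray]:
    px = params.pixel_size_um
    positions: list[np.ndarray] = []
    for sep_um in state.groups:
        if sep_um is None:
            positions.append(_sample_point(nuc, margin_px, rng, neighbors))
        else:
            p1, p2, _ = _sample_pair(nuc, sep_um / px, margin_px, rng,
                                     neighbors)
            positions.extend([p1, p2])
    return positions


def _render_spots(shape: tuple[int, int], spots: Sequence[np.ndarray],
                  amplitude: float, sigma_px: float) -> np.ndarray:
    canvas = np.zeros(shape, dtype=np.float64)
    rad = int(np.ceil(3 * sigma_px)) + 1
    h, w = shape
    for c in spots:
        r0 = max(int(np.floor(c[0])) - rad, 0)
        r1 = min(int(np.ceil(c[0])) + rad + 1, h)
        c0 = max(int(np.floor(c[1])) - rad, 0)
        c1 = min(int(np.ceil(c[1])) + rad + 1, w)
        rows, cols = np.mgrid[r0:r1, c0:c1]
        d2 = (rows - c[0]) ** 2 + (cols - c[1]) ** 2
        g = amplitude * np.exp(-d2 / (2 * sigma_px ** 2))
        g[d2 > (3 * sigma_px) ** 2] = 0.0  # truncate at 3 sigma
        canvas[r0:r1, c0:c1] += g
    return canvas


def simulate_well(params: SimParams) -> SimulatedWell:
    """Render one well (DAPI + two FISH channels) plus its ground truth."""
    from scipy.ndimage import gaussian_filter  # local import keeps startup light

    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    px = params.pixel_size_um
    sigma_px = params.spot_sigma_um / px
    spot_margin = 3 * sigma_px + 2

    nuclei = _place_nuclei(params, rng)

    # --- DAPI ---
    dapi = np.zeros((h, w), dtype=np.float64)
    for nuc in nuclei:
        mask, origin = _ellipse_mask(nuc, (h, w))
        nuc.area_px = int(mask.sum())
        sub = dapi[origin[0]:origin[0] + mask.shape[0],
                   origin[1]:origin[1] + mask.shape[1]]
        np.maximum(sub, mask * params.dapi_amplitude, out=sub)
    dapi = gaussian_filter(dapi, params.edge_sigma_px)
    dapi += params.dapi_background
    dapi += rng.normal(0.0, params.dapi_noise_sd, size=(h, w))
    np.clip(dapi, 0.0, None, out=dapi)

    # --- FISH spots ---
    spot_rows: list[dict] = []
    nuc_rows: list[dict] = []
    positions_by_channel: dict[str, list[np.ndarray]] = {
        ch.value: [] for ch in FISH_CHANNELS}
    for nuc in nuclei:
        n_pairs = params.polyploid_foci_factor if nuc.ploidy == 2 else 1
        neighbors = [o for o in nuclei if o.idx != nuc.idx
                     and np.linalg.norm(o.center_px - nuc.center_px)
                     < o.a_px + nuc.a_px + 4]
        states = {
            ch.value: _draw_channel_state(
                params, rng, params.pairing_fraction_for(ch.value), n_pairs)
            for ch in FISH_CHANNELS}
        per_channel = {
            ch.value: _place_channel_spots(
                nuc, states[ch.value], params, rng, spot_margin, neighbors)
            for ch in FISH_CHANNELS}
        paired_flags = {ch.value: states[ch.value].paired
                        for ch in FISH_CHANNELS}

        pa, pb = per_channel["FISH_A"], per_channel["FISH_B"]
        clustered = False
        if (len(pa) == 1 and len(pb) == 1
                and rng.random() < params.cluster_fraction):
            # plant a cross-channel overlap: same spot, sub-pixel offset
            pb[0] = pa[0] + rng.uniform(-0.5, 0.5, size=2)
            clustered = True
        else:
            # keep the channels apart so no accidental overlap arises;
            # only the placement is re-drawn, never the pairing state
            min_gap = 2 * (3 * sigma_px) + 3
            for _ in range(100):
                too_close = any(
                    np.linalg.norm(a - b) < min_gap for a in pa for b in pb)
                if not too_close:
                    break
                pb = _place_channel_spots(
                    nuc, states["FISH_B"], params, rng, spot_margin,
                    neighbors)
                per_channel["FISH_B"] = pb

        for ch in FISH_CHANNELS:
            positions_by_channel[ch.value].extend(per_channel[ch.value])
            for pos in per_channel[ch.value]:
                spot_rows.append({
                    "nucleus": nuc.idx + 1,
                    "channel": ch.value,
                    "x_um": pos[1] * px,
                    "y_um": pos[0] * px,
                })
        nuc_rows.append({
            "nucleus": nuc.idx + 1,
            "x_um": nuc.center_px[1] * px,
            "y_um": nuc.center_px[0] * px,
            "radius_um": nuc.radius_px * px,
            "area_px": nuc.area_px,
            "ploidy": nuc.ploidy,
            "touching": nuc.touching,
            "count_FISH_A": len(per_channel["FISH_A"]),
            "count_FISH_B": len(per_channel["FISH_B"]),
            "paired_FISH_A": paired_flags["FISH_A"],
            "paired_FISH_B": paired_flags["FISH_B"],
            "clustered": clustered,
        })

    planes: dict[str, np.ndarray] = {}
    for ch in FISH_CHANNELS:
        img = _render_spots((h, w), positions_by_channel[ch.value],
                            params.spot_amplitude, sigma_px)
        img += params.background_level
        img += rng.normal(0.0, params.noise_sd, size=(h, w))
        np.clip(img, 0.0, None, out=img)
        planes[ch.value] = img

    truth = GroundTruth(
        nuclei=pd.DataFrame(nuc_rows),
        foci=pd.DataFrame(
            spot_rows, columns=["nucleus", "channel", "x_um", "y_um"]),
    )
    return SimulatedWell(
        dapi=ImagePlane(dapi, Channel.DAPI, px),
        chan_a=ImagePlane(planes["FISH_A"], Channel.FISH_A, px),
        chan_b=ImagePlane(planes["FISH_B"], Channel.FISH_B, px),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# plate-level simulation

def derive_well_seed(master_seed: int, plate_id: str, well_id: str) -> int:
    """Deterministic, platform-stable per-well seed from (master, plate, well)."""
    ss = np.random.SeedSequence([
        int(master_seed) & 0x7FFFFFFF,
        zlib.crc32(str(plate_id).encode()),
        zlib.crc32(str(well_id).encode()),
    ])
    return int(ss.generate_state(1)[0]) % (2 ** 31)


def _apply_overrides(base: SimParams, overrides: Mapping[str, object]) -> SimParams:
    fields = {}
    for key, value in overrides.items():
        if not hasattr(base, key):
            raise LayoutError(f"unknown SimParams override: {key}")
        if key == "pairing_fraction" and isinstance(value, Mapping) \
                and isinstance(base.pairing_fraction, Mapping):
            merged = dict(base.pairing_fraction)
            merged.update({k: float(v) for k, v in value.items()})
            fields[key] = merged
        else:
            fields[key] = value
    return replace(base, **fields)


def simulate_plate(
    layout: pd.DataFrame,
    base_params: SimParams,
    out_dir: str | Path,
    master_seed: int,
    well_effects: Mapping[str, Mapping[str, object]] | None = None,
) -> pd.DataFrame:
    """Simulate every well of a plate layout and write images + truth.

    ``layout`` needs columns plate, well, role, target; ``well_effects``
    maps well id -> SimParams field overrides (e.g. a lowered
    pairing_fraction for planted hit wells).  Per-well seeds derive
    deterministically from (master_seed, plate, well), so replicate plates
    simulated from different master seeds share the planted effect map but
    not the rasters.
    """
    from .io import write_well_images  # deferred: io imports tifffile

    if layout.duplicated(subset=["plate", "well"]).any():
        dupes = layout[layout.duplicated(subset=["plate", "well"], keep=False)]
        raise LayoutError(f"duplicate well addresses:\n{dupes}")
    out_dir = Path(out_dir)
    well_effects = well_effects or {}
    rows = []
    for _, rec in layout.sort_values(["plate", "well"]).iterrows():
        plate, well = str(rec["plate"]), str(rec["well"])
        seed = derive_well_seed(master_seed, plate, well)
        params = _apply_overrides(base_params, well_effects.get(well, {}))
        params = replace(params, seed=seed)
        sim = simulate_well(params)
        plate_dir = out_dir / plate
        plate_dir.mkdir(parents=True, exist_ok=True)
        write_well_images(plate_dir / f"{well}.tif", sim.planes)
        sim.truth.nuclei.to_csv(plate_dir / f"{well}.truth.tsv",
                                sep="\t", index=False, float_format="%.6g")
        sim.truth.foci.to_csv(plate_dir / f"{well}.truth_foci.tsv",
                              sep="\t", index=False, float_format="%.6g")
        rows.append({"plate": plate, "well": well, "role": rec.get("role", "library"),
                     "target": rec.get("target", ""), "seed": seed})
    return pd.DataFrame(rows)


def simulate_screen_plate(
    wells: Sequence[str],
    seed: int,
    baseline_pct_single: float = 80.0,
    between_well_sd: float = 3.0,
    effects: Mapping[str, float] | None = None,
    channel: str = "FISH_B",
) -> dict[str, WellSummary]:
    """Draw one plate of per-well summaries at the statistics level.

    Emulates the screen's well-to-well spread (the screen average was
    80 +/- 3% single-signal nuclei) without rendering images: each well's
    pct_single is baseline + effect + N(0, between_well_sd), clipped to
    [0, 100].  Used for power/specificity studies of the hit-calling
    machinery, where tens of thousands of wells are needed.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    out: dict[str, WellSummary] = {}
    for wl in wells:
        val = baseline_pct_single + effects.get(wl, 0.0) \
            + rng.normal(0.0, between_well_sd)
        out[wl] = WellSummary.from_metrics(
            pct_single=float(np.clip(val, 0.0, 100.0)),
            channel=channel, well_id=wl)
    return out
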