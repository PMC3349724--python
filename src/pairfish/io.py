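"""File formats: multi-page TIFF wells, TSV tables, plate maps.

One TIFF per well, one page per channel in the order given by the channel
map (default DAPI, FISH_A, FISH_B).  All tables are tab-separated with a
header row and a stable column order; coordinates are micrometres in the
image frame.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, LayoutError
from .image import Channel, ImagePlane

DEFAULT_CHANNEL_ORDER: tuple[str, ...] = ("DAPI", "FISH_A", "FISH_B")

#: stable column orders for the output tables (golden-file tested)
PER_NUCLEUS_COLUMNS = [
    "plate", "well", "nucleus", "x_um", "y_um", "area_px", "area_um2",
    "volume_proxy_um3", "touches_border", "is_large",
    "count_FISH_A", "count_FISH_B", "paired_FISH_A", "paired_FISH_B",
    "mean_intersignal_um", "clustered",
]
PER_WELL_COLUMNS = [
    "plate", "well", "role", "target", "n_nuclei", "pct_large",
    "pct_1R1G", "pct_1R1G_touch", "mean_intersignal_um",
    "pct_single_FISH_A", "pct_paired_FISH_A", "pct_far_FISH_A",
    "bin0_FISH_A", "bin1_FISH_A", "bin2_FISH_A", "bin3_FISH_A",
    "bin4_FISH_A", "bin5plus_FISH_A",
    "pct_single_FISH_B", "pct_paired_FISH_B", "pct_far_FISH_B",
    "bin0_FISH_B", "bin1_FISH_B", "bin2_FISH_B", "bin3_FISH_B",
    "bin4_FISH_B", "bin5plus_FISH_B",
]
HITS_COLUMNS = [
    "well", "target", "category", "metric", "z_rep1", "z_rep2",
    "validation_p", "validated",
]
FOCI_COLUMNS = [
    "plate", "well", "nucleus", "channel", "x_um", "y_um", "area_px", "peak",
]

_WELL_RE = re.compile(r"^[A-P](0[1-9]|1[0-9]|2[0-4])$")
VALID_ROLES = {"library", "neg_control", "pos_control", "blank"}


def write_well_images(path: str | Path, planes: Mapping[str, ImagePlane],
                      channel_order: Sequence[str] = DEFAULT_CHANNEL_ORDER) -> None:
    """Write a well's channels as a multi-page float32 TIFF."""
    pages = []
    for name in channel_order:
        if name not in planes:
            raise FormatError(f"missing channel {name!r} for {path}")
        pages.append(planes[name].raster.astype(np.float32))
    tifffile.imwrite(str(path), np.stack(pages), photometric="minisblack")


def read_well_images(
    path: str | Path,
    pixel_size_um: float,
    channel_order: Sequence[str] = DEFAULT_CHANNEL_ORDER,
) -> dict[str, ImagePlane]:
    """Read a multi-page well TIFF into channel-tagged planes."""
    path = Path(path)
    try:
        stack = tifffile.imread(str(path))
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(channel_order):
        raise FormatError(
            f"{path}: {stack.shape[0]} page(s) but channel map lists "
            f"{len(channel_order)} ({', '.join(channel_order)})")
    shapes = {page.shape for page in stack}
    if len(shapes) != 1:
        raise FormatError(f"{path}: channel pages differ in shape")
    return {
        name: ImagePlane(np.asarray(stack[i], dtype=np.float64),
                         Channel(name), pixel_size_um)
        for i, name in enumerate(channel_order)
    }


def read_platemap(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV plate map (plate, well, role, target)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"plate", "well", "role"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"plate map missing columns: {sorted(missing)}")
    if "target" not in df.columns:
        df["target"] = ""
    bad_wells = df.loc[~df["well"].str.match(_WELL_RE), "well"]
    if len(bad_wells):
        raise LayoutError(
            f"invalid 384-well addresses: {sorted(set(bad_wells))[:5]}")
    bad_roles = set(df["role"]) - VALID_ROLES
    if bad_roles:
        raise LayoutError(f"unknown roles: {sorted(bad_roles)}")
    if df.duplicated(subset=["plate", "well"]).any():
        dupes = df[df.duplicated(subset=["plate", "well"], keep=False)]
        raise LayoutError(f"duplicate (plate, well) addresses:\n{dupes}")
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write a TSV with a fixed column order and stable float formatting."""
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_label_mask(path: str | Path, mask: np.ndarray) -> None:
    """Persist a label mask as 16-bit TIFF (labels above 65535 are rare
    enough to be an error rather than silently wrapped)."""
    if mask.max() > np.iinfo(np.uint16).max:
        raise FormatError("more than 65535 labels; cannot write 16-bit mask")
    tifffile.imwrite(str(path), mask.astype(np.uint16))
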