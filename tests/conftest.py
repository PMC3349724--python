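"""Shared fixtures: small, fast synthetic wells and matching helpers."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from pairfish import SimParams, simulate_well
from pairfish.foci import FocusRecord
from pairfish.image import Channel


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """A quick well: 12 nuclei in a 384x384 field, default optics."""
    return dataclasses.replace(SimParams(), image_shape=(384, 384), n_nuclei=12)


@pytest.fixture(scope="session")
def sim_well(small_params):
    return simulate_well(dataclasses.replace(small_params, seed=7))


def match_truth(truth_nuclei, records, max_um: float = 1.0):
    """One-to-one match of truth nuclei to recovered records by centroid.

    Returns (pairs, distances_um): pairs of (truth_row_index, record_index)
    within max_um of each other.
    """
    rec = np.array([r.centroid_um for r in records]).reshape(-1, 2)
    tru = truth_nuclei[["x_um", "y_um"]].to_numpy()
    if rec.size == 0 or tru.size == 0:
        return [], []
    d = cdist(tru, rec)
    ri, ci = linear_sum_assignment(d)
    pairs, dists = [], []
    for i, j in zip(ri, ci):
        if d[i, j] <= max_um:
            pairs.append((int(i), int(j)))
            dists.append(float(d[i, j]))
    return pairs, dists


def make_focus(x_um, y_um, nucleus_label=1, channel=Channel.FISH_A,
               pixels=None, pixel_size_um=0.2):
    """Hand-built FocusRecord for unit tests of the scoring operations."""
    if pixels is None:
        r, c = int(round(y_um / pixel_size_um)), int(round(x_um / pixel_size_um))
        pixels = np.array([[r, c], [r, c + 1]])
    return FocusRecord(
        channel=channel, nucleus_label=nucleus_label,
        pixels=np.asarray(pixels), area_px=len(pixels),
        centroid_um=(float(x_um), float(y_um)), peak_intensity=100.0)
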