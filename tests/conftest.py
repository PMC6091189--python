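"""Shared fixtures: synthetic sections are generated once per session and
reused across test modules to keep the suite inside its time budget."""

from __future__ import annotations

import numpy as np
import pytest

from musclehca import segmentation as seg
from musclehca.morphometry import measure_section, region_label_images
from musclehca.synthetic import SynthParams, generate_section


def run_segmentation(section):
    """laminin -> pretreat -> segment with default parameters."""
    pre = seg.pretreat(section.channel("laminin"))
    return seg.segment_fibers(pre, scale_um_per_px=section.scale_um_per_px)


def full_geometry(section):
    """Segment and build morphometry + ROIs + region label images."""
    fiber_map = run_segmentation(section)
    morphs, rois = measure_section(fiber_map)
    region_imgs = region_label_images(rois, fiber_map.labels.shape)
    return fiber_map, morphs, rois, region_imgs


def iou_match(truth_labels: np.ndarray, pred_labels: np.ndarray) -> dict:
    """Best-IoU predicted label for every truth label.

    Returns ``{truth_id: (iou, pred_id)}`` computed from the full confusion
    counts (brute force, independent of the segmentation path).
    """
    from collections import Counter

    t = truth_labels.ravel()
    p = pred_labels.ravel()
    keep = (t > 0) | (p > 0)
    t, p = t[keep], p[keep]
    inter = Counter(zip(t.tolist(), p.tolist()))
    t_area = Counter(t.tolist())
    p_area = Counter(p.tolist())
    best: dict = {}
    for (ti, pi), c in inter.items():
        if ti == 0 or pi == 0:
            continue
        iou = c / (t_area[ti] + p_area[pi] - c)
        if iou > best.get(ti, (0.0, None))[0]:
            best[ti] = (iou, pi)
    return best


@pytest.fixture(scope="session")
def cnf_section():
    """One 150-fiber section with 30% centronucleated fibers, plus truth."""
    params = SynthParams(n_fibers=150, cnf_fraction=0.30,
                         channels=("laminin", "dapi"))
    return generate_section(params, seed=42)


@pytest.fixture(scope="session")
def cnf_geometry(cnf_section):
    section, truth = cnf_section
    return full_geometry(section)


@pytest.fixture(scope="session")
def marker_section():
    """Section with satellites and vessels for the cell-detection tests."""
    params = SynthParams(
        n_fibers=120,
        cnf_fraction=0.0,
        satellites_per_fiber_dist={0: 0.6, 1: 0.4},
        vessels_per_fiber_dist={3: 0.5, 4: 0.5},
        channels=("laminin", "dapi", "pax7", "cd31"),
    )
    return generate_section(params, seed=7)


@pytest.fixture(scope="session")
def marker_geometry(marker_section):
    section, truth = marker_section
    return full_geometry(section)


@pytest.fixture(scope="session")
def plain_section():
    """Laminin-only 150-fiber section (segmentation/geometry tests)."""
    params = SynthParams(n_fibers=150, channels=("laminin",))
    return generate_section(params, seed=5)


@pytest.fixture(scope="session")
def plain_geometry(plain_section):
    section, truth = plain_section
    return full_geometry(section)
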