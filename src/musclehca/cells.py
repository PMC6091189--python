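"""Satellite-cell (Pax7) and vessel (CD31) detection and quantification.

A Pax7 blob is accepted as a satellite cell when at least 90% of its area
overlaps the detected-nuclei mask AND its centroid lies in some fiber's
sub-laminal annulus (``roi_sc``).  CD31 blobs are counted per fiber when
their centroid falls in that fiber's peri-fiber band (``roi_v``); bands of
adjacent fibers overlap, so one vessel may count for several fibers, while
the per-mm^2 density uses each unique object once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from musclehca.nuclei import BlobParams, DetectedObject, detect_blobs

#: Default minimum fraction of a Pax7 blob that must overlap nuclei.
OVERLAP_THRESHOLD = 0.90

PAX7_PARAMS = BlobParams(min_area_um2=8.0, max_area_um2=120.0)
CD31_PARAMS = BlobParams(min_area_um2=5.0, max_area_um2=400.0)


@dataclass
class SatelliteCall:
    object_id: int
    overlap_fraction: float
    fiber_id: int | None
    accepted: bool
    centroid_xy_um: tuple


@dataclass
class VesselMetrics:
    per_fiber_counts: dict  # fiber_id -> vessels whose centroid is in roi_v
    density_per_mm2: float  # unique CD31 objects / section area (mm^2)
    pct_area: float  # CD31 mask area / section area * 100


def detect_marker_objects(
    channel: np.ndarray,
    role: str,
    scale_um_per_px: float,
    params: BlobParams | None = None,
) -> list:
    """Detect Pax7 or CD31 blobs with role-specific area bounds."""
    if role not in ("pax7", "cd31"):
        raise ValueError(f"role must be pax7 or cd31, got {role!r}")
    if params is None:
        params = PAX7_PARAMS if role == "pax7" else CD31_PARAMS
    return detect_blobs(channel, role, scale_um_per_px, params)


def _blob_overlap(obj: DetectedObject, mask: np.ndarray) -> float:
    r0, c0 = obj.origin
    h, w = obj.mask.shape
    window = mask[r0 : r0 + h, c0 : c0 + w]
    inter = int((obj.mask & window).sum())
    return inter / int(obj.mask.sum())


def call_satellites(
    pax7: list,
    nuclei_mask: np.ndarray,
    roisets: dict,
    region_images: dict,
    overlap_threshold: float = OVERLAP_THRESHOLD,
) -> list:
    """Apply the nucleus-overlap and sub-laminal position rules to Pax7 blobs.

    ``overlap_fraction`` = |blob intersect nuclei| / |blob|; a call is
    accepted iff the fraction reaches ``overlap_threshold`` and the blob's
    centroid lies in some fiber's ``roi_sc`` (the owning fiber).
    """
    sc_img = region_images["sc"]
    shape = sc_img.shape
    calls: list = []
    for obj in pax7:
        frac = _blob_overlap(obj, nuclei_mask)
        r, c = obj.centroid_px
        ri, ci = int(round(r)), int(round(c))
        fid = None
        if 0 <= ri < shape[0] and 0 <= ci < shape[1]:
            owner = int(sc_img[ri, ci])
            if owner > 0:
                fid = owner
        calls.append(
            SatelliteCall(
                object_id=obj.object_id,
                overlap_fraction=frac,
                fiber_id=fid,
                accepted=(frac >= overlap_threshold) and fid is not None,
                centroid_xy_um=obj.centroid_xy_um,
            )
        )
    return calls


def quantify_vessels(
    cd31: list,
    roisets: dict,
    section_mask: np.ndarray,
    scale_um_per_px: float,
) -> VesselMetrics:
    """Per-fiber vessel counts plus the two section-level vascular metrics."""
    section_px = int(section_mask.sum())
    if section_px == 0:
        raise ValueError("zero section area")
    s = scale_um_per_px
    section_mm2 = section_px * s * s / 1e6

    per_fiber = {fid: 0 for fid in roisets}
    for obj in cd31:
        r, c = obj.centroid_px
        for fid, rs in roisets.items():
            if rs.contains("v", r, c):
                per_fiber[fid] += 1

    # pct_area from the union of detected CD31 masks clipped to the section
    cd31_px = 0
    for obj in cd31:
        r0, c0 = obj.origin
        h, w = obj.mask.shape
        cd31_px += int((obj.mask & section_mask[r0 : r0 + h, c0 : c0 + w]).sum())

    return VesselMetrics(
        per_fiber_counts=per_fiber,
        density_per_mm2=len(cd31) / section_mm2,
        pct_area=100.0 * cd31_px / section_px,
    )


def satellite_vessel_distances(satellites: list, vessels: list) -> dict:
    """Per accepted satellite, the minimum centroid-to-centroid distance (um)
    to any vessel; missing (None) when there are no vessels."""
    out: dict = {}
    vpts = np.array([v.centroid_xy_um for v in vessels], dtype=np.float64)
    for sat in satellites:
        if not sat.accepted:
            continue
        if len(vpts) == 0:
            out[sat.object_id] = None
            continue
        p = np.asarray(sat.centroid_xy_um, dtype=np.float64)
        out[sat.object_id] = float(np.sqrt(((vpts - p) ** 2).sum(axis=1)).min())
    return out
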