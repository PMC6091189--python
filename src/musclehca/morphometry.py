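"""Per-fiber morphometry and the Feret-proportional regions of interest.

Every fiber gets four nested/adjacent regions:

* ``roi_f``   — the fiber mask itself;
* ``roi_cnf`` — central zone: erosion of ``roi_f`` by a disc of radius
  one fifth of the minimum Feret diameter (nuclei here count as central);
* ``roi_sc``  — sub-laminal annulus: exactly ``roi_f`` minus ``roi_cnf``
  (where satellite cells and peripheral myonuclei sit);
* ``roi_v``   — peri-fiber band: dilation of ``roi_f`` by one eighth of the
  minimum Feret diameter, minus ``roi_f`` (where vessels are counted).

Margins are proportional to the minimum Feret diameter, so the construction
works for any fiber size.  ROI masks are stored as bounding-box crops with a
``(row, col)`` origin offset to keep whole-section memory bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure

#: ROI margin fractions of the minimum Feret diameter.
CNF_FRACTION = 1.0 / 5.0
V_FRACTION = 1.0 / 8.0

_CORNERS = np.array(
    [[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]], dtype=np.float64
)


@dataclass
class FiberMorphometry:
    fiber_id: int
    csa_um2: float
    min_feret_um: float
    max_feret_um: float
    circularity: float
    gc_xy_um: tuple  # (row_um, col_um) gravity center


@dataclass
class RoiSet:
    """The four binary masks of one fiber (crops at ``origin``), plus the
    discrete erosion/dilation radii actually used."""

    fiber_id: int
    origin: tuple  # (row0, col0) of the crop in section coordinates
    roi_f: np.ndarray
    roi_cnf: np.ndarray
    roi_sc: np.ndarray
    roi_v: np.ndarray
    cnf_radius_px: int
    v_radius_px: int

    def contains(self, roi: str, row: float, col: float) -> bool:
        """Whether section-coordinate point (row, col) falls in the named ROI."""
        mask = getattr(self, f"roi_{roi}")
        r = int(round(row)) - self.origin[0]
        c = int(round(col)) - self.origin[1]
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]:
            return bool(mask[r, c])
        return False


def _hull_points(mask: np.ndarray) -> np.ndarray:
    """Convex hull vertices of the mask's pixel *extents* (centers +- 1/2).

    Using pixel corners rather than centers makes analytic shapes exact: a
    100-px-wide square has Feret width 100 px, not 99.
    """
    eroded = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1))
    brows, bcols = np.nonzero(mask & ~eroded)
    if len(brows) == 0:  # single-pixel or line-like mask
        brows, bcols = np.nonzero(mask)
    bpts = np.stack([brows, bcols], axis=1).astype(np.float64)
    corners = (bpts[:, None, :] + _CORNERS[None, :, :]).reshape(-1, 2)
    if len(np.unique(corners[:, 0])) == 1 or len(np.unique(corners[:, 1])) == 1:
        return corners
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def feret_diameters(mask: np.ndarray) -> tuple:
    """(min, max) Feret diameters of a binary mask, in pixels.

    Rotating calipers on the convex hull of boundary-pixel corner points:
    the maximum Feret is the hull diameter; the minimum Feret is the
    smallest width over hull edges (for a convex polygon the minimum caliper
    width is attained with one caliper flush against an edge).
    """
    pts = _hull_points(mask)
    if len(pts) == 1:
        return 1.0, 1.0
    diff = pts[:, None, :] - pts[None, :, :]
    dmax = float(np.sqrt((diff**2).sum(-1)).max())
    n = len(pts)
    widths = []
    for i in range(n):
        p, q = pts[i], pts[(i + 1) % n]
        edge = q - p
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        proj = (pts - p) @ normal
        widths.append(proj.max() - proj.min())
    dmin = float(min(widths)) if widths else dmax
    return dmin, dmax


def measure_fiber(
    mask: np.ndarray,
    scale_um_per_px: float,
    fiber_id: int = 0,
    origin: tuple = (0, 0),
) -> FiberMorphometry:
    """Morphometry of one connected fiber mask.

    CSA is pixel count x scale^2; Feret diameters come from rotating
    calipers on the hull of boundary-pixel corners; the perimeter uses the
    corner-corrected boundary estimate of ``skimage.measure.perimeter``; the
    gravity center is the unweighted pixel centroid in micrometres.
    ``origin`` shifts the gravity center when ``mask`` is a crop.
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty fiber mask")
    if int(measure.label(mask).max()) != 1:
        raise ValueError("fiber mask must be a single connected component")
    dmin_px, dmax_px = feret_diameters(mask)
    perim_px = measure.perimeter_crofton(mask, directions=4)
    circ = 4.0 * np.pi * n_px / perim_px**2 if perim_px > 0 else 1.0
    rows, cols = np.nonzero(mask)
    s = scale_um_per_px
    return FiberMorphometry(
        fiber_id=fiber_id,
        csa_um2=n_px * s * s,
        min_feret_um=dmin_px * s,
        max_feret_um=dmax_px * s,
        circularity=min(circ, 1.0),
        gc_xy_um=(
            (float(rows.mean()) + origin[0]) * s,
            (float(cols.mean()) + origin[1]) * s,
        ),
    )


def _erode_disc(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Erosion by a Euclidean disc: keep pixels farther than radius from outside."""
    if radius_px <= 0:
        return mask.copy()
    return ndi.distance_transform_edt(mask) > radius_px


def _dilate_disc(mask: np.ndarray, radius_px: int) -> np.ndarray:
    if radius_px <= 0:
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= radius_px


def build_rois(
    mask: np.ndarray,
    morph: FiberMorphometry,
    scale_um_per_px: float,
    cnf_fraction: float = CNF_FRACTION,
    v_fraction: float = V_FRACTION,
    origin: tuple = (0, 0),
    other_fibers: np.ndarray | None = None,
) -> RoiSet:
    """Build the four ROIs of one fiber from its mask and morphometry.

    Erosion radius = round(min_feret * cnf_fraction / scale) px and dilation
    radius = round(min_feret * v_fraction / scale) px; discs are Euclidean
    distance thresholds (isotropic).  If the erosion would empty the central
    zone, the ultimate-erosion pixel set (deepest interior pixels) is used
    instead so every fiber keeps a defined center.

    ``mask`` should be a crop padded by at least the dilation radius so the
    peri-fiber band is not clipped; ``origin`` anchors it in the section.
    ``other_fibers`` (same crop geometry) marks neighbouring fibers' pixels;
    the peri-fiber band never covers any fiber, only walls and interstitium.
    """
    mask = np.asarray(mask, dtype=bool)
    r_cnf = int(round(morph.min_feret_um * cnf_fraction / scale_um_per_px))
    r_v = int(round(morph.min_feret_um * v_fraction / scale_um_per_px))
    roi_cnf = _erode_disc(mask, r_cnf)
    if not roi_cnf.any():
        dist = ndi.distance_transform_edt(mask)
        roi_cnf = dist == dist.max()
    roi_sc = mask & ~roi_cnf
    roi_v = _dilate_disc(mask, max(r_v, 1)) & ~mask
    if other_fibers is not None:
        roi_v &= ~other_fibers
    return RoiSet(
        fiber_id=morph.fiber_id,
        origin=tuple(origin),
        roi_f=mask,
        roi_cnf=roi_cnf,
        roi_sc=roi_sc,
        roi_v=roi_v,
        cnf_radius_px=r_cnf,
        v_radius_px=r_v,
    )


def measure_section(fiber_map, cnf_fraction: float = CNF_FRACTION,
                    v_fraction: float = V_FRACTION) -> tuple:
    """Measure every fiber of a label map and build its ROIs.

    Returns ``(morphs, roisets)`` keyed by fiber id.  Crops are padded by
    the dilation radius plus a safety margin so peri-fiber bands fit.
    """
    labels = fiber_map.labels
    scale = fiber_map.scale_um_per_px
    shape = labels.shape
    slices = ndi.find_objects(labels)
    morphs: dict = {}
    roisets: dict = {}
    for fid in fiber_map.fiber_ids():
        sl = slices[fid - 1]
        if sl is None:
            continue
        crop = labels[sl] == fid
        m = measure_fiber(crop, scale, fiber_id=int(fid),
                          origin=(sl[0].start, sl[1].start))
        pad = int(round(m.min_feret_um * v_fraction / scale)) + 2
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, shape[1])
        window = labels[r0:r1, c0:c1]
        padded = window == fid
        roisets[int(fid)] = build_rois(
            padded, m, scale, cnf_fraction=cnf_fraction,
            v_fraction=v_fraction, origin=(r0, c0),
            other_fibers=(window > 0) & ~padded,
        )
        morphs[int(fid)] = m
    return morphs, roisets


def region_label_images(roisets: dict, shape: tuple) -> dict:
    """Paint per-fiber ROI crops into whole-section label images.

    Returns ``{"f": img, "cnf": img, "sc": img, "v": img}`` where each pixel
    holds the owning fiber id (0 = none).  f/cnf/sc are conflict-free since
    fibers are disjoint; in the v image, overlapping bands of adjacent
    fibers keep the id painted last — per-fiber vessel counting therefore
    uses the individual masks, not this image.
    """
    out = {k: np.zeros(shape, dtype=np.int32) for k in ("f", "cnf", "sc", "v")}
    for fid, rs in roisets.items():
        r0, c0 = rs.origin
        h, w = rs.roi_f.shape
        for kind in ("f", "cnf", "sc", "v"):
            view = out[kind][r0 : r0 + h, c0 : c0 + w]
            view[getattr(rs, f"roi_{kind}")] = fid
    return out
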