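"""Laminin pretreatment, fiber segmentation and the two quality controls.

The laminin channel stains the basal lamina, i.e. the walls between fibers.
Segmentation thresholds the pretreated walls, takes the connected components
of their complement inside the tissue mask as fiber interiors, and splits
interiors merged through wall gaps by a marker-based watershed on the
distance transform.

Two quality controls follow: a whole-section check on the fraction of tissue
area left unsegmented (user-set artifact tolerance), and a per-fiber pass
removing fibers with cross-sectional area above mean + 3 SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters, morphology, segmentation as skseg
from skimage.measure import label as cc_label


@dataclass
class SegConfig:
    rolling_ball_radius_px: int = 50
    clahe_clip: float = 0.005
    min_fiber_area_um2: float = 50.0
    #: components above this area are segmentation failures (e.g. merged
    #: regions behind destroyed walls), not fibers; they stay unlabeled so
    #: the section-QC area ratio sees them as unsegmented tissue
    max_fiber_area_um2: float = 15000.0
    artifact_tolerance: float = 0.10
    #: watershed marker suppression depth, in distance-transform pixels
    marker_h_px: float = 3.0
    #: gaussian sigma applied to the distance map before marker extraction;
    #: calms ridge undulation from ragged thresholded boundaries
    marker_smooth_px: float = 1.5
    #: closing radius (px) used to build the tissue section mask
    section_close_px: int = 5


@dataclass
class FiberLabelMap:
    """Labelled fibers of one section.

    ``labels`` is a 2-D integer grid with 0 for non-fiber pixels and
    consecutive ids ``1..n_fibers`` for fibers.  ``section_mask`` is the
    binary tissue mask of the whole section.  ``excluded_ids`` records ids
    removed by QC together with the removal reason.
    """

    labels: np.ndarray
    section_mask: np.ndarray
    scale_um_per_px: float
    wall_mask: np.ndarray | None = None
    excluded_ids: dict = field(default_factory=dict)

    @property
    def n_fibers(self) -> int:
        return int(self.labels.max())

    def fiber_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def fiber_mask(self, fiber_id: int) -> np.ndarray:
        return self.labels == fiber_id


@dataclass
class QcReport:
    """Whole-section segmentation quality report.

    ``fiber_area_ratio`` is the sum of segmented fiber areas divided by the
    tissue section area; the section is accepted when the unsegmented
    fraction ``1 - ratio`` does not exceed the user's artifact tolerance.
    """

    fiber_area_ratio: float
    accepted: bool
    artifact_tolerance: float
    csa_mean_um2: float = float("nan")
    csa_sd_um2: float = float("nan")
    n_removed_outliers: int = 0


class NoTissueError(ValueError):
    """Raised when an image contains no tissue above threshold."""


def pretreat(laminin: np.ndarray, params: SegConfig | None = None) -> np.ndarray:
    """Background reduction and local contrast enhancement of the wall channel.

    Rolling-ball-style background subtraction (white top-hat with a disc of
    the configured radius) followed by tile-based adaptive histogram
    equalization.  The result is normalized to [0, 1].  Exactly invariant to
    a constant intensity offset; a constant image maps to all zeros.
    """
    if params is None:
        params = SegConfig()
    img = np.asarray(laminin, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"laminin channel must be 2-D, got shape {img.shape}")
    footprint = morphology.disk(params.rolling_ball_radius_px, decomposition="sequence")
    flat = morphology.white_tophat(img, footprint=footprint)
    peak = flat.max()
    if peak <= 0:
        return np.zeros_like(flat)
    flat /= peak
    out = exposure.equalize_adapthist(flat, clip_limit=params.clahe_clip)
    return out.astype(np.float64)


def _tissue_mask(wall_mask: np.ndarray, close_px: int) -> np.ndarray:
    closed = morphology.closing(wall_mask, morphology.disk(close_px))
    return ndi.binary_fill_holes(closed)


def segment_fibers(pretreated: np.ndarray, params: SegConfig | None = None,
                   scale_um_per_px: float = 1.0) -> FiberLabelMap:
    """Segment every fiber from the pretreated laminin channel.

    Walls come from a global Otsu threshold; fiber interiors are the
    connected components of the wall complement restricted to the tissue
    mask.  Touching interiors (wall gaps) are split by watershed seeded at
    the regional maxima of the interior distance transform (suppressed by
    ``marker_h_px`` to ignore rasterization bumps).  Components smaller than
    ``min_fiber_area_um2`` and fibers touching the image border are
    discarded; surviving labels are compacted to 1..n.
    """
    if params is None:
        params = SegConfig()
    img = np.asarray(pretreated, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("pretreated input must be 2-D")
    if not np.any(img > 0):
        raise NoTissueError("no tissue: image is empty after pretreatment")

    thr = filters.threshold_otsu(img)
    walls = img >= thr
    if not walls.any():
        raise NoTissueError("no tissue above threshold")

    section_mask = _tissue_mask(walls, params.section_close_px)
    interiors = section_mask & ~walls

    min_area_px = params.min_fiber_area_um2 / scale_um_per_px**2
    # noise speckles misclassified as wall inside a fiber are holes in the
    # interior mask (the true wall network connects to the section rim)
    interiors = morphology.remove_small_holes(interiors, max_size=max(2, int(min_area_px // 2)))
    interiors = morphology.remove_small_objects(interiors, max_size=max(1, int(min_area_px) - 1))
    if not interiors.any():
        raise NoTissueError("no tissue: no fiber interiors found")

    # Distance transform of a convex interior is concave, so each true fiber
    # contributes exactly one (possibly plateau) regional maximum; merged
    # dumbbell interiors contribute one per lobe.
    dist = ndi.distance_transform_edt(interiors)
    if params.marker_smooth_px > 0:
        dist = ndi.gaussian_filter(dist, params.marker_smooth_px)
    maxima = morphology.h_maxima(dist, params.marker_h_px)
    markers = cc_label(maxima)
    labels = skseg.watershed(-dist, markers, mask=interiors)

    # drop border-touching fibers (truncated CSA would bias the mean+3SD QC)
    # and components flush against the section exterior with no wall between
    # (slivers the closing step can create along the outer rim)
    outside_adjacent = morphology.dilation(
        ~section_mask, morphology.disk(1)
    )
    border_ids = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1],
        labels[outside_adjacent],
    ]))
    excluded: dict = {}
    for bid in border_ids[border_ids > 0]:
        labels[labels == bid] = 0
        excluded[int(bid)] = "border"

    # re-apply the area floor (and the failure ceiling) after watershed
    max_area_px = params.max_fiber_area_um2 / scale_um_per_px**2
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    for fid, cnt in zip(ids, counts):
        if cnt < min_area_px:
            labels[labels == fid] = 0
            excluded[int(fid)] = "below_min_area"
        elif cnt > max_area_px:
            labels[labels == fid] = 0
            excluded[int(fid)] = "above_max_area"

    labels = _compact(labels)
    return FiberLabelMap(
        labels=labels,
        section_mask=section_mask,
        scale_um_per_px=scale_um_per_px,
        wall_mask=walls & section_mask,
        excluded_ids=excluded,
    )


def _compact(labels: np.ndarray) -> np.ndarray:
    """Relabel surviving ids to consecutive 1..n, preserving order."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=labels.dtype)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


def qc_section(fiber_map: FiberLabelMap, artifact_tolerance: float) -> QcReport:
    """Whole-section QC: accepted iff 1 - fiber_area_ratio <= tolerance.

    The denominator is the tissue area that should become fibers, i.e. the
    section minus the basal-lamina walls themselves (walls are segmented
    structure, not analysis failures); the unsegmented fraction is tissue
    that ended up neither wall nor labeled fiber.
    """
    section_area = int(fiber_map.section_mask.sum())
    if section_area == 0:
        raise ValueError("zero section area")
    if fiber_map.wall_mask is not None:
        section_area -= int(fiber_map.wall_mask.sum())
    if section_area <= 0:
        raise ValueError("section is all wall")
    fiber_area = int((fiber_map.labels > 0).sum())
    ratio = min(fiber_area / section_area, 1.0)
    return QcReport(
        fiber_area_ratio=ratio,
        accepted=(1.0 - ratio) <= artifact_tolerance,
        artifact_tolerance=artifact_tolerance,
    )


def qc_fibers(fiber_map: FiberLabelMap, csa_um2: dict) -> FiberLabelMap:
    """Remove fibers with CSA above the section mean + 3 SD.

    Single, non-iterated pass with the sample standard deviation; removed
    ids are recorded with reason ``"csa_outlier"`` and the surviving labels
    compacted.  With fewer than two fibers the map is returned unchanged.
    """
    ids = fiber_map.fiber_ids()
    if len(ids) < 2:
        return fiber_map
    values = np.array([csa_um2[int(i)] for i in ids], dtype=np.float64)
    mean = values.mean()
    sd = values.std(ddof=1)
    cutoff = mean + 3.0 * sd
    labels = fiber_map.labels.copy()
    excluded = dict(fiber_map.excluded_ids)
    for fid, v in zip(ids, values):
        if v > cutoff:
            labels[labels == fid] = 0
            excluded[int(fid)] = "csa_outlier"
    n_removed = sum(1 for r in excluded.values() if r == "csa_outlier")
    return FiberLabelMap(
        labels=_compact(labels),
        section_mask=fiber_map.section_mask,
        scale_um_per_px=fiber_map.scale_um_per_px,
        wall_mask=fiber_map.wall_mask,
        excluded_ids=excluded,
    )
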