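"""Nucleus detection in the DAPI channel and centronucleation calling.

A fiber is centronucleated when at least one detected nucleus has its
centroid inside the fiber's central zone (``roi_cnf``); nuclei whose
centroid falls in the sub-laminal annulus (``roi_sc``) count as peripheral
myonuclei.  Centroid containment makes the two classes mutually exclusive.
Nuclei landing outside every fiber (on walls or interstitium) are reported
separately as interstitial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as skseg
from skimage.measure import label as cc_label


@dataclass
class BlobParams:
    """Shared blob-detection knobs (area bounds in um^2)."""

    min_area_um2: float = 10.0
    max_area_um2: float = 200.0
    tophat_radius_px: int = 25
    smooth_sigma_px: float = 1.0
    #: watershed marker suppression depth in distance-transform pixels
    marker_h_px: float = 1.0
    #: reject thresholds that sit within this many robust sigmas of the
    #: background mode (guards against segmenting pure noise)
    noise_guard_sigmas: float = 2.0


@dataclass
class DetectedObject:
    object_id: int
    mask: np.ndarray  # crop
    origin: tuple  # (row0, col0) of the crop
    area_um2: float
    centroid_xy_um: tuple  # (row_um, col_um)
    mean_intensity: float
    channel_role: str

    @property
    def centroid_px(self) -> tuple:
        s = self._scale
        return self.centroid_xy_um[0] / s, self.centroid_xy_um[1] / s

    _scale: float = field(default=1.0, repr=False)


@dataclass
class CnfResult:
    fiber_id: int
    n_centronuclei: int
    n_peripheral: int

    @property
    def is_cnf(self) -> bool:
        return self.n_centronuclei >= 1


def detect_blobs(
    channel: np.ndarray,
    role: str,
    scale_um_per_px: float,
    params: BlobParams | None = None,
) -> list:
    """Generic blob pipeline: background subtraction, automatic threshold,
    distance-transform watershed to split touching blobs, area filter.

    Returns a list of :class:`DetectedObject`; an empty list is a valid
    result (blank channel).
    """
    if params is None:
        params = BlobParams()
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("channel must be 2-D")
    if img.max() == img.min():
        return []

    if params.smooth_sigma_px > 0:
        img = ndi.gaussian_filter(img, params.smooth_sigma_px)
    footprint = morphology.disk(params.tophat_radius_px, decomposition="sequence")
    flat = morphology.white_tophat(img, footprint=footprint)
    if flat.max() <= 0:
        return []
    thr = filters.threshold_otsu(flat)

    # noise guard: on a signal-free channel Otsu just splits the noise
    med = np.median(flat)
    sigma = 1.4826 * np.median(np.abs(flat - med))
    if sigma > 0 and thr < med + params.noise_guard_sigmas * sigma:
        return []

    fg = flat >= thr
    if not fg.any():
        return []

    min_px = params.min_area_um2 / scale_um_per_px**2
    max_px = params.max_area_um2 / scale_um_per_px**2
    fg = morphology.remove_small_objects(fg, max_size=max(1, int(round(min_px))) - 1)
    if not fg.any():
        return []

    dist = ndi.distance_transform_edt(fg)
    markers = cc_label(morphology.h_maxima(dist, params.marker_h_px))
    labels = skseg.watershed(-dist, markers, mask=fg)

    raw = np.asarray(channel, dtype=np.float64)
    out: list = []
    oid = 0
    slices = ndi.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        crop = labels[sl] == lab
        n_px = int(crop.sum())
        if not (min_px <= n_px <= max_px):
            continue
        rows, cols = np.nonzero(crop)
        r0, c0 = sl[0].start, sl[1].start
        oid += 1
        s = scale_um_per_px
        obj = DetectedObject(
            object_id=oid,
            mask=crop,
            origin=(r0, c0),
            area_um2=n_px * s * s,
            centroid_xy_um=((rows.mean() + r0) * s, (cols.mean() + c0) * s),
            mean_intensity=float(raw[sl][crop].mean()),
            channel_role=role,
        )
        obj._scale = s
        out.append(obj)
    return out


def detect_nuclei(
    dapi: np.ndarray,
    scale_um_per_px: float,
    params: BlobParams | None = None,
) -> list:
    """Detect nuclei in the DAPI channel (area bounds default 10-200 um^2)."""
    return detect_blobs(dapi, "dapi", scale_um_per_px, params or BlobParams())


def nuclei_mask(nuclei: list, shape: tuple) -> np.ndarray:
    """Union binary mask of detected nuclei (used for the satellite overlap rule)."""
    out = np.zeros(shape, dtype=bool)
    for obj in nuclei:
        r0, c0 = obj.origin
        h, w = obj.mask.shape
        out[r0 : r0 + h, c0 : c0 + w] |= obj.mask
    return out


def classify_cnf(nuclei: list, roisets: dict, region_images: dict) -> tuple:
    """Assign each nucleus by centroid containment and tally per fiber.

    ``region_images`` are the whole-section ``cnf``/``sc`` fiber-id images
    from :func:`musclehca.morphometry.region_label_images` (conflict-free
    because both regions are subsets of disjoint fibers).

    Returns ``(results, n_interstitial)`` where ``results`` maps fiber id to
    :class:`CnfResult`; every surviving fiber gets a row even with zero
    counts.  ``n_interstitial`` counts nuclei whose centroid lies in no
    fiber.
    """
    results = {fid: CnfResult(fiber_id=fid, n_centronuclei=0, n_peripheral=0)
               for fid in roisets}
    cnf_img = region_images["cnf"]
    sc_img = region_images["sc"]
    shape = cnf_img.shape
    n_interstitial = 0
    for obj in nuclei:
        r, c = obj.centroid_px
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < shape[0] and 0 <= ci < shape[1]):
            n_interstitial += 1
            continue
        fid = int(cnf_img[ri, ci])
        if fid > 0:
            results[fid].n_centronuclei += 1
            continue
        fid = int(sc_img[ri, ci])
        if fid > 0:
            results[fid].n_peripheral += 1
        else:
            n_interstitial += 1
    return results, n_interstitial


def cnf_distribution(results) -> dict:
    """Percentage of fibers with 0, 1, 2 and >=3 centronuclei.

    Accepts a dict or list of :class:`CnfResult`; bins sum to 100.
    """
    vals = list(results.values()) if isinstance(results, dict) else list(results)
    if not vals:
        raise ValueError("no fibers to tally")
    counts = np.array([r.n_centronuclei for r in vals])
    n = len(counts)
    bins = {
        "0": int((counts == 0).sum()),
        "1": int((counts == 1).sum()),
        "2": int((counts == 2).sum()),
        ">=3": int((counts >= 3).sum()),
    }
    return {k: 100.0 * v / n for k, v in bins.items()}
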