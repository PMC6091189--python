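"""Synthetic calibrated muscle sections with complete per-fiber ground truth.

Fiber geometry comes from a centroidally relaxed random tessellation clipped
to an elliptical "section": seed points inside the ellipse, every tissue
pixel assigned to its nearest seed, a few Lloyd iterations to even out cell
sizes.  Walls (the basal-lamina signal) are the rasterized boundaries
between cells; nuclei, Pax7 and CD31 blobs are discs planted at positions
that respect their biological geometry (central nuclei deep inside the
fiber, peripheral nuclei and satellites just under the wall, vessels on the
wall), and typing channels are filled per true label.  All randomness flows
through one seeded generator, so the same parameters and seed reproduce
pixel-identical images and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from musclehca.image_io import CalibratedSection
from musclehca.morphometry import feret_diameters

#: pure-type label -> set of positive stain roles (hybrids/ND derived)
_LABEL_POSITIVES = {
    "I": {"stain1"},
    "IIA": {"stain2"},
    "IIB": {"stain3"},
    "IIX": set(),
    "I-IIA": {"stain1", "stain2"},
    "I-IIB": {"stain1", "stain3"},
    "IIA-IIB": {"stain2", "stain3"},
    "ND": {"stain1", "stain2", "stain3"},
}


@dataclass
class SynthParams:
    n_fibers: int = 150
    mean_csa_um2: float = 900.0
    csa_cv: float = 0.25  # loosely honored; Lloyd relaxation sets the floor
    cnf_fraction: float = 0.0
    #: distribution of centronuclei counts for CNF-designated fibers
    centronuclei_dist: dict = field(default_factory=lambda: {1: 1.0})
    peripheral_per_fiber: int = 4
    satellites_per_fiber_dist: dict = field(default_factory=lambda: {0: 1.0})
    vessels_per_fiber_dist: dict = field(default_factory=lambda: {0: 1.0})
    type_mix: dict | None = None
    noise_sigma: float = 4.0
    blur_sigma: float = 0.6
    scale_um_per_px: float = 1.0
    wall_um: float = 2.0
    channels: tuple = ("laminin", "dapi")
    margin_px: int = 20
    lloyd_iters: int = 3
    nucleus_radius_um: float = 3.1
    pax7_radius_um: float = 2.0
    vessel_radius_um: float = 1.8
    wall_intensity: float = 180.0
    tissue_intensity: float = 35.0
    outside_intensity: float = 12.0


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic section."""

    params: SynthParams
    seed: int
    label_image: np.ndarray  # truth fiber interiors, 0 = wall/background
    section_mask: np.ndarray
    fibers: pd.DataFrame  # one row per planted fiber
    objects: pd.DataFrame  # one row per planted nucleus/pax7/cd31 blob

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)


def _sample_counts(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    keys = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[int(k)] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=n, p=probs)


def _ellipse_geometry(params: SynthParams) -> tuple:
    """Image shape and ellipse axes sized so mean interior CSA hits target."""
    s = params.scale_um_per_px
    w_px = params.wall_um / s
    mean_px = params.mean_csa_um2 / s**2
    # hexagonal cell of area A loses a half-wall ring: interior = A - P*w/2,
    # P ~= 3.72 sqrt(A); solve A - 1.86 w sqrt(A) - interior = 0 for sqrt(A)
    b_coef = 1.86 * w_px
    sqrt_a = (b_coef + np.sqrt(b_coef**2 + 4 * mean_px)) / 2
    cell_px = sqrt_a**2
    total = params.n_fibers * cell_px
    aspect = 1.3
    a = np.sqrt(total * aspect / np.pi)
    b = a / aspect
    h = int(np.ceil(2 * b)) + 2 * params.margin_px
    w = int(np.ceil(2 * a)) + 2 * params.margin_px
    return (h, w), a, b


def _tessellate(rng: np.random.Generator, params: SynthParams):
    shape, a, b = _ellipse_geometry(params)
    cr, cc = shape[0] / 2, shape[1] / 2
    rr, cc_grid = np.mgrid[0 : shape[0], 0 : shape[1]]
    ellipse = ((rr - cr) / b) ** 2 + ((cc_grid - cc) / a) ** 2 <= 1.0
    tissue_pts = np.stack(np.nonzero(ellipse), axis=1).astype(np.float64)

    # rejection-sample seeds inside the ellipse
    seeds = []
    while len(seeds) < params.n_fibers:
        r = rng.uniform(cr - b, cr + b)
        c = rng.uniform(cc - a, cc + a)
        if ((r - cr) / b) ** 2 + ((c - cc) / a) ** 2 <= 0.97:
            seeds.append((r, c))
    seeds = np.array(seeds)

    for _ in range(params.lloyd_iters):
        _, owner = cKDTree(seeds).query(tissue_pts, k=1)
        sums_r = np.bincount(owner, weights=tissue_pts[:, 0], minlength=len(seeds))
        sums_c = np.bincount(owner, weights=tissue_pts[:, 1], minlength=len(seeds))
        counts = np.bincount(owner, minlength=len(seeds))
        nz = counts > 0
        seeds[nz, 0] = sums_r[nz] / counts[nz]
        seeds[nz, 1] = sums_c[nz] / counts[nz]

    _, owner = cKDTree(seeds).query(tissue_pts, k=1)
    cells = np.zeros(shape, dtype=np.int32)
    cells[tuple(tissue_pts.astype(int).T)] = owner + 1
    return cells, ellipse


def _wall_mask(cells: np.ndarray, wall_px: float) -> np.ndarray:
    """Pixels within wall_px/2 of an inter-cell or outer boundary."""
    mx = ndi.maximum_filter(cells, size=3)
    mn = ndi.minimum_filter(cells, size=3)
    edge = (mx != mn) & (cells > 0)
    half = max(wall_px / 2.0 - 1.0, 0.0)
    if half > 0:
        edge = ndi.distance_transform_edt(~edge) <= half
    return edge


def _draw_disc(canvas: np.ndarray, r: float, c: float, radius: float, value: float) -> None:
    r0 = max(int(np.floor(r - radius - 1)), 0)
    r1 = min(int(np.ceil(r + radius + 2)), canvas.shape[0])
    c0 = max(int(np.floor(c - radius - 1)), 0)
    c1 = min(int(np.ceil(c + radius + 2)), canvas.shape[1])
    if r1 <= r0 or c1 <= c0:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    disc = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
    region = canvas[r0:r1, c0:c1]
    region[disc] = np.maximum(region[disc], value)


def _ring_positions(rng, interior: np.ndarray, origin, centroid, k: int,
                    depth_range=(2.0, 3.5)) -> list:
    """k positions just inside the interior boundary, spread in angle."""
    if k <= 0:
        return []
    # pad so depth is measured to the true boundary even at the bbox edge
    dist = ndi.distance_transform_edt(np.pad(interior, 1))[1:-1, 1:-1]
    ring = (dist >= 1.0) & (dist <= depth_range[1])
    pts = np.stack(np.nonzero(ring), axis=1).astype(np.float64)
    if len(pts) == 0:
        return []
    ang = np.arctan2(pts[:, 0] - (centroid[0] - origin[0]),
                     pts[:, 1] - (centroid[1] - origin[1]))
    order = np.argsort(ang)
    offset = rng.integers(0, len(order))
    picks = [order[(offset + int(i * len(order) / k)) % len(order)] for i in range(k)]
    out = []
    for p in picks:
        rr, cc = pts[p]
        out.append((rr + origin[0], cc + origin[1]))
    return out


def _central_positions(rng, interior: np.ndarray, origin, r_cnf_px: float,
                       k: int, spacing: float) -> list:
    """k positions deep inside the fiber (distance > r_cnf_px + 2 from wall)."""
    if k <= 0:
        return []
    dist = ndi.distance_transform_edt(np.pad(interior, 1))[1:-1, 1:-1]
    deep = dist > (r_cnf_px + 5.0)
    if not deep.any():
        deep = dist == dist.max()
    pts = np.stack(np.nonzero(deep), axis=1).astype(np.float64)
    order = rng.permutation(len(pts))
    # greedy with a hard spacing floor; planting fewer than requested is
    # preferred over planting nuclei the detector cannot separate (the
    # recorded truth reflects what was actually placed)
    chosen: list = []
    for idx in order:
        p = pts[idx]
        if all(np.hypot(*(p - q)) >= spacing for q in chosen):
            chosen.append(p)
        if len(chosen) == k:
            break
    return [(p[0] + origin[0], p[1] + origin[1]) for p in chosen]


def generate_section(params: SynthParams | None = None, seed: int = 0,
                     **overrides) -> tuple:
    """Generate one calibrated synthetic section and its ground truth.

    Returns ``(CalibratedSection, SyntheticTruth)``.  Keyword overrides are
    applied on top of ``params`` (or the defaults).
    """
    params = replace(params or SynthParams(), **overrides)
    if params.nucleus_radius_um**2 * np.pi >= params.mean_csa_um2:
        raise ValueError("infeasible: nuclei larger than fibers")
    for role in params.channels:
        if role not in ("laminin", "dapi", "pax7", "cd31", "stain1", "stain2", "stain3"):
            raise ValueError(f"unknown channel role {role!r}")
    if "laminin" not in params.channels:
        raise ValueError("laminin channel is required")

    rng = np.random.default_rng(seed)
    s = params.scale_um_per_px
    cells, ellipse = _tessellate(rng, params)
    wall = _wall_mask(cells, params.wall_um / s)
    interiors = np.where(wall, 0, cells)

    # fiber bookkeeping
    slices = ndi.find_objects(interiors)
    fiber_rows = []
    geo = {}
    for fid in range(1, int(cells.max()) + 1):
        sl = slices[fid - 1] if fid - 1 < len(slices) else None
        if sl is None:
            continue
        crop = interiors[sl] == fid
        area_px = int(crop.sum())
        if area_px * s * s < 50.0:
            interiors[interiors == fid] = 0
            continue
        rows, cols = np.nonzero(crop)
        origin = (sl[0].start, sl[1].start)
        centroid = (rows.mean() + origin[0], cols.mean() + origin[1])
        dmin_px, dmax_px = feret_diameters(crop)
        geo[fid] = {"crop": crop, "origin": origin, "centroid": centroid,
                    "min_feret_px": dmin_px}
        fiber_rows.append({
            "fiber_id": fid,
            "centroid_r_px": centroid[0],
            "centroid_c_px": centroid[1],
            "area_px": area_px,
            "csa_um2": area_px * s * s,
            "min_feret_um": dmin_px * s,
            "max_feret_um": dmax_px * s,
        })
    fibers = pd.DataFrame(fiber_rows).set_index("fiber_id", drop=False)
    fids = list(fibers.fiber_id)

    # --- plant objects -------------------------------------------------
    want_dapi = "dapi" in params.channels
    want_pax7 = "pax7" in params.channels
    want_cd31 = "cd31" in params.channels
    stains = [c for c in params.channels if c.startswith("stain")]

    n = len(fids)
    is_cnf = np.zeros(n, dtype=bool)
    if params.cnf_fraction > 0:
        k = int(round(params.cnf_fraction * n))
        is_cnf[rng.choice(n, size=k, replace=False)] = True
    central_counts = np.where(
        is_cnf, _sample_counts(rng, params.centronuclei_dist, n), 0
    )
    sat_counts = (_sample_counts(rng, params.satellites_per_fiber_dist, n)
                  if want_pax7 else np.zeros(n, dtype=int))
    vessel_counts = (_sample_counts(rng, params.vessels_per_fiber_dist, n)
                     if want_cd31 else np.zeros(n, dtype=int))

    type_labels = ["IIX"] * n
    if params.type_mix:
        labels = sorted(params.type_mix)
        probs = np.array([params.type_mix[l] for l in labels], dtype=float)
        probs /= probs.sum()
        type_labels = list(rng.choice(labels, size=n, p=probs))

    obj_rows = []
    peripheral_counts = np.zeros(n, dtype=int)
    r_nuc = params.nucleus_radius_um / s
    vessel_positions: list = []  # global, to keep planted vessels separable
    vessel_min_gap = 2 * params.vessel_radius_um / s + 1.5
    for i, fid in enumerate(fids):
        g = geo[fid]
        r_cnf_px = g["min_feret_px"] / 5.0
        n_central = int(central_counts[i])
        centrals = _central_positions(
            rng, g["crop"], g["origin"], r_cnf_px, n_central, spacing=2.8 * r_nuc
        ) if want_dapi else []
        n_central = len(centrals)
        central_counts[i] = n_central
        peripherals = _ring_positions(
            rng, g["crop"], g["origin"], g["centroid"], params.peripheral_per_fiber
        ) if want_dapi else []
        peripheral_counts[i] = len(peripherals)
        for rr, cc in centrals:
            obj_rows.append({"kind": "nucleus_central", "fiber_id": fid,
                             "r_px": rr, "c_px": cc, "radius_px": r_nuc})
        for rr, cc in peripherals:
            obj_rows.append({"kind": "nucleus_peripheral", "fiber_id": fid,
                             "r_px": rr, "c_px": cc, "radius_px": r_nuc})
        # satellites sit on a subset of the peripheral nuclei
        k_sat = min(int(sat_counts[i]), len(peripherals)) if want_pax7 else 0
        sat_counts[i] = k_sat
        for rr, cc in peripherals[:k_sat]:
            obj_rows.append({"kind": "pax7", "fiber_id": fid, "r_px": rr,
                             "c_px": cc, "radius_px": params.pax7_radius_um / s})
        # vessels pushed just outside the interior boundary, onto the wall
        if want_cd31 and vessel_counts[i] > 0:
            boundary = _ring_positions(
                rng, g["crop"], g["origin"], g["centroid"], int(vessel_counts[i]),
                depth_range=(1.0, 1.8),
            )
            placed = 0
            for rr, cc in boundary:
                dr = rr - g["centroid"][0]
                dc = cc - g["centroid"][1]
                norm = np.hypot(dr, dc)
                if norm == 0:
                    continue
                rr_o = rr + 2.6 * dr / norm
                cc_o = cc + 2.6 * dc / norm
                ri, ci = int(round(rr_o)), int(round(cc_o))
                if not (0 <= ri < cells.shape[0] and 0 <= ci < cells.shape[1]):
                    continue
                if interiors[ri, ci] != 0:  # must not land inside any fiber
                    continue
                if vessel_positions:
                    arr = np.array(vessel_positions)
                    if np.hypot(arr[:, 0] - rr_o, arr[:, 1] - cc_o).min() < vessel_min_gap:
                        continue
                vessel_positions.append((rr_o, cc_o))
                obj_rows.append({"kind": "cd31", "fiber_id": fid, "r_px": rr_o,
                                 "c_px": cc_o, "radius_px": params.vessel_radius_um / s})
                placed += 1
            vessel_counts[i] = placed

    objects = pd.DataFrame(
        obj_rows, columns=["kind", "fiber_id", "r_px", "c_px", "radius_px"]
    )

    fibers["n_central"] = central_counts
    fibers["n_peripheral"] = peripheral_counts
    fibers["n_satellites"] = sat_counts
    fibers["n_vessels"] = vessel_counts
    fibers["type_label"] = type_labels

    # --- render channels ----------------------------------------------
    shape = cells.shape
    chans: dict = {}

    lam = np.full(shape, params.outside_intensity, dtype=np.float64)
    lam[ellipse] = params.tissue_intensity
    lam[wall] = params.wall_intensity
    chans["laminin"] = lam

    if want_dapi:
        dapi = np.full(shape, 10.0)
        for row in obj_rows:
            if row["kind"].startswith("nucleus"):
                _draw_disc(dapi, row["r_px"], row["c_px"], row["radius_px"], 200.0)
        chans["dapi"] = dapi
    if want_pax7:
        pax = np.full(shape, 10.0)
        for row in obj_rows:
            if row["kind"] == "pax7":
                _draw_disc(pax, row["r_px"], row["c_px"], row["radius_px"], 200.0)
        chans["pax7"] = pax
    if want_cd31:
        cd = np.full(shape, 10.0)
        for row in obj_rows:
            if row["kind"] == "cd31":
                _draw_disc(cd, row["r_px"], row["c_px"], row["radius_px"], 200.0)
        chans["cd31"] = cd
    for stain in stains:
        ch = np.full(shape, 100.0)
        for i, fid in enumerate(fids):
            if stain in _LABEL_POSITIVES.get(type_labels[i], set()):
                g = geo[fid]
                r0, c0 = g["origin"]
                h, w = g["crop"].shape
                view = ch[r0 : r0 + h, c0 : c0 + w]
                view[g["crop"]] = 100.0 + 8.0 * max(params.noise_sigma, 1.0)
        chans[stain] = ch

    for role, ch in chans.items():
        if params.blur_sigma > 0:
            ch = ndi.gaussian_filter(ch, params.blur_sigma)
        if params.noise_sigma > 0:
            ch = ch + rng.normal(0.0, params.noise_sigma, size=shape)
        chans[role] = np.clip(ch, 0, 65535).astype(np.uint16)

    section = CalibratedSection(
        pixels={r: chans[r] for r in params.channels},
        scale_um_per_px=s,
        channel_roles={r: i for i, r in enumerate(params.channels)},
        source_path=f"synthetic(seed={seed})",
    )
    truth = SyntheticTruth(
        params=params,
        seed=seed,
        label_image=interiors,
        section_mask=ellipse,
        fibers=fibers,
        objects=objects,
    )
    return section, truth


def degrade(section: CalibratedSection, truth: SyntheticTruth, mode: str,
            severity: float, seed: int = 0) -> tuple:
    """Controlled corruption for QC tests; returns (section, expected_unsegmentable).

    * ``broken_walls`` — a bright stain blot obliterates wall structure over
      ``severity`` fraction of the tissue area, making it unsegmentable;
    * ``uneven_illumination`` — multiplies the laminin channel by a smooth
      left-to-right gradient of amplitude ``severity``;
    * ``debris`` — plants bright off-tissue blobs on the laminin channel
      (fiber truth unchanged).

    ``severity`` 0 is the identity for every mode.
    """
    if mode not in ("broken_walls", "uneven_illumination", "debris"):
        raise ValueError(f"unknown degrade mode {mode!r}")
    if severity < 0:
        raise ValueError("severity must be >= 0")
    pixels = {r: a.copy() for r, a in section.pixels.items()}
    expected_unseg = 0.0
    if severity > 0:
        rng = np.random.default_rng(seed)
        lam = pixels["laminin"].astype(np.float64)
        if mode == "broken_walls":
            tissue = truth.section_mask
            area = tissue.sum()
            radius = np.sqrt(severity * area / np.pi)
            rows, cols = np.nonzero(tissue)
            # center the blot well inside the tissue so it stays fully covered
            dist = ndi.distance_transform_edt(tissue)
            deep = dist >= min(radius, dist.max() * 0.9)
            drows, dcols = np.nonzero(deep)
            k = rng.integers(0, len(drows))
            yy, xx = np.mgrid[0 : lam.shape[0], 0 : lam.shape[1]]
            blot = ((yy - drows[k]) ** 2 + (xx - dcols[k]) ** 2 <= radius**2) & tissue
            # walls vanish: the blot flattens to interior-level signal
            interior_level = float(np.median(lam[tissue]))
            lam[blot] = interior_level + rng.normal(0.0, 1.0, size=int(blot.sum()))
            # fibers touching the blot lose part of their wall and merge into
            # it, so the whole fiber becomes unsegmentable
            touched = np.unique(truth.label_image[blot])
            touched = touched[touched > 0]
            unseg = blot | np.isin(truth.label_image, touched)
            # expected fraction on the section-QC scale, whose denominator
            # excludes surviving (bright) wall pixels
            wall_truth = tissue & (truth.label_image == 0)
            denom = tissue.sum() - (wall_truth & ~unseg).sum()
            expected_unseg = unseg.sum() / denom
        elif mode == "uneven_illumination":
            ramp = 1.0 + severity * (
                np.linspace(-0.5, 0.5, lam.shape[1])[None, :]
            )
            lam = lam * ramp
        else:  # debris
            outside = ~truth.section_mask
            drows, dcols = np.nonzero(outside)
            n_blobs = max(1, int(round(severity * 10)))
            for _ in range(n_blobs):
                k = rng.integers(0, len(drows))
                _draw_disc(lam, float(drows[k]), float(dcols[k]),
                           8.0, float(lam.max()))
        pixels["laminin"] = np.clip(lam, 0, 65535).astype(section.pixels["laminin"].dtype)
    out = CalibratedSection(
        pixels=pixels,
        scale_um_per_px=section.scale_um_per_px,
        channel_roles=dict(section.channel_roles),
        source_path=section.source_path + f"+{mode}({severity})",
    )
    return out, expected_unseg
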