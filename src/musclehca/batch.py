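"""Batch orchestration: run the full pipeline over a folder of images.

A run creates exactly four subfolders in the output directory —
``Artefacts`` (images rejected by the section QC, plus quarantined
failures), ``Cartography`` (JPEG + PNG renderings), ``Results by file``
(one tab-delimited per-fiber table per image, plus per-object CSVs) and
``ROI`` (zipped per-fiber ROI archives) — together with a
``RunGlobalResult_<run id>.txt`` summary table (one row per image) and a
``RunLog_<run id>.txt`` recording every configuration value and the
per-channel typing thresholds.
"""

from __future__ import annotations

import dataclasses
import shutil
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from musclehca import cartography as carto
from musclehca import segmentation as seg
from musclehca.cells import (
    call_satellites,
    detect_marker_objects,
    quantify_vessels,
)
from musclehca.fibertype import (
    DEFAULT_SNR_FACTOR,
    DEFAULT_TYPE_MAP,
    call_types,
    compute_threshold,
    type_distribution,
)
from musclehca.image_io import CalibratedSection, max_project, read_section
from musclehca.morphometry import (
    CNF_FRACTION,
    V_FRACTION,
    measure_section,
    region_label_images,
)
from musclehca.nuclei import (
    classify_cnf,
    cnf_distribution,
    detect_nuclei,
    nuclei_mask,
)
from musclehca.roi_export import write_roi_archive

FEATURES = ("morphometry", "cnf", "satellites", "vessels", "typing")
FOLDERS = ("Artefacts", "Cartography", "Results by file", "ROI")


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    channel_map: dict
    scale_um_per_px: float | None = None  # None -> from TIFF metadata
    zstack: bool = False
    features: tuple = ("morphometry",)
    cartographies: tuple = ()
    artifact_tolerance: float = 0.10
    seg: seg.SegConfig = field(default_factory=seg.SegConfig)
    cnf_fraction: float = CNF_FRACTION
    v_fraction: float = V_FRACTION
    snr_factor: float = DEFAULT_SNR_FACTOR
    overlap_threshold: float = 0.90
    type_map: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MAP))
    legend: bool = True
    run_id: str | None = None  # None -> timestamp
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        bad_carto = set(self.cartographies) - set(carto.KINDS)
        if bad_carto:
            raise ValueError(f"unknown cartographies: {sorted(bad_carto)}")
        roles = set(self.channel_map)
        if "laminin" not in roles:
            raise ValueError("laminin channel is always required")
        if ("cnf" in self.features or "satellites" in self.features) and "dapi" not in roles:
            raise ValueError("dapi channel required for cnf/satellite analysis")
        if "satellites" in self.features and "pax7" not in roles:
            raise ValueError("pax7 channel required for satellite analysis")
        if "vessels" in self.features and "cd31" not in roles:
            raise ValueError("cd31 channel required for vessel analysis")
        if "typing" in self.features and not any(r.startswith("stain") for r in roles):
            raise ValueError("at least one typing channel required for typing")


@dataclass
class SectionSummary:
    """One aggregate row per processed image (None = feature not requested)."""

    image: str
    accepted: bool
    qc_ratio: float
    n_fibers: int = 0
    csa_mean_um2: float | None = None
    csa_median_um2: float | None = None
    n_csa_outliers: int = 0
    pct_cnf: float | None = None
    cnf_dist: dict | None = None
    peripheral_per_fiber_mean: float | None = None
    satellites_per_mm2: float | None = None
    vessels_per_mm2: float | None = None
    vessel_pct_area: float | None = None
    type_pcts: dict | None = None
    thresholds: dict | None = None
    error: str | None = None


def _read_image(path: Path, cfg: RunConfig) -> CalibratedSection:
    if cfg.zstack:
        arr = tifffile.imread(path)
        if arr.ndim == 4:  # (Z, C, H, W): project before binding roles
            n_ch = arr.shape[1]
            slices = []
            for z in range(arr.shape[0]):
                pixels = {r: arr[z, int(i)] for r, i in cfg.channel_map.items()
                          if int(i) < n_ch}
                slices.append(CalibratedSection(
                    pixels=pixels,
                    scale_um_per_px=cfg.scale_um_per_px or 1.0,
                    channel_roles=dict(cfg.channel_map),
                    source_path=str(path),
                ))
            return max_project(slices)
    return read_section(path, cfg.channel_map,
                        scale=cfg.scale_um_per_px or "from metadata")


def _analyze_image(section: CalibratedSection, cfg: RunConfig, name: str):
    """Full single-image pipeline; returns (summary, fiber_table, objects,
    roisets, fiber_map, cartography values)."""
    scale = section.scale_um_per_px
    pre = seg.pretreat(section.channel("laminin"), cfg.seg)
    fiber_map = seg.segment_fibers(pre, cfg.seg, scale_um_per_px=scale)
    qc = seg.qc_section(fiber_map, cfg.artifact_tolerance)
    if not qc.accepted:
        return SectionSummary(image=name, accepted=False,
                              qc_ratio=qc.fiber_area_ratio), None, None, None, fiber_map, {}

    # per-fiber CSA outlier pass (mean + 3 SD) before full morphometry
    ids, counts = np.unique(fiber_map.labels[fiber_map.labels > 0],
                            return_counts=True)
    csa = {int(i): float(c) * scale * scale for i, c in zip(ids, counts)}
    qc.csa_mean_um2 = float(np.mean(list(csa.values()))) if csa else float("nan")
    qc.csa_sd_um2 = float(np.std(list(csa.values()))) if csa else float("nan")
    fiber_map = seg.qc_fibers(fiber_map, csa)
    qc.n_removed_outliers = sum(
        1 for r in fiber_map.excluded_ids.values() if r == "csa_outlier"
    )

    morphs, roisets = measure_section(fiber_map, cfg.cnf_fraction, cfg.v_fraction)
    region_imgs = region_label_images(roisets, fiber_map.labels.shape)

    rows = {
        fid: {
            "Fiber": fid,
            "CSA": m.csa_um2,
            "MinFeret": m.min_feret_um,
            "MaxFeret": m.max_feret_um,
            "Circularity": m.circularity,
            "GC_X": m.gc_xy_um[1],
            "GC_Y": m.gc_xy_um[0],
        }
        for fid, m in morphs.items()
    }
    summary = SectionSummary(
        image=name,
        accepted=True,
        qc_ratio=qc.fiber_area_ratio,
        n_fibers=len(morphs),
        csa_mean_um2=float(np.mean([m.csa_um2 for m in morphs.values()])) if morphs else None,
        csa_median_um2=float(np.median([m.csa_um2 for m in morphs.values()])) if morphs else None,
        n_csa_outliers=qc.n_removed_outliers,
    )
    carto_values: dict = {"csa": {f: m.csa_um2 for f, m in morphs.items()}}
    object_rows: list = []

    nuclei = None
    if "cnf" in cfg.features or "satellites" in cfg.features:
        nuclei = detect_nuclei(section.channel("dapi"), scale)

    if "cnf" in cfg.features:
        results, _ = classify_cnf(nuclei, roisets, region_imgs)
        for fid, r in results.items():
            rows[fid]["NbCentroNuclei"] = r.n_centronuclei
            rows[fid]["NbPeripheralNuclei"] = r.n_peripheral
            rows[fid]["IsCNF"] = int(r.is_cnf)
        n = len(results)
        summary.pct_cnf = 100.0 * sum(r.is_cnf for r in results.values()) / n if n else None
        summary.cnf_dist = cnf_distribution(results) if n else None
        summary.peripheral_per_fiber_mean = (
            float(np.mean([r.n_peripheral for r in results.values()])) if n else None
        )
        carto_values["centronuclei"] = {f: r.n_centronuclei for f, r in results.items()}

    section_mm2 = float(fiber_map.section_mask.sum()) * scale * scale / 1e6

    if "satellites" in cfg.features:
        pax7 = detect_marker_objects(section.channel("pax7"), "pax7", scale)
        nmask = nuclei_mask(nuclei, fiber_map.labels.shape)
        calls = call_satellites(pax7, nmask, roisets, region_imgs,
                                cfg.overlap_threshold)
        per_fiber = {fid: 0 for fid in roisets}
        for c in calls:
            if c.accepted:
                per_fiber[c.fiber_id] += 1
        for fid in rows:
            rows[fid]["NbSatellites"] = per_fiber.get(fid, 0)
        summary.satellites_per_mm2 = sum(c.accepted for c in calls) / section_mm2
        carto_values["satellites"] = per_fiber
        by_id = {o.object_id: o for o in pax7}
        for c in calls:
            o = by_id[c.object_id]
            object_rows.append({
                "ObjectId": o.object_id, "Role": "pax7",
                "Area_um2": o.area_um2, "MeanIntensity": o.mean_intensity,
                "GC_X": o.centroid_xy_um[1], "GC_Y": o.centroid_xy_um[0],
                "FiberId": c.fiber_id if c.fiber_id is not None else "",
                "Accepted": int(c.accepted),
            })

    if "vessels" in cfg.features:
        cd31 = detect_marker_objects(section.channel("cd31"), "cd31", scale)
        vm = quantify_vessels(cd31, roisets, fiber_map.section_mask, scale)
        for fid in rows:
            rows[fid]["NbVessels"] = vm.per_fiber_counts.get(fid, 0)
        summary.vessels_per_mm2 = vm.density_per_mm2
        summary.vessel_pct_area = vm.pct_area
        carto_values["vessels"] = vm.per_fiber_counts
        for o in cd31:
            object_rows.append({
                "ObjectId": o.object_id, "Role": "cd31",
                "Area_um2": o.area_um2, "MeanIntensity": o.mean_intensity,
                "GC_X": o.centroid_xy_um[1], "GC_Y": o.centroid_xy_um[0],
                "FiberId": "", "Accepted": 1,
            })

    if "typing" in cfg.features:
        stains = sorted(r for r in section.pixels if r.startswith("stain"))
        thresholds = {
            r: compute_threshold(section.channel(r), fiber_map.section_mask,
                                 fiber_map.labels, cfg.snr_factor, role=r)
            for r in stains
        }
        calls = call_types({r: section.channel(r) for r in stains},
                           thresholds, roisets, cfg.type_map)
        for fid, c in calls.items():
            rows[fid]["Type"] = c.label
            for r in stains:
                rows[fid][f"MeanIntensity_{r}"] = c.mean_intensities[r]
        summary.type_pcts = type_distribution(calls) if calls else None
        summary.thresholds = {r: t.threshold for r, t in thresholds.items()}
        carto_values["fibertype"] = {f: c.label for f, c in calls.items()}

    fiber_table = pd.DataFrame([rows[f] for f in sorted(rows)])
    objects = pd.DataFrame(object_rows) if object_rows else None
    return summary, fiber_table, objects, roisets, fiber_map, carto_values


def _summary_frame(summaries: list, cfg: RunConfig) -> pd.DataFrame:
    recs = []
    for s in summaries:
        rec = {
            "Image": s.image,
            "Accepted": int(s.accepted),
            "QcRatio": round(s.qc_ratio, 6),
            "NbFibers": s.n_fibers,
        }
        if "morphometry" in cfg.features or True:
            rec["MeanCSA"] = s.csa_mean_um2
            rec["MedianCSA"] = s.csa_median_um2
            rec["NbCsaOutliersRemoved"] = s.n_csa_outliers
        if "cnf" in cfg.features:
            rec["PctCNF"] = s.pct_cnf
            for k in ("0", "1", "2", ">=3"):
                rec[f"PctCentro_{k}"] = (s.cnf_dist or {}).get(k)
            rec["MeanPeripheralNuclei"] = s.peripheral_per_fiber_mean
        if "satellites" in cfg.features:
            rec["SatellitesPerMm2"] = s.satellites_per_mm2
        if "vessels" in cfg.features:
            rec["VesselsPerMm2"] = s.vessels_per_mm2
            rec["VesselPctArea"] = s.vessel_pct_area
        if "typing" in cfg.features:
            for lab, pct in (s.type_pcts or {}).items():
                rec[f"PctType_{lab}"] = pct
            for r, t in (s.thresholds or {}).items():
                rec[f"Threshold_{r}"] = t
        if s.error:
            rec["Error"] = s.error
        recs.append(rec)
    return pd.DataFrame(recs)


def run_batch(cfg: RunConfig) -> pd.DataFrame:
    """Process every TIFF in the input folder; returns the global table."""
    in_dir = Path(cfg.input_dir)
    out_dir = Path(cfg.output_dir)
    images = sorted(p for p in in_dir.iterdir()
                    if p.suffix.lower() in (".tif", ".tiff"))
    if not images:
        raise FileNotFoundError(f"no TIFF images in {in_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)
    for folder in FOLDERS:
        (out_dir / folder).mkdir(exist_ok=True)
    run_id = cfg.run_id or datetime.now().strftime("%Y%m%d-%H%M%S")

    summaries = []
    log_lines = [f"run_id\t{run_id}"]
    for key, value in dataclasses.asdict(cfg).items():
        log_lines.append(f"config.{key}\t{value}")

    for path in images:
        name = path.stem
        try:
            section = _read_image(path, cfg)
            summary, fiber_table, objects, roisets, fiber_map, values = \
                _analyze_image(section, cfg, name)
        except Exception as exc:  # quarantine the image, keep the batch alive
            summaries.append(SectionSummary(
                image=name, accepted=False, qc_ratio=float("nan"),
                error=f"{type(exc).__name__}: {exc}",
            ))
            shutil.copy2(path, out_dir / "Artefacts" / path.name)
            log_lines.append(f"image.{name}.error\t{type(exc).__name__}: {exc}")
            continue

        summaries.append(summary)
        if not summary.accepted:
            shutil.copy2(path, out_dir / "Artefacts" / path.name)
            log_lines.append(f"image.{name}.qc\trejected ratio={summary.qc_ratio:.4f}")
            continue

        fiber_table.to_csv(out_dir / "Results by file" / f"{name}_fibers.txt",
                           sep="\t", index=False)
        if objects is not None:
            objects.to_csv(out_dir / "Results by file" / f"{name}_objects.csv",
                           index=False)
        write_roi_archive(out_dir / "ROI" / f"{name}_rois.zip", roisets)
        for kind in cfg.cartographies:
            if kind not in values:
                continue
            spec = carto.spec_for(kind, values.get(kind), legend=cfg.legend)
            img = carto.render_cartography(fiber_map, values[kind], spec)
            pil = Image.fromarray(img)
            pil.save(out_dir / "Cartography" / f"{name}_{kind}.jpg", quality=92)
            pil.save(out_dir / "Cartography" / f"{name}_{kind}.png")
        if summary.thresholds:
            for r, t in summary.thresholds.items():
                log_lines.append(f"image.{name}.threshold.{r}\t{t:.4f}")

    table = _summary_frame(summaries, cfg)
    table.to_csv(out_dir / f"RunGlobalResult_{run_id}.txt", sep="\t", index=False)
    (out_dir / f"RunLog_{run_id}.txt").write_text("\n".join(log_lines) + "\n")
    return table
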