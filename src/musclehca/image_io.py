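"""Reading calibrated multichannel sections from TIFF files.

Channel roles are always explicit configuration (a mapping ``role -> channel
index``); they are never inferred from wavelength metadata.  Pixel size must
be isotropic and strictly positive; it is taken from TIFF metadata when
available and not overridden, otherwise it must be supplied by the caller.

Coordinate convention: 0-based ``(row, col)`` pixel indices; physical
coordinates are ``index * scale_um_per_px`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

#: Roles a channel may be bound to.
VALID_ROLES = frozenset(
    {"laminin", "dapi", "pax7", "cd31", "stain1", "stain2", "stain3"}
)

#: Maximum number of simultaneously mapped channels.
MAX_CHANNELS = 4


class ScaleError(ValueError):
    """Pixel size missing, non-positive, or anisotropic."""


@dataclass
class CalibratedSection:
    """A multichannel 2-D image with physical calibration and channel roles.

    Parameters
    ----------
    pixels
        Mapping ``role -> 2-D intensity array``.  All channels must share
        the same height and width.  Intensities keep their source dynamic
        range (8/16-bit integers or floats); they are never rescaled.
    scale_um_per_px
        Isotropic pixel size in micrometres per pixel, ``> 0``.
    channel_roles
        Mapping ``role -> source channel index`` recording where each role
        came from in the source file.
    source_path
        Identifier of the origin file ("" for in-memory sections).
    """

    pixels: dict
    scale_um_per_px: float
    channel_roles: dict = field(default_factory=dict)
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("section must have at least one channel")
        unknown = set(self.pixels) - VALID_ROLES
        if unknown:
            raise ValueError(f"unknown channel roles: {sorted(unknown)}")
        if "laminin" not in self.pixels:
            raise ValueError("laminin channel is required")
        if len(self.pixels) > MAX_CHANNELS:
            raise ValueError(
                f"at most {MAX_CHANNELS} channels may be mapped simultaneously, "
                f"got {len(self.pixels)}"
            )
        shapes = {np.asarray(a).shape for a in self.pixels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in geometry: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2-D, got shape {shape}")
        if not (np.isfinite(self.scale_um_per_px) and self.scale_um_per_px > 0):
            raise ScaleError(f"scale must be > 0 um/px, got {self.scale_um_per_px}")
        self.pixels = {r: np.asarray(a) for r, a in self.pixels.items()}

    @property
    def shape(self) -> tuple:
        return next(iter(self.pixels.values())).shape

    @property
    def roles(self) -> tuple:
        return tuple(self.pixels)

    def channel(self, role: str) -> np.ndarray:
        if role not in self.pixels:
            raise KeyError(
                f"role {role!r} not mapped in this section (has {sorted(self.pixels)})"
            )
        return self.pixels[role]


def _scale_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Extract an isotropic um/px scale from TIFF metadata, or None.

    Raises ScaleError when x and y resolutions disagree (anisotropic pixels).
    """
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    unit = page.tags.get("ResolutionUnit")
    if xres is None or yres is None:
        return None
    xr = xres.value[0] / xres.value[1] if isinstance(xres.value, tuple) else xres.value
    yr = yres.value[0] / yres.value[1] if isinstance(yres.value, tuple) else yres.value
    if xr <= 0 or yr <= 0:
        return None
    # pixels per unit -> um per pixel
    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", None) and unit.value)
    if unit_um is None:
        return None
    sx, sy = unit_um / xr, unit_um / yr
    if not np.isclose(sx, sy, rtol=1e-3):
        raise ScaleError(f"anisotropic pixel size {sx:.4g} x {sy:.4g} um/px")
    return float(sx)


def _load_channels(path: Path) -> np.ndarray:
    """Read a TIFF as a (C, H, W) array, accepting 2-D, (C,H,W) and (H,W,C<=4)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim == 3:
        # channel-last only when the trailing axis is small and leading is not
        if arr.shape[-1] <= MAX_CHANNELS < arr.shape[0]:
            return np.moveaxis(arr, -1, 0)
        return arr
    raise ValueError(f"unsupported TIFF dimensionality {arr.shape} in {path}")


def read_section(
    path,
    channel_map: Mapping[str, int],
    scale: float | str | None = "from metadata",
) -> CalibratedSection:
    """Read a multichannel TIFF and bind channels to roles.

    Parameters
    ----------
    path
        A single multichannel TIFF, or a directory holding a per-channel
        TIFF series (files sorted by name give channel order).
    channel_map
        ``role -> channel index`` (0-based) into the file's channel axis.
    scale
        Micrometres per pixel.  The default ``"from metadata"`` uses the
        TIFF resolution tags and raises :class:`ScaleError` when they are
        absent or anisotropic.  A number always overrides metadata.

    Intensities are returned exactly as stored (no rescaling, bit depth
    preserved).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")

    if path.is_dir():
        series = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not series:
            raise FileNotFoundError(f"no TIFF files in series directory {path}")
        planes = [tifffile.imread(p) for p in series]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"per-channel series {path} has mixed geometries {shapes}")
        channels = np.stack(planes)
        meta_scale = None
        with tifffile.TiffFile(series[0]) as tf:
            meta_scale = _scale_from_tiff(tf)
    else:
        channels = _load_channels(path)
        with tifffile.TiffFile(path) as tf:
            meta_scale = _scale_from_tiff(tf)

    n = channels.shape[0]
    for role, idx in channel_map.items():
        if role not in VALID_ROLES:
            raise ValueError(f"unknown role {role!r}")
        if not (0 <= int(idx) < n):
            raise IndexError(
                f"channel index out of range: {role}={idx} but file has {n} channel(s)"
            )

    if scale == "from metadata" or scale is None:
        if meta_scale is None:
            raise ScaleError(
                f"{path}: no pixel-size metadata; pass scale explicitly"
            )
        scale_um = meta_scale
    else:
        scale_um = float(scale)

    pixels = {role: channels[int(idx)] for role, idx in channel_map.items()}
    return CalibratedSection(
        pixels=pixels,
        scale_um_per_px=scale_um,
        channel_roles=dict(channel_map),
        source_path=str(path),
    )


def write_section(path, section: CalibratedSection, channel_order: Sequence[str] | None = None) -> None:
    """Write a section as a (C, H, W) TIFF with resolution tags in um/px."""
    order = list(channel_order) if channel_order else list(section.pixels)
    stack = np.stack([section.pixels[r] for r in order])
    ppcm = 10000.0 / section.scale_um_per_px  # pixels per centimetre
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
        metadata={"axes": "CYX", "channel_roles": order},
    )


def max_project(stack: Sequence[CalibratedSection]) -> CalibratedSection:
    """Per-pixel, per-channel maximum-intensity projection over z-slices.

    All slices must share geometry, roles and scale.  A single slice is
    returned unchanged (idempotence); the operation is invariant to slice
    order.
    """
    slices = list(stack)
    if not slices:
        raise ValueError("empty z-stack")
    first = slices[0]
    for s in slices[1:]:
        if s.shape != first.shape:
            raise ValueError(f"slice geometry mismatch: {s.shape} vs {first.shape}")
        if set(s.pixels) != set(first.pixels):
            raise ValueError("slice channel roles differ")
        if not np.isclose(s.scale_um_per_px, first.scale_um_per_px):
            raise ValueError("slice scales differ")
    if len(slices) == 1:
        return first
    pixels = {
        role: np.maximum.reduce([s.pixels[role] for s in slices])
        for role in first.pixels
    }
    return CalibratedSection(
        pixels=pixels,
        scale_um_per_px=first.scale_um_per_px,
        channel_roles=dict(first.channel_roles),
        source_path=first.source_path,
    )
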