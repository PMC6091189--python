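"""Export per-fiber ROI masks as ImageJ-compatible polygon records.

Each fiber contributes up to four entries (``<id>_F``, ``<id>_CNF``,
``<id>_SC``, ``<id>_V``) to a zip archive, alongside a plain-text CSV index.
The ``.roi`` records use the classic ImageJ polygon layout (64-byte header,
then x then y vertex offsets as int16) so they load in the ROI Manager.
Annular regions (SC, V) are exported by their outer outline only; the CSV
index records the region kind so downstream tools can reconstruct the hole
from the paired CNF/F outlines.
"""

from __future__ import annotations

import io
import struct
import zipfile

import numpy as np
from skimage import measure

_POLYGON = 0
_VERSION = 227


def polygon_outline(mask: np.ndarray, origin=(0, 0)) -> np.ndarray:
    """Outer outline of a binary mask as (N, 2) integer (row, col) vertices."""
    contours = measure.find_contours(np.pad(mask, 1), 0.5)
    if not contours:
        raise ValueError("empty mask has no outline")
    contour = max(contours, key=len) - 1.0  # undo padding
    pts = np.round(contour).astype(np.int32)
    # drop consecutive duplicates introduced by rounding
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    pts[:, 0] += origin[0]
    pts[:, 1] += origin[1]
    return pts


def encode_imagej_roi(vertices_rc: np.ndarray) -> bytes:
    """Encode (row, col) vertices as an ImageJ polygon ``.roi`` record."""
    rows = vertices_rc[:, 0].astype(np.int32)
    cols = vertices_rc[:, 1].astype(np.int32)
    top, left = int(rows.min()), int(cols.min())
    bottom, right = int(rows.max()), int(cols.max())
    n = len(vertices_rc)
    buf = io.BytesIO()
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = _POLYGON
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    buf.write(bytes(header))
    buf.write(np.asarray(cols - left, dtype=">i2").tobytes())
    buf.write(np.asarray(rows - top, dtype=">i2").tobytes())
    return buf.getvalue()


def decode_imagej_roi(data: bytes) -> np.ndarray:
    """Inverse of :func:`encode_imagej_roi` (round-trip testing)."""
    if data[0:4] != b"Iout":
        raise ValueError("not an ImageJ ROI record")
    top, left, _, _ = struct.unpack_from(">hhhh", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(np.int32)
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(np.int32)
    return np.stack([ys + top, xs + left], axis=1)


def write_roi_archive(path, roisets: dict) -> None:
    """Write all fibers' ROI outlines plus index.csv into a zip archive."""
    index_lines = ["fiber_id,roi_kind,entry,n_vertices"]
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for fid in sorted(roisets):
            rs = roisets[fid]
            for kind, attr in (("F", "roi_f"), ("CNF", "roi_cnf"),
                               ("SC", "roi_sc"), ("V", "roi_v")):
                mask = getattr(rs, attr)
                if not mask.any():
                    continue
                pts = polygon_outline(mask, origin=rs.origin)
                name = f"{fid:04d}_{kind}.roi"
                zf.writestr(name, encode_imagej_roi(pts))
                index_lines.append(f"{fid},{kind},{name},{len(pts)}")
        zf.writestr("index.csv", "\n".join(index_lines) + "\n")
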