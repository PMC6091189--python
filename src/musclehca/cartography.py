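"""Color-coded in situ cartographies of per-fiber results.

Each fiber of the reconstructed section is painted with the color of its
value class; walls and background stay neutral.  Fixed class scales:

* centronuclei: 0 -> white, 1 -> yellow, 2 -> orange, >=3 -> red;
* vessels per fiber: six purple classes 0-1, 2-3, 4-5, 6-7, 8-9, >9;
* satellites per fiber: 0 -> white, 1 -> light pink, >1 -> dark pink;
* CSA: eight within-section quantile bins, light to dark green;
* fiber type: categorical palette over I/IIA/IIB/IIX/hybrids/ND.

Color lookup is a pure function of (value, spec); re-rendering is
bit-identical.  Fibers with a missing value are painted a distinct
"no-data" gray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKGROUND_RGB = (30, 30, 30)
NODATA_RGB = (128, 128, 128)

CENTRONUCLEI_PALETTE = [
    (255, 255, 255),  # 0
    (255, 221, 0),    # 1
    (255, 140, 0),    # 2
    (214, 28, 28),    # >= 3
]

VESSEL_PALETTE = [  # light -> dark purple, classes 0-1, 2-3, 4-5, 6-7, 8-9, >9
    (243, 231, 255),
    (216, 191, 242),
    (186, 147, 227),
    (152, 103, 204),
    (114, 62, 174),
    (74, 20, 134),
]

SATELLITE_PALETTE = [
    (255, 255, 255),  # 0
    (247, 168, 204),  # 1
    (199, 21, 133),   # > 1
]

CSA_GREENS = [  # 8 octile bins, light -> dark green
    (229, 245, 224),
    (199, 233, 192),
    (161, 217, 155),
    (116, 196, 118),
    (65, 171, 93),
    (35, 139, 69),
    (0, 109, 44),
    (0, 68, 27),
]

FIBERTYPE_PALETTE = {
    "I": (33, 102, 172),
    "IIA": (103, 169, 207),
    "IIB": (5, 48, 97),
    "IIX": (209, 229, 240),
    "I-IIA": (146, 197, 222),
    "I-IIB": (67, 147, 195),
    "IIA-IIB": (54, 75, 154),
    "ND": (150, 150, 150),
}

KINDS = ("csa", "centronuclei", "vessels", "satellites", "fibertype")


@dataclass
class CartographySpec:
    """Class edges + ordered palette for one cartography kind.

    ``class_edges`` are the strictly increasing lower bounds of classes
    1..n-1 (class 0 is everything below ``class_edges[0]``); for categorical
    kinds (fibertype) ``categories`` replaces the edges.
    """

    kind: str
    class_edges: list = field(default_factory=list)
    palette: list = field(default_factory=list)
    categories: list = field(default_factory=list)
    legend: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown cartography kind {self.kind!r}")
        if self.categories:
            if len(self.palette) != len(self.categories):
                raise ValueError("palette size must match category count")
        else:
            if list(self.class_edges) != sorted(set(self.class_edges)):
                raise ValueError("class_edges must be strictly increasing")
            if len(self.palette) != len(self.class_edges) + 1:
                raise ValueError("palette must have len(class_edges) + 1 colors")

    def class_index(self, value) -> int:
        if self.categories:
            return self.categories.index(value)
        return int(np.searchsorted(self.class_edges, value, side="right"))

    def color_for(self, value) -> tuple:
        return tuple(self.palette[self.class_index(value)])

    def class_labels(self) -> list:
        if self.categories:
            return list(self.categories)
        edges = [-np.inf] + list(self.class_edges) + [np.inf]
        labels = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo == -np.inf:
                labels.append(f"< {hi:g}")
            elif hi == np.inf:
                labels.append(f">= {lo:g}")
            else:
                labels.append(f"{lo:g}-{hi:g}")
        return labels


def spec_for(kind: str, values: dict | None = None, legend: bool = True) -> CartographySpec:
    """Build the fixed class scale for a kind (CSA needs the section's values
    to place its octile edges)."""
    if kind == "centronuclei":
        return CartographySpec(kind, class_edges=[1, 2, 3],
                               palette=list(CENTRONUCLEI_PALETTE), legend=legend)
    if kind == "vessels":
        return CartographySpec(kind, class_edges=[2, 4, 6, 8, 10],
                               palette=list(VESSEL_PALETTE), legend=legend)
    if kind == "satellites":
        return CartographySpec(kind, class_edges=[1, 2],
                               palette=list(SATELLITE_PALETTE), legend=legend)
    if kind == "fibertype":
        return CartographySpec(kind, categories=list(FIBERTYPE_PALETTE),
                               palette=list(FIBERTYPE_PALETTE.values()), legend=legend)
    if kind == "csa":
        if not values:
            raise ValueError("csa cartography needs per-fiber values to set octiles")
        v = np.array(list(values.values()), dtype=np.float64)
        qs = np.quantile(v, np.arange(1, 8) / 8.0)
        # deduplicate while preserving order (degenerate CSA distributions)
        edges, palette = [], [CSA_GREENS[0]]
        for q, col in zip(qs, CSA_GREENS[1:]):
            if not edges or q > edges[-1]:
                edges.append(float(q))
                palette.append(col)
        return CartographySpec(kind, class_edges=edges, palette=palette, legend=legend)
    raise ValueError(f"unknown cartography kind {kind!r}")


_SWATCH = 14  # px legend swatch edge


def render_cartography(
    fiber_map,
    values: dict,
    spec: CartographySpec,
    missing_log: list | None = None,
) -> np.ndarray:
    """Paint each fiber's class color into an RGB (H, W, 3) uint8 image.

    ``values`` maps fiber id to the quantity the spec classifies.  Fibers
    without a value get the no-data gray and are appended to
    ``missing_log``.  When ``spec.legend`` is true a swatch column is burned
    into the top-left corner (one ``_SWATCH``-px square per class, top to
    bottom, matching palette order).
    """
    labels = fiber_map.labels
    img = np.empty(labels.shape + (3,), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    for fid in fiber_map.fiber_ids():
        fid = int(fid)
        if fid in values and values[fid] is not None:
            color = spec.color_for(values[fid])
        else:
            color = NODATA_RGB
            if missing_log is not None:
                missing_log.append(fid)
        img[labels == fid] = color
    if spec.legend:
        _burn_legend(img, spec)
    return img


def _burn_legend(img: np.ndarray, spec: CartographySpec) -> None:
    pad = 4
    for i, color in enumerate(spec.palette):
        r0 = pad + i * (_SWATCH + 2)
        if r0 + _SWATCH + pad > img.shape[0]:
            break
        img[r0 : r0 + _SWATCH, pad : pad + _SWATCH] = color
        # 1-px dark frame so white swatches stay visible
        img[r0 - 1, pad - 1 : pad + _SWATCH + 1] = (0, 0, 0)
        img[r0 + _SWATCH, pad - 1 : pad + _SWATCH + 1] = (0, 0, 0)
        img[r0 - 1 : r0 + _SWATCH + 1, pad - 1] = (0, 0, 0)
        img[r0 - 1 : r0 + _SWATCH + 1, pad + _SWATCH] = (0, 0, 0)


def legend_swatch_color(img: np.ndarray, class_index: int) -> tuple:
    """Read back the legend swatch color for a class (pixel test helper)."""
    pad = 4
    r0 = pad + class_index * (_SWATCH + 2)
    return tuple(int(v) for v in img[r0 + _SWATCH // 2, pad + _SWATCH // 2])
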