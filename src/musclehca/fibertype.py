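"""Intensity-threshold fiber typing from up to three intrafiber stainings.

Per channel, a signal-to-noise threshold is derived from the non-fiber
tissue pixels: threshold = background mode + snr_factor x robust sigma
(1.4826 x median absolute deviation).  A fiber is positive for a channel
when its mean intensity over ``roi_f`` exceeds the threshold.  The label
follows the cardinality of the positive set: none -> IIX (deduced,
unlabeled), one -> the matching pure type, two -> hybrid, three -> ND.
Thresholds are always recorded so results stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default channel-role -> pure-type mapping (panel order I, IIA, IIB).
DEFAULT_TYPE_MAP = {"stain1": "I", "stain2": "IIA", "stain3": "IIB"}

TYPE_LABELS = ("I", "IIA", "IIB", "IIX", "I-IIA", "I-IIB", "IIA-IIB", "ND")

DEFAULT_SNR_FACTOR = 3.0


@dataclass
class TypingThresholds:
    channel_role: str
    threshold: float
    background_mode: float
    robust_sigma: float
    snr_factor: float


@dataclass
class FiberTypeCall:
    fiber_id: int
    positives: frozenset
    label: str
    mean_intensities: dict  # channel role -> mean over roi_f


def compute_threshold(
    channel: np.ndarray,
    section_mask: np.ndarray,
    fiber_labels: np.ndarray,
    snr_factor: float = DEFAULT_SNR_FACTOR,
    role: str = "stain1",
) -> TypingThresholds:
    """Derive one channel's positivity threshold from non-fiber tissue pixels.

    Background = modal intensity of tissue pixels outside every fiber;
    sigma = 1.4826 x MAD of those pixels; threshold = mode + factor x sigma.
    """
    bg_region = np.asarray(section_mask, dtype=bool) & (fiber_labels == 0)
    vals = np.asarray(channel, dtype=np.float64)[bg_region]
    if vals.size == 0:
        raise ValueError("empty background region")
    # mode via integer-rounded histogram (intensities are quantized anyway)
    ints = np.round(vals).astype(np.int64)
    ints -= ints.min()
    mode = float(np.bincount(ints).argmax() + np.round(vals).min())
    sigma = float(1.4826 * np.median(np.abs(vals - np.median(vals))))
    return TypingThresholds(
        channel_role=role,
        threshold=mode + snr_factor * sigma,
        background_mode=mode,
        robust_sigma=sigma,
        snr_factor=snr_factor,
    )


def label_from_positives(positives: frozenset, type_map: dict | None = None) -> str:
    """Cardinality rule: 0 -> IIX, 1 -> pure type, 2 -> hybrid, 3 -> ND."""
    if type_map is None:
        type_map = DEFAULT_TYPE_MAP
    names = sorted((type_map[p] for p in positives),
                   key=lambda t: ("I", "IIA", "IIB").index(t))
    if len(names) == 0:
        return "IIX"
    if len(names) == 1:
        return names[0]
    if len(names) == 2:
        return f"{names[0]}-{names[1]}"
    return "ND"


def call_types(
    channels: dict,
    thresholds: dict,
    roisets: dict,
    type_map: dict | None = None,
    statistic: str = "mean",
) -> dict:
    """Type every fiber from its per-channel intensity over ``roi_f``.

    ``channels`` maps role -> grid and ``thresholds`` role ->
    :class:`TypingThresholds`.  Returns fiber id -> :class:`FiberTypeCall`.
    """
    if not channels:
        raise ValueError("at least one typing channel required")
    if set(channels) != set(thresholds):
        raise ValueError("channels and thresholds must cover the same roles")
    reduce = {"mean": np.mean, "median": np.median}[statistic]
    arrays = {r: np.asarray(g, dtype=np.float64) for r, g in channels.items()}
    calls: dict = {}
    for fid, rs in roisets.items():
        r0, c0 = rs.origin
        h, w = rs.roi_f.shape
        intensities = {}
        pos = set()
        for role, arr in arrays.items():
            vals = arr[r0 : r0 + h, c0 : c0 + w][rs.roi_f]
            m = float(reduce(vals))
            intensities[role] = m
            if m > thresholds[role].threshold:
                pos.add(role)
        calls[fid] = FiberTypeCall(
            fiber_id=fid,
            positives=frozenset(pos),
            label=label_from_positives(frozenset(pos), type_map),
            mean_intensities=intensities,
        )
    return calls


def type_distribution(calls) -> dict:
    """Percentages per label over all typed fibers; values sum to 100."""
    vals = list(calls.values()) if isinstance(calls, dict) else list(calls)
    if not vals:
        raise ValueError("no typed fibers")
    n = len(vals)
    out = {lab: 0 for lab in TYPE_LABELS}
    for c in vals:
        out[c.label] += 1
    return {lab: 100.0 * k / n for lab, k in out.items()}
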