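"""Nucleus detection in two-channel fluorescence fields.

Point detection only: the labeling-index analysis needs nucleus counts and
positions, not segmented shapes.  The DAPI channel yields all nuclei, the
BrdU channel the labeled subset; DAPI detections are marked labeled when a
BrdU detection lies within a matching radius (greedy nearest-first, each
BrdU spot consumed at most once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian

__all__ = ["detect_nuclei", "label_nuclei", "LabelResult", "records_from_images"]


def detect_nuclei(
    image: np.ndarray,
    pixel_size: float,
    sigma: float = 4.0,
    rel_threshold: float = 0.2,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Detect nucleus centers as smoothed local maxima.

    The image is Gaussian-smoothed at half the expected spot scale
    ``sigma`` (um) — enough to suppress pixel noise without blending
    neighboring spots; local maxima above ``rel_threshold`` times the
    smoothed dynamic range, separated by at least ``2 * sigma``, are
    returned as an ``(n, 2)`` array of (x, y) in um (pixel centers at
    half-integer pixel coordinates).  Two spots closer than ``2 * sigma``
    merge into one detection.  A blank or constant image yields an empty
    array.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    img = np.asarray(image, dtype=float)
    if img.size == 0 or np.ptp(img) == 0:
        return np.empty((0, 2))
    smoothed = gaussian(img, sigma=0.5 * sigma / pixel_size, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.empty((0, 2))
    # threshold relative to the smoothed dynamic range so a constant
    # background offset does not mask dim spots
    thr = smoothed.min() + rel_threshold * np.ptp(smoothed)
    # Euclidean (disk) suppression footprint: peaks closer than 2 sigma merge
    radius = max(int(round(2.0 * sigma / pixel_size)), 1)
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    footprint = (yy**2 + xx**2) <= radius**2
    coords = peak_local_max(
        smoothed,
        footprint=footprint,
        threshold_abs=thr,
        exclude_border=False,
    )
    if len(coords) == 0:
        return np.empty((0, 2))
    # plateau ties survive the footprint filter; enforce the separation
    # floor greedily, brightest first (deterministic: ties by array order)
    intensities = smoothed[coords[:, 0], coords[:, 1]]
    keep: list[int] = []
    for idx in np.argsort(-intensities, kind="stable"):
        pt = coords[idx]
        if all(np.hypot(*(coords[k] - pt)) >= radius for k in keep):
            keep.append(idx)
    coords = coords[sorted(keep)]
    x = (coords[:, 1] + 0.5) * pixel_size + origin[0]
    y = (coords[:, 0] + 0.5) * pixel_size + origin[1]
    return np.column_stack([x, y])


@dataclass
class LabelResult:
    """Labeled nucleus records plus matching QC."""

    records: pd.DataFrame  # chip, x_um, y_um, labeled
    n_unmatched_brdu: int


def label_nuclei(
    dapi_positions,
    brdu_positions,
    match_radius: float = 6.0,
    chip_id: str = "chip00",
) -> LabelResult:
    """Mark DAPI detections BrdU-positive by greedy nearest-first matching.

    Candidate (DAPI, BrdU) pairs within ``match_radius`` um are consumed
    in order of increasing distance, ties broken by smaller indices, so
    the assignment is deterministic; each BrdU detection labels at most
    one nucleus.  BrdU detections left unmatched are reported as a QC
    count, never silently dropped.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    if not chip_id:
        raise ValueError("chip_id must be non-empty")
    dapi = np.atleast_2d(np.asarray(dapi_positions, dtype=float)).reshape(-1, 2)
    brdu = np.atleast_2d(np.asarray(brdu_positions, dtype=float)).reshape(-1, 2)
    labeled = np.zeros(len(dapi), dtype=bool)
    n_unmatched = len(brdu)
    if len(dapi) and len(brdu):
        tree = cKDTree(dapi)
        pairs = []
        for j, pos in enumerate(brdu):
            for i in tree.query_ball_point(pos, match_radius):
                pairs.append((float(np.linalg.norm(dapi[i] - pos)), i, j))
        pairs.sort()
        used_dapi: set[int] = set()
        used_brdu: set[int] = set()
        for _, i, j in pairs:
            if i in used_dapi or j in used_brdu:
                continue
            used_dapi.add(i)
            used_brdu.add(j)
            labeled[i] = True
        n_unmatched = len(brdu) - len(used_brdu)
    records = pd.DataFrame(
        {
            "chip": chip_id,
            "x_um": dapi[:, 0] if len(dapi) else np.array([]),
            "y_um": dapi[:, 1] if len(dapi) else np.array([]),
            "labeled": labeled,
        }
    )
    return LabelResult(records=records, n_unmatched_brdu=n_unmatched)


def records_from_images(
    dapi: np.ndarray,
    brdu: np.ndarray,
    pixel_size: float,
    sigma: float = 4.0,
    rel_threshold: float = 0.2,
    match_radius: float = 6.0,
    origin: tuple[float, float] = (0.0, 0.0),
    chip_id: str = "chip00",
) -> LabelResult:
    """Full image path: detect both channels, then match to label nuclei."""
    dapi_pos = detect_nuclei(dapi, pixel_size, sigma, rel_threshold, origin)
    brdu_pos = detect_nuclei(brdu, pixel_size, sigma, rel_threshold, origin)
    return label_nuclei(dapi_pos, brdu_pos, match_radius, chip_id)
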