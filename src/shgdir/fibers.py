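"""Collagen fiber segmentation and width estimation.

A transparent skeleton-based estimator: threshold the section into a
collagen-positive mask, skeletonize, split the skeleton at branch points,
and report per-segment widths from the Euclidean distance transform
(width ~ 2 * EDT - 1 pixels on the medial axis).  Widths are reported per
segment between branch points, so densely crossing fibers are measured as
fiber bundles — the same granularity a fiber-network tracer reports when
individual fibers cannot be separated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters, morphology

__all__ = [
    "FiberRecord",
    "WidthSummary",
    "segment_fibers",
    "extract_fiber_widths",
    "summarize_widths",
]


@dataclass
class FiberRecord:
    """One skeleton segment: centerline pixels plus width/length in um."""

    centerline: np.ndarray  # (n, 2) row/col
    mean_width: float
    length: float

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline)
        if len(self.centerline) < 2:
            raise ValueError("centerline needs >= 2 points")
        if self.mean_width <= 0 or self.length <= 0:
            raise ValueError("width and length must be > 0")


@dataclass
class WidthSummary:
    group_label: str
    mean_width: float
    standard_error: float
    std_dev: float
    n_fibers: int


def segment_fibers(
    section: np.ndarray,
    method: str = "otsu",
    min_object_px: int = 20,
    threshold: float | None = None,
) -> np.ndarray:
    """Foreground mask of collagen-positive pixels.

    ``method='otsu'`` separates the intensity histogram automatically; a
    constant image yields an empty mask.  ``method='fixed'`` uses the
    supplied ``threshold``.
    """
    section = np.asarray(section, dtype=float)
    if section.size == 0:
        raise ValueError("empty image")
    if method == "otsu":
        if np.ptp(section[np.isfinite(section)]) == 0:
            return np.zeros(section.shape, dtype=bool)
        t = filters.threshold_otsu(section[np.isfinite(section)])
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        t = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = section > t
    if min_object_px > 0:
        mask = morphology.remove_small_objects(mask, min_size=min_object_px)
    return mask


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def extract_fiber_widths(
    mask: np.ndarray,
    pixel_size: float,
    min_segment_px: int = 10,
) -> list[FiberRecord]:
    """Per-segment fiber/bundle widths from a binary mask.

    Skeletonize, cut the skeleton at branch points (8-neighbour count
    > 2), and measure each remaining segment: width = (2 * mean EDT - 1)
    pixels on the centerline, length = pixel count along the centerline.
    Segments shorter than ``min_segment_px`` (skeleton spurs) are dropped.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return []
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    skel = morphology.skeletonize(mask)
    edt = ndimage.distance_transform_edt(mask)
    neighbors = ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant")
    branch_points = skel & (neighbors > 2)
    segments = skel & ~branch_points
    labels, n_seg = ndimage.label(segments, structure=np.ones((3, 3)))
    records: list[FiberRecord] = []
    for lab in range(1, n_seg + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < max(2, min_segment_px):
            continue
        # EDT reaches the nearest background pixel *center*, ~0.25 px past
        # the region boundary on average over orientations; -0.5 centers
        # the estimator between the aligned (-1) and oblique (0) cases
        width_px = 2.0 * edt[coords[:, 0], coords[:, 1]].mean() - 0.5
        if width_px <= 0:
            continue
        records.append(
            FiberRecord(
                centerline=coords,
                mean_width=width_px * pixel_size,
                length=len(coords) * pixel_size,
            )
        )
    return records


def summarize_widths(
    widths_by_group: dict[str, np.ndarray],
) -> tuple[list[WidthSummary], pd.DataFrame]:
    """Group width summaries plus pairwise two-sample t-tests.

    Returns a summary per group (mean, SE = SD/sqrt(n), SD, n) and a
    DataFrame of Welch t statistics and two-sided p-values for every
    group pair.
    """
    summaries = []
    for label, widths in widths_by_group.items():
        w = np.asarray(widths, dtype=float)
        if w.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sd = float(w.std(ddof=1)) if w.size > 1 else float("nan")
        se = sd / np.sqrt(w.size) if w.size > 1 else float("nan")
        summaries.append(
            WidthSummary(
                group_label=label,
                mean_width=float(w.mean()),
                standard_error=se,
                std_dev=sd,
                n_fibers=int(w.size),
            )
        )
    rows = []
    for (la, wa), (lb, wb) in itertools.combinations(widths_by_group.items(), 2):
        wa = np.asarray(wa, dtype=float)
        wb = np.asarray(wb, dtype=float)
        if np.ptp(wa) == 0 and np.ptp(wb) == 0 and wa.mean() == wb.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(wa, wb, equal_var=False)
        rows.append({"group_a": la, "group_b": lb, "t": float(t), "p": float(p)})
    return summaries, pd.DataFrame(rows)
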