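"""Forward/backward stack preprocessing and local creation-ratio extraction.

A depth stack is acquired simultaneously in a forward (transmitted) and a
backward (epi) channel, one optical section per micrometre.  After
trimming boundary sections, removing saturated pixels and calibrating the
channel efficiencies, each section is tiled into non-overlapping patches
(default 30 x 30 px, sized to hold whole fiber structures); the patch-wise
measured F/B is inverted through a Monte Carlo lookup table at the
section's depth to yield a local F_SHG/B_SHG heat map.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from .mc import EmissionLookupTable, invert_measured_fb
from .optics import DetectionGeometry

__all__ = [
    "ImageStackPair",
    "PatchGrid",
    "RatioHeatMapStack",
    "preprocess_stack",
    "apply_calibration",
    "compute_patch_grid",
    "extract_ratio_heatmaps",
    "patch_size_sweep",
    "read_stack_pair",
    "write_heatmaps",
]

FLAG_OK = "ok"
FLAG_CLAMPED_LOW = "clamped_low"
FLAG_CLAMPED_HIGH = "clamped_high"
FLAG_INVALID = "invalid"


@dataclass
class ImageStackPair:
    """Co-registered forward and backward 3-D intensity stacks.

    Invalid (saturated) pixels are NaN in both channels.  ``depth_offset``
    is the depth in micrometres of the first retained section, measured
    from the backward-collection face.
    """

    forward: np.ndarray
    backward: np.ndarray
    pixel_size: float = 170.0 / 512.0
    section_spacing: float = 1.0
    depth_offset: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        if self.forward.shape != self.backward.shape:
            raise ValueError("forward/backward shapes differ")
        if self.forward.ndim != 3:
            raise ValueError("stacks must be 3-D (sections, rows, cols)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.forward) < 0 or np.nanmin(self.backward) < 0:
                raise ValueError("intensities must be >= 0")

    @property
    def n_sections(self) -> int:
        return self.forward.shape[0]

    def section_depth(self, index: int) -> float:
        return self.depth_offset + index * self.section_spacing

    @property
    def depths(self) -> np.ndarray:
        return self.depth_offset + np.arange(self.n_sections) * self.section_spacing


@dataclass
class PatchGrid:
    """Patch-averaged channel intensities and measured F/B for one section."""

    patch_size: int
    mean_forward: np.ndarray
    mean_backward: np.ndarray
    measured_fb: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        bad = ~self.valid & np.isfinite(self.measured_fb)
        if bad.any():
            raise ValueError("measured_fb defined on invalid patches")


@dataclass
class RatioHeatMapStack:
    """Per-section patch grids of extracted F_SHG/B_SHG.

    ``ratios`` is NaN where ``flags == 'invalid'``; clamped patches carry
    the grid boundary value.  ``provenance`` records the lookup-table
    fingerprint used for the inversion.
    """

    ratios: np.ndarray
    flags: np.ndarray
    depth_per_section: np.ndarray
    patch_size: int
    provenance: str = ""
    mean_forward: np.ndarray | None = None
    mean_backward: np.ndarray | None = None

    def valid_ratios(self) -> np.ndarray:
        """Ratios of all ok/clamped patches, flattened."""
        return self.ratios[self.flags != FLAG_INVALID]

    def flag_counts(self) -> dict:
        flags, counts = np.unique(self.flags, return_counts=True)
        return dict(zip(flags.tolist(), counts.tolist()))


def preprocess_stack(
    pair: ImageStackPair,
    saturation_level: float,
    noise_filter: str = "median3",
    trim_sections: int = 10,
) -> ImageStackPair:
    """Trim boundary sections, remove saturated pixels, denoise.

    The first and last ``trim_sections`` optical sections are dropped
    (boundary effects).  A pixel at or above ``saturation_level`` in either
    channel is marked invalid (NaN) in both, since the patch ratio needs
    both channels.  Denoising (3x3 median per section) is applied
    identically to both channels before the saturation mask is imposed.
    """
    if saturation_level <= 0:
        raise ValueError("saturation_level must be > 0")
    if noise_filter not in ("median3", "none"):
        raise ValueError(f"unknown noise_filter {noise_filter!r}")
    if pair.n_sections <= 2 * trim_sections:
        raise ValueError(
            f"stack has {pair.n_sections} sections; needs > {2 * trim_sections}"
        )
    sl = slice(trim_sections, pair.n_sections - trim_sections if trim_sections else None)
    fwd = pair.forward[sl].copy()
    bwd = pair.backward[sl].copy()
    saturated = (fwd >= saturation_level) | (bwd >= saturation_level)
    if noise_filter == "median3":
        for k in range(fwd.shape[0]):
            fwd[k] = ndimage.median_filter(fwd[k], size=3, mode="nearest")
            bwd[k] = ndimage.median_filter(bwd[k], size=3, mode="nearest")
    fwd[saturated] = np.nan
    bwd[saturated] = np.nan
    return ImageStackPair(
        forward=fwd,
        backward=bwd,
        pixel_size=pair.pixel_size,
        section_spacing=pair.section_spacing,
        depth_offset=pair.depth_offset + trim_sections * pair.section_spacing,
        metadata=dict(pair.metadata),
    )


def apply_calibration(pair: ImageStackPair, geometry: DetectionGeometry) -> ImageStackPair:
    """Divide the forward channel by the collection-efficiency ratio.

    After this, an isotropic emitter in a non-scattering mount yields
    measured F/B = 1.
    """
    return ImageStackPair(
        forward=pair.forward / geometry.calibration_factor,
        backward=pair.backward.copy(),
        pixel_size=pair.pixel_size,
        section_spacing=pair.section_spacing,
        depth_offset=pair.depth_offset,
        metadata=dict(pair.metadata),
    )


def _tile(section: np.ndarray, patch_size: int) -> np.ndarray:
    """Tile a 2-D array into (gr, gc, p, p); trailing margins discarded."""
    h, w = section.shape
    gr, gc = h // patch_size, w // patch_size
    trimmed = section[: gr * patch_size, : gc * patch_size]
    return trimmed.reshape(gr, patch_size, gc, patch_size).swapaxes(1, 2)


def compute_patch_grid(
    section_forward: np.ndarray,
    section_backward: np.ndarray,
    patch_size: int = 30,
    min_valid_fraction: float = 0.5,
    min_total_intensity: float = 0.0,
) -> PatchGrid:
    """Patch-average one section and form the measured F/B per patch.

    The patch ratio is mean(F)/mean(B) over valid pixels — the
    photon-count estimator, robust to near-zero individual pixels.  A
    patch is valid iff at least ``min_valid_fraction`` of its pixels are
    valid in both channels, its mean backward intensity is positive, and
    its mean total intensity (F + B) reaches ``min_total_intensity`` —
    the threshold that excludes collagen-free regions where only dark
    counts are present.
    """
    section_forward = np.asarray(section_forward, dtype=float)
    section_backward = np.asarray(section_backward, dtype=float)
    if section_forward.shape != section_backward.shape or section_forward.ndim != 2:
        raise ValueError("sections must be 2-D and same shape")
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if patch_size > min(section_forward.shape):
        raise ValueError("patch_size larger than image")

    tf = _tile(section_forward, patch_size)
    tb = _tile(section_backward, patch_size)
    finite = np.isfinite(tf) & np.isfinite(tb)
    n_valid = finite.sum(axis=(2, 3))
    with np.errstate(invalid="ignore"):
        mean_f = np.where(n_valid > 0, np.nansum(np.where(finite, tf, 0.0), axis=(2, 3)), np.nan)
        mean_b = np.where(n_valid > 0, np.nansum(np.where(finite, tb, 0.0), axis=(2, 3)), np.nan)
    mean_f = mean_f / np.where(n_valid > 0, n_valid, 1)
    mean_b = mean_b / np.where(n_valid > 0, n_valid, 1)
    with np.errstate(invalid="ignore"):
        valid = (
            (n_valid >= min_valid_fraction * patch_size**2)
            & (mean_b > 0)
            & (mean_f > 0)
            & (mean_f + mean_b >= min_total_intensity)
        )
    fb = np.full(mean_f.shape, np.nan)
    fb[valid] = mean_f[valid] / mean_b[valid]
    return PatchGrid(
        patch_size=patch_size,
        mean_forward=mean_f,
        mean_backward=mean_b,
        measured_fb=fb,
        valid=valid,
    )


def extract_ratio_heatmaps(
    pair: ImageStackPair,
    table: EmissionLookupTable,
    patch_size: int = 30,
    min_valid_fraction: float = 0.5,
    min_total_intensity: float = 0.0,
) -> RatioHeatMapStack:
    """Extract the local F_SHG/B_SHG heat-map stack.

    Per section: patch-average both channels, then invert each valid
    patch's measured F/B through the lookup table at the section's depth.
    """
    depths = pair.depths
    if depths.min() < table.depth_axis.min() - 1e-9 or depths.max() > table.depth_axis.max() + 1e-9:
        raise ValueError(
            f"section depths [{depths.min():.1f}, {depths.max():.1f}] um outside "
            f"lookup-table range [{table.depth_axis.min():.1f}, {table.depth_axis.max():.1f}]"
        )
    expected = pair.metadata.get("optics_fingerprint")
    if expected is not None and expected != table.optics_fingerprint:
        import warnings

        warnings.warn(
            "lookup-table optics fingerprint does not match stack metadata",
            stacklevel=2,
        )

    ratio_maps, flag_maps, mf_maps, mb_maps = [], [], [], []
    for k in range(pair.n_sections):
        grid = compute_patch_grid(
            pair.forward[k],
            pair.backward[k],
            patch_size,
            min_valid_fraction,
            min_total_intensity,
        )
        ratios = np.full(grid.measured_fb.shape, np.nan)
        flags = np.full(grid.measured_fb.shape, FLAG_INVALID, dtype=object)
        if grid.valid.any():
            r, f = invert_measured_fb(
                grid.measured_fb[grid.valid], depths[k], table
            )
            ratios[grid.valid] = r
            flags[grid.valid] = f
        ratio_maps.append(ratios)
        flag_maps.append(flags)
        mf_maps.append(grid.mean_forward)
        mb_maps.append(grid.mean_backward)

    return RatioHeatMapStack(
        ratios=np.stack(ratio_maps),
        flags=np.stack(flag_maps),
        depth_per_section=depths,
        patch_size=patch_size,
        provenance=table.optics_fingerprint,
        mean_forward=np.stack(mf_maps),
        mean_backward=np.stack(mb_maps),
    )


@dataclass
class SweepEntry:
    heatmaps: RatioHeatMapStack
    fit_failure_fraction: float


def patch_size_sweep(
    pair: ImageStackPair,
    table: EmissionLookupTable,
    sizes: tuple = (1, 10, 20, 30, 50),
    min_valid_fraction: float = 0.5,
    min_total_intensity: float = 0.0,
) -> dict[int, SweepEntry]:
    """Heat maps at several patch sizes plus the fit-failure fraction.

    The failure fraction (patches flagged invalid) falls with patch size
    as shot noise averages out; the diagnostic motivates the default 30 px
    patch, large enough to hold whole fiber bundles but small enough to
    stay local.
    """
    out: dict[int, SweepEntry] = {}
    for size in sizes:
        if size < 1:
            raise ValueError("patch sizes must be positive")
        hm = extract_ratio_heatmaps(
            pair, table, size, min_valid_fraction, min_total_intensity
        )
        n = hm.flags.size
        failures = (hm.flags == FLAG_INVALID).sum() / n if n else np.nan
        out[int(size)] = SweepEntry(heatmaps=hm, fit_failure_fraction=float(failures))
    return out


# ------------------------------------------------------------------- io


def read_stack_pair(
    forward_path: str | Path,
    backward_path: str | Path,
    pixel_size: float = 170.0 / 512.0,
    section_spacing: float = 1.0,
    depth_offset: float = 0.0,
    metadata: Mapping | None = None,
) -> ImageStackPair:
    """Read a forward/backward multi-page TIFF pair."""
    import tifffile

    fwd = tifffile.imread(forward_path)
    bwd = tifffile.imread(backward_path)
    return ImageStackPair(
        forward=fwd,
        backward=bwd,
        pixel_size=pixel_size,
        section_spacing=section_spacing,
        depth_offset=depth_offset,
        metadata=dict(metadata or {}),
    )


def write_heatmaps(hm: RatioHeatMapStack, out_prefix: str | Path) -> None:
    """Write a heat-map stack as float TIFF plus long-format CSV."""
    import pandas as pd
    import tifffile

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(f"{out_prefix}_ratios.tif", hm.ratios.astype(np.float32))
    s, r, c = np.meshgrid(
        np.arange(hm.ratios.shape[0]),
        np.arange(hm.ratios.shape[1]),
        np.arange(hm.ratios.shape[2]),
        indexing="ij",
    )
    pd.DataFrame(
        {
            "section": s.ravel(),
            "row": r.ravel(),
            "col": c.ravel(),
            "depth_um": hm.depth_per_section[s.ravel()],
            "ratio": hm.ratios.ravel(),
            "flag": [str(f) for f in hm.flags.ravel()],
        }
    ).to_csv(f"{out_prefix}_ratios.csv", index=False)
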