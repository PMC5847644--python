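"""Heterogeneity and correlation analytics for creation-ratio heat maps.

Per tissue volume the heat-map stack is summarized by the mean local
F_SHG/B_SHG and the within-volume standard deviation of patch values
(the heterogeneity metric).  Per optical section, the Pearson correlation
between the self-normalized heat map and the patch-averaged SHG intensity
quantifies how tightly directionality tracks brightness — high when the
underlying phase-mismatch distribution is narrow.  GLCM texture features
are provided as the intensity-only control, which does not separate the
tissue classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import graycomatrix

from .stacks import FLAG_INVALID, ImageStackPair, RatioHeatMapStack

__all__ = [
    "HeterogeneitySummary",
    "CorrelationResult",
    "heterogeneity_summary",
    "section_pearson",
    "stack_correlation",
    "compare_groups",
    "glcm_features",
]


@dataclass
class HeterogeneitySummary:
    """Group-level dispersion summary of local creation ratios.

    ``mean_ratio`` averages per-volume means of valid patch ratios across
    the group's volumes (+/- SE over volumes); ``within_volume_std``
    averages the per-volume SD of patch ratios — the heterogeneity of the
    directionality field inside a single tissue volume.
    """

    group_label: str
    mean_ratio: float
    mean_ratio_se: float
    within_volume_std: float
    within_volume_std_se: float
    n_volumes: int
    volume_means: list = field(default_factory=list)
    volume_stds: list = field(default_factory=list)


def _volume_stats(hm: RatioHeatMapStack) -> tuple[float, float]:
    vals = hm.valid_ratios()
    if vals.size == 0:
        return np.nan, np.nan
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def heterogeneity_summary(
    heatmaps_by_group: dict[str, list[RatioHeatMapStack]],
) -> list[HeterogeneitySummary]:
    """Table of mean F_SHG/B_SHG and within-volume SD per tissue group."""
    out = []
    for label, volumes in heatmaps_by_group.items():
        means, sds = [], []
        for hm in volumes:
            m, s = _volume_stats(hm)
            if not np.isfinite(m):
                warnings.warn(
                    f"volume in group {label!r} has no valid patches; excluded",
                    stacklevel=2,
                )
                continue
            means.append(m)
            sds.append(s)
        if not means:
            raise ValueError(f"group {label!r} has no usable volumes")
        means_a, sds_a = np.array(means), np.array(sds)
        n = means_a.size
        sem = means_a.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        ses = sds_a.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        out.append(
            HeterogeneitySummary(
                group_label=label,
                mean_ratio=float(means_a.mean()),
                mean_ratio_se=float(sem),
                within_volume_std=float(sds_a.mean()),
                within_volume_std_se=float(ses),
                n_volumes=int(n),
                volume_means=means,
                volume_stds=sds,
            )
        )
    return out


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def section_pearson(
    ratio_patches: np.ndarray,
    intensity_patches: np.ndarray,
    normalization: str = "minmax_per_section",
) -> float:
    """Pearson r between a section's heat map and its patch intensities.

    Both matrices are self-normalized per section (min-max to [0, 1];
    Pearson is affine-invariant, so this is kept for heat-map
    comparability, not because it changes r).  Patches invalid in either
    matrix are excluded; NaN is returned when fewer than 3 valid patches
    remain or either side has zero variance.
    """
    if normalization not in ("minmax_per_section", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    r = np.asarray(ratio_patches, dtype=float)
    i = np.asarray(intensity_patches, dtype=float)
    if r.shape != i.shape:
        raise ValueError("ratio and intensity grids must have the same shape")
    valid = np.isfinite(r) & np.isfinite(i)
    if valid.sum() < 3:
        return float("nan")
    rv, iv = r[valid], i[valid]
    if normalization == "minmax_per_section":
        rv, iv = _minmax(rv), _minmax(iv)
    if np.ptp(rv) == 0 or np.ptp(iv) == 0:
        return float("nan")
    rho, _ = stats.pearsonr(rv, iv)
    return float(rho)


@dataclass
class CorrelationResult:
    """Per-section Pearson r of one heat-map stack and its mean."""

    per_section_r: np.ndarray
    stack_mean_r: float
    se: float

    def __post_init__(self) -> None:
        self.per_section_r = np.asarray(self.per_section_r, dtype=float)


def stack_correlation(
    hm: RatioHeatMapStack,
    pair: ImageStackPair | None = None,
    channel: str = "forward",
) -> CorrelationResult:
    """Average the per-section heat-map/intensity Pearson r over a stack.

    Intensity is the patch-averaged forward channel stored on the heat-map
    stack (or recomputed from ``pair`` if given; ``channel`` may be
    'forward', 'backward' or 'sum').  Sections with undefined r are
    dropped from the average.
    """
    if pair is not None:
        from .stacks import compute_patch_grid

        intens = []
        for k in range(pair.n_sections):
            grid = compute_patch_grid(
                pair.forward[k], pair.backward[k], hm.patch_size
            )
            if channel == "forward":
                intens.append(grid.mean_forward)
            elif channel == "backward":
                intens.append(grid.mean_backward)
            elif channel == "sum":
                intens.append(grid.mean_forward + grid.mean_backward)
            else:
                raise ValueError(f"unknown channel {channel!r}")
        intensity = np.stack(intens)
    else:
        if hm.mean_forward is None:
            raise ValueError("heat-map stack carries no intensities; pass `pair`")
        intensity = (
            hm.mean_forward
            if channel == "forward"
            else hm.mean_backward
            if channel == "backward"
            else hm.mean_forward + hm.mean_backward
        )

    ratios = np.where(hm.flags != FLAG_INVALID, hm.ratios, np.nan)
    rs = np.array(
        [
            section_pearson(ratios[k], intensity[k])
            for k in range(ratios.shape[0])
        ]
    )
    finite = rs[np.isfinite(rs)]
    if finite.size == 0:
        warnings.warn("no section yielded a defined correlation", stacklevel=2)
        return CorrelationResult(per_section_r=rs, stack_mean_r=float("nan"), se=float("nan"))
    se = finite.std(ddof=1) / np.sqrt(finite.size) if finite.size > 1 else float("nan")
    return CorrelationResult(
        per_section_r=rs, stack_mean_r=float(finite.mean()), se=float(se)
    )


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means +/- SE and pairwise two-sample t-tests (Welch default).

    Used for per-stack mean Pearson r and any other per-volume scalar.
    Pairs where either group has fewer than two values are skipped with a
    warning.
    """
    summary_rows = []
    for label, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
        summary_rows.append(
            {"group": label, "mean": v.mean() if v.size else np.nan, "se": se, "n": v.size}
        )
    rows = []
    for (la, va), (lb, vb) in itertools.combinations(values_by_group.items(), 2):
        va = np.asarray(va, dtype=float)
        vb = np.asarray(vb, dtype=float)
        if va.size < 2 or vb.size < 2:
            warnings.warn(
                f"t-test skipped for {la!r} vs {lb!r}: fewer than 2 values",
                stacklevel=2,
            )
            continue
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va.mean() == vb.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
        rows.append({"group_a": la, "group_b": lb, "t": float(t), "p": float(p)})
    return pd.DataFrame(summary_rows), pd.DataFrame(rows)


_DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
_OFFSET_TO_ANGLE = {
    (0, 1): 0.0,
    (1, 1): np.pi / 4,
    (1, 0): np.pi / 2,
    (1, -1): 3 * np.pi / 4,
}


def glcm_features(
    image: np.ndarray,
    levels: int = 16,
    offsets: tuple = _DEFAULT_OFFSETS,
) -> dict[str, float]:
    """Gray-level co-occurrence energy, entropy, homogeneity.

    The image is quantized to ``levels`` equal-width bins over its valid
    range; the symmetric, normalized co-occurrence matrix P is averaged
    over the given pixel offsets.  energy = sum(P^2),
    entropy = -sum(P log2 P) with 0 log 0 = 0,
    homogeneity = sum(P / (1 + |i - j|)).  A constant image gives
    energy 1, entropy 0, homogeneity 1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(image, dtype=float)
    finite = np.isfinite(img)
    if not finite.all():
        raise ValueError("image must be finite; mask or fill invalid pixels first")
    lo, hi = img.min(), img.max()
    if hi == lo:
        q = np.zeros(img.shape, dtype=np.uint8)
    else:
        q = np.clip(((img - lo) / (hi - lo) * levels).astype(int), 0, levels - 1).astype(
            np.uint8
        )
    try:
        angles = [_OFFSET_TO_ANGLE[tuple(o)] for o in offsets]
    except KeyError as exc:
        raise ValueError(f"unsupported offset {exc.args[0]}") from None
    glcm = graycomatrix(q, [1], angles, levels=levels, symmetric=True, normed=True)
    p = glcm[:, :, 0, :].mean(axis=-1)
    idx = np.arange(levels)
    abs_diff = np.abs(idx[:, None] - idx[None, :])
    nz = p[p > 0]
    return {
        "energy": float((p**2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "homogeneity": float((p / (1.0 + abs_diff)).sum()),
    }
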