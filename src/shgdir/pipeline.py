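"""End-to-end orchestration of the local-directionality workflow.

One run: build (or load) the Monte Carlo lookup table, obtain a cohort of
forward/backward stacks (synthetic by default, or from disk), preprocess
and calibrate, extract patch-wise F_SHG/B_SHG heat maps, and produce the
dispersion summary, intensity-correlation comparison, fiber-width table
and GLCM control features as CSV bundles with full provenance.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, fibers, stacks, synthetic
from .mc import EmissionLookupTable, build_lookup_table
from .optics import DetectionGeometry, MCConfig, OpticalProperties
from .phase_matching import DirectionalityMap

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Single-file configuration for a full analysis run."""

    seed: int = 0
    out_dir: str = "shgdir_run"
    # optics / MC
    mu_s_reduced: float = 2.0
    anisotropy_g: float = 0.9
    refractive_index: float = 1.4
    thickness: float = 150.0
    calibration_factor: float = 1.0
    photons_per_condition: int = 10_000
    n_lut_depths: int = 20
    lut_path: str | None = None
    # cohort
    classes: tuple = synthetic.CLASS_ORDER
    n_volumes_per_class: int = 3
    shape: tuple = (256, 256)
    n_sections: int = 64
    mean_counts: float = 50.0
    noise: bool = True
    depth_offset: float = 10.0
    # analysis
    patch_size: int = 30
    min_valid_fraction: float = 0.5
    min_intensity_fraction: float = 0.05  # of mean_counts; drops dark-only patches
    trim_sections: int = 0
    saturation_level: float | None = None
    glcm_levels: int = 16

    def optics(self) -> OpticalProperties:
        return OpticalProperties(
            mu_s_reduced=self.mu_s_reduced,
            anisotropy_g=self.anisotropy_g,
            refractive_index=self.refractive_index,
            thickness=self.thickness,
        )

    def geometry(self) -> DetectionGeometry:
        return DetectionGeometry(calibration_factor=self.calibration_factor)

    def mc_config(self) -> MCConfig:
        depth_hi = min(self.thickness, self.depth_offset + self.n_sections + 1.0)
        return MCConfig(
            photons_per_condition=self.photons_per_condition,
            rng_seed=self.seed,
            depth_grid=tuple(np.linspace(0.0, depth_hi, self.n_lut_depths)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["classes"] = list(d["classes"])
        d["shape"] = list(d["shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _get_lut(config: RunConfig) -> EmissionLookupTable:
    if config.lut_path and Path(config.lut_path).exists():
        return EmissionLookupTable.load(config.lut_path)
    lut = build_lookup_table(config.optics(), config.geometry(), config.mc_config())
    if config.lut_path:
        lut.save(config.lut_path)
    return lut


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete workflow and write the report bundle.

    Returns a dict of DataFrames: heterogeneity (Table-1 style),
    correlations (Fig.-5 style), pairwise t-tests, fiber widths and GLCM
    features; everything is also written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    lut = _get_lut(config)
    dmap = DirectionalityMap()
    profiles = synthetic.default_profiles(dmap, config.optics())
    profiles = {c: profiles[c] for c in config.classes}

    cohort, manifest = synthetic.generate_cohort(
        profiles,
        lut,
        dmap,
        n_volumes_per_class=config.n_volumes_per_class,
        shape=tuple(config.shape),
        n_sections=config.n_sections,
        mean_counts=config.mean_counts,
        seed=config.seed,
        noise=config.noise,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    min_intensity = config.min_intensity_fraction * config.mean_counts
    heatmaps: dict[str, list] = {}
    corr_by_group: dict[str, list] = {}
    widths_by_group: dict[str, np.ndarray] = {}
    glcm_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, volumes in cohort.items():
            hms, rs, widths = [], [], []
            for vi, (pair, _truth) in enumerate(volumes):
                if config.trim_sections:
                    sat = config.saturation_level or np.inf
                    pair = stacks.preprocess_stack(
                        pair, sat, "none", config.trim_sections
                    )
                pair = stacks.apply_calibration(pair, config.geometry())
                hm = stacks.extract_ratio_heatmaps(
                    pair,
                    lut,
                    config.patch_size,
                    config.min_valid_fraction,
                    min_intensity,
                )
                hms.append(hm)
                rs.append(analysis.stack_correlation(hm).stack_mean_r)
                mid = pair.forward[pair.n_sections // 2]
                mask = fibers.segment_fibers(np.nan_to_num(mid))
                for rec in fibers.extract_fiber_widths(mask, pair.pixel_size):
                    widths.append(rec.mean_width)
                feats = analysis.glcm_features(
                    np.nan_to_num(mid), levels=config.glcm_levels
                )
                glcm_rows.append({"group": label, "volume": vi, **feats})
            heatmaps[label] = hms
            corr_by_group[label] = rs
            widths_by_group[label] = np.asarray(widths)

    het = analysis.heterogeneity_summary(heatmaps)
    het_df = pd.DataFrame(
        [
            {
                "group": h.group_label,
                "mean_ratio": h.mean_ratio,
                "mean_ratio_se": h.mean_ratio_se,
                "within_volume_std": h.within_volume_std,
                "within_volume_std_se": h.within_volume_std_se,
                "n_volumes": h.n_volumes,
            }
            for h in het
        ]
    )
    corr_df, corr_tests = analysis.compare_groups(corr_by_group)
    width_summaries, width_tests = fibers.summarize_widths(
        {k: v for k, v in widths_by_group.items() if v.size}
    )
    width_df = pd.DataFrame([dataclasses.asdict(s) for s in width_summaries])
    glcm_df = pd.DataFrame(glcm_rows)

    het_df.to_csv(out / "heterogeneity.csv", index=False)
    corr_df.to_csv(out / "correlations.csv", index=False)
    corr_tests.to_csv(out / "correlation_tests.csv", index=False)
    width_df.to_csv(out / "fiber_widths.csv", index=False)
    width_tests.to_csv(out / "fiber_width_tests.csv", index=False)
    glcm_df.to_csv(out / "glcm_features.csv", index=False)
    for label, hms in heatmaps.items():
        for vi, hm in enumerate(hms):
            stacks.write_heatmaps(hm, out / "heatmaps" / f"{label}_{vi:02d}")

    log = {
        "lookup_fingerprint": lut.optics_fingerprint,
        "manifest_hash": manifest["hash"],
        "seed": config.seed,
        "stages": [
            "lookup_table",
            "generate_cohort",
            "calibrate",
            "extract_heatmaps",
            "heterogeneity",
            "correlations",
            "fiber_widths",
            "glcm",
        ],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))

    return {
        "heterogeneity": het_df,
        "correlations": corr_df,
        "correlation_tests": corr_tests,
        "fiber_widths": width_df,
        "fiber_width_tests": width_tests,
        "glcm": glcm_df,
        "heatmaps": heatmaps,
        "lookup_table": lut,
        "manifest": manifest,
    }
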