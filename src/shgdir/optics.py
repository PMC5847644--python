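"""Optical and detection parameters for SHG photon transport.

The slab model is a single homogeneous scattering layer.  Depth ``z`` is
measured from the objective-side face (where backward SHG is collected),
increasing toward the condenser (forward collection), in micrometres.
Scattering is parameterized by the reduced scattering coefficient
``mu_s' = mu_s (1 - g)`` at the SHG wavelength, with a Henyey-Greenstein
phase function of anisotropy ``g``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a tissue slab at the SHG wavelength.

    Parameters
    ----------
    mu_s_reduced : float
        Reduced scattering coefficient mu_s' in mm^-1 (at 494 nm).
    anisotropy_g : float
        Scattering anisotropy (mean cosine), in [0, 1).
    refractive_index : float
        Tissue refractive index, > 1.
    mu_a : float
        Absorption coefficient in mm^-1; negligible in ovarian tissue at
        494 nm, so the default is 0.
    thickness : float
        Slab thickness in micrometres.
    """

    mu_s_reduced: float = 2.0
    anisotropy_g: float = 0.9
    refractive_index: float = 1.4
    mu_a: float = 0.0
    thickness: float = 150.0

    def __post_init__(self) -> None:
        if self.mu_s_reduced < 0:
            raise ValueError("mu_s_reduced must be >= 0")
        if not 0.0 <= self.anisotropy_g < 1.0:
            raise ValueError("anisotropy_g must be in [0, 1)")
        if self.refractive_index <= 1.0:
            raise ValueError("refractive_index must be > 1")
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if not math.isfinite(self.mu_s):
            raise ValueError("derived mu_s is not finite")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g), in mm^-1."""
        return self.mu_s_reduced / (1.0 - self.anisotropy_g)

    @property
    def mu_s_per_um(self) -> float:
        return self.mu_s * 1e-3

    @property
    def mu_a_per_um(self) -> float:
        return self.mu_a * 1e-3


@dataclass(frozen=True)
class DetectionGeometry:
    """Forward/backward collection geometry.

    ``calibration_factor`` is the forward/backward collection-efficiency
    ratio of the two detection paths, measured with isotropic emitters
    (fluorescent microspheres); dividing the forward channel by it
    baselines an isotropic source to measured F/B = 1.
    """

    forward_na: float = 0.9
    backward_na: float = 0.8
    immersion_index: float = 1.33
    calibration_factor: float = 1.0

    def __post_init__(self) -> None:
        for na in (self.forward_na, self.backward_na):
            if not 0.0 < na < self.immersion_index:
                raise ValueError("NA values must lie in (0, immersion_index)")
        if self.calibration_factor <= 0:
            raise ValueError("calibration_factor must be > 0")


def _default_ratio_grid() -> tuple:
    # creation-ratio inversion grid: 1.0 to 19.9 in 0.3 steps (64 values)
    return tuple(round(1.0 + 0.3 * i, 10) for i in range(64))


def _default_depth_grid() -> tuple:
    return tuple(float(d) for d in range(0, 151, 1))


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run configuration.

    ``emission_half_angle`` is the half-angle (radians, inside the tissue)
    of the launch cone about +/-z.  ``None`` means: use the excitation
    focal cone refracted into the tissue, asin(backward_na / n_tissue).
    """

    photons_per_condition: int = 100_000
    rng_seed: int = 0
    ratio_grid: tuple = field(default_factory=_default_ratio_grid)
    depth_grid: tuple = field(default_factory=_default_depth_grid)
    emission_half_angle: float | None = None

    def __post_init__(self) -> None:
        if self.photons_per_condition < 1_000:
            raise ValueError("photons_per_condition must be >= 1000")
        grid = tuple(float(r) for r in self.ratio_grid)
        if len(grid) == 0 or any(r < 1.0 for r in grid):
            raise ValueError("ratio_grid values must all be >= 1")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("ratio_grid must be strictly increasing")
        object.__setattr__(self, "ratio_grid", grid)
        depths = tuple(float(d) for d in self.depth_grid)
        if len(depths) == 0 or any(d < 0 for d in depths):
            raise ValueError("depth_grid must be nonnegative")
        object.__setattr__(self, "depth_grid", depths)

    def half_angle(self, optics: OpticalProperties, geometry: DetectionGeometry) -> float:
        if self.emission_half_angle is not None:
            return float(self.emission_half_angle)
        return math.asin(geometry.backward_na / optics.refractive_index)


def optics_fingerprint(
    optics: OpticalProperties, geometry: DetectionGeometry, config: MCConfig
) -> str:
    """Deterministic hash of the full simulation parameterization."""
    payload = {
        "optics": dataclasses.asdict(optics),
        "geometry": dataclasses.asdict(geometry),
        "config": dataclasses.asdict(config),
    }
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def fingerprint_payload(
    optics: OpticalProperties, geometry: DetectionGeometry, config: MCConfig
) -> str:
    payload = {
        "optics": dataclasses.asdict(optics),
        "geometry": dataclasses.asdict(geometry),
        "config": dataclasses.asdict(config),
    }
    return json.dumps(payload, sort_keys=True)
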