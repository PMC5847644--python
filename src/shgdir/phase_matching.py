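"""Heuristic SHG phase-matching model.

Under relaxed phase matching, the harmonic field generated over an
interaction length L with wavevector mismatch dk is

    E_2w = kappa * E_w**2 * sinc(dk * L / 2),   sinc(x) = sin(x) / x,

so a smaller |dk| gives both a brighter and a more forward-directed
signal.  The mapping from |dk| to the creation ratio F_SHG/B_SHG is not
specified by first principles here; the default is the simplest monotone
form, an exponential decay from the maximum grid ratio down to 1:

    ratio(|dk|) = 1 + (r_max - 1) * exp(-|dk| / d).

Both pieces are used by the synthetic-tissue generator, and their joint
behaviour explains why tissues with a narrow dk distribution show a high
Pearson correlation between local intensity and directionality while
heterogeneous tissues decorrelate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PhaseMatchParams",
    "DirectionalityMap",
    "shg_field",
    "shg_intensity",
    "dk_to_creation_ratio",
    "predicted_intensity_ratio_correlation",
]


@dataclass(frozen=True)
class PhaseMatchParams:
    """Inputs to the harmonic-field expression.

    kappa and e_omega are arbitrary-unit constants (only ratios and
    correlations are used downstream); lambda_shg is the SHG wavelength
    in nm (494 for 988-nm excitation).
    """

    delta_k: float
    interaction_length_L: float
    kappa: float = 1.0
    e_omega: float = 1.0
    lambda_shg: float = 494.0

    def __post_init__(self) -> None:
        if self.interaction_length_L <= 0:
            raise ValueError("interaction_length_L must be > 0")
        if self.e_omega < 0:
            raise ValueError("e_omega must be >= 0")
        if self.lambda_shg <= 0:
            raise ValueError("lambda_shg must be > 0")


def _sinc(x: np.ndarray) -> np.ndarray:
    # np.sinc is normalized (sin(pi x)/(pi x)); we need sin(x)/x
    return np.sinc(np.asarray(x) / np.pi)


def shg_field(params: PhaseMatchParams) -> float:
    """Harmonic field amplitude kappa * E_w^2 * sinc(dk L / 2)."""
    x = params.delta_k * params.interaction_length_L / 2.0
    return float(params.kappa * params.e_omega**2 * _sinc(x))


def shg_intensity(
    delta_k: np.ndarray,
    interaction_length: np.ndarray,
    kappa: float = 1.0,
    e_omega: float = 1.0,
) -> np.ndarray:
    """Vectorized harmonic intensity |E_2w|^2; symmetric in dk."""
    x = np.asarray(delta_k) * np.asarray(interaction_length) / 2.0
    return (kappa * e_omega**2 * _sinc(x)) ** 2


@dataclass(frozen=True)
class DirectionalityMap:
    """Monotone nonincreasing |dk| -> creation ratio map.

    ratio(0) = ratio_max, ratio(inf) -> 1; decay constant in rad/um.
    The half-way point sits at |dk| = decay * ln 2.
    """

    ratio_max: float = 19.9
    decay: float = 0.65

    def __post_init__(self) -> None:
        if self.ratio_max <= 1:
            raise ValueError("ratio_max must be > 1")
        if self.decay <= 0:
            raise ValueError("decay must be > 0")

    def ratio_of_dk(self, abs_dk: np.ndarray) -> np.ndarray:
        abs_dk = np.asarray(abs_dk, dtype=float)
        if np.any(abs_dk < 0):
            raise ValueError("abs_dk must be >= 0")
        return 1.0 + (self.ratio_max - 1.0) * np.exp(-abs_dk / self.decay)

    def dk_of_ratio(self, ratio: np.ndarray) -> np.ndarray:
        """Inverse map, for calibrating dk distributions to target ratios."""
        ratio = np.asarray(ratio, dtype=float)
        if np.any(ratio <= 1.0) or np.any(ratio >= self.ratio_max):
            raise ValueError("ratio must lie strictly inside (1, ratio_max)")
        return -self.decay * np.log((ratio - 1.0) / (self.ratio_max - 1.0))


def dk_to_creation_ratio(abs_dk, dmap: DirectionalityMap):
    """Creation ratio F_SHG/B_SHG for a phase mismatch magnitude."""
    out = dmap.ratio_of_dk(abs_dk)
    if np.isscalar(abs_dk):
        return float(out)
    return out


def predicted_intensity_ratio_correlation(
    dk_samples: np.ndarray,
    params: PhaseMatchParams,
    dmap: DirectionalityMap,
) -> float:
    """Pearson r between model intensity and creation ratio over dk samples.

    For dk distributions confined to the monotone lobe (|dk| L / 2 < pi)
    both quantities decrease in |dk| and r approaches 1; distributions
    spanning past the first sinc zero decorrelate.
    """
    dk = np.asarray(dk_samples, dtype=float)
    if dk.size < 3:
        raise ValueError("need at least 3 dk samples")
    intensity = shg_intensity(
        dk, params.interaction_length_L, params.kappa, params.e_omega
    )
    ratio = dmap.ratio_of_dk(np.abs(dk))
    if np.ptp(intensity) == 0 or np.ptp(ratio) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(intensity, ratio)
    return float(r)
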