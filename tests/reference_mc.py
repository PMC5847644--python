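"""Naive per-photon reference Monte Carlo (independent oracle).

Deliberately written as a straightforward scalar loop with the standard
library RNG — no shared code or vectorization with the production
transport core — so agreement between the two is a meaningful check.
"""

from __future__ import annotations

import math
import random


def reference_simulate(
    depth: float,
    creation_ratio: float,
    mu_s_reduced_mm: float,
    g: float,
    n_tissue: float,
    thickness: float,
    forward_na: float = 0.9,
    backward_na: float = 0.8,
    n_out: float = 1.33,
    half_angle: float | None = None,
    mu_a_mm: float = 0.0,
    n_photons: int = 50_000,
    seed: int = 0,
) -> dict:
    """Transport n_photons one at a time; return collection statistics."""
    rng = random.Random(seed)
    if half_angle is None:
        half_angle = math.asin(backward_na / n_tissue)
    cos_max = math.cos(half_angle)
    mu_s = (mu_s_reduced_mm / (1.0 - g)) * 1e-3 if g < 1 else 0.0  # per um
    mu_a = mu_a_mm * 1e-3
    mu_t = mu_s + mu_a
    albedo = mu_s / mu_t if mu_t > 0 else 1.0
    p_forward = creation_ratio / (1.0 + creation_ratio)

    n_f = 0
    n_b = 0
    w_f = w_b = w_esc = w_abs = 0.0

    for _ in range(n_photons):
        # launch: uniform solid angle in a cone about +/-z
        sign = 1.0 if rng.random() < p_forward else -1.0
        cos_t = cos_max + (1.0 - cos_max) * rng.random()
        sin_t = math.sqrt(1.0 - cos_t * cos_t)
        phi = 2.0 * math.pi * rng.random()
        ux = sin_t * math.cos(phi)
        uy = sin_t * math.sin(phi)
        uz = sign * cos_t
        z = depth
        w = 1.0
        fate = None

        for _event in range(100_000):
            if mu_t > 0:
                s = -math.log(1.0 - rng.random()) / mu_t
            else:
                s = math.inf
            # walk the step with boundary handling
            for _bounce in range(200):
                if uz > 0:
                    db = (thickness - z) / uz
                elif uz < 0:
                    db = -z / uz
                else:
                    db = math.inf
                if s < db:
                    z += uz * s
                    break
                # hit a face
                z = thickness if uz > 0 else 0.0
                s -= db
                sin_i = math.sqrt(max(0.0, 1.0 - uz * uz))
                n_sin = n_tissue * sin_i
                if n_sin <= n_out:  # refracts out
                    na = forward_na if uz > 0 else backward_na
                    if n_sin <= na:
                        fate = "F" if uz > 0 else "B"
                    else:
                        fate = "escaped"
                    break
                uz = -uz  # total internal reflection
            else:
                fate = "escaped"
            if fate is not None:
                break
            if mu_t == 0:
                fate = "escaped"
                break
            # scatter: absorb weight, then HG deflection
            w_abs += w * (1.0 - albedo)
            w *= albedo
            if w < 1e-6:
                fate = "absorbed_cutoff"
                break
            u = rng.random()
            if g == 0.0:
                cos_s = 2.0 * u - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cos_s = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            sin_s = math.sqrt(max(0.0, 1.0 - cos_s * cos_s))
            phi = 2.0 * math.pi * rng.random()
            cp, sp = math.cos(phi), math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sin_s * cp
                uy = sin_s * sp
                uz = math.copysign(cos_s, uz)
            else:
                den = math.sqrt(1.0 - uz * uz)
                nx = sin_s * (ux * uz * cp - uy * sp) / den + ux * cos_s
                ny = sin_s * (uy * uz * cp + ux * sp) / den + uy * cos_s
                nz = -sin_s * cp * den + uz * cos_s
                norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                ux, uy, uz = nx / norm, ny / norm, nz / norm
        else:
            fate = "absorbed_cutoff"

        if fate == "F":
            n_f += 1
            w_f += w
        elif fate == "B":
            n_b += 1
            w_b += w
        elif fate == "escaped":
            w_esc += w
        else:
            w_abs += w

    cf = w_f / n_photons
    cb = w_b / n_photons
    fb = cf / cb if cb > 0 else math.inf
    se = fb * math.sqrt(1.0 / n_f + 1.0 / n_b) if n_f and n_b else math.inf
    return {
        "collected_forward": cf,
        "collected_backward": cb,
        "measured_fb": fb,
        "se": se,
        "escaped": w_esc / n_photons,
        "absorbed": w_abs / n_photons,
    }
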