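"""Monte Carlo photon transport for SHG emission directionality.

SHG photons are created at a known depth inside a homogeneous scattering
slab with an intrinsic forward/backward creation ratio ``F_SHG/B_SHG``
(probability r/(1+r) of launching into the forward cone, 1/(1+r) into the
backward cone).  Photons random-walk through the slab (Henyey-Greenstein
scattering, exponential step lengths, weight-based absorption) and are
"collected" when they exit the correct face within the NA acceptance cone
of the forward (condenser) or backward (objective) detection path,
after Snell refraction at the face.

Tabulating the collected-F / collected-B ratio over a grid of creation
ratios and emission depths yields a lookup table; inverting the measured
(depth-dependent) F/B through that table recovers the creation ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .optics import (
    DetectionGeometry,
    MCConfig,
    OpticalProperties,
    fingerprint_payload,
    optics_fingerprint,
)

__all__ = [
    "EmissionResult",
    "EmissionLookupTable",
    "simulate_emission",
    "build_lookup_table",
    "invert_measured_fb",
]

# photons below this weight are terminated, their residue booked as absorbed,
# so the energy ledger stays exact (no roulette amplification)
_WEIGHT_CUTOFF = 1e-6
_MAX_EVENTS = 100_000


class EmissionResult(NamedTuple):
    """Outcome of one Monte Carlo emission condition.

    Fractions are of total launched photon weight.  ``se`` is the standard
    error of the measured F/B ratio ``collected_forward/collected_backward``.
    """

    collected_forward: float
    collected_backward: float
    se: float
    escaped: float
    absorbed: float
    n_photons: int

    @property
    def measured_fb(self) -> float:
        return self.collected_forward / self.collected_backward


def _launch(
    n: int,
    creation_ratio: float,
    half_angle: float,
    rng: np.random.Generator,
    stratified: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Launch directions: uniform in solid angle within a cone about +/-z.

    Bernoulli mode launches forward with probability r/(1+r) at unit
    weight.  Stratified mode launches exactly half the photons each way
    and carries the direction probabilities as weights — the same
    expectation with far lower variance of the backward estimate at high
    ratios (used for lookup-table construction).
    """
    p_forward = creation_ratio / (1.0 + creation_ratio)
    if stratified:
        nf = n // 2
        sign = np.where(np.arange(n) < nf, 1.0, -1.0)
        w = np.where(
            sign > 0, p_forward * n / nf, (1.0 - p_forward) * n / (n - nf)
        )
    else:
        sign = np.where(rng.random(n) < p_forward, 1.0, -1.0)
        w = np.ones(n)
    cos_max = np.cos(half_angle)
    cos_t = cos_max + (1.0 - cos_max) * rng.random(n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * np.pi * rng.random(n)
    ux = sin_t * np.cos(phi)
    uy = sin_t * np.sin(phi)
    uz = sign * cos_t
    return ux, uy, uz, w


def _hg_cos(g: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample the Henyey-Greenstein deflection cosine."""
    u = rng.random(n)
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


def _scatter(ux, uy, uz, g: float, rng: np.random.Generator):
    """Rotate direction vectors by an HG-sampled deflection."""
    n = ux.size
    cos_t = _hg_cos(g, n, rng)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    phi = 2.0 * np.pi * rng.random(n)
    cos_p, sin_p = np.cos(phi), np.sin(phi)

    near_pole = np.abs(uz) > 0.99999
    denom = np.sqrt(np.maximum(1e-30, 1.0 - uz**2))

    nux = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
    nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
    nuz = -sin_t * cos_p * denom + uz * cos_t

    pux = sin_t * cos_p
    puy = sin_t * sin_p
    puz = np.sign(uz) * cos_t

    ux = np.where(near_pole, pux, nux)
    uy = np.where(near_pole, puy, nuy)
    uz = np.where(near_pole, puz, nuz)
    norm = np.sqrt(ux**2 + uy**2 + uz**2)
    return ux / norm, uy / norm, uz / norm


def _transport(
    depth: float,
    creation_ratio: float,
    optics: OpticalProperties,
    geometry: DetectionGeometry,
    half_angle: float,
    n_photons: int,
    rng: np.random.Generator,
    stratified: bool = False,
) -> EmissionResult:
    """Vectorized slab transport of one emission condition."""
    thickness = optics.thickness
    n_t = optics.refractive_index
    n_out = geometry.immersion_index
    mu_s = optics.mu_s_per_um
    mu_a = optics.mu_a_per_um
    mu_t = mu_s + mu_a
    albedo = mu_s / mu_t if mu_t > 0 else 1.0
    g = optics.anisotropy_g

    ux, uy, uz, w = _launch(n_photons, creation_ratio, half_angle, rng, stratified)
    z = np.full(n_photons, float(depth))

    w_forward = 0.0
    w_backward = 0.0
    w2_forward = 0.0  # sums of squared weights -> effective counts
    w2_backward = 0.0
    w_escaped = 0.0
    w_absorbed = 0.0

    for _ in range(_MAX_EVENTS):
        n_alive = z.size
        if n_alive == 0:
            break
        if mu_t > 0:
            s = -np.log1p(-rng.random(n_alive)) / mu_t
        else:
            s = np.full(n_alive, np.inf)

        # walk the step, reflecting at faces (TIR) until consumed or exited
        dead = np.zeros(n_alive, dtype=bool)
        for _bounce in range(200):
            with np.errstate(divide="ignore", invalid="ignore"):
                db = np.where(
                    uz > 0, (thickness - z) / uz, np.where(uz < 0, -z / uz, np.inf)
                )
            crossing = (~dead) & (s >= db) & np.isfinite(db)
            if not crossing.any():
                break
            if _bounce == 199:
                # unphysical TIR trap (possible only at mu_t = 0): drop them
                w_escaped += w[crossing].sum()
                dead[crossing] = True
                break
            # move to face
            z = np.where(crossing, np.where(uz > 0, thickness, 0.0), z)
            s = np.where(crossing, s - db, s)
            sin_i = np.sqrt(np.maximum(0.0, 1.0 - uz[crossing] ** 2))
            n_sin = n_t * sin_i  # Snell invariant across the face
            can_exit = n_sin <= n_out
            fwd_face = uz[crossing] > 0
            na_face = np.where(fwd_face, geometry.forward_na, geometry.backward_na)
            collected = can_exit & (n_sin <= na_face)

            idx = np.flatnonzero(crossing)
            wc = w[idx]
            fwd_mask = collected & fwd_face
            bwd_mask = collected & ~fwd_face
            w_forward += wc[fwd_mask].sum()
            w_backward += wc[bwd_mask].sum()
            w2_forward += (wc[fwd_mask] ** 2).sum()
            w2_backward += (wc[bwd_mask] ** 2).sum()
            w_escaped += wc[can_exit & ~collected].sum()
            dead[idx[can_exit]] = True
            # total internal reflection: flip and keep walking the residue
            tir_idx = idx[~can_exit]
            uz[tir_idx] = -uz[tir_idx]

        alive = ~dead
        if mu_t == 0:
            # ballistic photons always reach a face; none can remain alive
            break
        # photons finishing the step inside the slab scatter there
        z = np.where(alive, z + uz * s, z)
        ux, uy, uz, z, w = ux[alive], uy[alive], uz[alive], z[alive], w[alive]
        if z.size == 0:
            continue
        # absorption by weight at the interaction
        w_absorbed += (w * (1.0 - albedo)).sum()
        w = w * albedo
        low = w < _WEIGHT_CUTOFF
        if low.any():
            w_absorbed += w[low].sum()
            keep = ~low
            ux, uy, uz, z, w = ux[keep], uy[keep], uz[keep], z[keep], w[keep]
            if z.size == 0:
                continue
        ux, uy, uz = _scatter(ux, uy, uz, g, rng)
    else:
        w_absorbed += w.sum()

    cf = w_forward / n_photons
    cb = w_backward / n_photons
    if w_forward > 0 and w_backward > 0:
        # effective (Kish) counts reduce to plain counts at unit weight
        n_eff_f = w_forward**2 / w2_forward
        n_eff_b = w_backward**2 / w2_backward
        fb = cf / cb
        se = fb * np.sqrt(1.0 / n_eff_f + 1.0 / n_eff_b)
    else:
        se = np.inf
    return EmissionResult(
        collected_forward=float(cf),
        collected_backward=float(cb),
        se=float(se),
        escaped=float(w_escaped / n_photons),
        absorbed=float(w_absorbed / n_photons),
        n_photons=n_photons,
    )


def simulate_emission(
    depth: float,
    creation_ratio: float,
    optics: OpticalProperties,
    geometry: DetectionGeometry,
    config: MCConfig,
    rng: np.random.Generator | None = None,
) -> EmissionResult:
    """Simulate one (depth, creation ratio) emission condition.

    Parameters
    ----------
    depth : float
        Emission depth in micrometres from the backward-collection face.
    creation_ratio : float
        Intrinsic F_SHG/B_SHG at the point of creation, >= 1.
    rng : numpy Generator, optional
        Supplied by :func:`build_lookup_table` for per-condition streams;
        defaults to a generator seeded from ``config.rng_seed``.
    """
    if not np.isfinite(depth) or not (0.0 <= depth <= optics.thickness):
        raise ValueError(f"depth {depth} outside slab [0, {optics.thickness}]")
    if not np.isfinite(creation_ratio) or creation_ratio < 1.0:
        raise ValueError("creation_ratio must be >= 1 (grid floor)")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    half = config.half_angle(optics, geometry)
    return _transport(
        depth, creation_ratio, optics, geometry, half, config.photons_per_condition, rng
    )


@dataclass
class EmissionLookupTable:
    """Simulated measured F/B versus (creation ratio, emission depth).

    ``measured_fb[i, j]`` is the collected-forward / collected-backward
    ratio for creation ratio ``ratio_axis[i]`` emitted at depth
    ``depth_axis[j]``; ``collected_f``/``collected_b`` hold the absolute
    detection fractions used by the forward renderer.
    """

    ratio_axis: np.ndarray
    depth_axis: np.ndarray
    measured_fb: np.ndarray
    standard_errors: np.ndarray
    collected_f: np.ndarray
    collected_b: np.ndarray
    optics_fingerprint: str
    fingerprint_payload: str = ""

    def __post_init__(self) -> None:
        self.ratio_axis = np.asarray(self.ratio_axis, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        self.measured_fb = np.asarray(self.measured_fb, dtype=float)
        shape = (self.ratio_axis.size, self.depth_axis.size)
        if self.measured_fb.shape != shape:
            raise ValueError("measured_fb shape does not match axes")
        if not np.all(self.measured_fb > 0):
            raise ValueError("measured_fb must be strictly positive")

    def nearest_depth_index(self, depth: float) -> int:
        return int(np.argmin(np.abs(self.depth_axis - depth)))

    def lookup_fractions(self, ratios: np.ndarray, depth: float):
        """Interpolated (collected_f, collected_b) at the nearest depth row."""
        j = self.nearest_depth_index(depth)
        r = np.clip(ratios, self.ratio_axis[0], self.ratio_axis[-1])
        cf = np.interp(r, self.ratio_axis, self.collected_f[:, j])
        cb = np.interp(r, self.ratio_axis, self.collected_b[:, j])
        return cf, cb

    def lookup_fb(self, ratios: np.ndarray, depth: float) -> np.ndarray:
        """Interpolated measured F/B at the nearest depth row."""
        j = self.nearest_depth_index(depth)
        r = np.clip(ratios, self.ratio_axis[0], self.ratio_axis[-1])
        return np.interp(r, self.ratio_axis, self.measured_fb[:, j])

    def direction_probs(self, depth: float) -> tuple[float, float, float, float]:
        """Direction-conditional collection probabilities at one depth.

        Transport is independent of the creation ratio given the launch
        direction, so cf(r) = (p_Ff r + p_Fb)/(1+r) and
        cb(r) = (p_Bf r + p_Bb)/(1+r) exactly; both are linear in their
        parameters after multiplying by (1+r), and fitting them across
        the whole ratio axis averages the per-node MC noise.
        Returns (p_Ff, p_Fb, p_Bf, p_Bb).
        """
        j = self.nearest_depth_index(depth)
        cache = getattr(self, "_prob_cache", None)
        if cache is None:
            cache = {}
            self._prob_cache = cache
        if j not in cache:
            r = self.ratio_axis
            X = np.column_stack([r, np.ones_like(r)])
            pf, *_ = np.linalg.lstsq(X, self.collected_f[:, j] * (1.0 + r), rcond=None)
            pb, *_ = np.linalg.lstsq(X, self.collected_b[:, j] * (1.0 + r), rcond=None)
            cache[j] = (
                float(max(pf[0], 0.0)),
                float(max(pf[1], 0.0)),
                float(max(pb[0], 0.0)),
                float(max(pb[1], 0.0)),
            )
        return cache[j]

    def fitted_fractions(self, ratios: np.ndarray, depth: float):
        """Denoised (collected_f, collected_b) from the fitted direction
        probabilities; preferred by the forward renderer."""
        p_ff, p_fb, p_bf, p_bb = self.direction_probs(depth)
        r = np.clip(ratios, self.ratio_axis[0], self.ratio_axis[-1])
        cf = (p_ff * r + p_fb) / (1.0 + r)
        cb = (p_bf * r + p_bb) / (1.0 + r)
        return cf, cb

    # ---------------------------------------------------------------- io
    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in (
                "ratio_axis",
                "depth_axis",
                "measured_fb",
                "standard_errors",
                "collected_f",
                "collected_b",
            ):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["optics_fingerprint"] = self.optics_fingerprint
            f.attrs["fingerprint_payload"] = self.fingerprint_payload

    @classmethod
    def load(cls, path: str | Path) -> "EmissionLookupTable":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                ratio_axis=f["ratio_axis"][:],
                depth_axis=f["depth_axis"][:],
                measured_fb=f["measured_fb"][:],
                standard_errors=f["standard_errors"][:],
                collected_f=f["collected_f"][:],
                collected_b=f["collected_b"][:],
                optics_fingerprint=str(f.attrs["optics_fingerprint"]),
                fingerprint_payload=str(f.attrs["fingerprint_payload"]),
            )

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rr, dd = np.meshgrid(self.ratio_axis, self.depth_axis, indexing="ij")
        pd.DataFrame(
            {
                "ratio": rr.ravel(),
                "depth_um": dd.ravel(),
                "fb": self.measured_fb.ravel(),
                "se": self.standard_errors.ravel(),
            }
        ).to_csv(path, index=False)


def monotonicity_z(n_comparisons: int, alpha: float = 0.01) -> float:
    """Per-comparison z threshold for the joint monotonicity check.

    A fixed 3 SE per comparison would false-alarm on almost every large
    grid (~1200 comparisons at ~0.1% each); Bonferroni-adjust to a joint
    level ``alpha``, never below 3 SE.
    """
    from scipy.stats import norm

    if n_comparisons < 1:
        return 3.0
    return float(max(3.0, norm.isf(alpha / (2 * n_comparisons))))


def build_lookup_table(
    optics: OpticalProperties,
    geometry: DetectionGeometry,
    config: MCConfig,
    check_monotone: bool = True,
) -> EmissionLookupTable:
    """Simulate the full (creation ratio x depth) grid into a lookup table.

    Per-condition RNG streams are spawned deterministically from
    ``config.rng_seed`` keyed by (ratio index, depth index), so tables are
    reproducible regardless of evaluation order.
    """
    ratios = np.asarray(config.ratio_grid)
    depths = np.asarray(config.depth_grid)
    if depths.max() > optics.thickness:
        raise ValueError("depth_grid extends beyond the slab thickness")
    half = config.half_angle(optics, geometry)

    shape = (ratios.size, depths.size)
    fb = np.empty(shape)
    se = np.empty(shape)
    cf = np.empty(shape)
    cb = np.empty(shape)
    for i, r in enumerate(ratios):
        for j, d in enumerate(depths):
            ss = np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(i, j))
            rng = np.random.default_rng(ss)
            res = _transport(
                float(d), float(r), optics, geometry, half,
                config.photons_per_condition, rng, stratified=True,
            )
            fb[i, j] = res.measured_fb
            se[i, j] = res.se
            cf[i, j] = res.collected_forward
            cb[i, j] = res.collected_backward

    if check_monotone:
        diff = np.diff(fb, axis=0)
        z = monotonicity_z(diff.size)
        tol = z * np.sqrt(se[:-1, :] ** 2 + se[1:, :] ** 2)
        bad = diff < -tol
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise RuntimeError(
                "measured F/B not monotone in creation ratio beyond "
                f"{z:.1f} SE at ratio={ratios[i]:.2f}, depth={depths[j]:.1f} um; "
                "increase photons_per_condition"
            )

    return EmissionLookupTable(
        ratio_axis=ratios,
        depth_axis=depths,
        measured_fb=fb,
        standard_errors=se,
        collected_f=cf,
        collected_b=cb,
        optics_fingerprint=optics_fingerprint(optics, geometry, config),
        fingerprint_payload=fingerprint_payload(optics, geometry, config),
    )


def _monotone_curve(table: EmissionLookupTable, depth_index: int) -> np.ndarray:
    """Denoised monotone inversion curve for one depth column, cached.

    Because transport is independent of the creation ratio given the
    launch direction, the measured F/B at fixed depth is exactly a
    rational-linear (Moebius) function of the creation ratio,
    fb(r) = (p_Ff r + p_Fb) / (p_Bf r + p_Bb), with direction-conditional
    collection probabilities p.  Fitting that 3-parameter model to all
    grid nodes (weighted by 1/SE^2) averages the per-node MC noise; a
    weighted isotonic projection is the fallback if the fit misbehaves.
    """
    cache = getattr(table, "_iso_cache", None)
    if cache is None:
        cache = {}
        table._iso_cache = cache
    if depth_index not in cache:
        r = table.ratio_axis
        y = table.measured_fb[:, depth_index]
        se = table.standard_errors[:, depth_index]
        curve = None
        if r.size >= 4:
            p_ff, p_fb, p_bf, p_bb = table.direction_probs(
                float(table.depth_axis[depth_index])
            )
            denom = p_bf * r + p_bb
            if np.all(denom > 0):
                fit = (p_ff * r + p_fb) / denom
                resid_z = np.abs(fit - y) / np.where(se > 0, se, np.inf)
                if (
                    np.all(np.diff(fit) > 0)
                    and np.all(fit > 0)
                    and np.nanmax(resid_z) < monotonicity_z(r.size)
                ):
                    curve = fit
        if curve is None:
            from scipy.optimize import isotonic_regression

            with np.errstate(divide="ignore"):
                wts = 1.0 / np.where(np.isfinite(se) & (se > 0), se, np.inf) ** 2
            if not np.any(wts > 0):
                wts = np.ones_like(y)
            wts = np.where(wts > 0, wts, wts[wts > 0].min())
            curve = np.maximum.accumulate(isotonic_regression(y, weights=wts).x)
        cache[depth_index] = curve
    return cache[depth_index]


def invert_measured_fb(
    measured_fb: float | np.ndarray,
    depth: float,
    table: EmissionLookupTable,
):
    """Invert measured F/B to a creation ratio at one depth.

    Selects the nearest depth row, projects the simulated curve onto the
    monotone cone (weighted isotonic regression: the physical response is
    nondecreasing, residual wiggle is MC noise), then inverts it by
    piecewise-linear interpolation along the ratio axis.  Values outside
    the simulated range are clamped to the grid with a flag.

    Returns
    -------
    (ratio, flag) for scalar input, or (ratios, flags) arrays; flags are
    strings in {"ok", "clamped_low", "clamped_high"}.
    """
    if table.ratio_axis.size == 0:
        raise ValueError("empty lookup table")
    scalar = np.isscalar(measured_fb)
    fb = np.atleast_1d(np.asarray(measured_fb, dtype=float))
    if not np.all(np.isfinite(fb)) or np.any(fb <= 0):
        raise ValueError("measured_fb must be finite and positive")
    j = table.nearest_depth_index(depth)
    curve = _monotone_curve(table, j)

    flags = np.full(fb.shape, "ok", dtype=object)
    flags[fb < curve[0]] = "clamped_low"
    flags[fb > curve[-1]] = "clamped_high"
    ratios = np.interp(fb, curve, table.ratio_axis)
    if scalar:
        return float(ratios[0]), str(flags[0])
    return ratios, flags
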