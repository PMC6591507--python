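"""Time-resolved Monte Carlo photon transport in a semi-infinite medium.

The workhorse is :func:`run_white_mc`, a variance-reduced simulation run at
zero absorption ("white" Monte Carlo).  Because packet weight is untouched
by absorption during the walk, a single run stores enough information
(per-packet path lengths) to reconstruct the TPSF at any absorption level
via Beer-Lambert reweighting — see :mod:`wmcfit.lut`.

The elementary building blocks (Henyey-Greenstein sampling, exponential
step lengths, Fresnel/Snell boundary interaction, fiber detection test)
are exposed as plain vectorizable functions; the compiled kernel in
:mod:`wmcfit._kernel` inlines the same formulas.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import _kernel
from .model import C_MM_PER_PS, OpticalProperties, ProbeGeometry, SimConfig, WhiteRunResult

__all__ = [
    "hg_sample",
    "step_length",
    "fresnel_unpolarized",
    "boundary_interact",
    "detect_check",
    "time_of_flight",
    "run_white_mc",
]


def hg_sample(g: float, u):
    """Sample cos(theta) of the Henyey-Greenstein phase function.

    Uses the closed-form inverse CDF; ``u`` may be a scalar or array of
    uniform variates in [0, 1).  For g = 0 the distribution is isotropic,
    cos(theta) = 2u - 1.
    """
    if not -1 < g < 1:
        raise ValueError(f"g must be in (-1, 1), got {g}")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - s * s) / (2.0 * g)
    return np.clip(out, -1.0, 1.0)[()] if out.ndim == 0 else np.clip(out, -1.0, 1.0)


def step_length(mus: float, u):
    """Free path length to the next scattering event, mm.

    l = -ln(u) / mus, exponentially distributed with mean 1/mus.
    ``u`` must be in (0, 1]; u = 0 (an infinite step) is rejected.
    """
    if mus <= 0:
        raise ValueError(f"mus must be > 0, got {mus}")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("u must be in (0, 1]")
    out = -np.log(u) / mus
    return out[()] if out.ndim == 0 else out


def fresnel_unpolarized(n1: float, n2: float, cos_incident):
    """Unpolarized Fresnel reflectance at a planar index step.

    Average of the s- and p-polarized reflectances for light in medium
    ``n1`` striking the interface to ``n2`` with incidence cosine
    ``cos_incident``; returns 1 beyond the critical angle when n1 > n2.
    """
    ci = np.asarray(cos_incident, dtype=float)
    if np.any(ci < 0) or np.any(ci > 1):
        raise ValueError("cos_incident must be in [0, 1]")
    si = np.sqrt(1.0 - ci**2)
    st = n1 / n2 * si
    with np.errstate(invalid="ignore"):
        ct = np.sqrt(1.0 - st**2)
        rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
        rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
        r = 0.5 * (rs**2 + rp**2)
    r = np.where(st >= 1.0, 1.0, r)
    # normal incidence limit handled exactly
    r = np.where(ci >= 1.0, ((n1 - n2) / (n1 + n2)) ** 2, r)
    return r[()] if r.ndim == 0 else r


def boundary_interact(direction, n_inside: float, n_outside: float, u: float):
    """Resolve a packet hitting the medium boundary from inside.

    With probability equal to the unpolarized Fresnel reflectance the
    packet is specularly reflected (z-component of ``direction`` flipped)
    and stays inside; otherwise it is refracted by Snell's law into the
    outer medium.  ``u`` is the uniform variate deciding the outcome.

    Returns ``(transmitted: bool, new_direction: ndarray)``.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ci = abs(d[2])
    refl = fresnel_unpolarized(n_inside, n_outside, ci)
    if u < refl:
        out = d.copy()
        out[2] = -out[2]
        return False, out
    si = np.sqrt(max(0.0, 1.0 - ci * ci))
    st = n_inside / n_outside * si
    ct = np.sqrt(1.0 - st * st)
    if si > 0:
        scale = st / si
    else:
        scale = 0.0
    out = np.array([d[0] * scale, d[1] * scale, np.sign(d[2]) * ct])
    return True, out


def detect_check(exit_position, exit_direction_outside, probe: ProbeGeometry,
                 ring: bool = False) -> bool:
    """Fiber acceptance test for a packet transmitted across the boundary.

    True iff the exit point lies on the detector (a spot of
    ``detector_radius`` centered ``separation`` from the source axis, or
    the full annulus of that radius in ring mode) and the exit polar
    angle satisfies sin(theta) <= NA.
    """
    x, y = float(exit_position[0]), float(exit_position[1])
    d = np.asarray(exit_direction_outside, dtype=float)
    d = d / np.linalg.norm(d)
    sin_theta = np.sqrt(max(0.0, 1.0 - d[2] ** 2))
    if sin_theta > probe.detector_na:
        return False
    if ring:
        return abs(np.hypot(x, y) - probe.separation) <= probe.detector_radius
    return (x - probe.separation) ** 2 + y**2 <= probe.detector_radius**2


def time_of_flight(path_length, n: float):
    """Time of flight t = L * n / c in ps, for path length in mm."""
    L = np.asarray(path_length, dtype=float)
    if np.any(L < 0):
        raise ValueError("path_length must be >= 0")
    out = L * n / C_MM_PER_PS
    return out[()] if out.ndim == 0 else out


@lru_cache(maxsize=32)
def _nee_cone_table(g: float, cos_cone: float, n_alpha: int = 1025,
                    n_theta: int = 48, n_phi: int = 96) -> np.ndarray:
    """Tabulate the HG probability mass inside the acceptance cone.

    ``I(cos alpha)`` is the probability that a Henyey-Greenstein
    deflection from a direction at angle alpha to the cone axis lands
    inside a cone of half-angle ``arccos(cos_cone)``; used by the local
    estimator in the transport kernel.
    """
    theta_c = np.arccos(cos_cone)
    ca = np.linspace(-1.0, 1.0, n_alpha)
    th = np.linspace(0.0, theta_c, n_theta)
    ph = np.linspace(0.0, 2.0 * np.pi, n_phi)
    sa = np.sqrt(1.0 - ca**2)
    # cos of the deflection angle between the incoming direction and a
    # cone direction (theta, phi) measured from the cone axis
    cg = (ca[:, None, None] * np.cos(th)[None, :, None]
          + sa[:, None, None] * np.sin(th)[None, :, None]
          * np.cos(ph)[None, None, :])
    if g == 0.0:
        p = np.full_like(cg, 1.0 / (4.0 * np.pi))
    else:
        p = (1.0 - g * g) / (4.0 * np.pi
                             * (1.0 + g * g - 2.0 * g * cg) ** 1.5)
    integrand = p * np.sin(th)[None, :, None]
    return np.ascontiguousarray(
        np.trapezoid(np.trapezoid(integrand, ph, axis=2), th, axis=1))


def _ring_area_correction(probe: ProbeGeometry) -> float:
    """Spot-to-annulus area ratio for ring-detector reweighting."""
    spot = np.pi * probe.detector_radius**2
    annulus = np.pi * (
        (probe.separation + probe.detector_radius) ** 2
        - (probe.separation - probe.detector_radius) ** 2
    )
    return spot / annulus


def run_white_mc(props: OpticalProperties, probe: ProbeGeometry,
                 config: SimConfig,
                 band: tuple[float, float] | None = None,
                 analog_ring: bool = False) -> WhiteRunResult:
    """Run a zero-absorption Monte Carlo simulation.

    The medium must have ``mua == 0`` (white MC); absorption is imposed
    later by reweighting.  Packets are launched from the source fiber
    until ``config.n_detected_target`` detection records accumulate or
    the launch budget runs out.  Packets whose time of flight reaches
    ``t_max`` are truncated.

    With ``config.ring_detector`` (the default) the variance-reduced
    estimator is used: detection on the azimuthal annulus of the
    detector's radial extent (exploiting cylindrical symmetry; spot/
    annulus area ratio recorded in ``area_correction``), deterministic
    Fresnel splitting at the boundary, weight roulette, and path-length
    roulette below ``config.depth_roulette_start``.  With ``False`` the
    analog reference estimator is used: physical detector spot,
    probabilistic reflection, unit packet weights, and exact weight
    conservation across detected/escaped/truncated (``analog_ring=True``
    swaps the spot for the azimuthal annulus while keeping the analog
    estimator — the intermediate rung of the validation ladder).

    ``band`` (variance-reduced estimator only) widens the radial
    collection annulus to [band[0], band[1]] mm; such a run is not a
    detector run itself but raw material for :func:`slice_white_run` /
    :func:`scale_white_run`, which recover physical-annulus runs at the
    run's own or any other mus' via the exact similarity of a
    non-absorbing half-space (all lengths scale as 1/mus).
    """
    if props.mua != 0:
        raise ValueError("white MC requires mua = 0; absorption is applied "
                         "by rescaling (see wmcfit.lut.rescale_to_mua)")
    target = config.n_detected_target
    max_launch = config.max_launch
    if max_launch is None:
        max_launch = int(min(2**62, 200_000 * target))

    l_max = config.t_max * C_MM_PER_PS / props.n
    bin_scale = props.n / (C_MM_PER_PS * config.bin_width)

    out_w = np.empty(target, dtype=np.float64)
    out_l = np.empty(target, dtype=np.float64)
    out_m = np.empty(target, dtype=np.int64)
    out_d = np.empty(target, dtype=np.float64)
    out_bin = np.empty(target, dtype=np.int64)
    out_r = np.empty(target, dtype=np.float64)

    if config.ring_detector:
        z_roul = config.depth_roulette_start
        z_roul = 1e30 if z_roul is None else z_roul
        if band is None:
            band_lo = probe.separation - probe.detector_radius
            band_hi = probe.separation + probe.detector_radius
        else:
            band_lo, band_hi = band
            if not 0 < band_lo < band_hi:
                raise ValueError("band must satisfy 0 < lo < hi")
        # fiber acceptance: sin(theta) <= NA outside -> in-medium cone
        # half-angle asin(NA / n) in both contact and immersed geometry
        cone_cos = float(np.sqrt(1.0 - (probe.detector_na / props.n) ** 2))
        nee_table = _nee_cone_table(props.g, cone_cos)
        if probe.immersion_depth == 0.0:
            r0 = ((props.n - probe.n_outside) / (props.n + probe.n_outside)) ** 2
            t_norm = 1.0 - r0
        else:
            t_norm = 1.0
        n_det, n_launch, escaped, truncated = _kernel.run_white_kernel(
            props.mus, props.g, props.n, probe.n_outside,
            probe.source_radius, np.cos(np.deg2rad(probe.source_half_angle)),
            band_lo, band_hi,
            probe.immersion_depth,
            l_max, z_roul, bin_scale, config.n_bins,
            nee_table, t_norm,
            target, max_launch, config.seed,
            out_w, out_l, out_m, out_d, out_bin, out_r,
        )
    else:
        if band is not None:
            raise ValueError("band collection requires the variance-reduced "
                             "estimator (ring_detector=True)")
        n_det, n_launch, escaped, truncated = _kernel.run_white_reference_kernel(
            props.mus, props.g, props.n, probe.n_outside,
            probe.source_radius, np.cos(np.deg2rad(probe.source_half_angle)),
            probe.detector_radius, probe.detector_na, probe.separation,
            probe.immersion_depth,
            l_max, bin_scale, config.n_bins,
            target, max_launch, analog_ring, config.seed,
            out_w, out_l, out_m, out_d, out_bin, out_r,
        )

    ring_like = config.ring_detector or analog_ring
    area = _ring_area_correction(probe) if ring_like else 1.0
    return WhiteRunResult(
        weight=out_w[:n_det].copy(),
        path_length=out_l[:n_det].copy(),
        n_scatter=out_m[:n_det].copy(),
        max_depth=out_d[:n_det].copy(),
        arrival_bin=out_bin[:n_det].copy(),
        exit_radius=out_r[:n_det].copy(),
        launched_weight=float(n_launch),
        escaped_weight=float(escaped),
        truncated_weight=float(truncated),
        area_correction=area,
        props=props,
        probe=probe,
        config=config,
        band=(float(band[0]), float(band[1])) if band is not None else None,
    )


def scale_white_run(base: WhiteRunResult, musp: float) -> WhiteRunResult:
    """Derive a physical-annulus white run at ``musp`` from a band run.

    In a non-absorbing half-space with fixed anisotropy and indices, the
    photon-path ensemble is exactly self-similar under a joint rescaling
    of the scattering coefficient and all lengths: a trajectory simulated
    at mus_base is a trajectory at mus_target with every length
    multiplied by k = mus_base / mus_target.  A record that exited at
    radius r therefore represents, at the target mus, a detection at
    radius k*r with path length k*L and maximum depth k*d.  This selects
    the records whose rescaled exit radius falls on the physical detector
    annulus and re-bins their rescaled flight times, yielding a white run
    statistically equivalent to a direct simulation at the target
    (the only approximation: source spot radius and any immersion depth
    are nominally rescaled by k as well; both are either zero or small
    compared to the fiber separation here).

    The base run must have been collected with a ``band`` covering the
    annulus divided by k; escaped/truncated bookkeeping does not survive
    slicing and is set to NaN.
    """
    if base.props.mua != 0:
        raise ValueError("base run must be a white (mua = 0) run")
    if musp <= 0:
        raise ValueError("musp must be > 0")
    k = base.props.musp / musp
    probe = base.probe
    lo = (probe.separation - probe.detector_radius) / k
    hi = (probe.separation + probe.detector_radius) / k
    if base.band is None:
        src_lo = probe.separation - probe.detector_radius
        src_hi = probe.separation + probe.detector_radius
    else:
        src_lo, src_hi = base.band
    if lo < src_lo - 1e-12 or hi > src_hi + 1e-12:
        raise ValueError(
            f"target musp {musp:g} needs base exit radii in [{lo:.3f}, "
            f"{hi:.3f}] mm, outside the collected band [{src_lo:g}, {src_hi:g}]")

    cfg = base.config
    l_max = cfg.t_max * C_MM_PER_PS / base.props.n
    bin_scale = base.props.n / (C_MM_PER_PS * cfg.bin_width)
    r_scaled = base.exit_radius * k
    l_scaled = base.path_length * k
    sel = (np.abs(r_scaled - probe.separation) <= probe.detector_radius) \
        & (l_scaled < l_max)
    props = OpticalProperties.from_musp(0.0, musp, g=base.props.g,
                                        n=base.props.n)
    return WhiteRunResult(
        weight=base.weight[sel].copy(),
        path_length=l_scaled[sel],
        n_scatter=base.n_scatter[sel].copy(),
        max_depth=base.max_depth[sel] * k,
        arrival_bin=(l_scaled[sel] * bin_scale).astype(np.int64),
        exit_radius=r_scaled[sel],
        launched_weight=base.launched_weight,
        escaped_weight=float("nan"),
        truncated_weight=float("nan"),
        area_correction=_ring_area_correction(probe),
        props=props,
        probe=probe,
        config=cfg,
        band=None,
    )


def slice_white_run(base: WhiteRunResult) -> WhiteRunResult:
    """Restrict a band run to the physical detector annulus at its own mus'."""
    return scale_white_run(base, base.props.musp)
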