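"""Numba inner loops for the white (zero-absorption) Monte Carlo run.

All geometry conventions live here: z is depth below the fiber-tip plane,
the medium extends to z = +inf.  In surface mode the medium boundary is
the tip plane itself (z = 0, outside medium above).  In immersed mode the
fibers sit ``immersion_depth`` below a liquid-air interface, so the liquid
also fills -immersion_depth < z < 0 and the tip plane is purely a
detection plane with no index step.

Two estimators are provided:

``run_white_kernel`` — variance-reduced production mode.  Detection uses
the local (next-event) estimator: at every scattering event close enough
to the surface (optical depth to it below ``_NEE_TAU_MAX``) and radially
inside the collection band [band_lo, band_hi], the expected weight
scattered into the fiber-acceptance cone and escaping without further
interaction is scored as a detection record,

    contribution = w * I_cone(cos alpha) * exp(-mus * z) * T_norm,

where I_cone is the Henyey-Greenstein probability mass inside the
acceptance cone around the surface normal given the pre-scatter
direction (precomputed table over cos alpha), exp(-mus z) the escape
probability, and T_norm the near-normal Fresnel transmission.  Actual
boundary transmissions are then all booked as escape (never scored, to
avoid double counting), the reflected weight fraction always continues
(deterministic splitting), with weight roulette and a depth roulette
that thins packets diving below ``z_roulette`` (they feed only the late
tail).  Unbiased in expectation; record weights are small and variable,
so statistical quality is measured by the effective sample size
(sum w)^2 / sum w^2, not the record count.  The exit radius is stored
per record so a wide band can later be sliced or similarity-rescaled to
the physical detector annulus.

``run_white_reference_kernel`` — analog reference mode: spot or ring
detection, probabilistic Fresnel reflection, no roulette.  One unit
weight per packet, exact weight conservation across the
detected/escaped/truncated categories.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - s * s) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def _fresnel(n1, n2, ci):
    """Unpolarized Fresnel reflectance for incidence cosine ci in medium n1."""
    if ci >= 1.0:
        r = (n1 - n2) / (n1 + n2)
        return r * r
    si = math.sqrt(1.0 - ci * ci)
    st = n1 / n2 * si
    if st >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st * st)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _scatter(g, ux, uy, uz):
    ct = _hg_cos(g, np.random.random())
    st = math.sqrt(1.0 - ct * ct)
    psi = 2.0 * math.pi * np.random.random()
    cp = math.cos(psi)
    sp = math.sin(psi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


_W_MIN = 1e-2          # weight-roulette threshold
_W_SURVIVE = 0.1       # survival probability of the weight roulette
_Z_STEP = 1.0          # mm between successive depth-roulette thresholds
_Z_SURVIVE = 0.5       # survival probability per depth threshold
_NEE_TAU_MAX = 6.0     # score scatters with optical depth mus*z below this
_NEE_THIN = 0.01       # roulette-thin records below this intrinsic contribution


@njit(cache=True, fastmath=True)
def run_white_kernel(
    mus, g, n_med, n_out,
    src_radius, cos_cone, band_lo, band_hi, immersion_depth,
    l_max, z_roulette, bin_scale, n_bins,
    nee_table, t_norm,
    target, max_launch, seed,
    out_w, out_l, out_m, out_d, out_bin, out_r,
):
    """Variance-reduced white run; see module docstring.

    Traces packets until ``target`` detection records or ``max_launch``
    launches.  Returns (n_detected, n_launched, escaped_w, truncated_w).
    ``bin_scale`` converts path length to bin index: bin = int(L*bin_scale);
    ``l_max`` is the path-length equivalent of the time-of-flight cutoff;
    depth roulette starts at ``z_roulette`` mm (>= huge disables).
    ``nee_table[i]`` tabulates the acceptance-cone HG mass I_cone on a
    uniform grid of cos(alpha) in [-1, 1]; ``t_norm`` is the near-normal
    boundary transmission factor applied to every scored record.
    """
    np.random.seed(seed)
    surface = immersion_depth == 0.0
    z_if = -immersion_depth
    z_nee_max = _NEE_TAU_MAX / mus
    band_lo2 = band_lo * band_lo
    band_hi2 = band_hi * band_hi
    n_tab = nee_table.size
    tab_scale = (n_tab - 1) / 2.0

    n_det = 0
    n_launch = 0
    escaped = 0.0
    truncated = 0.0

    while n_det < target and n_launch < max_launch:
        n_launch += 1
        r = src_radius * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        x = r * math.cos(phi)
        y = r * math.sin(phi)
        z = 0.0
        ct = 1.0 - (1.0 - cos_cone) * np.random.random()
        st = math.sqrt(1.0 - ct * ct)
        psi = 2.0 * math.pi * np.random.random()
        ux = st * math.cos(psi)
        uy = st * math.sin(psi)
        uz = ct
        w = 1.0
        L = 0.0
        M = 0
        dmax = 0.0
        next_z_roul = z_roulette
        alive = True

        while alive:
            s = -math.log(1.0 - np.random.random()) / mus
            while s > 0.0 and alive:
                z_new = z + uz * s
                if surface and z_new < 0.0:
                    s1 = (0.0 - z) / uz
                    L += s1
                    if L >= l_max:
                        truncated += w
                        alive = False
                        break
                    x += ux * s1
                    y += uy * s1
                    z = 0.0
                    ci = -uz
                    refl = _fresnel(n_med, n_out, ci)
                    # transmissions are all escape: cone exits are already
                    # accounted for by the local estimator at scatter time
                    escaped += w * (1.0 - refl)
                    w *= refl
                    if w < _W_MIN:
                        if np.random.random() < _W_SURVIVE:
                            w /= _W_SURVIVE
                        else:
                            escaped += w
                            alive = False
                            break
                    uz = -uz
                    s -= s1
                    continue
                elif (not surface) and uz < 0.0 and z > 0.0 and z_new < 0.0:
                    # crossing the detection (fiber-tip) plane from below:
                    # pass through; collection is scored at scatter events
                    s1 = (0.0 - z) / uz
                    L += s1
                    if L >= l_max:
                        truncated += w
                        alive = False
                        break
                    x += ux * s1
                    y += uy * s1
                    s -= s1
                    z = -1e-12
                    continue
                elif (not surface) and z_new < z_if:
                    # liquid-air interface above the fibers
                    s1 = (z_if - z) / uz
                    L += s1
                    if L >= l_max:
                        truncated += w
                        alive = False
                        break
                    x += ux * s1
                    y += uy * s1
                    z = z_if
                    ci = -uz
                    refl = _fresnel(n_med, n_out, ci)
                    escaped += w * (1.0 - refl)
                    w *= refl
                    if w < _W_MIN:
                        if np.random.random() < _W_SURVIVE:
                            w /= _W_SURVIVE
                        else:
                            escaped += w
                            alive = False
                            break
                    uz = -uz
                    s -= s1
                    continue
                else:
                    L += s
                    if L >= l_max:
                        truncated += w
                        alive = False
                        break
                    x += ux * s
                    y += uy * s
                    z = z_new
                    if z > dmax:
                        dmax = z
                        while dmax > next_z_roul and alive:
                            if np.random.random() < _Z_SURVIVE:
                                w /= _Z_SURVIVE
                                next_z_roul += _Z_STEP
                            else:
                                truncated += w
                                alive = False
                    s = 0.0
            if alive:
                # local estimator: expected weight scattered into the
                # acceptance cone and escaping directly from this event
                if 0.0 < z < z_nee_max:
                    r2 = x * x + y * y
                    if band_lo2 <= r2 <= band_hi2 and L + z < l_max:
                        ca = -uz
                        pos = (ca + 1.0) * tab_scale
                        i0 = int(pos)
                        if i0 >= n_tab - 1:
                            i0 = n_tab - 2
                        frac = pos - i0
                        icone = nee_table[i0] * (1.0 - frac) \
                            + nee_table[i0 + 1] * frac
                        c_rel = icone * math.exp(-mus * z) * t_norm
                        # roulette-thin tiny contributions to keep the
                        # record arrays compact (adds negligible variance)
                        if c_rel < _NEE_THIN:
                            if np.random.random() * _NEE_THIN < c_rel:
                                c_rel = _NEE_THIN
                            else:
                                c_rel = 0.0
                        if c_rel > 0.0:
                            b = int((L + z) * bin_scale)
                            if b < n_bins:
                                out_w[n_det] = w * c_rel
                                out_l[n_det] = L + z
                                out_m[n_det] = M + 1
                                out_d[n_det] = dmax
                                out_bin[n_det] = b
                                out_r[n_det] = math.sqrt(r2)
                                n_det += 1
                                if n_det >= target:
                                    alive = False
                ux, uy, uz = _scatter(g, ux, uy, uz)
                M += 1

    return n_det, n_launch, escaped, truncated


@njit(cache=True, fastmath=True)
def run_white_reference_kernel(
    mus, g, n_med, n_out,
    src_radius, cos_cone, det_radius, det_na, separation, immersion_depth,
    l_max, bin_scale, n_bins,
    target, max_launch, ring, seed,
    out_w, out_l, out_m, out_d, out_bin, out_r,
):
    """Analog estimator: probabilistic Fresnel, unit weights, no roulette."""
    np.random.seed(seed)
    surface = immersion_depth == 0.0
    z_if = -immersion_depth
    n_rel = n_med / n_out
    na_in_liquid = det_na / n_med

    n_det = 0
    n_launch = 0
    escaped = 0.0
    truncated = 0.0

    while n_det < target and n_launch < max_launch:
        n_launch += 1
        r = src_radius * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        x = r * math.cos(phi)
        y = r * math.sin(phi)
        z = 0.0
        ct = 1.0 - (1.0 - cos_cone) * np.random.random()
        st = math.sqrt(1.0 - ct * ct)
        psi = 2.0 * math.pi * np.random.random()
        ux = st * math.cos(psi)
        uy = st * math.sin(psi)
        uz = ct
        L = 0.0
        M = 0
        dmax = 0.0
        alive = True

        while alive:
            s = -math.log(1.0 - np.random.random()) / mus
            while s > 0.0 and alive:
                z_new = z + uz * s
                if surface and z_new < 0.0:
                    s1 = (0.0 - z) / uz
                    L += s1
                    if L >= l_max:
                        truncated += 1.0
                        alive = False
                        break
                    x += ux * s1
                    y += uy * s1
                    z = 0.0
                    ci = -uz
                    if np.random.random() < _fresnel(n_med, n_out, ci):
                        uz = -uz
                        s -= s1
                        continue
                    si = math.sqrt(max(0.0, 1.0 - ci * ci))
                    rr = math.sqrt(x * x + y * y)
                    if ring:
                        hit = abs(rr - separation) <= det_radius
                    else:
                        dx = x - separation
                        hit = dx * dx + y * y <= det_radius * det_radius
                    if hit and n_rel * si <= det_na:
                        b = int(L * bin_scale)
                        if b < n_bins:
                            out_w[n_det] = 1.0
                            out_l[n_det] = L
                            out_m[n_det] = M
                            out_d[n_det] = dmax
                            out_bin[n_det] = b
                            out_r[n_det] = rr
                            n_det += 1
                        else:
                            truncated += 1.0
                    else:
                        escaped += 1.0
                    alive = False
                    break
                elif (not surface) and uz < 0.0 and z > 0.0 and z_new < 0.0:
                    s1 = (0.0 - z) / uz
                    L += s1
                    if L >= l_max:
                        truncated += 1.0
                        alive = False
                        break
                    x += ux * s1
                    y += uy * s1
                    z = 0.0
                    rr = math.sqrt(x * x + y * y)
                    if ring:
                        hit = abs(rr - separation) <= det_radius
                    else:
                        dx = x - separation
                        hit = dx * dx + y * y <= det_radius * det_radius
                    sin_med = math.sqrt(max(0.0, 1.0 - uz * uz))
                    if hit and sin_med <= na_in_liquid:
                        b = int(L * bin_scale)
                        if b < n_bins:
                            out_w[n_det] = 1.0
                            out_l[n_det] = L
                            out_m[n_det] = M
                            out_d[n_det] = dmax
                            out_bin[n_det] = b
                            out_r[n_det] = rr
                            n_det += 1
                        else:
                            truncated += 1.0
                        alive = False
                        break
                    s -= s1
                    z = -1e-12
                    continue
                elif (not surface) and z_new < z_if:
                    s1 = (z_if - z) / uz
                    L += s1
                    if L >= l_max:
                        truncated += 1.0
                        alive = False
                        break
                    x += ux * s1
                    y += uy * s1
                    z = z_if
                    ci = -uz
                    if np.random.random() < _fresnel(n_med, n_out, ci):
                        uz = -uz
                        s -= s1
                        continue
                    escaped += 1.0
                    alive = False
                    break
                else:
                    L += s
                    if L >= l_max:
                        truncated += 1.0
                        alive = False
                        break
                    x += ux * s
                    y += uy * s
                    z = z_new
                    if z > dmax:
                        dmax = z
                    s = 0.0
            if alive:
                ux, uy, uz = _scatter(g, ux, uy, uz)
                M += 1

    return n_det, n_launch, escaped, truncated
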