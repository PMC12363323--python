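"""Numba kernels for droplet tracking in the idealized airway.

The geometry is consumed as sampled polyline arrays (points, unit tangents,
arc-length fractions, radii).  All kernels work in SI units and are
deterministic; droplet-level loops are serial so results are independent of
execution order.

Status codes used by the trackers:

* 0 -- airborne at the end of the simulated interval
* 1 -- trapped on the wall (arc-length fraction reported)
* 2 -- escaped through the nasopharyngeal outlet plane
* 3 -- escaped forward out of the nostril
* -1 -- non-finite state (integration failure)
"""

import numpy as np
from numba import njit

_SAFFMAN_K = 2.594  # Saffman-Mei constant in the generalized shear form
_WINDOW = 12        # local nearest-segment search half-width


@njit(cache=True)
def _locate(px, py, pz, P, hint):
    """Nearest point on the centerline polyline.

    Windowed search around ``hint`` with a global fallback when the best
    match sits on the window edge.  Returns (segment index, parameter along
    segment, distance, closest point xyz).
    """
    nseg = P.shape[0] - 1
    lo = hint - _WINDOW
    hi = hint + _WINDOW
    if lo < 0:
        lo = 0
    if hi > nseg - 1:
        hi = nseg - 1
    for _pass in range(2):
        best = 1e300
        ib = lo
        tb = 0.0
        bx = by = bz = 0.0
        for i in range(lo, hi + 1):
            ax = P[i, 0]
            ay = P[i, 1]
            az = P[i, 2]
            dx = P[i + 1, 0] - ax
            dy = P[i + 1, 1] - ay
            dz = P[i + 1, 2] - az
            seg2 = dx * dx + dy * dy + dz * dz
            t = ((px - ax) * dx + (py - ay) * dy + (pz - az) * dz) / seg2
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            cx = ax + t * dx
            cy = ay + t * dy
            cz = az + t * dz
            d2 = (px - cx) ** 2 + (py - cy) ** 2 + (pz - cz) ** 2
            if d2 < best:
                best = d2
                ib = i
                tb = t
                bx = cx
                by = cy
                bz = cz
        interior = (ib > lo or lo == 0) and (ib < hi or hi == nseg - 1)
        if interior or (lo == 0 and hi == nseg - 1):
            return ib, tb, np.sqrt(best), bx, by, bz
        lo = 0
        hi = nseg - 1
    return ib, tb, np.sqrt(best), bx, by, bz


@njit(cache=True)
def locate_point(p, P, T, S, R):
    """Arc-length fraction, radial distance and local radius at ``p``."""
    i, t, dist, _, _, _ = _locate(p[0], p[1], p[2], P, 0)
    s = S[i] * (1.0 - t) + S[i + 1] * t
    r = R[i] * (1.0 - t) + R[i + 1] * t
    return s, dist, r


@njit(cache=True)
def flow_velocity(p, P, T, S, R, q, out):
    """Quasi-1D parabolic air velocity at ``p``; returns False outside."""
    i, t, dist, _, _, _ = _locate(p[0], p[1], p[2], P, 0)
    r = R[i] * (1.0 - t) + R[i + 1] * t
    out[0] = 0.0
    out[1] = 0.0
    out[2] = 0.0
    if dist >= r:
        return False
    tx = T[i, 0] * (1.0 - t) + T[i + 1, 0] * t
    ty = T[i, 1] * (1.0 - t) + T[i + 1, 1] * t
    tz = T[i, 2] * (1.0 - t) + T[i + 1, 2] * t
    tn = np.sqrt(tx * tx + ty * ty + tz * tz)
    umax = 2.0 * q / (np.pi * r * r)
    mag = umax * (1.0 - (dist / r) ** 2)
    out[0] = mag * tx / tn
    out[1] = mag * ty / tn
    out[2] = mag * tz / tn
    return True


@njit(cache=True)
def _accel(
    px, py, pz, vx, vy, vz, tau, q, P, T, S, R,
    gx, gy, gz, lift_coeff, nu, hint,
):
    """Acceleration (drag + gravity + Saffman lift) at one droplet state.

    ``lift_coeff`` is 2*K*sqrt(nu)*rho_air / (rho_d * D); pass 0 to disable
    the lift force.  The local shear is the radial derivative of the
    parabolic axial profile, the dominant velocity-gradient component of the
    quasi-1D field.
    """
    i, t, dist, cx, cy, cz = _locate(px, py, pz, P, hint)
    r = R[i] * (1.0 - t) + R[i + 1] * t
    tx = T[i, 0] * (1.0 - t) + T[i + 1, 0] * t
    ty = T[i, 1] * (1.0 - t) + T[i + 1, 1] * t
    tz = T[i, 2] * (1.0 - t) + T[i + 1, 2] * t
    tn = np.sqrt(tx * tx + ty * ty + tz * tz)
    tx /= tn
    ty /= tn
    tz /= tn

    ux = uy = uz = 0.0
    dudrho = 0.0
    if dist < r:
        umax = 2.0 * q / (np.pi * r * r)
        mag = umax * (1.0 - (dist / r) ** 2)
        ux = mag * tx
        uy = mag * ty
        uz = mag * tz
        dudrho = -2.0 * umax * dist / (r * r)

    wx = ux - vx
    wy = uy - vy
    wz = uz - vz

    ax = wx / tau + gx
    ay = wy / tau + gy
    az = wz / tau + gz

    if lift_coeff != 0.0 and dudrho != 0.0 and dist > 1e-12:
        rhx = (px - cx) / dist
        rhy = (py - cy) / dist
        rhz = (pz - cz) / dist
        # deformation tensor d = 0.5*dudrho*(t (x) rh + rh (x) t)
        tw = tx * wx + ty * wy + tz * wz
        rw = rhx * wx + rhy * wy + rhz * wz
        mx = 0.5 * dudrho * (tx * rw + rhx * tw)
        my = 0.5 * dudrho * (ty * rw + rhy * tw)
        mz = 0.5 * dudrho * (tz * rw + rhz * tw)
        dnorm = (0.5 * dudrho * dudrho) ** 0.25  # (d:d)^(1/4)
        ax += lift_coeff * mx / dnorm
        ay += lift_coeff * my / dnorm
        az += lift_coeff * mz / dnorm
    return ax, ay, az, i


@njit(cache=True)
def _rk4_substep(
    px, py, pz, vx, vy, vz, h, tau, q, P, T, S, R,
    gx, gy, gz, lift_coeff, nu, hint,
):
    """One classical RK4 step of the droplet equation of motion."""
    a1x, a1y, a1z, h1 = _accel(
        px, py, pz, vx, vy, vz, tau, q, P, T, S, R, gx, gy, gz, lift_coeff, nu, hint
    )
    h2 = 0.5 * h
    p2x = px + h2 * vx
    p2y = py + h2 * vy
    p2z = pz + h2 * vz
    v2x = vx + h2 * a1x
    v2y = vy + h2 * a1y
    v2z = vz + h2 * a1z
    a2x, a2y, a2z, _ = _accel(
        p2x, p2y, p2z, v2x, v2y, v2z, tau, q, P, T, S, R, gx, gy, gz, lift_coeff, nu, h1
    )
    p3x = px + h2 * v2x
    p3y = py + h2 * v2y
    p3z = pz + h2 * v2z
    v3x = vx + h2 * a2x
    v3y = vy + h2 * a2y
    v3z = vz + h2 * a2z
    a3x, a3y, a3z, _ = _accel(
        p3x, p3y, p3z, v3x, v3y, v3z, tau, q, P, T, S, R, gx, gy, gz, lift_coeff, nu, h1
    )
    p4x = px + h * v3x
    p4y = py + h * v3y
    p4z = pz + h * v3z
    v4x = vx + h * a3x
    v4y = vy + h * a3y
    v4z = vz + h * a3z
    a4x, a4y, a4z, _ = _accel(
        p4x, p4y, p4z, v4x, v4y, v4z, tau, q, P, T, S, R, gx, gy, gz, lift_coeff, nu, h1
    )
    h6 = h / 6.0
    npx = px + h6 * (vx + 2.0 * v2x + 2.0 * v3x + v4x)
    npy = py + h6 * (vy + 2.0 * v2y + 2.0 * v3y + v4y)
    npz = pz + h6 * (vz + 2.0 * v2z + 2.0 * v3z + v4z)
    nvx = vx + h6 * (a1x + 2.0 * a2x + 2.0 * a3x + a4x)
    nvy = vy + h6 * (a1y + 2.0 * a2y + 2.0 * a3y + a4y)
    nvz = vz + h6 * (a1z + 2.0 * a2z + 2.0 * a3z + a4z)
    return npx, npy, npz, nvx, nvy, nvz, h1


@njit(cache=True)
def _wall_crossing_s(ax, ay, az, bx, by, bz, P, T, S, R, hint, tol):
    """Bisect the segment a->b for the first wall crossing; returns s there."""
    lo = 0.0
    hi = 1.0
    seg = np.sqrt((bx - ax) ** 2 + (by - ay) ** 2 + (bz - az) ** 2)
    if seg == 0.0:
        i, t, dist, _, _, _ = _locate(ax, ay, az, P, hint)
        return S[i] * (1.0 - t) + S[i + 1] * t
    for _ in range(60):
        if (hi - lo) * seg < tol:
            break
        mid = 0.5 * (lo + hi)
        mx = ax + mid * (bx - ax)
        my = ay + mid * (by - ay)
        mz = az + mid * (bz - az)
        i, t, dist, _, _, _ = _locate(mx, my, mz, P, hint)
        r = R[i] * (1.0 - t) + R[i + 1] * t
        if dist >= r:
            hi = mid
        else:
            lo = mid
    mx = ax + hi * (bx - ax)
    my = ay + hi * (by - ay)
    mz = az + hi * (bz - az)
    i, t, dist, _, _, _ = _locate(mx, my, mz, P, hint)
    return S[i] * (1.0 - t) + S[i + 1] * t


@njit(cache=True)
def track_one(
    p0, v0, tau, q, P, T, S, R, gx, gy, gz,
    lift_coeff, nu, dt, t_max, n_sub, wall_tol,
):
    """Track a single droplet until trapped, escaped, or ``t_max``.

    Returns (status, s_at_event, time, final position xyz, final velocity
    xyz).  The flow time step ``dt`` is divided into ``n_sub`` RK4
    sub-steps so the drag relaxation is resolved for small droplets.
    """
    px, py, pz = p0[0], p0[1], p0[2]
    vx, vy, vz = v0[0], v0[1], v0[2]

    i, t, dist, _, _, _ = _locate(px, py, pz, P, 0)
    hint = i
    r = R[i] * (1.0 - t) + R[i + 1] * t
    s_here = S[i] * (1.0 - t) + S[i + 1] * t
    if dist >= r:
        return 1, s_here, 0.0, px, py, pz, vx, vy, vz

    ex = P[-1, 0]
    ey = P[-1, 1]
    ez = P[-1, 2]
    etx = T[-1, 0]
    ety = T[-1, 1]
    etz = T[-1, 2]
    nx = P[0, 0]
    ny = P[0, 1]
    nz = P[0, 2]
    ntx = T[0, 0]
    nty = T[0, 1]
    ntz = T[0, 2]

    h = dt / n_sub
    nflow = int(np.ceil(t_max / dt))
    time = 0.0
    for _step in range(nflow):
        for _k in range(n_sub):
            opx, opy, opz = px, py, pz
            px, py, pz, vx, vy, vz, hint = _rk4_substep(
                px, py, pz, vx, vy, vz, h, tau, q, P, T, S, R,
                gx, gy, gz, lift_coeff, nu, hint,
            )
            time += h
            if not (
                np.isfinite(px) and np.isfinite(py) and np.isfinite(pz)
                and np.isfinite(vx) and np.isfinite(vy) and np.isfinite(vz)
            ):
                return -1, np.nan, time, px, py, pz, vx, vy, vz
            # outlet plane first: the posterior end is open
            if (px - ex) * etx + (py - ey) * ety + (pz - ez) * etz > 0.0:
                return 2, 1.0, time, px, py, pz, vx, vy, vz
            if (px - nx) * ntx + (py - ny) * nty + (pz - nz) * ntz < 0.0:
                return 3, 0.0, time, px, py, pz, vx, vy, vz
            i, t, dist, _, _, _ = _locate(px, py, pz, P, hint)
            hint = i
            r = R[i] * (1.0 - t) + R[i + 1] * t
            if dist >= r:
                s_hit = _wall_crossing_s(
                    opx, opy, opz, px, py, pz, P, T, S, R, hint, wall_tol
                )
                return 1, s_hit, time, px, py, pz, vx, vy, vz
    return 0, S[hint], t_max, px, py, pz, vx, vy, vz


@njit(cache=True)
def track_cluster(
    pos0, vel0, tau, q, P, T, S, R, gx, gy, gz,
    lift_coeff, nu, dt, t_max, n_sub, wall_tol,
):
    """Track a monodispersed droplet cluster; serial and order-independent."""
    n = pos0.shape[0]
    status = np.empty(n, dtype=np.int64)
    s_event = np.empty(n)
    t_event = np.empty(n)
    for j in range(n):
        st, s, tt, _, _, _, _, _, _ = track_one(
            pos0[j], vel0[j], tau, q, P, T, S, R, gx, gy, gz,
            lift_coeff, nu, dt, t_max, n_sub, wall_tol,
        )
        status[j] = st
        s_event[j] = s
        t_event[j] = tt
    return status, s_event, t_event
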