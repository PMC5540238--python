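"""Numba-compiled Euler–Maruyama kernels.

All kernels integrate the overdamped Langevin equations of an active
Brownian sphere: positions advance by propulsion + flow + translational
noise, orientations diffuse on the unit sphere via geodesic rotation
steps with 2D Gaussian tangent angles (norm-preserving; orientation
autocorrelation exp(-2 D_r t) accurate to O(dt^2)).

Propulsion is gated by the angle beta between the orientation vector and
the local up-gradient direction: V = V0_local * ((1 + cos beta)/2)^(p/2),
which is the gating law V0 cos(beta/2)^p written without trig calls.
In gated mode V0_local = min(v_cap, chi * |grad C|); in constant-speed
mode the particle self-propels at v_cap regardless of orientation.

The free-space kernel consumes pre-generated Gaussian noise passed in
chunks from the caller (NumPy's bit generators fill large arrays several
times faster than per-value draws inside compiled code); the dish and
capillary kernels, whose particles terminate early, draw their own.

Everything here is internal; the public surface lives in simulate.py,
capillary.py and friends.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .fields import FIELD_DIFFUSIVE_1D, FIELD_LINEAR, FIELD_NONE, FIELD_RADIAL_DISK


@njit(cache=True, inline="always")
def _field_eval(code, fp, x, y, z, t):
    """Return (C, gx, gy, gz) for the packed field description."""
    if code == FIELD_NONE:
        return 0.0, 0.0, 0.0, 0.0
    if code == FIELD_LINEAR:
        C0 = fp[0]
        g = fp[1]
        dx, dy, dz = fp[2], fp[3], fp[4]
        C = C0 + g * (x * dx + y * dy + z * dz)
        if C <= 0.0:
            return 0.0, 0.0, 0.0, 0.0
        return C, g * dx, g * dy, g * dz
    if code == FIELD_DIFFUSIVE_1D:
        C0 = fp[0]
        s0 = fp[1]
        dx, dy, dz = fp[2], fp[3], fp[4]
        Ds = fp[5]
        t0 = fp[6]
        if t <= t0:
            return 0.0, 0.0, 0.0, 0.0
        s = x * dx + y * dy + z * dz - s0
        if s <= 0.0:
            return C0, 0.0, 0.0, 0.0
        w = 2.0 * math.sqrt(Ds * (t - t0))
        xi = s / w
        C = C0 * math.erfc(xi)
        dCds = -C0 * 2.0 / math.sqrt(math.pi) * math.exp(-xi * xi) / w
        return C, dCds * dx, dCds * dy, dCds * dz
    # radial disk
    C0 = fp[0]
    a_s = fp[1]
    sx, sy = fp[2], fp[3]
    Ds = fp[5]
    t0 = fp[6]
    if t <= t0:
        return 0.0, 0.0, 0.0, 0.0
    ddx = x - sx
    ddy = y - sy
    rho = math.sqrt(ddx * ddx + ddy * ddy)
    if rho <= a_s:
        return C0, 0.0, 0.0, 0.0
    w = 2.0 * math.sqrt(Ds * (t - t0))
    xi = (rho - a_s) / w
    C = C0 * math.erfc(xi)
    dCdr = -C0 * 2.0 / math.sqrt(math.pi) * math.exp(-xi * xi) / w
    return C, dCdr * ddx / rho, dCdr * ddy / rho, 0.0


@njit(cache=True, inline="always")
def _gated_speed(gated, chi, v_cap, p_half, nx, ny, nz, gx, gy, gz):
    if not gated:
        return v_cap
    gm = math.sqrt(gx * gx + gy * gy + gz * gz)
    if gm <= 0.0:
        return 0.0
    v0 = chi * gm
    if v0 > v_cap:
        v0 = v_cap
    c = (nx * gx + ny * gy + nz * gz) / gm
    if c < -1.0:
        c = -1.0
    elif c > 1.0:
        c = 1.0
    return v0 * ((1.0 + c) * 0.5) ** p_half


@njit(cache=True, inline="always")
def _rotate_vals(nx, ny, nz, ex, ey, ez, sig_r):
    """Geodesic rotational-diffusion step from given Gaussian components."""
    dot = nx * ex + ny * ey + nz * ez
    wx = sig_r * (ex - dot * nx)
    wy = sig_r * (ey - dot * ny)
    wz = sig_r * (ez - dot * nz)
    theta = math.sqrt(wx * wx + wy * wy + wz * wz)
    if theta < 1e-14:
        return nx, ny, nz
    ct = math.cos(theta)
    st_over = math.sin(theta) / theta
    mx = nx * ct + wx * st_over
    my = ny * ct + wy * st_over
    mz = nz * ct + wz * st_over
    inv = 1.0 / math.sqrt(mx * mx + my * my + mz * mz)
    return mx * inv, my * inv, mz * inv


@njit(cache=True, inline="always")
def _rotate(nx, ny, nz, sig_r):
    ex = np.random.standard_normal()
    ey = np.random.standard_normal()
    ez = np.random.standard_normal()
    return _rotate_vals(nx, ny, nz, ex, ey, ez, sig_r)


@njit(cache=True, fastmath=True)
def step_free_chunk(x, y, z, nx, ny, nz, noise, t_chunk_start, dt,
                    sig_t, sig_r, fx, fy, fz, code, fp,
                    chi, v_cap, p_half, gated):
    """Advance all particles by ``noise.shape[0]`` steps, in place.

    ``noise`` has shape (steps, n, 6): translational (0..2) and
    rotational (3..5) standard-normal components.
    """
    csteps = noise.shape[0]
    n = x.shape[0]
    for s in range(csteps):
        t = t_chunk_start + s * dt
        for i in range(n):
            C, gx, gy, gz = _field_eval(code, fp, x[i], y[i], z[i], t)
            V = _gated_speed(gated, chi, v_cap, p_half,
                             nx[i], ny[i], nz[i], gx, gy, gz)
            x[i] += (V * nx[i] + fx) * dt + sig_t * noise[s, i, 0]
            y[i] += (V * ny[i] + fy) * dt + sig_t * noise[s, i, 1]
            z[i] += (V * nz[i] + fz) * dt + sig_t * noise[s, i, 2]
            nx[i], ny[i], nz[i] = _rotate_vals(
                nx[i], ny[i], nz[i],
                noise[s, i, 3], noise[s, i, 4], noise[s, i, 5], sig_r)


@njit(cache=True, fastmath=True)
def integrate_dish(pos0, ori0, n_steps, dt, sig_t, sig_r,
                   code, fp, chi, v_cap, p_half, gated,
                   dish_radius, rec_steps, seed):
    """2D dish with a reflecting circular wall; snapshots at given steps.

    Positions are in the dish plane; orientations remain 3D unit vectors
    (the vesicle tumbles in three dimensions, only its in-plane motion is
    followed).  ``rec_steps`` are the 1-based step indices at which the
    positions are stored.  Returns (n_particles, len(rec_steps), 2).
    """
    np.random.seed(seed)
    n = pos0.shape[0]
    P = np.empty((n, rec_steps.shape[0], 2))
    x = pos0[:, 0].copy()
    y = pos0[:, 1].copy()
    nx = ori0[:, 0].copy()
    ny = ori0[:, 1].copy()
    nz = ori0[:, 2].copy()
    rec = 0
    for s in range(1, n_steps + 1):
        t = (s - 1) * dt
        for i in range(n):
            C, gx, gy, gz = _field_eval(code, fp, x[i], y[i], 0.0, t)
            V = _gated_speed(gated, chi, v_cap, p_half,
                             nx[i], ny[i], nz[i], gx, gy, gz)
            x[i] += V * nx[i] * dt + sig_t * np.random.standard_normal()
            y[i] += V * ny[i] * dt + sig_t * np.random.standard_normal()
            rho = math.sqrt(x[i] * x[i] + y[i] * y[i])
            if rho > dish_radius:
                # radial mirror reflection at the wall
                new_rho = 2.0 * dish_radius - rho
                if new_rho < 0.0:
                    new_rho = 0.0
                x[i] *= new_rho / rho
                y[i] *= new_rho / rho
            nx[i], ny[i], nz[i] = _rotate(nx[i], ny[i], nz[i], sig_r)
        while rec < rec_steps.shape[0] and rec_steps[rec] == s:
            for i in range(n):
                P[i, rec, 0] = x[i]
                P[i, rec, 1] = y[i]
            rec += 1
    return P


@njit(cache=True, fastmath=True)
def integrate_capillary(y0, z0, n, dt, sig_t, sig_r,
                        vessel_radius, vessel_length, u_mean,
                        contact_radius, v_wall, p_half,
                        max_steps, seed):
    """Particles advected through a cylindrical vessel with sticky walls.

    Axis along x; Poiseuille profile u(rho) = 2 u_mean (1 - rho^2/a^2).
    The chemotactic gradient points radially outward with an effective
    wall propulsion speed ``v_wall`` gated by orientation.  A particle
    binds irreversibly when its centre comes within ``contact_radius`` of
    the wall, and exits when x >= vessel_length.

    Returns (fates, bind_x) where fate 1 = bound, 2 = exited (particles
    still in transit after ``max_steps`` are counted as exited).
    """
    np.random.seed(seed)
    fates = np.zeros(n, dtype=np.int64)
    bind_x = np.full(n, np.nan)
    a2 = vessel_radius * vessel_radius
    r_bind = vessel_radius - contact_radius
    for i in range(n):
        x = 0.0
        y = y0[i]
        z = z0[i]
        # random initial orientation
        nx = np.random.standard_normal()
        ny = np.random.standard_normal()
        nz = np.random.standard_normal()
        inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
        nx *= inv
        ny *= inv
        nz *= inv
        for s in range(max_steps):
            rho2 = y * y + z * z
            u = 2.0 * u_mean * (1.0 - rho2 / a2)
            if u < 0.0:
                u = 0.0
            rho = math.sqrt(rho2)
            if rho > 0.0:
                gy = y / rho
                gz = z / rho
                c = ny * gy + nz * gz
                if c < -1.0:
                    c = -1.0
                elif c > 1.0:
                    c = 1.0
                V = v_wall * ((1.0 + c) * 0.5) ** p_half
            else:
                V = 0.0
            x += (u + V * nx) * dt + sig_t * np.random.standard_normal()
            y += V * ny * dt + sig_t * np.random.standard_normal()
            z += V * nz * dt + sig_t * np.random.standard_normal()
            nx, ny, nz = _rotate(nx, ny, nz, sig_r)
            if y * y + z * z >= r_bind * r_bind:
                fates[i] = 1
                bind_x[i] = x
                break
            if x >= vessel_length:
                fates[i] = 2
                break
        if fates[i] == 0:
            fates[i] = 2
    return fates, bind_x
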