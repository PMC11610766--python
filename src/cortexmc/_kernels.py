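"""Numba kernels for voxel Monte Carlo photon transport.

Single-photon random walks on a labeled voxel grid:

* free paths sampled from the scattering coefficient of the current voxel's
  class (white mode) or from the total attenuation (analog mode);
* exact ray/voxel stepping with the remaining optical path rescaled by the
  coefficient ratio when the class changes across a face;
* Henyey-Greenstein scattering with the class anisotropy;
* unpolarized Fresnel reflection/refraction at the top and bottom faces and
  (optionally) at internal class interfaces, with total internal reflection;
* cyclic lateral boundaries;
* a counter-based per-photon RNG (splitmix64 seeded by (seed, photon id),
  xorshift64* stream), so photon ``i`` is identical regardless of how many
  photons are launched.

Geometry: the volume occupies ``[0, n*pitch)`` per axis, ``z`` increases
downward from the illuminated top face, photons launch at ``z = 0`` heading
in ``+z``.  Photons refracted out of the top face are detected; photons
leaving the bottom are lost.
"""
from __future__ import annotations

import math

import numba as nb
import numpy as np

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@nb.njit(nb.uint64(nb.uint64), cache=True, inline="always")
def _splitmix64(state):
    z = (state + nb.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = ((z ^ (z >> nb.uint64(30))) * nb.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> nb.uint64(27))) * nb.uint64(0x94D049BB133111EB)) & _MASK
    return z ^ (z >> nb.uint64(31))


@nb.njit(nb.uint64(nb.uint64, nb.uint64), cache=True)
def _stream_init(seed, photon_id):
    # two rounds of splitmix64 over (seed, id) decorrelate nearby ids
    s = _splitmix64(seed ^ (photon_id * nb.uint64(0x2545F4914F6CDD1D)))
    s = _splitmix64(s + photon_id)
    if s == nb.uint64(0):
        s = nb.uint64(0x106689D45497FDB5)
    return s


@nb.njit(nb.types.Tuple((nb.float64, nb.uint64))(nb.uint64), cache=True,
         inline="always")
def _next_uniform(state):
    # xorshift64* step; uniform in (0, 1]
    x = state
    x ^= x >> nb.uint64(12)
    x ^= (x << nb.uint64(25)) & _MASK
    x ^= x >> nb.uint64(27)
    val = ((x * nb.uint64(0x2545F4914F6CDD1D)) & _MASK) >> nb.uint64(11)
    return (np.float64(val) + 1.0) * (1.0 / 9007199254740992.0), x


@nb.njit(nb.float64(nb.float64, nb.float64, nb.float64), cache=True)
def fresnel_reflectance_kernel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance; 1 beyond the critical angle."""
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    eta = n1 / n2
    sin_t2 = eta * eta * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@nb.njit(nb.types.Tuple((nb.float64, nb.uint64))(nb.float64, nb.uint64),
         cache=True)
def hg_cosine(g, state):
    """Sample the Henyey-Greenstein deflection cosine."""
    xi, state = _next_uniform(state)
    if abs(g) < 1e-6:
        return 1.0 - 2.0 * xi, state
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct, state


@nb.njit(cache=True, inline="always")
def _scatter(ux, uy, uz, ct, phi):
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@nb.njit(cache=True)
def trace_photons(labels, coeff, g_arr, n_arr, absorb_prob, n_ambient,
                  pitch, n_photons, seed, max_path_mm, internal_mismatch,
                  specular_at_launch,
                  exit_x, exit_y, theta_x, theta_y, ppl, total_path):
    """Trace photons; returns (n_detected, n_bottom, n_cap, n_specular, n_absorbed).

    ``coeff[c]`` is the sampling coefficient of class ``c`` (mu_s in white
    mode, mu_t in analog mode); ``absorb_prob[c]`` is the per-interaction
    absorption probability (all zeros in white mode).  Detected-photon
    records are written into the preallocated output arrays.
    """
    nx, ny, nz = labels.shape
    lx = nx * pitch
    ly = ny * pitch
    n_det = 0
    n_bottom = 0
    n_cap = 0
    n_spec = 0
    n_abs = 0
    useed = nb.uint64(seed)

    for pid in range(n_photons):
        state = _stream_init(useed, nb.uint64(pid))
        xi, state = _next_uniform(state)
        x = lx * (1.0 - xi)
        xi, state = _next_uniform(state)
        y = ly * (1.0 - xi)
        z = 0.0
        ix = min(int(x / pitch), nx - 1)
        iy = min(int(y / pitch), ny - 1)
        iz = 0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        cls = labels[ix, iy, iz]
        if specular_at_launch:
            r_spec = fresnel_reflectance_kernel(n_ambient, n_arr[cls], 1.0)
            xi, state = _next_uniform(state)
            if xi <= r_spec:
                n_spec += 1
                continue
        for c in range(ppl.shape[1]):
            ppl[n_det, c] = 0.0

        xi, state = _next_uniform(state)
        s = -math.log(xi) / coeff[cls]
        path = 0.0
        alive = True
        while alive:
            # distance to the walls of the current voxel
            if ux > 1e-12:
                tx = ((ix + 1) * pitch - x) / ux
            elif ux < -1e-12:
                tx = (ix * pitch - x) / ux
            else:
                tx = 1e30
            if uy > 1e-12:
                ty = ((iy + 1) * pitch - y) / uy
            elif uy < -1e-12:
                ty = (iy * pitch - y) / uy
            else:
                ty = 1e30
            if uz > 1e-12:
                tz = ((iz + 1) * pitch - z) / uz
            elif uz < -1e-12:
                tz = (iz * pitch - z) / uz
            else:
                tz = 1e30
            tx = max(tx, 0.0)
            ty = max(ty, 0.0)
            tz = max(tz, 0.0)
            tb = tx
            axis = 0
            if ty < tb:
                tb = ty
                axis = 1
            if tz < tb:
                tb = tz
                axis = 2

            if s <= tb:
                # interaction inside the voxel
                x += ux * s
                y += uy * s
                z += uz * s
                ppl[n_det, cls] += s
                path += s
                if path > max_path_mm:
                    n_cap += 1
                    alive = False
                    break
                if absorb_prob[cls] > 0.0:
                    xi, state = _next_uniform(state)
                    if xi <= absorb_prob[cls]:
                        n_abs += 1
                        alive = False
                        break
                ct, state = hg_cosine(g_arr[cls], state)
                xi, state = _next_uniform(state)
                ux, uy, uz = _scatter(ux, uy, uz, ct, 2.0 * math.pi * xi)
                xi, state = _next_uniform(state)
                s = -math.log(xi) / coeff[cls]
                continue

            # advance to the voxel face
            x += ux * tb
            y += uy * tb
            z += uz * tb
            ppl[n_det, cls] += tb
            path += tb
            s -= tb
            if path > max_path_mm:
                n_cap += 1
                alive = False
                break

            if axis == 2:
                if uz < 0.0 and iz == 0:
                    # top face: escape into ambient or reflect back
                    cos_i = -uz
                    r = fresnel_reflectance_kernel(n_arr[cls], n_ambient, cos_i)
                    xi, state = _next_uniform(state)
                    if xi <= r:
                        uz = -uz
                        z = 0.0
                        continue
                    eta = n_arr[cls] / n_ambient
                    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
                    cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                    utx = eta * ux
                    uty = eta * uy
                    # wrap the exit position into the top face
                    ex = x % lx
                    ey = y % ly
                    exit_x[n_det] = ex
                    exit_y[n_det] = ey
                    theta_x[n_det] = math.atan2(utx, cos_t)
                    theta_y[n_det] = math.atan2(uty, cos_t)
                    total_path[n_det] = path
                    n_det += 1
                    alive = False
                    break
                if uz > 0.0 and iz == nz - 1:
                    # bottom face: transmitted photons are lost
                    cos_i = uz
                    r = fresnel_reflectance_kernel(n_arr[cls], n_ambient, cos_i)
                    xi, state = _next_uniform(state)
                    if xi <= r:
                        uz = -uz
                        z = nz * pitch
                        continue
                    n_bottom += 1
                    alive = False
                    break

            # neighbour voxel (cyclic laterally)
            jx, jy, jz = ix, iy, iz
            if axis == 0:
                if ux > 0.0:
                    jx += 1
                    if jx == nx:
                        jx = 0
                        x -= lx
                else:
                    jx -= 1
                    if jx < 0:
                        jx = nx - 1
                        x += lx
            elif axis == 1:
                if uy > 0.0:
                    jy += 1
                    if jy == ny:
                        jy = 0
                        y -= ly
                else:
                    jy -= 1
                    if jy < 0:
                        jy = ny - 1
                        y += ly
            else:
                jz += 1 if uz > 0.0 else -1

            new_cls = labels[jx, jy, jz]
            if new_cls != cls:
                if internal_mismatch and n_arr[new_cls] != n_arr[cls]:
                    if axis == 0:
                        cos_i = abs(ux)
                    elif axis == 1:
                        cos_i = abs(uy)
                    else:
                        cos_i = abs(uz)
                    r = fresnel_reflectance_kernel(
                        n_arr[cls], n_arr[new_cls], cos_i)
                    xi, state = _next_uniform(state)
                    if xi <= r:
                        # specular bounce off the interface: stay in voxel
                        if axis == 0:
                            ux = -ux
                        elif axis == 1:
                            uy = -uy
                        else:
                            uz = -uz
                        continue
                    eta = n_arr[cls] / n_arr[new_cls]
                    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
                    cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                    if axis == 0:
                        sgn = 1.0 if ux > 0.0 else -1.0
                        ux, uy, uz = sgn * cos_t, eta * uy, eta * uz
                    elif axis == 1:
                        sgn = 1.0 if uy > 0.0 else -1.0
                        ux, uy, uz = eta * ux, sgn * cos_t, eta * uz
                    else:
                        sgn = 1.0 if uz > 0.0 else -1.0
                        ux, uy, uz = eta * ux, eta * uy, sgn * cos_t
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                # remaining optical path is conserved across the interface
                s *= coeff[cls] / coeff[new_cls]
                cls = new_cls
            ix, iy, iz = jx, jy, jz

    return n_det, n_bottom, n_cap, n_spec, n_abs
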