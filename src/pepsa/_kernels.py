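"""Compiled inner loop for energy/force evaluation.

The numba kernel mirrors the vectorized numpy implementation in
:mod:`pepsa.forcefield` term for term; a unit test asserts the two
backends agree to machine precision.  All arrays are packed by
:class:`~pepsa.forcefield.EnergySystem` at compile time.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def energy_forces_kernel(
    x,
    f,
    bond_i, bond_j, bond_kc, bond_r0,
    ang_i, ang_j, ang_k, ang_kc, ang_t0,
    dih_i, dih_j, dih_k, dih_l, dih_v2, dih_n, dih_g,
    nb_i, nb_j, nb_qq, nb_rs, nb_ep,
    s14_i, s14_j, s14_qq, s14_rs, s14_ep,
    inv_ee14, inv_vdw14,
    cutoff2,
    res_idx, res_anchor, res_k,
):
    e_bond = 0.0
    for b in range(len(bond_i)):
        i, j = bond_i[b], bond_j[b]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e_bond += bond_kc[b] * dr * dr
        fm = -2.0 * bond_kc[b] * dr / r
        f[i, 0] += fm * dx
        f[i, 1] += fm * dy
        f[i, 2] += fm * dz
        f[j, 0] -= fm * dx
        f[j, 1] -= fm * dy
        f[j, 2] -= fm * dz

    e_angle = 0.0
    for a in range(len(ang_i)):
        i, j, k = ang_i[a], ang_j[a], ang_k[a]
        ux, uy, uz = x[i, 0] - x[j, 0], x[i, 1] - x[j, 1], x[i, 2] - x[j, 2]
        vx, vy, vz = x[k, 0] - x[j, 0], x[k, 1] - x[j, 1], x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        dt = theta - ang_t0[a]
        e_angle += ang_kc[a] * dt * dt
        st = np.sqrt(max(1.0 - ct * ct, 1e-12))
        dedt = 2.0 * ang_kc[a] * dt
        inv_nu2 = 1.0 / (nu * nu)
        inv_nv2 = 1.0 / (nv * nv)
        inv_nunv = 1.0 / (nu * nv)
        gix = (ct * ux * inv_nu2 - vx * inv_nunv) / st
        giy = (ct * uy * inv_nu2 - vy * inv_nunv) / st
        giz = (ct * uz * inv_nu2 - vz * inv_nunv) / st
        gkx = (ct * vx * inv_nv2 - ux * inv_nunv) / st
        gky = (ct * vy * inv_nv2 - uy * inv_nunv) / st
        gkz = (ct * vz * inv_nv2 - uz * inv_nunv) / st
        f[i, 0] -= dedt * gix
        f[i, 1] -= dedt * giy
        f[i, 2] -= dedt * giz
        f[k, 0] -= dedt * gkx
        f[k, 1] -= dedt * gky
        f[k, 2] -= dedt * gkz
        f[j, 0] += dedt * (gix + gkx)
        f[j, 1] += dedt * (giy + gky)
        f[j, 2] += dedt * (giz + gkz)

    e_dih = 0.0
    for d in range(len(dih_i)):
        i, j, k, l = dih_i[d], dih_j[d], dih_k[d], dih_l[d]
        b1x, b1y, b1z = x[j, 0] - x[i, 0], x[j, 1] - x[i, 1], x[j, 2] - x[i, 2]
        b2x, b2y, b2z = x[k, 0] - x[j, 0], x[k, 1] - x[j, 1], x[k, 2] - x[j, 2]
        b3x, b3y, b3z = x[l, 0] - x[k, 0], x[l, 1] - x[k, 1], x[l, 2] - x[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        m1x = (n1y * b2z - n1z * b2y) / nb2
        m1y = (n1z * b2x - n1x * b2z) / nb2
        m1z = (n1x * b2y - n1y * b2x) / nb2
        cosp = n1x * n2x + n1y * n2y + n1z * n2z
        sinp = m1x * n2x + m1y * n2y + m1z * n2z
        phi = np.arctan2(sinp, cosp)
        arg = dih_n[d] * phi - dih_g[d]
        e_dih += dih_v2[d] * (1.0 + np.cos(arg))
        dedphi = -dih_v2[d] * dih_n[d] * np.sin(arg)
        sq1 = n1x * n1x + n1y * n1y + n1z * n1z
        sq2 = n2x * n2x + n2y * n2y + n2z * n2z
        c1 = nb2 / sq1
        c2 = nb2 / sq2
        gix, giy, giz = c1 * n1x, c1 * n1y, c1 * n1z
        glx, gly, glz = -c2 * n2x, -c2 * n2y, -c2 * n2z
        inv_nb22 = 1.0 / (nb2 * nb2)
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) * inv_nb22
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) * inv_nb22
        gjx = -(1.0 + c12) * gix + c32 * glx
        gjy = -(1.0 + c12) * giy + c32 * gly
        gjz = -(1.0 + c12) * giz + c32 * glz
        gkx = c12 * gix - (1.0 + c32) * glx
        gky = c12 * giy - (1.0 + c32) * gly
        gkz = c12 * giz - (1.0 + c32) * glz
        f[i, 0] -= dedphi * gix
        f[i, 1] -= dedphi * giy
        f[i, 2] -= dedphi * giz
        f[j, 0] -= dedphi * gjx
        f[j, 1] -= dedphi * gjy
        f[j, 2] -= dedphi * gjz
        f[k, 0] -= dedphi * gkx
        f[k, 1] -= dedphi * gky
        f[k, 2] -= dedphi * gkz
        f[l, 0] -= dedphi * glx
        f[l, 1] -= dedphi * gly
        f[l, 2] -= dedphi * glz

    e_lj = 0.0
    e_coul = 0.0
    for p in range(len(nb_i)):
        i, j = nb_i[p], nb_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cutoff2:
            continue
        inv_r2 = 1.0 / r2
        rs2 = nb_rs[p] * nb_rs[p]
        s6 = (rs2 * inv_r2) ** 3
        lj = nb_ep[p] * (s6 * s6 - 2.0 * s6)
        coul = nb_qq[p] * inv_r2
        e_lj += lj
        e_coul += coul
        dlj = nb_ep[p] * (-12.0 * s6 * s6 + 12.0 * s6) * inv_r2
        dcoul = -2.0 * coul * inv_r2
        fm = -(dlj + dcoul)
        f[i, 0] += fm * dx
        f[i, 1] += fm * dy
        f[i, 2] += fm * dz
        f[j, 0] -= fm * dx
        f[j, 1] -= fm * dy
        f[j, 2] -= fm * dz

    for p in range(len(s14_i)):
        i, j = s14_i[p], s14_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        inv_r2 = 1.0 / r2
        rs2 = s14_rs[p] * s14_rs[p]
        s6 = (rs2 * inv_r2) ** 3
        lj = s14_ep[p] * (s6 * s6 - 2.0 * s6) * inv_vdw14
        coul = s14_qq[p] * inv_r2 * inv_ee14
        e_lj += lj
        e_coul += coul
        dlj = s14_ep[p] * (-12.0 * s6 * s6 + 12.0 * s6) * inv_r2 * inv_vdw14
        dcoul = -2.0 * coul * inv_r2
        fm = -(dlj + dcoul)
        f[i, 0] += fm * dx
        f[i, 1] += fm * dy
        f[i, 2] += fm * dz
        f[j, 0] -= fm * dx
        f[j, 1] -= fm * dy
        f[j, 2] -= fm * dz

    e_res = 0.0
    for r in range(len(res_idx)):
        i = res_idx[r]
        dx = x[i, 0] - res_anchor[r, 0]
        dy = x[i, 1] - res_anchor[r, 1]
        dz = x[i, 2] - res_anchor[r, 2]
        e_res += res_k * (dx * dx + dy * dy + dz * dz)
        f[i, 0] -= 2.0 * res_k * dx
        f[i, 1] -= 2.0 * res_k * dy
        f[i, 2] -= 2.0 * res_k * dz

    return e_bond, e_angle, e_dih, e_lj, e_coul, e_res
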