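"""Numba-compiled core of the reduced-kinematics state evaluation.

The equilibrium solvers evaluate the kinematic state tens of thousands of
times per heart beat; the arrays involved are tiny (a few hundred material
points), so vectorized numpy spends most of its time in per-call overhead.
This kernel performs the full evaluation — shell geometry, meridional
volume remap, stretches, strain energy and the analytic gradients for all
three generalized coordinates — in explicit loops compiled by numba.

See :meth:`lvcomp.tissue.ReducedLVMechanics._eval` for the mathematical
definition of the kinematic family.
"""

import numpy as np
from numba import njit

__all__ = ["eval_state", "tension_kernel"]


@njit(cache=True, fastmath=False)
def eval_state(V, a, b,
               xi, l0, r0, v0_enc, V0, L, w_t,
               b1_ref, b2_ref, P_ref, dPref_dc,
               sin_phi, ds0, dV0,
               cos2a, sin2a, sincosa,
               c1, c2, c3, c4, q_clip,
               cpr_init):
    nl = xi.shape[0]
    ns = sin_phi.shape[0]
    lam_c = np.empty((nl, ns))
    lam_m = np.empty((nl, ns))
    lam_t = np.empty((nl, ns))
    lam_f = np.empty((nl, ns))
    dlf = np.empty((3, nl, ns))
    cpr_out = np.empty((nl, ns))
    dU3 = np.zeros(3)
    U = 0.0
    ok = True

    dl = np.empty(3)
    dlp = np.empty(3)
    dr = np.empty(3)
    drp = np.empty(3)
    db1 = np.empty(3)
    db2 = np.empty(3)
    dcp = np.empty(3)
    dsp = np.empty(3)

    two_pi = 2.0 * np.pi
    for i in range(nl):
        v = V + (v0_enc[i] - V0)
        l = a * L + b * xi[i] * w_t
        lp = b * w_t
        r = np.sqrt(3.0 * v / (two_pi * l))
        A = b2_ref[i] + 2.0 * b1_ref[i]
        rp = (A - lp * r * r) / (2.0 * l * r)
        if rp <= 0.0:
            ok = False
            break
        dl[0] = 0.0
        dl[1] = L
        dl[2] = xi[i] * w_t
        dlp[0] = 0.0
        dlp[1] = 0.0
        dlp[2] = w_t
        dr[0] = r / (2.0 * v)
        dr[1] = -(r / (2.0 * l)) * L
        dr[2] = -(r / (2.0 * l)) * dl[2]
        for x in range(3):
            drp[x] = (-(dlp[x] * r * r + 2.0 * lp * r * dr[x])
                      / (2.0 * l * r)
                      - rp * (dl[x] * r + l * dr[x]) / (l * r))
            db1[x] = dl[x] * r * rp + l * dr[x] * rp + l * r * drp[x]
            db2[x] = dlp[x] * r * r + 2.0 * lp * r * dr[x]
        b1 = l * r * rp
        b2 = lp * r * r
        b13 = b1 - b2
        b2p2b1 = b2 + 2.0 * b1

        c2a = cos2a[i]
        s2a = sin2a[i]
        sca = sincosa[i]

        for j in range(ns):
            # meridional remap: monotone cubic, Newton from the warm start
            c = cpr_init[i, j]
            target = P_ref[i, j]
            for _ in range(80):
                P = b13 * c * c * c - 3.0 * b1 * c + b2p2b1
                Pd = 3.0 * b13 * c * c - 3.0 * b1
                step = (P - target) / Pd
                c -= step
                if c < 0.0:
                    c = 0.0
                elif c > 1.0:
                    c = 1.0
                if abs(step) < 1e-13:
                    break
            cpr_out[i, j] = c
            s2 = 1.0 - c * c
            if s2 < 1e-30:
                s2 = 1e-30
            spr = np.sqrt(s2)
            Pd = 3.0 * b13 * c * c - 3.0 * b1
            f1 = c * c * c - 3.0 * c + 2.0
            f2 = 1.0 - c * c * c
            for x in range(3):
                dcp[x] = -(db1[x] * f1 + db2[x] * f2) / Pd
                dsp[x] = -c / spr * dcp[x]

            den = r0[i] * sin_phi[j]
            lc = r * spr / den
            M = np.sqrt(r * r * c * c + l * l * s2)
            lm = M * sin_phi[j] * dPref_dc[i, j] / (spr * Pd * ds0[i, j])
            lt = 1.0 / (lc * lm)
            lam_c[i, j] = lc
            lam_m[i, j] = lm
            lam_t[i, j] = lt

            e_c = 0.5 * (lc * lc - 1.0)
            e_m = 0.5 * (lm * lm - 1.0)
            e_t = 0.5 * (lt * lt - 1.0)
            e11 = e_c * c2a + e_m * s2a
            e22 = e_c * s2a + e_m * c2a
            e12 = (e_m - e_c) * sca
            q = (c2 * e11 * e11 + c3 * (e22 * e22 + e_t * e_t)
                 + 2.0 * c4 * e12 * e12)
            clipped = q > q_clip
            if clipped:
                q = q_clip
            expq = np.exp(q)
            w = 0.5 * c1 * (expq - 1.0)
            U += w * dV0[i, j]

            lf = np.sqrt(lc * lc * c2a + lm * lm * s2a)
            lam_f[i, j] = lf

            for x in range(3):
                dlc_x = (dr[x] * spr + r * dsp[x]) / den
                dM_x = (r * dr[x] * c * c + r * r * c * dcp[x]
                        + l * dl[x] * s2 + l * l * spr * dsp[x]) / M
                dPd_x = (3.0 * (db1[x] - db2[x]) * c * c
                         + 6.0 * b13 * c * dcp[x] - 3.0 * db1[x])
                dlm_x = lm * (dM_x / M - dsp[x] / spr - dPd_x / Pd)
                dlt_x = -lt * (dlc_x / lc + dlm_x / lm)
                dlf[x, i, j] = (lc * c2a * dlc_x + lm * s2a * dlm_x) / lf
                if not clipped:
                    dec = lc * dlc_x
                    dem = lm * dlm_x
                    det = lt * dlt_x
                    de11 = dec * c2a + dem * s2a
                    de22 = dec * s2a + dem * c2a
                    de12 = (dem - dec) * sca
                    dq = (2.0 * c2 * e11 * de11
                          + 2.0 * c3 * (e22 * de22 + e_t * det)
                          + 4.0 * c4 * e12 * de12)
                    dU3[x] += 0.5 * c1 * expq * dq * dV0[i, j]

    return ok, U, dU3, lam_f, dlf, lam_c, lam_m, lam_t, cpr_out


@njit(cache=True)
def tension_kernel(lam_f, lam_f_ed, q_fm, f_xb,
                   lam_sarc_ed, strain_coupling, lam_lo, lam_hi,
                   t_ref, beta_len, fm_a, velocity_dependence):
    """Active fiber tension field T_a = T_ref·g(Q)·h(λ_cell)·f_xb."""
    nl, ns = lam_f.shape
    ta = np.empty((nl, ns))
    for i in range(nl):
        for j in range(ns):
            lam_cell = lam_sarc_ed * (
                1.0 + strain_coupling * (lam_f[i, j] / lam_f_ed[i, j] - 1.0))
            if lam_cell < lam_lo:
                lam_cell = lam_lo
            elif lam_cell > lam_hi:
                lam_cell = lam_hi
            h = 1.0 + beta_len * (lam_cell - 1.0)
            if h < 0.0:
                h = 0.0
            if velocity_dependence:
                q = q_fm[i, j]
                if q < 0.0:
                    g = (1.0 + fm_a * q) / (1.0 - q)
                else:
                    g = (1.0 + (2.0 + fm_a) * q) / (1.0 + q)
                if g < 0.0:
                    g = 0.0
            else:
                g = 1.0
            ta[i, j] = t_ref * g * h * f_xb
    return ta
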