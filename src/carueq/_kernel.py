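"""Numba integration kernel for the CaRU lattice.

One call advances the lattice through a prescribed sequence of time steps,
performing per step: (a) stochastic Markov channel-count updates at frozen
voltage and calcium (sub-stepped so every exit probability stays below the
step bound), (b) an exact exponential substep for the stiff dyadic
compartment with closed-form integrated fluxes, and (c) an explicit-Euler
update of the remaining compartments, buffers and inter-CaRU Laplacians.

Mass balance is exact by construction: every flux increment is applied with
equal magnitude and opposite sign (after volume referral) to its two
compartments, and the returned ΔQ integrals are the same sums that entered
the concentration updates.

Channel populations are stored as per-CaRU state counts; transitions are
sampled with exact binomial/conditional-binomial draws (channels within a
CaRU are exchangeable, so this is distributionally identical to per-channel
first-order sampling).

Status codes: 0 ok, 1 negative/non-finite concentration (dt instability),
2 Markov step bound violated.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---- packed-parameter vector layout ------------------------------------- #
(
    IP_VD_VI, IP_VS_VI, IP_VD_VS, IP_VD_VJSR, IP_VI_VNSR, IP_VJSR_VI, IP_VNSR_VI,
    IP_ITAUD, IP_ITAUS, IP_ITAUTR,
    IP_GREL,
    IP_NUUP, IP_IKI2, IP_IKSR2,           # SERCA: 1/K_i², 1/K_sr²
    IP_BCSQ, IP_KCSQ,
    IP_DI_DX2, IP_DI_DY2, IP_DI_DZ2,      # D_i / h² per axis
    IP_DS_DX2, IP_DS_DY2,                 # D_s (z blocked)
    IP_DSR_DX2, IP_DSR_DY2, IP_DSR_DZ2,
    IP_GLCC, IP_GCLOSE, IP_KINL, IP_KINL_K2, IP_RREC, IP_LI12, IP_LI21,
    IP_LI2C2, IP_LC2I2,
    IP_RNUO, IP_RKO, IP_RNO, IP_RKLUMN, IP_RNLUM, IP_RKCLOSE, IP_RNUI, IP_RKIN2,
    IP_RKTERM, IP_RTHETA, IP_RI1O, IP_RI12, IP_RI21, IP_RI2C,
    IP_PBOUND,
    NP_PARAMS,
) = range(49)


def pack_params(params) -> np.ndarray:
    """Pack a ModelParams into the kernel's flat float64 vector."""
    p = np.zeros(NP_PARAMS)
    p[IP_VD_VI] = params.v_d / params.v_i
    p[IP_VS_VI] = params.v_s / params.v_i
    p[IP_VD_VS] = params.v_d / params.v_s
    p[IP_VD_VJSR] = params.v_d / params.v_jsr
    p[IP_VI_VNSR] = params.v_i / params.v_nsr
    p[IP_VJSR_VI] = params.v_jsr / params.v_i
    p[IP_VNSR_VI] = params.v_nsr / params.v_i
    p[IP_ITAUD] = 1.0 / params.tau_d
    p[IP_ITAUS] = 1.0 / params.tau_s
    p[IP_ITAUTR] = 1.0 / params.tau_tr
    p[IP_GREL] = params.g_rel
    p[IP_NUUP] = params.nu_up
    p[IP_IKI2] = 1.0 / params.K_i**2
    p[IP_IKSR2] = 1.0 / params.K_sr**2
    p[IP_BCSQ] = params.B_CSQ
    p[IP_KCSQ] = params.K_CSQ
    p[IP_DI_DX2] = params.D_i / params.dx**2
    p[IP_DI_DY2] = params.D_i / params.dy**2
    p[IP_DI_DZ2] = params.D_i / params.dz**2
    p[IP_DS_DX2] = params.D_s / params.dx**2
    p[IP_DS_DY2] = params.D_s / params.dy**2
    p[IP_DSR_DX2] = params.D_sr / params.dx**2
    p[IP_DSR_DY2] = params.D_sr / params.dy**2
    p[IP_DSR_DZ2] = params.D_sr / params.dz**2
    lcc = params.lcc_params
    p[IP_GLCC] = lcc.g_lcc
    p[IP_GCLOSE] = lcc.g_close
    p[IP_KINL] = lcc.k_inact_max
    p[IP_KINL_K2] = lcc.K_inact**2
    p[IP_RREC] = lcc.r_recover
    p[IP_LI12] = lcc.k_i12
    p[IP_LI21] = lcc.k_i21
    p[IP_LI2C2] = lcc.k_i2c2
    p[IP_LC2I2] = lcc.k_c2i2
    ryr = params.ryr_params
    p[IP_RNUO] = ryr.nu_open_max
    p[IP_RKO] = ryr.K_open**ryr.n_open  # K^n, precomputed
    p[IP_RNO] = ryr.n_open
    p[IP_RKLUMN] = ryr.K_lum**ryr.n_lum  # K^n, precomputed
    p[IP_RNLUM] = ryr.n_lum
    p[IP_RKCLOSE] = ryr.k_close
    p[IP_RNUI] = ryr.nu_inact_max
    p[IP_RKIN2] = ryr.K_inact**2
    p[IP_RKTERM] = ryr.K_term
    p[IP_RTHETA] = ryr.theta_term
    p[IP_RI1O] = ryr.k_i1o
    p[IP_RI12] = ryr.k_i12
    p[IP_RI21] = ryr.k_i21
    p[IP_RI2C] = ryr.k_i2c
    from .params import MARKOV_STEP_BOUND

    p[IP_PBOUND] = MARKOV_STEP_BOUND
    return p


N_TRACE_COLS = 9  # ci, cs, cd, csr_free, csr_tot, J_lcc, J_ncx_out, J_ryr, J_up


@njit(cache=False, inline="always", fastmath=True)
def _binom(n, p):
    """Exact Binomial(n, p) sample for small p (one uniform on the fast path)."""
    if n <= 0 or p <= 0.0:
        return 0
    u = np.random.random()
    if u < 1.0 - n * p:  # 1 - np is a lower bound on P(K = 0)
        return 0
    q = math.exp(n * math.log1p(-p))
    if u < q:
        return 0
    c = q
    k = 0
    r = p / (1.0 - p)
    pk = q
    while k < n:
        k += 1
        pk *= r * (n - k + 1) / k
        c += pk
        if u < c:
            return k
    return n


@njit(cache=False, inline="always", fastmath=True)
def _csq_free(ct, b_csq, k_csq):
    bb = k_csq + b_csq - ct
    v = 0.5 * (-bb + math.sqrt(bb * bb + 4.0 * k_csq * ct))
    return v if v > 0.0 else 0.0


@njit(cache=False, fastmath=True)
def advance(
    cd, cs, ci, cnsr, cjt, buf,
    lcc, ryr, nbr,
    P, buf_bt, buf_kon, buf_koff, buf_comp,
    dts, nsubs,
    alphas, betas, fvs, rrecs, ki2c2s, a1s, a2s, ncx_b1s, ncx_b2s,
    rec_idx, traces,
    seed,
):
    """Advance the lattice through len(dts) steps.  Returns
    (status, dq_in, dq_out, dq_rel, dq_up) with ΔQ in μmol/Lcyt."""
    np.random.seed(seed)
    n = cd.shape[0]
    nb = buf_bt.shape[0]
    n_steps = dts.shape[0]

    cs2 = np.empty(n)
    ci2 = np.empty(n)
    cnsr2 = np.empty(n)

    vd_vi = P[IP_VD_VI]
    vs_vi = P[IP_VS_VI]
    vd_vs = P[IP_VD_VS]
    vd_vjsr = P[IP_VD_VJSR]
    vi_vnsr = P[IP_VI_VNSR]
    itaud = P[IP_ITAUD]
    itaus = P[IP_ITAUS]
    itautr = P[IP_ITAUTR]
    grel = P[IP_GREL]
    nuup = P[IP_NUUP]
    iki2 = P[IP_IKI2]
    iksr2 = P[IP_IKSR2]
    bcsq = P[IP_BCSQ]
    kcsq = P[IP_KCSQ]
    pbound = P[IP_PBOUND]
    glcc = P[IP_GLCC]

    kinl = P[IP_KINL]
    kinl_k2 = P[IP_KINL_K2]
    rno = P[IP_RNO]
    rnlum = P[IP_RNLUM]
    rnuo = P[IP_RNUO]
    rko = P[IP_RKO]
    rklumn = P[IP_RKLUMN]
    rnui = P[IP_RNUI]
    rkin2 = P[IP_RKIN2]
    rtheta = P[IP_RTHETA]
    rkterm = P[IP_RKTERM]
    vjsr_vi = P[IP_VJSR_VI]
    vnsr_vi = P[IP_VNSR_VI]
    di_dx2 = P[IP_DI_DX2]
    di_dy2 = P[IP_DI_DY2]
    di_dz2 = P[IP_DI_DZ2]
    ds_dx2 = P[IP_DS_DX2]
    ds_dy2 = P[IP_DS_DY2]
    dsr_dx2 = P[IP_DSR_DX2]
    dsr_dy2 = P[IP_DSR_DY2]
    dsr_dz2 = P[IP_DSR_DZ2]

    acc_in = 0.0
    acc_out = 0.0
    acc_rel = 0.0
    acc_up = 0.0
    ri = 0
    status = 0

    for k in range(n_steps):
        dt = dts[k]
        nsub = nsubs[k]
        dtm = dt / nsub
        alpha = alphas[k]
        beta = betas[k]
        fv = fvs[k]
        rrec = rrecs[k]
        ki2c2 = ki2c2s[k]
        a1 = a1s[k]
        a2 = a2s[k]
        ncx_b1 = ncx_b1s[k]
        ncx_b2 = ncx_b2s[k]

        s_in = 0.0
        s_out = 0.0
        s_rel = 0.0
        s_up = 0.0
        s_ci = 0.0
        s_cs = 0.0
        s_cd = 0.0
        s_csr = 0.0
        s_csrt = 0.0

        do_rec = ri < rec_idx.shape[0] and rec_idx[ri] == k

        # per-(sub)step constant transition probabilities
        p_oc = P[IP_RKCLOSE] * dtm
        i1m_oc = 1.0 / (1.0 - p_oc)
        p_ri1o = P[IP_RI1O] * dtm
        p_ri12c = P[IP_RI12] * dtm / (1.0 - p_ri1o)
        p_ri21 = P[IP_RI21] * dtm
        p_ri2c = P[IP_RI2C] * dtm / (1.0 - p_ri21)
        p_ogc = P[IP_GCLOSE] * dtm
        i1m_ogc = 1.0 / (1.0 - p_ogc)
        p_f = fv * dtm
        p_beta_c = beta * dtm / (1.0 - p_f)
        p_alpha = alpha * dtm
        p_c2i2c = P[IP_LC2I2] * dtm / (1.0 - p_alpha)
        p_rrec = rrec * dtm
        p_li12c = P[IP_LI12] * dtm / (1.0 - p_rrec)
        p_li21 = P[IP_LI21] * dtm
        p_i2c2c = ki2c2 * dtm / (1.0 - p_li21)
        bad_c1 = (fv + beta) * dtm >= pbound

        for i in range(n):
            cd0 = cd[i]
            cs0 = cs[i]
            ci0 = ci[i]
            cnsr0 = cnsr[i]
            cjt0 = cjt[i]
            cjsr = _csq_free(cjt0, bcsq, kcsq)

            # ---- channel rates at frozen (V, c) ---------------------- #
            cd2 = cd0 * cd0
            k_inact_l = kinl * cd2 / (cd2 + kinl_k2)
            if rno == 3.0:
                cdn = cd2 * cd0
            elif rno == 2.0:
                cdn = cd2
            else:
                cdn = cd0 ** rno
            cj2 = cjsr * cjsr
            if rnlum == 4.0:
                cjn = cj2 * cj2
            elif rnlum == 2.0:
                cjn = cj2
            else:
                cjn = cjsr ** rnlum
            kon_r = rnuo * cdn / (cdn + rko) * cjn / (cjn + rklumn)
            kin_r = (
                rnui
                * cd2 / (cd2 + rkin2)
                * (1.0 + rtheta * rkterm / (cjsr + rkterm))
            )

            # ---- Markov sub-steps ------------------------------------ #
            lO = lcc[0, i]
            lC1 = lcc[1, i]
            lC2 = lcc[2, i]
            lI1 = lcc[3, i]
            lI2 = lcc[4, i]
            rO = ryr[0, i]
            rC = ryr[1, i]
            rI1 = ryr[2, i]
            rI2 = ryr[3, i]

            p_co = kon_r * dtm
            p_oi = kin_r * dtm
            p_oic = p_oi * i1m_oc
            p_oin = k_inact_l * dtm
            p_oinc = p_oin * i1m_ogc
            if (rC > 0 and p_co >= pbound) or (
                rO > 0 and p_oc + p_oi >= pbound
            ):
                status = 2
            if lO > 0 and p_ogc + p_oin >= pbound:
                status = 2
            if lC1 > 0 and bad_c1:
                status = 2
            for _ in range(nsub):
                # RyR: C->O; O->C, O->I1; I1->O, I1->I2; I2->I1, I2->C
                a = _binom(rC, p_co)
                b1 = _binom(rO, p_oc)
                b2 = _binom(rO - b1, p_oic)
                c1 = _binom(rI1, p_ri1o)
                c2 = _binom(rI1 - c1, p_ri12c)
                d1 = _binom(rI2, p_ri21)
                d2 = _binom(rI2 - d1, p_ri2c)
                rO += a + c1 - b1 - b2
                rC += b1 + d2 - a
                rI1 += b2 + d1 - c1 - c2
                rI2 += c2 - d1 - d2

                # LCC: O->C1/I1; C1->O/C2; C2->C1/I2; I1->O/I2; I2->I1/C2
                e1_ = _binom(lO, p_ogc)
                e2_ = _binom(lO - e1_, p_oinc)
                f1 = _binom(lC1, p_f)
                f2 = _binom(lC1 - f1, p_beta_c)
                g1 = _binom(lC2, p_alpha)
                g2 = _binom(lC2 - g1, p_c2i2c)
                h1 = _binom(lI1, p_rrec)
                h2 = _binom(lI1 - h1, p_li12c)
                m1 = _binom(lI2, p_li21)
                m2 = _binom(lI2 - m1, p_i2c2c)
                lO += f1 + h1 - e1_ - e2_
                lC1 += e1_ + g1 - f1 - f2
                lC2 += f2 + m2 - g1 - g2
                lI1 += e2_ + m1 - h1 - h2
                lI2 += g2 + h2 - m1 - m2

            lcc[0, i] = lO
            lcc[1, i] = lC1
            lcc[2, i] = lC2
            lcc[3, i] = lI1
            lcc[4, i] = lI2
            ryr[0, i] = rO
            ryr[1, i] = rC
            ryr[2, i] = rI1
            ryr[3, i] = rI2

            # ---- dyad: exact exponential substep --------------------- #
            gro = grel * rO
            glo = glcc * lO
            lam = gro + itaud + glo * a1
            A = gro * cjsr + cs0 * itaud + glo * a2
            ceq = A / lam
            em = math.exp(-lam * dt)
            i_cd = ceq * dt + (cd0 - ceq) * (1.0 - em) / lam
            i_ryr = gro * (cjsr * dt - i_cd)
            i_lcc = glo * (a2 * dt - a1 * i_cd)
            i_ds = (i_cd - cs0 * dt) * itaud
            cd[i] = cd0 + i_ryr + i_lcc - i_ds

            # ---- deterministic fluxes -------------------------------- #
            x2 = ci0 * ci0 * iki2
            y2 = cnsr0 * cnsr0 * iksr2
            j_up = nuup * (x2 - y2) / (1.0 + x2 + y2)
            j_tr = (cnsr0 - cjsr) * itautr

            # ---- Laplacians (old fields) ----------------------------- #
            n0 = nbr[i, 0]
            n1 = nbr[i, 1]
            n2 = nbr[i, 2]
            n3 = nbr[i, 3]
            n4 = nbr[i, 4]
            n5 = nbr[i, 5]
            lap_i = (
                di_dx2 * (ci[n0] + ci[n1] - 2.0 * ci0)
                + di_dy2 * (ci[n2] + ci[n3] - 2.0 * ci0)
                + di_dz2 * (ci[n4] + ci[n5] - 2.0 * ci0)
            )
            lap_s = ds_dx2 * (cs[n0] + cs[n1] - 2.0 * cs0) + ds_dy2 * (
                cs[n2] + cs[n3] - 2.0 * cs0
            )
            lap_n = (
                dsr_dx2 * (cnsr[n0] + cnsr[n1] - 2.0 * cnsr0)
                + dsr_dy2 * (cnsr[n2] + cnsr[n3] - 2.0 * cnsr0)
                + dsr_dz2 * (cnsr[n4] + cnsr[n5] - 2.0 * cnsr0)
            )

            # ---- subsarcolemma: exact exponential substep ------------- #
            # NCX and the cs->ci relaxation are linear in cs; frozen-source
            # exponential update with closed-form integrated fluxes keeps
            # the scheme stable at the coarse step and mass-exact.
            lam_s = itaus + ncx_b2
            a_src = ncx_b1 + ci0 * itaus + vd_vs * i_ds / dt + lap_s
            ceq_s = a_src / lam_s
            em_s = math.exp(-lam_s * dt)
            i_cs = ceq_s * dt + (cs0 - ceq_s) * (1.0 - em_s) / lam_s
            i_ncx = ncx_b1 * dt - ncx_b2 * i_cs
            i_si = (i_cs - ci0 * dt) * itaus

            # ---- transport updates ----------------------------------- #
            cs_p = cs0 + i_ncx - i_si + vd_vs * i_ds + dt * lap_s
            ci_p = ci0 + dt * (-j_up + lap_i) + vs_vi * i_si

            # ---- semi-implicit buffer exchange ------------------------ #
            # Backward-Euler bound-calcium update against the post-transport
            # free concentration (scalar Newton, monotone); the increment is
            # applied with opposite sign to the free pool, so the exchange
            # conserves mass exactly regardless of Newton residual.
            for comp_code in range(2):
                c_p = ci_p if comp_code == 0 else cs_p
                has = False
                for b in range(nb):
                    if buf_comp[b] == comp_code:
                        has = True
                if not has:
                    continue
                c = c_p if c_p > 0.0 else 0.0
                for _ in range(2):
                    resid = c - c_p
                    dres = 1.0
                    for b in range(nb):
                        if buf_comp[b] != comp_code:
                            continue
                        iden = 1.0 / (1.0 + dt * (buf_kon[b] * c + buf_koff[b]))
                        bn = (buf[b, i] + dt * buf_kon[b] * c * buf_bt[b]) * iden
                        resid += bn - buf[b, i]
                        dres += dt * buf_kon[b] * (buf_bt[b] - bn) * iden
                    c -= resid / dres
                    if c < 0.0:
                        c = 0.0
                dtot = 0.0
                for b in range(nb):
                    if buf_comp[b] != comp_code:
                        continue
                    iden = 1.0 / (1.0 + dt * (buf_kon[b] * c + buf_koff[b]))
                    bn = (buf[b, i] + dt * buf_kon[b] * c * buf_bt[b]) * iden
                    dtot += bn - buf[b, i]
                    buf[b, i] = bn
                if comp_code == 0:
                    ci_p = ci_p - dtot
                else:
                    cs_p = cs_p - dtot

            cs2[i] = cs_p
            ci2[i] = ci_p
            cnsr2[i] = cnsr0 + dt * (-j_tr + vi_vnsr * j_up + lap_n)
            cjt[i] = cjt0 + dt * j_tr - vd_vjsr * i_ryr

            ok = (
                cs2[i] >= 0.0 and ci2[i] >= 0.0 and cnsr2[i] >= 0.0
                and cjt[i] >= 0.0 and cd[i] >= 0.0
                and cs2[i] == cs2[i] and ci2[i] == ci2[i]
                and cnsr2[i] == cnsr2[i] and cjt[i] == cjt[i]
            )
            if not ok:
                status = 1

            s_in += i_lcc
            s_out -= i_ncx
            s_rel += i_ryr
            s_up += dt * j_up
            if do_rec:
                s_ci += ci0
                s_cs += cs0
                s_cd += cd0
                s_csr += vjsr_vi * cjsr + vnsr_vi * cnsr0
                s_csrt += vjsr_vi * cjt0 + vnsr_vi * cnsr0

        for i in range(n):
            cs[i] = cs2[i]
            ci[i] = ci2[i]
            cnsr[i] = cnsr2[i]

        acc_in += s_in
        acc_out += s_out
        acc_rel += s_rel
        acc_up += s_up

        if do_rec:
            traces[ri, 0] = s_ci / n
            traces[ri, 1] = s_cs / n
            traces[ri, 2] = s_cd / n
            traces[ri, 3] = s_csr / n
            traces[ri, 4] = s_csrt / n
            traces[ri, 5] = s_in / dt / n * vd_vi
            traces[ri, 6] = s_out / dt / n * vs_vi
            traces[ri, 7] = s_rel / dt / n * vd_vi
            traces[ri, 8] = s_up / dt / n
            ri += 1

        if status != 0:
            return status, 0.0, 0.0, 0.0, 0.0

    dq_in = acc_in * vd_vi / n
    dq_out = acc_out * vs_vi / n
    dq_rel = acc_rel * vd_vi / n
    dq_up = acc_up / n
    return status, dq_in, dq_out, dq_rel, dq_up
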