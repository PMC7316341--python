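"""Deterministic flux laws of the CaRU lattice.

Sign conventions: every flux is expressed in μM/ms in the volume of the
compartment it is "defined in" (the compartment whose rate equation carries
it without a volume-ratio prefactor):

===========  =======================  ==========================================
flux         defined in               positive direction
===========  =======================  ==========================================
j_LCC        dyad (d)                 calcium entry into the dyad
j_RyR        dyad (d)                 release jSR → dyad
j_ds         dyad (d)                 dyad → subsarcolemma (down-gradient)
j_NCX        subsarcolemma (s)        calcium entry (reverse mode); forward
                                      extrusion is negative
j_si         subsarcolemma (s)        subsarcolemma → cytosol
j_SrCa       cytosol (i)              SERCA uptake cytosol → network SR
j_tr         junctional SR (jsr)      network SR → junctional SR
===========  =======================  ==========================================

All functions are pure, accept scalars or numpy arrays, and are continuous on
their admissible domains (the removable singularity of the GHK driving force
at V = 0 is handled explicitly).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "serca_flux",
    "ryr_flux",
    "ncx_flux",
    "lcc_driving_terms",
    "lcc_current",
    "intra_caru_diffusion",
    "build_neighbor_table",
    "lattice_laplacian",
    "buffer_kinetics",
    "csq_free_from_total",
    "FRT",
]

#: F/RT at 37 °C, mV⁻¹.
FRT = 1.0 / 26.712


def serca_flux(c_i, c_nsr, nu_up: float, K_i: float, K_sr: float):
    """Thermodynamically limited SERCA uptake, μM/ms (cytosol-referred).

    j = ν_up·[(c_i/K_i)² − (c_nsr/K_sr)²] / [1 + (c_i/K_i)² + (c_nsr/K_sr)²].
    Positive (forward pumping) iff (c_i/K_i)² > (c_nsr/K_sr)²; magnitude is
    strictly below ν_up, and the flux is odd under (c_i/K_i) ↔ (c_nsr/K_sr).
    """
    x2 = (np.asarray(c_i, dtype=float) / K_i) ** 2
    y2 = (np.asarray(c_nsr, dtype=float) / K_sr) ** 2
    out = nu_up * (x2 - y2) / (1.0 + x2 + y2)
    return out if out.ndim else float(out)


def ryr_flux(c_jsr, c_d, O_RyR, g_rel: float):
    """Diffusive RyR release, μM/ms in the dyad: g_rel·O_RyR·(c_jsr − c_d)."""
    out = g_rel * np.asarray(O_RyR, dtype=float) * (
        np.asarray(c_jsr, dtype=float) - np.asarray(c_d, dtype=float)
    )
    return out if out.ndim else float(out)


def ncx_flux(c_s, V, Na_i: float, Na_o: float, Ca_o: float, ncx) -> float:
    """Electrogenic 3Na⁺:1Ca²⁺ exchange, μM/ms in the subsarcolemma.

    Standard saturating closed form
    j = v_NCX·(e^{ηVF/RT}·Na_i³·Ca_o − e^{(η−1)VF/RT}·Na_o³·c_s)
        / [(K_mNa³ + Na_o³)(K_mCa + Ca_o)(1 + k_sat·e^{(η−1)VF/RT})].

    Positive values are calcium entry (reverse mode); at diastolic voltage
    and physiological c_s the exchanger extrudes (negative).  ``c_s`` in μM,
    sodium and Ca_o in mM.
    """
    cs_mM = np.asarray(c_s, dtype=float) * 1e-3
    e1 = np.exp(ncx.eta * np.asarray(V, dtype=float) * FRT)
    e2 = np.exp((ncx.eta - 1.0) * np.asarray(V, dtype=float) * FRT)
    num = e1 * Na_i**3 * Ca_o - e2 * Na_o**3 * cs_mM
    den = (ncx.K_mNa**3 + Na_o**3) * (ncx.K_mCa + Ca_o) * (1.0 + ncx.k_sat * e2)
    out = ncx.v_ncx * num / den
    return out if np.ndim(out) else float(out)


def lcc_driving_terms(V, Ca_o: float, gamma_o: float = 0.341):
    """GHK driving-force coefficients (a1, a2) such that the unitary influx is
    g_lcc·(a2 − a1·c_d), with c_d in μM and Ca_o in mM.

    a1 = γ·u·eᵘ/(eᵘ − 1), a2 = γ·u·Ca_o[μM]/(eᵘ − 1) with u = 2VF/RT and the
    same divalent activity coefficient γ on both faces of the membrane; the
    removable singularity at V = 0 is evaluated by series (u/(eᵘ−1) → 1 − u/2 + …).
    """
    u = 2.0 * np.asarray(V, dtype=float) * FRT
    ca_o_uM = Ca_o * 1e3
    small = np.abs(u) < 1e-4
    us = np.where(small, 1.0, u)  # avoid 0/0 in the vector branch
    em1 = np.expm1(us)
    a1 = np.where(small, 1.0 + u / 2.0 + u * u / 12.0, us * np.exp(us) / em1) * gamma_o
    a2 = np.where(small, (1.0 - u / 2.0 + u * u / 12.0), us / em1) * gamma_o * ca_o_uM
    if np.ndim(V) == 0:
        return float(a1), float(a2)
    return a1, a2


def lcc_current(V, c_d, Ca_o: float, n_open, lcc) -> float:
    """Calcium influx through open LCCs, μM/ms in the dyad.

    Proportional to the open count; inward (positive) at plateau voltages
    with physiological extracellular calcium.
    """
    a1, a2 = lcc_driving_terms(V, Ca_o, lcc.gamma_o)
    out = lcc.g_lcc * np.asarray(n_open, dtype=float) * (
        a2 - a1 * np.asarray(c_d, dtype=float)
    )
    return out if np.ndim(out) else float(out)


def intra_caru_diffusion(c_d, c_s, c_i, c_nsr, c_jsr, tau_d, tau_s, tau_tr):
    """Linear intra-CaRU relaxation fluxes (j_ds, j_si, j_tr).

    j_ds = (c_d − c_s)/τ_d, j_si = (c_s − c_i)/τ_s, j_tr = (c_nsr − c_jsr)/τ_tr;
    each is antisymmetric under swapping its two compartments.
    """
    j_ds = (np.asarray(c_d, dtype=float) - c_s) / tau_d
    j_si = (np.asarray(c_s, dtype=float) - c_i) / tau_s
    j_tr = (np.asarray(c_nsr, dtype=float) - c_jsr) / tau_tr
    if np.ndim(c_d) == 0 and np.ndim(c_s) == 0 and np.ndim(c_nsr) == 0:
        return float(j_ds), float(j_si), float(j_tr)
    return j_ds, j_si, j_tr


# ---------------------------------------------------------------------- #
# lattice diffusion


def build_neighbor_table(nx: int, ny: int, nz: int) -> np.ndarray:
    """(N, 6) flat-index neighbor table (x−, x+, y−, y+, z−, z+).

    No-flux (reflecting) boundaries are encoded by pointing a missing
    neighbor back at the cell itself, which zeroes its second-difference
    contribution.  Flat index = (ix*ny + iy)*nz + iz.
    """
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    nbr = np.empty((nx * ny * nz, 6), dtype=np.int64)
    for a, (axis, sign) in enumerate(
        [(0, -1), (0, +1), (1, -1), (1, +1), (2, -1), (2, +1)]
    ):
        shifted = idx.copy()
        if sign < 0:
            sl = [slice(None)] * 3
            sl[axis] = slice(1, None)
            tgt = [slice(None)] * 3
            tgt[axis] = slice(0, -1)
            shifted[tuple(sl)] = idx[tuple(tgt)]
        else:
            sl = [slice(None)] * 3
            sl[axis] = slice(0, -1)
            tgt = [slice(None)] * 3
            tgt[axis] = slice(1, None)
            shifted[tuple(sl)] = idx[tuple(tgt)]
        nbr[:, a] = shifted.ravel()
    return nbr


def lattice_laplacian(
    field: np.ndarray,
    D: float,
    nbr: np.ndarray,
    dx: float,
    dy: float,
    dz: float,
    z_blocked: bool = False,
) -> np.ndarray:
    """D·∇² with anisotropic spacing and reflecting boundaries, μM/ms.

    ``z_blocked=True`` suppresses z-coupling (the subsarcolemmal shell does
    not exist across z-planes).  The volume-weighted lattice sum of the
    output is zero: every pair term appears antisymmetrically.
    """
    f = np.asarray(field, dtype=float).ravel()
    out = (f[nbr[:, 0]] + f[nbr[:, 1]] - 2.0 * f) / dx**2
    out += (f[nbr[:, 2]] + f[nbr[:, 3]] - 2.0 * f) / dy**2
    if not z_blocked:
        out += (f[nbr[:, 4]] + f[nbr[:, 5]] - 2.0 * f) / dz**2
    return D * out


# ---------------------------------------------------------------------- #
# buffers


def buffer_kinetics(c_free, bound, B_total: float, k_on: float, k_off: float):
    """Mass-action buffer kinetics.

    Returns (dc_free/dt contribution, dbound/dt) with
    dbound/dt = k_on·c_free·(B_total − bound) − k_off·bound and the free
    contribution equal and opposite, so the pair conserves mass exactly.
    """
    db = k_on * np.asarray(c_free, dtype=float) * (
        B_total - np.asarray(bound, dtype=float)
    ) - k_off * np.asarray(bound, dtype=float)
    if np.ndim(c_free) == 0 and np.ndim(bound) == 0:
        return -float(db), float(db)
    return -db, db


def csq_free_from_total(c_jsr_tot, B_CSQ: float, K_CSQ: float):
    """Free jSR calcium from total via the calsequestrin rapid-buffer quadratic.

    c_jsr = ½[c_tot − (K + B) + √((K + B − c_tot)² + 4K·c_tot)].
    Monotone increasing in c_tot, bounded above by the identity, and exactly
    inverts c_tot = c + c·B/(c + K).
    """
    ct = np.asarray(c_jsr_tot, dtype=float)
    b = K_CSQ + B_CSQ - ct
    out = 0.5 * (-b + np.sqrt(b * b + 4.0 * K_CSQ * ct))
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)
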