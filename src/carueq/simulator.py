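"""Voltage-clamped pacing of the full CaRU lattice.

A beat begins at stimulus onset; "diastolic" (pre-systolic) values are read
at beat start.  The integrator uses a fine step ``params.dt`` during the
systolic/release window ``[0, t_fine)`` of each beat and the coarser
``params.dt_diastole`` afterwards, with the Markov update sub-stepped at the
fine dt so channel exit probabilities always respect the step bound.

Per-beat integrated fluxes (ΔQ_in, ΔQ_out, ΔQ_rel, ΔQ_up, μmol/Lcyt) are
accumulated step-by-step inside the kernel and exactly match the discrete
mass increments, so ΔQ_T = ΔQ_in − ΔQ_out and ΔQ_SR = ΔQ_up − ΔQ_rel hold to
rounding per beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .channels import lcc_rates, ryr_rates, stationary_distribution
from .fluxes import FRT, build_neighbor_table, csq_free_from_total, lcc_driving_terms
from .pacing import APClamp, ap_waveform
from .params import (
    CellState,
    ModelParams,
    sr_calcium,
    total_cell_calcium,
)

__all__ = [
    "APClamp",
    "ap_waveform",
    "BeatRecord",
    "step",
    "run_beat",
    "run_paced",
    "init_from_diastolic",
]

#: trace sampling interval, ms
RECORD_EVERY_MS = 1.0

# analysis-grid range accepted by init_from_diastolic (generous physiological
# bounds around the default 50–400 nM × 10–80 μmol/Lcyt grids)
CI0_RANGE_UM = (0.005, 3.0)
CSR0_RANGE = (1.0, 200.0)


@dataclass
class BeatRecord:
    """Lattice-averaged traces and exact per-beat flux integrals.

    Traces are sampled roughly every ms; fluxes are step means in
    μmol/(Lcyt·ms): ``J_LCC`` entry-positive, ``J_NCX`` extrusion-positive,
    ``J_RyR`` release-positive, ``J_SrCa`` uptake-positive.  ``c_sr`` is the
    free SR calcium referred to litres of cytosol.
    """

    t: np.ndarray
    V: np.ndarray
    c_i: np.ndarray
    c_s: np.ndarray
    c_d: np.ndarray
    c_sr: np.ndarray
    c_sr_tot: np.ndarray
    J_LCC: np.ndarray
    J_NCX: np.ndarray
    J_RyR: np.ndarray
    J_SrCa: np.ndarray
    dq_in: float
    dq_out: float
    dq_rel: float
    dq_up: float
    q_t_start: float
    q_t_end: float
    q_sr_start: float
    q_sr_end: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t,
                "V_mV": self.V,
                "c_i_uM": self.c_i,
                "c_s_uM": self.c_s,
                "c_d_uM": self.c_d,
                "c_sr_umol_per_Lcyt": self.c_sr,
                "c_sr_tot_umol_per_Lcyt": self.c_sr_tot,
                "J_LCC": self.J_LCC,
                "J_NCX": self.J_NCX,
                "J_RyR": self.J_RyR,
                "J_SrCa": self.J_SrCa,
            }
        )

    @property
    def transient_amplitude(self) -> float:
        """Beat max of lattice-averaged c_i minus its pre-systolic value, μM."""
        return float(np.max(self.c_i) - self.c_i[0])


# ---------------------------------------------------------------------- #
# step plans


def _step_plan(params: ModelParams, t0: float, duration: float):
    """Per-step (t, dt, nsub) arrays covering [t0, t0 + duration) in beat phase."""
    phase0 = t0 % params.pacing.period
    dts = []
    nsubs = []
    ts = []
    t = 0.0
    eps = 1e-9
    while t < duration - eps:
        phase = (phase0 + t) % params.pacing.period
        if phase < params.t_fine - eps:
            dt = min(params.dt, params.t_fine - phase, duration - t)
            nsub = 1
        else:
            dt = min(
                params.dt_diastole, params.pacing.period - phase, duration - t
            )
            nsub = max(1, int(np.ceil(dt / params.dt - 1e-12)))
        ts.append(t0 + t)
        dts.append(dt)
        nsubs.append(nsub)
        t += dt
    return (
        np.asarray(ts),
        np.asarray(dts, dtype=float),
        np.asarray(nsubs, dtype=np.int64),
    )


def _lcc_voltage_rates(V: np.ndarray, params: ModelParams):
    p = params.lcc_params
    sig_a = 1.0 / (1.0 + np.exp(-(V - p.v_half_act) / p.k_act))
    alpha = p.alpha_max * sig_a
    beta = p.beta_max / (1.0 + np.exp((V - p.v_half_deact) / p.k_deact))
    f_open = p.f_max * sig_a
    rec_gate = 1.0 / (1.0 + np.exp((V - p.v_half_rec) / p.k_rec))
    return alpha, beta, f_open, p.r_recover * rec_gate, p.k_i2c2 * rec_gate


def _ncx_voltage_terms(V: np.ndarray, params: ModelParams):
    """Per-step coefficients (b1, b2) with j_ncx = b1 − b2·c_s[μM]."""
    ncx = params.ncx_params
    e1 = np.exp(ncx.eta * V * FRT)
    e2 = np.exp((ncx.eta - 1.0) * V * FRT)
    den = (
        (ncx.K_mNa**3 + params.Na_o**3)
        * (ncx.K_mCa + params.Ca_o)
        * (1.0 + ncx.k_sat * e2)
    )
    b1 = ncx.v_ncx * e1 * params.Na_i**3 * params.Ca_o / den
    b2 = ncx.v_ncx * e2 * params.Na_o**3 * 1e-3 / den
    return b1, b2


_KERNEL_ERRORS = {
    1: "negative or non-finite concentration (dt instability)",
    2: "Markov exit probability exceeded the step bound (dt too large)",
}


def _advance(state: CellState, params: ModelParams, clamp: APClamp,
             duration: float, rng: np.random.Generator, record: bool):
    ts, dts, nsubs = _step_plan(params, state.t, duration)
    V = ap_waveform(ts, clamp)
    alpha, beta, f_open, rrec, ki2c2 = _lcc_voltage_rates(V, params)
    a1, a2 = lcc_driving_terms(V, params.Ca_o, params.lcc_params.gamma_o)
    a1 = np.broadcast_to(np.asarray(a1, dtype=float), V.shape).copy()
    a2 = np.broadcast_to(np.asarray(a2, dtype=float), V.shape).copy()
    b1, b2 = _ncx_voltage_terms(V, params)

    if record:
        rec_idx = np.arange(0, len(ts), dtype=np.int64)
        keep = np.zeros(len(ts), dtype=bool)
        acc = 0.0
        nxt = 0.0
        for k in range(len(ts)):
            if acc >= nxt - 1e-9:
                keep[k] = True
                nxt += RECORD_EVERY_MS
            acc += dts[k]
        rec_idx = rec_idx[keep]
    else:
        rec_idx = np.empty(0, dtype=np.int64)
    traces = np.empty((len(rec_idx), _kernel.N_TRACE_COLS))

    nbr = _neighbor_table_cached(params)
    bt, kon, koff, comp = params.buffer_arrays()
    seed = int(rng.integers(0, 2**31 - 1))
    status, dq_in, dq_out, dq_rel, dq_up = _kernel.advance(
        state.c_d, state.c_s, state.c_i, state.c_nsr, state.c_jsr_tot,
        state.buffer_bound, state.lcc_counts, state.ryr_counts, nbr,
        _kernel.pack_params(params), bt, kon, koff, comp,
        dts, nsubs, alpha, beta, f_open, rrec, ki2c2, a1, a2, b1, b2,
        rec_idx, traces, seed,
    )
    if status != 0:
        raise RuntimeError(f"integration failed: {_KERNEL_ERRORS[status]}")
    state.t += float(np.sum(dts))
    return ts[rec_idx], V[rec_idx], traces, dq_in, dq_out, dq_rel, dq_up


_NBR_CACHE: dict = {}


def _neighbor_table_cached(params: ModelParams) -> np.ndarray:
    key = (params.grid_nx, params.grid_ny, params.grid_nz)
    if key not in _NBR_CACHE:
        _NBR_CACHE[key] = build_neighbor_table(*key)
    return _NBR_CACHE[key]


# ---------------------------------------------------------------------- #
# public operations


def step(
    state: CellState,
    params: ModelParams,
    clamp: APClamp | None = None,
    dt: float | None = None,
    rng: np.random.Generator | None = None,
) -> CellState:
    """One operator-split step (Markov update at frozen V, c; then fluxes).

    Returns a new CellState advanced by ``dt`` (default ``params.dt``).
    Raises on negative concentrations or a violated Markov step bound.
    """
    clamp = clamp or params.pacing
    rng = rng or np.random.default_rng(params.seed)
    dt = params.dt if dt is None else dt
    new = state.copy()
    ts = np.array([state.t])
    V = ap_waveform(ts, clamp)
    alpha, beta, f_open, rrec, ki2c2 = _lcc_voltage_rates(V, params)
    a1, a2 = lcc_driving_terms(V, params.Ca_o, params.lcc_params.gamma_o)
    a1 = np.atleast_1d(np.asarray(a1, dtype=float))
    a2 = np.atleast_1d(np.asarray(a2, dtype=float))
    b1, b2 = _ncx_voltage_terms(V, params)
    nsub = max(1, int(np.ceil(dt / params.dt - 1e-12)))
    bt, kon, koff, comp = params.buffer_arrays()
    status, *_ = _kernel.advance(
        new.c_d, new.c_s, new.c_i, new.c_nsr, new.c_jsr_tot,
        new.buffer_bound, new.lcc_counts, new.ryr_counts,
        _neighbor_table_cached(params),
        _kernel.pack_params(params), bt, kon, koff, comp,
        np.array([dt]), np.array([nsub], dtype=np.int64),
        alpha, beta, f_open, rrec, ki2c2, a1, a2, b1, b2,
        np.empty(0, dtype=np.int64), np.empty((0, _kernel.N_TRACE_COLS)),
        int(rng.integers(0, 2**31 - 1)),
    )
    if status != 0:
        raise RuntimeError(f"integration failed: {_KERNEL_ERRORS[status]}")
    new.t = state.t + dt
    return new


def run_beat(
    state: CellState,
    params: ModelParams,
    clamp: APClamp | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CellState, BeatRecord]:
    """Advance exactly one pacing period from beat onset.

    Returns the end state and a BeatRecord whose ΔQ integrals satisfy the
    whole-cell and SR mass identities exactly.
    """
    clamp = clamp or params.pacing
    rng = rng or np.random.default_rng(params.seed)
    new = state.copy()
    q_t0 = total_cell_calcium(new, params)
    q_sr0 = sr_calcium(new, params)
    t, V, traces, dq_in, dq_out, dq_rel, dq_up = _advance(
        new, params, clamp, clamp.period, rng, record=True
    )
    new.beat += 1
    rec = BeatRecord(
        t=t, V=V,
        c_i=traces[:, 0], c_s=traces[:, 1], c_d=traces[:, 2],
        c_sr=traces[:, 3], c_sr_tot=traces[:, 4],
        J_LCC=traces[:, 5], J_NCX=traces[:, 6],
        J_RyR=traces[:, 7], J_SrCa=traces[:, 8],
        dq_in=dq_in, dq_out=dq_out, dq_rel=dq_rel, dq_up=dq_up,
        q_t_start=q_t0, q_t_end=total_cell_calcium(new, params),
        q_sr_start=q_sr0, q_sr_end=sr_calcium(new, params),
    )
    return new, rec


def run_paced(
    state: CellState,
    params: ModelParams,
    clamp: APClamp | None = None,
    n_beats: int = 1,
    rng: np.random.Generator | None = None,
    record: bool = True,
) -> tuple[CellState, list[BeatRecord]]:
    """Chain ``run_beat`` for n_beats; exposes the beat-to-beat Q_T, Q_SR maps
    through the per-beat records."""
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    clamp = clamp or params.pacing
    rng = rng or np.random.default_rng(params.seed)
    records = []
    for _ in range(n_beats):
        if record:
            state, rec = run_beat(state, params, clamp, rng)
            records.append(rec)
        else:
            q_t0 = total_cell_calcium(state, params)
            q_sr0 = sr_calcium(state, params)
            _, _, _, dq_in, dq_out, dq_rel, dq_up = _advance(
                state, params, clamp, clamp.period, rng, record=False
            )
            state.beat += 1
            records.append(
                BeatRecord(
                    t=np.empty(0), V=np.empty(0), c_i=np.empty(0),
                    c_s=np.empty(0), c_d=np.empty(0), c_sr=np.empty(0),
                    c_sr_tot=np.empty(0), J_LCC=np.empty(0),
                    J_NCX=np.empty(0), J_RyR=np.empty(0), J_SrCa=np.empty(0),
                    dq_in=dq_in, dq_out=dq_out, dq_rel=dq_rel, dq_up=dq_up,
                    q_t_start=q_t0,
                    q_t_end=total_cell_calcium(state, params),
                    q_sr_start=q_sr0,
                    q_sr_end=sr_calcium(state, params),
                )
            )
    return state, records


def init_from_diastolic(
    c_i0: float,
    c_sr0: float,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> CellState:
    """Uniform diastolic lattice with fast variables at their equilibria.

    ``c_i0`` is the cytosolic free calcium in μM (also applied to the dyadic
    and subsarcolemmal spaces); ``c_sr0`` is the free SR calcium in
    μmol/Lcyt, converted to the local concentration through the SR/cytosol
    volume-referral ratio and applied to both SR compartments.  Dynamic
    buffers start at binding equilibrium with their compartment; channel
    states are sampled per CaRU from the stationary distribution of their
    rate matrices at (V_rest, local calcium).
    """
    rng = rng or np.random.default_rng(params.seed)
    if not (CI0_RANGE_UM[0] <= c_i0 <= CI0_RANGE_UM[1]):
        raise ValueError(f"c_i0={c_i0} μM outside the analysis range {CI0_RANGE_UM}")
    if not (CSR0_RANGE[0] <= c_sr0 <= CSR0_RANGE[1]):
        raise ValueError(
            f"c_sr0={c_sr0} μmol/Lcyt outside the analysis range {CSR0_RANGE}"
        )
    n = params.n_units
    c_loc = c_sr0 / params.sr_referral_ratio  # local free SR μM
    state = CellState.zeros(params)
    state.c_d[:] = c_i0
    state.c_s[:] = c_i0
    state.c_i[:] = c_i0
    state.c_nsr[:] = c_loc
    state.c_jsr_tot[:] = c_loc + c_loc * params.B_CSQ / (c_loc + params.K_CSQ)

    for b, buf in enumerate(params.buffer_table):
        cfree = c_i0  # both compartments initialized at c_i0
        state.buffer_bound[b, :] = buf.B_total * cfree / (cfree + buf.K_d)

    v_rest = params.pacing.v_rest
    pi_lcc = stationary_distribution(lcc_rates(v_rest, c_i0, params.lcc_params))
    pi_ryr = stationary_distribution(
        ryr_rates(c_i0, c_loc, params.ryr_params)
    )
    state.lcc_counts[:] = rng.multinomial(params.N_LCC, pi_lcc, size=n).T
    state.ryr_counts[:] = rng.multinomial(params.N_RyR, pi_ryr, size=n).T
    state.validate(params)
    return state
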