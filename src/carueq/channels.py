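"""Stochastic Markov-chain gating of the LCC and RyR channel schemes.

State orderings (shared with the lattice kernel):

* LCC, 5 states: ``(O, C1, C2, I1, I2)`` — voltage-dependent activation along
  C2↔C1↔O, dyadic-calcium-dependent inactivation O↔I1, slow I1↔I2 and
  I2↔C2 recovery.
* RyR, 4 states: ``(O, C, I1, I2)`` — calcium-induced opening C→O driven by
  dyadic calcium and modulated by the luminal (jSR) load, dyadic-calcium
  inactivation O→I1 accelerated by luminal depletion, and the I1→I2→C
  recovery path (~100 ms at diastolic calcium).

A ``RateMatrix`` is a square array of transition rates in ms⁻¹ indexed by
(from_state, to_state) with a zero diagonal.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .params import LCCParams, RyRParams, MARKOV_STEP_BOUND

__all__ = [
    "LCC_STATES",
    "RYR_STATES",
    "lcc_rates",
    "ryr_rates",
    "step_markov",
    "stationary_distribution",
]

LCC_STATES = ("O", "C1", "C2", "I1", "I2")
RYR_STATES = ("O", "C", "I1", "I2")


def _sig(V: float, v_half: float, k: float) -> float:
    return 1.0 / (1.0 + np.exp(-(V - v_half) / k))


def _hill(c: float, K: float, n: float = 2.0) -> float:
    c = max(float(c), 0.0)
    cn = c**n
    return cn / (cn + K**n)


def lcc_rates(V: float, c_d: float, p: LCCParams | None = None) -> np.ndarray:
    """5×5 LCC rate matrix at membrane potential V (mV) and dyadic Ca (μM).

    Activation (C2→C1, C1→O) rises sigmoidally with V; deactivation falls;
    O→I1 inactivation is a saturating Hill function of c_d, so doubling c_d
    never decreases any inactivation entry.  Recovery from inactivation
    (I1→O, I2→C2) is gated to hyperpolarized potentials.
    """
    if p is None:
        p = LCCParams()
    if not np.isfinite(V):
        raise ValueError("V must be finite")
    if c_d < 0:
        raise ValueError("c_d must be nonnegative")
    m = np.zeros((5, 5))
    alpha = p.alpha_max * _sig(V, p.v_half_act, p.k_act)
    beta = p.beta_max / (1.0 + np.exp((V - p.v_half_deact) / p.k_deact))
    f_open = p.f_max * _sig(V, p.v_half_act, p.k_act)
    k_inact = p.k_inact_max * _hill(c_d, p.K_inact)
    rec_gate = 1.0 / (1.0 + np.exp((V - p.v_half_rec) / p.k_rec))
    m[2, 1] = alpha
    m[1, 2] = beta
    m[1, 0] = f_open
    m[0, 1] = p.g_close
    m[0, 3] = k_inact
    m[3, 0] = p.r_recover * rec_gate
    m[3, 4] = p.k_i12
    m[4, 3] = p.k_i21
    m[4, 2] = p.k_i2c2 * rec_gate
    m[2, 4] = p.k_c2i2
    return m


def ryr_rates(c_d: float, c_jsr: float, p: RyRParams | None = None) -> np.ndarray:
    """4×4 RyR rate matrix at dyadic and junctional-SR calcium (μM).

    The C→O opening rate is strictly increasing in c_d (the CICR trigger,
    zero at c_d = 0) and increases with luminal load c_jsr; the O→I1
    termination rate grows with c_d and speeds up as the jSR depletes.
    """
    if p is None:
        p = RyRParams()
    if c_d < 0 or c_jsr < 0:
        raise ValueError("concentrations must be nonnegative")
    m = np.zeros((4, 4))
    lum_act = _hill(c_jsr, p.K_lum, p.n_lum)
    k_open = p.nu_open_max * _hill(c_d, p.K_open, p.n_open) * lum_act
    k_inact = (
        p.nu_inact_max
        * _hill(c_d, p.K_inact)
        * (1.0 + p.theta_term * p.K_term / (c_jsr + p.K_term))
    )
    m[1, 0] = k_open
    m[0, 1] = p.k_close
    m[0, 2] = k_inact
    m[2, 0] = p.k_i1o
    m[2, 3] = p.k_i12
    m[3, 2] = p.k_i21
    m[3, 1] = p.k_i2c
    return m


def step_markov(
    states: np.ndarray, rates: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """One first-order transition step for a population of channels.

    Each channel independently stays put or moves to a neighbor state with
    probability rate·dt.  Raises if any total exit probability reaches the
    step bound (signals dt too large for these rates).  Bit-reproducible
    under a fixed generator state.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite and nonnegative")
    p = rates * dt
    exit_p = p.sum(axis=1)
    if np.any(exit_p >= MARKOV_STEP_BOUND):
        raise ValueError(
            f"Markov exit probability {exit_p.max():.3f} >= {MARKOV_STEP_BOUND}; "
            "reduce dt"
        )
    states = np.asarray(states)
    cum = np.cumsum(p, axis=1)  # (k, k)
    u = rng.random(states.shape[0])
    row = cum[states]  # (n, k)
    moving = u < exit_p[states]
    dest = np.argmax(u[:, None] < row, axis=1)
    return np.where(moving, dest, states)


def stationary_distribution(rates: np.ndarray) -> np.ndarray:
    """Stationary probability vector of a rate matrix.

    Solves global balance πQ = 0 with Σπ = 1 by a dense least-squares solve.
    Raises on a reducible or degenerate matrix (the chain must be irreducible
    on its state space).
    """
    rates = np.asarray(rates, dtype=float)
    k = rates.shape[0]
    if rates.shape != (k, k):
        raise ValueError("rate matrix must be square")
    n_comp, _ = connected_components(
        csr_matrix(rates > 0), directed=True, connection="strong"
    )
    if n_comp != 1:
        raise ValueError("rate matrix is reducible; stationary state not unique")
    q = rates.copy()
    np.fill_diagonal(q, -rates.sum(axis=1))
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    if np.max(np.abs(q.T @ pi)) > 1e-10 * max(rates.max(), 1.0):
        raise ValueError("degenerate rate matrix: global balance not satisfied")
    return pi
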