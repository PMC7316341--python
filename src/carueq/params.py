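"""Model constants, lattice state, and whole-cell mass accounting.

Unit conventions
----------------
Local (per-compartment) free-calcium concentrations are in μM; whole-cell
bookkeeping quantities (Q_T, Q_SR, the per-beat ΔQ integrals) are referred to
one litre of cytosol, μmol/Lcyt.  A local concentration c in a compartment of
volume v contributes c·v/v_i to the cytosol-referred total of its CaRU.  Fixed
ionic concentrations ([Na]_i, [Na]_o, [Ca]_o) are in mM.  Rates are in ms⁻¹,
lengths in μm, volumes in μm³, voltages in mV.

Each CaRU (calcium release unit) has five compartments — dyadic junction (d),
subsarcolemma (s), cytosol (i), junctional SR (jsr, where calsequestrin
lives) and network SR (nsr) — one cluster of N_RyR ryanodine receptors, and a
group of N_LCC L-type channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .pacing import APClamp

__all__ = [
    "LCCParams",
    "RyRParams",
    "NCXParams",
    "Buffer",
    "ModelParams",
    "CellState",
    "CaRUState",
    "make_default_params",
    "total_cell_calcium",
    "sr_calcium",
    "MARKOV_STEP_BOUND",
]

#: Maximum allowed per-substep Markov exit probability (rate·dt guard).
MARKOV_STEP_BOUND = 0.2

#: Unitary-RyR-conductance scale of the reduced-RyR (therapy-failure) preset.
#: Strong enough a knockdown that release becomes slow and nearly
#: insensitive to SR load, which flips the response to a SERCA shock.
REDUCED_RYR_FACTOR = 0.03

# State index conventions shared with the channels module and the kernel.
LCC_STATES = ("O", "C1", "C2", "I1", "I2")
RYR_STATES = ("O", "C", "I1", "I2")


@dataclass(frozen=True)
class LCCParams:
    """Five-state L-type channel Markov scheme: {O, C1, C2, I1, I2}.

    Voltage-dependent activation (C2↔C1↔O) uses bounded sigmoidal rates;
    inactivation into I1 is driven by dyadic calcium through a saturating
    Hill term, so every rate has a finite worst case (needed for the dt
    guard).  ``g_lcc`` scales the unitary GHK-type current.
    """

    g_lcc: float = 1.2          # ms⁻¹, unitary current prefactor (calibrated)
    gamma_o: float = 0.341      # extracellular Ca²⁺ activity coefficient
    alpha_max: float = 1.5      # C2→C1 sigmoid ceiling, ms⁻¹
    v_half_act: float = -5.0    # mV, activation midpoint
    k_act: float = 6.0          # mV, activation slope
    beta_max: float = 0.9       # C1→C2 ceiling, ms⁻¹
    v_half_deact: float = -25.0
    k_deact: float = 6.0
    f_max: float = 0.12         # C1→O ceiling, ms⁻¹ (same sigmoid as alpha)
    g_close: float = 0.3        # O→C1, ms⁻¹
    k_inact_max: float = 0.2    # O→I1 Ca-dependent ceiling, ms⁻¹
    K_inact: float = 20.0       # μM, dyadic Ca half-saturation of inactivation
    r_recover: float = 0.06     # I1→O at rest, ms⁻¹
    k_i12: float = 0.1          # I1→I2
    k_i21: float = 0.005        # I2→I1
    k_i2c2: float = 0.01        # I2→C2 at rest (≈100 ms recovery)
    k_c2i2: float = 0.0005      # C2→I2
    v_half_rec: float = -60.0   # mV, recovery-from-inactivation gate midpoint
    k_rec: float = 6.0          # mV, recovery gate slope (recovery needs repolarization)

    def max_exit_rate(self) -> float:
        """Worst-case total exit rate over all states, ms⁻¹."""
        return max(
            self.g_close + self.k_inact_max,                 # O
            self.beta_max + self.f_max,                      # C1
            self.alpha_max + self.k_c2i2,                    # C2
            self.r_recover + self.k_i12,                     # I1
            self.k_i21 + self.k_i2c2,                        # I2
        )


@dataclass(frozen=True)
class RyRParams:
    """Four-state ryanodine-receptor scheme: {O, C, I1, I2}.

    Opening (C→O) is the CICR trigger: a Hill function of dyadic calcium
    modulated by junctional-SR (luminal) load.  Inactivation (O→I1) is also
    dyadic-Ca driven and accelerates as the jSR depletes, which terminates
    release.  I1→I2→C sets the ~100 ms recovery time scale.
    """

    nu_open_max: float = 1.4    # C→O ceiling, ms⁻¹
    K_open: float = 12.5        # μM, dyadic trigger half-saturation
    n_open: float = 3.0         # Hill exponent of the trigger
    K_lum: float = 485.0        # μM, luminal (jSR) activation constant
    n_lum: float = 4.0          # Hill exponent of luminal activation
    k_close: float = 0.3        # O→C, ms⁻¹
    nu_inact_max: float = 0.2   # O→I1 ceiling at reference luminal load
    K_inact: float = 50.0       # μM
    K_term: float = 500.0       # μM, luminal-depletion acceleration of O→I1
    theta_term: float = 1.5     # O→I1 multiplier spans [1, 1+theta_term]
    k_i12: float = 0.05         # I1→I2
    k_i21: float = 0.001        # I2→I1
    k_i2c: float = 0.0125       # I2→C
    k_i1o: float = 0.0001       # I1→O (kept small: reopening from I1 is a leak pathway)

    def max_exit_rate(self) -> float:
        return max(
            self.k_close + self.nu_inact_max * (1.0 + self.theta_term),  # O
            self.nu_open_max,                                            # C
            self.k_i1o + self.k_i12,                                     # I1
            self.k_i21 + self.k_i2c,                                     # I2
        )


@dataclass(frozen=True)
class NCXParams:
    """Electrogenic 3Na⁺:1Ca²⁺ exchanger (standard saturating closed form)."""

    v_ncx: float = 1150.0   # μM/ms, strength (subsarcolemma-referred; calibrated)
    K_mNa: float = 87.5     # mM
    K_mCa: float = 1.38     # mM
    k_sat: float = 0.1
    eta: float = 0.35       # energy-barrier position


@dataclass(frozen=True)
class Buffer:
    """One dynamic (explicitly integrated) calcium buffer species."""

    name: str
    B_total: float          # μM, site concentration in its compartment
    k_on: float             # μM⁻¹ ms⁻¹
    k_off: float            # ms⁻¹
    compartment: Literal["i", "s"] = "i"

    @property
    def K_d(self) -> float:
        return self.k_off / self.k_on


_POSITIVE_SCALARS = (
    "dx", "dy", "dz", "v_i", "v_s", "v_d", "v_jsr", "v_nsr",
    "tau_d", "tau_s", "tau_tr", "g_rel", "nu_up", "K_i", "K_sr",
    "B_CSQ", "K_CSQ", "Na_i", "Na_o", "Ca_o", "dt", "dt_diastole", "t_fine",
)


@dataclass(frozen=True)
class ModelParams:
    """Every constant of the lattice model, with provenance tags.

    ``provenance`` maps field names to one of "paper" (value printed in the
    source description of the model), "cited-source" (taken from the model
    families this one follows) or "calibrated" (free scalar tuned so the
    wildtype 2 Hz steady state lands at the reference diastolic point).
    """

    # lattice geometry
    grid_nx: int = 25
    grid_ny: int = 25
    grid_nz: int = 50
    dx: float = 0.5             # μm
    dy: float = 0.5
    dz: float = 2.0
    # per-CaRU volumes, μm³
    v_i: float = 0.25
    v_s: float = 0.04
    v_d: float = 1.0e-4
    v_jsr: float = 0.01
    v_nsr: float = 0.01
    # inter-CaRU diffusion, μm²/ms (D_s acts only in x–y)
    D_i: float = 0.15
    D_sr: float = 0.06
    D_s: float = 0.15
    # intra-CaRU diffusion time constants, ms
    tau_d: float = 0.2
    tau_s: float = 0.25
    tau_tr: float = 30.0
    # RyR cluster / LCC group
    g_rel: float = 2.0          # ms⁻¹ per open RyR (calibrated)
    N_RyR: int = 40
    N_LCC: int = 5
    # SERCA
    nu_up: float = 0.5          # μM/ms, maximum uptake
    K_i: float = 0.69           # μM
    K_sr: float = 4000.0        # μM
    # calsequestrin (jSR fast buffer)
    B_CSQ: float = 3300.0       # μM
    K_CSQ: float = 600.0        # μM
    # dynamic buffers
    buffer_table: tuple[Buffer, ...] = (
        Buffer("TnC", 70.0, 0.0327, 0.0196, "i"),
        Buffer("CaM", 24.0, 0.034, 0.238, "i"),
        Buffer("SRB", 47.0, 0.115, 0.1, "i"),
    )
    # exchanger and fixed ionic concentrations (mM)
    ncx_params: NCXParams = field(default_factory=NCXParams)
    Na_i: float = 10.0
    Na_o: float = 136.0
    Ca_o: float = 1.8
    # channel gating
    lcc_params: LCCParams = field(default_factory=LCCParams)
    ryr_params: RyRParams = field(default_factory=RyRParams)
    # pacing
    pacing: APClamp = field(default_factory=APClamp)
    # integration
    dt: float = 0.1             # ms, fine step (systole/release window)
    dt_diastole: float = 0.25   # ms, coarse step after t_fine
    t_fine: float = 210.0       # ms from stimulus onset using the fine step
    seed: int = 2020
    provenance: dict = field(default_factory=dict, compare=False, repr=False)

    # ------------------------------------------------------------------ #
    def __post_init__(self) -> None:
        for name in ("grid_nx", "grid_ny", "grid_nz", "N_RyR", "N_LCC"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for name in _POSITIVE_SCALARS:
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("D_i", "D_sr", "D_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not math.isclose(self.v_jsr, self.v_nsr, rel_tol=1e-12):
            raise ValueError("v_jsr must equal v_nsr")
        for b in self.buffer_table:
            if b.B_total <= 0 or b.k_on <= 0 or b.k_off <= 0:
                raise ValueError(f"buffer {b.name}: constants must be positive")
            if b.compartment not in ("i", "s"):
                raise ValueError(f"buffer {b.name}: compartment must be 'i' or 's'")
        if self.ncx_params.v_ncx <= 0:
            raise ValueError("ncx_params.v_ncx must be strictly positive")
        if self.lcc_params.g_lcc < 0:
            raise ValueError("lcc_params.g_lcc must be nonnegative")
        # Markov step guard against worst-case rates (substep = fine dt).
        worst = max(
            self.lcc_params.max_exit_rate(), self.ryr_params.max_exit_rate()
        )
        if worst * self.dt >= MARKOV_STEP_BOUND:
            raise ValueError(
                f"dt={self.dt} too large: worst-case Markov exit probability "
                f"{worst * self.dt:.3f} >= {MARKOV_STEP_BOUND}"
            )
        if self.dt_diastole < self.dt:
            raise ValueError("dt_diastole must be >= dt")
        # explicit-diffusion stability (cytosol is the fastest field)
        dmax = max(self.D_i, self.D_s, self.D_sr)
        lim = 2.0 * dmax * (
            2.0 / self.dx**2 + 2.0 / self.dy**2 + 2.0 / self.dz**2
        )
        if lim * self.dt_diastole >= 2.0:
            raise ValueError(
                "dt_diastole violates the explicit diffusion stability bound"
            )

    # ------------------------------------------------------------------ #
    @property
    def n_units(self) -> int:
        return self.grid_nx * self.grid_ny * self.grid_nz

    @property
    def sr_referral_ratio(self) -> float:
        """(v_jsr + v_nsr)/v_i — converts a uniform local free SR μM to μmol/Lcyt."""
        return (self.v_jsr + self.v_nsr) / self.v_i

    @property
    def n_markov_substeps_diastole(self) -> int:
        return max(1, int(math.ceil(self.dt_diastole / self.dt - 1e-12)))

    def with_grid(self, nx: int, ny: int, nz: int) -> "ModelParams":
        """Same per-CaRU model on a different lattice (intensive quantities
        are grid-size-insensitive on average)."""
        return replace(self, grid_nx=nx, grid_ny=ny, grid_nz=nz)

    def buffer_arrays(self):
        """(B_total, k_on, k_off, compartment-code) float/int arrays."""
        nb = len(self.buffer_table)
        bt = np.array([b.B_total for b in self.buffer_table], dtype=float)
        kon = np.array([b.k_on for b in self.buffer_table], dtype=float)
        koff = np.array([b.k_off for b in self.buffer_table], dtype=float)
        comp = np.array(
            [0 if b.compartment == "i" else 1 for b in self.buffer_table],
            dtype=np.int64,
        )
        return bt.reshape(nb), kon, koff, comp


# ---------------------------------------------------------------------- #
# presets


def _tag_all(params: ModelParams, extra: dict) -> ModelParams:
    tags = {
        "grid_nx": "paper", "grid_ny": "paper", "grid_nz": "paper",
        "dx": "paper", "dy": "paper", "dz": "paper",
        "v_i": "paper", "v_jsr": "paper", "v_nsr": "paper",
        "v_s": "cited-source", "v_d": "cited-source",
        "D_i": "calibrated", "D_sr": "calibrated", "D_s": "calibrated",
        "tau_d": "calibrated", "tau_s": "calibrated", "tau_tr": "calibrated",
        "g_rel": "calibrated", "N_RyR": "paper", "N_LCC": "paper",
        "nu_up": "paper", "K_i": "cited-source", "K_sr": "cited-source",
        "B_CSQ": "calibrated", "K_CSQ": "cited-source",
        "buffer_table": "cited-source",
        "ncx_params": "cited-source+calibrated", "lcc_params": "cited-source+calibrated",
        "ryr_params": "cited-source+calibrated",
        "Na_i": "cited-source", "Na_o": "cited-source", "Ca_o": "cited-source",
        "pacing": "paper",
    }
    tags.update(extra)
    return replace(params, provenance=tags)


def make_default_params(
    variant: Literal["wildtype", "modified_rabbit", "reduced_ryr"] = "wildtype",
) -> ModelParams:
    """Fully populated, validated parameter preset.

    ``wildtype``
        The calibrated 2 Hz rabbit model (ν_up = 0.5 μM/ms, 40 RyR + 5 LCC
        per CaRU on a 25×25×50 lattice, T = 500 ms).
    ``modified_rabbit``
        Same structure with different cytosolic buffer levels and a slightly
        reduced maximum SERCA uptake (qualitative reconstruction of the
        counterintuitive-regulation variant).
    ``reduced_ryr``
        Identical to wildtype except the unitary RyR conductance g_rel is
        halved (exchanger and LCC untouched) — the therapy-failure preset.
    """
    wt = _tag_all(ModelParams(), {})
    if variant == "wildtype":
        return wt
    if variant == "modified_rabbit":
        new_buffers = (
            Buffer("TnC", 115.0, 0.0327, 0.0196, "i"),
            Buffer("CaM", 24.0, 0.034, 0.238, "i"),
            Buffer("SRB", 24.0, 0.115, 0.1, "i"),
        )
        return replace(wt, buffer_table=new_buffers, nu_up=0.42)
    if variant == "reduced_ryr":
        return replace(wt, g_rel=wt.g_rel * REDUCED_RYR_FACTOR)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------- #
# state containers


@dataclass
class CellState:
    """Full dynamic state of the lattice (arrays are flat, length N).

    ``lcc_counts``/``ryr_counts`` hold per-CaRU channel-state occupation
    counts in the (O, C1, C2, I1, I2) / (O, C, I1, I2) orders; channels
    within a CaRU are exchangeable, so counts are a complete description.
    ``buffer_bound`` is (n_buffers, N) bound-calcium concentration in each
    buffer's own compartment.
    """

    c_d: np.ndarray
    c_s: np.ndarray
    c_i: np.ndarray
    c_nsr: np.ndarray
    c_jsr_tot: np.ndarray
    buffer_bound: np.ndarray
    lcc_counts: np.ndarray
    ryr_counts: np.ndarray
    t: float = 0.0
    beat: int = 0

    @classmethod
    def zeros(cls, params: ModelParams) -> "CellState":
        n = params.n_units
        nb = len(params.buffer_table)
        lcc = np.zeros((5, n), dtype=np.int64)
        ryr = np.zeros((4, n), dtype=np.int64)
        lcc[2, :] = params.N_LCC   # all closed (C2)
        ryr[1, :] = params.N_RyR   # all closed (C)
        return cls(
            c_d=np.zeros(n), c_s=np.zeros(n), c_i=np.zeros(n),
            c_nsr=np.zeros(n), c_jsr_tot=np.zeros(n),
            buffer_bound=np.zeros((nb, n)),
            lcc_counts=lcc, ryr_counts=ryr,
        )

    def copy(self) -> "CellState":
        return CellState(
            self.c_d.copy(), self.c_s.copy(), self.c_i.copy(),
            self.c_nsr.copy(), self.c_jsr_tot.copy(),
            self.buffer_bound.copy(), self.lcc_counts.copy(),
            self.ryr_counts.copy(), self.t, self.beat,
        )

    def validate(self, params: ModelParams) -> None:
        from .fluxes import csq_free_from_total

        for name in ("c_d", "c_s", "c_i", "c_nsr", "c_jsr_tot"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} contains negative or non-finite values")
        cj = csq_free_from_total(self.c_jsr_tot, params.B_CSQ, params.K_CSQ)
        if np.any(cj > self.c_jsr_tot + 1e-9):
            raise ValueError("free jSR calcium exceeds total jSR calcium")
        back = cj + cj * params.B_CSQ / (cj + params.K_CSQ)
        scale = np.maximum(self.c_jsr_tot, 1.0)
        if np.max(np.abs(back - self.c_jsr_tot) / scale) > 1e-10:
            raise ValueError("calsequestrin free/total split is inconsistent")
        if np.any(self.lcc_counts < 0) or np.any(
            self.lcc_counts.sum(axis=0) != params.N_LCC
        ):
            raise ValueError("LCC state counts do not sum to N_LCC")
        if np.any(self.ryr_counts < 0) or np.any(
            self.ryr_counts.sum(axis=0) != params.N_RyR
        ):
            raise ValueError("RyR state counts do not sum to N_RyR")
        bt, _, _, _ = params.buffer_arrays()
        if self.buffer_bound.size and (
            np.any(self.buffer_bound < 0)
            or np.any(self.buffer_bound > bt[:, None] + 1e-9)
        ):
            raise ValueError("buffer occupancy outside [0, B_total]")


@dataclass(frozen=True)
class CaRUState:
    """Read-only snapshot of a single CaRU, for inspection and tests."""

    c_d: float
    c_s: float
    c_i: float
    c_nsr: float
    c_jsr_tot: float
    c_jsr: float
    buffer_bound: tuple
    lcc_counts: tuple
    ryr_counts: tuple

    @classmethod
    def from_cell(cls, state: CellState, params: ModelParams, idx: int) -> "CaRUState":
        from .fluxes import csq_free_from_total

        return cls(
            c_d=float(state.c_d[idx]),
            c_s=float(state.c_s[idx]),
            c_i=float(state.c_i[idx]),
            c_nsr=float(state.c_nsr[idx]),
            c_jsr_tot=float(state.c_jsr_tot[idx]),
            c_jsr=float(
                csq_free_from_total(state.c_jsr_tot[idx], params.B_CSQ, params.K_CSQ)
            ),
            buffer_bound=tuple(state.buffer_bound[:, idx]),
            lcc_counts=tuple(int(x) for x in state.lcc_counts[:, idx]),
            ryr_counts=tuple(int(x) for x in state.ryr_counts[:, idx]),
        )

    @property
    def O_LCC(self) -> int:
        return self.lcc_counts[0]

    @property
    def O_RyR(self) -> int:
        return self.ryr_counts[0]


# ---------------------------------------------------------------------- #
# mass accounting


def total_cell_calcium(state: CellState, params: ModelParams) -> float:
    """Total cell calcium Q_T in μmol/Lcyt (free + bound, all compartments).

    Linear in every concentration field; deterministic given the state.
    """
    per_unit = (
        params.v_d * state.c_d
        + params.v_s * state.c_s
        + params.v_i * state.c_i
        + params.v_jsr * state.c_jsr_tot
        + params.v_nsr * state.c_nsr
    )
    if state.buffer_bound.size:
        _, _, _, comp = params.buffer_arrays()
        vols = np.where(comp == 0, params.v_i, params.v_s)
        per_unit = per_unit + vols @ state.buffer_bound
    return float(np.mean(per_unit) / params.v_i)


def sr_calcium(state: CellState, params: ModelParams) -> float:
    """Q_SR in μmol/Lcyt: SR free + calsequestrin-bound, volume-referred."""
    per_unit = params.v_jsr * state.c_jsr_tot + params.v_nsr * state.c_nsr
    return float(np.mean(per_unit) / params.v_i)


def free_sr_calcium(state: CellState, params: ModelParams) -> float:
    """Free SR calcium c_sr in μmol/Lcyt (average of c_jsr and c_nsr, referred)."""
    from .fluxes import csq_free_from_total

    cj = csq_free_from_total(state.c_jsr_tot, params.B_CSQ, params.K_CSQ)
    per_unit = params.v_jsr * cj + params.v_nsr * state.c_nsr
    return float(np.mean(per_unit) / params.v_i)
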