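"""Pacing, operator-split stepping, mass audits, and reproducibility."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import carueq as cq
from carueq import APClamp, ap_waveform
from carueq.fluxes import (
    csq_free_from_total,
    intra_caru_diffusion,
    lcc_driving_terms,
    ncx_flux,
    serca_flux,
)
from conftest import frozen_channel_params


def _all_closed(state, params):
    state.lcc_counts[:] = 0
    state.lcc_counts[2, :] = params.N_LCC
    state.ryr_counts[:] = 0
    state.ryr_counts[1, :] = params.N_RyR


class TestAPWaveform:
    def test_periodicity(self):
        clamp = APClamp()
        for t in (0.0, 13.7, 250.0):
            assert ap_waveform(t, clamp) == pytest.approx(
                ap_waveform(t + clamp.period, clamp)
            )
        assert ap_waveform(0.0, clamp) == pytest.approx(
            ap_waveform(clamp.period, clamp)
        )

    def test_diastolic_clamp(self):
        clamp = APClamp()
        t = np.linspace(clamp.apd + 1, clamp.period - 1, 50)
        assert np.allclose(ap_waveform(t, clamp), clamp.v_rest)

    def test_rectangular_dialect_mean(self):
        # rise/repol -> 0, flat plateau: mean = v_rest + (pulse area)/T
        clamp = APClamp(rise_ms=0.0, repol_ms=0.0, plateau_droop=0.0)
        t = np.arange(0, clamp.period, 0.01)
        expected = clamp.v_rest + (clamp.v_peak - clamp.v_rest) * clamp.apd / clamp.period
        assert np.mean(ap_waveform(t, clamp)) == pytest.approx(expected, rel=1e-3)

    def test_bounded_between_rest_and_peak(self):
        clamp = APClamp()
        v = ap_waveform(np.linspace(0, 1000, 5000), clamp)
        assert v.min() >= clamp.v_rest - 1e-9
        assert v.max() <= clamp.v_peak + 1e-9


class TestStep:
    def test_null_dynamics_leaves_state_unchanged(self, tiny_params, rng):
        # no open channels, no gradients, vanishing pump/exchanger/diffusion
        p = frozen_channel_params(tiny_params)
        p = replace(p, nu_up=1e-300, D_i=0.0, D_s=0.0, D_sr=0.0,
                    ncx_params=replace(p.ncx_params, v_ncx=1e-300))
        s = cq.init_from_diastolic(0.15, 40.0, p, rng)
        _all_closed(s, p)
        s.c_d[:] = s.c_i
        s.c_s[:] = s.c_i
        s2 = cq.step(s, p, rng=rng)
        for name in ("c_d", "c_s", "c_i", "c_nsr", "c_jsr_tot", "buffer_bound"):
            assert np.allclose(
                getattr(s2, name), getattr(s, name), rtol=0, atol=1e-9
            ), name

    def test_jtr_transfer_conserves_sr_mass(self, tiny_params, rng):
        p = frozen_channel_params(tiny_params)
        p = replace(p, nu_up=1e-300, D_i=0.0, D_s=0.0, D_sr=0.0,
                    ncx_params=replace(p.ncx_params, v_ncx=1e-300))
        s = cq.init_from_diastolic(0.15, 40.0, p, rng)
        _all_closed(s, p)
        s.c_d[:] = s.c_i
        s.c_s[:] = s.c_i
        s.c_nsr[:] += 50.0  # create a nsr->jsr gradient
        s2 = cq.step(s, p, rng=rng)
        d_nsr = s2.c_nsr - s.c_nsr
        d_jsr_tot = s2.c_jsr_tot - s.c_jsr_tot
        assert np.all(np.abs(p.v_nsr * d_nsr + p.v_jsr * d_jsr_tot) < 1e-12)
        assert np.all(d_nsr < 0)

    def test_single_caru_matches_stiff_ode_oracle(self, rng):
        # frozen channels, constant diastolic voltage: the hybrid integrator
        # must track an adaptive high-accuracy ODE solution to 1e-5 relative
        p = frozen_channel_params(cq.make_default_params().with_grid(1, 1, 1))
        p = replace(p, dt=0.0005, dt_diastole=0.0005, D_i=0.0, D_s=0.0, D_sr=0.0)
        s = cq.init_from_diastolic(0.15, 40.0, p, rng)
        s.ryr_counts[:, 0] = (2, p.N_RyR - 2, 0, 0)   # 2 open RyR
        s.lcc_counts[:, 0] = (1, 0, p.N_LCC - 1, 0, 0)  # 1 open LCC
        s.t = 300.0  # diastole: V is constant v_rest

        y0 = [s.c_d[0], s.c_s[0], s.c_i[0], s.c_nsr[0], s.c_jsr_tot[0],
              *s.buffer_bound[:, 0]]
        V = p.pacing.v_rest
        a1, a2 = lcc_driving_terms(V, p.Ca_o, p.lcc_params.gamma_o)
        bt, kon, koff, comp = p.buffer_arrays()

        def rhs(t, y):
            cd, cs, ci, cnsr, cjt = y[:5]
            bound = y[5:]
            cjsr = csq_free_from_total(cjt, p.B_CSQ, p.K_CSQ)
            j_ds, j_si, j_tr = intra_caru_diffusion(
                cd, cs, ci, cnsr, cjsr, p.tau_d, p.tau_s, p.tau_tr
            )
            j_ryr = p.g_rel * 2 * (cjsr - cd)
            j_lcc = p.lcc_params.g_lcc * 1 * (a2 - a1 * cd)
            j_ncx = ncx_flux(cs, V, p.Na_i, p.Na_o, p.Ca_o, p.ncx_params)
            j_up = serca_flux(ci, cnsr, p.nu_up, p.K_i, p.K_sr)
            dbound = kon * np.maximum(ci, 0) * (bt - bound) - koff * bound
            dcd = j_ryr + j_lcc - j_ds
            dcs = j_ncx - j_si + p.v_d / p.v_s * j_ds
            dci = -j_up + p.v_s / p.v_i * j_si - dbound.sum()
            dcjt = j_tr - p.v_d / p.v_jsr * j_ryr
            dcnsr = -j_tr + p.v_i / p.v_nsr * j_up
            return [dcd, dcs, dci, dcnsr, dcjt, *dbound]

        T = 100.0
        sol = solve_ivp(rhs, (0, T), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12, dense_output=True)
        ref = sol.y[:, -1]

        from carueq.simulator import _advance

        st = s.copy()
        _advance(st, p, p.pacing, T, rng, record=False)
        got = np.array([st.c_d[0], st.c_s[0], st.c_i[0], st.c_nsr[0],
                        st.c_jsr_tot[0], *st.buffer_bound[:, 0]])
        assert np.allclose(got, ref, rtol=1e-5)


class TestRunBeat:
    def test_mass_and_sr_audits(self, small_params, rng):
        s = cq.init_from_diastolic(0.15, 40.0, small_params, rng)
        s, rec = cq.run_beat(s, small_params, rng=rng)
        assert abs(
            (rec.q_t_end - rec.q_t_start) - (rec.dq_in - rec.dq_out)
        ) <= 1e-6
        assert abs(
            (rec.q_sr_end - rec.q_sr_start) - (rec.dq_up - rec.dq_rel)
        ) <= 1e-6

    def test_transient_shape(self, small_params, rng):
        # cytosolic transient rises then falls; SR dips then recovers
        s = cq.init_from_diastolic(0.15, 40.0, small_params, rng)
        for _ in range(3):
            s, rec = cq.run_beat(s, small_params, rng=rng)
        ipk = int(np.argmax(rec.c_i))
        assert 0 < ipk < len(rec.c_i) - 1
        assert rec.c_i[ipk] > rec.c_i[0] + 0.05
        assert rec.c_i[-1] < rec.c_i[ipk] - 0.02
        isr = int(np.argmin(rec.c_sr))
        assert rec.c_sr[0] - rec.c_sr[isr] > 1.0    # dip
        assert rec.c_sr[-1] - rec.c_sr[isr] > 0.5   # recovery

    def test_advances_exactly_one_period(self, tiny_params, rng):
        s = cq.init_from_diastolic(0.15, 40.0, tiny_params, rng)
        s2, _ = cq.run_beat(s, tiny_params, rng=rng)
        assert s2.t - s.t == pytest.approx(tiny_params.pacing.period)
        assert s2.beat == s.beat + 1


class TestRunPaced:
    def test_seed_determinism_and_decorrelation(self, tiny_params):
        def go(seed):
            rng = np.random.default_rng(seed)
            s = cq.init_from_diastolic(0.15, 40.0, tiny_params, rng)
            _, recs = cq.run_paced(s, tiny_params, n_beats=2, rng=rng)
            return np.array([[r.dq_in, r.dq_out, r.dq_rel, r.dq_up] for r in recs])

        a, b, c = go(9), go(9), go(10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_lcc_conductance_step_up_loads_the_sr(self, small_params):
        # raising LCC conductance mid-run drives the SR load upward
        rng = np.random.default_rng(3)
        s = cq.init_from_diastolic(0.15, 40.0, small_params, rng)
        s, _ = cq.run_paced(s, small_params, n_beats=6, rng=rng, record=False)
        before = cq.free_sr_calcium(s, small_params)
        boosted = replace(
            small_params,
            lcc_params=replace(
                small_params.lcc_params,
                g_lcc=2.5 * small_params.lcc_params.g_lcc,
            ),
        )
        s, recs = cq.run_paced(s, boosted, n_beats=10, rng=rng, record=False)
        after = np.mean([r.q_sr_end for r in recs[-3:]]) - np.mean(
            [r.q_sr_end for r in recs[:3]]
        )
        assert after > 0
        assert cq.free_sr_calcium(s, small_params) > before

    def test_whole_run_mass_conservation(self, small_params, rng):
        s = cq.init_from_diastolic(0.18, 45.0, small_params, rng)
        q0 = cq.total_cell_calcium(s, small_params)
        s, recs = cq.run_paced(s, small_params, n_beats=5, rng=rng, record=False)
        net = sum(r.dq_in - r.dq_out for r in recs)
        q1 = cq.total_cell_calcium(s, small_params)
        assert abs((q1 - q0) - net) <= 1e-5


class TestInit:
    def test_invariants_and_buffer_equilibrium(self, tiny_params, rng):
        s = cq.init_from_diastolic(0.15, 40.0, tiny_params, rng)
        s.validate(tiny_params)
        bt, kon, koff, comp = tiny_params.buffer_arrays()
        for b in range(len(bt)):
            db = kon[b] * 0.15 * (bt[b] - s.buffer_bound[b]) - koff[b] * s.buffer_bound[b]
            assert np.allclose(db, 0.0, atol=1e-12)

    def test_sr_referral(self, tiny_params, rng):
        s = cq.init_from_diastolic(0.15, 40.0, tiny_params, rng)
        assert np.allclose(s.c_nsr, 500.0)
        assert cq.free_sr_calcium(s, tiny_params) == pytest.approx(40.0, rel=1e-9)

    def test_out_of_range_rejected(self, tiny_params, rng):
        with pytest.raises(ValueError):
            cq.init_from_diastolic(50.0, 40.0, tiny_params, rng)
        with pytest.raises(ValueError):
            cq.init_from_diastolic(0.15, 1e4, tiny_params, rng)


class TestNumerics:
    def test_dt_halving_deterministic_convergence(self, rng):
        # frozen channels isolate the deterministic discretization; halving
        # dt must change the single-beat ΔQ integrals by far less than 1%
        p = frozen_channel_params(cq.make_default_params().with_grid(2, 2, 4))
        res = {}
        for label, (dt, dtd) in (("dt", (0.1, 0.2)), ("half", (0.05, 0.1))):
            pp = replace(p, dt=dt, dt_diastole=dtd)
            r = np.random.default_rng(5)
            s = cq.init_from_diastolic(0.15, 40.0, pp, r)
            s.ryr_counts[:] = 0
            s.ryr_counts[0, :], s.ryr_counts[1, :] = 2, pp.N_RyR - 2
            s.lcc_counts[:] = 0
            s.lcc_counts[0, :], s.lcc_counts[2, :] = 1, pp.N_LCC - 1
            _, rec = cq.run_beat(s, pp, rng=r)
            res[label] = np.array([rec.dq_in, rec.dq_out, rec.dq_rel, rec.dq_up])
        rel = np.abs(res["dt"] - res["half"]) / np.abs(res["half"])
        assert np.all(rel < 0.01)

    def test_grid_intensive_fluxes(self):
        # intensive per-beat ΔQ from identical ICs agree across lattice sizes
        from carueq.equilibrium import beat_fluxes

        res = {}
        for grid in ((4, 4, 8), (6, 6, 8)):
            p = cq.make_default_params().with_grid(*grid)
            res[grid] = beat_fluxes(
                150.0, 40.0, p, R=5, rng=np.random.default_rng(17)
            )
        a, b = res.values()
        for name in ("dq_in", "dq_out", "dq_rel", "dq_up"):
            se = np.hypot(getattr(a, f"se_{name[3:]}"), getattr(b, f"se_{name[3:]}"))
            assert abs(getattr(a, name) - getattr(b, name)) < 3 * se + 0.05 * abs(
                getattr(a, name)
            )
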