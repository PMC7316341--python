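"""Nullcline extraction, crossing location, shocks — mostly on analytic
synthetic surfaces where the answers are known in closed form."""

import numpy as np
import pytest

import carueq as cq
from carueq.equilibrium import (
    FluxSurfaces,
    MultipleCrossingsError,
    NoCrossingError,
    beat_fluxes,
    build_surfaces,
    extract_nullcline,
    find_crossing,
    load_surfaces,
    nullcline_shift_report,
    save_surfaces,
)


def synthetic_surfaces(f_res, g_res, grid_ci=None, grid_csr=None):
    """FluxSurfaces whose f/g residuals equal the given callables."""
    gci = np.linspace(0.0, 1.0, 11) if grid_ci is None else grid_ci
    gcsr = np.linspace(0.0, 1.0, 11) if grid_csr is None else grid_csr
    X, Y = np.meshgrid(gci, gcsr, indexing="ij")
    zeros = np.zeros_like(X)
    return FluxSurfaces(
        grid_ci=gci, grid_csr=gcsr,
        dq_in=f_res(X, Y), dq_out=zeros,
        dq_up=g_res(X, Y), dq_rel=zeros,
        se_in=zeros, se_out=zeros, se_rel=zeros, se_up=zeros,
        n_replicates=1,
    )


class TestExtractNullcline:
    def test_linear_residual_gives_the_diagonal(self):
        surf = synthetic_surfaces(lambda x, y: x - y, lambda x, y: x + y - 1)
        pts = extract_nullcline(surf, "f")
        assert np.max(np.abs(pts[:, 0] - pts[:, 1])) < 1e-9

    def test_points_satisfy_interpolated_residual(self):
        surf = synthetic_surfaces(
            lambda x, y: x**2 + y**2 - 0.49, lambda x, y: x - y
        )
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (surf.grid_ci, surf.grid_csr), surf.residual("f")
        )
        pts = extract_nullcline(surf, "f")
        scale = np.abs(surf.residual("f")).max()
        assert np.max(np.abs(interp(pts))) < 1e-9 * scale

    def test_quadratic_zero_set_hausdorff_vs_brute_force(self):
        # dense sign-grid oracle: sample the analytic circle of radius 0.7
        surf = synthetic_surfaces(
            lambda x, y: x**2 + y**2 - 0.49, lambda x, y: x - y
        )
        pts = extract_nullcline(surf, "f")
        theta = np.linspace(0, np.pi / 2, 2000)
        circle = 0.7 * np.column_stack([np.cos(theta), np.sin(theta)])
        cell = np.hypot(0.1, 0.1)

        def hausdorff(a, b):
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            return max(d.min(axis=1).max(), d.min(axis=0).max())

        assert hausdorff(pts, circle) < cell

    def test_no_sign_change_raises(self):
        surf = synthetic_surfaces(lambda x, y: x + y + 1.0, lambda x, y: x - y)
        with pytest.raises(NoCrossingError, match="sign change"):
            extract_nullcline(surf, "f")


class TestFindCrossing:
    def test_linear_analytic_crossing(self):
        surf = synthetic_surfaces(
            lambda x, y: x - 0.3, lambda x, y: y - 0.6
        )
        ci, csr = find_crossing(surf)
        assert (ci, csr) == pytest.approx((0.3, 0.6), abs=1e-9)

    def test_linear_system_crossing(self):
        # residuals (x - y, x + y - 0.8) -> (0.4, 0.4)
        surf = synthetic_surfaces(
            lambda x, y: x - y, lambda x, y: x + y - 0.8
        )
        assert find_crossing(surf) == pytest.approx((0.4, 0.4), abs=1e-9)

    def test_recovers_root_to_1e6_of_grid_span(self):
        surf = synthetic_surfaces(
            lambda x, y: x**2 + y - 0.7123, lambda x, y: y - x - 0.2001
        )
        ci, csr = find_crossing(surf)
        # brute-force dense-grid oracle on the same bilinear interpolants
        from scipy.interpolate import RegularGridInterpolator

        fi = RegularGridInterpolator((surf.grid_ci, surf.grid_csr), surf.residual("f"))
        gi = RegularGridInterpolator((surf.grid_ci, surf.grid_csr), surf.residual("g"))
        xs = np.linspace(0, 1, 1201)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        err = np.abs(fi((X, Y))) + np.abs(gi((X, Y)))
        i, j = np.unravel_index(np.argmin(err), err.shape)
        assert abs(ci - xs[i]) < 1e-6 + xs[1] - xs[0]
        assert abs(csr - xs[j]) < 1e-6 + xs[1] - xs[0]

    def test_multiple_crossings_reported(self):
        surf = synthetic_surfaces(
            lambda x, y: (x - 0.5) ** 2 + (y - 0.5) ** 2 - 0.09,
            lambda x, y: y - 0.5,
        )
        with pytest.raises(MultipleCrossingsError) as exc:
            find_crossing(surf)
        assert len(exc.value.crossings) == 2

    def test_disjoint_nullclines_raise(self):
        surf = synthetic_surfaces(lambda x, y: x - 0.2, lambda x, y: x - 0.8)
        with pytest.raises(NoCrossingError):
            find_crossing(surf)


class TestShiftReport:
    def test_identical_surfaces_zero_displacement(self):
        surf = synthetic_surfaces(lambda x, y: x - y, lambda x, y: x + y - 1)
        rep = nullcline_shift_report(surf, surf)
        assert rep["classification"] == "none"
        assert np.nanmax(np.abs(rep["f"]["displacement_csr"])) == 0.0

    def test_pure_uptake_perturbation_moves_only_g(self):
        import dataclasses

        before = synthetic_surfaces(lambda x, y: x - y, lambda x, y: x + y - 1)
        after = dataclasses.replace(before, dq_up=before.dq_up + 0.2)
        rep = nullcline_shift_report(before, after)
        assert rep["classification"] == "single"
        assert abs(rep["f"]["mean_displacement_csr"]) < 1e-12
        assert rep["g"]["mean_displacement_csr"] == pytest.approx(-0.2, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        a = synthetic_surfaces(lambda x, y: x - y, lambda x, y: x + y - 1)
        b = synthetic_surfaces(
            lambda x, y: x - y, lambda x, y: x + y - 1,
            grid_ci=np.linspace(0, 2, 11),
        )
        with pytest.raises(ValueError, match="grid"):
            nullcline_shift_report(a, b)


class TestBeatFluxes:
    def test_determinism_under_fixed_seed(self, tiny_params):
        a = beat_fluxes(150.0, 40.0, tiny_params, R=2, rng=np.random.default_rng(5))
        b = beat_fluxes(150.0, 40.0, tiny_params, R=2, rng=np.random.default_rng(5))
        assert (a.dq_in, a.dq_out, a.dq_rel, a.dq_up) == (
            b.dq_in, b.dq_out, b.dq_rel, b.dq_up,
        )

    def test_release_grows_with_sr_load(self, small_params):
        lo = beat_fluxes(150.0, 25.0, small_params, R=3, rng=np.random.default_rng(2))
        hi = beat_fluxes(150.0, 55.0, small_params, R=3, rng=np.random.default_rng(3))
        margin = 3 * np.hypot(lo.se_rel, hi.se_rel)
        assert hi.dq_rel > lo.dq_rel + margin

    def test_no_entry_without_lcc_conductance(self, tiny_params):
        # zero LCC conductance closes the only entry pathway exactly
        from dataclasses import replace

        p = replace(
            tiny_params,
            lcc_params=replace(tiny_params.lcc_params, g_lcc=0.0),
        )
        bf = beat_fluxes(150.0, 40.0, p, R=1, rng=np.random.default_rng(0))
        assert bf.dq_in == 0.0


class TestBuildSurfaces:
    def test_2x2_grid_plumbing_and_io_round_trip(self, tiny_params, tmp_path):
        gci = np.array([100.0, 200.0])
        gcsr = np.array([30.0, 50.0])
        surf = build_surfaces(
            gci, gcsr, tiny_params, R=1, rng=np.random.default_rng(8)
        )
        assert surf.dq_in.shape == (2, 2)
        assert np.all(np.isfinite(surf.dq_rel))
        # higher load row releases more on average (coarse sanity)
        assert surf.dq_rel[:, 1].mean() > surf.dq_rel[:, 0].mean()
        save_surfaces(surf, tmp_path / "s")
        back = load_surfaces(tmp_path / "s")
        assert np.allclose(back.dq_in, surf.dq_in)
        assert np.allclose(back.grid_csr, surf.grid_csr)
        assert back.n_replicates == surf.n_replicates


class TestShockSweep:
    def test_sweep_machinery_and_reporting(self, small_params):
        # exercise the sweep plumbing end to end on a coarse grid: per-value
        # crossings, amplitude normalization to the reference value, and
        # graceful per-value error reporting
        from carueq.equilibrium import shock_sweep

        gci = np.linspace(90.0, 260.0, 4)
        gcsr = np.linspace(15.0, 70.0, 4)
        out = shock_sweep(
            "nu_up", [0.4, 0.7], small_params,
            grid_ci=gci, grid_csr=gcsr, R=2,
            rng=np.random.default_rng(21),
        )
        assert out["param"] == "nu_up"
        assert out["reference_value"] == 0.5
        assert set(out["results"]) == {0.4, 0.5, 0.7}
        ref = out["results"][0.5]
        assert ref["amplitude_pct"] == pytest.approx(100.0)
        for v in (0.4, 0.7):
            entry = out["results"][v]
            assert "crossing" in entry, entry.get("error")
            assert entry["surfaces"].n_replicates == 2
        # stronger uptake moves the steady state toward higher SR load
        assert out["results"][0.7]["crossing"][1] > out["results"][0.4]["crossing"][1]

    def test_unknown_parameter_rejected(self, tiny_params):
        from carueq.equilibrium import shock_sweep

        with pytest.raises(AttributeError, match="mystery"):
            shock_sweep("mystery", [1.0], tiny_params)
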