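"""Two-variable general-equilibrium analysis of calcium homeostasis.

The homeostatic steady state of the paced cell is predicted from single-beat
measurements: four per-beat flux integrals ΔQ_in, ΔQ_out, ΔQ_rel, ΔQ_up are
evaluated over a grid of diastolic initial conditions (c_i, c_sr), giving
four surfaces.  The f-nullcline is the zero set of ΔQ_in − ΔQ_out (cell
influx balances efflux), the g-nullcline the zero set of ΔQ_up − ΔQ_rel (SR
uptake balances release); their crossing is the predicted fixed point of the
beat-to-beat maps for total-cell and SR calcium.

Grid conventions: c_i in nM, c_sr in μmol/Lcyt (cytosol-referred free SR
calcium); ΔQ in μmol/Lcyt per beat.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import LineString, MultiLineString
from skimage.measure import find_contours

from .pacing import APClamp
from .params import ModelParams
from .simulator import init_from_diastolic, run_beat, run_paced

__all__ = [
    "BeatFluxes",
    "save_surfaces",
    "load_surfaces",
    "equilibrium_report",
    "FluxSurfaces",
    "EquilibriumReport",
    "NoCrossingError",
    "MultipleCrossingsError",
    "beat_fluxes",
    "build_surfaces",
    "extract_nullcline",
    "find_crossing",
    "validate_crossing",
    "shock_sweep",
    "nullcline_shift_report",
    "DEFAULT_GRID_CI",
    "DEFAULT_GRID_CSR",
    "DEFAULT_REPLICATES",
]

DEFAULT_GRID_CI = np.linspace(50.0, 400.0, 9)    # nM
DEFAULT_GRID_CSR = np.linspace(10.0, 80.0, 9)    # μmol/Lcyt
DEFAULT_REPLICATES = 8

_RESIDUAL_TOL = 1e-9


class NoCrossingError(RuntimeError):
    """The residual field does not change sign on the grid."""


class MultipleCrossingsError(RuntimeError):
    def __init__(self, crossings):
        self.crossings = crossings
        super().__init__(
            f"{len(crossings)} nullcline crossings found on the grid: {crossings}"
        )


@dataclass(frozen=True)
class BeatFluxes:
    """Replicate-averaged per-beat flux integrals for one initial condition."""

    c_i0: float                 # nM
    c_sr0: float                # μmol/Lcyt
    dq_in: float
    dq_out: float
    dq_rel: float
    dq_up: float
    se_in: float
    se_out: float
    se_rel: float
    se_up: float
    n_replicates: int


@dataclass(frozen=True)
class FluxSurfaces:
    """The four ΔQ scalar fields over the (c_i, c_sr) product grid.

    Arrays are indexed [i_ci, j_csr]; ``se_*`` are replicate standard errors.
    """

    grid_ci: np.ndarray
    grid_csr: np.ndarray
    dq_in: np.ndarray
    dq_out: np.ndarray
    dq_rel: np.ndarray
    dq_up: np.ndarray
    se_in: np.ndarray
    se_out: np.ndarray
    se_rel: np.ndarray
    se_up: np.ndarray
    n_replicates: int

    def __post_init__(self):
        ci = np.asarray(self.grid_ci, dtype=float)
        csr = np.asarray(self.grid_csr, dtype=float)
        if np.any(np.diff(ci) <= 0) or np.any(np.diff(csr) <= 0):
            raise ValueError("grid vectors must be strictly increasing")
        shape = (len(ci), len(csr))
        for name in ("dq_in", "dq_out", "dq_rel", "dq_up"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise ValueError(f"{name} shape does not match the grid")

    def residual(self, which: str) -> np.ndarray:
        if which == "f":
            return np.asarray(self.dq_in) - np.asarray(self.dq_out)
        if which == "g":
            return np.asarray(self.dq_up) - np.asarray(self.dq_rel)
        raise ValueError("which must be 'f' or 'g'")


@dataclass
class EquilibriumReport:
    """Nullclines, crossing, local slopes and optional validation gap."""

    f_nullcline: np.ndarray     # (n, 2) points (c_i nM, c_sr μmol/Lcyt)
    g_nullcline: np.ndarray
    crossing: tuple             # (c_i*, c_sr*)
    slopes: dict                # dc_i/dc_sr of each nullcline at the crossing
    validation: dict | None = None


# ---------------------------------------------------------------------- #
# surface construction


def beat_fluxes(
    c_i0: float,
    c_sr0: float,
    params: ModelParams,
    clamp: APClamp | None = None,
    R: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
) -> BeatFluxes:
    """R independent single-beat evaluations from one diastolic initial
    condition (c_i0 in nM, c_sr0 in μmol/Lcyt); mean and SE of the four ΔQ."""
    if R < 1:
        raise ValueError("R must be >= 1")
    clamp = clamp or params.pacing
    rng = rng or np.random.default_rng(params.seed)
    vals = np.empty((R, 4))
    for r in range(R):
        state = init_from_diastolic(c_i0 * 1e-3, c_sr0, params, rng)
        _, rec = run_beat(state, params, clamp, rng)
        vals[r] = (rec.dq_in, rec.dq_out, rec.dq_rel, rec.dq_up)
    mean = vals.mean(axis=0)
    se = (
        vals.std(axis=0, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(4)
    )
    return BeatFluxes(
        c_i0=float(c_i0), c_sr0=float(c_sr0),
        dq_in=mean[0], dq_out=mean[1], dq_rel=mean[2], dq_up=mean[3],
        se_in=se[0], se_out=se[1], se_rel=se[2], se_up=se[3],
        n_replicates=R,
    )


def build_surfaces(
    grid_ci: np.ndarray | None = None,
    grid_csr: np.ndarray | None = None,
    params: ModelParams | None = None,
    clamp: APClamp | None = None,
    R: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
    progress: bool = False,
) -> FluxSurfaces:
    """Evaluate ``beat_fluxes`` on the product grid.

    Each grid point gets its own child generator derived from the caller's
    seed and the point index, so results are deterministic per (point, seed)
    and independent of evaluation order.
    """
    if params is None:
        raise ValueError("params is required")
    grid_ci = DEFAULT_GRID_CI if grid_ci is None else np.asarray(grid_ci, float)
    grid_csr = DEFAULT_GRID_CSR if grid_csr is None else np.asarray(grid_csr, float)
    clamp = clamp or params.pacing
    rng = rng or np.random.default_rng(params.seed)
    base = int(rng.integers(0, 2**31 - 1))
    ni, nj = len(grid_ci), len(grid_csr)
    out = {
        k: np.empty((ni, nj))
        for k in ("dq_in", "dq_out", "dq_rel", "dq_up",
                  "se_in", "se_out", "se_rel", "se_up")
    }
    for i, ci in enumerate(grid_ci):
        for j, csr in enumerate(grid_csr):
            pt_rng = np.random.default_rng([base, i, j])
            bf = beat_fluxes(ci, csr, params, clamp, R, pt_rng)
            for k in ("dq_in", "dq_out", "dq_rel", "dq_up",
                      "se_in", "se_out", "se_rel", "se_up"):
                out[k][i, j] = getattr(bf, k)
            if progress:
                print(f"  grid point ({ci:.0f} nM, {csr:.0f}) done", flush=True)
    return FluxSurfaces(
        grid_ci=grid_ci, grid_csr=grid_csr, n_replicates=R, **out
    )


# ---------------------------------------------------------------------- #
# nullclines


def _nullcline_segments(surfaces: FluxSurfaces, which: str) -> list[np.ndarray]:
    res = surfaces.residual(which)
    if res.min() > 0 or res.max() < 0:
        raise NoCrossingError(
            f"{which}-nullcline: residual has no sign change on the grid "
            "(grid range too narrow)"
        )
    segs = find_contours(res, 0.0)
    out = []
    for seg in segs:
        # fractional indices -> physical coordinates (linear within cells)
        ci = np.interp(seg[:, 0], np.arange(len(surfaces.grid_ci)), surfaces.grid_ci)
        csr = np.interp(seg[:, 1], np.arange(len(surfaces.grid_csr)), surfaces.grid_csr)
        out.append(np.column_stack([ci, csr]))
    return out


def extract_nullcline(surfaces: FluxSurfaces, which: str) -> np.ndarray:
    """Zero-level contour of the bilinearly interpolated residual.

    ``which='f'`` balances cell influx/efflux (ΔQ_in = ΔQ_out); ``'g'``
    balances SR uptake/release (ΔQ_up = ΔQ_rel).  Returns an ordered (n, 2)
    point list in (c_i nM, c_sr μmol/Lcyt); raises ``NoCrossingError`` when
    the residual does not change sign on the grid.
    """
    segs = _nullcline_segments(surfaces, which)
    return np.vstack(segs)


def _interpolator(surfaces: FluxSurfaces, which: str):
    return RegularGridInterpolator(
        (surfaces.grid_ci, surfaces.grid_csr),
        surfaces.residual(which),
        method="linear",
        bounds_error=False,
        fill_value=None,
    )


def find_crossing(surfaces: FluxSurfaces) -> tuple[float, float]:
    """Locate the (c_i*, c_sr*) root of both interpolated residuals.

    Seeds a root solve from the intersection of the two marching-squares
    contours and polishes on the bilinear interpolants until both residuals
    are below 1e−9 of their field scale.  Raises when no crossing exists or
    when several distinct crossings are found (multiplicity reported).
    """
    f_segs = _nullcline_segments(surfaces, "f")
    g_segs = _nullcline_segments(surfaces, "g")
    f_lines = MultiLineString([LineString(s) for s in f_segs if len(s) > 1])
    g_lines = MultiLineString([LineString(s) for s in g_segs if len(s) > 1])
    inter = f_lines.intersection(g_lines)
    seeds = []
    if inter.is_empty:
        raise NoCrossingError("f- and g-nullclines do not intersect on the grid")
    if inter.geom_type == "Point":
        seeds = [(inter.x, inter.y)]
    elif inter.geom_type in ("MultiPoint", "GeometryCollection"):
        for g in inter.geoms:
            if g.geom_type == "Point":
                seeds.append((g.x, g.y))
            else:
                seeds.append((g.centroid.x, g.centroid.y))
    else:  # overlapping lines — degenerate
        seeds.append((inter.centroid.x, inter.centroid.y))

    f_scale = max(np.abs(surfaces.residual("f")).max(), 1e-300)
    g_scale = max(np.abs(surfaces.residual("g")).max(), 1e-300)

    roots = []
    for seed in seeds:
        x, r = _polish_crossing(surfaces, np.asarray(seed, dtype=float))
        if max(abs(r[0]) / f_scale, abs(r[1]) / g_scale) > _RESIDUAL_TOL:
            continue
        if not any(np.hypot(x[0] - a, x[1] - b) < 1e-6 * max(
            np.ptp(surfaces.grid_ci), np.ptp(surfaces.grid_csr)
        ) for a, b in roots):
            roots.append((float(x[0]), float(x[1])))
    if not roots:
        raise NoCrossingError(
            "no nullcline crossing satisfied the residual tolerance"
        )
    if len(roots) > 1:
        raise MultipleCrossingsError(roots)
    return roots[0]


def _bilinear_cell(surfaces, which, i, j):
    res = surfaces.residual(which)
    return res[i, j], res[i, j + 1], res[i + 1, j], res[i + 1, j + 1]


def _polish_crossing(surfaces: FluxSurfaces, x0: np.ndarray):
    """Newton iteration on the in-cell bilinear forms of both residuals
    (analytic Jacobian), re-locating the containing cell as needed.  Exact
    for bilinear interpolants; used to refine the contour-intersection seed
    to the residual tolerance."""
    gci, gcsr = surfaces.grid_ci, surfaces.grid_csr
    x = x0.copy()
    r = np.array([np.inf, np.inf])
    for _ in range(60):
        i = int(np.clip(np.searchsorted(gci, x[0]) - 1, 0, len(gci) - 2))
        j = int(np.clip(np.searchsorted(gcsr, x[1]) - 1, 0, len(gcsr) - 2))
        dci = gci[i + 1] - gci[i]
        dcsr = gcsr[j + 1] - gcsr[j]
        u = (x[0] - gci[i]) / dci
        v = (x[1] - gcsr[j]) / dcsr
        vals = []
        jac = np.empty((2, 2))
        for row, which in enumerate(("f", "g")):
            r00, r01, r10, r11 = _bilinear_cell(surfaces, which, i, j)
            vals.append(
                r00 * (1 - u) * (1 - v) + r01 * (1 - u) * v
                + r10 * u * (1 - v) + r11 * u * v
            )
            jac[row, 0] = ((1 - v) * (r10 - r00) + v * (r11 - r01)) / dci
            jac[row, 1] = ((1 - u) * (r01 - r00) + u * (r11 - r10)) / dcsr
        r = np.asarray(vals)
        if abs(np.linalg.det(jac)) < 1e-300:
            break
        step = np.linalg.solve(jac, -r)
        # damp so the iterate never jumps more than one cell at a time
        scale = max(abs(step[0]) / dci, abs(step[1]) / dcsr, 1.0)
        x = x + step / scale
        x[0] = float(np.clip(x[0], gci[0], gci[-1]))
        x[1] = float(np.clip(x[1], gcsr[0], gcsr[-1]))
        if np.max(np.abs(step)) < 1e-13 * max(np.ptp(gci), np.ptp(gcsr)):
            break
    # final residual at the polished point
    i = int(np.clip(np.searchsorted(gci, x[0]) - 1, 0, len(gci) - 2))
    j = int(np.clip(np.searchsorted(gcsr, x[1]) - 1, 0, len(gcsr) - 2))
    u = (x[0] - gci[i]) / (gci[i + 1] - gci[i])
    v = (x[1] - gcsr[j]) / (gcsr[j + 1] - gcsr[j])
    out = []
    for which in ("f", "g"):
        r00, r01, r10, r11 = _bilinear_cell(surfaces, which, i, j)
        out.append(
            r00 * (1 - u) * (1 - v) + r01 * (1 - u) * v
            + r10 * u * (1 - v) + r11 * u * v
        )
    return x, np.asarray(out)


def _local_slope(surfaces: FluxSurfaces, which: str, point) -> float:
    """dc_i/dc_sr of the nullcline at the crossing from bilinear partials."""
    ci, csr = point
    res = surfaces.residual(which)
    gci, gcsr = surfaces.grid_ci, surfaces.grid_csr
    i = int(np.clip(np.searchsorted(gci, ci) - 1, 0, len(gci) - 2))
    j = int(np.clip(np.searchsorted(gcsr, csr) - 1, 0, len(gcsr) - 2))
    dci = gci[i + 1] - gci[i]
    dcsr = gcsr[j + 1] - gcsr[j]
    u = (ci - gci[i]) / dci
    v = (csr - gcsr[j]) / dcsr
    r00, r01 = res[i, j], res[i, j + 1]
    r10, r11 = res[i + 1, j], res[i + 1, j + 1]
    d_dci = ((1 - v) * (r10 - r00) + v * (r11 - r01)) / dci
    d_dcsr = ((1 - u) * (r01 - r00) + u * (r11 - r10)) / dcsr
    if d_dci == 0:
        return float("inf")
    return -d_dcsr / d_dci


def equilibrium_report(surfaces: FluxSurfaces) -> EquilibriumReport:
    """Extract both nullclines, locate the crossing, and compute slopes."""
    crossing = find_crossing(surfaces)
    return EquilibriumReport(
        f_nullcline=extract_nullcline(surfaces, "f"),
        g_nullcline=extract_nullcline(surfaces, "g"),
        crossing=crossing,
        slopes={
            "f": _local_slope(surfaces, "f", crossing),
            "g": _local_slope(surfaces, "g", crossing),
        },
    )


# ---------------------------------------------------------------------- #
# validation and shocks


def validate_crossing(
    crossing: tuple,
    params: ModelParams,
    clamp: APClamp | None = None,
    n_beats: int = 100,
    rng: np.random.Generator | None = None,
    start: tuple | None = None,
    n_average: int = 10,
) -> dict:
    """Long-run check of the predicted fixed point.

    Paces the lattice for ``n_beats`` from an arbitrary in-range initial
    condition and compares the evolved diastolic (c_i, c_sr) — averaged over
    the final ``n_average`` beats — with the prediction.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be >= 2")
    clamp = clamp or params.pacing
    rng = rng or np.random.default_rng(params.seed)
    ci_star, csr_star = crossing
    if start is None:
        start = (250.0, 60.0)
    state = init_from_diastolic(start[0] * 1e-3, start[1], params, rng)
    ci_hist = []
    csr_hist = []
    for _ in range(n_beats):
        state, rec = run_beat(state, params, clamp, rng)
        ci_hist.append(rec.c_i[0] * 1e3)   # nM at beat start
        csr_hist.append(rec.c_sr[0])
    ci_tail = np.array(ci_hist[-n_average:])
    csr_tail = np.array(csr_hist[-n_average:])
    evolved = (float(ci_tail.mean()), float(csr_tail.mean()))
    return {
        "predicted": (float(ci_star), float(csr_star)),
        "evolved": evolved,
        "gap_ci_nM": abs(evolved[0] - ci_star),
        "gap_csr": abs(evolved[1] - csr_star),
        "rel_gap_ci": abs(evolved[0] - ci_star) / abs(ci_star),
        "rel_gap_csr": abs(evolved[1] - csr_star) / abs(csr_star),
        "se_ci_nM": float(ci_tail.std(ddof=1) / np.sqrt(len(ci_tail))),
        "se_csr": float(csr_tail.std(ddof=1) / np.sqrt(len(csr_tail))),
        "ci_history_nM": ci_hist,
        "csr_history": csr_hist,
        "start": (float(start[0]), float(start[1])),
        "n_beats": n_beats,
    }


def _set_param(params: ModelParams, path: str, value):
    """Return a copy of params with the (possibly nested) field replaced."""
    parts = path.split(".")
    if len(parts) == 1:
        if not hasattr(params, parts[0]):
            raise AttributeError(f"unknown parameter {path!r}")
        return replace(params, **{parts[0]: value})
    if len(parts) == 2:
        sub = getattr(params, parts[0])
        if not hasattr(sub, parts[1]):
            raise AttributeError(f"unknown parameter {path!r}")
        return replace(params, **{parts[0]: dataclasses.replace(sub, **{parts[1]: value})})
    raise AttributeError(f"parameter path {path!r} too deep")


def transient_amplitude_at(
    point: tuple,
    params: ModelParams,
    clamp: APClamp | None = None,
    rng: np.random.Generator | None = None,
    n_settle: int = 5,
    n_measure: int = 5,
) -> float:
    """Steady-state calcium-transient amplitude (μM): beat max of the
    lattice-averaged cytosolic trace minus its pre-systolic value, averaged
    over ``n_measure`` beats after ``n_settle`` settling beats from
    ``point`` = (c_i nM, c_sr μmol/Lcyt)."""
    clamp = clamp or params.pacing
    rng = rng or np.random.default_rng(params.seed)
    state = init_from_diastolic(point[0] * 1e-3, point[1], params, rng)
    state, _ = run_paced(state, params, clamp, n_settle, rng, record=False)
    amps = []
    for _ in range(n_measure):
        state, rec = run_beat(state, params, clamp, rng)
        amps.append(rec.transient_amplitude)
    return float(np.mean(amps))


def shock_sweep(
    param_path: str,
    values,
    params: ModelParams,
    clamp: APClamp | None = None,
    grid_ci: np.ndarray | None = None,
    grid_csr: np.ndarray | None = None,
    R: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
    validate: bool = False,
    n_beats_validate: int = 60,
    reference_value: float | None = None,
    progress: bool = False,
) -> dict:
    """Steady-state response to a parameter shock.

    For each value of ``param_path`` (e.g. ``"nu_up"``): rebuild the four
    surfaces, extract nullclines and crossing, measure the steady-state
    transient amplitude, and optionally validate by a long paced run.
    Per-value failures are reported in the result and the sweep continues.
    The ``amplitude_pct`` entries are normalized to 100% at
    ``reference_value`` (default: the parameter's value in ``params``).
    """
    values = [float(v) for v in values]
    if any(v <= 0 for v in values):
        raise ValueError("shock values must be positive")
    clamp = clamp or params.pacing
    rng = rng or np.random.default_rng(params.seed)
    base = int(rng.integers(0, 2**31 - 1))
    if reference_value is None:
        obj = params
        for part in param_path.split(".")[:-1]:
            obj = getattr(obj, part)
        reference_value = float(getattr(obj, param_path.split(".")[-1]))

    per_value = {}
    sweep_values = list(values)
    if reference_value not in sweep_values:
        sweep_values.append(reference_value)
    for v in sweep_values:
        entry = {"value": v}
        try:
            p_v = _set_param(params, param_path, v)
            rng_v = np.random.default_rng([base, hash(f"{v:.12g}") % 2**31])
            surfaces = build_surfaces(
                grid_ci, grid_csr, p_v, clamp, R, rng_v, progress=progress
            )
            report = equilibrium_report(surfaces)
            entry["crossing"] = report.crossing
            entry["slopes"] = report.slopes
            entry["surfaces"] = surfaces
            entry["report"] = report
            entry["amplitude_uM"] = transient_amplitude_at(
                report.crossing, p_v, clamp, rng_v
            )
            if validate:
                entry["validation"] = validate_crossing(
                    report.crossing, p_v, clamp, n_beats_validate, rng_v
                )
        except Exception as exc:  # noqa: BLE001 — per-value failures reported
            entry["error"] = f"{type(exc).__name__}: {exc}"
        per_value[v] = entry
        if progress:
            print(f"sweep {param_path}={v} done", flush=True)

    ref_amp = per_value.get(reference_value, {}).get("amplitude_uM")
    for v, entry in per_value.items():
        if ref_amp and "amplitude_uM" in entry:
            entry["amplitude_pct"] = 100.0 * entry["amplitude_uM"] / ref_amp
    return {
        "param": param_path,
        "values": values,
        "reference_value": reference_value,
        "results": per_value,
    }


def nullcline_shift_report(
    surfaces_before: FluxSurfaces,
    surfaces_after: FluxSurfaces,
    shift_tol_frac: float = 0.02,
) -> dict:
    """Signed displacement of each nullcline along the c_sr axis at matched
    c_i values; classifies the shock as single- or double-nullcline.

    Displacement at a grid c_i is the shift of the zero of the residual along
    the c_sr row (linear interpolation between sign changes); NaN where a
    nullcline does not cross that row.
    """
    if (
        not np.array_equal(surfaces_before.grid_ci, surfaces_after.grid_ci)
        or not np.array_equal(surfaces_before.grid_csr, surfaces_after.grid_csr)
    ):
        raise ValueError("surface grids do not match")

    def row_zero(res_row, grid):
        s = np.sign(res_row)
        for j in range(len(grid) - 1):
            if s[j] == 0:
                return float(grid[j])
            if s[j] * s[j + 1] < 0:
                frac = res_row[j] / (res_row[j] - res_row[j + 1])
                return float(grid[j] + frac * (grid[j + 1] - grid[j]))
        if s[-1] == 0:
            return float(grid[-1])
        return np.nan

    out = {}
    span = float(np.ptp(surfaces_before.grid_csr))
    moved = {}
    for which in ("f", "g"):
        rb = surfaces_before.residual(which)
        ra = surfaces_after.residual(which)
        disp = np.array(
            [
                row_zero(ra[i], surfaces_before.grid_csr)
                - row_zero(rb[i], surfaces_before.grid_csr)
                for i in range(len(surfaces_before.grid_ci))
            ]
        )
        valid = disp[np.isfinite(disp)]
        mean_disp = float(valid.mean()) if valid.size else np.nan
        out[which] = {
            "displacement_csr": disp,
            "mean_displacement_csr": mean_disp,
        }
        moved[which] = bool(
            np.isfinite(mean_disp) and abs(mean_disp) > shift_tol_frac * span
        )
    if moved["f"] and moved["g"]:
        kind = "double"
    elif moved["f"] or moved["g"]:
        kind = "single"
    else:
        kind = "none"
    out["classification"] = kind
    return out


# ---------------------------------------------------------------------- #
# surface persistence (CSV matrices + JSON metadata)


def save_surfaces(surfaces: FluxSurfaces, out_dir) -> None:
    """Write the four ΔQ grids (and their SEs) as CSV matrices with the grid
    vectors as index/columns, plus a JSON metadata file."""
    import json
    from pathlib import Path

    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("dq_in", "dq_out", "dq_rel", "dq_up",
                 "se_in", "se_out", "se_rel", "se_up"):
        pd.DataFrame(
            getattr(surfaces, name),
            index=surfaces.grid_ci,
            columns=surfaces.grid_csr,
        ).to_csv(out_dir / f"{name}.csv", index_label="c_i_nM")
    with open(out_dir / "surfaces.json", "w") as fh:
        json.dump(
            {
                "grid_ci_nM": list(surfaces.grid_ci),
                "grid_csr_umol_per_Lcyt": list(surfaces.grid_csr),
                "n_replicates": surfaces.n_replicates,
                "units": "umol/Lcyt per beat",
            },
            fh,
            indent=2,
        )


def load_surfaces(in_dir) -> FluxSurfaces:
    """Inverse of :func:`save_surfaces`."""
    import json
    from pathlib import Path

    import pandas as pd

    in_dir = Path(in_dir)
    with open(in_dir / "surfaces.json") as fh:
        meta = json.load(fh)
    arrays = {}
    for name in ("dq_in", "dq_out", "dq_rel", "dq_up",
                 "se_in", "se_out", "se_rel", "se_up"):
        df = pd.read_csv(in_dir / f"{name}.csv", index_col=0)
        arrays[name] = df.to_numpy()
    return FluxSurfaces(
        grid_ci=np.asarray(meta["grid_ci_nM"], dtype=float),
        grid_csr=np.asarray(meta["grid_csr_umol_per_Lcyt"], dtype=float),
        n_replicates=int(meta["n_replicates"]),
        **arrays,
    )
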