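"""Effective-diffusivity estimation from colour-kinetics measurements.

The measurable is CIELAB redness a*, a linear proxy for dye concentration
(validated per run by a straight-line calibration against solution-phase
concentrations).  Raw readings are normalised to

    a* = (a(t) - a_s) / (a_i - a_s)

with a_i the initial flesh redness and a_s the redness at the dye-bath
contact, so staining (uptake) and de-staining (release) runs share the
same dimensionless model: a* decays from 1 towards 0.

Diffusivities are estimated by nonlinear least squares over
(log10 D_flesh, log10 D_skin): a multi-start grid spanning the physically
plausible box [1e-14, 1e-6] m^2/s feeds a damped Gauss-Newton refinement,
and a subsequent minimum-chi-square pass re-weights residuals by the model
prediction (Pearson form).  Residuals compare either per-position radial
profiles (``series_profile``) or the volume-average curve derived from
solution-phase kinetics (``series_volume_average``); the default "auto"
mode picks whichever observation operator matches the data actually
present in the series.

Time-resolved diffusivity curves are produced by cumulative-window
refits: for each sampling time from the third onward the fit is repeated
on all data up to that time, and the first-60-min summary is the mean and
standard deviation of those window estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import model_core as mc
from .model_core import DomainError, Geometry

__all__ = [
    "DyeCondition",
    "RednessSeries",
    "CalibrationFit",
    "FitConfig",
    "DiffusivityFit",
    "TimeResolvedResult",
    "calibrate_linear",
    "normalize",
    "goodness",
    "chi_square_ssr",
    "fit_diffusivities",
    "time_resolved_diffusivity",
    "read_series_csv",
    "position_to_R",
]

#: radial measurement stations, mm from where the flesh begins
STUDY_POSITIONS_MM = (2.63, 5.26, 10.53)
EXTERIOR = "exterior"

#: Pearson chi-square prediction floor
CHI2_EPS = 1e-6

DATA_COLUMNS = [
    "dye",
    "temperature_C",
    "concentration_ppm",
    "experiment",
    "t_min",
    "position",
    "replicate",
    "a_star_raw",
    "solution_ppm",
]


class DataQualityWarning(UserWarning):
    pass


class NonConvergenceError(RuntimeError):
    """No optimisation start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[dict]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class DyeCondition:
    """One cell of the study grid: dye x temperature x bath concentration."""

    dye: str
    temperature_C: float
    concentration_ppm: float

    STUDY_DYES = ("erythrosine", "red_gardenia")
    STUDY_TEMPERATURES = (40.0, 50.0, 60.0)
    STUDY_CONCENTRATIONS = (119.0, 238.0, 357.0)

    def key(self) -> str:
        return f"{self.dye}_{self.temperature_C:g}C_{self.concentration_ppm:g}ppm"

    def in_study_grid(self) -> bool:
        return (
            self.dye in self.STUDY_DYES
            and self.temperature_C in self.STUDY_TEMPERATURES
            and self.concentration_ppm in self.STUDY_CONCENTRATIONS
        )


@dataclass
class RednessSeries:
    """Colour kinetics for one condition and experiment direction.

    ``records`` holds one row per (t_min, position, replicate) reading of
    raw redness; ``position`` is a station in mm from the flesh origin
    (as a string, e.g. "2.63") or "exterior".  ``solution_conc`` holds
    UV-VIS bath readings (t_min, replicate, ppm) when available, with
    ``c_equil_ppm`` the full-release equilibrium concentration that
    normalises them.
    """

    condition: DyeCondition
    experiment: Literal["uptake", "release"]
    records: pd.DataFrame
    a_i: float
    a_s: float
    solution_conc: pd.DataFrame | None = None
    c_equil_ppm: float | None = None

    def __post_init__(self) -> None:
        if self.a_i == self.a_s:
            raise DomainError("degenerate normalization: a_i == a_s")
        if len(self.records) and (self.records["t_min"] < 0).any():
            raise DomainError("negative sampling times")

    @property
    def normalized(self) -> bool:
        return "a_star" in self.records.columns

    def times(self) -> np.ndarray:
        return np.unique(self.records["t_min"].to_numpy(dtype=float))


def position_to_R(position: str | float, geom: Geometry) -> float:
    """Map a measurement station to dimensionless radius R.

    Stations are distances in mm from where the flesh begins (the cavity
    wall); "exterior" maps to the flesh surface R = 1.
    """
    if isinstance(position, str) and position.strip().lower() == EXTERIOR:
        return 1.0
    p_mm = float(position)
    r = geom.r_inner + p_mm * 1e-3
    if not (geom.r_inner <= r <= geom.r_flesh + 1e-12):
        raise DomainError(
            f"position {p_mm} mm falls outside the flesh span "
            f"[0, {(geom.r_flesh - geom.r_inner) * 1e3:.2f}] mm"
        )
    return min(r / geom.r_flesh, 1.0)


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float


def calibrate_linear(pairs: Sequence[tuple[float, float]]) -> CalibrationFit:
    """Straight-line redness-vs-concentration calibration by OLS.

    ``pairs`` are (a_star_raw, concentration_ppm); returns the closed-form
    least-squares line a* = slope * c + intercept.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or len(arr) < 3:
        raise DomainError("need at least 3 (redness, concentration) pairs")
    y, x = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DomainError("concentrations are constant; line is rank-deficient")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(slope=slope, intercept=intercept, r_squared=r2)


def normalize(series: RednessSeries) -> RednessSeries:
    """Attach the normalised redness column a* = (a - a_s)/(a_i - a_s)."""
    rec = series.records.copy()
    rec["a_star"] = (rec["a_star_raw"] - series.a_s) / (series.a_i - series.a_s)
    return replace(series, records=rec)


def denormalize(a_star: np.ndarray, a_i: float, a_s: float) -> np.ndarray:
    if a_i == a_s:
        raise DomainError("degenerate normalization: a_i == a_s")
    return a_s + np.asarray(a_star) * (a_i - a_s)


def goodness(obs: Sequence[float], pred: Sequence[float]) -> tuple[float, float, float]:
    """(R^2, RMSE, Pearson chi-square) for observed vs predicted values."""
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or len(o) < 2:
        raise DomainError("obs and pred must be equal-length vectors with >= 2 entries")
    ss_res = float(np.sum((o - p) ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("zero variance in observations; R^2 undefined")
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / len(o))
    chi2 = float(np.sum((o - p) ** 2 / np.maximum(p, CHI2_EPS)))
    return r2, rmse, chi2


def chi_square_ssr(obs: Sequence[float], pred: Sequence[float], n_params: int = 2) -> float:
    """Reduced-sum-of-squares chi-square alias, SSR / (n - p)."""
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if len(o) <= n_params:
        raise DomainError("need more observations than parameters")
    return float(np.sum((o - p) ** 2) / (len(o) - n_params))


# ---------------------------------------------------------------------------
# Nonlinear diffusivity fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Controls for the diffusivity fit.

    ``objective``: "per_position" compares radial-profile predictions to
    the positional colour readings; "volume_average" compares the
    volume-average series to solution-phase kinetics; "auto" (the
    default) picks per_position when positional records exist, else
    volume_average.
    """

    objective: Literal["auto", "per_position", "volume_average"] = "auto"
    n_terms: int = mc.DEFAULT_N_TERMS
    log10_bounds: tuple[float, float] = (-14.0, -6.0)
    n_starts: tuple[int, int] = (5, 5)
    # number of screened starts refined by Gauss-Newton; None picks 4 for
    # per-position fits and 8 for volume-average ones, where an
    # impermeable-skin local optimum shadows the global basin
    n_refine: int | None = None
    max_iter: int = 200
    grad_tol: float = 1e-10
    fd_step: float = 1e-6
    chi2_refine: bool = True


@dataclass
class DiffusivityFit:
    D_flesh_hat: float
    D_skin_hat: float
    se_log10_D: tuple[float, float]
    r_squared: float
    rmse: float
    chi_square: float
    chi_square_refined: float
    D_flesh_chi2: float
    D_skin_chi2: float
    n_terms: int
    n_obs: int
    converged: bool
    at_bounds: bool
    n_starts_used: int
    objective: str
    diagnostics: list[dict] = field(default_factory=list)


def _observations(
    series: RednessSeries, geom: Geometry, cfg: FitConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    """Extract (t_min, R-or-nan, observed a*) vectors and the mode used.

    Positional colour rows at t = 0 are dropped: the initial condition is
    imposed, not fitted, and the truncated radial series carries visible
    ripples there.  Solution-phase rows keep t = 0 (the bath genuinely
    starts dye-free and the volume-average series is ripple-free), so the
    kinetic curve is anchored at its origin as in any rate fit.
    """
    mode = cfg.objective
    has_positions = len(series.records) > 0
    has_solution = (
        series.solution_conc is not None
        and len(series.solution_conc) > 0
        and series.c_equil_ppm is not None
    )
    if mode == "auto":
        mode = "per_position" if has_positions else "volume_average"
    if mode == "per_position":
        if not has_positions:
            raise DomainError("no positional records for per_position objective")
        if not series.normalized:
            raise DomainError("series must be normalised before fitting")
        rec = series.records[series.records["t_min"] > 0]
        t = rec["t_min"].to_numpy(dtype=float)
        R = np.array([position_to_R(p, geom) for p in rec["position"]])
        obs = rec["a_star"].to_numpy(dtype=float)
    else:
        if not has_solution:
            raise DomainError(
                "volume_average objective needs solution-phase kinetics with c_equil_ppm"
            )
        sol = series.solution_conc
        t = sol["t_min"].to_numpy(dtype=float)
        R = np.full(len(sol), np.nan)
        frac = sol["ppm"].to_numpy(dtype=float) / series.c_equil_ppm
        # remaining fruit content: a*_V = 1 - released fraction
        obs = 1.0 - frac
    # two distinct positive times is the identifiability floor for the
    # 2-parameter fit; cumulative windows start there (full series carry
    # the >= 4 sampling times demanded by time_resolved_diffusivity)
    if len(np.unique(t[t > 0])) < 2:
        raise DomainError("need at least 2 distinct positive sampling times")
    return t, R, obs, mode


def _make_predictor(
    t_min: np.ndarray,
    R: np.ndarray,
    geom: Geometry,
    cfg: FitConfig,
    forcing: mc.ForcingParams,
    mode: str,
):
    """Residual-model factory: maps (log10 D_F, log10 D_S) -> predictions."""
    t_s = t_min * 60.0
    A = geom.A
    ratio = geom.r_flesh / geom.skin_thickness
    if mode == "per_position":
        # group rows by unique (t, R) to evaluate the series once per pair
        keys = np.stack([t_s, R], axis=1)
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        uniq_t = uniq[:, 0]
        uniq_R = uniq[:, 1]

        def predict(lf: float, ls: float) -> np.ndarray:
            D_F = 10.0**lf
            H = (10.0**ls / D_F) * ratio
            eig = mc.solve_eigenvalues(A, H, cfg.n_terms)
            thetas = D_F * uniq_t / geom.r_flesh**2
            out = np.empty(len(uniq))
            for th in np.unique(thetas):
                sel = thetas == th
                out[sel] = mc.series_profile(th, uniq_R[sel], eig, forcing)
            return out[inverse]

    else:

        def predict(lf: float, ls: float) -> np.ndarray:
            D_F = 10.0**lf
            H = (10.0**ls / D_F) * ratio
            eig = mc.solve_eigenvalues(A, H, cfg.n_terms)
            thetas = D_F * t_s / geom.r_flesh**2
            return np.asarray(mc.series_volume_average(thetas, eig, forcing))

    return predict


def _gauss_newton(
    residual,
    x0: np.ndarray,
    bounds: tuple[float, float],
    max_iter: int,
    grad_tol: float,
    fd_step: float,
) -> tuple[np.ndarray, float, bool, int, np.ndarray]:
    """Damped Gauss-Newton with step-halving, projected onto box bounds."""
    lo, hi = bounds
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    r = residual(*x)
    ssr = float(r @ r)
    converged = False
    J = np.zeros((len(r), len(x)))
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(len(x)):
            xp = x.copy()
            xp[j] += fd_step
            J[:, j] = (residual(*xp) - r) / fd_step
        g = J.T @ r
        if np.max(np.abs(g)) < grad_tol:
            converged = True
            break
        JtJ = J.T @ J
        try:
            d = -np.linalg.solve(JtJ + 1e-12 * np.eye(len(x)), g)
        except np.linalg.LinAlgError:
            break
        improved = False
        for _ in range(30):  # step-halving safeguard
            cand = np.clip(x + d, lo, hi)
            rc = residual(*cand)
            sc = float(rc @ rc)
            if sc < ssr:
                x, r, ssr = cand, rc, sc
                improved = True
                break
            d /= 2.0
        if not improved:
            converged = np.max(np.abs(g)) < max(grad_tol, 1e-6 * (1 + ssr))
            break
        if np.max(np.abs(d)) < 1e-12:
            converged = True
            break
    return x, ssr, converged, it, J


def fit_diffusivities(
    series: RednessSeries,
    geom: Geometry | None = None,
    cfg: FitConfig | None = None,
) -> DiffusivityFit:
    """Estimate (D_flesh, D_skin) by multi-start nonlinear least squares.

    A log-spaced start grid over the bound box is screened on residual
    sum of squares; the best ``n_refine`` starts are refined by damped
    Gauss-Newton, then a Pearson minimum-chi-square pass (guarded never
    to increase the chi-square it minimises) refines the least-squares
    optimum.  Standard errors are curvature-based in log10 space.
    """
    geom = geom or Geometry.cherry()
    cfg = cfg or FitConfig()
    t, R, obs, mode = _observations(series, geom, cfg)
    if np.any((obs < -0.5) | (obs > 1.5)):
        import warnings

        warnings.warn(
            "normalised observations outside [-0.5, 1.5]; check a_i/a_s references",
            DataQualityWarning,
            stacklevel=2,
        )
    forcing = mc.ForcingParams()
    predict = _make_predictor(t, R, geom, cfg, forcing, mode)

    def residual(lf: float, ls: float) -> np.ndarray:
        return obs - predict(lf, ls)

    lo, hi = cfg.log10_bounds
    nf, ns = cfg.n_starts
    grid_f = np.linspace(lo, hi, nf)
    grid_s = np.linspace(lo, hi, ns)
    starts = [(lf, ls) for lf in grid_f for ls in grid_s]
    screened = []
    for lf, ls in starts:
        r = residual(lf, ls)
        screened.append((float(r @ r), lf, ls))
    screened.sort(key=lambda z: z[0])

    n_refine = cfg.n_refine
    if n_refine is None:
        n_refine = 4 if mode == "per_position" else 8
    diagnostics: list[dict] = []
    best: tuple[float, np.ndarray, bool, np.ndarray] | None = None
    for ssr0, lf, ls in screened[: max(n_refine, 1)]:
        x, ssr, conv, iters, J = _gauss_newton(
            residual,
            np.array([lf, ls]),
            (lo, hi),
            cfg.max_iter,
            cfg.grad_tol,
            cfg.fd_step,
        )
        diagnostics.append(
            {
                "start": (lf, ls),
                "ssr_start": ssr0,
                "ssr": ssr,
                "x": tuple(x),
                "converged": bool(conv),
                "iterations": iters,
            }
        )
        if best is None or ssr < best[0]:
            best = (ssr, x, conv, J)
    if best is None or not any(d["converged"] for d in diagnostics):
        if best is None:
            raise NonConvergenceError("no optimisation start usable", diagnostics)
    ssr, x, conv, J = best
    lf_hat, ls_hat = float(x[0]), float(x[1])

    pred = predict(lf_hat, ls_hat)
    try:
        r2, rmse, chi2_ls = goodness(obs, pred)
    except DomainError:  # constant observations: R^2 undefined, rest still is
        r2 = float("nan")
        rmse = math.sqrt(float(np.mean((obs - pred) ** 2)))
        chi2_ls = float(np.sum((obs - pred) ** 2 / np.maximum(pred, CHI2_EPS)))

    # minimum-chi-square refinement: Pearson weighting by model prediction
    lf_c, ls_c, chi2_ref = lf_hat, ls_hat, chi2_ls
    if cfg.chi2_refine:

        def residual_w(lf: float, ls: float) -> np.ndarray:
            p = predict(lf, ls)
            return (obs - p) / np.sqrt(np.maximum(p, CHI2_EPS))

        xc, chi2_val, _, _, _ = _gauss_newton(
            residual_w,
            np.array([lf_hat, ls_hat]),
            (lo, hi),
            cfg.max_iter,
            cfg.grad_tol,
            cfg.fd_step,
        )
        if chi2_val <= chi2_ls:  # guarded: never accept an increase
            lf_c, ls_c, chi2_ref = float(xc[0]), float(xc[1]), float(chi2_val)

    # curvature-based standard errors in log10 space
    dof = max(len(obs) - 2, 1)
    sigma2 = ssr / dof
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J + 1e-300 * np.eye(2))
        se = (float(math.sqrt(max(cov[0, 0], 0.0))), float(math.sqrt(max(cov[1, 1], 0.0))))
    except np.linalg.LinAlgError:
        se = (float("nan"), float("nan"))

    margin = 1e-6
    at_bounds = bool(
        min(lf_hat - lo, hi - lf_hat, ls_hat - lo, hi - ls_hat) < margin
    )
    return DiffusivityFit(
        D_flesh_hat=10.0**lf_hat,
        D_skin_hat=10.0**ls_hat,
        se_log10_D=se,
        r_squared=r2,
        rmse=rmse,
        chi_square=chi2_ls,
        chi_square_refined=chi2_ref,
        D_flesh_chi2=10.0**lf_c,
        D_skin_chi2=10.0**ls_c,
        n_terms=cfg.n_terms,
        n_obs=len(obs),
        converged=bool(conv and not at_bounds),
        at_bounds=at_bounds,
        n_starts_used=len(starts),
        objective=mode,
        diagnostics=diagnostics,
    )


@dataclass
class TimeResolvedResult:
    """Cumulative-window diffusivity estimates and the <=60-min summary."""

    windows: pd.DataFrame  # columns: t_min, D_flesh, D_skin, r_squared, converged
    mean_D_flesh: float
    sd_D_flesh: float
    mean_D_skin: float
    sd_D_skin: float
    n_windows_60min: int


def time_resolved_diffusivity(
    series: RednessSeries,
    geom: Geometry | None = None,
    cfg: FitConfig | None = None,
    summary_window_min: float = 60.0,
) -> TimeResolvedResult:
    """Refit on expanding data windows [0, t_j] for each t_j from the 3rd on.

    Mirrors time-resolved effective-diffusivity analyses: early windows
    capture the fast initial ingress, later windows the slow-down as the
    matrix saturates.  The headline first-hour value is the mean +/- SD
    over windows with t_j <= ``summary_window_min``.
    """
    geom = geom or Geometry.cherry()
    cfg = cfg or FitConfig()
    times = series.times()
    times = times[times >= 0]
    if len(times) < 4:
        raise DomainError("need at least 4 distinct sampling times")
    window_ends = times[2:]
    in_window = window_ends[window_ends <= summary_window_min + 1e-9]
    if len(in_window) < 2:
        raise DomainError(
            f"fewer than 2 cumulative windows end within {summary_window_min} min; "
            "summary unavailable"
        )
    rows = []
    for t_end in window_ends:
        sub_rec = series.records[series.records["t_min"] <= t_end + 1e-9]
        sub_sol = (
            series.solution_conc[series.solution_conc["t_min"] <= t_end + 1e-9]
            if series.solution_conc is not None
            else None
        )
        sub = replace(series, records=sub_rec, solution_conc=sub_sol)
        try:
            fit = fit_diffusivities(sub, geom, cfg)
        except (DomainError, NonConvergenceError):
            continue
        rows.append(
            {
                "t_min": float(t_end),
                "D_flesh": fit.D_flesh_hat,
                "D_skin": fit.D_skin_hat,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    win = pd.DataFrame(rows)
    if len(win) == 0:
        raise NonConvergenceError("no cumulative window produced a fit", [])
    early = win[win["t_min"] <= summary_window_min + 1e-9]
    n = len(early)
    ddof = 1 if n > 1 else 0
    return TimeResolvedResult(
        windows=win,
        mean_D_flesh=float(early["D_flesh"].mean()),
        sd_D_flesh=float(early["D_flesh"].std(ddof=ddof)) if n > 1 else 0.0,
        mean_D_skin=float(early["D_skin"].mean()),
        sd_D_skin=float(early["D_skin"].std(ddof=ddof)) if n > 1 else 0.0,
        n_windows_60min=n,
    )


# ---------------------------------------------------------------------------
# I/O: long-format CSV schema shared with the synthetic-data generator
# ---------------------------------------------------------------------------


def read_series_csv(
    data_path: str | Path, meta_path: str | Path
) -> list[RednessSeries]:
    """Load RednessSeries objects from the long-format data + metadata CSVs.

    ``data_path`` rows: dye, temperature_C, concentration_ppm, experiment,
    t_min, position, replicate, a_star_raw, solution_ppm (positional rows
    leave solution_ppm empty and vice versa).  ``meta_path`` rows supply
    per-series a_i, a_s and c_equil_ppm.
    """
    data = pd.read_csv(data_path, dtype={"position": str})
    missing = [c for c in DATA_COLUMNS if c not in data.columns]
    if missing:
        raise DomainError(f"data file missing required columns: {missing}")
    meta = pd.read_csv(meta_path)
    meta_missing = [
        c
        for c in ("dye", "temperature_C", "concentration_ppm", "experiment", "a_i", "a_s")
        if c not in meta.columns
    ]
    if meta_missing:
        raise DomainError(f"metadata file missing required columns: {meta_missing}")
    out: list[RednessSeries] = []
    group_cols = ["dye", "temperature_C", "concentration_ppm", "experiment"]
    meta_idx = meta.set_index(group_cols)
    for key, grp in data.groupby(group_cols, sort=True):
        cond = DyeCondition(str(key[0]), float(key[1]), float(key[2]))
        try:
            mrow = meta_idx.loc[key]
        except KeyError as err:
            raise DomainError(f"no metadata row for series {key}") from err
        pos_rows = grp[grp["a_star_raw"].notna()].copy()
        sol_rows = grp[grp["solution_ppm"].notna()]
        solution = None
        if len(sol_rows):
            solution = sol_rows[["t_min", "replicate", "solution_ppm"]].rename(
                columns={"solution_ppm": "ppm"}
            ).reset_index(drop=True)
        c_equil = (
            float(mrow["c_equil_ppm"])
            if "c_equil_ppm" in meta.columns and pd.notna(mrow.get("c_equil_ppm"))
            else None
        )
        out.append(
            RednessSeries(
                condition=cond,
                experiment=str(key[3]),
                records=pos_rows[
                    ["t_min", "position", "replicate", "a_star_raw"]
                ].reset_index(drop=True),
                a_i=float(mrow["a_i"]),
                a_s=float(mrow["a_s"]),
                solution_conc=solution,
                c_equil_ppm=c_equil,
            )
        )
    return out
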