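"""End-to-end study runner: configuration, logging and report bundle.

Drives the full analysis on either generated fixtures or user CSVs:
for every study condition the uptake colour kinetics are normalised and
fitted (radial-profile objective), the release solution kinetics are
fitted (volume-average objective), cumulative-window refits give the
time-resolved diffusivity curve and its first-hour mean +/- SD, and the
per-condition window estimates feed ANOVA + Tukey-Kramer letters across
conditions.  Outputs are a diffusivity summary table (one row per
condition and tissue, with letters), a pairwise-comparison table, a JSON
fit report and optional redness surface grids.

Units at this boundary are user-facing (minutes, mm, ppm, degrees C);
everything below works in SI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimation as est
from . import group_stats as gs
from . import model_core as mc
from . import pde_solver as ps
from . import synthetic_data as sd
from .model_core import DomainError, Geometry

__all__ = ["RunConfig", "load_config", "run_study", "export_surfaces"]

log = logging.getLogger("cherrydiff")


@dataclass(frozen=True)
class RunConfig:
    """Study-level configuration (user units; validated on load)."""

    r_skin_mm: float = 13.5  # half the 27 mm fruit calibre
    skin_thickness_mm: float = 0.4
    r_inner_mm: float = 1.1
    n_terms: int = mc.DEFAULT_N_TERMS
    mesh_nodes: int = ps.DEFAULT_N_NODES
    surface_t_max_min: float = 60.0
    fit_log10_bounds: tuple[float, float] = (-14.0, -6.0)
    alpha: float = 0.05
    seed: int = 0
    noise_sigma: float = 0.02
    sampling_times_min: tuple[float, ...] = sd.DEFAULT_SAMPLING_MIN
    conditions: tuple[str, ...] = ()  # empty = full 18-condition grid
    out_dir: str = "results"
    write_surfaces: bool = False

    def geometry(self) -> Geometry:
        return Geometry(
            r_inner=self.r_inner_mm * 1e-3,
            r_flesh=(self.r_skin_mm - self.skin_thickness_mm) * 1e-3,
            r_skin=self.r_skin_mm * 1e-3,
        )

    def fit_config(self) -> est.FitConfig:
        return est.FitConfig(
            n_terms=self.n_terms, log10_bounds=tuple(self.fit_log10_bounds)
        )

    def design(self) -> sd.StudyDesign:
        conds = sd.full_grid()
        if self.conditions:
            wanted = set(self.conditions)
            conds = [c for c in conds if c.key() in wanted]
            if len(conds) != len(wanted):
                missing = wanted - {c.key() for c in conds}
                raise DomainError(f"unknown condition keys: {sorted(missing)}")
        n_times = len(self.sampling_times_min)
        reps = sd.DEFAULT_REPLICATES[:n_times]
        if len(reps) < n_times:
            reps = reps + (3,) * (n_times - len(reps))
        return sd.StudyDesign(
            conditions=tuple(conds),
            sampling_times_min=tuple(self.sampling_times_min),
            replicates=reps,
            noise_sigma=self.noise_sigma,
            seed=self.seed,
        )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config; unknown keys are rejected; kwargs override."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise DomainError(f"unknown config keys: {sorted(unknown)}")
    for key in ("fit_log10_bounds", "sampling_times_min", "conditions"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _setup_logging(out_dir: Path) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)


def _fit_record(cond: est.DyeCondition, tissue: str, tr: est.TimeResolvedResult,
                fit: est.DiffusivityFit) -> dict:
    mean = tr.mean_D_flesh if tissue == "flesh" else tr.mean_D_skin
    sd_ = tr.sd_D_flesh if tissue == "flesh" else tr.sd_D_skin
    return {
        "dye": cond.dye,
        "temperature_C": cond.temperature_C,
        "concentration_ppm": cond.concentration_ppm,
        "tissue": tissue,
        "D_mean": mean,
        "D_sd": sd_,
        "n": tr.n_windows_60min,
        "r_squared": fit.r_squared,
        "rmse": fit.rmse,
        "chi_square": fit.chi_square_refined,
    }


def _calibrate_if_possible(s: est.RednessSeries) -> dict | None:
    """Straight-line redness-vs-concentration check where both exist.

    Release series carry exterior colour readings and bath concentrations
    at shared times; the exterior redness is paired with the dye still
    held near the surface (c_equil - c_bath) to verify the linear
    redness-concentration proxy the whole analysis rests on.
    """
    if (
        s.solution_conc is None
        or s.c_equil_ppm is None
        or len(s.records) == 0
    ):
        return None
    ext = (
        s.records[s.records["position"] == "exterior"]
        .groupby("t_min")["a_star_raw"]
        .mean()
    )
    sol = s.solution_conc.groupby("t_min")["ppm"].mean()
    common = ext.index.intersection(sol.index)
    if len(common) < 3:
        return None
    remaining = s.c_equil_ppm - sol.loc[common]
    try:
        cal = est.calibrate_linear(list(zip(ext.loc[common], remaining)))
    except DomainError:
        return None
    return {
        "slope": cal.slope,
        "intercept": cal.intercept,
        "r_squared": cal.r_squared,
        "n_pairs": int(len(common)),
    }


def run_study(
    config: RunConfig, data_source: str | Path = "fixtures"
) -> dict:
    """Run the whole study and write the report bundle to config.out_dir.

    ``data_source``: "fixtures" generates the synthetic study from the
    config seed; otherwise it is a directory holding ``data.csv`` and
    ``series_meta.csv`` in the estimation schema.  Per-condition failures
    are collected and reported; the bundle's ``failures`` list is empty on
    a clean run.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    geom = config.geometry()
    fit_cfg = config.fit_config()
    log.info("run config hash %s seed %d", config.hash(), config.seed)

    if str(data_source) == "fixtures":
        design = config.design()
        uptake = sd.generate_uptake(design, geom=geom, n_terms=config.n_terms)
        release = sd.generate_release(design, geom=geom, n_terms=config.n_terms)
        series = uptake.series + release.series
        truth = uptake.truth
    else:
        src = Path(data_source)
        series = est.read_series_csv(src / "data.csv", src / "series_meta.csv")
        truth = None
    log.info("analysing %d series", len(series))

    summary_rows: list[dict] = []
    fit_reports: dict[str, dict] = {}
    failures: list[dict] = []
    window_groups: dict[tuple[str, str], list[gs.GroupSummary]] = {}

    for s in sorted(series, key=lambda s: (s.experiment, s.condition.key())):
        cond = s.condition
        name = f"{cond.key()}|{s.experiment}"
        try:
            if s.experiment == "uptake":
                s_norm = est.normalize(s)
                fit = est.fit_diffusivities(s_norm, geom, fit_cfg)
                tr = est.time_resolved_diffusivity(s_norm, geom, fit_cfg)
                for tissue in ("flesh", "skin"):
                    summary_rows.append(_fit_record(cond, tissue, tr, fit))
                    col = "D_flesh" if tissue == "flesh" else "D_skin"
                    vals = np.log10(tr.windows[tr.windows["t_min"] <= 60.0][col])
                    window_groups.setdefault((cond.dye, tissue), []).append(
                        gs.GroupSummary.from_values(
                            f"{cond.temperature_C:g}C_{cond.concentration_ppm:g}ppm",
                            vals,
                        )
                    )
            else:
                # release runs are fitted on the solution-phase kinetics
                rel_cfg = dataclasses.replace(fit_cfg, objective="volume_average")
                fit = est.fit_diffusivities(s, geom, rel_cfg)
            calibration = _calibrate_if_possible(s)
            fit_reports[name] = {
                "D_flesh_hat": fit.D_flesh_hat,
                "D_skin_hat": fit.D_skin_hat,
                "se_log10_D": list(fit.se_log10_D),
                "r_squared": fit.r_squared,
                "rmse": fit.rmse,
                "chi_square": fit.chi_square,
                "chi_square_refined": fit.chi_square_refined,
                "n_obs": fit.n_obs,
                "objective": fit.objective,
                "converged": fit.converged,
                "calibration": calibration,
            }
        except (DomainError, est.NonConvergenceError) as err:
            log.warning("condition %s failed: %s", name, err)
            failures.append({"series": name, "error": str(err)})

    # cross-condition statistics on log10 window estimates
    comparison_rows = []
    letters_by_group: dict[tuple[str, str], dict[str, str]] = {}
    for (dye, tissue), groups in sorted(window_groups.items()):
        if len(groups) < 2:
            continue
        F, p = gs.anova_oneway(groups)
        tab = gs.tukey_kramer(groups, alpha=config.alpha)
        letters_by_group[(dye, tissue)] = tab.letters
        for _, row in tab.pairwise.iterrows():
            comparison_rows.append(
                {
                    "dye": dye,
                    "tissue": tissue,
                    "anova_F": F,
                    "anova_p": p,
                    **row.to_dict(),
                }
            )

    summary = pd.DataFrame(summary_rows)
    if len(summary):
        summary["letters"] = [
            letters_by_group.get((r.dye, r.tissue), {}).get(
                f"{r.temperature_C:g}C_{r.concentration_ppm:g}ppm", ""
            )
            for r in summary.itertuples()
        ]
        summary = summary.sort_values(
            ["tissue", "dye", "concentration_ppm", "temperature_C"]
        ).reset_index(drop=True)
    comparisons = pd.DataFrame(comparison_rows)

    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.10g")
    comparisons.to_csv(out_dir / "comparisons.csv", index=False, float_format="%.10g")
    report = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "fits": fit_reports,
        "failures": failures,
    }
    (out_dir / "fits.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    if config.write_surfaces and truth is not None:
        for cond in config.design().conditions:
            export_surfaces(config, cond.key(), out_dir=out_dir)
    log.info("wrote %s (%d rows), %d failures", summary_path, len(summary), len(failures))
    return {
        "summary": summary,
        "comparisons": comparisons,
        "fits": fit_reports,
        "failures": failures,
        "out_dir": out_dir,
    }


def export_surfaces(
    config: RunConfig,
    condition_key: str,
    D_flesh: float | None = None,
    D_skin: float | None = None,
    out_dir: str | Path | None = None,
) -> ps.SolutionGrid:
    """Dimensional redness surface for one condition on the study mesh.

    Diffusivities default to the generator's per-condition reference
    values; pass fitted values to render a fitted surface.  The grid is
    written as long-format CSV plus a JSON sidecar.
    """
    matches = [c for c in sd.full_grid() if c.key() == condition_key]
    if not matches:
        raise DomainError(f"unknown condition key {condition_key!r}")
    cond = matches[0]
    geom = config.geometry()
    if D_flesh is None or D_skin is None:
        D_flesh, D_skin = sd.default_truth().lookup(cond)
    params = mc.TransportParams.from_geometry(D_flesh, D_skin, geom)
    t_min = np.linspace(0.0, config.surface_t_max_min, 61)
    theta = params.D_flesh * t_min * 60.0 / geom.r_flesh**2
    problem = ps.default_problem(
        geom, params, n_nodes=config.mesh_nodes, theta_eval=theta
    )
    a_i, a_s = sd._redness_refs(cond, "uptake")
    grid = ps.surface_grid(problem, geom, params, (a_i, a_s))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ps.write_grid_csv(grid, out / f"surface_{condition_key}.csv")
    return grid
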