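"""Seeded generator of synthetic colour-kinetics datasets.

Emulates the cherry-staining study design so the whole pipeline can run
and be validated without the laboratory dataset: CIELAB redness read at
the radial stations 2.63, 5.26 and 10.53 mm (from where the flesh
begins) plus the fruit exterior; five replicates at the first two
sampling times, three afterwards; uptake (staining) and release (egress)
experiments over the full 18-condition grid of 2 dyes x 3 temperatures
x 3 bath concentrations; per-condition true diffusivities of the
magnitudes observed for erythrosine and red gardenia in cherry flesh
and skin; and multiplicative Gaussian measurement noise (colour readings
scale with signal).

Noise draws are seeded per record from the master seed hashed with the
record key, so subsetting the design never reshuffles the noise and the
same seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import model_core as mc
from .estimation import (
    DATA_COLUMNS,
    DyeCondition,
    RednessSeries,
    denormalize,
    position_to_R,
)
from .model_core import DomainError, Geometry

__all__ = [
    "StudyDesign",
    "TruthTable",
    "SyntheticDataset",
    "default_truth",
    "generate_uptake",
    "generate_release",
    "write_fixtures",
]

#: default sampling schedule (minutes): dense while the main molecular
#: movement happens (first ~40-60 min), sparse during stabilisation
DEFAULT_SAMPLING_MIN = (0.0, 10.0, 20.0, 30.0, 40.0, 60.0, 90.0, 120.0, 180.0, 240.0)

#: replicate schedule: n=5 at the first two sampling times (high external
#: colour variability early on), n=3 once dyeing evens the fruit out
DEFAULT_REPLICATES = (5, 5, 3, 3, 3, 3, 3, 3, 3, 3)

#: radial stations (mm from the flesh origin) plus the fruit exterior
DEFAULT_POSITIONS = ("2.63", "5.26", "10.53", "exterior")

#: reference effective diffusivities (m^2/s) per study condition,
#: (D_flesh, D_skin); first-hour means for erythrosine and red gardenia
#: in cherry flesh and skin
_REFERENCE_DIFFUSIVITIES: dict[tuple[str, float, float], tuple[float, float]] = {
    ("erythrosine", 40.0, 119.0): (3.87e-11, 6.57e-12),
    ("erythrosine", 50.0, 119.0): (7.69e-11, 1.31e-11),
    ("erythrosine", 60.0, 119.0): (1.18e-10, 2.01e-11),
    ("erythrosine", 40.0, 238.0): (3.79e-11, 8.04e-12),
    ("erythrosine", 50.0, 238.0): (8.40e-11, 1.55e-11),
    ("erythrosine", 60.0, 238.0): (1.51e-10, 2.56e-11),
    ("erythrosine", 40.0, 357.0): (2.04e-10, 3.46e-11),
    ("erythrosine", 50.0, 357.0): (4.29e-10, 7.28e-11),
    ("erythrosine", 60.0, 357.0): (6.96e-10, 1.18e-10),
    ("red_gardenia", 40.0, 119.0): (1.07e-10, 1.81e-11),
    ("red_gardenia", 50.0, 119.0): (1.90e-10, 3.23e-11),
    ("red_gardenia", 60.0, 119.0): (2.74e-10, 4.66e-11),
    ("red_gardenia", 40.0, 238.0): (1.85e-10, 1.94e-11),
    ("red_gardenia", 50.0, 238.0): (1.99e-10, 3.56e-11),
    ("red_gardenia", 60.0, 238.0): (4.37e-10, 4.03e-11),
    ("red_gardenia", 40.0, 357.0): (1.43e-08, 2.42e-09),
    ("red_gardenia", 50.0, 357.0): (2.28e-08, 3.87e-09),
    ("red_gardenia", 60.0, 357.0): (3.89e-08, 6.61e-09),
}

#: redness references: bleached (desulphited) flesh, and the calibration
#: slope tying the dye-saturated boundary redness to bath concentration
#: (a_s = A_I_DEFAULT + CAL_SLOPE * ppm; 35 at the top 357 ppm bath)
A_I_DEFAULT = 5.0
CAL_SLOPE = 30.0 / 357.0


def full_grid() -> list[DyeCondition]:
    return [
        DyeCondition(d, t, c)
        for d in DyeCondition.STUDY_DYES
        for t in DyeCondition.STUDY_TEMPERATURES
        for c in DyeCondition.STUDY_CONCENTRATIONS
    ]


@dataclass(frozen=True)
class StudyDesign:
    conditions: tuple[DyeCondition, ...] = tuple(full_grid())
    sampling_times_min: tuple[float, ...] = DEFAULT_SAMPLING_MIN
    replicates: tuple[int, ...] = DEFAULT_REPLICATES
    positions: tuple[str, ...] = DEFAULT_POSITIONS
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times_min)
        if np.any(np.diff(t) <= 0):
            raise DomainError("sampling times must be strictly increasing")
        if len(self.replicates) != len(self.sampling_times_min):
            raise DomainError("replicate schedule length must match sampling times")
        if self.noise_sigma < 0:
            raise DomainError("noise sigma must be non-negative")


@dataclass(frozen=True)
class TruthTable:
    """True (D_flesh, D_skin) per condition, m^2/s."""

    values: dict[tuple[str, float, float], tuple[float, float]] = field(
        default_factory=lambda: dict(_REFERENCE_DIFFUSIVITIES)
    )

    def lookup(self, cond: DyeCondition) -> tuple[float, float]:
        key = (cond.dye, float(cond.temperature_C), float(cond.concentration_ppm))
        try:
            return self.values[key]
        except KeyError as err:
            raise DomainError(f"truth table has no entry for condition {key}") from err


def default_truth() -> TruthTable:
    return TruthTable()


@dataclass
class SyntheticDataset:
    series: list[RednessSeries]
    truth: TruthTable
    design: StudyDesign
    provenance: dict


def _record_rng(master_seed: int, key: str) -> np.random.Generator:
    """Deterministic per-record generator: master seed + CRC32(record key)."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(key.encode())])
    )


def _redness_refs(cond: DyeCondition, experiment: str) -> tuple[float, float]:
    """Per-condition (a_i, a_s) raw-redness references.

    Uptake: bleached flesh (a_i) stains towards the concentration-scaled
    boundary value.  Release: the saturated fruit starts at that boundary
    value and relaxes back towards dye-free redness.
    """
    a_sat = A_I_DEFAULT + CAL_SLOPE * cond.concentration_ppm
    if experiment == "uptake":
        return A_I_DEFAULT, a_sat
    return a_sat, A_I_DEFAULT


def _noiseless_profiles(
    cond: DyeCondition,
    truth: TruthTable,
    geom: Geometry,
    design: StudyDesign,
    n_terms: int,
) -> tuple[np.ndarray, np.ndarray, mc.EigenSystem]:
    """Matrix a*(t_i, position_j) of noiseless normalised redness."""
    d_f, d_s = truth.lookup(cond)
    h = mc.skin_factor(d_s, d_f, geom)
    eig = mc.solve_eigenvalues(geom.A, h, n_terms)
    R = np.array([position_to_R(p, geom) for p in design.positions])
    thetas = d_f * np.asarray(design.sampling_times_min) * 60.0 / geom.r_flesh**2
    prof = np.empty((len(thetas), len(R)))
    for i, th in enumerate(thetas):
        prof[i] = mc.series_profile(th, R, eig) if th > 0 else 1.0
    return prof, thetas, eig


def _positional_records(
    cond: DyeCondition,
    experiment: str,
    truth: TruthTable,
    geom: Geometry,
    design: StudyDesign,
    n_terms: int,
) -> RednessSeries:
    prof, _, _ = _noiseless_profiles(cond, truth, geom, design, n_terms)
    a_i, a_s = _redness_refs(cond, experiment)
    rows = []
    for i, t in enumerate(design.sampling_times_min):
        n_rep = design.replicates[i]
        for j, pos in enumerate(design.positions):
            a_true = float(denormalize(np.array([prof[i, j]]), a_i, a_s)[0])
            for rep in range(1, n_rep + 1):
                key = f"{cond.key()}|{experiment}|t={t:g}|pos={pos}|rep={rep}"
                eps = (
                    float(_record_rng(design.seed, key).normal(0.0, design.noise_sigma))
                    if design.noise_sigma > 0
                    else 0.0
                )
                rows.append(
                    {
                        "t_min": t,
                        "position": pos,
                        "replicate": rep,
                        "a_star_raw": a_true * (1.0 + eps),
                    }
                )
    return RednessSeries(
        condition=cond,
        experiment=experiment,
        records=pd.DataFrame(rows),
        a_i=a_i,
        a_s=a_s,
    )


def generate_uptake(
    design: StudyDesign | None = None,
    truth: TruthTable | None = None,
    geom: Geometry | None = None,
    n_terms: int = mc.DEFAULT_N_TERMS,
) -> SyntheticDataset:
    """Staining kinetics: dye enters the initially bleached fruit.

    Noiseless truth curves come from the series profile at the design
    stations (exterior mapped to R = 1), de-normalised with the
    condition's (a_i, a_s); each replicate reading gets multiplicative
    Gaussian noise a_obs = a_true * (1 + eps), eps ~ N(0, sigma^2).
    """
    design = design or StudyDesign()
    truth = truth or default_truth()
    geom = geom or Geometry.cherry()
    series = [
        _positional_records(cond, "uptake", truth, geom, design, n_terms)
        for cond in design.conditions
    ]
    return SyntheticDataset(
        series=series,
        truth=truth,
        design=design,
        provenance={"seed": design.seed, "experiment": "uptake"},
    )


def generate_release(
    design: StudyDesign | None = None,
    truth: TruthTable | None = None,
    geom: Geometry | None = None,
    bath_volume_L: float = 2.0,
    fruit_dye_mass_mg: float = 1.0,
    n_terms: int = mc.DEFAULT_N_TERMS,
) -> SyntheticDataset:
    """Egress kinetics: a saturated fruit releases dye into a clean bath.

    The fruit starts uniformly saturated (a* = 1) and the bath is
    dye-free, so the normalised model is the same decay problem as
    uptake.  The UV-VIS observable is the bath concentration: cumulative
    released dye mass, ``fruit_dye_mass_mg * (1 - a*_V(Theta))`` scaled
    by the condition's bath concentration, divided by ``bath_volume_L``.
    Concentration readings (triplicate) carry the same multiplicative
    noise as the colour readings.
    """
    if bath_volume_L <= 0:
        raise DomainError("bath volume must be positive")
    design = design or StudyDesign()
    truth = truth or default_truth()
    geom = geom or Geometry.cherry()
    series = []
    for cond in design.conditions:
        s = _positional_records(cond, "release", truth, geom, design, n_terms)
        d_f, d_s = truth.lookup(cond)
        h = mc.skin_factor(d_s, d_f, geom)
        eig = mc.solve_eigenvalues(geom.A, h, n_terms)
        thetas = (
            d_f * np.asarray(design.sampling_times_min) * 60.0 / geom.r_flesh**2
        )
        a_v = np.asarray(mc.series_volume_average(thetas, eig))
        a_v[thetas == 0] = 1.0
        # dye capacity scales with the staining-bath concentration
        capacity_mg = fruit_dye_mass_mg * cond.concentration_ppm / 357.0
        c_equil = capacity_mg / bath_volume_L  # mg/L == ppm in dilute solution
        released_ppm = c_equil * (1.0 - a_v)
        rows = []
        for i, t in enumerate(design.sampling_times_min):
            for rep in range(1, 4):  # UV-VIS readings in triplicate
                key = f"{cond.key()}|release|solution|t={t:g}|rep={rep}"
                eps = (
                    float(
                        _record_rng(design.seed, key).normal(0.0, design.noise_sigma)
                    )
                    if design.noise_sigma > 0
                    else 0.0
                )
                rows.append(
                    {
                        "t_min": t,
                        "replicate": rep,
                        "ppm": released_ppm[i] * (1.0 + eps),
                    }
                )
        s.solution_conc = pd.DataFrame(rows)
        s.c_equil_ppm = c_equil
        series.append(s)
    return SyntheticDataset(
        series=series,
        truth=truth,
        design=design,
        provenance={
            "seed": design.seed,
            "experiment": "release",
            "bath_volume_L": bath_volume_L,
            "fruit_dye_mass_mg": fruit_dye_mass_mg,
        },
    )


def write_fixtures(dataset: SyntheticDataset, path: str | Path) -> dict[str, Path]:
    """Write the dataset as CSV fixtures in the estimation input schema.

    Produces ``data.csv`` (long format), ``series_meta.csv`` (per-series
    redness references), ``truth.json`` and ``design.yaml``; the files
    round-trip through :func:`cherrydiff.estimation.read_series_csv`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data_rows = []
    meta_rows = []
    for s in dataset.series:
        base = {
            "dye": s.condition.dye,
            "temperature_C": s.condition.temperature_C,
            "concentration_ppm": s.condition.concentration_ppm,
            "experiment": s.experiment,
        }
        for _, r in s.records.iterrows():
            data_rows.append(
                {
                    **base,
                    "t_min": r["t_min"],
                    "position": r["position"],
                    "replicate": int(r["replicate"]),
                    "a_star_raw": r["a_star_raw"],
                    "solution_ppm": np.nan,
                }
            )
        if s.solution_conc is not None:
            for _, r in s.solution_conc.iterrows():
                data_rows.append(
                    {
                        **base,
                        "t_min": r["t_min"],
                        "position": "",
                        "replicate": int(r["replicate"]),
                        "a_star_raw": np.nan,
                        "solution_ppm": r["ppm"],
                    }
                )
        meta_rows.append(
            {
                **base,
                "a_i": s.a_i,
                "a_s": s.a_s,
                "c_equil_ppm": s.c_equil_ppm if s.c_equil_ppm is not None else np.nan,
            }
        )
    data = pd.DataFrame(data_rows, columns=DATA_COLUMNS)
    meta = pd.DataFrame(meta_rows)
    data_path = path / "data.csv"
    meta_path = path / "series_meta.csv"
    data.to_csv(data_path, index=False, float_format="%.12g")
    meta.to_csv(meta_path, index=False, float_format="%.12g")
    truth_path = path / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "_".join(map(str, k)): list(v)
                for k, v in sorted(dataset.truth.values.items())
            },
            indent=2,
        )
        + "\n"
    )
    design_path = path / "design.yaml"
    d = dataset.design
    design_path.write_text(
        yaml.safe_dump(
            {
                "conditions": [c.key() for c in d.conditions],
                "sampling_times_min": list(d.sampling_times_min),
                "replicates": list(d.replicates),
                "positions": list(d.positions),
                "noise_sigma": d.noise_sigma,
                "seed": d.seed,
                "provenance": dataset.provenance,
            },
            sort_keys=True,
        )
    )
    return {
        "data": data_path,
        "meta": meta_path,
        "truth": truth_path,
        "design": design_path,
    }
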