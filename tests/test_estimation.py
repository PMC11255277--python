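"""Calibration, normalisation, goodness statistics and the diffusivity fit."""

import numpy as np
import pandas as pd
import pytest

from cherrydiff import estimation as est
from cherrydiff import model_core as mc
from cherrydiff import synthetic_data as sd
from cherrydiff.model_core import DomainError


class TestCalibrateLinear:
    def test_exact_line(self):
        pairs = [(2 * c + 1, c) for c in (10.0, 20.0, 30.0, 40.0)]
        fit = est.calibrate_linear(pairs)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_points_leave_fit_unchanged(self):
        pairs = [(5.0, 100.0), (8.0, 200.0), (12.0, 300.0)]
        fit1 = est.calibrate_linear(pairs)
        fit2 = est.calibrate_linear(pairs + pairs)
        assert fit1.slope == pytest.approx(fit2.slope, rel=1e-12)
        assert fit1.intercept == pytest.approx(fit2.intercept, rel=1e-12)

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(0)
        c = np.linspace(50, 400, 50)
        a = 0.08 * c + 3.0 + rng.normal(0, 0.05, 50)
        fit = est.calibrate_linear(list(zip(a, c)))
        se = 0.05 / np.sqrt(np.sum((c - c.mean()) ** 2))
        assert abs(fit.slope - 0.08) < 3 * se

    def test_degenerate_inputs(self):
        with pytest.raises(DomainError):
            est.calibrate_linear([(1.0, 5.0), (2.0, 5.0), (3.0, 5.0)])
        with pytest.raises(DomainError):
            est.calibrate_linear([(1.0, 1.0), (2.0, 2.0)])


class TestNormalize:
    @pytest.fixture()
    def series(self, one_condition):
        rec = pd.DataFrame(
            {
                "t_min": [0.0, 10.0, 20.0],
                "position": ["2.63"] * 3,
                "replicate": [1, 1, 1],
                "a_star_raw": [5.0, 20.0, 35.0],
            }
        )
        return est.RednessSeries(
            condition=one_condition, experiment="uptake", records=rec, a_i=5.0, a_s=35.0
        )

    def test_reference_points_and_midpoint(self, series):
        out = est.normalize(series)
        assert out.records["a_star"].tolist() == pytest.approx([1.0, 0.5, 0.0])

    def test_round_trip(self, series):
        out = est.normalize(series)
        raw = est.denormalize(out.records["a_star"].to_numpy(), 5.0, 35.0)
        assert np.max(np.abs(raw - series.records["a_star_raw"].to_numpy())) <= 1e-12

    def test_degenerate_references_rejected(self, one_condition, series):
        with pytest.raises(DomainError, match="degenerate"):
            est.RednessSeries(
                condition=one_condition,
                experiment="uptake",
                records=series.records,
                a_i=7.0,
                a_s=7.0,
            )


class TestGoodness:
    def test_perfect_fit(self):
        assert est.goodness([1.0, 0.5, 0.2], [1.0, 0.5, 0.2]) == (1.0, 0.0, 0.0)

    def test_hand_computed_case(self):
        r2, rmse, _ = est.goodness([1.0, 0.0], [0.5, 0.5])
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert rmse == pytest.approx(0.5, rel=1e-12)

    def test_chi_square_ssr_alias(self):
        assert est.chi_square_ssr([1.0, 0.0, 0.5], [0.9, 0.1, 0.5], n_params=2) == (
            pytest.approx(0.02, rel=1e-12)
        )

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            est.goodness([1.0], [1.0])
        with pytest.raises(DomainError, match="zero variance"):
            est.goodness([0.3, 0.3, 0.3], [0.2, 0.3, 0.4])


def _uptake_series(truth_pair, sigma, seed, cond):
    truth = sd.TruthTable(
        values={(cond.dye, cond.temperature_C, cond.concentration_ppm): truth_pair}
    )
    design = sd.StudyDesign(conditions=(cond,), noise_sigma=sigma, seed=seed)
    return est.normalize(sd.generate_uptake(design, truth).series[0])


class TestFitDiffusivities:
    def test_noiseless_recovery(self, geom, one_condition):
        series = _uptake_series((1.5e-10, 2.5e-11), 0.0, 0, one_condition)
        fit = est.fit_diffusivities(series, geom)
        assert fit.D_flesh_hat == pytest.approx(1.5e-10, rel=5e-3)
        assert fit.D_skin_hat == pytest.approx(2.5e-11, rel=5e-3)
        assert fit.r_squared >= 1 - 1e-8
        assert fit.converged

    def test_constant_data_pins_to_lower_bound(self, geom, one_condition):
        rec = pd.DataFrame(
            {
                "t_min": np.repeat([0.0, 10, 20, 30, 60], 2),
                "position": ["2.63", "exterior"] * 5,
                "replicate": [1] * 10,
                "a_star_raw": [5.0] * 10,  # no diffusion observed at all
            }
        )
        series = est.normalize(
            est.RednessSeries(
                condition=one_condition,
                experiment="uptake",
                records=rec,
                a_i=5.0,
                a_s=35.0,
            )
        )
        fit = est.fit_diffusivities(series, geom)
        assert fit.at_bounds
        assert not fit.converged
        # the skin diffusivity is driven to the impermeable lower bound;
        # the flesh value is unidentified but must predict "no change"
        assert fit.D_skin_hat <= 10 ** (-14 + 1e-3)
        assert fit.rmse <= 1e-3

    def test_chi_square_refinement_never_increases(self, geom, one_condition):
        series = _uptake_series((1.5e-10, 2.5e-11), 0.02, 11, one_condition)
        fit = est.fit_diffusivities(series, geom)
        assert fit.chi_square_refined <= fit.chi_square + 1e-15

    def test_scale_equivariance(self, geom, one_condition):
        """Times scaled by k with D scaled by 1/k leave the fit unchanged."""
        k = 4.0
        s1 = _uptake_series((1.5e-10, 2.5e-11), 0.0, 0, one_condition)
        rec = s1.records.copy()
        rec["t_min"] = rec["t_min"] * k
        s2 = est.RednessSeries(
            condition=s1.condition,
            experiment="uptake",
            records=rec,
            a_i=s1.a_i,
            a_s=s1.a_s,
        )
        f1 = est.fit_diffusivities(s1, geom)
        f2 = est.fit_diffusivities(s2, geom)
        assert f2.D_flesh_hat * k == pytest.approx(f1.D_flesh_hat, rel=1e-6)
        assert f2.D_skin_hat * k == pytest.approx(f1.D_skin_hat, rel=1e-6)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-8)

    def test_data_quality_warning(self, geom, one_condition):
        rec = pd.DataFrame(
            {
                "t_min": [10.0, 20.0, 30.0, 60.0],
                "position": ["2.63"] * 4,
                "replicate": [1] * 4,
                "a_star_raw": [100.0, 20.0, 25.0, 30.0],  # wild outlier
            }
        )
        series = est.normalize(
            est.RednessSeries(
                condition=one_condition,
                experiment="uptake",
                records=rec,
                a_i=5.0,
                a_s=35.0,
            )
        )
        with pytest.warns(est.DataQualityWarning):
            est.fit_diffusivities(series, geom)

    def test_volume_average_objective_from_solution_kinetics(self, geom, one_condition):
        truth = sd.TruthTable(
            values={
                (one_condition.dye, one_condition.temperature_C,
                 one_condition.concentration_ppm): (1.5e-10, 2.5e-11)
            }
        )
        design = sd.StudyDesign(conditions=(one_condition,), noise_sigma=0.0, seed=0)
        series = sd.generate_release(design, truth).series[0]
        cfg = est.FitConfig(objective="volume_average")
        fit = est.fit_diffusivities(series, geom, cfg)
        assert fit.objective == "volume_average"
        assert fit.D_flesh_hat == pytest.approx(1.5e-10, rel=5e-3)


class TestTimeResolved:
    def test_constant_truth_gives_flat_windows(self, geom, one_condition):
        series = _uptake_series((1.5e-10, 2.5e-11), 0.0, 0, one_condition)
        out = est.time_resolved_diffusivity(series, geom)
        d = out.windows["D_flesh"].to_numpy()
        assert np.max(np.abs(d / d[0] - 1)) <= 0.01
        assert out.sd_D_flesh <= 0.01 * out.mean_D_flesh

    def test_window_bookkeeping(self, geom, one_condition):
        # sampling times 0,10,...,240: windows end at 20,30,40,60 within 1 h
        series = _uptake_series((1.5e-10, 2.5e-11), 0.0, 0, one_condition)
        out = est.time_resolved_diffusivity(series, geom)
        assert out.n_windows_60min == 4
        assert len(out.windows) == 8

    def test_summary_unavailable_with_sparse_schedule(self, geom, one_condition):
        truth = sd.TruthTable(
            values={
                (one_condition.dye, one_condition.temperature_C,
                 one_condition.concentration_ppm): (1.5e-10, 2.5e-11)
            }
        )
        design = sd.StudyDesign(
            conditions=(one_condition,),
            sampling_times_min=(0.0, 10.0, 90.0, 120.0, 180.0),
            replicates=(5, 5, 3, 3, 3),
            noise_sigma=0.0,
            seed=0,
        )
        series = est.normalize(sd.generate_uptake(design, truth).series[0])
        with pytest.raises(DomainError, match="summary unavailable"):
            est.time_resolved_diffusivity(series, geom)


class TestIO:
    def test_missing_column_named_in_error(self, tmp_path):
        data = pd.DataFrame({"dye": ["erythrosine"], "t_min": [0.0]})
        data.to_csv(tmp_path / "data.csv", index=False)
        pd.DataFrame({"a_i": [5.0]}).to_csv(tmp_path / "meta.csv", index=False)
        with pytest.raises(DomainError, match="temperature_C"):
            est.read_series_csv(tmp_path / "data.csv", tmp_path / "meta.csv")

    def test_position_mapping(self, geom):
        assert est.position_to_R("exterior", geom) == 1.0
        assert est.position_to_R("2.63", geom) == pytest.approx(
            (1.1 + 2.63) / 13.1, rel=1e-12
        )
        with pytest.raises(DomainError):
            est.position_to_R("15.0", geom)
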