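import datetime as dt

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ads_star.errors import ValidationError
from ads_star.exposure_calendar import OTHER, label_periods
from ads_star.star_model import (
    ModelSpec,
    PanelData,
    aic,
    build_design,
    estimate_variances,
    fit_pirls,
)
from ads_star.synthetic_data import SimConfig, generate_panel

GLM_SPEC = ModelSpec(
    pollutants=("NOx", "O3", "PM10"),
    use_time_smooth=False,
    use_temp_smooth=False,
    use_spatial=False,
)


def _oracle_glm(design):
    return sm.GLM(
        design.y, design.C, family=sm.families.Poisson(), offset=design.offset
    ).fit()


class TestPanelValidation:
    def test_negative_counts_rejected(self, small_sim):
        panel, _, _ = small_sim
        bad = panel.panel.copy()
        bad.loc[0, "count"] = -1
        with pytest.raises(ValidationError):
            PanelData(panel=bad, covariates=panel.covariates)

    def test_duplicate_rows_rejected(self, small_sim):
        panel, _, _ = small_sim
        bad = pd.concat([panel.panel, panel.panel.iloc[:1]])
        with pytest.raises(ValidationError):
            PanelData(panel=bad, covariates=panel.covariates)

    def test_date_gaps_need_flag(self, small_sim):
        panel, _, _ = small_sim
        gap = panel.panel[panel.panel["date"] != dt.date(2002, 6, 1)]
        with pytest.raises(ValidationError):
            PanelData(panel=gap, covariates=panel.covariates)
        PanelData(panel=gap, covariates=panel.covariates, allow_gaps=True)

    def test_nonpositive_population_rejected(self, small_sim):
        panel, _, _ = small_sim
        bad = panel.panel.copy()
        bad.loc[0, "population"] = 0
        with pytest.raises(ValidationError):
            PanelData(panel=bad, covariates=panel.covariates)


class TestBuildDesign:
    def test_reference_row_is_all_zero(self, small_sim):
        panel, truth, graph = small_sim
        design = build_design(panel, truth.calendar, graph, GLM_SPEC)
        cal = truth.calendar.frame
        ref_days = set(
            cal.loc[(cal["dow"] == "Sun") & (cal["period"] == OTHER), "date"]
        )
        rows = panel.panel.sort_values(["date", "district"]).reset_index(drop=True)
        mask = rows["date"].isin(ref_days).to_numpy()
        fixed = design.C[:, 1:9]
        assert np.all(fixed[mask] == 0)
        assert np.all(design.C[:, 0] == 1)

    def test_row_count_and_offset(self, small_sim):
        panel, truth, graph = small_sim
        design = build_design(panel, truth.calendar, graph, GLM_SPEC)
        assert design.n_obs == 8 * 365
        pop = panel.panel.sort_values(["date", "district"])["population"].to_numpy()
        np.testing.assert_allclose(design.offset, np.log(pop))

    def test_missing_district_in_graph_listed(self, small_sim):
        panel, truth, graph = small_sim
        import ads_star.spatial_graph as sg

        small_graph = sg.lattice_graph(4)  # ids don't match the panel's
        with pytest.raises(ValidationError, match="missing from adjacency"):
            build_design(panel, truth.calendar, small_graph, ModelSpec())

    def test_unknown_pollutant_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(pollutants=("XX",))

    def test_pollutant_lag_shifts_series(self, small_sim):
        panel, truth, graph = small_sim
        spec = ModelSpec(pollutants=("NOx",), pollutant_lag=1, use_time_smooth=False,
                         use_temp_smooth=False, use_spatial=False, )
        with pytest.raises(ValidationError, match="missing from the covariate"):
            # first study day has no lag-1 value, so the join must fail loudly
            build_design(panel, truth.calendar, graph, spec)


class TestPirls:
    def test_intercept_only_closed_form(self, small_sim):
        panel, truth, graph = small_sim
        spec = ModelSpec(use_time_smooth=False, use_temp_smooth=False, use_spatial=False)
        design = build_design(panel, truth.calendar, None, spec)
        design.C = design.C[:, :1]
        design.col_names = ["(Intercept)"]
        fit = fit_pirls(design, {}, tol=1e-12)
        expected = np.log(design.y.sum() / np.exp(design.offset).sum())
        assert fit.beta[0] == pytest.approx(expected, abs=1e-9)
        assert fit.edf_total == pytest.approx(1.0, abs=1e-9)

    def test_matches_glm_oracle(self, small_sim):
        panel, truth, graph = small_sim
        design = build_design(panel, truth.calendar, None, GLM_SPEC)
        fit = fit_pirls(design, {}, tol=1e-12)
        oracle = _oracle_glm(design)
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-6, rtol=1e-6)
        np.testing.assert_allclose(fit.se, oracle.bse, atol=1e-6, rtol=1e-6)
        assert fit.aic == pytest.approx(oracle.aic, abs=1e-6)
        assert aic(fit) == pytest.approx(fit.aic)

    def test_spatial_penalty_to_infinity_zeroes_field(self, small_design):
        fit = fit_pirls(small_design, {"time": 1.0, "temp": 1.0, "spatial": 1e-12})
        sl = fit.block_slice("spatial")
        np.testing.assert_allclose(fit.beta[sl], 0, atol=1e-4)

    def test_penalized_deviance_monotone(self, small_design):
        fit = fit_pirls(small_design, {"time": 0.01, "temp": 0.01, "spatial": 0.01})
        pdevs = [t["penalized_deviance"] for t in fit.trace]
        for a, b in zip(pdevs, pdevs[1:]):
            assert b <= a * (1 + 1e-10) + 1e-8

    def test_nonintegral_counts_rejected(self, small_design):
        y = small_design.y.copy()
        small_design_bad = small_design
        old = small_design_bad.y
        small_design_bad.y = y + 0.5
        try:
            with pytest.raises(ValidationError):
                fit_pirls(small_design_bad, {})
        finally:
            small_design_bad.y = old

    def test_covariance_symmetric_psd(self, small_design):
        fit = fit_pirls(small_design, {})
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(fit.cov).min() > 0

    def test_adding_noise_pollutant_never_worsens_deviance(self, small_sim):
        panel, truth, graph = small_sim
        spec1 = ModelSpec(pollutants=("NOx",), use_time_smooth=False,
                          use_temp_smooth=False, use_spatial=False)
        spec2 = ModelSpec(pollutants=("NOx", "CO"), use_time_smooth=False,
                          use_temp_smooth=False, use_spatial=False)
        f1 = fit_pirls(build_design(panel, truth.calendar, None, spec1), {}, tol=1e-10)
        f2 = fit_pirls(build_design(panel, truth.calendar, None, spec2), {}, tol=1e-10)
        assert -2 * f2.loglik <= -2 * f1.loglik + 1e-6


class TestReml:
    def test_refit_at_converged_variances_is_fixed_point(self, small_design, small_spec):
        fit = estimate_variances(small_design, small_spec)
        refit = fit_pirls(small_design, fit.tau2, beta0=fit.beta)
        np.testing.assert_allclose(refit.beta, fit.beta, atol=1e-8)

    def test_edf_bounds_and_aic_identity(self, small_design, small_spec):
        fit = estimate_variances(small_design, small_spec)
        for b in fit.blocks:
            size = b.sl.stop - b.sl.start
            assert 0 < fit.edf_blocks[b.name] <= size + 1e-9
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.edf_total)

    def test_offset_correctness(self, small_sim, small_spec):
        """Doubling every population shifts only the intercept, by -log 2."""
        panel, truth, graph = small_sim
        design = build_design(panel, truth.calendar, graph, small_spec)
        fit = estimate_variances(design, small_spec)
        doubled = PanelData(
            panel=panel.panel.assign(population=2 * panel.panel["population"]),
            covariates=panel.covariates,
        )
        design2 = build_design(doubled, truth.calendar, graph, small_spec)
        fit2 = fit_pirls(design2, fit.tau2, beta0=fit.beta)
        assert fit2.beta[0] - fit.beta[0] == pytest.approx(-np.log(2), abs=1e-6)
        np.testing.assert_allclose(fit2.beta[1:], fit.beta[1:], atol=1e-5)

    def test_linear_temperature_truth_shrinks_temp_smooth(self):
        """With an exactly linear temperature effect the temp smooth collapses
        towards its (post-constraint) null space: edf near the 2 parameters of
        a line, averaged over replicates."""
        edfs = []
        for seed in (9, 21, 33):
            cfg = SimConfig(
                seed=seed, n_districts=12, start=dt.date(2002, 1, 1),
                end=dt.date(2003, 12, 31),
                temperature_effect=lambda tp: 0.01 * tp, baseline_rate=5e-3,
            )
            panel, truth, graph = generate_panel(cfg)
            spec = ModelSpec(time_n_basis=8, temp_n_basis=8, ig_damping=False)
            design = build_design(panel, truth.calendar, graph, spec)
            fit = estimate_variances(design, spec)
            edfs.append(fit.edf_blocks["temp"])
        assert np.mean(edfs) == pytest.approx(2.0, abs=0.75)

    def test_nonlinear_temperature_recovered(self):
        """Strongly nonlinear truth: tau2 stays away from zero and the fitted
        curve tracks truth inside its 95% band at most grid points
        (scaled-down replicate count)."""
        from ads_star.effects_reporting import smoother_curve
        from ads_star.synthetic_data import default_temperature_effect

        fractions = []
        for seed in (11, 17):
            cfg = SimConfig(seed=seed, n_districts=8, start=dt.date(2002, 1, 1),
                            end=dt.date(2003, 12, 31))
            panel, truth, graph = generate_panel(cfg)
            spec = ModelSpec(time_n_basis=8, temp_n_basis=8)
            design = build_design(panel, truth.calendar, graph, spec)
            fit = estimate_variances(design, spec)
            assert fit.tau2["temp"] > 1e-8
            tp = panel.covariates["temperature"].to_numpy()
            grid = np.linspace(np.percentile(tp, 2), np.percentile(tp, 98), 40)
            curve = smoother_curve(fit, "temp", grid)
            tru = default_temperature_effect(grid) - default_temperature_effect(tp).mean()
            inside = np.mean(
                (np.exp(tru) >= curve["rr_low_95"]) & (np.exp(tru) <= curve["rr_high_95"])
            )
            fractions.append(inside)
        assert np.mean(fractions) >= 0.85

    def test_ig_damping_toggle_changes_little(self, small_design, small_spec):
        from dataclasses import replace

        fit_on = estimate_variances(small_design, small_spec)
        fit_off = estimate_variances(small_design, replace(small_spec, ig_damping=False))
        np.testing.assert_allclose(fit_on.beta[:9], fit_off.beta[:9], atol=5e-3)


class TestPersistence:
    def test_fit_result_json_round_trip(self, small_design, small_spec, tmp_path):
        from ads_star.star_model import FitResult

        fit = estimate_variances(small_design, small_spec)
        fit.save(tmp_path / "fit.json")
        back = FitResult.load(tmp_path / "fit.json")
        np.testing.assert_allclose(back.beta, fit.beta)
        np.testing.assert_allclose(back.cov, fit.cov)
        assert back.col_names == fit.col_names
        assert back.tau2 == pytest.approx(fit.tau2)
        assert back.meta["spatial_ids"] == fit.meta["spatial_ids"]
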