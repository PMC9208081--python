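import numpy as np
import pandas as pd
import pytest

from organoscore import (
    DoseResponseTransformer,
    compute_auc,
    fit_curve,
    normalize_auc_cohort,
    normalize_viability,
    summarize_cohort,
)

GRID = 10.0 / 10.0 ** np.arange(6)  # 10, 1, ... 1e-4 µM


def _table(rows):
    return pd.DataFrame(rows, columns=["organoid", "drug", "concentration_um",
                                       "replicate", "signal", "is_vehicle"])


class TestNormalizeViability:
    def test_signal_at_vehicle_mean_maps_to_one(self):
        t = _table([
            ("A", "d", 0.0, 1, 9000, True),
            ("A", "d", 0.0, 2, 11000, True),
            ("A", "d", 1.0, 1, 10000, False),
        ])
        out = normalize_viability(t)
        assert out.loc[2, "viability_fraction"] == pytest.approx(1.0)

    def test_half_vehicle_signal_maps_to_half(self):
        t = _table([
            ("A", "d", 0.0, 1, 9000, True),
            ("A", "d", 0.0, 2, 11000, True),
            ("A", "d", 1.0, 1, 5000, False),
        ])
        assert normalize_viability(t).loc[2, "viability_fraction"] == pytest.approx(0.5)

    def test_zero_signal_maps_to_zero(self):
        t = _table([
            ("A", "d", 0.0, 1, 10000, True),
            ("A", "d", 1.0, 1, 0, False),
        ])
        assert normalize_viability(t).loc[1, "viability_fraction"] == 0.0

    def test_missing_vehicle_error_names_group(self):
        t = _table([("A", "d", 0.0, 1, 10000, True),
                    ("B", "d", 1.0, 1, 5000, False)])
        with pytest.raises(ValueError, match="B"):
            normalize_viability(t)

    def test_zero_vehicle_mean_rejected(self):
        t = _table([("A", "d", 0.0, 1, 0.0, True),
                    ("A", "d", 1.0, 1, 5000, False)])
        with pytest.raises(ValueError, match="zero"):
            normalize_viability(t)

    def test_groups_by_plate_when_present(self):
        t = _table([
            ("A", "d", 0.0, 1, 1000, True),
            ("A", "d", 1.0, 1, 500, False),
            ("A", "e", 0.0, 1, 2000, True),
            ("A", "e", 1.0, 1, 500, False),
        ])
        t["plate"] = ["p1", "p1", "p2", "p2"]
        out = normalize_viability(t)
        assert out.loc[1, "viability_fraction"] == pytest.approx(0.5)
        assert out.loc[3, "viability_fraction"] == pytest.approx(0.25)


def _4pl(c, top, bottom, hill, ic50):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


class TestFitCurve:
    def test_noiseless_recovery_within_one_percent(self):
        y = _4pl(GRID, 1.0, 0.0, 1.0, 0.1)
        fit = fit_curve(GRID, y)
        assert not fit.ic50_censored
        assert fit.ic50 == pytest.approx(0.1, rel=0.01)

    def test_flat_viability_reports_right_censored_ic50(self):
        fit = fit_curve(GRID, np.ones_like(GRID))
        assert fit.ic50_censored
        assert fit.ic50 == pytest.approx(10.0)

    def test_fit_passes_through_4pl_midpoint(self):
        ic50 = 0.1
        y = _4pl(GRID, 1.0, 0.1, 1.0, ic50)
        fit = fit_curve(GRID, y)
        mid = fit.bottom + (fit.top - fit.bottom) / 2
        fitted_at_ic50 = _4pl(np.array([fit.ic50]), fit.top, fit.bottom,
                              fit.hill, fit.ic50)[0]
        assert fitted_at_ic50 == pytest.approx(mid, abs=1e-6)
        assert fitted_at_ic50 == pytest.approx(0.55, abs=0.01)

    def test_replicate_level_input_accepted(self):
        doses = np.repeat(GRID, 3)
        rng = np.random.default_rng(0)
        y = _4pl(doses, 1.0, 0.0, 1.0, 0.5) * (1 + rng.normal(0, 0.05, doses.size))
        fit = fit_curve(doses, y)
        assert fit.ic50 == pytest.approx(0.5, rel=0.3)

    def test_fewer_than_four_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_curve(np.array([1.0, 0.1, 0.01]), np.array([1.0, 0.5, 0.1]))

    def test_non_finite_fractions_rejected(self):
        y = np.ones_like(GRID)
        y[2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_curve(GRID, y)

    def test_recovery_under_assay_noise(self):
        # small-scale version of the cohort-level recovery property
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(20):
            true = 10.0 ** rng.uniform(-2, 0.5)
            doses = np.repeat(GRID, 3)
            y = np.maximum(_4pl(doses, 1.0, 0.1, 1.0, true)
                           * (1 + rng.normal(0, 0.10, doses.size)), 0)
            fit = fit_curve(doses, y)
            if not fit.ic50_censored:
                errors.append(abs(np.log10(fit.ic50 / true)))
        assert np.median(errors) < 0.15


class TestComputeAuc:
    def test_constant_viability_over_five_decades(self):
        auc_raw, auc_span = compute_auc(GRID, np.ones(6))
        assert auc_raw == pytest.approx(5.0)
        assert auc_span == pytest.approx(1.0)

    def test_zero_viability(self):
        assert compute_auc(GRID, np.zeros(6)) == (0.0, 0.0)

    def test_linear_in_log_dose_gives_half_span(self):
        y = np.linspace(0.0, 1.0, 6)  # 0 at 10 µM .. 1 at 1e-4 µM
        _, auc_span = compute_auc(GRID, y)
        assert auc_span == pytest.approx(0.5)

    def test_negative_viability_clipped_before_integration(self):
        y = np.array([-0.5, -0.5, 0.0, 1.0, 1.0, 1.0])
        auc_raw, _ = compute_auc(GRID, y)
        assert auc_raw >= 0

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            compute_auc(np.array([1.0]), np.array([0.5]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fine_grid_riemann_oracle(self, seed):
        # on piecewise-linear input the trapezoid equals a dense Riemann sum
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 1.2, size=6)
        log_c = np.log10(np.sort(GRID))
        y_sorted = y[np.argsort(GRID)]
        dense = np.linspace(log_c[0], log_c[-1], 200001)
        yd = np.interp(dense, log_c, y_sorted)
        oracle = float(np.sum((yd[:-1] + yd[1:]) / 2) * (dense[1] - dense[0]))
        auc_raw, _ = compute_auc(GRID, y)
        assert auc_raw == pytest.approx(oracle, abs=1e-9)


class TestComputeAucFromFit:
    def test_agrees_with_measured_grid_on_noiseless_curve(self):
        from organoscore import compute_auc_from_fit

        y = _4pl(GRID, 1.0, 0.1, 1.0, 0.1)
        fit = fit_curve(GRID, y)
        _, span_meas = compute_auc(GRID, y)
        _, span_fit = compute_auc_from_fit(fit, GRID.min(), GRID.max())
        assert span_fit == pytest.approx(span_meas, abs=0.01)

    def test_invalid_dose_range_rejected(self):
        from organoscore import compute_auc_from_fit

        fit = fit_curve(GRID, _4pl(GRID, 1.0, 0.1, 1.0, 0.1))
        with pytest.raises(ValueError):
            compute_auc_from_fit(fit, 10.0, 1.0)


class TestNormalizeAucCohort:
    def test_divides_by_cohort_max(self):
        vals = pd.Series({"a": 0.2, "b": 0.4, "c": 0.8})
        out = normalize_auc_cohort(vals)
        assert out.to_dict() == pytest.approx({"a": 0.25, "b": 0.5, "c": 1.0})

    def test_single_organoid_gets_one(self):
        assert normalize_auc_cohort(pd.Series({"a": 0.37})).loc["a"] == 1.0

    def test_order_preserved(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.uniform(0.01, 1, 20))
        out = normalize_auc_cohort(vals)
        assert (vals.rank() == out.rank()).all()

    def test_ties_at_max_all_get_one(self):
        out = normalize_auc_cohort(pd.Series([0.5, 0.8, 0.8]))
        assert out.tolist() == pytest.approx([0.625, 1.0, 1.0])

    def test_zero_cohort_max_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_auc_cohort(pd.Series([0.0, 0.0]))


class TestDoseResponseTransformer:
    def test_cohort_maximal_organoid_scores_exactly_one(self, small_cohort):
        tr = DoseResponseTransformer().fit(small_cohort.viability)
        curves = tr.transform(small_cohort.viability)
        for _, grp in curves.groupby("drug"):
            assert grp["auc_norm"].max() == pytest.approx(1.0)
            assert (grp["auc_norm"] <= 1 + 1e-12).all()

    def test_auc_norm_rank_matches_auc_span_rank(self, small_cohort):
        curves = DoseResponseTransformer().fit_transform(small_cohort.viability)
        for _, grp in curves.groupby("drug"):
            assert (grp["auc_span"].rank() == grp["auc_norm"].rank()).all()

    def test_auc_monotone_in_latent_resistance_noiseless(self):
        from organoscore import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_organoids=8, drugs={"X": (-2.0, 1.0)},
                               noise_cv=0.0, seed=5, n_bsc=0,
                               n_low_concordance=0, n_post_treatment=0,
                               n_lost_followup=0, n_palliative=0)
        cohort = simulate_cohort(cfg)
        curves = DoseResponseTransformer().fit_transform(cohort.viability)
        merged = curves.set_index("organoid").join(cohort.rho.rename(columns={"X": "rho"}))
        order = merged.sort_values("rho")["auc_span"].to_numpy()
        assert (np.diff(order) >= -1e-12).all()

    def test_sklearn_params_round_trip(self):
        tr = DoseResponseTransformer(fit_ic50=True)
        assert tr.get_params() == {"fit_ic50": True}
        tr.set_params(fit_ic50=False)
        assert tr.fit_ic50 is False

    def test_transform_before_fit_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="not fitted"):
            DoseResponseTransformer().transform(small_cohort.viability)

    def test_summarize_includes_ic50_when_requested(self, small_cohort):
        curves = summarize_cohort(small_cohort.viability, fit_ic50=True)
        assert {"ic50", "ic50_censored", "top", "bottom", "hill"} <= set(curves.columns)
        assert curves["ic50"].gt(0).all()
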