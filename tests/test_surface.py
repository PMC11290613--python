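"""Grids, profiles, prediction surfaces, bands and hover lookup."""

import numpy as np
import pytest

from survcontour.cox import fit_cox
from survcontour.data import SurvivalDataset
from survcontour.errors import RangeError
from survcontour.surface import (
    GridSpec,
    SurvivalSurface,
    build_grid,
    compute_surface,
    default_profile,
    surface_ci,
    value_at,
)
from survcontour.synthetic import SimSpec, gen_ph_weibull, true_survival_ph_weibull
from survcontour.weibull import fit_weibull


def _simple_ds(x):
    return SurvivalDataset.from_arrays(times=np.ones(len(x)), events=np.ones(len(x), int),
                                       predictor=np.asarray(x, float))


class TestBuildGrid:
    def test_linear_five_points(self):
        g = build_grid(_simple_ds([0.0, 1.0]), strategy="linear", n_points=5)
        assert np.allclose(g.covariate_values, [0, 0.25, 0.5, 0.75, 1.0])

    def test_quantile_collapses_duplicates(self):
        g = build_grid(_simple_ds([1.0, 1.0, 1.0, 2.0]), strategy="quantile", n_points=3)
        assert np.array_equal(g.covariate_values, [1.0, 2.0])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            build_grid(_simple_ds([0.0, 1.0]), n_points=1)

    def test_time_grid_prepends_zero(self, ph_dataset):
        g = build_grid(ph_dataset, n_points=10)
        assert g.time_grid[0] == 0.0
        assert np.all(np.diff(g.time_grid) > 0)


class TestDefaultProfile:
    def test_median_and_mode(self):
        ds = SurvivalDataset.from_arrays(
            times=[1, 2, 3], events=[1, 1, 1], predictor=[0.0, 1.0, 2.0],
            adjusters={"age": np.array([1.0, 2.0, 3.0]),
                       "sex": np.array(["F", "F", "M"])},
            adjuster_kinds={"age": "continuous", "sex": "categorical"},
        )
        prof = default_profile(ds)
        assert prof["age"] == 2.0
        assert prof["sex"] == "F"
        assert prof.sources["age"] == "default"

    def test_frequency_tie_broken_by_sorted_order(self):
        ds = SurvivalDataset.from_arrays(
            times=[1, 2], events=[1, 1], predictor=[0.0, 1.0],
            adjusters={"g": np.array(["b", "a"])}, adjuster_kinds={"g": "categorical"},
        )
        assert default_profile(ds)["g"] == "a"


class TestComputeSurface:
    def test_zero_beta_rows_identical(self):
        # symmetric design: beta exactly 0, all rows = baseline survival
        ds = SurvivalDataset.from_arrays(
            times=[1.0, 1.0, 2.0, 2.0, 3.0, 3.0], events=[1] * 6,
            predictor=[0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        )
        fit = fit_cox(ds, ties="breslow")
        surf = compute_surface(fit, build_grid(ds, n_points=7), ci_level=None)
        assert np.allclose(surf.values, surf.values[0][None, :], atol=1e-12)

    def test_rows_ordered_by_predictor_when_beta_positive(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        assert fit.beta[0] > 0
        surf = compute_surface(fit, build_grid(ph_dataset, n_points=12), ci_level=None)
        diffs = np.diff(surf.values, axis=0)  # higher predictor -> lower survival
        assert np.all(diffs <= 1e-12)

    def test_rows_monotone_in_time(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        surf = compute_surface(fit, build_grid(ph_dataset, n_points=12))
        assert np.all(np.diff(surf.values, axis=1) <= 1e-12)
        assert surf.values.min() >= 0 and surf.values.max() <= 1

    def test_weibull_closed_form_cell(self):
        ds = gen_ph_weibull(SimSpec(n=60, beta=(0.1,), seed=14))
        fit = fit_weibull(ds)
        fit.shape, fit.scale = 1.0, 1.0
        fit.gamma = np.array([np.log(2.0)])
        grid = GridSpec(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        surf = compute_surface(fit, grid, ci_level=None)
        assert surf.values[1, 1] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_bands_present_and_ordered_for_cox(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        surf = compute_surface(fit, build_grid(ph_dataset, n_points=8), ci_level=0.95)
        assert surf.has_bands
        assert np.all(surf.lower <= surf.values + 1e-12)
        assert np.all(surf.values <= surf.upper + 1e-12)
        assert np.all((surf.lower >= 0) & (surf.upper <= 1))

    def test_band_collapses_at_survival_one(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        surf = compute_surface(fit, build_grid(ph_dataset, n_points=5))
        assert np.all(surf.values[:, 0] == 1.0)  # t = 0
        assert np.all(surf.lower[:, 0] == 1.0) and np.all(surf.upper[:, 0] == 1.0)

    def test_extrapolation_warns(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        far = GridSpec(np.linspace(-50, 50, 5), np.array([0.0, 1.0]))
        with pytest.warns(UserWarning, match="extrapolation"):
            compute_surface(fit, far, ci_level=None)

    def test_json_roundtrip_exact(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        surf = compute_surface(fit, build_grid(ph_dataset, n_points=6))
        back = SurvivalSurface.from_json(surf.to_json())
        assert np.array_equal(back.values, surf.values)
        assert np.array_equal(back.lower, surf.lower)
        assert np.array_equal(back.time_grid, surf.time_grid)


class TestSurfaceCI:
    def test_bootstrap_and_delta_band_widths_agree(self):
        ds = gen_ph_weibull(SimSpec(n=500, beta=(0.5,), censoring_rate=0.3, seed=23))
        fit = fit_cox(ds)
        grid = build_grid(ds, n_points=5, time_grid=np.quantile(
            ds.times[ds.events == 1], [0.0, 0.25, 0.5, 0.75]))
        delta = compute_surface(fit, grid, ci_level=0.95)
        boot = surface_ci(fit, delta, method="bootstrap", n_boot=100, seed=4)
        wd = np.median((delta.upper - delta.lower)[:, 1:])
        wb = np.median((boot.upper - boot.lower)[:, 1:])
        assert abs(wd - wb) / wd < 0.3

    def test_delta_band_covers_truth_at_median_row(self):
        # single-replicate sanity; the acceptance suite measures coverage
        spec = SimSpec(n=300, beta=(0.5,), censoring_rate=0.3, seed=77)
        ds = gen_ph_weibull(spec)
        fit = fit_cox(ds)
        xmed = float(np.median(ds.predictor))
        tq = np.quantile(ds.times[ds.events == 1], [0.25, 0.5, 0.75])
        grid = GridSpec(np.array([xmed - 1, xmed, xmed + 1]), np.r_[0.0, tq])
        surf = compute_surface(fit, grid, ci_level=0.95)
        truth = true_survival_ph_weibull(spec, [xmed], tq)
        i = 1  # median row
        assert np.all(surf.lower[i, 1:] <= truth + 0.05)
        assert np.all(truth <= surf.upper[i, 1:] + 0.05)


class TestValueAt:
    @pytest.fixture
    def surf(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        return compute_surface(fit, build_grid(ph_dataset, n_points=9))

    def test_grid_node_returns_stored_cell(self, surf):
        i, j = 4, 10
        est, lo, hi = value_at(surf, float(surf.time_grid[j]),
                               float(surf.covariate_values[i]))
        assert est == surf.values[i, j]
        assert lo == surf.lower[i, j] and hi == surf.upper[i, j]

    def test_linear_interpolation_between_rows(self):
        surf = SurvivalSurface(
            time_grid=np.array([0.0, 1.0]),
            covariate_values=np.array([0.0, 1.0]),
            values=np.array([[1.0, 0.4], [1.0, 0.6]]),
            outcome_type="survival",
        )
        est, _, _ = value_at(surf, 1.0, 0.5)
        assert est == pytest.approx(0.5)

    def test_before_first_event_time_is_one(self, surf):
        t_first = surf.time_grid[1]
        est, _, _ = value_at(surf, float(t_first) * 0.5, float(surf.covariate_values[0]))
        assert est == 1.0

    def test_out_of_range_rejected(self, surf):
        with pytest.raises(RangeError):
            value_at(surf, float(surf.time_grid[-1]) * 1.01, float(surf.covariate_values[0]))
        with pytest.raises(RangeError):
            value_at(surf, 0.0, float(surf.covariate_values[-1]) + 1.0)
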