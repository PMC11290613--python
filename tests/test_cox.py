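"""Cox model: partial likelihood, baseline, prediction, stratification."""

import numpy as np
import pytest
from scipy import optimize

from survcontour.cox import breslow_baseline, fit_cox, fit_stratified_cox, predict_survival_cox
from survcontour.data import SurvivalDataset
from survcontour.errors import ConvergenceError, DegenerateDesignError
from survcontour.km import nelson_aalen
from survcontour.synthetic import SimSpec, gen_ph_weibull, gen_stratified


def _ds(times, events, x):
    return SurvivalDataset.from_arrays(times=times, events=events, predictor=x)


class TestFitCox:
    def test_symmetric_design_gives_zero_beta(self):
        ds = _ds([1.0, 1.0, 2.0, 2.0], [1, 1, 1, 1], [0.0, 1.0, 0.0, 1.0])
        fit = fit_cox(ds)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_partial_likelihood_scan(self):
        # independent oracle: the partial likelihood written out longhand,
        # maximized by a 1-D bounded scan
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_pl(beta):
            ll = 0.0
            for i in range(4):
                if events[i]:
                    risk = times >= times[i]
                    ll += x[i] * beta - np.log(np.sum(np.exp(x[risk] * beta)))
            return -ll

        brute = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                         options={"xatol": 1e-10})
        fit = fit_cox(_ds(times, events, x), ties="breslow")
        assert abs(fit.beta[0] - brute.x) < 1e-3

    def test_perfect_risk_ordering_diverges(self):
        ds = _ds([1.0, 2.0], [1, 1], [1.0, 0.0])
        with pytest.raises(ConvergenceError, match="monotone"):
            fit_cox(ds)

    def test_constant_covariate_degenerate(self):
        ds = _ds([1.0, 2.0, 3.0], [1, 1, 1], [2.0, 2.0, 2.0])
        with pytest.raises(DegenerateDesignError):
            fit_cox(ds)

    def test_competing_codes_censored_with_warning(self):
        ds = SurvivalDataset.from_arrays(
            times=[1.0, 2.0, 3.0, 4.0], events=[1, 2, 1, 0], predictor=[0.5, 1.0, 0.0, 1.5]
        )
        with pytest.warns(UserWarning, match="competing"):
            fit = fit_cox(ds)
        ds_cens = SurvivalDataset.from_arrays(
            times=[1.0, 2.0, 3.0, 4.0], events=[1, 0, 1, 0], predictor=[0.5, 1.0, 0.0, 1.5]
        )
        assert fit.beta == pytest.approx(fit_cox(ds_cens).beta)

    def test_efron_differs_from_breslow_under_ties(self):
        ds = _ds([1.0, 1.0, 2.0, 3.0, 3.0, 4.0], [1, 1, 1, 1, 1, 0],
                 [0.3, 1.2, -0.5, 0.8, -1.0, 0.1])
        be = fit_cox(ds, ties="efron").beta[0]
        bb = fit_cox(ds, ties="breslow").beta[0]
        assert be != pytest.approx(bb, abs=1e-6)


class TestBreslowBaseline:
    def test_nelson_aalen_at_zero_beta(self):
        # symmetric design forces beta = 0; baseline must equal Nelson-Aalen
        times = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]
        fit = fit_cox(_ds(times, [1] * 6, [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]),
                      ties="breslow")
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-9)
        na = nelson_aalen(times, [1] * 6)
        bl = breslow_baseline(fit)
        for t in (1.0, 2.0, 3.0):
            assert bl(t) == pytest.approx(na(t), abs=1e-12)
        # hand-checkable increments: 2/6, 2/4, 2/2
        assert bl(1.0) == pytest.approx(1 / 3, abs=1e-12)
        assert bl(2.0) == pytest.approx(1 / 3 + 1 / 2, abs=1e-12)
        assert bl(3.0) == pytest.approx(1 / 3 + 1 / 2 + 1, abs=1e-12)

    def test_no_events_baseline_zero(self):
        # a stratum with no events contributes a flat zero baseline
        ds = SurvivalDataset.from_arrays(
            times=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0], events=[1, 1, 1, 1, 0, 0],
            predictor=[0.1, 0.9, 0.2, 0.8, 0.4, 0.6],
            strata=["a", "a", "a", "a", "b", "b"],
        )
        fit = fit_stratified_cox(ds)
        assert breslow_baseline(fit)["b"](10.0) == 0.0


class TestPredictSurvival:
    def test_closed_form_cell(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        # S = exp(-Lambda0 * e^{x beta}); check against the baseline directly
        bl = breslow_baseline(fit)
        t = float(np.median(ph_dataset.times))
        row = np.array([0.7])
        res = predict_survival_cox(fit, row, [t])
        assert res.values[0] == pytest.approx(
            np.exp(-bl(t) * np.exp(0.7 * fit.beta[0]))
        )

    def test_survival_one_at_time_zero(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        assert predict_survival_cox(fit, [2.0], [0.0]).values[0] == 1.0

    def test_negative_time_rejected(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        with pytest.raises(ValueError):
            predict_survival_cox(fit, [0.0], [-1.0])

    def test_curve_monotone_in_unit_interval(self, ph_dataset):
        fit = fit_cox(ph_dataset)
        grid = np.linspace(0, ph_dataset.times.max(), 60)
        vals = predict_survival_cox(fit, [1.5], grid).values
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_delta_variance_close_to_bootstrap(self):
        """Asymptotic Var[Shat(t|x)] vs the empirical variance over refits."""
        spec = SimSpec(n=200, beta=(0.5,), censoring_rate=0.3, seed=99)
        ds = gen_ph_weibull(spec)
        fit = fit_cox(ds)
        t = float(np.quantile(ds.times[ds.events == 1], 0.5))
        row = np.array([0.0])
        res = fit.predict_curve(row, [t])
        S, var_loglam = res.values[0], res.var_log_cumhaz[0]
        # delta step: Var(S) = (S log S)^2 Var(log Lambda)
        var_delta = (S * np.log(S)) ** 2 * var_loglam
        rng = np.random.default_rng(7)
        boots = []
        for _ in range(500):
            idx = rng.integers(0, ds.n, ds.n)
            try:
                bfit = fit_cox(ds.take(idx))
            except Exception:
                continue
            boots.append(bfit.predict_curve(row, [t]).values[0])
        var_emp = np.var(boots)
        assert abs(var_delta - var_emp) / var_emp < 0.25


class TestStratifiedCox:
    def test_two_identical_strata_match_unstratified(self, ph_dataset):
        base = fit_cox(ph_dataset, ties="breslow")
        doubled = SurvivalDataset.from_arrays(
            times=np.concatenate([ph_dataset.times] * 2),
            events=np.concatenate([ph_dataset.events] * 2),
            predictor=np.concatenate([ph_dataset.predictor] * 2),
            strata=np.repeat(["a", "b"], ph_dataset.n),
        )
        strat = fit_stratified_cox(doubled, ties="breslow")
        assert strat.beta == pytest.approx(base.beta, abs=1e-7)

    def test_singleton_strata_degenerate(self):
        ds = SurvivalDataset.from_arrays(
            times=[1.0, 2.0, 3.0], events=[1, 1, 1], predictor=[0.1, 0.5, 0.9],
            strata=["a", "b", "c"],
        )
        with pytest.raises(DegenerateDesignError):
            fit_stratified_cox(ds)

    def test_recovers_shared_beta_across_different_baselines(self):
        spec = SimSpec(n=250, beta=(0.7,), censoring_rate=0.2, seed=17)
        ds = gen_stratified(spec, scales=(0.7, 2.0))
        fit = fit_stratified_cox(ds)
        se = np.sqrt(fit.covariance[0, 0])
        assert abs(fit.beta[0] - 0.7) < 3 * se
        assert set(fit.baselines) == {"s0", "s1"}
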