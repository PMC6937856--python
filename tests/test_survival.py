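from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sdvimpact.survival import (
    CovariateTerm, CoxFit, cox_fit, hr_contrast, incidence_at, km_estimate,
    place_knots, rcs_basis,
)


def km_bruteforce(times, events):
    """Exact rational product-limit values at each event time (independent
    oracle for n <= 20)."""
    times = list(times)
    events = list(events)
    ev = sorted({t for t, e in zip(times, events) if e})
    out = {}
    s = Fraction(1)
    for u in ev:
        n = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e)
        s *= Fraction(n - d, n)
        out[u] = s
    return out


class TestKaplanMeier:
    def test_hand_product_limit_values(self):
        s = km_estimate([1, 2, 3], [1, 0, 1])
        assert s.survival_at(1) == pytest.approx(2 / 3)
        assert s.survival_at(3) == 0.0

    def test_all_censored_is_flat_one(self):
        s = km_estimate([5, 8, 2], [0, 0, 0])
        assert (s.survival == 1.0).all()
        assert s.n_event.sum() == 0

    def test_matches_exact_rational_oracle_small_n(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 21))
            t = rng.integers(1, 10, size=n).astype(float)
            e = rng.random(n) < 0.6
            if not e.any():
                continue
            s = km_estimate(t, e)
            oracle = km_bruteforce(t, e)
            for u, frac in oracle.items():
                assert s.survival_at(u) == pytest.approx(float(frac), abs=1e-12)

    def test_matches_lifelines_including_greenwood_ci(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 400)
        e = rng.random(400) < 0.7
        s = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ll = kmf.survival_function_at_times(s.times).to_numpy()
        assert np.abs(ll - s.survival).max() < 1e-12
        ci = kmf.confidence_interval_survival_function_
        idx = np.searchsorted(ci.index.to_numpy(), s.times)
        assert np.abs(ci.iloc[idx, 0].to_numpy() - s.ci_low).max() < 1e-9
        assert np.abs(ci.iloc[idx, 1].to_numpy() - s.ci_high).max() < 1e-9

    def test_exponential_closed_form_large_n(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1 / 0.1, 20_000)  # rate 0.1 / year
        s = km_estimate(t, np.ones_like(t, bool))
        grid = np.linspace(0.01, 5, 200)
        est = np.array([s.survival_at(g) for g in grid])
        assert np.abs(est - np.exp(-0.1 * grid)).max() < 0.01

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestIncidence:
    def test_zero_horizon(self):
        s = km_estimate([1, 2, 3], [1, 0, 1])
        inc, _, ex = incidence_at(s, 0)
        assert inc == 0.0 and not ex

    def test_complement_identity(self):
        s = km_estimate([100, 500, 1094, 2000], [1, 0, 1, 0])
        inc, _, _ = incidence_at(s, 1096)
        assert inc == pytest.approx(1 - s.survival_at(1094))

    def test_exponential_three_year_closed_form(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1 / 0.1, 20_000)
        s = km_estimate(t, np.ones_like(t, bool))
        inc, _, _ = incidence_at(s, 3.0)
        assert abs(inc - (1 - np.exp(-0.3))) < 0.01

    def test_extrapolation_flagged(self):
        s = km_estimate([1, 2], [1, 1])
        _, _, ex = incidence_at(s, 10)
        assert ex


class TestSplines:
    def test_uniform_grid_knots_at_expected_percentiles(self):
        knots = place_knots(np.arange(101), 4)
        assert np.allclose(knots, [5, 35, 65, 95])

    def test_constant_input_fatal(self):
        with pytest.raises(ValueError):
            place_knots(np.full(50, 3.0), 4)

    def test_knots_strictly_increasing(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=200)
            k = place_knots(x, 4)
            assert (np.diff(k) > 0).all()

    def test_four_knots_give_three_columns(self):
        x = np.linspace(0, 10, 50)
        B = rcs_basis(x, place_knots(x, 4))
        assert B.shape == (50, 3)

    def test_nonlinear_columns_vanish_below_first_knot(self):
        knots = np.array([2.0, 4.0, 6.0, 8.0])
        B = rcs_basis(np.linspace(-5, 1.9, 40), knots)
        assert np.abs(B[:, 1:]).max() == 0.0

    def test_linear_beyond_boundary_knots(self):
        knots = np.array([2.0, 4.0, 6.0, 8.0])
        x = np.linspace(8.5, 30, 500)
        B = rcs_basis(x, knots)
        d2 = np.diff(B, n=2, axis=0)
        assert np.abs(d2).max() < 1e-8

    def test_non_finite_input_fatal(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([1.0, np.nan]), np.array([0, 1, 2, 3.0]))


def _toy_table(times, events, x, site="s1"):
    return pd.DataFrame({
        "time_to_death_or_censor": times, "death_indicator": events,
        "x": x, "included": True, "analysis_site": site})


def pl_grid_oracle(times, events, x, grid):
    """Brute-force Breslow partial likelihood over a beta grid (no ties)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    lls = []
    for b in grid:
        w = np.exp(b * x)
        ll = 0.0
        for t in np.sort(times[events]):
            risk = times >= t
            i = np.flatnonzero((times == t) & events)[0]
            ll += b * x[i] - np.log(w[risk].sum())
        lls.append(ll)
    return np.asarray(lls)


class TestCoxFit:
    def test_small_sample_coefficient_matches_grid_search(self):
        """NR optimum equals the brute-force partial-likelihood maximizer on
        a six-subject dataset with an interior maximum."""
        times = [2, 4, 6, 8, 10, 12]
        events = [1, 1, 0, 1, 1, 0]
        x = [1, 0, 1, 1, 0, 0]
        fit = cox_fit(_toy_table(times, events, x), "death",
                      [CovariateTerm("x", "linear")])
        grid = np.arange(-4, 4, 1e-4)
        lls = pl_grid_oracle(times, events, x, grid)
        b_grid = grid[np.argmax(lls)]
        assert fit.converged
        assert abs(fit.coef.iloc[0] - b_grid) <= 1e-4

    def test_constant_covariate_zero_information(self):
        fit = cox_fit(_toy_table([1, 2, 3, 4], [1, 1, 0, 1], [1, 1, 1, 1]),
                      "death", [CovariateTerm("x", "linear")])
        assert fit.coef.iloc[0] == pytest.approx(0.0)

    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(6)
        n = 300
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(0.6 * x)))
        e = rng.random(n) < 0.8
        tab = _toy_table(t, e, x)
        f1 = cox_fit(tab, "death", [CovariateTerm("x", "linear")],
                     strata="analysis_site")
        f2 = cox_fit(tab, "death", [CovariateTerm("x", "linear")], strata=None)
        assert np.abs(f1.coef.to_numpy() - f2.coef.to_numpy()).max() < 1e-8

    def test_matches_lifelines_with_strata_and_efron_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(7)
        n = 600
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = rng.normal(size=n)
        t = np.ceil(rng.exponential(1 / (0.05 * np.exp(0.5 * x1 + 0.3 * x2))) * 4)
        e = rng.random(n) < 0.7
        site = np.where(rng.random(n) < 0.5, "a", "b")
        tab = pd.DataFrame({"time_to_death_or_censor": t, "death_indicator": e,
                            "x1": x1, "x2": x2, "included": True,
                            "analysis_site": site})
        fit = cox_fit(tab, "death", [CovariateTerm("x1", "linear"),
                                     CovariateTerm("x2", "linear")])
        cph = CoxPHFitter().fit(
            tab[["time_to_death_or_censor", "death_indicator", "x1", "x2",
                 "analysis_site"]],
            "time_to_death_or_censor", "death_indicator", strata=["analysis_site"])
        assert np.abs(fit.coef.to_numpy() - cph.params_.to_numpy()).max() < 1e-5
        assert np.abs(fit.cov - cph.variance_matrix_.to_numpy()).max() < 1e-6

    def test_optimum_beats_random_perturbations(self):
        rng = np.random.default_rng(8)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.1 * np.exp(0.4 * x)))
        e = np.ones(n, bool)
        tab = _toy_table(t, e, x)
        fit = cox_fit(tab, "death", [CovariateTerm("x", "linear")])

        def pl(b):
            return pl_grid_oracle(t, e, x, [b])[0]

        ll_opt = pl(float(fit.coef.iloc[0]))
        for _ in range(100):
            b = float(fit.coef.iloc[0]) + rng.normal(scale=0.5)
            assert pl(b) <= ll_opt + 1e-9

    def test_stratum_without_events_dropped_with_message(self):
        tab = pd.concat([
            _toy_table([1, 2, 3, 5], [1, 0, 1, 1], [1, 0, 1, 0], site="a"),
            _toy_table([4, 6], [0, 0], [1, 0], site="b")], ignore_index=True)
        fit = cox_fit(tab, "death", [CovariateTerm("x", "linear")])
        assert fit.strata_labels == ["a"]
        assert any("no events" in m for m in fit.messages)

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.normal(size=(n, 1))
        tab = pd.DataFrame({"time_to_death_or_censor": rng.exponential(5, n),
                            "death_indicator": rng.random(n) < 0.6,
                            "x": x[:, 0], "included": True, "analysis_site": "s"})
        fit = cox_fit(tab, "death", [CovariateTerm("x", "linear")])
        assert np.allclose(fit.cov, fit.cov.T)
        assert (np.linalg.eigvalsh(fit.cov) >= -1e-10).all()


class TestContrasts:
    def test_reference_contrast_is_exactly_one(self):
        fit = CoxFit(coef=pd.Series([0.2, 0.1, 0.05],
                                    index=["age", "age'", "age''"]),
                     cov=np.eye(3) * 0.01, loglik=0.0, converged=True, n_iter=3,
                     ties="efron", strata_labels=["s"],
                     terms=[CovariateTerm("age", "rcs",
                                          knots=np.array([20., 30., 50., 60.]))])
        hr, (lo, hi) = hr_contrast(fit, "age", 40, 40)
        assert hr == 1.0 and (lo, hi) == (1.0, 1.0)

    def test_binary_closed_form(self):
        fit = CoxFit(coef=pd.Series([np.log(2)], index=["ivdu=yes"]),
                     cov=np.zeros((1, 1)), loglik=0.0, converged=True, n_iter=3,
                     ties="efron", strata_labels=["s"],
                     terms=[CovariateTerm("ivdu", "binary", reference="no",
                                          levels=("no", "yes"))])
        hr, (lo, hi) = hr_contrast(fit, "ivdu", "yes", "no")
        assert hr == pytest.approx(2.0)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_spline_contrast_matches_manual_basis_arithmetic(self):
        knots = np.array([20.0, 30.0, 50.0, 60.0])
        beta = np.array([0.03, 0.4, -0.2])
        fit = CoxFit(coef=pd.Series(beta, index=["age", "age'", "age''"]),
                     cov=np.eye(3) * 1e-4, loglik=0.0, converged=True, n_iter=3,
                     ties="efron", strata_labels=["s"],
                     terms=[CovariateTerm("age", "rcs", knots=knots)])
        hr, _ = hr_contrast(fit, "age", 50, 40)
        db = rcs_basis(np.array([50.0]), knots)[0] - rcs_basis(np.array([40.0]), knots)[0]
        assert hr == pytest.approx(np.exp(db @ beta), rel=1e-12)

    def test_unknown_variable_fatal(self):
        fit = CoxFit(coef=pd.Series([0.1], index=["x"]), cov=np.eye(1),
                     loglik=0.0, converged=True, n_iter=1, ties="efron",
                     strata_labels=["s"],
                     terms=[CovariateTerm("x", "linear")])
        with pytest.raises(KeyError):
            hr_contrast(fit, "y", 1, 0)
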