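"""ML variance-component fitting, LRTs, model selection, profile CIs."""

import numpy as np
import pytest
from scipy import stats

from twinace import (
    DegenerateDataError,
    InsufficientDataError,
    MeanModel,
    ModelFit,
    ValidationError,
    VarianceComponents,
    component_ci,
    fit_twin_model,
    intrapair_correlation,
    likelihood_ratio_test,
    lrt_from_logliks,
    select_model,
)
from tests.conftest import make_pairs, simulated_pairs


def _ols_gaussian_loglik(pairs):
    """Independent oracle for the E-only model: plain OLS + normal MLE."""
    import statsmodels.api as sm

    y = np.array([v for p in pairs for v in p.values])
    age = np.array([a for p in pairs for a in p.ages])
    sex = np.array([1.0 if s == "M" else 0.0 for p in pairs for s in p.sexes])
    X = sm.add_constant(np.column_stack([age, sex]))
    res = sm.OLS(y, X).fit()
    sigma2 = res.ssr / len(y)
    return float(np.sum(stats.norm.logpdf(y, res.fittedvalues, np.sqrt(sigma2))))


def grid_search_loglik(mz, dz, steps=51):
    """Independent oracle: best log-likelihood over a proportion-simplex grid.

    For each (a2, c2) grid point the pair data are whitened by the Cholesky
    factor of the implied correlation matrix, the mean model is fit by plain
    least squares on the whitened system, the total variance is the ML
    residual variance, and the log-likelihood is summed from scipy's
    bivariate-normal densities.
    """

    def group_arrays(pairs):
        y = np.array([p.values for p in pairs])
        age = np.array([p.ages for p in pairs])
        sex = np.array([[1.0 if s == "M" else 0.0 for s in p.sexes] for p in pairs])
        return y, age, sex

    data = {"MZ": group_arrays(mz), "DZ": group_arrays(dz)}
    n_subj = 2 * (len(mz) + len(dz))
    grid = np.linspace(0.0, 1.0, steps)
    best = -np.inf
    for a2 in grid:
        for c2 in grid:
            if a2 + c2 > 1.0 + 1e-12:
                continue
            rs = {"MZ": a2 + c2, "DZ": 0.5 * a2 + c2}
            if any(r >= 1.0 - 1e-9 for r in rs.values()):
                continue
            rows_X, rows_y = [], []
            for z, (y, age, sex) in data.items():
                R = np.array([[1.0, rs[z]], [rs[z], 1.0]])
                Linv = np.linalg.inv(np.linalg.cholesky(R))
                n = y.shape[0]
                X = np.stack(
                    [np.stack([np.ones(n), age[:, m], sex[:, m]], axis=1) for m in (0, 1)],
                    axis=1,
                )  # (n, 2, 3)
                rows_X.append((Linv @ X).reshape(-1, 3))
                rows_y.append((Linv @ y[:, :, None]).reshape(-1))
            Xw = np.vstack(rows_X)
            yw = np.concatenate(rows_y)
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            v_hat = float(np.sum((yw - Xw @ beta) ** 2) / n_subj)
            ll = 0.0
            for z, (y, age, sex) in data.items():
                n = y.shape[0]
                X = np.stack(
                    [np.stack([np.ones(n), age[:, m], sex[:, m]], axis=1) for m in (0, 1)],
                    axis=1,
                )
                dev = y - (X @ beta)
                cov = v_hat * np.array([[1.0, rs[z]], [rs[z], 1.0]])
                ll += float(np.sum(stats.multivariate_normal.logpdf(dev, cov=cov)))
            best = max(best, ll)
    return best


class TestFitting:
    def test_parameter_recovery_ace(self):
        # mean estimate over replicates recovers the generating triple
        comps = []
        for seed in range(21, 26):
            mz, dz = simulated_pairs(0.6, 0.2, 2000, seed=seed)
            fit = fit_twin_model(mz, dz, "ACE")
            assert fit.converged
            c = fit.components
            comps.append((c.a2, c.c2, c.e2))
            assert fit.total_sd == pytest.approx(10.0, rel=0.05)
        mean = np.mean(comps, axis=0)
        assert mean == pytest.approx((0.6, 0.2, 0.2), abs=0.03)

    def test_covariate_betas_recovered(self):
        mz, dz = simulated_pairs(0.6, 0.2, 5000, seed=22)
        fit = fit_twin_model(mz, dz, "ACE")
        # generating effects: beta_age = -0.3, beta_sex = +5 (see conftest)
        assert fit.mean_model.beta_age == pytest.approx(-0.3, abs=0.05)
        assert fit.mean_model.beta_sex == pytest.approx(5.0, abs=1.0)
        assert fit.mean_model.intercept == pytest.approx(100.0, abs=3.0)

    def test_ce_boundary_matches_ace_loglik(self):
        mz, dz = simulated_pairs(0.0, 0.7, 2000, seed=23)
        ace = fit_twin_model(mz, dz, "ACE")
        ce = fit_twin_model(mz, dz, "CE")
        assert ace.loglik - ce.loglik < 0.5
        assert ace.loglik >= ce.loglik - 1e-6

    def test_nesting_loglik_ordering(self):
        mz, dz = simulated_pairs(0.5, 0.2, 500, seed=24)
        fits = {m: fit_twin_model(mz, dz, m) for m in ("ACE", "AE", "CE", "E")}
        assert fits["ACE"].loglik >= fits["AE"].loglik - 1e-6
        assert fits["ACE"].loglik >= fits["CE"].loglik - 1e-6
        assert fits["AE"].loglik >= fits["E"].loglik - 1e-6

    def test_e_only_equals_independent_gaussian_fit(self):
        mz, dz = simulated_pairs(0.5, 0.2, 200, seed=25)
        fit = fit_twin_model(mz, dz, "E")
        assert fit.components.e2 == 1.0
        assert fit.components.a2 == 0.0
        assert fit.loglik == pytest.approx(_ols_gaussian_loglik(mz + dz), abs=1e-6)

    def test_standardized_components_sum_to_one(self):
        mz, dz = simulated_pairs(0.4, 0.3, 300, seed=26)
        for m in ("ACE", "AE", "CE"):
            c = fit_twin_model(mz, dz, m).components
            assert c.a2 + c.c2 + c.d2 + c.e2 == pytest.approx(1.0, abs=1e-9)

    def test_implied_correlation_matches_empirical(self):
        from twinace import residualize

        mz, dz = simulated_pairs(0.7, 0.1, 1000, seed=27)
        fit = fit_twin_model(mz, dz, "ACE")
        r_mz_hat = fit.components.a2 + fit.components.c2
        r_dz_hat = fit.components.a2 / 2 + fit.components.c2
        assert r_mz_hat == pytest.approx(intrapair_correlation(residualize(mz)).r, abs=0.05)
        assert r_dz_hat == pytest.approx(intrapair_correlation(residualize(dz)).r, abs=0.05)

    def test_constant_trait_rejected(self):
        mz = make_pairs([(1, 1)] * 5, zygosity="MZ")
        dz = make_pairs([(1, 1)] * 5, zygosity="DZ")
        with pytest.raises(DegenerateDataError):
            fit_twin_model(mz, dz, "ACE")

    def test_unknown_model_rejected(self):
        mz, dz = simulated_pairs(0.5, 0.0, 10, seed=28)
        with pytest.raises(ValidationError, match="unknown model"):
            fit_twin_model(mz, dz, "ACDE")

    def test_too_few_pairs_rejected(self):
        mz, dz = simulated_pairs(0.5, 0.0, 10, seed=29)
        with pytest.raises(InsufficientDataError):
            fit_twin_model(mz[:2], dz, "ACE")

    def test_optimizer_matches_grid_search_small_data(self):
        # coarse-grid sanity version of the oracle-equivalence property
        for seed in (31, 32, 33):
            mz, dz = simulated_pairs(0.6, 0.1, 25, seed=seed)
            fit = fit_twin_model(mz, dz, "ACE")
            assert fit.loglik >= grid_search_loglik(mz, dz, steps=11) - 1e-4


class TestLRT:
    def test_hand_oracle(self):
        stat, df, p = lrt_from_logliks(-100.0, -102.5, 1)
        assert stat == pytest.approx(5.0)
        assert p == pytest.approx(stats.chi2.sf(5.0, 1), abs=1e-12)
        assert p == pytest.approx(0.0253, abs=5e-4)

    def test_identical_fits_give_zero_statistic(self):
        mz, dz = simulated_pairs(0.5, 0.2, 100, seed=34)
        fit = fit_twin_model(mz, dz, "ACE")
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert stat == 0.0
        assert p == 1.0

    def test_statistic_floored_at_zero(self):
        stat, _, p = lrt_from_logliks(-102.5, -100.0, 1)
        assert stat == 0.0
        assert p == 1.0

    def test_non_nested_pair_rejected(self):
        mz, dz = simulated_pairs(0.5, 0.2, 100, seed=35)
        ae = fit_twin_model(mz, dz, "AE")
        ce = fit_twin_model(mz, dz, "CE")
        with pytest.raises(ValidationError, match="nested"):
            likelihood_ratio_test(ae, ce)

    def test_different_data_rejected(self):
        mz1, dz1 = simulated_pairs(0.5, 0.2, 100, seed=36)
        mz2, dz2 = simulated_pairs(0.5, 0.2, 100, seed=37)
        full = fit_twin_model(mz1, dz1, "ACE")
        red = fit_twin_model(mz2, dz2, "AE")
        with pytest.raises(ValidationError, match="different data"):
            likelihood_ratio_test(full, red)

    def test_df_counts_free_variance_parameters(self):
        mz, dz = simulated_pairs(0.5, 0.2, 100, seed=38)
        ace = fit_twin_model(mz, dz, "ACE")
        ae = fit_twin_model(mz, dz, "AE")
        e = fit_twin_model(mz, dz, "E")
        assert likelihood_ratio_test(ace, ae)[1] == 1
        assert likelihood_ratio_test(ace, e)[1] == 2
        assert likelihood_ratio_test(ae, e)[1] == 1

    def test_boundary_mixture_halves_p(self):
        mz, dz = simulated_pairs(0.5, 0.2, 100, seed=39)
        ace = fit_twin_model(mz, dz, "ACE")
        ae = fit_twin_model(mz, dz, "AE")
        stat, _, p_naive = likelihood_ratio_test(ace, ae)
        _, _, p_mix = likelihood_ratio_test(ace, ae, boundary_mixture=True)
        if stat > 0:
            assert p_mix == pytest.approx(p_naive / 2)


class TestSelection:
    def _dummy_fit(self, model, loglik, a2=0.5):
        comps = {"ACE": dict(a2=a2, c2=0.2, e2=1 - a2 - 0.2),
                 "AE": dict(a2=a2, e2=1 - a2),
                 "CE": dict(a2=0.0, c2=a2, e2=1 - a2)}[model]
        return ModelFit(
            model=model,
            components=VarianceComponents(**{k: float(v) for k, v in comps.items()}),
            mean_model=MeanModel(0.0, 0.0, 0.0),
            total_sd=1.0,
            loglik=loglik,
            n_pairs=(10, 10),
        )

    def test_tie_breaks_toward_ae(self):
        fits = {m: self._dummy_fit(m, -100.0) for m in ("ACE", "AE", "CE")}
        assert select_model(fits).chosen == "AE"

    def test_higher_loglik_reduced_model_wins(self):
        fits = {
            "ACE": self._dummy_fit("ACE", -100.0),
            "AE": self._dummy_fit("AE", -100.4),
            "CE": self._dummy_fit("CE", -100.1),
        }
        res = select_model(fits)
        assert res.chosen == "CE"
        assert res.rationale == "negligible_A"

    def test_both_significant_retains_ace(self):
        fits = {
            "ACE": self._dummy_fit("ACE", -100.0),
            "AE": self._dummy_fit("AE", -110.0),
            "CE": self._dummy_fit("CE", -110.0),
        }
        res = select_model(fits)
        assert res.chosen == "ACE"
        assert res.rationale == "both_significant"

    def test_missing_fit_rejected(self):
        fits = {"ACE": self._dummy_fit("ACE", -100.0), "AE": self._dummy_fit("AE", -100.0)}
        with pytest.raises(ValidationError, match="CE"):
            select_model(fits)

    def test_ae_chosen_on_heritable_data(self):
        mz, dz = simulated_pairs(0.8, 0.0, 1000, seed=41)
        fits = {m: fit_twin_model(mz, dz, m) for m in ("ACE", "AE", "CE")}
        res = select_model(fits)
        assert res.chosen == "AE"
        assert res.rationale == "negligible_C"


class TestProfileCI:
    def test_interval_contains_point_estimate(self):
        mz, dz = simulated_pairs(0.8, 0.0, 500, seed=42)
        fit = fit_twin_model(mz, dz, "AE")
        lo, hi = component_ci(fit, "a2")
        assert lo <= fit.components.a2 <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_e2_interval_excludes_zero_with_discordant_pairs(self):
        mz, dz = simulated_pairs(0.8, 0.0, 500, seed=43)
        fit = fit_twin_model(mz, dz, "AE")
        lo, _ = component_ci(fit, "e2")
        assert lo > 0.0

    def test_endpoints_monotone_in_level(self):
        mz, dz = simulated_pairs(0.7, 0.1, 300, seed=44)
        fit = fit_twin_model(mz, dz, "ACE")
        intervals = [component_ci(fit, "a2", level=lv) for lv in (0.5, 0.8, 0.95, 0.99)]
        for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            assert lo2 <= lo1 + 1e-9
            assert hi2 >= hi1 - 1e-9

    def test_interval_narrows_with_sample_size(self):
        widths = []
        for n in (200, 2000):
            mz, dz = simulated_pairs(0.8, 0.0, n, seed=45)
            fit = fit_twin_model(mz, dz, "AE")
            lo, hi = component_ci(fit, "a2")
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_component_not_in_model_rejected(self):
        mz, dz = simulated_pairs(0.8, 0.0, 100, seed=46)
        fit = fit_twin_model(mz, dz, "AE")
        with pytest.raises(ValidationError, match="not free"):
            component_ci(fit, "c2")
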