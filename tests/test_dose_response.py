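import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from btiscan.dose_response import (
    BioassayTable,
    DoseResponseFit,
    abbott_correct,
    fit_probit,
    lethal_concentration,
    resistance_ratio,
)
from btiscan.synthetic_data import simulate_bioassay

DOSES = 10.0 ** np.array([-1.0, -0.5, 0.0, 0.5, 1.0])


def noise_free_table(alpha=0.0, beta=2.0, n=1000, doses=DOSES, control=0.0):
    p = stats.norm.cdf(alpha + beta * np.log10(doses))
    rows = [(d, n, pi * n, 1) for d, pi in zip(doses, p)]
    if control > 0:
        rows.insert(0, (0.0, n, control * n, 1))
    df = pd.DataFrame(rows, columns=["concentration", "n_exposed", "n_dead", "replicate"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return BioassayTable("noise-free", df)


class TestAbbott:
    @pytest.mark.parametrize(
        "obs,ctrl,expected", [(0.7, 0.0, 0.7), (0.55, 0.10, 0.5)]
    )
    def test_formula(self, obs, ctrl, expected):
        assert abbott_correct(obs, ctrl) == pytest.approx(expected)

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert abbott_correct(0.05, 0.10) == 0.0

    def test_monotone_in_observed(self):
        vals = [abbott_correct(o, 0.2) for o in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_full_control_mortality_rejected(self):
        with pytest.raises(ValueError):
            abbott_correct(0.5, 1.0)


class TestProbitFit:
    def test_noise_free_recovery_to_four_decimals(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_probit(noise_free_table())
        assert fit.alpha == pytest.approx(0.0, abs=1e-4)
        assert fit.beta == pytest.approx(2.0, abs=1e-4)
        lc50 = lethal_concentration(fit, 0.5)[0]
        assert lc50 == pytest.approx(1.0, abs=1e-4)

    def test_lc95_closed_form(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_probit(noise_free_table())
        lc95 = lethal_concentration(fit, 0.95)[0]
        assert lc95 == pytest.approx(10 ** (stats.norm.ppf(0.95) / 2), abs=1e-4)

    def test_abbott_applied_before_fit(self):
        # 10% control mortality baked into the curve should be removed
        p_true = stats.norm.cdf(2.0 * np.log10(DOSES))
        p_obs = 0.1 + 0.9 * p_true
        rows = [(0.0, 1000, 100, 1)] + [
            (d, 1000, pi * 1000, 1) for d, pi in zip(DOSES, p_obs)
        ]
        df = pd.DataFrame(rows, columns=["concentration", "n_exposed", "n_dead", "replicate"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_probit(BioassayTable("ctrl", df))
        assert fit.beta == pytest.approx(2.0, abs=1e-3)

    def test_matches_direct_likelihood_maximization(self, rng):
        # independent route: maximize the binomial log-likelihood numerically
        tbl = simulate_bioassay(1.0, 2.0, DOSES, n_per_dose=30, replicates=4, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_probit(tbl)
        rec = tbl.records[tbl.records.concentration > 0]
        x = np.log10(rec.concentration.to_numpy())
        dead = rec.n_dead.to_numpy()
        n = rec.n_exposed.to_numpy()

        def nll(params):
            a, b = params
            p = np.clip(stats.norm.cdf(a + b * x), 1e-12, 1 - 1e-12)
            return -(dead * np.log(p) + (n - dead) * np.log(1 - p)).sum()

        res = optimize.minimize(nll, [0.0, 1.0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        assert fit.alpha == pytest.approx(res.x[0], abs=1e-4)
        assert fit.beta == pytest.approx(res.x[1], abs=1e-4)

    def test_all_or_nothing_rejected(self):
        rows = [(d, 50, 50 if d > 1 else 0, 1) for d in DOSES]
        df = pd.DataFrame(rows, columns=["concentration", "n_exposed", "n_dead", "replicate"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tbl = BioassayTable("sep", df)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_probit(tbl)


class TestLethalConcentration:
    def test_degenerate_variance_collapses_limits(self):
        fit = DoseResponseFit("x", alpha=0.0, beta=2.0, cov=np.zeros((2, 2)),
                              heterogeneity=1.0, heterogeneity_significant=False,
                              df_resid=3, converged=True, n_total=100)
        lc, lo, hi = lethal_concentration(fit, 0.5)
        assert lc == lo == hi == pytest.approx(1.0)

    def test_limits_bracket_estimate(self, rng):
        tbl = simulate_bioassay(2.0, 1.5, [0.5, 1, 2, 4, 8], 25, 4, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_probit(tbl)
        for q in (0.5, 0.95):
            lc, lo, hi = lethal_concentration(fit, q)
            assert lo < lc < hi
        lc50 = lethal_concentration(fit, 0.5)[0]
        lc95 = lethal_concentration(fit, 0.95)[0]
        assert lc50 < lc95

    def test_imprecise_slope_rejected(self):
        fit = DoseResponseFit("x", alpha=0.0, beta=0.1,
                              cov=np.array([[0.5, 0.0], [0.0, 0.5]]),
                              heterogeneity=1.0, heterogeneity_significant=False,
                              df_resid=3, converged=True, n_total=40)
        with pytest.raises(ValueError, match="g >= 1"):
            lethal_concentration(fit, 0.5)

    def test_dose_unit_equivariance(self, rng):
        # rescaling doses by 1000 (e.g. mg -> ug) rescales LC, not RR
        tbl = simulate_bioassay(1.0, 2.0, DOSES, 25, 4, rng=np.random.default_rng(5))
        scaled = tbl.records.copy()
        scaled["concentration"] *= 1000.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_probit(tbl)
            f2 = fit_probit(BioassayTable("scaled", scaled))
        lc1 = lethal_concentration(f1, 0.5)[0]
        lc2 = lethal_concentration(f2, 0.5)[0]
        assert lc2 == pytest.approx(1000 * lc1, rel=1e-6)
        rr = resistance_ratio(f2, f2, 0.5)
        assert rr.ratio == pytest.approx(1.0)


class TestResistanceRatio:
    def _fit(self, alpha, beta, var=1e-4):
        return DoseResponseFit("x", alpha=alpha, beta=beta,
                               cov=np.array([[var, 0.0], [0.0, var]]),
                               heterogeneity=1.0, heterogeneity_significant=False,
                               df_resid=3, converged=True, n_total=100)

    def test_self_ratio_not_significant(self):
        f = self._fit(0.0, 2.0)
        rr = resistance_ratio(f, f, 0.5)
        assert rr.ratio == pytest.approx(1.0)
        assert not rr.significant

    def test_extreme_bounds_arithmetic(self, monkeypatch):
        # pop LC 2.0 with CI (1.8, 2.2); ref LC 1.0 with CI (0.9, 1.1)
        import btiscan.dose_response as dr
        cis = {2.0: (2.0, 1.8, 2.2), 1.0: (1.0, 0.9, 1.1)}
        fits = {2.0: self._fit(-np.log10(2.0) * 2, 2.0), 1.0: self._fit(0.0, 2.0)}
        monkeypatch.setattr(
            dr, "lethal_concentration",
            lambda fit, q=0.5: cis[2.0 if fit.alpha != 0 else 1.0],
        )
        rr = dr.resistance_ratio(fits[2.0], fits[1.0], 0.5)
        assert rr.ratio == pytest.approx(2.0)
        assert rr.ci_low == pytest.approx(1.8 / 1.1)
        assert rr.ci_high == pytest.approx(2.2 / 0.9)
        assert rr.significant  # intervals disjoint and CI > 1

    def test_overlapping_intervals_never_significant(self, monkeypatch):
        # under the extreme-bounds CI, the ratio CI excludes 1 only when the
        # fiducial intervals are disjoint, so overlap kills the flag even
        # when the point ratio is large
        import btiscan.dose_response as dr
        cis = {"pop": (2.0, 1.05, 3.0), "ref": (1.0, 0.9, 1.1)}
        f_pop, f_ref = self._fit(-0.602, 2.0), self._fit(0.0, 2.0)
        monkeypatch.setattr(
            dr, "lethal_concentration",
            lambda fit, q=0.5: cis["pop" if fit is f_pop else "ref"],
        )
        rr = dr.resistance_ratio(f_pop, f_ref, 0.5)
        assert rr.ratio == pytest.approx(2.0)
        assert rr.ci_low < 1.0  # extreme-bounds CI straddles 1 under overlap
        assert not rr.significant
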