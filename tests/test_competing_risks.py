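import subprocess

import numpy as np
import pandas as pd
import pytest

from burdencif.competing_risks import (
    cif_aalen_johansen,
    fit_fine_gray,
    gray_test,
    kaplan_meier,
    logrank_test,
)

from conftest import make_dataset, simulate_competing


class TestKaplanMeier:
    def test_all_events_hand_values(self):
        km = kaplan_meier(make_dataset([1, 2, 3], [1, 1, 1]))
        assert km(1) == pytest.approx(2 / 3)
        assert km(2) == pytest.approx(1 / 3)
        assert km(3) == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        with pytest.warns(UserWarning, match="no events"):
            km = kaplan_meier(make_dataset([1, 2, 3], [0, 0, 0]))
        assert km([0.5, 1.5, 10]).tolist() == [1.0, 1.0, 1.0]

    def test_censoring_hand_product_limit(self):
        # times (1,2,3,4), events (1,0,1,0): S(1)=3/4, S(3)=3/4 * 1/2
        km = kaplan_meier(make_dataset([1, 2, 3, 4], [1, 0, 1, 0]))
        assert km(1) == pytest.approx(0.75)
        assert km(3) == pytest.approx(0.375)
        assert km(0.99) == pytest.approx(1.0)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(0)
        t = rng.exponential(1, 200).round(2) + 0.01  # rounded -> ties
        e = rng.integers(0, 2, 200)
        km = kaplan_meier(make_dataset(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0.01, t.max(), 50)
        np.testing.assert_allclose(
            km(grid), kmf.survival_function_at_times(grid).to_numpy(), atol=1e-12
        )


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 0]
        data = make_dataset(t + t, e + e)
        stat, df, p = logrank_test(data, [0] * 5 + [1] * 5)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        # hand computation: O_A = 3, E_A = 1/2 + 2/5 + 1/4 = 1.15,
        # V = 0.25 + 0.24 + 0.1875 -> chi2 about 5, p < 0.05
        data = make_dataset([1, 2, 3, 10, 20, 30], [1, 1, 1, 1, 1, 1])
        stat, df, p = logrank_test(data, ["A", "A", "A", "B", "B", "B"])
        assert p < 0.05

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="two"):
            logrank_test(make_dataset([1, 2], [1, 1]), ["A", "A"])

    def test_permutation_oracle(self):
        # the chi-square p-value should agree with a label-permutation
        # reference distribution within Monte-Carlo error
        rng = np.random.default_rng(4)
        n = 60
        t = rng.exponential(1, n)
        e = (rng.uniform(size=n) < 0.8).astype(int)
        g = rng.integers(0, 2, n)
        data = make_dataset(t, e)
        stat, _, p = logrank_test(data, g)
        perm_stats = np.empty(2000)
        for i in range(2000):
            perm_stats[i] = logrank_test(data, rng.permutation(g))[0]
        p_perm = np.mean(perm_stats >= stat)
        assert p == pytest.approx(p_perm, abs=3.5 * np.sqrt(p_perm * (1 - p_perm) / 2000) + 0.01)


class TestAalenJohansen:
    def test_no_censoring_empirical_subdistribution(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 100)
        e = rng.integers(1, 3, 100)
        cifs = cif_aalen_johansen(make_dataset(t, e))
        for c in (1, 2):
            grid = np.quantile(t, [0.2, 0.5, 0.9])
            emp = [(t[e == c] <= g).sum() / 100 for g in grid]
            np.testing.assert_allclose(cifs[c](grid), emp, atol=1e-12)

    def test_hand_oracle_with_censoring(self):
        # times (1,2,3,4), events (1,2,0,1); at-risk 4,3,2,1
        # S(1-)=1: dCIF1(1)=1/4;  S(1)=3/4, dCIF2(2)=(3/4)(1/3)=1/4
        # S(2)=1/2; t=3 censored; S(3-)=1/2, dCIF1(4)=(1/2)(1/1)=1/2
        cifs = cif_aalen_johansen(make_dataset([1, 2, 3, 4], [1, 2, 0, 1]))
        assert cifs[1](1) == pytest.approx(0.25)
        assert cifs[1](3.9) == pytest.approx(0.25)
        assert cifs[1](4) == pytest.approx(0.75)
        assert cifs[2](4) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_identity(self, seed):
        rng = np.random.default_rng(seed)
        t, e, _ = simulate_competing(rng, 300)
        t = t.round(2) + 0.01  # force ties
        data = make_dataset(t, e)
        cifs = cif_aalen_johansen(data)
        km = kaplan_meier(data)
        grid = np.unique(t)
        total = cifs[1](grid) + cifs[2](grid) + km(grid)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_per_group_estimates(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 2, 0, 1, 1, 2, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        out = cif_aalen_johansen(make_dataset(t, e), groups=np.array(g))
        assert set(out) == {(0, 1), (0, 2), (1, 1), (1, 2)}
        np.testing.assert_allclose(out[(0, 1)].cif_values,
                                   out[(1, 1)].cif_values)


class TestGrayTest:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 2, 0, 1, 2, 1]
        data = make_dataset(t + t, e + e)
        res = gray_test(data, [0] * 6 + [1] * 6, cause=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.df == 1

    def test_agrees_with_cmprsk_reference(self):
        # fixed dataset; compare the chi-square statistic with the
        # R cmprsk implementation of the same test
        rng = np.random.default_rng(42)
        n = 160
        g = rng.integers(0, 2, n)
        t, e, _ = simulate_competing(rng, n, beta1=0.5, x=g.astype(float))
        df = pd.DataFrame({"time": t, "event": e, "grp": g})
        res = gray_test(make_dataset(t, e), g, cause=1)
        script = (
            'd <- read.csv("{path}"); suppressMessages(library(cmprsk));'
            "z <- cuminc(d$time, d$event, d$grp, cencode=0);"
            'cat(sprintf("%.10f", z$Tests[1, 1]))'
        )
        import tempfile, os

        with tempfile.TemporaryDirectory() as tmp:
            path = os.path.join(tmp, "d.csv")
            df.to_csv(path, index=False)
            out = subprocess.run(
                ["Rscript", "-e", script.format(path=path)],
                capture_output=True, text=True, check=True,
            )
        ref = float(out.stdout.strip())
        assert res.statistic == pytest.approx(ref, rel=0.05)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(2)
        n = 400
        g = rng.integers(0, 2, n)
        t, e, _ = simulate_competing(rng, n, beta1=np.log(3.0),
                                     x=g.astype(float))
        res = gray_test(make_dataset(t, e), g, cause=1)
        assert res.p_value < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            gray_test(make_dataset([1, 2], [1, 1]), ["A", "A"], cause=1)
        with pytest.raises(ValueError, match="cause"):
            gray_test(make_dataset([1, 2], [2, 2]), ["A", "B"], cause=1)

    def test_three_groups_df(self):
        rng = np.random.default_rng(9)
        t, e, _ = simulate_competing(rng, 150)
        res = gray_test(make_dataset(t, e), rng.integers(0, 3, 150), cause=1)
        assert res.df == 2
        assert 0 <= res.p_value <= 1


class TestFineGray:
    def test_reduces_to_cox_without_competing_or_censoring(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.4 * x))
        data = make_dataset(t, np.ones(n, int))
        fit = fit_fine_gray(data, pd.DataFrame({"x": x}), cause=1)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": t, "E": 1, "x": x}), "T", "E",
            fit_options={"precision": 1e-12},
        )
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-6)

    def test_competing_relabelled_as_late_censoring_matches_cox(self):
        # with no censoring, cause-2 subjects stay in the risk set forever
        # with weight 1, exactly like subjects censored far in the future
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        t, e, x = simulate_competing(rng, 200, beta1=0.5, censor=(50, 60))
        assert (e == 0).sum() == 0
        fit = fit_fine_gray(make_dataset(t, e), pd.DataFrame({"x": x}), cause=1)
        df = pd.DataFrame(
            {"T": np.where(e == 1, t, 1e6), "E": (e == 1).astype(int), "x": x}
        )
        cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-12})
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-6)

    def test_matches_cmprsk_crr(self):
        rng = np.random.default_rng(8)
        t, e, x = simulate_competing(rng, 250, beta1=0.5)
        x2 = rng.binomial(1, 0.4, 250).astype(float)
        df = pd.DataFrame({"time": t, "event": e, "x1": x, "x2": x2})
        fit = fit_fine_gray(make_dataset(t, e),
                            pd.DataFrame({"x1": x, "x2": x2}), cause=1)
        import os, tempfile

        script = (
            'd <- read.csv("{path}"); suppressMessages(library(cmprsk));'
            "f <- crr(d$time, d$event, cbind(d$x1, d$x2), failcode=1,"
            " cencode=0);"
            'cat(sprintf("%.10f %.10f %.8f %.8f %.6f", f$coef[1], f$coef[2],'
            " sqrt(f$var[1,1]), sqrt(f$var[2,2]), f$loglik))"
        )
        with tempfile.TemporaryDirectory() as tmp:
            path = os.path.join(tmp, "d.csv")
            df.to_csv(path, index=False)
            out = subprocess.run(["Rscript", "-e", script.format(path=path)],
                                 capture_output=True, text=True, check=True)
        b1, b2, s1, s2, ll = map(float, out.stdout.split())
        assert fit.coef[0] == pytest.approx(b1, abs=2e-6)
        assert fit.coef[1] == pytest.approx(b2, abs=2e-6)
        assert fit.loglik == pytest.approx(ll, abs=1e-4)
        # crr's variance includes IPCW-estimation terms ours approximates
        assert fit.se_robust[0] == pytest.approx(s1, rel=0.02)
        assert fit.se_robust[1] == pytest.approx(s2, rel=0.02)

    def test_constant_covariate_not_estimable(self):
        rng = np.random.default_rng(6)
        t, e, x = simulate_competing(rng, 50)
        fit = fit_fine_gray(make_dataset(t, e),
                            pd.DataFrame({"c": np.ones(50)}), cause=1)
        assert not fit.estimable[0]
        assert np.isnan(fit.coef[0])
        assert not fit.converged

    def test_covariate_constant_among_events_not_estimable(self):
        # dosage present only in subjects who never experience cause 1
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 2, 2, 0, 0])
        x = np.array([0.0, 0.0, 1.0, 2.0, 1.0, 0.0])
        fit = fit_fine_gray(make_dataset(t, e), pd.DataFrame({"x": x}), cause=1)
        assert not fit.estimable[0]

    def test_own_cluster_equals_unclustered(self):
        rng = np.random.default_rng(7)
        t, e, x = simulate_competing(rng, 150, beta1=0.3)
        data = make_dataset(t, e)
        f1 = fit_fine_gray(data, pd.DataFrame({"x": x}), cause=1)
        f2 = fit_fine_gray(data, pd.DataFrame({"x": x}), cause=1,
                           cluster=np.arange(150))
        assert f1.se_robust[0] == pytest.approx(f2.se_robust[0], abs=1e-12)

    def test_clustering_changes_robust_se_only(self):
        rng = np.random.default_rng(17)
        t, e, x = simulate_competing(rng, 150, beta1=0.3)
        data = make_dataset(t, e)
        fam = np.repeat(np.arange(30), 5)
        f1 = fit_fine_gray(data, pd.DataFrame({"x": x}), cause=1)
        f2 = fit_fine_gray(data, pd.DataFrame({"x": x}), cause=1, cluster=fam)
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-12)
        assert f1.se_model[0] == pytest.approx(f2.se_model[0], abs=1e-12)
        assert f1.se_robust[0] != f2.se_robust[0]

    def test_wald_p_is_chi2_tail(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        t, e, x = simulate_competing(rng, 100, beta1=0.5)
        fit = fit_fine_gray(make_dataset(t, e), pd.DataFrame({"x": x}), cause=1)
        z2 = (fit.coef[0] / fit.se_robust[0]) ** 2
        assert fit.wald_p[0] == pytest.approx(stats.chi2.sf(z2, 1), abs=1e-12)

    def test_hr_and_ci_identities(self):
        rng = np.random.default_rng(11)
        t, e, x = simulate_competing(rng, 100, beta1=0.5)
        fit = fit_fine_gray(make_dataset(t, e), pd.DataFrame({"x": x}), cause=1)
        assert fit.hr[0] == pytest.approx(np.exp(fit.coef[0]))
        lo, hi = fit.ci95[0]
        assert lo == pytest.approx(np.exp(fit.coef[0] - 1.96 * fit.se_robust[0]))
        assert hi == pytest.approx(np.exp(fit.coef[0] + 1.96 * fit.se_robust[0]))
        assert lo < fit.hr[0] < hi
        assert np.isfinite(fit.aic) == fit.converged

    def test_no_events_of_cause_errors(self):
        with pytest.raises(ValueError, match="no events"):
            fit_fine_gray(make_dataset([1, 2], [2, 0]),
                          pd.DataFrame({"x": [0.0, 1.0]}), cause=1)
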