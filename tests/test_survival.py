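"""Signature scoring, density dichotomization, KM / log-rank / Cox."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from ubinom import (
    compare_scores,
    cox_hr,
    density_dichotomize,
    km_estimate,
    logrank_test,
    signature_score,
    simulate_survival,
    trim_by_survival,
)
from ubinom.differential import welch_t


def _cohort(time, event, stratum=None):
    df = pd.DataFrame({"time": time, "event": event})
    if stratum is not None:
        df["stratum"] = stratum
    return df


class TestSignatureScore:
    def test_geometric_mean_in_log_space(self):
        # linear values 4 and 16 -> geometric mean 8 -> log2 score 3
        m = pd.DataFrame({"s1": [2.0, 4.0]}, index=["gA", "gB"])
        assert signature_score(m, ["gA", "gB"])["s1"] == pytest.approx(3.0)

    def test_constant_profile_identity(self):
        m = pd.DataFrame(np.full((5, 3), 7.25),
                         index=list("abcde"), columns=["x", "y", "z"])
        assert (signature_score(m, list("abcde")) == 7.25).all()

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(0, 10, (6, 4)),
                         index=list("abcdef"), columns=list("wxyz"))
        s1 = signature_score(m, list("abcdef"))
        s2 = signature_score(m, list("fedcba"))
        assert np.allclose(s1, s2)

    def test_missing_genes_logged_absent_all_raises(self):
        m = pd.DataFrame({"s": [1.0]}, index=["gA"])
        assert signature_score(m, ["gA", "nope"])["s"] == 1.0
        with pytest.raises(ValueError, match="no signature genes"):
            signature_score(m, ["nope"])


class TestDichotomize:
    def test_bimodal_mixture(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1, 200)])
        threshold, labels, info = density_dichotomize(x)
        assert 2 < threshold < 4
        assert info["rule"] == "between_peaks_minimum"
        high = (labels == "high").mean()
        assert abs(high - 0.5) < 0.10

    def test_unimodal_median_fallback(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 300)
        threshold, labels, info = density_dichotomize(x)
        if info["rule"] == "median_fallback":
            assert threshold == pytest.approx(np.median(x))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 150), rng.normal(5, 1, 150)])
        t0, _, _ = density_dichotomize(x)
        t1, _, _ = density_dichotomize(x + 17.5)
        assert t1 - t0 == pytest.approx(17.5, abs=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 100)
        assert density_dichotomize(x)[0] == density_dichotomize(x)[0]

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="identical"):
            density_dichotomize(np.ones(50))
        with pytest.raises(ValueError, match="at least 10"):
            density_dichotomize(np.arange(5))


class TestKM:
    def test_hand_product_limit(self):
        km = km_estimate(_cohort([1, 2, 3], [1, 1, 1]))
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)
        assert lookup[0.0] == 1.0

    def test_no_events_flat_one(self):
        km = km_estimate(_cohort([5, 6, 7], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()

    def test_censoring_no_step_but_smaller_risk_set(self):
        km = km_estimate(_cohort([1, 2, 3], [1, 0, 1]))
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(2 / 3)  # censoring: no drop
        assert lookup[3.0] == pytest.approx(0.0)  # risk set of 1 remains

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 80)
        km = km_estimate(_cohort(t, np.ones(80, dtype=int)))
        for time, surv in zip(km["time"], km["survival"]):
            assert surv == pytest.approx((t > time).mean(), abs=1e-12)

    def test_monotone_in_unit_interval(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        km = km_estimate(_cohort(t, e))
        s = km["survival"].to_numpy()
        assert ((s[1:] - s[:-1]) <= 1e-12).all()
        assert (s >= 0).all() and (s <= 1).all()


def manual_logrank(time, event, group):
    """Direct O−E / V tabulation of the two-group log-rank statistic."""
    time, event, group = map(np.asarray, (time, event, group))
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_hand_worked_six_subjects(self):
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 1, 0, 1, 1, 1]
        group = [0, 1, 0, 1, 0, 1]
        expected = manual_logrank(time, event, group)
        cohort = _cohort(time, event,
                         ["low" if g == 0 else "high" for g in group])
        stat, p = logrank_test(cohort)
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_label_exchange_symmetry(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 40)
        e = np.ones(40, dtype=int)
        strat = np.array(["a"] * 20 + ["b"] * 20)
        s1, _ = logrank_test(_cohort(t, e, strat))
        s2, _ = logrank_test(_cohort(t, e, np.where(strat == "a", "b", "a")))
        assert s1 == pytest.approx(s2)

    def test_single_stratum_raises(self):
        with pytest.raises(ValueError, match="2 strata"):
            logrank_test(_cohort([1, 2], [1, 1], ["a", "a"]))

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="one event"):
            logrank_test(_cohort([1, 2], [0, 0], ["a", "b"]))


class TestCox:
    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 400)
        t, e = simulate_survival(np.zeros(400), beta=0.0, rng=rng)
        res = cox_hr(t, e, x)
        assert res.converged
        assert abs(res.coef) < 3 * res.se

    def test_recovers_planted_log_hazard(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 500)
        t, e = simulate_survival(x, beta=0.7, censor_rate=0.2, rng=rng)
        res = cox_hr(t, e, x)
        assert res.converged
        assert abs(res.coef - 0.7) < 3 * res.se

    @pytest.mark.parametrize("beta", [0.0, 0.35, 0.7])
    def test_recovery_grid(self, beta):
        rng = np.random.default_rng(int(beta * 100) + 9)
        x = rng.normal(0, 1, 500)
        t, e = simulate_survival(x, beta=beta, censor_rate=0.2, rng=rng)
        res = cox_hr(t, e, x)
        assert abs(res.coef - beta) < 3 * res.se

    def test_time_rescaling_leaves_hr_unchanged(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 120)
        t, e = simulate_survival(x, beta=0.5, rng=rng)
        r1 = cox_hr(t, e, x)
        r2 = cox_hr(t * 365.25, e, x)
        assert r1.hr == pytest.approx(r2.hr, rel=1e-8)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 150)
        t, e = simulate_survival(x, beta=0.6, censor_rate=0.25, rng=rng)
        assert len(np.unique(t)) == len(t)  # no ties: Breslow = Efron
        mine = cox_hr(t, e, x)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"T": t, "E": e, "x": x}),
                duration_col="T", event_col="E")
        assert mine.coef == pytest.approx(cph.params_["x"], abs=1e-6)
        assert mine.se == pytest.approx(cph.standard_errors_["x"], rel=1e-4)

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant"):
            cox_hr([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0])

    def test_separation_flagged_not_silent(self):
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        e = np.ones(8, dtype=int)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        res = cox_hr(t, e, x)
        assert res.flag or res.converged  # monotone likelihood must be flagged
        if not res.converged:
            assert res.flag in {"monotone_likelihood", "max_iter",
                                "singular_information"}


class TestCompareScores:
    def test_identical_groups(self):
        out = compare_scores({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out.iloc[0]["difference"] == 0.0
        assert out.iloc[0]["p"] > 0.999

    def test_shift_recovered(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 30)
        out = compare_scores({"primary": a, "metastasis": a + 1.5})
        assert out.iloc[0]["difference"] == pytest.approx(1.5)

    def test_matches_welch_bit_for_bit(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        out = compare_scores({"a": a, "b": b})
        stat, p = welch_t(b, a)
        assert out.iloc[0]["t"] == stat and out.iloc[0]["p"] == p

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_scores({"a": [1.0], "b": [1.0, 2.0]})


class TestTrim:
    @staticmethod
    def _hazard_cohort(seed=16, n=200, n_genes=30, n_causal=5):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n_genes)]
        expr = pd.DataFrame(rng.normal(0, 1, (n_genes, n)), index=genes,
                            columns=[f"p{i}" for i in range(n)])
        causal = genes[:n_causal]
        lin = 0.6 * expr.loc[causal].sum(axis=0).to_numpy() / np.sqrt(n_causal)
        t, e = simulate_survival(lin, beta=1.0, censor_rate=0.2, rng=rng)
        cohort = pd.DataFrame({"sample_id": expr.columns, "time": t,
                               "event": e})
        return expr, cohort, genes, causal

    def test_identity_at_full_k(self):
        expr, cohort, genes, _ = self._hazard_cohort()
        assert set(trim_by_survival(expr, cohort, genes, k=len(genes))) == set(genes)

    def test_subset_property(self):
        expr, cohort, genes, _ = self._hazard_cohort()
        assert set(trim_by_survival(expr, cohort, genes, k=10)) <= set(genes)

    def test_hazard_genes_rank_into_top_20(self):
        expr, cohort, genes, causal = self._hazard_cohort()
        top = trim_by_survival(expr, cohort, genes, k=20)
        assert set(causal) <= set(top)

    def test_k_too_large_raises(self):
        expr, cohort, genes, _ = self._hazard_cohort()
        with pytest.raises(ValueError, match="exceeds"):
            trim_by_survival(expr, cohort, genes, k=len(genes) + 1)
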