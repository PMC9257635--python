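"""Biomarkers, KM/log-rank, optimal cutpoints, Cox fits and subtype pooling."""

import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from tibrep.clone_io import CohortTables
from tibrep.exceptions import AnalysisError
from tibrep import survival as sv
from tibrep.simulate import CohortSimConfig, simulate_cohort

COVS = ("gender", "age", "smoking", "drinking", "stage", "infiltration")


def product_limit_oracle(times, events):
    """Hand-coded product-limit estimate at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


def make_tables(n=120, seed=0, **cfg_kw):
    sim = simulate_cohort(
        CohortSimConfig(n_patients=n, with_repertoires=False, seed=seed, **cfg_kw)
    )
    return sim


@pytest.fixture(scope="module")
def cohort():
    return make_tables(n=160, seed=21)


class TestBiomarkers:
    def test_gene_sum(self):
        expr = pd.DataFrame(
            {"P1": [4.0, 3.0, 2.0, 1.0, 5.0]},
            index=["IGHG1", "IGHG2", "IGHG3", "IGHG4", "MS4A1"],
        )
        md = pd.DataFrame({"os_time": [10.0], "os_event": [1]}, index=["P1"])
        tables = CohortTables(metadata=md, expression=expr, scale_flag="fpkm")
        bm = sv.compute_biomarker(tables, sv.GeneSum(sv.IGHG_GENES, name="IGHG"))
        assert bm.values["P1"] == pytest.approx(10.0)

    def test_gene_ratio_without_pseudocount(self):
        expr = pd.DataFrame(
            {"P1": [6.0, 3.0]}, index=["IGHG2", "MS4A1"]
        )
        md = pd.DataFrame({"os_time": [10.0], "os_event": [1]}, index=["P1"])
        tables = CohortTables(metadata=md, expression=expr, scale_flag="fpkm")
        bm = sv.compute_biomarker(
            tables, sv.GeneRatio(("IGHG2",), "MS4A1", eps=0.0)
        )
        assert bm.values["P1"] == pytest.approx(2.0)

    def test_log_scale_back_transformed_before_summing(self):
        expr = pd.DataFrame({"P1": [3.0]}, index=["IGHG1"])
        md = pd.DataFrame({"os_time": [10.0], "os_event": [1]}, index=["P1"])
        tables = CohortTables(metadata=md, expression=expr, scale_flag="log2fpkm1")
        bm = sv.compute_biomarker(tables, sv.GeneSum(("IGHG1",)))
        assert bm.values["P1"] == pytest.approx(2.0**3 - 1.0)  # = 7

    def test_missing_gene_named(self):
        expr = pd.DataFrame({"P1": [1.0]}, index=["IGHG1"])
        md = pd.DataFrame({"os_time": [1.0], "os_event": [1]}, index=["P1"])
        tables = CohortTables(metadata=md, expression=expr, scale_flag="fpkm")
        with pytest.raises(AnalysisError, match="IGHG2"):
            sv.compute_biomarker(tables, sv.GeneSum(("IGHG1", "IGHG2")))


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        curve = sv.km_estimator([5, 8, 13, 21], [0, 0, 0, 0])
        assert np.allclose(curve.survival, 1.0)

    def test_three_events_product_limit(self):
        curve = sv.km_estimator([1, 2, 3], [1, 1, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(1 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_matches_product_limit_oracle_on_random_data(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            times = np.round(rng.exponential(10, n), 1)
            events = rng.integers(0, 2, n)
            curve = sv.km_estimator(times, events)
            for t, s in product_limit_oracle(times, events).items():
                assert curve.survival_at(t) == pytest.approx(s)

    def test_empty_input_errors(self):
        with pytest.raises(AnalysisError):
            sv.km_estimator([], [])


class TestLogrank:
    def test_duplicated_groups_give_zero_chi2(self):
        times = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        labels = ["a"] * 4 + ["b"] * 4
        chi2, p = sv.logrank_test(labels, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_contingency(self):
        # group A: all events at t=1; group B: all censored at t=2
        times = [1.0, 1.0, 2.0, 2.0]
        events = [1, 1, 0, 0]
        labels = ["A", "A", "B", "B"]
        chi2, p = sv.logrank_test(labels, times, events)
        # single event time t=1: O_A=2, E_A=2*(2/4)=1, V=2*(1/2)(1/2)(2/3)
        o_minus_e = 2 - 1.0
        var = 2 * 0.5 * 0.5 * (4 - 2) / (4 - 1)
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_internal_standardized_statistic_matches_lifelines(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            times = rng.exponential(10, n)
            events = rng.integers(0, 2, n)
            group = rng.integers(0, 2, n).astype(bool)
            if group.all() or not group.any():
                continue
            order = np.argsort(times, kind="stable")
            t_s, e_s, g_s = times[order], events[order], group[order]
            first = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
            z = sv._standardized_logrank(e_s, g_s, first, n)
            ref = lifelines_logrank(
                times[group], times[~group], events[group], events[~group]
            ).test_statistic
            assert z**2 == pytest.approx(ref, rel=1e-8, abs=1e-10)

    def test_empty_group_errors(self):
        with pytest.raises(AnalysisError):
            sv.logrank_test(["a", "a"], [1.0, 2.0], [1, 1])


class TestOptimalCutpoint:
    def test_separable_marker_cut_between_clusters(self, rng):
        n = 60
        marker = np.r_[rng.normal(0, 0.1, 30), rng.normal(5, 0.1, 30)]
        times = np.r_[rng.exponential(2, 30), rng.exponential(30, 30)]
        events = np.ones(n, int)
        cp = sv.optimal_cutpoint(marker, times, events)
        assert 1.0 < cp.cutpoint < 4.0
        assert cp.n_low == 30

    def test_constant_marker_errors(self):
        with pytest.raises(AnalysisError, match="no admissible split"):
            sv.optimal_cutpoint(
                np.ones(60), np.arange(1.0, 61.0), np.ones(60, int),
                min_group_n=5,
            )

    def test_matches_exhaustive_lifelines_search(self, rng):
        for _ in range(10):
            n = 60
            marker = rng.normal(0, 1, n)
            hazard = 0.05 * np.exp(-0.8 * (marker > rng.normal()))
            times = rng.exponential(1 / hazard)
            events = (times < 40).astype(int)
            times = np.minimum(times, 40.0)
            cp = sv.optimal_cutpoint(marker, times, events, min_group_n=10)
            order = np.argsort(marker)
            m_sorted = marker[order]
            best = (-1.0, None)
            gmin = max(int(np.ceil(0.15 * n)), 10)
            for k in range(gmin, n - gmin + 1):
                if m_sorted[k - 1] >= m_sorted[k]:
                    continue
                cut = 0.5 * (m_sorted[k - 1] + m_sorted[k])
                low = marker <= cut
                chi2 = lifelines_logrank(
                    times[low], times[~low], events[low], events[~low]
                ).test_statistic
                if chi2 > best[0] + 1e-12:
                    best = (chi2, cut)
            assert cp.cutpoint == pytest.approx(best[1])
            assert cp.statistic**2 == pytest.approx(best[0], rel=1e-8)


class TestCox:
    def test_null_covariate_ci_covers_one(self, rng):
        n = 600
        data = pd.DataFrame(
            {
                "os_time": rng.exponential(20, n),
                "os_event": np.ones(n, int),
                "noise": rng.normal(0, 1, n),
            }
        )
        out = sv.cox_fit(data)
        assert out.loc["noise", "hr_lower"] < 1.0 < out.loc["noise", "hr_upper"]

    def test_planted_binary_log_hr_recovered(self):
        """Nominal ~95% coverage: the planted effect sits within 2 SE for
        at least 8 of 10 independent replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            n = 500
            x = rng.integers(0, 2, n)
            hazard = 0.05 * np.exp(-0.9 * x)
            t = rng.exponential(1 / hazard)
            c = rng.exponential(40, n)
            data = pd.DataFrame(
                {
                    "os_time": np.minimum(t, c),
                    "os_event": (t <= c).astype(int),
                    "x": x.astype(float),
                }
            )
            out = sv.cox_fit(data)
            hits += abs(out.loc["x", "coef"] - (-0.9)) < 2 * out.loc["x", "se"]
        assert hits >= 8

    def test_matches_scikit_survival_partial_likelihood(self, rng):
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        for _ in range(20):
            n = 80
            x = rng.normal(0, 1, (n, 3))
            hazard = 0.05 * np.exp(x @ np.array([0.5, -0.3, 0.2]))
            t = rng.exponential(1 / hazard)
            c = rng.exponential(40, n)
            data = pd.DataFrame(x, columns=["a", "b", "c"])
            data["os_time"] = np.minimum(t, c)
            data["os_event"] = (t <= c).astype(int)
            mine = sv.cox_fit(data)
            y = np.array(
                list(zip(data["os_event"].astype(bool), data["os_time"])),
                dtype=[("e", bool), ("t", float)],
            )
            ref = CoxPHSurvivalAnalysis(ties="efron").fit(x, y)
            np.testing.assert_allclose(
                mine["coef"].to_numpy(), ref.coef_, rtol=1e-4, atol=1e-6
            )

    def test_constant_covariate_errors(self):
        data = pd.DataFrame(
            {"os_time": [1.0, 2.0, 3.0], "os_event": [1, 1, 1], "k": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(AnalysisError, match="constant"):
            sv.cox_fit(data)


class TestStratificationModel:
    def test_fit_reports_groups_curves_and_cox(self, cohort):
        bm = sv.compute_biomarker(
            cohort.tables, sv.GeneRatio(("IGHG2",), "MS4A1", name="IGHG2_ratio")
        )
        model = sv.MarkerStratification.from_cohort(cohort.tables, bm, COVS)
        with pytest.warns(UserWarning, match="anti-conservative"):
            res = model.fit()
        n = len(cohort.tables.metadata)
        assert res.n_low + res.n_high == n
        assert min(res.n_low, res.n_high) >= max(int(np.ceil(0.15 * n)), 20)
        for curve in (res.km_low, res.km_high):
            assert curve.survival[0] == 1.0
            assert (np.diff(curve.survival) <= 1e-12).all()
        assert "IGHG2_ratio_high" in res.cox_summary.index
        assert "anti-conservative" in " ".join(res.warnings)
        assert "Cox proportional hazards" in res.summary()

    def test_fixed_cutpoint_skips_selection(self, cohort):
        bm = sv.compute_biomarker(
            cohort.tables, sv.GeneRatio(("IGHG2",), "MS4A1", name="m")
        )
        model = sv.MarkerStratification.from_cohort(cohort.tables, bm, COVS)
        med = float(np.median(bm.values))
        res = model.fit(cutpoint=med)
        assert res.cutpoint == med
        assert not res.cutpoint_selected


class TestSubtypeCombined:
    @staticmethod
    def _run(sim):
        bm = sv.compute_biomarker(
            sim.tables, sv.GeneRatio(("IGHG2",), "MS4A1", name="m")
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sv.subtype_combined_stratification(sim.tables, bm, COVS)

    def test_single_subtype_cohort_pooled_equals_subtype(self):
        sim = make_tables(
            n=120, seed=33,
            subtype_mixture={"differentiated": 1.0, "immunogenic": 0.0,
                             "metabolic": 0.0, "stemness": 0.0},
        )
        combo = self._run(sim)
        assert list(combo.per_subtype) == ["differentiated"]
        assert combo.pooled is not None
        sub = combo.per_subtype["differentiated"]
        assert combo.pooled.cutpoint == sub.cutpoint
        assert combo.pooled.logrank_p == pytest.approx(sub.logrank_p)
        assert combo.pooled.hazard_ratio == pytest.approx(sub.hazard_ratio)

    def test_effect_recovered_only_where_planted(self):
        """With the protective ratio effect planted in three subtypes and none
        in stemness, the per-subtype log-HRs are clearly negative only where
        planted, the pooled non-stemness estimate is protective and
        significant, and dropping the no-effect subtype strengthens the
        pooled point estimate relative to the full cohort."""
        planted_coefs, stemness_coefs = [], []
        pooled_protective = 0
        pooled_stronger = 0
        n_seeds = 10
        for seed in range(n_seeds):
            sim = make_tables(
                n=400, seed=500 + seed,
                marker_log_hr=float(np.log(0.4)),
                no_effect_subtypes=("stemness",),
            )
            combo = self._run(sim)
            assert combo.pooled is not None
            if combo.pooled.hazard_ratio < 1.0 and combo.pooled.logrank_p < 0.05:
                pooled_protective += 1
            if combo.pooled.hazard_ratio < combo.full.hazard_ratio:
                pooled_stronger += 1
            for subtype, res in combo.per_subtype.items():
                (stemness_coefs if subtype == "stemness" else planted_coefs).append(
                    res.log_hr
                )
        assert pooled_protective >= 8
        assert pooled_stronger >= 7
        assert np.mean(planted_coefs) < -0.3
        assert abs(np.mean(stemness_coefs)) < 0.3
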