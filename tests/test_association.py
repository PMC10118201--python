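import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import glycassoc as ga
from glycassoc.association import _ols_multi, GDM_PREDICTOR
from glycassoc.errors import (DegenerateDataError, InsufficientDataError,
                              ValidationError)
from glycassoc.preprocess import rank_inverse_normal
from glycassoc.tables_io import PanelSchema, PeakTable


class TestOLSCore:
    def test_matches_normal_equations_oracle(self):
        """Brute-force (X'X)^-1 X'y solved independently, to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, k = 12, 3
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = rng.normal(size=(n, 2))
            beta, se, t, p, df = _ols_multi(X, y)
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_matches_statsmodels_inference(self):
        rng = np.random.default_rng(1)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.uniform(25, 40, n)])
        y = X @ [0.5, 0.8, 0.01] + rng.normal(size=n)
        beta, se, t, p, df = _ols_multi(X, y[:, None])
        fit = sm.OLS(y, X).fit()
        np.testing.assert_allclose(beta[:, 0], fit.params, atol=1e-10)
        np.testing.assert_allclose(se[:, 0], fit.bse, atol=1e-10)
        np.testing.assert_allclose(p[:, 0], fit.pvalues, atol=1e-12)


class TestFitMarkerAssociation:
    def test_identical_vectors_give_unit_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        age = rng.uniform(27, 38, size=50)
        r = ga.fit_marker_association(x, x.copy(), age)
        assert r.beta == pytest.approx(1.0, abs=1e-9)
        assert r.p < 1e-30

    def test_null_betas_small_and_p_uniform(self):
        """Independent marker: betas shrink and p is Uniform(0,1) across
        independent replicates."""
        rng = np.random.default_rng(3)
        ps, betas = [], []
        for _ in range(200):
            t = rng.normal(size=200)
            m = rng.normal(size=200)
            age = rng.uniform(27, 38, size=200)
            r = ga.fit_marker_association(t, m, age)
            ps.append(r.p)
            betas.append(r.beta)
        assert np.quantile(np.abs(betas), 0.95) < 0.15
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_symmetric_in_trait_and_marker_with_constant_age(self):
        rng = np.random.default_rng(4)
        t, m = rng.normal(size=60), rng.normal(size=60)
        age = np.full(60, 33.0)
        # constant covariate would be collinear with the intercept; drop it
        # by fitting both directions with the same design structure
        y1 = rank_inverse_normal(t)
        x1 = rank_inverse_normal(m)
        X = np.column_stack([np.ones(60), x1])
        b1 = _ols_multi(X, y1[:, None])[0][1, 0]
        X2 = np.column_stack([np.ones(60), y1])
        b2 = _ols_multi(X2, x1[:, None])[0][1, 0]
        assert b1 == pytest.approx(b2, abs=1e-9)

    def test_insufficient_cases_error(self):
        with pytest.raises(InsufficientDataError):
            ga.fit_marker_association(np.arange(5.0), np.arange(5.0),
                                      np.full(5, 30.0))

    def test_complete_cases_taken_per_test(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=30)
        m = rng.normal(size=30)
        m[:5] = np.nan
        r = ga.fit_marker_association(t, m, rng.uniform(27, 38, 30))
        assert r.n == 25


class TestFitGroupDifference:
    def test_permutation_type_one_error_calibrated(self):
        """Permuting labels of one sample set: rejection rate at alpha=0.05
        stays within 0.05 +/- 0.02."""
        rng = np.random.default_rng(6)
        y = rng.normal(size=89)
        age = rng.uniform(27, 38, size=89)
        labels = np.array(["control"] * 48 + ["case"] * 41)
        rejections = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            r = ga.fit_group_difference(y, perm, age)
            rejections += r.p < 0.05
        assert rejections / n_perm == pytest.approx(0.05, abs=0.02)

    def test_power_for_one_sd_shift_at_study_size(self):
        """+1 SD latent case shift at n=89 (48/41): power > 0.9 at raw 0.05."""
        rng = np.random.default_rng(7)
        labels = np.array(["control"] * 48 + ["case"] * 41)
        age = rng.uniform(27, 38, size=89)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            y = rng.normal(size=89)
            y[48:] += 1.0
            hits += ga.fit_group_difference(y, labels, age).p < 0.05
        assert hits / n_sim > 0.9

    def test_single_group_input_errors(self):
        rng = np.random.default_rng(8)
        with pytest.raises(DegenerateDataError):
            ga.fit_group_difference(rng.normal(size=20),
                                    np.array(["case"] * 20),
                                    rng.uniform(27, 38, 20))


class TestSummarizeGroup:
    def test_separated_toy_groups_against_exact_enumeration(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        status = np.array(["control"] * 5 + ["case"] * 5)
        g = ga.summarize_group(values, status)
        assert g.groups["control"]["median"] == 3 and g.groups["case"]["median"] == 8
        exact = stats.mannwhitneyu(values[:5], values[5:],
                                   alternative="two-sided", method="exact").pvalue
        assert exact == pytest.approx(0.0079, abs=2e-4)
        assert abs(g.wilcoxon_p - exact) < 0.01  # continuity-corrected normal approx

    def test_identical_groups_p_near_one(self):
        v = np.tile(np.arange(10.0), 2)
        status = np.array(["control"] * 10 + ["case"] * 10)
        assert ga.summarize_group(v, status).wilcoxon_p == pytest.approx(1.0, abs=1e-9)

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(9)
        g = ga.summarize_group(rng.normal(size=50),
                               np.array(["control"] * 25 + ["case"] * 25))
        for d in g.groups.values():
            assert d["q1"] <= d["median"] <= d["q3"]

    def test_empty_group_errors(self):
        with pytest.raises(DegenerateDataError):
            ga.summarize_group(np.arange(5.0), np.array(["control"] * 5))


class TestRunAllAssociations:
    @pytest.fixture()
    def tiny_family(self):
        rng = np.random.default_rng(10)
        schema = PanelSchema(panel_id="plasma", peak_ids=("GP1", "GP2", "GP3"))
        vals = rng.dirichlet(np.ones(3), size=20) * 100
        pt = PeakTable(pd.DataFrame(vals, index=[f"s{i}" for i in range(20)],
                                    columns=list(schema.peak_ids)),
                       unit="percent", schema=schema)
        clin = ga.ClinicalTable(pd.DataFrame({
            "age": rng.uniform(27, 38, 20),
            "gdm_status": ["control"] * 10 + ["case"] * 10,
            "fasting_insulin": rng.lognormal(3.8, 0.4, 20),
            "fasting_glucose": rng.normal(4.8, 0.3, 20),
        }, index=[f"s{i}" for i in range(20)]))
        return pt, clin

    def test_enumeration_counts_rows(self, tiny_family):
        pt, clin = tiny_family
        res = ga.run_all_associations({"plasma": pt}, {}, clin,
                                      markers=["fasting_insulin", "fasting_glucose"])
        assert len(res.data) == 3 * (2 + 1)  # 3 glycans x (2 markers + GDM)
        assert res.meta["m"] == 9

    def test_row_order_deterministic_and_gdm_last(self, tiny_family):
        pt, clin = tiny_family
        res = ga.run_all_associations({"plasma": pt}, {}, clin,
                                      markers=["fasting_insulin", "fasting_glucose"])
        preds = res.data["predictor"].tolist()
        assert preds == (["fasting_insulin"] * 3 + ["fasting_glucose"] * 3
                         + [GDM_PREDICTOR] * 3)
        assert res.data["trait"].tolist()[:3] == ["GP1", "GP2", "GP3"]

    def test_default_family_size_on_full_cohort(self, null_bundle):
        # 93 peaks + 37 derived traits = 130 variables; 7 markers + GDM
        assert null_bundle.meff.m == 1040
        assert null_bundle.meff.M_vars == 130

    def test_vectorized_family_agrees_with_single_fits(self, null_cohort):
        peaks, clinical, _ = null_cohort
        pct = ga.normalize_total_area(peaks["igg"])
        res = ga.run_all_associations({"igg": pct}, {}, clinical,
                                      markers=["fasting_insulin"])
        row = res.data[(res.data.trait == "GP7")
                       & (res.data.predictor == "fasting_insulin")].iloc[0]
        single = ga.fit_marker_association(
            pct.data["GP7"].to_numpy(),
            clinical.data["fasting_insulin"].to_numpy(),
            clinical.data["age"].to_numpy())
        assert row.beta == pytest.approx(single.beta, abs=1e-12)
        assert row.p == pytest.approx(single.p, abs=1e-12)

    def test_empty_predictor_set_errors(self, tiny_family):
        pt, clin = tiny_family
        with pytest.raises(ValidationError):
            ga.run_all_associations({"plasma": pt}, {}, clin, markers=[],
                                    include_gdm=False)
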