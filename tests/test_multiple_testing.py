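import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

import glycassoc as ga
from glycassoc.errors import DegenerateDataError, ValidationError
from glycassoc.tables_io import ResultTable


class TestTraitCorrelation:
    def test_identical_columns_correlate_perfectly(self):
        x = np.random.default_rng(0).normal(size=50)
        corr = ga.trait_correlation(pd.DataFrame({"a": x, "b": x}))
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(10_000, 6)))
        corr = ga.trait_correlation(frame).to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(2)
        corr = ga.trait_correlation(pd.DataFrame(rng.normal(size=(30, 4))))
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_constant_variable_named_in_error(self):
        frame = pd.DataFrame({"ok": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(DegenerateDataError, match="flat"):
            ga.trait_correlation(frame)


class TestLijiMeff:
    def test_identity_gives_full_count(self):
        assert ga.liji_meff(np.eye(10)) == pytest.approx(10.0)

    def test_all_ones_gives_one(self):
        assert ga.liji_meff(np.ones((5, 5))) == pytest.approx(1.0)

    def test_exchangeable_closed_form(self):
        # r = 0.6, 3x3: eigenvalues 2.2, 0.4, 0.4 -> 1.2 + 0.4 + 0.4 = 2.0
        r = 0.6
        mat = np.full((3, 3), r)
        np.fill_diagonal(mat, 1.0)
        assert ga.liji_meff(mat) == pytest.approx(2.0, abs=1e-9)

    @given(st.integers(2, 12), st.floats(0.0, 0.95))
    def test_exchangeable_matches_eigen_oracle(self, m, r):
        mat = np.full((m, m), r)
        np.fill_diagonal(mat, 1.0)
        lam = np.array([1 + (m - 1) * r] + [1 - r] * (m - 1))  # known spectrum
        expected = np.sum((lam >= 1) + (lam - np.floor(lam)))
        assert ga.liji_meff(mat) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_permutation_and_sign_flips(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 8)) @ rng.normal(size=(8, 8))
        corr = np.corrcoef(X, rowvar=False)
        base = ga.liji_meff(corr)
        perm = rng.permutation(8)
        signs = np.diag(rng.choice([-1.0, 1.0], size=8))
        flipped = signs @ corr[np.ix_(perm, perm)] @ signs
        assert ga.liji_meff(flipped) == pytest.approx(base, abs=1e-9)

    def test_rejects_invalid_matrix(self):
        with pytest.raises(ValidationError):
            ga.liji_meff(np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValidationError):
            ga.liji_meff(np.array([[2.0, 0.0], [0.0, 2.0]]))


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        out = ga.bh_adjust([0.01, 0.02, 0.03], m_eff=3)
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ga.bh_adjust([0.04], m_eff=1), [0.04])

    def test_fractional_meff_scales(self):
        out = ga.bh_adjust([0.01, 0.02, 0.03], m_eff=1.5)
        np.testing.assert_allclose(out, [0.015, 0.015, 0.015], atol=1e-12)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=200))
    def test_meff_equal_m_is_exactly_reference_bh(self, ps):
        ours = ga.bh_adjust(ps, m_eff=len(ps))
        ref = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(1e-6, 1, size=500)
        q = ga.bh_adjust(p, m_eff=200.0)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            ga.bh_adjust([0.0, 0.5], m_eff=2)
        with pytest.raises(ValidationError):
            ga.bh_adjust([0.5], m_eff=0.5)


def _family(pvals, n_vars):
    df = pd.DataFrame({
        "panel": "plasma",
        "trait": [f"V{i % n_vars}" for i in range(len(pvals))],
        "predictor": [f"M{i // n_vars}" for i in range(len(pvals))],
        "n": 89, "beta": 0.1, "se": 0.05, "ci_low": 0.0, "ci_high": 0.2,
        "p": pvals, "p_adj": np.nan})
    return ResultTable(data=df)


class TestAdjustFamily:
    def test_uncorrelated_variables_reduce_to_standard_bh(self):
        rng = np.random.default_rng(5)
        n, nv, npred = 5000, 20, 3
        glycans = pd.DataFrame(rng.normal(size=(n, nv)),
                               columns=[f"V{i}" for i in range(nv)])
        p = rng.uniform(1e-4, 1, size=nv * npred)
        res, meff = ga.adjust_family(_family(p, nv), glycans)
        assert meff.meff_vars == pytest.approx(nv, rel=0.02)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(res.data["p_adj"], ref, rtol=0.05)

    def test_duplicated_variables_halve_meff_and_shrink_p(self):
        nv = 10
        # population correlation of 10 independent variables, each entered
        # twice: block-diagonal in all-ones 2x2 blocks -> eigenvalues are
        # ten 2s and ten 0s, so the effective count is exactly half
        exact = np.kron(np.eye(nv), np.ones((2, 2)))
        assert ga.liji_meff(exact) == pytest.approx(nv, abs=1e-9)
        # on sampled data the cross-pair noise scatters eigenvalues around
        # the integer discontinuity of f, so assert the ordering properties
        rng = np.random.default_rng(6)
        base = rng.normal(size=(400, nv))
        dup = np.hstack([base, base])  # each variable twice
        glycans = pd.DataFrame(dup, columns=[f"V{i}" for i in range(2 * nv)])
        p = rng.uniform(1e-4, 1, size=2 * nv)
        res, meff = ga.adjust_family(_family(p, 2 * nv), glycans)
        assert meff.meff_vars < 2 * nv
        standard = multipletests(p, method="fdr_bh")[1]
        assert (res.data["p_adj"].to_numpy() <= standard + 1e-12).all()

    def test_meff_result_invariants(self, null_bundle):
        meff = null_bundle.meff
        assert 1 <= meff.meff_vars <= meff.M_vars
        assert meff.meff_tests <= meff.m
        assert np.sum(meff.eigenvalues) == pytest.approx(meff.M_vars, rel=1e-8)

    def test_fdr_calibration_with_true_effects(self):
        """Correlated variables, 10% carrying a real effect (beta 0.5 SD):
        plain BH keeps the realized false-discovery proportion under
        control, and the Meff-modified step-up stays at its own nominal
        level alpha * m0 / Meff (the power-for-strictness trade the
        eigenvalue correction makes under correlated tests)."""
        rng = np.random.default_rng(7)
        n, nv = 200, 130
        n_true = 13
        fdp_bh, fdp_meff, meffs = [], [], []
        for _ in range(200):
            marker = rng.normal(size=n)
            latent = rng.normal(size=(n, 10))
            mix = rng.normal(size=(10, nv)) * 0.4
            traits = latent @ mix + rng.normal(size=(n, nv))
            traits[:, :n_true] += 0.5 * np.sqrt(traits[:, :n_true].var(axis=0)) \
                * marker[:, None]
            frame = pd.DataFrame(traits, columns=[f"V{i}" for i in range(nv)])
            age = rng.uniform(27, 38, n)
            ps = np.array([ga.fit_marker_association(traits[:, i], marker, age).p
                           for i in range(nv)])
            res, meff = ga.adjust_family(_family(ps, nv), frame)
            meffs.append(meff.meff_vars)

            def fdp(q):
                disc = q < 0.05
                return disc[n_true:].sum() / disc.sum() if disc.any() else 0.0

            fdp_meff.append(fdp(res.data["p_adj"].to_numpy()))
            fdp_bh.append(fdp(ga.bh_adjust(ps, float(nv))))
        assert np.mean(fdp_bh) <= 0.08
        nominal_meff = 0.05 * (nv - n_true) / np.mean(meffs)
        margin = 2 * np.std(fdp_meff) / np.sqrt(len(fdp_meff))
        assert np.mean(fdp_meff) <= nominal_meff + margin

    def test_empty_family_errors(self):
        with pytest.raises(ValidationError):
            ga.adjust_family(ResultTable(data=_family([0.5], 1).data.iloc[:0]),
                             pd.DataFrame(np.random.default_rng(8).normal(size=(10, 2))))
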