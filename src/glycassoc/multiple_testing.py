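"""Li-Ji effective number of independent tests and modified BH FDR control.

The glycan variables entering the association family are strongly
correlated (peaks within a panel are compositional, derived traits are sums
of peaks), so counting each of the m tests as independent overcorrects.
The Li & Ji estimator summarizes the correlation matrix of the tested
variables through its eigenvalues lambda_i:

    Meff = sum_i [ I(|lambda_i| >= 1) + (|lambda_i| - floor(|lambda_i|)) ]

equal to M for independent variables and 1 for perfectly correlated ones.
The Benjamini-Hochberg step-up is then run with Meff-scaled test counts in
place of m in the numerator (reducing to standard BH when Meff = m).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .tables_io import ResultTable


@dataclass
class MeffResult:
    """Eigen-analysis summary of the association family's correlation."""

    m: int                       # total tests in the family
    M_vars: int                  # correlated variables entering the analysis
    eigenvalues: np.ndarray
    meff_vars: float             # effective variable count
    meff_tests: float            # effective test count used in BH
    alpha: float = 0.05
    mode: str = "bh_meff"
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (1.0 - 1e-9 <= self.meff_vars <= self.M_vars + 1e-9):
            raise ValidationError("meff_vars outside [1, M_vars]")
        if abs(float(np.sum(self.eigenvalues)) - self.M_vars) > 1e-6 * self.M_vars:
            raise ValidationError("eigenvalues do not sum to the matrix trace")


def trait_correlation(traits) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of the (rank-INT) variables."""
    frame = pd.DataFrame(traits)
    if frame.shape[0] < 3 or frame.shape[1] < 2:
        raise ValidationError("need >= 3 samples and >= 2 variables")
    sds = frame.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise DegenerateDataError(f"constant variable(s): {constant}")
    corr = frame.corr(method="pearson", min_periods=3)
    if corr.isna().any().any():
        raise ValidationError("correlation undefined for some variable pair")
    np.fill_diagonal(corr.values, 1.0)
    return corr


_EIG_TOL = 1e-9  # absorbs round-off at the floor discontinuity of f(lambda)


def _meff_from_eigenvalues(lam: np.ndarray) -> float:
    """f(lambda) = I(lambda >= 1) + (lambda - floor(lambda)), summed.

    The floor is evaluated with a small tolerance so that an eigenvalue that
    is an integer up to round-off (e.g. 2 - 1e-15) does not contribute a
    spurious fractional part of ~1.
    """
    lam = np.abs(np.asarray(lam, dtype=float))
    frac = np.maximum(lam - np.floor(lam + _EIG_TOL), 0.0)
    return float(np.sum((lam >= 1.0 - _EIG_TOL).astype(float) + frac))


def liji_meff(corr) -> float:
    """Effective number of independent variables from a correlation matrix."""
    mat = np.asarray(pd.DataFrame(corr), dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValidationError("correlation matrix must have unit diagonal")
    # round-off can leave tiny negative eigenvalues; |.| folds them back
    return _meff_from_eigenvalues(np.linalg.eigvalsh(mat))


def bh_adjust(pvalues, m_eff: float) -> np.ndarray:
    """BH step-up with an (effective) test count ``m_eff`` in the numerator.

    q_(i) = m_eff * p_(i) / i over ascending p, monotonized from the top and
    capped at 1; returned in the original order.  With m_eff = len(p) this
    is exactly standard Benjamini-Hochberg.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if m_eff < 1:
        raise ValidationError("m_eff must be >= 1")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = m_eff * ranked / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def adjust_family(results: ResultTable, glycan_matrix, *, alpha: float = 0.05,
                  mode: str = "bh_meff") -> tuple[ResultTable, MeffResult]:
    """Fill ``p_adj`` for the pooled family using the Li-Ji-modified BH.

    ``glycan_matrix`` is the samples x glycan-variables matrix (rank-INT
    scale) whose correlation defines the effective variable count; the
    effective test count is meff_vars x (predictors tested per variable),
    since each predictor contributes one test per variable.

    ``mode``: ``bh_meff`` (default), ``bh`` (ignore Meff), or
    ``bonferroni_meff`` (literal threshold-style correction).
    """
    df = results.data
    if len(df) == 0:
        raise ValidationError("empty result family")
    m = len(df)
    corr = trait_correlation(glycan_matrix)
    M_vars = corr.shape[0]
    lam = np.abs(np.linalg.eigvalsh(np.asarray(corr, dtype=float)))
    meff_vars = _meff_from_eigenvalues(lam)
    tests_per_var = m / M_vars
    meff_tests = meff_vars * tests_per_var
    if mode == "bh":
        m_used = float(m)
        p_adj = bh_adjust(df["p"].to_numpy(), m_used)
    elif mode == "bh_meff":
        m_used = meff_tests
        p_adj = bh_adjust(df["p"].to_numpy(), m_used)
    elif mode == "bonferroni_meff":
        m_used = meff_tests
        p_adj = np.minimum(df["p"].to_numpy() * m_used, 1.0)
    else:
        raise ValidationError(f"unknown FDR mode {mode!r}")
    out = df.copy()
    out["p_adj"] = p_adj
    meff = MeffResult(m=m, M_vars=M_vars, eigenvalues=lam, meff_vars=meff_vars,
                      meff_tests=meff_tests, alpha=alpha, mode=mode,
                      notes={"tests_per_variable": tests_per_var})
    meta = dict(results.meta)
    meta.update({"meff_vars": meff_vars, "meff_tests": meff_tests,
                 "alpha": alpha, "fdr_mode": mode})
    return ResultTable(data=out, meta=meta), meff
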