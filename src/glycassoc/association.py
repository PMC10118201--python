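"""Per-trait linear-model association tests and group descriptives.

Every glycan variable (each peak and each derived trait, all three panels)
is tested against every metabolic marker with an ordinary least-squares
model

    rank-INT(glycan) ~ intercept + rank-INT(marker) + age

and against GDM status with

    rank-INT(glycan) ~ intercept + I(case) + age

(the glycan alone is rank-INT transformed there; age stays on its natural
scale in both).  Inference for the predictor coefficient uses the t
reference with n - 3 degrees of freedom and Wald 95% intervals.  Group
descriptives are medians with IQRs and a continuity-corrected Wilcoxon
rank-sum test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .preprocess import rank_inverse_normal
from .tables_io import ClinicalTable, PeakTable, ResultTable

MIN_COMPLETE_CASES = 10
GDM_PREDICTOR = "GDM"


@dataclass(frozen=True)
class AssociationResult:
    """One (glycan variable, predictor) test."""

    panel_id: str
    trait_id: str
    predictor: str
    n: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float = float("nan")


@dataclass(frozen=True)
class GroupSummary:
    """Median (IQR) per group plus a Wilcoxon rank-sum comparison."""

    variable: str
    groups: dict  # group label -> dict(n, median, q1, q3)
    wilcoxon_p: float


# ---------------------------------------------------------------------------
# OLS core.  The family is refit many times in calibration simulations, so
# the solver is a multi-RHS least-squares shared by every fit in the package.

def _ols_multi(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y on X; returns beta, se, t, p matrices.

    X: (n, k) design with intercept column; Y: (n, m).  Residual df = n - k.
    """
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"{n} cases cannot identify {k} coefficients")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("singular design matrix") from exc
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / (n - k)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - k)
    return beta, se, tstat, p, n - k


def _single_fit(y, X, panel_id, trait_id, predictor, coef_index=1):
    beta, se, _, p, df = _ols_multi(X, y[:, None])
    b, s = float(beta[coef_index, 0]), float(se[coef_index, 0])
    tcrit = stats.t.ppf(0.975, df=df)
    return AssociationResult(
        panel_id=panel_id, trait_id=trait_id, predictor=predictor,
        n=X.shape[0], beta=b, se=s,
        ci_low=b - tcrit * s, ci_high=b + tcrit * s,
        p=float(p[coef_index, 0]))


def _complete(*cols):
    mask = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        mask &= ~np.isnan(np.asarray(c, dtype=float))
    return mask


def fit_marker_association(trait, marker, age, *, panel_id="", trait_id="",
                           predictor="marker") -> AssociationResult:
    """Age-adjusted association of one glycan variable with one marker.

    Both the glycan variable and the marker are rank-INT transformed on the
    complete cases of this test; ``beta`` is therefore on the doubly
    rank-INT (approximately standardized) scale.
    """
    trait = np.asarray(trait, dtype=float)
    marker = np.asarray(marker, dtype=float)
    age = np.asarray(age, dtype=float)
    mask = _complete(trait, marker, age)
    if mask.sum() < MIN_COMPLETE_CASES:
        raise InsufficientDataError(
            f"only {int(mask.sum())} complete cases (need {MIN_COMPLETE_CASES})")
    y = rank_inverse_normal(trait[mask])
    x = rank_inverse_normal(marker[mask])
    X = np.column_stack([np.ones(mask.sum()), x, age[mask]])
    return _single_fit(y, X, panel_id, trait_id, predictor)


def fit_group_difference(trait, status, age, *, panel_id="", trait_id=""
                         ) -> AssociationResult:
    """Age-adjusted case-vs-control difference of one glycan variable.

    Only the glycan variable is rank-INT transformed; ``beta`` is the
    case-minus-control shift on the rank-INT scale.
    """
    trait = np.asarray(trait, dtype=float)
    age = np.asarray(age, dtype=float)
    status = np.asarray(status)
    indicator = np.where(status == "case", 1.0,
                         np.where(status == "control", 0.0, np.nan))
    if np.isnan(indicator).any():
        raise ValidationError("status labels must be 'control' or 'case'")
    mask = _complete(trait, age)
    if mask.sum() < MIN_COMPLETE_CASES:
        raise InsufficientDataError(
            f"only {int(mask.sum())} complete cases (need {MIN_COMPLETE_CASES})")
    ind = indicator[mask]
    if len(np.unique(ind)) < 2:
        raise DegenerateDataError("both groups must be represented")
    y = rank_inverse_normal(trait[mask])
    X = np.column_stack([np.ones(mask.sum()), ind, age[mask]])
    return _single_fit(y, X, panel_id, trait_id, GDM_PREDICTOR)


def summarize_group(values, status, variable: str = "") -> GroupSummary:
    """Median (Q1; Q3) per group and a two-sided Wilcoxon rank-sum p.

    Quartiles use linear interpolation; the test is the normal approximation
    with continuity correction and tie-corrected variance.
    """
    values = np.asarray(values, dtype=float)
    status = np.asarray(status)
    groups = {}
    samples = []
    for label in ("control", "case"):
        x = values[(status == label) & ~np.isnan(values)]
        if x.size == 0:
            raise DegenerateDataError(f"group {label!r} has no non-missing values")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        groups[label] = {"n": int(x.size), "median": float(med),
                         "q1": float(q1), "q3": float(q3)}
        samples.append(x)
    res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    return GroupSummary(variable=variable, groups=groups,
                        wilcoxon_p=float(res.pvalue))


def summarize_clinical(clinical: ClinicalTable) -> pd.DataFrame:
    """Study-population descriptives table: one row per clinical variable."""
    rows = []
    status = clinical.data["gdm_status"].to_numpy()
    for var in ["age", *clinical.markers]:
        g = summarize_group(clinical.data[var].to_numpy(), status, variable=var)
        row = {"variable": var, "wilcoxon_p": g.wilcoxon_p}
        for label, d in g.groups.items():
            for k, v in d.items():
                row[f"{label}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full association family

def glycan_variable_frame(peak_tables: dict[str, PeakTable],
                          trait_tables: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack all panels' peaks and derived traits into one samples x
    variables frame; returns (frame, key table of (panel, trait) per column)."""
    pieces, keys = [], []
    for panel_id, pt in peak_tables.items():
        df = pt.data.copy()
        keys += [(panel_id, c) for c in df.columns]
        df.columns = [f"{panel_id}:{c}" for c in df.columns]
        pieces.append(df)
        tt = trait_tables.get(panel_id)
        if tt is not None:
            td = tt.data.copy()
            keys += [(panel_id, c) for c in td.columns]
            td.columns = [f"{panel_id}:{c}" for c in td.columns]
            pieces.append(td)
    frame = pd.concat(pieces, axis=1)
    key_df = pd.DataFrame(keys, columns=["panel", "trait"], index=frame.columns)
    return frame, key_df


def run_all_associations(peak_tables: dict[str, PeakTable], trait_tables: dict,
                         clinical: ClinicalTable, markers: list[str],
                         include_gdm: bool = True) -> ResultTable:
    """Fit the whole family: every glycan variable x every predictor.

    Row order is deterministic: predictors in the given order (GDM last),
    and within a predictor, panels and variables in table order.  Complete
    cases are taken per test; rank-INT is computed within each test's
    complete cases.  Glycan columns with missing values fall back to a
    per-column fit; fully observed columns share one vectorized solve per
    predictor.
    """
    if not markers and not include_gdm:
        raise ValidationError("empty predictor set")
    for m in markers:
        if m not in clinical.data.columns:
            raise ValidationError(f"marker {m!r} not present in clinical table")
    glycans, keys = glycan_variable_frame(peak_tables, trait_tables)
    glycans = glycans.loc[clinical.data.index.intersection(glycans.index)]
    clin = clinical.data.loc[glycans.index]
    age = clin["age"].to_numpy(dtype=float)
    G = glycans.to_numpy(dtype=float)

    predictors = list(markers) + ([GDM_PREDICTOR] if include_gdm else [])
    rows = []
    for pred in predictors:
        if pred == GDM_PREDICTOR:
            x_raw = np.where(clin["gdm_status"].to_numpy() == "case", 1.0, 0.0)
            transform_x = False
        else:
            x_raw = clin[pred].to_numpy(dtype=float)
            transform_x = True
        base_mask = _complete(x_raw, age)
        Gm = G[base_mask]
        x = x_raw[base_mask]
        if transform_x:
            x = rank_inverse_normal(x)
        X = np.column_stack([np.ones(base_mask.sum()), x, age[base_mask]])
        complete_cols = ~np.isnan(Gm).any(axis=0)
        Y = Gm[:, complete_cols]
        if Y.shape[1]:
            Y = np.apply_along_axis(rank_inverse_normal, 0, Y)
        beta, se, _, pmat, df = _ols_multi(X, Y)
        tcrit = stats.t.ppf(0.975, df=df)
        fast = {}
        for j, col in enumerate(np.flatnonzero(complete_cols)):
            b, s = beta[1, j], se[1, j]
            fast[col] = (X.shape[0], b, s, b - tcrit * s, b + tcrit * s, pmat[1, j])
        for col, name in enumerate(glycans.columns):
            panel, trait = keys.loc[name, "panel"], keys.loc[name, "trait"]
            if col in fast:
                n, b, s, lo, hi, p = fast[col]
            else:  # missing glycan values: per-test complete cases
                if pred == GDM_PREDICTOR:
                    r = fit_group_difference(G[:, col], clin["gdm_status"].to_numpy(),
                                             age, panel_id=panel, trait_id=trait)
                else:
                    r = fit_marker_association(G[:, col], x_raw_full(clin, pred), age,
                                               panel_id=panel, trait_id=trait,
                                               predictor=pred)
                n, b, s, lo, hi, p = r.n, r.beta, r.se, r.ci_low, r.ci_high, r.p
            rows.append({"panel": panel, "trait": trait, "predictor": pred,
                         "n": n, "beta": b, "se": s, "ci_low": lo,
                         "ci_high": hi, "p": p, "p_adj": np.nan})
    result = pd.DataFrame(rows)
    meta = {"m": len(result), "n_glycan_variables": glycans.shape[1],
            "n_predictors": len(predictors), "predictors": predictors}
    return ResultTable(data=result, meta=meta)


def x_raw_full(clin: pd.DataFrame, pred: str) -> np.ndarray:
    return clin[pred].to_numpy(dtype=float)
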