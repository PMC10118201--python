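"""Transforms applied before any modelling.

Glycan peak areas are compositional: each sample's peaks are expressed as a
percentage of the total integrated chromatogram area.  Percentages are
mapped to the real line with a logit, and every variable entering a linear
model is rank-based inverse-normal (rank-INT) transformed so the marginal
is standard normal regardless of the original distribution shape.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .errors import DegenerateDataError, ValidationError
from .tables_io import PeakTable

#: Blom offset — the conventional rank-INT constant in omics association work.
DEFAULT_RINT_OFFSET = 3.0 / 8.0
#: Proportion-scale clip for the logit of boundary percentages.
DEFAULT_LOGIT_EPS = 1e-6


@dataclass
class TransformRecord:
    """Audit record of the transforms applied to a modelled variable."""

    name: str
    parameters: dict = field(default_factory=dict)
    applied_to: list = field(default_factory=list)

    def mark(self, column: str) -> None:
        if column in self.applied_to:
            raise ValidationError(
                f"transform {self.name!r} already applied to {column!r}")
        self.applied_to.append(column)


def normalize_total_area(peaks: PeakTable) -> PeakTable:
    """Express each peak as a percentage of the sample's total area.

    Scale-invariant per row; output rows sum to 100.
    """
    if peaks.unit != "raw_area":
        raise ValidationError(f"expected raw_area input, got {peaks.unit!r}")
    vals = peaks.data.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    dead = totals <= 0
    if dead.any():
        raise DegenerateDataError(
            f"all-zero chromatogram for sample(s) {peaks.data.index[dead].tolist()}")
    out = pd.DataFrame(100.0 * vals / totals[:, None],
                       index=peaks.data.index, columns=peaks.data.columns)
    return PeakTable(data=out, unit="percent", schema=peaks.schema)


def logit_percent(x, eps: float = DEFAULT_LOGIT_EPS):
    """ln(p / (1 - p)) with p = clip(x/100, eps, 1-eps); accepts scalars or arrays."""
    arr = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((arr < 0) | (arr > 100)):
            raise ValidationError("percentage outside [0, 100]")
    p = np.clip(arr / 100.0, eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def rank_inverse_normal(values, offset: float = DEFAULT_RINT_OFFSET):
    """Map values to standard-normal quantiles of their offset ranks.

    Non-missing entry with (average, tie-sharing) rank r among n non-missing
    values becomes ``ndtri((r - offset) / (n - 2*offset + 1))``.  Missing
    entries stay missing.  The output depends on the input only through
    ranks, so it is invariant under any strictly increasing transform.
    """
    series = isinstance(values, pd.Series)
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n < 3:
        raise DegenerateDataError("rank-INT needs at least 3 non-missing values")
    obs = arr[mask]
    if np.all(obs == obs[0]):
        raise DegenerateDataError("constant variable: rank transform undefined")
    ranks = rankdata(obs, method="average")
    out[mask] = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    if series:
        return pd.Series(out, index=values.index)
    return out


def rank_inverse_normal_columns(frame: pd.DataFrame,
                                offset: float = DEFAULT_RINT_OFFSET) -> pd.DataFrame:
    """Column-wise rank-INT of a DataFrame (each variable independently)."""
    return pd.DataFrame(
        {c: rank_inverse_normal(frame[c].to_numpy(), offset) for c in frame.columns},
        index=frame.index)
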