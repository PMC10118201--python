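"""Reading, validating and writing the tabular inputs and outputs.

Three kinds of table move through the pipeline: glycan peak-area tables
(samples x GP columns, one per chromatographic panel), a clinical table
(age, GDM status and metabolic markers), and tidy association-result
tables.  Input dialects: comma- or tab-delimited text and XLSX; decimal
commas are auto-detected per column.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

PANEL_IDS = ("plasma", "igg", "iga")
#: Number of integrated glycan peaks per built-in panel.
BUILTIN_N_PEAKS = {"plasma": 39, "igg": 24, "iga": 30}

#: Canonical metabolic-marker column names (units in docs/methods.md).
MARKER_COLUMNS = (
    "fasting_glucose", "hba1c_mmol_mol", "hba1c_pct", "fasting_insulin",
    "homa2_ir", "homa2_pct_b", "triglycerides", "hdl", "total_cholesterol",
    "total_proteins", "urate", "alt", "ast", "ggt", "fructosamine",
)

#: Default predictor set for the association family: glycaemia, insulin
#: resistance / beta-cell function, and lipid markers.
DEFAULT_MARKERS = (
    "fasting_glucose", "hba1c_mmol_mol", "fasting_insulin", "homa2_ir",
    "homa2_pct_b", "total_cholesterol", "triglycerides",
)

VALID_UNITS = ("raw_area", "percent", "logit")


@dataclass(frozen=True)
class PanelSchema:
    """Identity and peak layout of one chromatographic panel."""

    panel_id: str
    peak_ids: tuple[str, ...]
    annotations: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def __post_init__(self):
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise SchemaError(f"duplicate peak ids in panel {self.panel_id!r}")


def builtin_schema(panel_id: str) -> PanelSchema:
    """Built-in peak schema with reconstructed dominant-structure annotations.

    ``plasma`` has 39 peaks (GP1-GP39), ``igg`` 24 and ``iga`` 30.
    """
    if panel_id not in PANEL_IDS:
        raise SchemaError(f"unknown panel {panel_id!r}; expected one of {PANEL_IDS}")
    text = resources.files("glycassoc.data").joinpath(f"{panel_id}_peaks.tsv").read_text()
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    peak_ids = tuple(r[0] for r in rows)
    annotations = {r[0]: r[1] for r in rows}
    return PanelSchema(panel_id=panel_id, peak_ids=peak_ids, annotations=annotations)


@dataclass
class PeakTable:
    """Samples x glycan-peak matrix for one panel, with declared unit."""

    data: pd.DataFrame  # index = sample ids, columns = schema.peak_ids
    unit: str
    schema: PanelSchema

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        if list(self.data.columns) != list(self.schema.peak_ids):
            raise SchemaError(
                f"columns do not match schema for panel {self.schema.panel_id!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if self.unit != "logit" and np.nanmin(vals) < 0:
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value at sample {self.data.index[r]!r}, "
                f"peak {self.data.columns[c]!r}")
        if self.unit == "percent":
            sums = np.nansum(vals, axis=1)
            bad = np.abs(sums - 100.0) > 1e-6 * 100.0
            if bad.any():
                raise ValidationError(
                    f"rows do not sum to 100%: {self.data.index[bad].tolist()[:5]}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)


@dataclass
class ClinicalTable:
    """Per-sample age, GDM status and metabolic markers."""

    data: pd.DataFrame  # index = sample ids; columns: age, gdm_status, markers

    def __post_init__(self):
        for col in ("age", "gdm_status"):
            if col not in self.data.columns:
                raise ValidationError(f"clinical table lacks required column {col!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        status = self.data["gdm_status"]
        if status.isna().any():
            raise ValidationError("gdm_status contains missing values")
        bad = set(status.unique()) - {"control", "case"}
        if bad:
            raise ValidationError(f"gdm_status has invalid levels: {sorted(bad)}")
        age = self.data["age"]
        if (age.dropna() <= 0).any():
            raise ValidationError("non-positive age values present")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("age", "gdm_status")]

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.data["gdm_status"].value_counts().to_dict()


@dataclass
class ResultTable:
    """Tidy table of association tests plus family metadata.

    One row per (panel, glycan variable, predictor); the ``p_adj`` column is
    NaN until the multiple-testing stage fills it.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    COLUMNS = ("panel", "trait", "predictor", "n", "beta", "se",
               "ci_low", "ci_high", "p", "p_adj")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"result table lacks columns {missing}")
        keys = self.data[["panel", "trait", "predictor"]].apply(tuple, axis=1)
        if keys.duplicated().any():
            raise ValidationError("duplicate (panel, trait, predictor) rows")


# ---------------------------------------------------------------------------
# readers

def _read_any(path, sheet=0) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=sheet, dtype=object)
    if path.suffix.lower() == ".tsv":
        return pd.read_csv(path, sep="\t", dtype=object)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path, dtype=object)
    # fall back: sniff the delimiter from the header line
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=object)


def _to_numeric(series: pd.Series, colname: str) -> pd.Series:
    """Convert a column to float, auto-detecting decimal commas.

    A column where comma-decimal parsing succeeds on more cells than plain
    parsing is treated as comma-decimal; the choice is logged.
    """
    plain = pd.to_numeric(series, errors="coerce")
    as_str = series.astype(str).str.replace(",", ".", regex=False)
    commas = pd.to_numeric(as_str, errors="coerce")
    if commas.notna().sum() > plain.notna().sum():
        logger.info("column %r parsed with decimal commas", colname)
        plain = commas
    n_bad = int(series.notna().sum() - plain.notna().sum())
    if n_bad:
        logger.warning("column %r: %d unparseable cells set to missing",
                       colname, n_bad)
    return plain


def read_peak_table(path, schema: PanelSchema, unit: str) -> PeakTable:
    """Read a samples x peaks file and validate it against ``schema``.

    The first column is taken as the sample identifier.  Extra columns are
    ignored with a warning; a missing schema column is a :class:`SchemaError`.
    """
    raw = _read_any(path)
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.astype(str)
    missing = [p for p in schema.peak_ids if p not in raw.columns]
    if missing:
        raise SchemaError(
            f"peak table {path} lacks columns for panel "
            f"{schema.panel_id!r}: {missing}")
    extra = [c for c in raw.columns if c not in schema.peak_ids]
    if extra:
        logger.warning("ignoring %d extraneous columns: %s", len(extra), extra[:10])
    data = pd.DataFrame(
        {p: _to_numeric(raw[p], p) for p in schema.peak_ids}, index=raw.index)
    if data.isna().any().any():
        na = data.isna()
        r = na.any(axis=1).idxmax()
        raise ValidationError(f"non-numeric peak cell at sample {r!r}")
    return PeakTable(data=data, unit=unit, schema=schema)


def default_clinical_aliases() -> dict[str, list[str]]:
    """Built-in alias map from file column headers to canonical names."""
    text = resources.files("glycassoc.data").joinpath("clinical_aliases.yaml").read_text()
    return yaml.safe_load(text)


_GDM_LEVELS = {
    "control": "control", "ctrl": "control", "ngt": "control", "0": "control",
    "no": "control", "normal": "control",
    "case": "case", "gdm": "case", "1": "case", "yes": "case",
}


def read_clinical_table(path, aliases: Mapping[str, Sequence[str]] | None = None
                        ) -> ClinicalTable:
    """Read the clinical/metabolic-marker table.

    ``aliases`` maps canonical column names to acceptable file headers
    (matched case-insensitively); defaults ship with the package and can be
    extended via a YAML file.
    """
    if aliases is None:
        aliases = default_clinical_aliases()
    raw = _read_any(path)
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.astype(str)
    lower = {str(c).strip().lower(): c for c in raw.columns}

    def find(canonical):
        for alias in [canonical, *aliases.get(canonical, [])]:
            col = lower.get(str(alias).strip().lower())
            if col is not None:
                return col
        return None

    age_col, gdm_col = find("age"), find("gdm_status")
    if age_col is None or gdm_col is None:
        raise ValidationError("clinical table must contain age and GDM status columns")
    out = {"age": _to_numeric(raw[age_col], "age")}
    status = raw[gdm_col].astype(str).str.strip().str.lower().map(_GDM_LEVELS)
    if status.isna().any():
        bad = raw[gdm_col][status.isna()].unique().tolist()
        raise ValidationError(f"unrecognized GDM status levels: {bad}")
    out["gdm_status"] = status
    n_markers = 0
    for canonical in MARKER_COLUMNS:
        col = find(canonical)
        if col is not None:
            out[canonical] = _to_numeric(raw[col], canonical)
            n_markers += 1
    if n_markers == 0:
        raise ValidationError("clinical table contains no recognized marker column")
    return ClinicalTable(data=pd.DataFrame(out, index=raw.index))


# ---------------------------------------------------------------------------
# writers

def _display(x) -> str:
    if pd.isna(x):
        return ""
    return f"{float(x):.3g}"


def write_peak_table(table: PeakTable, path) -> None:
    table.data.rename_axis("sample_id").to_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")


def write_results(results: ResultTable, path) -> None:
    """Write a tidy TSV: full-precision columns plus 3-significant-digit
    display companions for beta, p and p_adj."""
    df = results.data.loc[:, list(ResultTable.COLUMNS)].copy()
    for col in ("beta", "p", "p_adj"):
        df[f"{col}_display"] = df[col].map(_display)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> ResultTable:
    # round_trip parsing: written at 17 significant digits, read bit-exact
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df = df.loc[:, list(ResultTable.COLUMNS)]
    return ResultTable(data=df)


def align_samples(peaks: PeakTable, clinical: ClinicalTable
                  ) -> tuple[PeakTable, ClinicalTable]:
    """Restrict both tables to their sample-ID intersection (peak-table order).

    Counts of dropped samples are logged; order is never assumed equal.
    """
    common = [s for s in peaks.sample_ids if s in set(clinical.sample_ids)]
    d_peaks = peaks.n_samples - len(common)
    d_clin = len(clinical.sample_ids) - len(common)
    if d_peaks or d_clin:
        logger.warning("sample alignment dropped %d peak-table and %d clinical rows",
                       d_peaks, d_clin)
    return (PeakTable(peaks.data.loc[common], peaks.unit, peaks.schema),
            ClinicalTable(clinical.data.loc[common]))
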