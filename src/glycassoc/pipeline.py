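"""End-to-end orchestration: read -> normalize -> traits -> associate ->
adjust -> write, with a JSON run manifest capturing every decision knob."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import run_all_associations, summarize_clinical
from .derived_traits import builtin_panel, compute_panel_traits, load_trait_panel
from .errors import ValidationError
from .multiple_testing import MeffResult, adjust_family
from .preprocess import normalize_total_area, rank_inverse_normal_columns
from .tables_io import (ClinicalTable, DEFAULT_MARKERS, PANEL_IDS, PeakTable,
                        ResultTable, align_samples, builtin_schema,
                        read_clinical_table, read_peak_table, write_results)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths and decision knobs for one pipeline run."""

    peak_paths: dict          # panel_id -> path
    clinical_path: str
    output_dir: str
    trait_panel_paths: dict = field(default_factory=dict)  # optional overrides
    markers: tuple = DEFAULT_MARKERS
    alpha: float = 0.05
    unit: str = "raw_area"    # unit of the input peak tables
    fdr_mode: str = "bh_meff"
    rint_offset: float = 3.0 / 8.0
    logit_epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        unknown = set(self.peak_paths) - set(PANEL_IDS)
        if unknown:
            raise ValidationError(f"unknown panel ids: {sorted(unknown)}")


@dataclass
class AnalysisBundle:
    """Everything one run produces, in memory."""

    results: ResultTable
    meff: MeffResult
    trait_tables: dict
    group_summary: pd.DataFrame
    glycan_matrix: pd.DataFrame


def analyze_cohort(peak_tables: dict[str, PeakTable], clinical: ClinicalTable,
                   markers=DEFAULT_MARKERS, trait_panels: dict | None = None,
                   alpha: float = 0.05, fdr_mode: str = "bh_meff") -> AnalysisBundle:
    """Run the full statistical analysis on in-memory tables.

    Raw-area peak tables are total-area normalized first; percent tables
    pass through unchanged.
    """
    from .association import glycan_variable_frame
    percent_tables, trait_tables = {}, {}
    clin = clinical
    for panel_id, pt in peak_tables.items():
        pct = normalize_total_area(pt) if pt.unit == "raw_area" else pt
        pct, clin = align_samples(pct, clin)
        percent_tables[panel_id] = pct
    for panel_id, pct in percent_tables.items():
        panel = (trait_panels or {}).get(panel_id) or builtin_panel(panel_id, pct.schema)
        trait_tables[panel_id] = compute_panel_traits(pct, panel)

    results = run_all_associations(percent_tables, trait_tables, clin,
                                   markers=list(markers))
    glycans, _ = glycan_variable_frame(percent_tables, trait_tables)
    glycans = glycans.loc[clin.data.index]
    glycans_rint = rank_inverse_normal_columns(glycans)
    adjusted, meff = adjust_family(results, glycans_rint, alpha=alpha,
                                   mode=fdr_mode)
    group_summary = summarize_clinical(clin)
    return AnalysisBundle(results=adjusted, meff=meff, trait_tables=trait_tables,
                          group_summary=group_summary, glycan_matrix=glycans_rint)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> AnalysisBundle:
    """File-based pipeline: reads inputs, runs the analysis, writes the
    output bundle (trait tables, adjusted results, group summary, Meff
    record, manifest) under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    peak_tables = {}
    for panel_id, path in config.peak_paths.items():
        schema = builtin_schema(panel_id)
        peak_tables[panel_id] = read_peak_table(path, schema, unit=config.unit)
    clinical = read_clinical_table(config.clinical_path)
    trait_panels = {
        pid: load_trait_panel(path, builtin_schema(pid))
        for pid, path in config.trait_panel_paths.items()}

    bundle = analyze_cohort(peak_tables, clinical, markers=config.markers,
                            trait_panels=trait_panels, alpha=config.alpha,
                            fdr_mode=config.fdr_mode)

    for panel_id, tt in bundle.trait_tables.items():
        tt.data.rename_axis("sample_id").to_csv(out / f"traits_{panel_id}.tsv",
                                                sep="\t", float_format="%.17g")
    write_results(bundle.results, out / "associations.tsv")
    bundle.group_summary.to_csv(out / "group_summary.tsv", sep="\t", index=False,
                                float_format="%.17g")
    meff = bundle.meff
    manifest = {
        "software": {"name": "glycassoc", "version": __version__},
        "inputs": {
            "peaks": {p: {"path": str(path), "sha256": _sha256(path)}
                      for p, path in config.peak_paths.items()},
            "clinical": {"path": str(config.clinical_path),
                         "sha256": _sha256(config.clinical_path)},
        },
        "decisions": {
            "markers": list(config.markers), "alpha": config.alpha,
            "fdr_mode": config.fdr_mode, "unit": config.unit,
            "rint_offset": config.rint_offset,
            "logit_epsilon": config.logit_epsilon, "seed": config.seed,
        },
        "meff": {"m": meff.m, "M_vars": meff.M_vars,
                 "meff_vars": meff.meff_vars, "meff_tests": meff.meff_tests,
                 "alpha": meff.alpha, "mode": meff.mode},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d tests, Meff=%.1f, outputs in %s",
                meff.m, meff.meff_tests, out)
    return bundle


def significance_stars(p_adj: float) -> str:
    """Figure-caption star bins: * 0.05-0.01, ** 0.01-0.001, *** < 0.001."""
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def make_forest_table(results: ResultTable, threshold: float = 0.05) -> pd.DataFrame:
    """Plot-ready table of significant associations for a forest plot.

    Rows with p_adj < threshold, sorted by predictor then effect size, with
    CI bounds and significance stars.
    """
    df = results.data
    if df["p_adj"].isna().all() and len(df):
        raise ValidationError("results are not adjusted yet")
    keep = df[df["p_adj"] < threshold].copy()
    keep["stars"] = keep["p_adj"].map(significance_stars)
    keep = keep.sort_values(["predictor", "beta"], kind="mergesort")
    cols = ["panel", "trait", "predictor", "n", "beta", "ci_low", "ci_high",
            "p", "p_adj", "stars"]
    return keep.loc[:, cols].reset_index(drop=True)
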