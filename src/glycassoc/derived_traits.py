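"""Derived glycan traits: declarative ratio-of-sums summaries of peak tables.

A derived trait describes a glycosylation feature shared by many structures
(galactosylation G0..G4, sialylation S0..S4, bisecting GlcNAc B, core
fucosylation CF, branching LB/HB, oligomannose HM...) as

    100 * sum(w_i * GP_i, numerator) / sum(w_j * GP_j, denominator)

evaluated on percent-unit peak rows; the denominator symbol TOTAL means the
whole chromatogram (100).  Built-in panels — 16 traits for total plasma
proteins, 9 for IgG, 12 for IgA — are reconstructed from dominant-structure
peak annotations and shipped as editable text files.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError, ValidationError
from .tables_io import PanelSchema, PeakTable

logger = logging.getLogger(__name__)

TOTAL = "TOTAL"

#: Built-in derived-trait panel sizes.
BUILTIN_N_TRAITS = {"plasma": 16, "igg": 9, "iga": 12}


@dataclass(frozen=True)
class TraitDefinition:
    """One derived trait as weighted peak groups: numerator / denominator."""

    trait_id: str
    numerator: tuple[tuple[str, float], ...]
    denominator: tuple[tuple[str, float], ...] | str  # term list or TOTAL

    def __post_init__(self):
        if not self.numerator:
            raise ValidationError(f"trait {self.trait_id!r} has empty numerator")
        terms = list(self.numerator)
        if self.denominator != TOTAL:
            terms += list(self.denominator)
        for peak, w in terms:
            if w <= 0:
                raise ValidationError(
                    f"trait {self.trait_id!r}: non-positive weight on {peak}")

    def validate_against(self, schema: PanelSchema) -> None:
        known = set(schema.peak_ids)
        terms = list(self.numerator)
        if self.denominator != TOTAL:
            terms += list(self.denominator)
        for peak, _ in terms:
            if peak not in known:
                raise SchemaError(
                    f"trait {self.trait_id!r} references unknown peak {peak!r} "
                    f"for panel {schema.panel_id!r}")


@dataclass(frozen=True)
class TraitPanel:
    """Ordered collection of trait definitions for one panel."""

    panel_id: str
    traits: tuple[TraitDefinition, ...]
    provenance: str = "user"

    def __post_init__(self):
        ids = [t.trait_id for t in self.traits]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate trait ids in panel {self.panel_id!r}")

    @property
    def trait_ids(self) -> list[str]:
        return [t.trait_id for t in self.traits]


@dataclass
class TraitTable:
    """Samples x derived-traits matrix (percent-of-denominator units)."""

    data: pd.DataFrame
    panel: TraitPanel

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# grammar:  TRAIT_ID = (GP1 + 2*GP2 + ...) / (GP3 + ... | TOTAL)

_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\s*\*\s*)?(\w+)$")


def _parse_terms(text: str, lineno: int):
    terms = []
    for part in text.split("+"):
        m = _TERM.match(part.strip())
        if not m:
            raise ValidationError(f"line {lineno}: cannot parse term {part.strip()!r}")
        weight = float(m.group(1)) if m.group(1) else 1.0
        terms.append((m.group(2), weight))
    return tuple(terms)


def parse_trait_line(line: str, lineno: int = 0) -> TraitDefinition:
    lhs, _, rhs = line.partition("=")
    trait_id = lhs.strip()
    if not trait_id or not rhs.strip():
        raise ValidationError(f"line {lineno}: expected 'TRAIT = (...) / (...)'")
    num_txt, _, den_txt = rhs.partition("/")
    num_txt = num_txt.strip().strip("()")
    den_txt = den_txt.strip()
    if not den_txt:
        raise ValidationError(f"line {lineno}: missing denominator")
    numerator = _parse_terms(num_txt, lineno)
    if den_txt == TOTAL:
        denominator = TOTAL
    else:
        denominator = _parse_terms(den_txt.strip("()"), lineno)
    return TraitDefinition(trait_id, numerator, denominator)


def serialize_panel(panel: TraitPanel) -> str:
    lines = []
    for t in panel.traits:
        def side(terms):
            return " + ".join(p if w == 1 else f"{w:g}*{p}" for p, w in terms)
        den = TOTAL if t.denominator == TOTAL else f"({side(t.denominator)})"
        lines.append(f"{t.trait_id} = ({side(t.numerator)}) / {den}")
    return "\n".join(lines) + "\n"


def _parse_panel_text(text: str, panel_id: str, schema: PanelSchema,
                      provenance: str) -> TraitPanel:
    traits = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        defn = parse_trait_line(line, lineno)
        defn.validate_against(schema)
        traits.append(defn)
    if not traits:
        raise ValidationError("trait panel file defines no traits")
    return TraitPanel(panel_id=panel_id, traits=tuple(traits), provenance=provenance)


def load_trait_panel(path, schema: PanelSchema) -> TraitPanel:
    """Parse a trait-definition file and validate every peak reference."""
    with open(path) as fh:
        text = fh.read()
    return _parse_panel_text(text, schema.panel_id, schema, provenance=str(path))


def builtin_panel(panel_id: str, schema: PanelSchema | None = None) -> TraitPanel:
    """The reconstructed built-in trait panel for ``panel_id``."""
    from .tables_io import builtin_schema
    if schema is None:
        schema = builtin_schema(panel_id)
    text = resources.files("glycassoc.data").joinpath(f"{panel_id}_traits.txt").read_text()
    return _parse_panel_text(text, panel_id, schema,
                             provenance="built-in (reconstructed)")


# ---------------------------------------------------------------------------
# evaluation

def evaluate_trait(defn: TraitDefinition, row: pd.Series) -> float:
    """Evaluate one trait on one percent-unit peak row."""
    num = sum(w * row[p] for p, w in defn.numerator)
    if defn.denominator == TOTAL:
        den = 100.0
    else:
        den = sum(w * row[p] for p, w in defn.denominator)
    if den == 0:
        raise DegenerateDataError(
            f"zero denominator for trait {defn.trait_id!r}")
    return 100.0 * num / den


def compute_panel_traits(peaks: PeakTable, panel: TraitPanel) -> TraitTable:
    """Evaluate every panel trait on every sample (vectorized over samples).

    Samples with a zero trait denominator get a missing value and a logged
    warning rather than aborting the run.
    """
    if peaks.unit != "percent":
        raise ValidationError("traits are computed on percent-unit peak tables")
    for defn in panel.traits:
        defn.validate_against(peaks.schema)
    vals = peaks.data
    cols = {}
    for defn in panel.traits:
        num = sum(w * vals[p].to_numpy(dtype=float) for p, w in defn.numerator)
        if defn.denominator == TOTAL:
            den = np.full(len(vals), 100.0)
        else:
            den = sum(w * vals[p].to_numpy(dtype=float) for p, w in defn.denominator)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den == 0, np.nan, 100.0 * num / den)
        if np.isnan(out).any():
            logger.warning("trait %r degenerate (zero denominator) for %d sample(s)",
                           defn.trait_id, int(np.isnan(out).sum()))
        cols[defn.trait_id] = out
    data = pd.DataFrame(cols, index=vals.index)
    return TraitTable(data=data, panel=panel)
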