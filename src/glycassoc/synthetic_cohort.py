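"""Fully synthetic paired glycomics/clinical cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* compositional glycan peak vectors — per panel, peak log-weights are a
  fixed baseline plus a low-rank latent-factor term (which induces the
  correlated trait structure the Li-Ji correction exists for) plus noise,
  pushed through a softmax and scaled by a random positive total area;
* metabolic markers — each sample carries latent standard-normal marker
  scores (sharing a metabolic factor, with HOMA2 indices derived as noisy
  monotone functions of the insulin and glucose scores) that are mapped
  monotonically onto the marker's target median/IQR, so group descriptives
  mimic a pregnancy GDM-screening cohort (48 controls / 41 cases by
  default);
* a configurable effect matrix B linking marker scores to glycan latent
  factors, recording exactly which glycan variables truly associate with
  which markers;
* an age covariate and a case/control difference expressed through
  group-specific marker targets (or a latent shift).

Everything is deterministic under a fixed seed via a spawned-stream scheme,
so stages can be re-run independently yet reproducibly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import (ClinicalTable, MARKER_COLUMNS, PANEL_IDS, PeakTable,
                        builtin_schema)

#: Markers addressable by the effect matrix B (columns, in this order).
EFFECT_MARKERS = ("fasting_glucose", "hba1c_mmol_mol", "fasting_insulin",
                  "homa2_ir", "homa2_pct_b", "total_cholesterol",
                  "triglycerides")

#: Default per-group marker (Q1, median, Q3) targets: a GDM-screening cohort
#: at 24-28 weeks of gestation (glucose mmol/L, insulin pmol/L, lipids
#: mmol/L, enzymes U/L, urate/fructosamine umol/L, proteins g/L).
MARKER_TARGETS = {
    "fasting_glucose":   {"control": (4.5, 4.7, 4.9),      "case": (4.9, 5.1, 5.2)},
    "hba1c_mmol_mol":    {"control": (27, 29, 32),         "case": (29, 31, 33)},
    "hba1c_pct":         {"control": (4.7, 4.8, 5.1),      "case": (4.8, 5.0, 5.2)},
    "fasting_insulin":   {"control": (34.0, 43.5, 61.3),   "case": (44.3, 60.9, 78.5)},
    "homa2_ir":          {"control": (0.721, 0.925, 1.293), "case": (1.000, 1.282, 1.689)},
    "homa2_pct_b":       {"control": (88.5, 107.7, 132.4), "case": (92.5, 115.5, 136.1)},
    "triglycerides":     {"control": (1.22, 1.66, 2.06),   "case": (1.60, 2.12, 2.61)},
    "hdl":               {"control": (1.500, 1.785, 2.055), "case": (1.500, 1.620, 1.850)},
    "total_cholesterol": {"control": (5.59, 6.52, 7.73),   "case": (5.54, 6.45, 7.22)},
    "total_proteins":    {"control": (62, 64, 67),         "case": (63, 65, 67)},
    "urate":             {"control": (180, 201, 240),      "case": (168, 199, 259)},
    "alt":               {"control": (8.0, 11.5, 16.0),    "case": (7.0, 10.0, 12.0)},
    "ast":               {"control": (17.0, 22.5, 26.3),   "case": (16.0, 18.0, 22.0)},
    "ggt":               {"control": (8.0, 9.5, 13.0),     "case": (7.0, 8.0, 10.0)},
    "fructosamine":      {"control": (179.8, 184.0, 195.5), "case": (175.0, 187.0, 198.0)},
}

#: Loading of each marker's latent score on the shared metabolic factor.
_METABOLIC_LOADING = {
    "fasting_glucose": 0.55, "fasting_insulin": 0.60, "hba1c_mmol_mol": 0.45,
    "hba1c_pct": 0.45, "triglycerides": 0.40, "total_cholesterol": 0.30,
    "hdl": -0.30,
}
_DEFAULT_LOADING = 0.25

_Z75 = 0.6744897501960817  # Phi^-1(0.75)


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_control: int = 48
    n_case: int = 41
    seed: int = 0
    latent_dim: int = 4
    #: (latent_dim x len(EFFECT_MARKERS)) matrix; zero = global null.
    effect: np.ndarray | None = None
    #: optional per-marker latent shift for cases; None = use per-group targets
    case_shift: dict | None = None
    #: per-latent-dim direct GDM shift on glycan factors (cases only)
    gdm_glycan_shift: np.ndarray | None = None
    age_range: tuple = (27.0, 38.0)
    marker_base: dict = field(default_factory=lambda: {
        m: t["control"] for m, t in MARKER_TARGETS.items()})
    marker_case: dict = field(default_factory=lambda: {
        m: t["case"] for m, t in MARKER_TARGETS.items()})
    composition_noise_sd: float = 0.4
    total_area_mean: float = 1e5

    def __post_init__(self):
        if self.n_control < 2 or self.n_case < 2:
            raise ValidationError("need at least 2 samples per group")
        if self.composition_noise_sd <= 0:
            raise ValidationError("composition_noise_sd must be positive")
        if self.effect is None:
            self.effect = np.zeros((self.latent_dim, len(EFFECT_MARKERS)))
        self.effect = np.asarray(self.effect, dtype=float)
        if self.effect.shape != (self.latent_dim, len(EFFECT_MARKERS)):
            raise ValidationError(
                f"effect matrix must be {self.latent_dim} x {len(EFFECT_MARKERS)}")
        if self.gdm_glycan_shift is None:
            self.gdm_glycan_shift = np.zeros(self.latent_dim)
        self.gdm_glycan_shift = np.asarray(self.gdm_glycan_shift, dtype=float)
        if self.gdm_glycan_shift.shape != (self.latent_dim,):
            raise ValidationError("gdm_glycan_shift must have latent_dim entries")
        for m, (q1, med, q3) in self.marker_base.items():
            if not (0 < q1 < med < q3):
                raise ValidationError(f"marker_base for {m!r} must satisfy 0<Q1<med<Q3")


def _quantile_map(u: np.ndarray, targets) -> np.ndarray:
    """Monotone map from standard-normal scores to a (Q1, med, Q3) target.

    Two-sided log-linear interpolation: hits the median exactly and both
    quartiles in distribution; strictly increasing in u.
    """
    q1, med, q3 = targets
    up = np.log(q3 / med) / _Z75
    dn = np.log(med / q1) / _Z75
    return med * np.exp(np.where(u >= 0, up * u, dn * u))


def _panel_structure(panel_id: str, n_peaks: int, latent_dim: int):
    """Fixed (cohort-independent) baseline abundances and latent loadings."""
    panel_seed = {"plasma": 1039, "igg": 1024, "iga": 1030}[panel_id]
    rng = np.random.default_rng(panel_seed)
    baseline = rng.normal(0.0, 1.2, size=n_peaks)
    loadings = rng.normal(0.0, 0.35, size=(n_peaks, latent_dim))
    return baseline, loadings


def generate_cohort(config: SynthConfig):
    """Generate (peak tables by panel, clinical table, ground-truth record).

    Raw-area peak tables are strictly positive; normalize_total_area turns
    them into the percent tables the pipeline expects.  Bit-identical under
    a fixed seed.
    """
    n = config.n_control + config.n_case
    status = np.array(["control"] * config.n_control + ["case"] * config.n_case)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in
               zip(("age", "markers", "glycans", "totals"), ss.spawn(4))}

    rng = streams["age"]
    age = rng.uniform(*config.age_range, size=n).round(1)

    # latent marker scores: shared metabolic factor + marker noise
    rng = streams["markers"]
    z_met = rng.normal(size=n)
    u = {}
    for m in MARKER_COLUMNS:
        if m in ("homa2_ir", "homa2_pct_b"):
            continue
        rho = _METABOLIC_LOADING.get(m, _DEFAULT_LOADING)
        u[m] = rho * z_met + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
    # HOMA2 indices: noisy monotone functions of insulin and glucose scores
    e = rng.normal(size=(2, n))
    u["homa2_ir"] = (0.75 * u["fasting_insulin"] + 0.50 * u["fasting_glucose"]
                     + 0.35 * e[0]) / np.sqrt(0.75**2 + 0.50**2 + 0.35**2)
    u["homa2_pct_b"] = (0.75 * u["fasting_insulin"] - 0.45 * u["fasting_glucose"]
                        + 0.40 * e[1]) / np.sqrt(0.75**2 + 0.45**2 + 0.40**2)
    # HbA1c in % tracks HbA1c in mmol/mol by construction
    u["hba1c_pct"] = u["hba1c_mmol_mol"]

    case = status == "case"
    markers = {}
    for m in MARKER_COLUMNS:
        score = u[m].copy()
        if config.case_shift is not None:
            score[case] += config.case_shift.get(m, 0.0)
            markers[m] = _quantile_map(score, config.marker_base[m])
        else:
            vals = _quantile_map(score, config.marker_base[m])
            vals[case] = _quantile_map(score[case], config.marker_case[m])
            markers[m] = vals

    clinical = ClinicalTable(data=pd.DataFrame(
        {"age": age, "gdm_status": status, **{m: markers[m] for m in MARKER_COLUMNS}},
        index=pd.Index(sample_ids, name="sample_id")))

    # glycan latent factors driven by marker scores through B
    u_mat = np.column_stack([u[m] for m in EFFECT_MARKERS])  # (n, 7)
    rng = streams["glycans"]
    g = u_mat @ config.effect.T + rng.normal(size=(n, config.latent_dim))
    g[case] += config.gdm_glycan_shift

    peak_tables = {}
    loadings_by_panel = {}
    rng_tot = streams["totals"]
    for panel_id in PANEL_IDS:
        schema = builtin_schema(panel_id)
        baseline, lam = _panel_structure(panel_id, schema.n_peaks, config.latent_dim)
        loadings_by_panel[panel_id] = lam
        logw = baseline + g @ lam.T + rng.normal(
            0.0, config.composition_noise_sd, size=(n, schema.n_peaks))
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        props = w / w.sum(axis=1, keepdims=True)
        totals = config.total_area_mean * np.exp(rng_tot.normal(0.0, 0.2, size=n))
        data = pd.DataFrame(props * totals[:, None],
                            index=pd.Index(sample_ids, name="sample_id"),
                            columns=list(schema.peak_ids))
        peak_tables[panel_id] = PeakTable(data=data, unit="raw_area", schema=schema)

    ground_truth = {
        "effect": config.effect.copy(),
        "effect_markers": list(EFFECT_MARKERS),
        "loadings": loadings_by_panel,
        "gdm_glycan_shift": config.gdm_glycan_shift.copy(),
        "true_marker_latents": {
            EFFECT_MARKERS[j]: [k for k in range(config.latent_dim)
                                if config.effect[k, j] != 0]
            for j in range(len(EFFECT_MARKERS))},
    }
    return peak_tables, clinical, ground_truth


def top_loaded_peak(ground_truth, panel_id: str, latent: int) -> tuple[str, float]:
    """Peak most strongly loaded on a latent factor, and its loading sign."""
    lam = ground_truth["loadings"][panel_id][:, latent]
    i = int(np.argmax(np.abs(lam)))
    return f"GP{i + 1}", float(np.sign(lam[i]))


def recover_effects(config: SynthConfig, n_replicates: int = 20,
                    alpha: float = 0.05):
    """Run the full pipeline on replicate cohorts and score effect recovery.

    For every nonzero entry B[k, j], the plasma peak most loaded on latent k
    should associate with marker j with sign sign(B[k, j] * loading); the
    report gives the sign-match rate across replicates and the count of
    FDR discoveries among true-null tests.  Because the markers are
    mutually correlated (shared metabolic factor, HOMA2 derivations), a
    nonzero B makes most marker tests non-null; the guaranteed-null subset
    is the GDM contrast (glycan factors are independent of group given the
    marker scores), extended to every test when B is all zero.
    """
    from .association import GDM_PREDICTOR
    from .pipeline import analyze_cohort
    sign_checks, null_discoveries, total_null = [], 0, 0
    truly = {(EFFECT_MARKERS[j], k)
             for k in range(config.latent_dim)
             for j in range(len(EFFECT_MARKERS)) if config.effect[k, j] != 0}
    all_null = not truly and not config.gdm_glycan_shift.any()
    for rep in range(n_replicates):
        cfg_rep = SynthConfig(**{**config.__dict__,
                                 "seed": (config.seed + 1009 * rep) % (2**31),
                                 "effect": config.effect})
        peaks, clinical, truth = generate_cohort(cfg_rep)
        bundle = analyze_cohort(peaks, clinical, alpha=alpha)
        res = bundle.results.data
        for marker, k in truly:
            peak, lsign = top_loaded_peak(truth, "plasma", k)
            row = res[(res.panel == "plasma") & (res.trait == peak)
                      & (res.predictor == marker)].iloc[0]
            j = EFFECT_MARKERS.index(marker)
            expected = np.sign(config.effect[k, j]) * lsign
            sign_checks.append(np.sign(row.beta) == expected)
        if all_null:
            null_mask = np.ones(len(res), dtype=bool)
        elif config.case_shift is None:
            # per-group target mapping: latent scores are group-invariant,
            # so the GDM contrast on glycans stays null even with B != 0
            null_mask = (res.predictor == GDM_PREDICTOR).to_numpy()
        else:
            null_mask = np.zeros(len(res), dtype=bool)
        null_discoveries += int((res.loc[null_mask, "p_adj"] < alpha).sum())
        total_null += int(null_mask.sum())
    return {
        "n_replicates": n_replicates,
        "sign_match_rate": float(np.mean(sign_checks)) if sign_checks else float("nan"),
        "null_discoveries": null_discoveries,
        "n_null_tests": total_null,
    }


def ci_coverage_simulation(true_beta: float = 0.5, n: int = 200,
                           n_replicates: int = 500, seed: int = 0):
    """Coverage of the 95% Wald CI for a known standardized effect.

    Trait and marker are bivariate normal with standardized slope
    ``true_beta`` (age independent), so the truth on the doubly rank-INT
    scale is analytic; the compositional generator has no closed-form true
    slope after the softmax, hence this direct design.
    """
    from .association import fit_marker_association
    rng = np.random.default_rng(seed)
    covered, signs = 0, 0
    for _ in range(n_replicates):
        marker = rng.normal(size=n)
        trait = true_beta * marker + np.sqrt(1 - true_beta**2) * rng.normal(size=n)
        age = rng.uniform(27, 38, size=n)
        r = fit_marker_association(trait, marker, age)
        covered += int(r.ci_low <= true_beta <= r.ci_high)
        signs += int(np.sign(r.beta) == np.sign(true_beta))
    return {"coverage": covered / n_replicates,
            "sign_match_rate": signs / n_replicates,
            "n": n, "n_replicates": n_replicates}
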