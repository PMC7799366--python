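"""Synthetic cohorts of ex vivo tumor immunoassay measurements.

The study's raw cohort is not publicly deposited, so the pipeline is
exercised on simulated cohorts that reproduce the statistical structure the
analysis assumes: per-analyte lognormal baseline secretion, multiplicative
stimulation effects, latent responder / non-responder / hypo-responder
classes, assay quantification limits (LLOQ/ULOQ censoring), sporadic
missingness, and a survival table whose hazard depends log-linearly on one
designated prognostic analyte.  Ground-truth labels are returned alongside
the measurements so parameter-recovery tests can grade every downstream
stage.

Generative model, per tumor t, condition c, analyte a::

    conc[t, c, a] = baseline[t, a] * effect[t, c, a] * noise[t, c, a]

with ``baseline`` lognormal, ``effect`` the designed multiplicative
condition effect (1 for medium and the isotype control), and ``noise``
mean-1 lognormal with coefficient of variation ``measurement_cv``.
Responders carry induction effects (>= 2-fold in expectation) on at least
seven of the TCR-inducible analytes under PD-1 blockade; hypo-responders
carry suppression effects (< 0.1) on at least six analytes, with the
suppression depth tied to the tumor's CCR5+CTLA4+ Treg fraction through a
logistic link.  Combination conditions add a rescue boost on a
tumor-specific analyte subset for tumors drawn to be rescuable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

#: Bio-Plex Pro human 27-plex cytokine panel (standard analyte names).
PANEL_27 = [
    "IL-1b", "IL-1ra", "IL-2", "IL-4", "IL-5", "IL-6", "IL-7", "IL-8",
    "IL-9", "IL-10", "IL-12p70", "IL-13", "IL-15", "IL-17A", "Eotaxin",
    "FGF-basic", "G-CSF", "GM-CSF", "IFN-g", "CXCL10", "MCP-1", "MIP-1a",
    "MIP-1b", "PDGF-BB", "RANTES", "TNF-a", "VEGF",
]

#: Default TCR-inducible subset (a configurable convention, not a measured
#: fact: T-cell effector cytokines and chemokines plausibly induced by
#: TCR cross-linking).  17 of the 27 analytes.
DEFAULT_INDUCIBLE = [
    "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6", "IL-8", "IL-9", "IL-10",
    "IL-13", "IL-17A", "G-CSF", "GM-CSF", "IFN-g", "CXCL10", "MIP-1a",
    "MIP-1b", "TNF-a",
]

MEDIUM = "medium"
ISOTYPE = "isotype"
TCR_CONDITION = "aCD3_aCD28"
ANTI_PD1 = "aPD1"
COMBINATIONS = ["aPD1_aCTLA4", "aPD1_aCD73", "aPD1_aGITR", "aPD1_TLR4ag", "aPD1_rIL2"]
DEFAULT_CONDITIONS = [MEDIUM, ISOTYPE, TCR_CONDITION, ANTI_PD1] + COMBINATIONS

CLASSES = ("responder", "non_responder", "hypo_responder")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults mirror the study conditions: 42 tumors, the 27-plex panel with
    17 TCR-inducible analytes, a 17% responder fraction, measurement noise
    at 20% CV, and Luminex-like quantification limits.
    """

    n_tumors: int = 42
    histotype_weights: dict = field(
        default_factory=lambda: {"L": 0.45, "K": 0.20, "HN": 0.15, "O": 0.10, "B": 0.10}
    )
    analyte_names: list = field(default_factory=lambda: list(PANEL_27))
    n_tcr_inducible: int = 17
    inducible_analytes: list = field(default_factory=lambda: list(DEFAULT_INDUCIBLE))
    responder_fraction: float = 0.17
    hypo_responder_fraction: float = 0.14
    rescue_fraction: float = 0.5
    conditions: list = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    baseline_log_mean: dict = field(default_factory=dict)
    baseline_log_sd: float = 1.0
    induction_effect_log_mean: float = float(np.log(3.0))
    induction_effect_log_sd: float = 0.45
    min_induction_effect: float = 2.0
    suppression_floor: float = 0.05
    background_suppression_rate: float = 0.18
    measurement_cv: float = 0.2
    lloq: float = 2.0
    uloq: float = 50000.0
    missing_rate: float = 0.02
    prognostic_analyte: str = "CXCL10"
    survival_n_patients: int = 90
    survival_log_hazard_slope: float = -0.8
    seed: int = 0

    def __post_init__(self):
        if not self.baseline_log_mean:
            # heterogeneous abundances: chemokines high, growth factors low
            self.baseline_log_mean = {
                a: 3.0 + 0.8 * (i % 5) for i, a in enumerate(self.analyte_names)
            }

    def validate(self) -> None:
        if self.n_tumors <= 0:
            raise ConfigurationError("n_tumors must be positive")
        for name in ("responder_fraction", "hypo_responder_fraction",
                     "rescue_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.responder_fraction + self.hypo_responder_fraction > 1.0:
            raise ConfigurationError(
                "responder_fraction + hypo_responder_fraction exceeds 1"
            )
        if abs(sum(self.histotype_weights.values()) - 1.0) > 1e-9:
            raise ConfigurationError("histotype_weights must sum to 1")
        if any(w < 0 for w in self.histotype_weights.values()):
            raise ConfigurationError("histotype_weights must be nonnegative")
        if not 0 <= self.n_tcr_inducible <= len(self.analyte_names):
            raise ConfigurationError(
                "n_tcr_inducible must be between 0 and the number of analytes"
            )
        if len(self.inducible_analytes) != self.n_tcr_inducible:
            raise ConfigurationError(
                "inducible_analytes length must equal n_tcr_inducible"
            )
        if not set(self.inducible_analytes) <= set(self.analyte_names):
            raise ConfigurationError("inducible_analytes must be a subset of analyte_names")
        if not self.lloq < self.uloq:
            raise ConfigurationError("lloq must be smaller than uloq")
        if not 0 < self.suppression_floor < 0.1:
            raise ConfigurationError("suppression_floor must be in (0, 0.1)")
        if not 0.0 <= self.background_suppression_rate <= 1.0:
            raise ConfigurationError("background_suppression_rate must be in [0, 1]")
        if self.measurement_cv < 0:
            raise ConfigurationError("measurement_cv must be nonnegative")
        if MEDIUM not in self.conditions:
            raise ConfigurationError("conditions must include the medium control")
        if self.prognostic_analyte not in self.analyte_names:
            raise ConfigurationError("prognostic_analyte must be one of analyte_names")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


def default_config(**overrides) -> GeneratorConfig:
    """A validated default configuration; keyword overrides applied first."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def apply_censoring(true_conc, lloq: float, uloq: float):
    """Clamp a true concentration into the assay quantification range.

    Returns ``(reported, flag)`` with flag in {in_range, below_lloq,
    above_uloq}.  Accepts scalars or arrays.
    """
    if not lloq < uloq:
        raise ConfigurationError("lloq must be smaller than uloq")
    arr = np.asarray(true_conc, dtype=float)
    if np.any(arr < 0):
        raise DomainError("negative true concentration")
    reported = np.clip(arr, lloq, uloq)
    flag = np.where(arr < lloq, "below_lloq", np.where(arr > uloq, "above_uloq", "in_range"))
    if np.isscalar(true_conc) or arr.ndim == 0:
        return float(reported), str(flag)
    return reported, flag


def _noise(rng, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _subset_size(rng, n_inducible: int) -> int:
    """Number of responsive analytes for a responsive profile: 9..n when the
    inducible panel allows it (comfortably past the 7-positive classification
    bar), else the whole panel."""
    if n_inducible <= 9:
        return n_inducible
    return int(rng.integers(9, n_inducible + 1))


def _designed_effects(cfg: GeneratorConfig, rng, responder_class: str,
                      rescuing: list[str]) -> tuple[pd.DataFrame, dict]:
    """Draw the multiplicative condition effects for one tumor.

    Returns (conditions x analytes effect matrix, info dict with the Treg
    fraction and the responsive / suppressed analyte subsets).
    """
    analytes = cfg.analyte_names
    eff = pd.DataFrame(1.0, index=cfg.conditions, columns=analytes)
    inducible = list(cfg.inducible_analytes)

    def induction(k):
        draw = rng.lognormal(cfg.induction_effect_log_mean, cfg.induction_effect_log_sd, k)
        return np.maximum(draw, cfg.min_induction_effect)

    # TCR cross-linking induces every inducible analyte in every tumor
    if TCR_CONDITION in cfg.conditions and inducible:
        eff.loc[TCR_CONDITION, inducible] = induction(len(inducible))

    info = {"responsive_analytes": [], "suppressed_analytes": []}

    # CCR5+CTLA4+ Treg fraction: high in hypo-responders, low elsewhere
    if responder_class == "hypo_responder":
        treg = float(rng.beta(6, 18))       # mean 0.25
    else:
        treg = float(rng.beta(2, 38))       # mean 0.05
    info["treg_ccr5_ctla4_frac"] = treg

    pd1_like = [c for c in cfg.conditions if c == ANTI_PD1 or c.startswith(ANTI_PD1 + "_")]

    responsive: list[str] = []
    if responder_class == "responder" and inducible:
        # a reactive TME re-engages the whole TCR-dependent program: a
        # strong subset (>= 9 analytes, comfortably past the 7-positive
        # bar) plus a milder lift on the remaining inducible analytes
        k = _subset_size(rng, len(inducible))
        responsive = list(rng.choice(inducible, size=k, replace=False))
        info["responsive_analytes"] = sorted(responsive)
        rest = [a for a in analytes if a not in responsive]
        effects = induction(len(responsive))
        mild = np.exp(rng.uniform(np.log(1.1), np.log(1.8), size=len(rest)))
        for c in pd1_like:
            eff.loc[c, responsive] = effects
            if rest:
                eff.loc[c, rest] = mild

    # PD-1 engagement shuts down constitutive secretion of scattered
    # analytes in most tumors (the cohort-median hypo-responsive count is
    # nonzero); hypo-responders carry a dedicated, Treg-linked block on top.
    suppressed: set = set()
    bg_rate = 0.0 if responder_class == "responder" else cfg.background_suppression_rate
    bg_pool = [a for a in analytes if a not in responsive]
    bg_mask = rng.random(len(bg_pool)) < bg_rate
    suppressed.update(a for a, hit in zip(bg_pool, bg_mask) if hit)
    if responder_class == "hypo_responder":
        m_hi = max(10, min(14, len(analytes) + 1))
        m = int(rng.integers(min(9, len(analytes)), m_hi))
        block = rng.choice(analytes, size=min(m, len(analytes)), replace=False)
        suppressed.update(block)
    if suppressed:
        sub = sorted(suppressed)
        info["suppressed_analytes"] = sub
        if responder_class == "hypo_responder":
            # deeper suppression for higher Treg fractions (logistic link)
            s = _logistic(20.0 * (treg - 0.12))
            depth = cfg.suppression_floor ** s * 0.099 ** (1.0 - s)
        else:
            depth = float(np.exp(rng.uniform(np.log(cfg.suppression_floor), np.log(0.099))))
        jitter = np.exp(rng.normal(0.0, 0.1, size=len(sub)))
        for c in pd1_like:
            eff.loc[c, sub] = np.minimum(depth * jitter, 0.099)

    # rescue boost on combination conditions for rescuable tumors
    if rescuing and inducible:
        k = _subset_size(rng, len(inducible))
        subset = list(rng.choice(inducible, size=k, replace=False))
        effects = induction(len(subset))
        for c in rescuing:
            eff.loc[c, subset] = np.maximum(eff.loc[c, subset].to_numpy(), effects)
    return eff, info


def generate_cohort(config: GeneratorConfig):
    """Generate one synthetic cohort.

    Returns ``(concentrations, metadata, truth, phenotype, survival)`` as
    pandas DataFrames in the long layouts the I/O layer validates.  The
    class counts are deterministic (``round(fraction * n_tumors)``) so a
    fraction of 7/42 yields exactly seven responders; which tumors carry
    which class is randomized.  Identical (config, seed) pairs produce
    bit-identical tables: one root seed sequence is split up front into one
    stream per tumor plus cohort-level and survival streams, so per-tumor
    draws are independent of generation order.
    """
    config.validate()
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_tumors + 2)
    cohort_rng = np.random.default_rng(children[0])
    survival_rng = np.random.default_rng(children[1])
    tumor_rngs = [np.random.default_rng(c) for c in children[2:]]

    n = cfg.n_tumors
    n_resp = int(round(cfg.responder_fraction * n))
    n_hypo = int(round(cfg.hypo_responder_fraction * n))
    n_hypo = min(n_hypo, n - n_resp)
    classes = np.array(
        ["responder"] * n_resp + ["hypo_responder"] * n_hypo
        + ["non_responder"] * (n - n_resp - n_hypo)
    )
    cohort_rng.shuffle(classes)

    hist_names = list(cfg.histotype_weights)
    hist_p = np.array([cfg.histotype_weights[h] for h in hist_names], dtype=float)
    histotypes = cohort_rng.choice(hist_names, size=n, p=hist_p / hist_p.sum())

    combos = [c for c in cfg.conditions if c.startswith(ANTI_PD1 + "_")]
    tumor_ids = [f"T{i + 1:03d}" for i in range(n)]

    conc_rows, meta_rows, truth_rows, pheno_rows = [], [], [], []
    analytes = cfg.analyte_names
    n_a = len(analytes)

    for i, tumor in enumerate(tumor_ids):
        rng = tumor_rngs[i]
        cls = classes[i]

        rescuing: list[str] = []
        if cls != "responder" and combos and rng.random() < cfg.rescue_fraction:
            k = int(rng.integers(1, min(3, len(combos)) + 1))
            rescuing = sorted(rng.choice(combos, size=k, replace=False))

        baseline = np.array(
            [rng.lognormal(cfg.baseline_log_mean[a], cfg.baseline_log_sd) for a in analytes]
        )
        eff, info = _designed_effects(cfg, rng, cls, rescuing)

        for cond in cfg.conditions:
            noise = _noise(rng, cfg.measurement_cv, n_a)
            true_conc = baseline * eff.loc[cond].to_numpy() * noise
            reported, flags = apply_censoring(true_conc, cfg.lloq, cfg.uloq)
            reported = np.asarray(reported, dtype=float)
            flags = np.asarray(flags, dtype=object)
            missing = rng.random(n_a) < cfg.missing_rate
            reported[missing] = np.nan
            flags[missing] = "missing"
            for j, a in enumerate(analytes):
                conc_rows.append((tumor, cond, a, reported[j], flags[j]))

        meta_rows.append(
            {
                "tumor_id": tumor,
                "histotype": histotypes[i],
                "cd45_viable_pct": float(np.clip(rng.lognormal(np.log(5.0), 0.9), 0.25, 80.0)),
                "total_cells": int(rng.lognormal(np.log(8e6), 0.7)) + 1_100_000,
                "supernatant_total_protein": float(rng.lognormal(np.log(1.5), 0.3)),
                "provenance": "fresh",
            }
        )
        truth_rows.append(
            {
                "tumor_id": tumor,
                "responder_class": cls,
                "inducible_analytes": "|".join(cfg.inducible_analytes),
                "responsive_analytes": "|".join(info["responsive_analytes"]),
                "suppressed_analytes": "|".join(info["suppressed_analytes"]),
                "rescuing_conditions": "|".join(rescuing),
                "treg_ccr5_ctla4_frac": info["treg_ccr5_ctla4_frac"],
            }
        )
        # summary-level flow features; occasional low-event acquisitions
        treg = info["treg_ccr5_ctla4_frac"]
        ifn_pos = float(np.clip(
            rng.normal(18.0 if cls == "responder" else 6.0, 3.0), 0.1, 95.0))
        pheno_rows.extend(
            [
                {
                    "tumor_id": tumor, "subset": "Treg", "marker": "CCR5+CTLA4+",
                    "value": 100.0 * treg,
                    "n_events": int(rng.integers(300, 5000)),
                },
                {
                    "tumor_id": tumor, "subset": "CD8 T", "marker": "IFN-g+",
                    "value": ifn_pos,
                    "n_events": int(rng.integers(300, 5000)),
                },
                {
                    "tumor_id": tumor, "subset": "CD8 T", "marker": "CD107a+",
                    "value": float(np.clip(rng.normal(10.0, 4.0), 0.1, 95.0)),
                    "n_events": int(rng.integers(300, 5000)),
                },
            ]
        )

    concentrations = pd.DataFrame(
        conc_rows,
        columns=["tumor_id", "condition", "analyte", "concentration", "censor_flag"],
    )
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    phenotype = pd.DataFrame(pheno_rows)
    survival = _generate_survival(cfg, survival_rng)
    return concentrations, metadata, truth, phenotype, survival


def _generate_survival(cfg: GeneratorConfig, rng) -> pd.DataFrame:
    """Progression-free survival cohort with a log-linear biomarker hazard.

    The biomarker is the (standardized log) expression of the designated
    prognostic analyte; the hazard is ``h0 * exp(slope * z)`` with a
    12-month baseline median PFS and administrative censoring uniform on
    6-36 months.
    """
    n = cfg.survival_n_patients
    z = rng.normal(0.0, 1.0, size=n)
    h0 = np.log(2.0) / 12.0
    t_event = rng.exponential(1.0 / (h0 * np.exp(cfg.survival_log_hazard_slope * z)))
    t_cens = rng.uniform(6.0, 36.0, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "time": np.maximum(time, 1e-3),
            "event": event,
            "biomarker": z,
            "cohort": "synthetic",
        }
    )
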