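"""Synthetic cohort generation for castration-resistant prostate cancer outcome analysis.

This module simulates a one-year post-marketing-surveillance-style cohort of
docetaxel-refractory CRPC patients treated with cabazitaxel: baseline
characteristics, treatment exposure (dose, relative dose intensity, cycle
count), haematological adverse events, and right-censored survival outcomes
(overall survival and time-to-treatment-failure, both administratively
censored at 365 days).  The generative model has a *known* dependency
structure — a planted graph of signed effects — so that downstream network
inference can be scored for edge recovery (precision, recall, sign accuracy).

Outcome times follow Weibull proportional-hazards models; adverse events
follow logistic models driven by treatment exposure; a small random
early-dropout process adds within-year censoring on top of the 365-day
administrative cut-off.  Default parameters are calibrated so that the
marginal summary statistics of a generated cohort (median age 70 years,
Kaplan-Meier median OS ~319 days, median TTF ~116 days, neutropenia ~57.9%,
liver metastasis ~13.3%, ...) match the published cohort this design
emulates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised when a cohort configuration field is invalid; names the field."""


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass
class WeibullOutcomeModel:
    """Weibull proportional-hazards model for a time-to-event outcome.

    ``shape`` and ``scale`` (days) parameterize the baseline survival
    S0(t) = exp(-(t/scale)^shape); ``log_hr`` maps covariate names to
    log-hazard-ratios applied to *centred* covariates (continuous covariates
    are standardized against the reference mean/sd in ``STANDARDIZE_REF``).
    """

    shape: float
    scale: float
    log_hr: dict[str, float] = field(default_factory=dict)

    def validate(self, prefix: str) -> None:
        if not self.shape > 0:
            raise ConfigError(f"{prefix}.shape must be > 0")
        if not self.scale > 0:
            raise ConfigError(f"{prefix}.scale must be > 0")


@dataclass
class AdverseEventModel:
    """Logistic model for neutropenia-associated events.

    Any-grade neutropenia probability is logistic in standardized delivered
    dose and cycle count; Grade >=3 events are a fixed-probability subset of
    any-grade events, and febrile neutropenia a subset of Grade >=3 events
    (nesting mirrors how the events are clinically graded).  Bone-marrow
    suppression is neutropenia plus an independent extra incidence.
    """

    neut_intercept: float = 0.58
    neut_dose_coef: float = 1.10
    neut_cycles_coef: float = 1.30
    grade3_given_neut: float = 0.85
    febrile_given_grade3: float = 0.366
    bms_extra: float = 0.283

    def validate(self) -> None:
        for name in ("grade3_given_neut", "febrile_given_grade3", "bms_extra"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"ae_model.{name} must be a probability in [0, 1]")


@dataclass
class PsaResponseRule:
    """PSA response definition and its simulation hooks.

    A response is a >=30% decline from a baseline PSA of >=5 ng/mL.  The
    longitudinal PSA trajectory itself is not simulated; eligibility uses the
    simulated baseline PSA, and the response indicator is logistic in
    standardized treatment duration (longer time on treatment -> higher
    response probability).  A missingness rate mimics partially missing
    response assessments; ineligible patients are also missing.
    """

    threshold: float = 0.30
    floor: float = 5.0
    missing_rate: float = 0.15
    intercept: float = -0.90
    ttf_coef: float = 0.90

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("psa_response_rule.threshold must be in (0, 1)")
        if not self.floor > 0:
            raise ConfigError("psa_response_rule.floor must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("psa_response_rule.missing_rate must be in [0, 1)")


# Reference means/sds used to standardize covariates inside the hazard and
# logistic linear predictors.  Fixed constants (not per-sample moments) so the
# generative law does not depend on the realized sample.
STANDARDIZE_REF: dict[str, tuple[float, float]] = {
    "dose_per_cycle": (20.8, 3.4),
    "treatment_cycles": (5.5, 4.1),
    "relative_dose_intensity": (68.0, 16.4),
    "ttf_days": (150.0, 115.0),
}


@dataclass
class CohortConfig:
    """Full specification of the synthetic cohort generative model."""

    n_patients: int = 660
    n_explanatory: int = 91
    followup_days: int = 365

    # baseline characteristics
    age_median: float = 70.0
    age_sd: float = 9.5
    age_range: tuple[float, float] = (43.0, 91.0)
    ecog_probs: tuple[float, float, float] = (0.625, 0.295, 0.080)
    covariate_prevalences: dict[str, float] = field(default_factory=lambda: {
        "gleason_8_10": 0.782,
        "prior_docetaxel": 0.979,
        "prior_enzalutamide": 0.799,
        "prior_abiraterone": 0.550,
        "prior_radiation": 0.299,
        "bone_metastasis": 0.880,
        "prostate_lesion": 0.706,
        "regional_lymph_node_metastasis": 0.403,
        "distant_lymph_node_metastasis": 0.277,
        "liver_metastasis": 0.133,
        "seminal_vesicle_metastasis": 0.118,
        "lung_metastasis": 0.106,
        "bladder_metastasis": 0.099,
        "other_metastasis": 0.055,
        "prophylactic_gcsf": 0.60,
        "diarrhea": 0.100,
        "renal_impairment": 0.002,
        "severe_infection": 0.045,
        "anemia": 0.142,
        "peripheral_neuropathy": 0.015,
    })

    # treatment exposure
    dose_mean: float = 20.8
    dose_sd: float = 3.4
    dose_range: tuple[float, float] = (10.0, 26.3)
    # RDI = dose/25 * intensity factor; factor < 1 captures cycle delays
    rdi_factor_mean: float = 0.823
    rdi_factor_sd: float = 0.15
    rdi_factor_range: tuple[float, float] = (0.30, 1.01)
    rdi_range: tuple[float, float] = (17.8, 101.0)
    planned_dose: float = 25.0
    # cycles ~ TTF / 21 days scaled by a delay factor, capped at 18
    cycle_factor_mean: float = 0.75
    cycle_factor_sd: float = 0.30
    cycle_factor_range: tuple[float, float] = (0.30, 1.20)
    days_per_cycle: float = 21.0
    max_cycles: int = 18

    # outcomes
    os_model: WeibullOutcomeModel = field(default_factory=lambda: WeibullOutcomeModel(
        shape=1.25,
        scale=468.0,
        log_hr={
            "liver_metastasis": 1.25,
            "lung_metastasis": 1.20,
            "ecog_ps": 0.90,
            "neutropenia": -1.05,
            "ttf_days": -0.70,
        },
    ))
    ttf_model: WeibullOutcomeModel = field(default_factory=lambda: WeibullOutcomeModel(
        shape=1.05,
        scale=169.0,
        log_hr={"relative_dose_intensity": 0.65},
    ))
    ae_model: AdverseEventModel = field(default_factory=AdverseEventModel)
    psa_response_rule: PsaResponseRule = field(default_factory=PsaResponseRule)

    # baseline PSA (ng/mL), log-normal
    psa_log_mean: float = 4.3
    psa_log_sd: float = 1.5

    # early-dropout censoring within the year, on top of the 365-day cut
    dropout_rate: float = 0.05
    dropout_window: tuple[float, float] = (30.0, 365.0)

    # discontinuation-reason probabilities conditional on treatment failure
    disc_probs: dict[str, float] = field(default_factory=lambda: {
        "disc_adverse_event": 0.487,
        "disc_progression": 0.641,
        "disc_other": 0.492,
    })

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.followup_days <= 0:
            raise ConfigError("followup_days must be positive")
        if self.n_explanatory < len(STRUCTURAL_EXPLANATORY):
            raise ConfigError(
                f"n_explanatory must be >= {len(STRUCTURAL_EXPLANATORY)} "
                "(the number of named structural variables)")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"covariate_prevalences[{name!r}] must be in [0, 1]")
        if abs(sum(self.ecog_probs) - 1.0) > 1e-9:
            raise ConfigError("ecog_probs must sum to 1")
        for name, p in self.disc_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"disc_probs[{name!r}] must be in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        self.os_model.validate("os_model")
        self.ttf_model.validate("ttf_model")
        self.ae_model.validate()
        self.psa_response_rule.validate()

    def null(self) -> "CohortConfig":
        """A copy of this configuration with every planted effect size zeroed.

        The structural derivations (RDI from dose, cycles from treatment
        duration, adverse-event grade nesting, censoring bookkeeping) remain;
        only covariate -> outcome and exposure -> adverse-event effects vanish.
        """
        cfg = dataclasses.replace(
            self,
            os_model=dataclasses.replace(self.os_model, log_hr={}),
            ttf_model=dataclasses.replace(self.ttf_model, log_hr={}),
            ae_model=dataclasses.replace(
                self.ae_model, neut_dose_coef=0.0, neut_cycles_coef=0.0),
            psa_response_rule=dataclasses.replace(
                self.psa_response_rule, ttf_coef=0.0),
        )
        return cfg


# ---------------------------------------------------------------------------
# Variable dictionary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    name: str
    role: str   # response | explanatory | bookkeeping
    kind: str   # binary | ordinal | continuous | count
    units: str = ""


# Named structural explanatory variables (those that appear in the emulated
# study's tables); the remainder up to n_explanatory is independent noise.
STRUCTURAL_EXPLANATORY: list[VariableSpec] = [
    VariableSpec("age", "explanatory", "continuous", "years"),
    VariableSpec("gleason_8_10", "explanatory", "binary"),
    VariableSpec("ecog_ps", "explanatory", "ordinal"),
    VariableSpec("prior_docetaxel", "explanatory", "binary"),
    VariableSpec("prior_enzalutamide", "explanatory", "binary"),
    VariableSpec("prior_abiraterone", "explanatory", "binary"),
    VariableSpec("prior_radiation", "explanatory", "binary"),
    VariableSpec("bone_metastasis", "explanatory", "binary"),
    VariableSpec("prostate_lesion", "explanatory", "binary"),
    VariableSpec("regional_lymph_node_metastasis", "explanatory", "binary"),
    VariableSpec("distant_lymph_node_metastasis", "explanatory", "binary"),
    VariableSpec("liver_metastasis", "explanatory", "binary"),
    VariableSpec("seminal_vesicle_metastasis", "explanatory", "binary"),
    VariableSpec("lung_metastasis", "explanatory", "binary"),
    VariableSpec("bladder_metastasis", "explanatory", "binary"),
    VariableSpec("other_metastasis", "explanatory", "binary"),
    VariableSpec("baseline_psa", "explanatory", "continuous", "ng/mL"),
    VariableSpec("prophylactic_gcsf", "explanatory", "binary"),
    VariableSpec("dose_per_cycle", "explanatory", "continuous", "mg/m2"),
    VariableSpec("relative_dose_intensity", "explanatory", "continuous", "%"),
    VariableSpec("treatment_cycles", "explanatory", "count", "cycles"),
    VariableSpec("disc_adverse_event", "explanatory", "binary"),
    VariableSpec("disc_progression", "explanatory", "binary"),
    VariableSpec("disc_other", "explanatory", "binary"),
    VariableSpec("diarrhea", "explanatory", "binary"),
    VariableSpec("renal_impairment", "explanatory", "binary"),
    VariableSpec("severe_infection", "explanatory", "binary"),
    VariableSpec("anemia", "explanatory", "binary"),
    VariableSpec("peripheral_neuropathy", "explanatory", "binary"),
    VariableSpec("bone_marrow_suppression", "explanatory", "binary"),
    VariableSpec("neutropenia", "explanatory", "binary"),
    VariableSpec("grade3plus_neutropenia", "explanatory", "binary"),
    VariableSpec("febrile_neutropenia", "explanatory", "binary"),
]

RESPONSE_BOOKKEEPING: list[VariableSpec] = [
    VariableSpec("os_days", "response", "continuous", "days"),
    VariableSpec("os_event", "bookkeeping", "binary"),
    VariableSpec("ttf_days", "response", "continuous", "days"),
    VariableSpec("ttf_event", "bookkeeping", "binary"),
    VariableSpec("observation_days", "bookkeeping", "continuous", "days"),
    VariableSpec("psa_response", "response", "binary"),
]

_NOISE_PREVALENCES = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


def noise_variable_specs(config: CohortConfig) -> list[tuple[VariableSpec, float]]:
    """Deterministic padding variables: alternating binary/continuous noise.

    Returns (spec, prevalence) pairs; prevalence is meaningful for binary
    noise only (continuous noise is standard normal).
    """
    n_noise = config.n_explanatory - len(STRUCTURAL_EXPLANATORY)
    out = []
    for k in range(n_noise):
        idx = k + 1
        if k % 2 == 0:
            p = _NOISE_PREVALENCES[(k // 2) % len(_NOISE_PREVALENCES)]
            out.append((VariableSpec(f"noise_{idx:02d}", "explanatory", "binary"), p))
        else:
            out.append((VariableSpec(f"noise_{idx:02d}", "explanatory", "continuous"), np.nan))
    return out


def variable_dictionary(config: CohortConfig) -> list[VariableSpec]:
    """The data dictionary for a cohort generated under ``config``."""
    return (RESPONSE_BOOKKEEPING
            + STRUCTURAL_EXPLANATORY
            + [spec for spec, _ in noise_variable_specs(config)])


# ---------------------------------------------------------------------------
# Planted ground-truth graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEdge:
    source: str
    target: str
    sign: str          # "+", "-", or "+-": expected direction of the association
    effect_size: float  # log-hazard-ratio, log-odds, or coupling strength

    def pair(self) -> frozenset:
        return frozenset((self.source, self.target))


#: analysis-space aliases: a censored time-to-event outcome is observed
#: through two columns (the recorded time and the censoring indicator), and
#: its associations can surface on either; recovery scoring folds both views
#: onto the outcome-process node.
OUTCOME_VIEWS: dict[str, str] = {
    "os_censoring": "os_days",
    "os_event": "os_days",
    "ttf_censoring": "ttf_days",
    "ttf_event": "ttf_days",
}


@dataclass
class PlantedGraph:
    """Ground-truth dependency structure of the generative model.

    Nodes live at the *outcome-process* level: ``os_days`` stands for the
    whole OS process (recorded time plus censoring indicator) and
    ``ttf_days`` for the TTF process.  Edges are undirected pairs with the
    expected association direction and the generative effect size.  A sign of
    ``"+-"`` marks edges whose observable direction depends on which view of
    the censored outcome carries them (the observation-window couplings: the
    time view is positive, the dropout/censoring view negative).
    """

    nodes: list[str]
    edges: list[PlantedEdge]

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        for e in self.edges:
            if e.source == e.target:
                raise ConfigError(f"planted self-edge at {e.source!r}")
            if e.source not in declared or e.target not in declared:
                raise ConfigError(f"planted edge endpoint not declared: {e.source}-{e.target}")
            if e.effect_size == 0:
                raise ConfigError(f"planted edge {e.source}-{e.target} has zero effect size")

    def pairs(self) -> set[frozenset]:
        return {e.pair() for e in self.edges}

    def sign_of(self, a: str, b: str) -> str:
        key = frozenset((a, b))
        for e in self.edges:
            if e.pair() == key:
                return e.sign
        raise KeyError(f"no planted edge {a}-{b}")


def default_planted_graph(config: CohortConfig) -> PlantedGraph:
    """Enumerate every direct dependency wired into ``generate_cohort``.

    Signs record the expected direction of the association between the two
    variables (for outcome processes, the direction seen on the recorded-time
    view); effect sizes quote the generative coefficient (log-HR on the
    hazard scale for survival edges, log-odds for logistic edges, and 1.0 for
    deterministic-with-noise derivations).
    """
    os_hr = config.os_model.log_hr
    ttf_hr = config.ttf_model.log_hr
    ae = config.ae_model
    edges = [
        # treatment exposure couplings
        PlantedEdge("dose_per_cycle", "relative_dose_intensity", "+", 1.0),
        PlantedEdge("relative_dose_intensity", "ttf_days", "-",
                    ttf_hr.get("relative_dose_intensity", 0.0)),
        PlantedEdge("ttf_days", "treatment_cycles", "+", 1.0),
        # discontinuation reasons mark treatment failure
        PlantedEdge("ttf_days", "disc_adverse_event", "-", 1.0),
        PlantedEdge("ttf_days", "disc_progression", "-", 1.0),
        PlantedEdge("ttf_days", "disc_other", "-", 1.0),
        # overall survival effects
        PlantedEdge("os_days", "liver_metastasis", "-", os_hr.get("liver_metastasis", 0.0)),
        PlantedEdge("os_days", "lung_metastasis", "-", os_hr.get("lung_metastasis", 0.0)),
        PlantedEdge("os_days", "ecog_ps", "-", os_hr.get("ecog_ps", 0.0)),
        PlantedEdge("os_days", "neutropenia", "+", os_hr.get("neutropenia", 0.0)),
        PlantedEdge("os_days", "ttf_days", "+", os_hr.get("ttf_days", 0.0)),
        # observation-window truncation (sign depends on the observed view)
        PlantedEdge("os_days", "observation_days", "+-", 1.0),
        PlantedEdge("ttf_days", "observation_days", "+-", 1.0),
        # adverse-event cascade
        PlantedEdge("dose_per_cycle", "neutropenia", "+", ae.neut_dose_coef),
        PlantedEdge("treatment_cycles", "neutropenia", "+", ae.neut_cycles_coef),
        PlantedEdge("neutropenia", "grade3plus_neutropenia", "+", 1.0),
        PlantedEdge("grade3plus_neutropenia", "febrile_neutropenia", "+", 1.0),
        PlantedEdge("neutropenia", "bone_marrow_suppression", "+", 1.0),
        # PSA response
        PlantedEdge("ttf_days", "psa_response", "+",
                    config.psa_response_rule.ttf_coef),
    ]
    # drop edges whose generative coefficient has been zeroed (null configs)
    live = [e for e in edges if e.effect_size != 0.0]
    nodes = sorted({n for e in live for n in (e.source, e.target)})
    return PlantedGraph(nodes=nodes, edges=live)


def default_config() -> CohortConfig:
    """The default generative model, calibrated to the emulated cohort's
    printed marginal statistics (n=660, 91 explanatory variables, one-year
    administrative censoring)."""
    return CohortConfig()


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _zref(name: str, x: np.ndarray) -> np.ndarray:
    mu, sd = STANDARDIZE_REF[name]
    return (x - mu) / sd


def _weibull_times(rng: np.random.Generator, model: WeibullOutcomeModel,
                   eta: np.ndarray) -> np.ndarray:
    """Draw event times from S(t|x) = exp(-(t/scale)^shape * exp(eta))."""
    u = rng.uniform(size=eta.shape)
    return model.scale * (-np.log(u) / np.exp(eta)) ** (1.0 / model.shape)


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> tuple[pd.DataFrame, PlantedGraph]:
    """Generate one synthetic cohort and its ground-truth dependency graph.

    Identical ``(config, seed)`` pairs reproduce the table bit-for-bit.  The
    returned table has one row per patient and columns for the three response
    variables (with censor bookkeeping) plus ``config.n_explanatory``
    explanatory variables; ``psa_response`` carries missing values (NaN).
    """
    if config is None:
        config = default_config()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_patients
    fup = float(config.followup_days)
    cols: dict[str, np.ndarray] = {}

    # --- baseline characteristics -------------------------------------------------
    age = np.clip(rng.normal(config.age_median, config.age_sd, n), *config.age_range)
    cols["age"] = np.round(age)
    cols["ecog_ps"] = rng.choice(3, size=n, p=config.ecog_probs).astype(float)
    prev = config.covariate_prevalences
    for name, p in prev.items():
        cols[name] = (rng.uniform(size=n) < p).astype(float)
    cols["baseline_psa"] = np.round(
        np.exp(rng.normal(config.psa_log_mean, config.psa_log_sd, n)), 1)

    # --- treatment exposure -------------------------------------------------------
    dose = np.clip(rng.normal(config.dose_mean, config.dose_sd, n), *config.dose_range)
    cols["dose_per_cycle"] = np.round(dose, 1)
    f = np.clip(rng.normal(config.rdi_factor_mean, config.rdi_factor_sd, n),
                *config.rdi_factor_range)
    rdi = np.clip(dose / config.planned_dose * f * 100.0, *config.rdi_range)
    cols["relative_dose_intensity"] = np.round(rdi, 1)

    # --- time-to-treatment-failure ------------------------------------------------
    eta_ttf = np.zeros(n)
    for name, beta in config.ttf_model.log_hr.items():
        eta_ttf += beta * _zref(name, cols[name])
    ttf_raw = _weibull_times(rng, config.ttf_model, eta_ttf)

    # --- observation window: administrative 365-day cut plus early dropout --------
    dropped = rng.uniform(size=n) < config.dropout_rate
    dropout_time = rng.uniform(*config.dropout_window, size=n)
    observation = np.where(dropped, dropout_time, fup)
    cols["observation_days"] = np.round(observation, 1)

    ttf_days = np.minimum(ttf_raw, observation)
    ttf_event = (ttf_raw <= observation).astype(float)
    cols["ttf_days"] = np.round(np.maximum(ttf_days, 1.0), 1)
    cols["ttf_event"] = ttf_event

    # --- cycles delivered (derived from time on treatment, with delay noise) ------
    cyc_f = np.clip(rng.normal(config.cycle_factor_mean, config.cycle_factor_sd, n),
                    *config.cycle_factor_range)
    cycles = np.rint(cols["ttf_days"] / config.days_per_cycle * cyc_f)
    cols["treatment_cycles"] = np.clip(cycles, 1, config.max_cycles)

    # --- discontinuation reasons (only observed when treatment failed) ------------
    for name, p in config.disc_probs.items():
        cols[name] = np.where(ttf_event == 1.0,
                              (rng.uniform(size=n) < p).astype(float), 0.0)

    # --- neutropenia cascade ------------------------------------------------------
    ae = config.ae_model
    logit = (ae.neut_intercept
             + ae.neut_dose_coef * _zref("dose_per_cycle", cols["dose_per_cycle"])
             + ae.neut_cycles_coef * _zref("treatment_cycles", cols["treatment_cycles"]))
    p_neut = 1.0 / (1.0 + np.exp(-logit))
    neut = (rng.uniform(size=n) < p_neut).astype(float)
    g3 = neut * (rng.uniform(size=n) < ae.grade3_given_neut)
    feb = g3 * (rng.uniform(size=n) < ae.febrile_given_grade3)
    bms = np.maximum(neut, (rng.uniform(size=n) < ae.bms_extra).astype(float))
    cols["neutropenia"] = neut
    cols["grade3plus_neutropenia"] = g3
    cols["febrile_neutropenia"] = feb
    cols["bone_marrow_suppression"] = bms

    # --- overall survival ----------------------------------------------------------
    centred = {
        "liver_metastasis": prev["liver_metastasis"],
        "lung_metastasis": prev["lung_metastasis"],
        "ecog_ps": config.ecog_probs[1] + 2 * config.ecog_probs[2],
        "neutropenia": float(np.mean(p_neut)),
    }
    eta_os = np.zeros(n)
    for name, beta in config.os_model.log_hr.items():
        if name == "ttf_days":
            eta_os += beta * _zref("ttf_days", cols["ttf_days"])
        else:
            eta_os += beta * (cols[name] - centred[name])
    os_raw = _weibull_times(rng, config.os_model, eta_os)
    os_days = np.minimum(os_raw, observation)
    os_event = (os_raw <= observation).astype(float)
    cols["os_days"] = np.round(np.maximum(os_days, 1.0), 1)
    cols["os_event"] = os_event

    # --- PSA response ----------------------------------------------------------------
    rule = config.psa_response_rule
    eligible = cols["baseline_psa"] >= rule.floor
    p_resp = 1.0 / (1.0 + np.exp(-(rule.intercept
                                   + rule.ttf_coef * _zref("ttf_days", cols["ttf_days"]))))
    resp = (rng.uniform(size=n) < p_resp).astype(float)
    missing = (~eligible) | (rng.uniform(size=n) < rule.missing_rate)
    cols["psa_response"] = np.where(missing, np.nan, resp)

    # --- independent noise padding ----------------------------------------------------
    for spec, p in noise_variable_specs(config):
        if spec.kind == "binary":
            cols[spec.name] = (rng.uniform(size=n) < p).astype(float)
        else:
            cols[spec.name] = rng.normal(size=n)

    order = [v.name for v in variable_dictionary(config)]
    table = pd.DataFrame({name: cols[name] for name in order})
    return table, default_planted_graph(config)


# ---------------------------------------------------------------------------
# Summaries and recovery scoring
# ---------------------------------------------------------------------------

def summarize_cohort(table: pd.DataFrame) -> dict:
    """Marginal summary of a cohort: the machine twin of a baseline table.

    Returns a dict with ``median`` entries (median, min, max) for continuous
    and count variables, ``incidence`` percentages for binary variables, and
    Kaplan-Meier medians for OS and TTF when the censor flags are present.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    from .survival import km_curve

    summary: dict = {"n": int(len(table)), "median": {}, "incidence": {}, "km_median": {}}
    for name in table.columns:
        col = table[name].dropna()
        if len(col) == 0:
            continue
        values = set(np.unique(col))
        if values <= {0.0, 1.0}:
            summary["incidence"][name] = 100.0 * float(col.mean())
        else:
            summary["median"][name] = (float(col.median()), float(col.min()), float(col.max()))
    for stem in ("os", "ttf"):
        tcol, ecol = f"{stem}_days", f"{stem}_event"
        if tcol in table.columns and ecol in table.columns:
            curve = km_curve(table[tcol].to_numpy(), table[ecol].to_numpy())
            summary["km_median"][stem] = curve.median
    return summary


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    sign_accuracy: float
    n_selected: int
    n_truth: int
    undefined: list[str] = field(default_factory=list)


def recovery_metrics(selected, truth: PlantedGraph,
                     restrict_to_truth_nodes: bool = True,
                     fold_outcome_views: bool = True) -> RecoveryMetrics:
    """Score a set of selected edges against the planted ground truth.

    ``selected`` is an :class:`~cabanet.gm.EdgeSelection` or an iterable of
    ``(node_a, node_b, sign)`` triples (sign in {"positive", "negative",
    "indeterminate"}).  Edges are compared as unordered pairs.

    Two normalizations reflect what the ground truth can actually adjudicate:

    * ``fold_outcome_views`` maps the censoring-indicator nodes onto their
      outcome process (``os_censoring -> os_days``, ``ttf_censoring ->
      ttf_days``) before comparing.  Under heavy administrative censoring an
      outcome association may surface on the recorded-time column or on the
      censoring indicator — both are detections of the same planted
      dependency.  Pairs internal to one process (time vs its own censor
      flag) drop out.  When both views of a pair are selected, the
      time-view's sign wins.
    * ``restrict_to_truth_nodes`` limits the selected set to pairs whose
      endpoints both belong to the planted graph's node space; the
      full-network selection also contains pairs among padding noise
      variables, which the planted graph does not model.

    Precision = |selected ∩ truth| / |selected|; recall = |selected ∩ truth| /
    |truth|; sign accuracy is computed over the intersection (an indeterminate
    call never matches; a ``"+-"`` truth sign accepts either direction).
    Undefined ratios (empty denominator) are reported as NaN and flagged in
    ``undefined``.
    """
    if hasattr(selected, "edges"):
        triples = [(e.pair, e.sign) for e in selected.edges]
    else:
        triples = [(frozenset((a, b)), s) for a, b, s in selected]

    if fold_outcome_views:
        folded: dict[frozenset, tuple[str, bool]] = {}  # pair -> (sign, from_time_view)
        for p, s in triples:
            mapped = frozenset(OUTCOME_VIEWS.get(v, v) for v in p)
            if len(mapped) < 2:
                continue  # a view of an outcome paired with its own process
            time_view = mapped == p
            prev = folded.get(mapped)
            if prev is None or (time_view and not prev[1]):
                folded[mapped] = (s, time_view)
        triples = [(p, s) for p, (s, _) in folded.items()]

    truth_nodes = set(truth.nodes)
    if restrict_to_truth_nodes:
        triples = [(p, s) for p, s in triples if p <= truth_nodes]
    truth_pairs = truth.pairs()
    sel_pairs = {p for p, _ in triples}
    hit = sel_pairs & truth_pairs

    undefined = []
    if sel_pairs:
        precision = len(hit) / len(sel_pairs)
    else:
        precision, undefined = float("nan"), undefined + ["precision"]
    if truth_pairs:
        recall = len(hit) / len(truth_pairs)
    else:
        recall, undefined = float("nan"), undefined + ["recall"]
    acceptable = {"+": {"positive"}, "-": {"negative"},
                  "+-": {"positive", "negative"}}
    if hit:
        ok = 0
        for p, s in triples:
            if p in truth_pairs:
                a, b = sorted(p)
                if s in acceptable[truth.sign_of(a, b)]:
                    ok += 1
        sign_accuracy = ok / len(hit)
    else:
        sign_accuracy, undefined = float("nan"), undefined + ["sign_accuracy"]
    return RecoveryMetrics(precision, recall, sign_accuracy,
                           len(sel_pairs), len(truth_pairs), undefined)
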