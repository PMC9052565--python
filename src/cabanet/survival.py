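"""Kaplan-Meier subgroup confirmation of the network findings.

Product-limit survival curves with Greenwood variance and Brookmeyer-Crowley
(log-log) median confidence intervals, k-group log-rank tests, and univariate
Cox hazard ratios for the patient subgroups flagged by the machine-learning
stages: liver metastasis, lung metastasis, ECOG performance status,
neutropenia, febrile neutropenia, and cabazitaxel cycle count (>=4 vs <4).

Estimation is delegated to lifelines (KaplanMeierFitter, CoxPHFitter with
Efron tie handling, multivariate log-rank); this module owns the subgroup
definitions, degenerate-input handling and the reporting schema.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate on the observed event-time grid."""

    times: np.ndarray        # distinct observed times (events and censorings)
    survival: np.ndarray     # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    variance: np.ndarray     # Greenwood variance of S(t)
    median: float            # NaN when S never drops to <= 0.5
    median_ci: tuple[float, float]
    median_defined: bool

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Tied events at a time are handled simultaneously; subjects censored at t
    are still at risk at t.  The median is the smallest time with
    S(t) <= 0.5 (NaN, flagged, when the curve never reaches 0.5 — e.g. fully
    censored input); its 95% CI comes from the log-log (exponential
    Greenwood) confidence band, the Brookmeyer-Crowley construction.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not set(np.unique(events)) <= {0.0, 1.0}:
        raise ValueError("events must be binary")

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(tab.index).to_numpy()
    d = tab["observed"].to_numpy(dtype=float)
    n_risk = tab["at_risk"].to_numpy(dtype=float)
    censored = tab["censored"].to_numpy(dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.nan)
    var = surv**2 * np.cumsum(inc)

    median = float(kmf.median_survival_time_)
    defined = np.isfinite(median)
    if defined:
        ci = median_survival_times(kmf.confidence_interval_)
        lo = float(ci.iloc[0, 0])
        hi = float(ci.iloc[0, 1])
    else:
        median, lo, hi = float("nan"), float("nan"), float("nan")
        logger.info("KM median undefined: survival never reaches 0.5")
    return SurvivalCurve(times=grid, survival=surv, at_risk=n_risk, events=d,
                         censored=censored, variance=var, median=median,
                         median_ci=(lo, hi), median_defined=defined)


def logrank(group_times, group_events) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation; the statistic is chi-square on
    k - 1 degrees of freedom.  A group with no events contributes only
    expectations.  An empty group raises, naming the group.
    """
    if len(group_times) < 2:
        raise ValueError("need at least 2 groups")
    for k, t in enumerate(group_times):
        if len(np.asarray(t)) == 0:
            raise ValueError(f"group {k} is empty")
    durations = np.concatenate([np.asarray(t, dtype=float) for t in group_times])
    events = np.concatenate([np.asarray(e, dtype=float) for e in group_events])
    labels = np.concatenate([np.full(len(np.asarray(t)), k)
                             for k, t in enumerate(group_times)])
    res = multivariate_logrank_test(durations, labels, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardRatioResult:
    hr: float
    ci: tuple[float, float]
    log_hr: float
    se: float
    unbounded: bool = False  # monotone likelihood / complete separation


def hazard_ratio(times, events, group) -> HazardRatioResult:
    """Two-group hazard ratio from a univariate Cox model (Efron ties).

    ``group`` is a binary indicator; the reported HR is group 1 vs group 0
    with a Wald 95% CI.  Monotone partial likelihood (complete separation of
    the event times) is flagged and the CI reported as unbounded.
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=float),
        "group": np.asarray(group, dtype=float),
    })
    for lvl in (0.0, 1.0):
        sub = df[df["group"] == lvl]
        if len(sub) == 0 or sub["event"].sum() == 0:
            raise ValueError(f"group {int(lvl)} has no events")
    cph = CoxPHFitter()
    unbounded = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        cph.fit(df, duration_col="time", event_col="event")
        unbounded = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    if not np.isfinite(se) or se > 50:
        unbounded = True
    lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    if unbounded:
        lo, hi = 0.0, float("inf")
        logger.warning("monotone likelihood suspected; CI reported as unbounded")
    return HazardRatioResult(hr=float(np.exp(beta)), ci=(float(lo), float(hi)),
                             log_hr=beta, se=se, unbounded=unbounded)


@dataclass
class SubgroupComparison:
    name: str
    variable: str
    groups: list[dict] = field(default_factory=list)  # label, n, events, median, ci
    logrank_stat: float = float("nan")
    logrank_p: float = float("nan")
    hr: float = float("nan")          # contrast: highest level vs reference
    hr_ci: tuple[float, float] = (float("nan"), float("nan"))
    hr_contrast: str = ""
    skipped: bool = False
    skip_reason: str = ""


#: default subgroup set: the six panels confirmed against the network findings
DEFAULT_SUBGROUPS: list[tuple[str, str]] = [
    ("liver metastasis", "liver_metastasis"),
    ("lung metastasis", "lung_metastasis"),
    ("ECOG PS", "ecog_ps"),
    ("neutropenia", "neutropenia"),
    ("febrile neutropenia", "febrile_neutropenia"),
    ("cabazitaxel cycles >= 4", "treatment_cycles"),
]

CYCLE_CUTOFF = 4  # >=4 vs <4 cycles


def subgroup_analysis(table: pd.DataFrame,
                      subgroups: list[tuple[str, str]] | None = None,
                      time_col: str = "os_days",
                      event_col: str = "os_event",
                      cycle_cutoff: int = CYCLE_CUTOFF) -> list[SubgroupComparison]:
    """Overall-survival comparison for each requested subgroup split.

    Binary variables split present vs absent; ``ecog_ps`` splits 0 / 1 / >=2
    (log-rank over all levels, HR for >=2 vs 0); ``treatment_cycles``
    dichotomizes at ``cycle_cutoff``.  A subgroup whose split leaves an empty
    or event-free level is skipped with a warning.
    """
    subgroups = subgroups if subgroups is not None else DEFAULT_SUBGROUPS
    out = []
    t = table[time_col].to_numpy(dtype=float)
    e = table[event_col].to_numpy(dtype=float)
    for name, var in subgroups:
        if var not in table.columns:
            out.append(SubgroupComparison(name, var, skipped=True,
                                          skip_reason=f"column {var!r} missing"))
            continue
        x = table[var].to_numpy(dtype=float)
        if var == "treatment_cycles":
            levels = [(f"< {cycle_cutoff} cycles", x < cycle_cutoff),
                      (f">= {cycle_cutoff} cycles", x >= cycle_cutoff)]
        elif var == "ecog_ps":
            levels = [("PS 0", x == 0), ("PS 1", x == 1), ("PS >= 2", x >= 2)]
        else:
            levels = [("absent", x == 0), ("present", x == 1)]
        if any(mask.sum() == 0 for _, mask in levels):
            logger.warning("subgroup %r has an empty level; skipped", name)
            out.append(SubgroupComparison(name, var, skipped=True,
                                          skip_reason="empty level"))
            continue
        comp = SubgroupComparison(name, var)
        for label, mask in levels:
            curve = km_curve(t[mask], e[mask])
            comp.groups.append({
                "label": label, "n": int(mask.sum()), "events": int(e[mask].sum()),
                "median": curve.median, "median_ci": curve.median_ci,
            })
        comp.logrank_stat, comp.logrank_p = logrank(
            [t[mask] for _, mask in levels], [e[mask] for _, mask in levels])
        ref_label, ref_mask = levels[0]
        top_label, top_mask = levels[-1]
        both = ref_mask | top_mask
        try:
            hr = hazard_ratio(t[both], e[both], top_mask[both].astype(float))
            comp.hr, comp.hr_ci = hr.hr, hr.ci
            comp.hr_contrast = f"{top_label} vs {ref_label}"
        except ValueError as exc:
            logger.warning("HR unavailable for %r: %s", name, exc)
        out.append(comp)
    return out


def subgroup_frame(comparisons: list[SubgroupComparison]) -> pd.DataFrame:
    """Flatten subgroup comparisons into the per-group reporting table."""
    rows = []
    for c in comparisons:
        if c.skipped:
            continue
        for g in c.groups:
            rows.append({
                "subgroup": c.name, "group": g["label"], "n": g["n"],
                "events": g["events"], "median": g["median"],
                "median_ci_low": g["median_ci"][0], "median_ci_high": g["median_ci"][1],
                "hr": c.hr, "hr_ci_low": c.hr_ci[0], "hr_ci_high": c.hr_ci[1],
                "hr_contrast": c.hr_contrast, "logrank_p": c.logrank_p,
            })
    return pd.DataFrame(rows)
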