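"""Discrete-event simulation of a rapid-start basket protocol.

The simulated mechanics mirror the program being modeled: patients with a
qualifying alteration are identified as a homogeneous Poisson process;
each patient either enrolls at an already-open site or triggers a new site
opening with a log-normal start-up delay; the 16-week clinical-benefit
outcome is Bernoulli in the cohort's true rate and is revealed 16 weeks
after dosing; tumor-type cohorts form at >= 4 enrolled patients and are
monitored with the interim exceedance rules, closing to further accrual
once stopped. Replicating a scenario many times yields the design's
operating characteristics (stop probabilities, expected sample size).

All randomness flows from one seed through named substreams (accrual,
sites, outcomes) so that, e.g., changing a true rate perturbs outcomes but
not the arrival process — which is what makes common-random-number
comparisons across scenarios meaningful.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decisions import DecisionRuleConfig, Verdict, conjugate_engine, evaluate_cohort

#: Per-site-type log-normal start-up parameters (median weeks, log-scale sd),
#: calibrated so medians match the observed per-type medians and the
#: log-scale sd reproduces each type's mean/median ratio
#: (sigma = sqrt(2 ln(mean/median))).
DEFAULT_STARTUP: dict[str, tuple[float, float]] = {
    "research_network": (2.6, math.sqrt(2 * math.log(3.6 / 2.6))),
    "community": (3.6, math.sqrt(2 * math.log(5.4 / 3.6))),
    "academic": (8.1, math.sqrt(2 * math.log(10.7 / 8.1))),
}

DEFAULT_SITE_MIX: dict[str, float] = {
    "research_network": 118 / 396,
    "community": 197 / 396,
    "academic": 81 / 396,
}


@dataclass
class TrialScenario:
    """Inputs for one simulated basket protocol (a single agent arm)."""

    tumor_types: tuple[str, ...]
    prevalence: tuple[float, ...]
    true_rates: Mapping[str, float]
    p0: Mapping[str, float]
    identification_rate: float = 2.0      # patients identified per week
    site_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_MIX)
    )
    startup: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STARTUP)
    )
    site_reuse_prob: float = 0.5
    outcome_lag_weeks: float = 16.0
    max_patients: int = 100
    max_weeks: float = 1000.0
    cohort_min: int = 4
    decision_config: DecisionRuleConfig = field(default_factory=DecisionRuleConfig)
    look_at_n: tuple[int, ...] | None = None  # None = every new count >= min
    engine: Callable | None = None            # default: Beta(1,1) conjugate

    def __post_init__(self) -> None:
        if len(self.tumor_types) != len(self.prevalence):
            raise ValueError("tumor_types and prevalence lengths differ")
        if abs(sum(self.prevalence) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        for t in self.tumor_types:
            for source, name in ((self.true_rates, "true rate"), (self.p0, "p0")):
                v = source[t]
                if not 0.0 <= v <= 1.0 if name == "true rate" else not 0.0 < v < 1.0:
                    raise ValueError(f"{name} for {t} out of range")
        if self.identification_rate < 0:
            raise ValueError("identification rate must be >= 0")
        missing = set(self.site_mix) - set(self.startup)
        if missing:
            raise ValueError(f"no start-up parameters for site type(s) {missing}")


@dataclass
class TrialResult:
    verdicts: dict[str, Verdict]
    n_enrolled: dict[str, int]
    n_evaluable_at_stop: dict[str, int]
    stop_week: dict[str, float | None]
    total_enrolled: int
    events: pd.DataFrame


@dataclass
class OperatingCharacteristics:
    per_cohort: pd.DataFrame   # P(futility), P(success), P(continue), E[n], SEs
    n_replicates: int


def sample_startup(
    site_type: str, scenario: TrialScenario, rng: np.random.Generator
) -> float:
    """Draw a site start-up time (weeks): log-normal per site type."""
    try:
        median, sigma = scenario.startup[site_type]
    except KeyError:
        raise KeyError(f"unknown site type {site_type!r}") from None
    return float(math.exp(math.log(median) + sigma * rng.standard_normal()))


def simulate_trial(scenario: TrialScenario, seed: int = 0) -> TrialResult:
    """Run one replicate of the discrete-event basket-trial simulation."""
    ss = np.random.SeedSequence(seed)
    rng_accrual, rng_sites, rng_outcomes = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    engine = scenario.engine or conjugate_engine()
    cfg = scenario.decision_config
    types = scenario.tumor_types
    prev = np.asarray(scenario.prevalence)

    enrolled: dict[str, int] = {t: 0 for t in types}
    evaluable: dict[str, int] = {t: 0 for t in types}
    benefits: dict[str, int] = {t: 0 for t in types}
    verdicts: dict[str, Verdict] = {t: Verdict.CONTINUE for t in types}
    stop_week: dict[str, float | None] = {t: None for t in types}
    closed: set[str] = set()
    open_sites: list[tuple[str, float]] = []  # (site_type, open_week)
    outcome_heap: list[tuple[float, int, str, bool]] = []
    event_rows: list[dict] = []
    last_look_n: dict[str, int] = {}

    def look(week: float, tumor: str) -> None:
        """Interim look triggered by `tumor` reaching a new evaluable count."""
        n = evaluable[tumor]
        if n < cfg.futility_min_n or n == last_look_n.get(tumor):
            return
        if scenario.look_at_n is not None and n not in scenario.look_at_n:
            return
        if enrolled[tumor] < scenario.cohort_min:
            return
        last_look_n[tumor] = n
        data = {
            t: (benefits[t], evaluable[t], scenario.p0[t])
            for t in types
            if enrolled[t] >= scenario.cohort_min
        }
        probs = engine(data)
        verdict = evaluate_cohort(n, probs[tumor], cfg)
        event_rows.append(
            {"week": week, "event": "look", "tumor_type": tumor,
             "n_evaluable": n, "exceedance": probs[tumor],
             "verdict": verdict.value}
        )
        if verdict is not Verdict.CONTINUE:
            verdicts[tumor] = verdict
            stop_week[tumor] = week
            closed.add(tumor)

    def drain(until: float) -> None:
        while outcome_heap and outcome_heap[0][0] <= until:
            wk, _, tumor, benefit = heapq.heappop(outcome_heap)
            evaluable[tumor] += 1
            benefits[tumor] += int(benefit)
            event_rows.append(
                {"week": wk, "event": "outcome", "tumor_type": tumor,
                 "n_evaluable": evaluable[tumor],
                 "exceedance": None, "verdict": None}
            )
            if tumor not in closed:
                look(wk, tumor)

    week = 0.0
    counter = 0
    total = 0
    while total < scenario.max_patients and week < scenario.max_weeks:
        if scenario.identification_rate == 0:
            break
        week += rng_accrual.exponential(1.0 / scenario.identification_rate)
        if week >= scenario.max_weeks:
            break
        drain(week)
        if len(closed) == len(types):
            break
        tumor = types[rng_accrual.choice(len(types), p=prev)]
        if tumor in closed:
            continue
        if open_sites and rng_sites.uniform() < scenario.site_reuse_prob:
            site_type, open_week = open_sites[
                rng_sites.integers(len(open_sites))
            ]
            dose_week = max(week, open_week)
        else:
            mix_types = list(scenario.site_mix)
            mix_p = np.asarray([scenario.site_mix[t] for t in mix_types])
            site_type = mix_types[rng_sites.choice(len(mix_types), p=mix_p / mix_p.sum())]
            dose_week = week + sample_startup(site_type, scenario, rng_sites)
            open_sites.append((site_type, dose_week))
        benefit = bool(
            rng_outcomes.uniform() < scenario.true_rates[tumor]
        )
        enrolled[tumor] += 1
        total += 1
        counter += 1
        heapq.heappush(
            outcome_heap,
            (dose_week + scenario.outcome_lag_weeks, counter, tumor, benefit),
        )
        event_rows.append(
            {"week": week, "event": "enroll", "tumor_type": tumor,
             "n_evaluable": None, "exceedance": None, "verdict": None}
        )
    drain(math.inf)

    return TrialResult(
        verdicts=verdicts,
        n_enrolled=dict(enrolled),
        n_evaluable_at_stop={
            t: (last_look_n.get(t, evaluable[t]) if verdicts[t] is not Verdict.CONTINUE
                else evaluable[t])
            for t in types
        },
        stop_week=stop_week,
        total_enrolled=total,
        events=pd.DataFrame(
            event_rows,
            columns=["week", "event", "tumor_type", "n_evaluable",
                     "exceedance", "verdict"],
        ),
    )


def operating_characteristics(
    scenario: TrialScenario, n_replicates: int, seed: int = 0
) -> OperatingCharacteristics:
    """Estimate stop probabilities and expected sample size by replication."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    tallies = {
        t: {"futility": 0, "success": 0, "continue": 0, "n_eval": 0.0}
        for t in scenario.tumor_types
    }
    for rep_seed in child_seeds:
        res = simulate_trial(scenario, seed=int(rep_seed))
        for t in scenario.tumor_types:
            v = res.verdicts[t]
            key = {
                Verdict.STOP_FUTILITY: "futility",
                Verdict.STOP_SUCCESS: "success",
                Verdict.CONTINUE: "continue",
            }[v]
            tallies[t][key] += 1
            tallies[t]["n_eval"] += res.n_evaluable_at_stop[t]
    rows = []
    R = n_replicates
    for t, c in tallies.items():
        pf, psucc = c["futility"] / R, c["success"] / R
        rows.append(
            {
                "tumor_type": t,
                "p_futility": pf,
                "p_success": psucc,
                "p_continue": c["continue"] / R,
                "se_futility": math.sqrt(max(pf * (1 - pf), 0.0) / R),
                "se_success": math.sqrt(max(psucc * (1 - psucc), 0.0) / R),
                "expected_n_evaluable": c["n_eval"] / R,
            }
        )
    return OperatingCharacteristics(
        per_cohort=pd.DataFrame(rows), n_replicates=R
    )


def with_true_rate(scenario: TrialScenario, tumor: str, rate: float) -> TrialScenario:
    """Scenario copy with one cohort's true rate replaced (for couplings)."""
    rates = dict(scenario.true_rates)
    rates[tumor] = rate
    return replace(scenario, true_rates=rates)
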