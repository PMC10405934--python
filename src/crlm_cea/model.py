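"""Diagnostic decision tree feeding a five-state Markov cohort model.

Each imaging strategy splits the cohort at t=0 into true/false positives
and negatives given the CRLM prevalence and the strategy's sensitivity and
specificity.  True positives are resected immediately (success -> RESECTED,
failure -> RECURRENCE); false negatives enter UNDIAGNOSED_TUMOR and reach
delayed resection once clinically detected; true negatives and false
positives are tumour-free (false positives are charged a one-time work-up
cost).  The cohort then cycles annually through

    TUMOR_FREE, UNDIAGNOSED_TUMOR, RESECTED, RECURRENCE, DEATH

with age-dependent background mortality combined multiplicatively with
disease-specific mortality, accruing discounted costs and QALYs per cycle.
No half-cycle correction is applied; state rewards are counted at cycle
start and the t=0 work-up costs are undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .lifetable import LifeTable, annual_mortality
from .parameters import ParameterTable, StrategySpec

__all__ = [
    "HealthState",
    "InitialAllocation",
    "CohortTrace",
    "CEResult",
    "annual_recurrence_probability",
    "combine_mortality",
    "initial_allocation",
    "transition_matrix",
    "run_cohort",
    "evaluate_strategies",
    "state_costs",
    "state_utilities",
]

_ROW_TOL = 1e-12


class HealthState(IntEnum):
    TUMOR_FREE = 0
    UNDIAGNOSED_TUMOR = 1
    RESECTED = 2
    RECURRENCE = 3
    DEATH = 4


N_STATES = len(HealthState)
STATE_LABELS = [s.name.lower() for s in HealthState]


class ModelError(RuntimeError):
    """Internal consistency failure in the cohort engine."""


def annual_recurrence_probability(p_recurrence: float, mode: str):
    """Annual post-resection recurrence probability.

    ``cumulative_5y`` treats the input as a 5-year cumulative probability and
    converts via ``1 - (1-p)^(1/5)``; ``annual`` uses it as-is.
    """
    if mode == "annual":
        return p_recurrence
    if mode == "cumulative_5y":
        return 1.0 - (1.0 - p_recurrence) ** 0.2
    raise ValueError(f"unknown recurrence_input mode {mode!r}")


def combine_mortality(p_disease, q_background):
    """Independent competing annual risks: ``1 - (1-p)(1-q)``."""
    return 1.0 - (1.0 - p_disease) * (1.0 - q_background)


def transition_flows(v: Mapping[str, float], q_bg, recurrence_mode: str) -> dict:
    """Per-cycle transition probabilities, keyed by named flow.

    Shared by the 5x5 matrix builder, the vectorised PSA engine and (via
    :func:`transition_matrix`) the microsimulation oracle, so all three use
    one definition of the transition rules.  ``v`` may hold scalars or
    equal-length numpy arrays.
    """
    p_rec = annual_recurrence_probability(v["p_recurrence_5y"], recurrence_mode)
    u_death = combine_mortality(v["p_death_untreated"], q_bg)
    u_detect = (1.0 - u_death) * v["p_detect"]
    rec_death = combine_mortality(v["p_death_recurrence"], q_bg)
    return {
        "tf_stay": 1.0 - q_bg + 0.0 * u_death,
        "tf_death": q_bg + 0.0 * u_death,
        "u_death": u_death,
        "u_to_resected": u_detect * v["p_treatment_success"],
        "u_to_recurrence": u_detect * (1.0 - v["p_treatment_success"]),
        "u_stay": (1.0 - u_death) * (1.0 - v["p_detect"]),
        "r_death": q_bg + 0.0 * u_death,
        "r_to_recurrence": (1.0 - q_bg) * p_rec,
        "r_stay": (1.0 - q_bg) * (1.0 - p_rec),
        "rec_death": rec_death,
        "rec_stay": 1.0 - rec_death,
    }


def state_costs(v: Mapping[str, float], cycle_length: float = 1.0):
    """Per-cycle state running costs (USD), in :class:`HealthState` order."""
    return np.array(
        [0.0, v["undetected_annual_cost"], 0.0, v["annual_crlm_cost"], 0.0]
    ) * cycle_length


def state_utilities(v: Mapping[str, float]):
    """Utility weights per state, in :class:`HealthState` order."""
    return np.array(
        [v["u_tumor_free"], v["u_undetected"], v["u_post_resection"], v["u_recurrence"], 0.0]
    )


@dataclass(frozen=True)
class InitialAllocation:
    """Decision-tree branch masses and the t=0 cost of the work-up."""

    tp: float
    fn: float
    tn: float
    fp: float
    upfront_cost: float
    p_treatment_success: float

    def occupancy(self) -> np.ndarray:
        """Initial state-occupancy vector (TP already resected at t=0)."""
        v = np.zeros(N_STATES)
        v[HealthState.TUMOR_FREE] = self.tn + self.fp
        v[HealthState.UNDIAGNOSED_TUMOR] = self.fn
        v[HealthState.RESECTED] = self.tp * self.p_treatment_success
        v[HealthState.RECURRENCE] = self.tp * (1.0 - self.p_treatment_success)
        return v


def initial_allocation(strategy: StrategySpec, params: ParameterTable) -> InitialAllocation:
    """Split the cohort over TP/FN/TN/FP and price the diagnostic work-up.

    Everyone pays the imaging tariff; true positives additionally pay the
    one-time resection cost; false positives pay the confirmatory work-up
    cost.  Masses follow prevalence x accuracy and sum to one.
    """
    v = params.values()
    p_met = v["p_metastases"]
    tp = p_met * strategy.sensitivity
    fn = p_met * (1.0 - strategy.sensitivity)
    tn = (1.0 - p_met) * strategy.specificity
    fp = (1.0 - p_met) * (1.0 - strategy.specificity)
    upfront = (
        strategy.imaging_cost
        + tp * v["overall_resection_cost"]
        + fp * v["fp_workup_cost"]
    )
    return InitialAllocation(tp, fn, tn, fp, upfront, v["p_treatment_success"])


def transition_matrix(params: ParameterTable, lifetable: LifeTable, age: float) -> np.ndarray:
    """Row-stochastic 5x5 one-cycle transition matrix at the given age."""
    q_annual = annual_mortality(lifetable, age)
    q_bg = 1.0 - (1.0 - q_annual) ** params.cycle_length
    f = transition_flows(params.values(), q_bg, params.recurrence_input)
    M = np.zeros((N_STATES, N_STATES))
    M[HealthState.TUMOR_FREE, HealthState.TUMOR_FREE] = f["tf_stay"]
    M[HealthState.TUMOR_FREE, HealthState.DEATH] = f["tf_death"]
    M[HealthState.UNDIAGNOSED_TUMOR, HealthState.UNDIAGNOSED_TUMOR] = f["u_stay"]
    M[HealthState.UNDIAGNOSED_TUMOR, HealthState.RESECTED] = f["u_to_resected"]
    M[HealthState.UNDIAGNOSED_TUMOR, HealthState.RECURRENCE] = f["u_to_recurrence"]
    M[HealthState.UNDIAGNOSED_TUMOR, HealthState.DEATH] = f["u_death"]
    M[HealthState.RESECTED, HealthState.RESECTED] = f["r_stay"]
    M[HealthState.RESECTED, HealthState.RECURRENCE] = f["r_to_recurrence"]
    M[HealthState.RESECTED, HealthState.DEATH] = f["r_death"]
    M[HealthState.RECURRENCE, HealthState.RECURRENCE] = f["rec_stay"]
    M[HealthState.RECURRENCE, HealthState.DEATH] = f["rec_death"]
    M[HealthState.DEATH, HealthState.DEATH] = 1.0
    rowsum = M.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > _ROW_TOL):
        raise ModelError(f"transition rows deviate from 1: {rowsum}")
    return M


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted accruals of one strategy run."""

    strategy: str
    ages: np.ndarray            # age during each cycle t = 0..horizon
    occupancy: np.ndarray       # (horizon+1, 5); row t = start of cycle t
    disc_costs: np.ndarray      # (horizon,) discounted cost accrued in cycle t
    disc_qalys: np.ndarray      # (horizon,)

    def to_frame(self) -> pd.DataFrame:
        h = len(self.disc_costs)
        costs = np.append(self.disc_costs, 0.0)
        qalys = np.append(self.disc_qalys, 0.0)
        df = pd.DataFrame(self.occupancy, columns=STATE_LABELS)
        df.insert(0, "cycle", np.arange(h + 1))
        df.insert(1, "age", self.ages)
        df["disc_cost"] = costs
        df["disc_qaly"] = qalys
        df["cum_cost"] = np.cumsum(costs)
        df["cum_qaly"] = np.cumsum(qalys)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CEResult:
    """Total expected discounted cost and effectiveness of one strategy."""

    strategy: str
    cost: float
    qaly: float


def run_cohort(
    strategy: StrategySpec, params: ParameterTable, lifetable: LifeTable
) -> tuple[CohortTrace, CEResult]:
    """Propagate the cohort over the horizon and accrue discounted totals.

    Recursion ``v(t+1) = v(t) M(age_t)`` with the cohort aged
    ``start_age + t*cycle_length`` during cycle t.  Cycle-t rewards are the
    occupancy-weighted state costs/utilities discounted by
    ``(1+r)^(-t)``; the delayed-resection charge for undiagnosed patients
    reaching treatment is booked in the cycle the transition leaves.
    """
    h = params.horizon
    cl = params.cycle_length
    alloc = initial_allocation(strategy, params)
    v = alloc.occupancy()
    vals = params.values()
    costs_vec = state_costs(vals, cl)
    utils_vec = state_utilities(vals)
    occupancy = np.zeros((h + 1, N_STATES))
    disc_costs = np.zeros(h)
    disc_qalys = np.zeros(h)
    ages = params.start_age + cl * np.arange(h + 1)

    for t in range(h):
        occupancy[t] = v
        if abs(v.sum() - 1.0) > 1e-9:
            raise ModelError(f"occupancy lost mass at cycle {t}: {v.sum()}")
        M = transition_matrix(params, lifetable, ages[t])
        df = (1.0 + params.discount_rate) ** (-t)
        delayed_flow = v[HealthState.UNDIAGNOSED_TUMOR] * (
            M[HealthState.UNDIAGNOSED_TUMOR, HealthState.RESECTED]
            + M[HealthState.UNDIAGNOSED_TUMOR, HealthState.RECURRENCE]
        )
        cost_t = v @ costs_vec + delayed_flow * vals["delayed_resection_cost"]
        if t == 0:
            cost_t += alloc.upfront_cost
        disc_costs[t] = cost_t * df
        disc_qalys[t] = (v @ utils_vec) * cl * df
        v = v @ M
    occupancy[h] = v

    trace = CohortTrace(strategy.name, ages, occupancy, disc_costs, disc_qalys)
    result = CEResult(strategy.name, float(disc_costs.sum()), float(disc_qalys.sum()))
    return trace, result


def evaluate_strategies(
    params: ParameterTable, lifetable: LifeTable
) -> list[CEResult]:
    """Run every strategy defined in the table; results in table order."""
    return [run_cohort(s, params, lifetable)[1] for s in params.strategy_specs()]
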