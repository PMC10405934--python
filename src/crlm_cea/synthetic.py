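"""Synthetic inputs and an individual-level oracle for the cohort engine.

Everything here exists so the whole pipeline can be exercised without any
external data: random-but-valid parameter tables, Gompertz-style life
tables, and a patient-by-patient microsimulation that replays the exact
decision-tree and transition rules of the cohort model (it samples from
the very matrices :func:`crlm_cea.model.transition_matrix` returns) and
therefore estimates the same expected cost and QALYs up to Monte Carlo
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model as _model
from .lifetable import LifeTable
from .model import HealthState, initial_allocation, state_costs, state_utilities
from .parameters import (
    ParameterSpec,
    ParameterTable,
    StrategySpec,
    default_dispersion,
)

__all__ = [
    "SyntheticSpec",
    "random_parameter_table",
    "synthetic_lifetable",
    "MicrosimResult",
    "microsim_oracle",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs for the random-table generator (all draws seed-deterministic)."""

    seed: int = 0
    n_strategies: int = 3
    cost_scale: float = 20_000.0
    prevalence_range: tuple[float, float] = (0.1, 0.5)
    utility_range: tuple[float, float] = (0.5, 0.95)
    mortality_base: float = 0.01
    mortality_slope: float = 0.09
    horizon_range: tuple[int, int] = (3, 12)
    start_age: float = 68.0


def random_parameter_table(spec: SyntheticSpec) -> ParameterTable:
    """A random parameter table that passes full validation.

    Probabilities land in (0.05, 0.95), utilities inside the configured
    range, costs are positive multiples of ``cost_scale``; dispersions
    follow the same 20%-of-mean default rule as the built-in base case.
    """
    rng = np.random.default_rng(spec.seed)
    u = lambda lo, hi: float(rng.uniform(lo, hi))
    ulo, uhi = spec.utility_range

    def beta_spec(name, lo=0.05, hi=0.95):
        v = u(lo, hi)
        return ParameterSpec(name, v, "beta", default_dispersion(v, "beta"))

    def gamma_spec(name, scale):
        v = float(rng.uniform(0.2, 2.0) * scale)
        return ParameterSpec(name, v, "gamma", default_dispersion(v, "gamma"))

    specs = {}
    strategies = []
    for i in range(spec.n_strategies):
        slug = f"s{i + 1}"
        strategies.append((f"Strategy-{i + 1}", slug))
        specs[f"sens_{slug}"] = beta_spec(f"sens_{slug}", 0.4, 0.95)
        specs[f"spec_{slug}"] = beta_spec(f"spec_{slug}", 0.4, 0.95)
        specs[f"cost_{slug}"] = gamma_spec(f"cost_{slug}", spec.cost_scale / 20.0)
    resection = gamma_spec("overall_resection_cost", spec.cost_scale)
    specs["overall_resection_cost"] = resection
    specs["delayed_resection_cost"] = ParameterSpec(
        "delayed_resection_cost",
        1.3 * resection.base_value,
        "gamma",
        default_dispersion(1.3 * resection.base_value, "gamma"),
    )
    specs["annual_crlm_cost"] = gamma_spec("annual_crlm_cost", 3.0 * spec.cost_scale)
    specs["u_tumor_free"] = ParameterSpec("u_tumor_free", 1.0, "beta", 0.0)
    for name in ("u_post_resection", "u_recurrence", "u_undetected"):
        specs[name] = beta_spec(name, ulo, uhi)
    specs["p_metastases"] = beta_spec("p_metastases", *spec.prevalence_range)
    for name in ("p_treatment_success", "p_recurrence_5y", "p_death_untreated"):
        specs[name] = beta_spec(name)
    specs["p_detect"] = ParameterSpec("p_detect", u(0.3, 1.0), "beta", 0.0)
    specs["fp_workup_cost"] = gamma_spec("fp_workup_cost", spec.cost_scale / 20.0)
    specs["undetected_annual_cost"] = gamma_spec("undetected_annual_cost", spec.cost_scale)
    specs["p_death_recurrence"] = beta_spec("p_death_recurrence")

    return ParameterTable(
        specs,
        tuple(strategies),
        discount_rate=u(0.0, 0.05),
        wtp=u(20_000.0, 200_000.0),
        horizon=int(rng.integers(spec.horizon_range[0], spec.horizon_range[1] + 1)),
        cycle_length=1.0,
        start_age=spec.start_age,
    )


def synthetic_lifetable(
    base_rate: float, slope: float, age_range: tuple[int, int] = (65, 100)
) -> LifeTable:
    """Gompertz-style mortality: q(age) = min(1, base * exp(slope*(age-min)))."""
    if base_rate <= 0:
        raise ValueError("base_rate must be > 0")
    if slope < 0:
        raise ValueError("slope must be >= 0")
    ages = np.arange(age_range[0], age_range[1] + 1)
    qx = np.minimum(1.0, base_rate * np.exp(slope * (ages - ages[0])))
    return LifeTable(ages, qx)


@dataclass(frozen=True)
class MicrosimResult:
    mean_cost: float
    mean_qaly: float
    sem_cost: float
    sem_qaly: float
    n: int


def microsim_oracle(
    strategy: StrategySpec,
    params: ParameterTable,
    lifetable: LifeTable,
    n_patients: int,
    seed: int,
) -> MicrosimResult:
    """Simulate individual patient trajectories under the cohort's rules.

    Initial branches come from :func:`crlm_cea.model.initial_allocation`
    and every cycle samples next states from the rows of
    :func:`crlm_cea.model.transition_matrix` — the identical objects the
    cohort recursion multiplies — with the same discounting (t=0
    undiscounted) and the delayed-resection charge booked in the cycle the
    transition leaves.  Returns sample means and standard errors.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    vals = params.values()
    cl = params.cycle_length
    alloc = initial_allocation(strategy, params)

    # decision-tree branch per patient: TP, FN, TN, FP
    edges = np.cumsum([alloc.tp, alloc.fn, alloc.tn, alloc.fp])
    branch = np.minimum(np.searchsorted(edges, rng.random(n_patients), side="right"), 3)
    state = np.empty(n_patients, dtype=np.int64)
    state[branch == 1] = HealthState.UNDIAGNOSED_TUMOR
    state[branch >= 2] = HealthState.TUMOR_FREE
    is_tp = branch == 0
    success = rng.random(n_patients) < vals["p_treatment_success"]
    state[is_tp & success] = HealthState.RESECTED
    state[is_tp & ~success] = HealthState.RECURRENCE

    cost = np.full(n_patients, strategy.imaging_cost)
    cost[is_tp] += vals["overall_resection_cost"]
    cost[branch == 3] += vals["fp_workup_cost"]
    qaly = np.zeros(n_patients)

    costs_vec = state_costs(vals, cl)
    utils_vec = state_utilities(vals)
    for t in range(params.horizon):
        df = (1.0 + params.discount_rate) ** (-t)
        cost += costs_vec[state] * df
        qaly += utils_vec[state] * cl * df
        M = _model.transition_matrix(params, lifetable, params.start_age + t * cl)
        cum = np.cumsum(M, axis=1)
        draws = rng.random(n_patients)
        new_state = (draws[:, None] > cum[state]).sum(axis=1)
        delayed = (state == HealthState.UNDIAGNOSED_TUMOR) & (
            (new_state == HealthState.RESECTED) | (new_state == HealthState.RECURRENCE)
        )
        cost[delayed] += vals["delayed_resection_cost"] * df
        state = new_state

    return MicrosimResult(
        float(cost.mean()),
        float(qaly.mean()),
        float(cost.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        float(qaly.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        n_patients,
    )
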