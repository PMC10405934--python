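"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) and two-way analyses re-run the full cohort model at
perturbed parameter values; the tornado metric is the incremental net
monetary benefit between the two strategies that lead the base case, which
stays well defined even when dominance makes the ICER itself undefined.
The probabilistic analysis (PSA) redraws every distribution-tagged
parameter per iteration, re-evaluates all strategies through a vectorised
cohort engine, and summarises the winners as cost-effectiveness
acceptability curves (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .econ import icer, nmb
from .lifetable import LifeTable, annual_mortality
from .model import CEResult, evaluate_strategies, transition_flows
from .parameters import ParameterTable, make_distribution

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "one_way",
    "tornado",
    "two_way",
    "run_psa",
    "ceac",
    "acceptability_at",
    "DEFAULT_WTP_GRID",
]

DEFAULT_WTP_GRID = np.arange(0, 200_001, 5_000)


class SensitivityError(ValueError):
    """Invalid sensitivity-analysis request (e.g. range outside legal bounds)."""


# ---------------------------------------------------------------------------
# Deterministic analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    metric_low: float
    metric_high: float
    spread: float
    icer_low: float | None = None
    icer_high: float | None = None


def _legal_bounds(table: ParameterTable, name: str) -> tuple[float, float]:
    family = table.spec(name).dist_family
    if family == "beta":
        return 0.0, 1.0
    return 0.0, float("inf")


def _base_pair(table: ParameterTable, lifetable: LifeTable, wtp: float) -> tuple[str, str]:
    """The two strategies leading the base case by NMB (the tornado focus)."""
    results = evaluate_strategies(table, lifetable)
    ranked = sorted(results, key=lambda r: (-nmb(r, wtp), r.strategy))
    if len(ranked) < 2:
        raise SensitivityError("tornado needs at least two strategies")
    return ranked[0].strategy, ranked[1].strategy


def _pair_metric(
    table: ParameterTable, lifetable: LifeTable, wtp: float, pair: tuple[str, str]
) -> tuple[float, float | None]:
    results = {r.strategy: r for r in evaluate_strategies(table, lifetable)}
    best, second = results[pair[0]], results[pair[1]]
    metric = nmb(best, wtp) - nmb(second, wtp)
    pairwise = icer(best, second)
    return metric, pairwise.icer


def one_way(
    param_name: str,
    low: float,
    high: float,
    table: ParameterTable,
    lifetable: LifeTable,
    wtp: float | None = None,
    pair: tuple[str, str] | None = None,
) -> TornadoEntry:
    """Re-run the model with one parameter at ``low`` and at ``high``.

    Records the incremental NMB between the base-case leading pair at both
    ends (and the pairwise ICER where defined); the spread is the absolute
    difference of the two metric values.
    """
    if param_name not in table:
        raise SensitivityError(f"unknown parameter {param_name!r}")
    if low > high:
        raise SensitivityError(f"{param_name}: low {low} > high {high}")
    lo_b, hi_b = _legal_bounds(table, param_name)
    if low < lo_b or high > hi_b:
        raise SensitivityError(
            f"{param_name}: range [{low}, {high}] outside legal bounds [{lo_b}, {hi_b}]"
        )
    wtp = table.wtp if wtp is None else wtp
    if pair is None:
        pair = _base_pair(table, lifetable, wtp)
    m_low, i_low = _pair_metric(table.replace_values(**{param_name: low}), lifetable, wtp, pair)
    m_high, i_high = _pair_metric(table.replace_values(**{param_name: high}), lifetable, wtp, pair)
    return TornadoEntry(
        param_name, low, high, m_low, m_high, abs(m_high - m_low), i_low, i_high
    )


def tornado(
    table: ParameterTable,
    lifetable: LifeTable,
    range_frac: float = 0.25,
    params: list[str] | None = None,
    wtp: float | None = None,
    pair: tuple[str, str] | None = None,
) -> list[TornadoEntry]:
    """One-way analysis over all sampled parameters, sorted by spread.

    Default range is ±``range_frac`` of each base value, clipped to the
    parameter's legal bounds.  ``pair`` fixes the strategy comparison the
    metric tracks; by default the two leaders of the base case.
    """
    wtp = table.wtp if wtp is None else wtp
    if pair is None:
        pair = _base_pair(table, lifetable, wtp)
    names = params if params is not None else [s.name for s in table.sampled_specs()]
    entries = []
    for name in names:
        base = table[name]
        lo_b, hi_b = _legal_bounds(table, name)
        low = max(base * (1.0 - range_frac), lo_b)
        high = min(base * (1.0 + range_frac), hi_b)
        entries.append(one_way(name, low, high, table, lifetable, wtp, pair))
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "metric_low": e.metric_low,
                "metric_high": e.metric_high,
                "spread": e.spread,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
            }
            for e in entries
        ]
    )


def two_way(
    param_x: str,
    param_y: str,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    table: ParameterTable,
    lifetable: LifeTable,
    wtp: float | None = None,
) -> pd.DataFrame:
    """Winning strategy (max NMB) on a 2-D parameter grid.

    Returns a frame indexed by ``grid_y`` with one column per ``grid_x``
    value; cell (y, x) holds the name of the strategy with the highest net
    monetary benefit when both parameters are set accordingly.
    """
    wtp = table.wtp if wtp is None else wtp
    for name, grid in ((param_x, grid_x), (param_y, grid_y)):
        lo_b, hi_b = _legal_bounds(table, name)
        g = np.asarray(grid, dtype=float)
        if g.min() < lo_b or g.max() > hi_b:
            raise SensitivityError(f"{name}: grid leaves legal bounds [{lo_b}, {hi_b}]")
    winners = np.empty((len(grid_y), len(grid_x)), dtype=object)
    for i, y in enumerate(grid_y):
        for j, x in enumerate(grid_x):
            t = table.replace_values(**{param_x: float(x), param_y: float(y)})
            results = evaluate_strategies(t, lifetable)
            winners[i, j] = max(results, key=lambda r: (nmb(r, wtp), r.strategy)).strategy
    return pd.DataFrame(winners, index=np.asarray(grid_y), columns=np.asarray(grid_x))


# ---------------------------------------------------------------------------
# Probabilistic analysis
# ---------------------------------------------------------------------------


def _run_batch(
    values: dict[str, np.ndarray | float],
    table: ParameterTable,
    lifetable: LifeTable,
    slug: str,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cohort engine: one strategy, ``n`` parameter draws at once.

    Mirrors :func:`crlm_cea.model.run_cohort` exactly (same transition
    flows, same accrual and discounting conventions); a regression test
    pins the two to 1e-9 agreement on random draws.
    """
    g = lambda k: np.broadcast_to(np.asarray(values[k], dtype=float), (n,))
    sens, spec, img_cost = g(f"sens_{slug}"), g(f"spec_{slug}"), g(f"cost_{slug}")
    p_met = g("p_metastases")
    p_succ = g("p_treatment_success")
    tp = p_met * sens
    fn = p_met * (1.0 - sens)
    tn = (1.0 - p_met) * spec
    fp = (1.0 - p_met) * (1.0 - spec)

    tf = tn + fp
    und = fn.copy()
    res = tp * p_succ
    rec = tp * (1.0 - p_succ)

    total_cost = img_cost + tp * g("overall_resection_cost") + fp * g("fp_workup_cost")
    total_qaly = np.zeros(n)
    cl = table.cycle_length
    u_tf, u_und = g("u_tumor_free"), g("u_undetected")
    u_post, u_rec = g("u_post_resection"), g("u_recurrence")
    c_und, c_rec = g("undetected_annual_cost") * cl, g("annual_crlm_cost") * cl
    c_delayed = g("delayed_resection_cost")

    for t in range(table.horizon):
        q_annual = annual_mortality(lifetable, table.start_age + t * cl)
        q_bg = 1.0 - (1.0 - q_annual) ** cl
        f = transition_flows(values, q_bg, table.recurrence_input)
        df = (1.0 + table.discount_rate) ** (-t)
        delayed_flow = und * (f["u_to_resected"] + f["u_to_recurrence"])
        total_cost += df * (und * c_und + rec * c_rec + delayed_flow * c_delayed)
        total_qaly += df * cl * (tf * u_tf + und * u_und + res * u_post + rec * u_rec)
        tf, und, res, rec = (
            tf * f["tf_stay"],
            und * f["u_stay"],
            und * f["u_to_resected"] + res * f["r_stay"],
            und * f["u_to_recurrence"] + res * f["r_to_recurrence"] + rec * f["rec_stay"],
        )
    return total_cost, total_qaly


@dataclass
class PSAResult:
    """Per-iteration strategy outcomes of a probabilistic sensitivity analysis."""

    n: int
    seed: int
    strategies: tuple[str, ...]
    costs: np.ndarray  # (n, n_strategies)
    qalys: np.ndarray  # (n, n_strategies)
    wtp: float

    def scatter_frame(self) -> pd.DataFrame:
        """Long-format (iteration, strategy, cost, qaly) table."""
        frames = [
            pd.DataFrame(
                {
                    "iteration": np.arange(self.n),
                    "strategy": name,
                    "cost": self.costs[:, j],
                    "qaly": self.qalys[:, j],
                }
            )
            for j, name in enumerate(self.strategies)
        ]
        return pd.concat(frames, ignore_index=True)


def run_psa(
    table: ParameterTable, lifetable: LifeTable, n: int, seed: int
) -> PSAResult:
    """Monte Carlo PSA: redraw all distribution-tagged parameters ``n`` times.

    Parameters are sampled once per iteration in table order from a single
    seeded generator and shared across strategies, so results are
    independent of strategy evaluation order and bit-identical across
    reruns with the same seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray | float] = dict(table.values())
    for spec in table.specs.values():
        if spec.sampled:
            values[spec.name] = make_distribution(spec).rvs(n, random_state=rng)
    k = len(table.strategies)
    costs = np.empty((n, k))
    qalys = np.empty((n, k))
    for j, (_, slug) in enumerate(table.strategies):
        costs[:, j], qalys[:, j] = _run_batch(values, table, lifetable, slug, n)
    names = tuple(label for label, _ in table.strategies)
    return PSAResult(n, seed, names, costs, qalys, table.wtp)


def _winners(psa: PSAResult, wtp: float) -> np.ndarray:
    """Index of the max-NMB strategy per iteration, ties to the
    lexicographically first name (the same rule as the deterministic path)."""
    lex = np.argsort(np.array(psa.strategies))
    nmb_lex = wtp * psa.qalys[:, lex] - psa.costs[:, lex]
    return lex[np.argmax(nmb_lex, axis=1)]


def acceptability_at(psa: PSAResult, wtp: float) -> pd.Series:
    """Fraction of iterations each strategy is cost-effective at ``wtp``."""
    win = _winners(psa, wtp)
    frac = np.bincount(win, minlength=len(psa.strategies)) / psa.n
    return pd.Series(frac, index=list(psa.strategies), name=f"wtp={wtp:g}")


def ceac(psa: PSAResult, wtp_grid: np.ndarray = DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a WTP grid.

    Rows are WTP values, columns strategies; each row sums to one.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    rows = [acceptability_at(psa, w).to_numpy() for w in grid]
    df = pd.DataFrame(rows, index=grid, columns=list(psa.strategies))
    df.index.name = "wtp"
    return df
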