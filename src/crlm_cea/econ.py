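"""Incremental cost-effectiveness: ICERs, dominance, frontier, NMB.

The ICER of a strategy against a comparator is (e1-e0)/(q1-q0) — the extra
cost per extra QALY.  A strategy that is cheaper *and* more effective
dominates; the efficiency frontier removes strictly and extendedly
dominated options so the surviving ICERs increase with cost.  All cost/
effect ties are broken by lexicographic strategy name so every analysis
(including the PSA winner count) is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import CEResult

__all__ = ["ICERResult", "FrontierEntry", "icer", "nmb", "efficiency_frontier", "rank_table"]


@dataclass(frozen=True)
class ICERResult:
    new: str
    ref: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    flag: str  # "icer" | "dominant" | "dominated" | "undefined" | "tie"


def icer(new: CEResult, ref: CEResult) -> ICERResult:
    """Pairwise ICER of ``new`` against ``ref`` with dominance flags.

    ``dominant``: new is cheaper and more effective.  ``dominated``: dearer
    and less effective.  Equal effects make the ratio undefined (``tie`` if
    the costs match too; otherwise the cheaper strategy is preferred).
    """
    dc = new.cost - ref.cost
    dq = new.qaly - ref.qaly
    if dq == 0.0:
        flag = "tie" if dc == 0.0 else "undefined"
        return ICERResult(new.strategy, ref.strategy, dc, dq, None, flag)
    if dc < 0.0 and dq > 0.0:
        return ICERResult(new.strategy, ref.strategy, dc, dq, None, "dominant")
    if dc > 0.0 and dq < 0.0:
        return ICERResult(new.strategy, ref.strategy, dc, dq, None, "dominated")
    return ICERResult(new.strategy, ref.strategy, dc, dq, dc / dq, "icer")


def nmb(result: CEResult, wtp: float) -> float:
    """Net monetary benefit at the given willingness-to-pay: wtp*q - e."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * result.qaly - result.cost


@dataclass(frozen=True)
class FrontierEntry:
    result: CEResult
    label: str  # "frontier" | "dominated" | "extended"
    icer: float | None  # vs the previous frontier point (None for the cheapest)


def efficiency_frontier(results: list[CEResult]) -> list[FrontierEntry]:
    """Label each strategy on/off the efficiency frontier.

    Strictly dominated: some other strategy is at least as cheap and at
    least as effective, strictly better in one (exact ties resolved in
    favour of the lexicographically first name).  Extended dominance: the
    standard sweep removing cost-sorted interior points whose incremental
    ICER is not strictly increasing.  Input order does not matter.
    """
    if not results:
        raise ValueError("need at least one strategy")
    order = sorted(results, key=lambda r: (r.cost, -r.qaly, r.strategy))
    labels: dict[str, str] = {}
    for r in order:
        dominated = any(
            (s.cost <= r.cost and s.qaly >= r.qaly and (s.cost < r.cost or s.qaly > r.qaly))
            or (s.cost == r.cost and s.qaly == r.qaly and s.strategy < r.strategy)
            for s in order
            if s.strategy != r.strategy
        )
        labels[r.strategy] = "dominated" if dominated else "frontier"

    frontier = [r for r in order if labels[r.strategy] == "frontier"]
    # extended-dominance sweep: drop interior points until ICERs increase
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            prev_i = _pair_icer(frontier[i], frontier[i - 1])
            next_i = _pair_icer(frontier[i + 1], frontier[i])
            if next_i <= prev_i:
                labels[frontier[i].strategy] = "extended"
                frontier.pop(i)
                changed = True
                break

    icers: dict[str, float | None] = {frontier[0].strategy: None}
    for prev, cur in zip(frontier, frontier[1:]):
        icers[cur.strategy] = _pair_icer(cur, prev)
    return [FrontierEntry(r, labels[r.strategy], icers.get(r.strategy)) for r in order]


def _pair_icer(new: CEResult, ref: CEResult) -> float:
    dq = new.qaly - ref.qaly
    if dq == 0.0:
        return float("inf")
    return (new.cost - ref.cost) / dq


def rank_table(results: list[CEResult]) -> pd.DataFrame:
    """Cost-effectiveness ranking table (strategy, cost, ΔC, QALY, ΔE, ICER/flag)."""
    entries = efficiency_frontier(results)
    rows = []
    prev = None
    for e in entries:
        r = e.result
        rows.append(
            {
                "strategy": r.strategy,
                "cost": r.cost,
                "incr_cost": r.cost - prev.cost if prev else float("nan"),
                "qaly": r.qaly,
                "incr_qaly": r.qaly - prev.qaly if prev else float("nan"),
                "icer": e.icer if e.label == "frontier" else float("nan"),
                "status": e.label,
            }
        )
        prev = r
    return pd.DataFrame(rows)


def write_rank_table(results: list[CEResult], path: str | Path) -> None:
    rank_table(results).to_csv(path, index=False)
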