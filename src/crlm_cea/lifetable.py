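"""Age-dependent background (other-cause) mortality.

The Markov model needs an annual probability of death from any non-tumour
cause for each attained age.  A bundled all-population table covering ages
65-100 ships with the package (see ``data/lifetable_us2015_synthetic.csv``);
ages past the covered range are treated as certain death, which closes the
model for arbitrarily long horizons.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTableError",
    "LifeTable",
    "annual_mortality",
    "load_lifetable",
    "write_lifetable",
    "bundled_lifetable",
]

_BUNDLED_NAME = "lifetable_us2015_synthetic.csv"


class LifeTableError(ValueError):
    """Invalid life-table input."""


@dataclass(frozen=True)
class LifeTable:
    """Map from integer age to the annual death probability q(age)."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.size == 0:
            raise LifeTableError("life table is empty")
        if ages.size != qx.size:
            raise LifeTableError("age and qx columns differ in length")
        diffs = np.diff(ages)
        if np.any(diffs != 1):
            gap_at = int(ages[np.argmax(diffs != 1)])
            raise LifeTableError(f"age coverage not contiguous after age {gap_at}")
        bad = (qx < 0.0) | (qx > 1.0)
        if np.any(bad):
            age_bad = int(ages[np.argmax(bad)])
            raise LifeTableError(f"qx at age {age_bad} outside [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])


def annual_mortality(table: LifeTable, age: float) -> float:
    """Annual background death probability at the given (floored) age.

    Ages beyond the covered range return 1.0 — the cohort cannot outlive
    the table; ages below it are an error.
    """
    a = int(np.floor(age))
    if a < table.min_age:
        raise LifeTableError(f"age {age} below covered range (min {table.min_age})")
    if a > table.max_age:
        return 1.0
    return float(table.qx[a - table.min_age])


def load_lifetable(path: str | Path) -> LifeTable:
    """Read an ``age,qx`` CSV (lines starting with '#' are comments)."""
    df = pd.read_csv(path, comment="#")
    for col in ("age", "qx"):
        if col not in df.columns:
            raise LifeTableError(f"{path}: missing column {col!r}")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def write_lifetable(table: LifeTable, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("age,qx\n")
        for a, q in zip(table.ages, table.qx):
            fh.write(f"{int(a)},{q:.6f}\n")


def bundled_lifetable() -> LifeTable:
    """The life table shipped with the package (ages 65-100)."""
    ref = resources.files("crlm_cea").joinpath(f"data/{_BUNDLED_NAME}")
    with resources.as_file(ref) as path:
        return load_lifetable(path)
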