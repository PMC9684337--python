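"""Age-dependent background mortality.

A :class:`LifeTable` maps contiguous integer ages to annual death
probabilities q(age).  Tables can be read from a two-column CSV
(``age,qx``) or synthesized from a Gompertz–Makeham hazard so the model is
runnable without any external mortality download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "LifeTableError", "read_lifetable", "write_lifetable",
           "synthesize_lifetable"]


class LifeTableError(ValueError):
    """Raised for malformed lifetable inputs."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age) for contiguous integer ages.

    Ages beyond the last tabulated row are treated as certain death
    (q = 1), which defines the terminal age that bounds lifetime horizons.
    """

    start_age: int
    qx: tuple[float, ...]

    def __post_init__(self):
        if not self.qx:
            raise LifeTableError("lifetable must contain at least one age")
        for i, q in enumerate(self.qx):
            if not 0.0 <= q <= 1.0:
                raise LifeTableError(
                    f"q at age {self.start_age + i} must be in [0, 1], got {q}"
                )
        object.__setattr__(self, "qx", tuple(float(q) for q in self.qx))

    @property
    def ages(self) -> range:
        return range(self.start_age, self.start_age + len(self.qx))

    @property
    def terminal_age(self) -> int:
        """First age at which death is certain."""
        for i, q in enumerate(self.qx):
            if q >= 1.0:
                return self.start_age + i
        return self.start_age + len(self.qx)

    def annual_q(self, age: int) -> float:
        """Annual death probability at an integer age (1 beyond the table)."""
        if age < self.start_age:
            raise LifeTableError(
                f"age {age} below lifetable start age {self.start_age}"
            )
        i = age - self.start_age
        return self.qx[i] if i < len(self.qx) else 1.0

    def life_expectancy(self, from_age: int | None = None) -> float:
        """Curtate life expectancy by simple lifetable summation."""
        start = self.start_age if from_age is None else from_age
        survival = 1.0
        total = 0.0
        for age in range(start, self.terminal_age + 1):
            survival *= 1.0 - self.annual_q(age)
            total += survival
        return total


def read_lifetable(path: str | Path) -> LifeTable:
    """Read a lifetable from a CSV with header ``age,qx``.

    Validates contiguous ascending integer ages and probabilities in
    [0, 1]; errors name the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["age", "qx"]:
        raise LifeTableError(
            f"expected columns ['age', 'qx'], got {list(df.columns)}"
        )
    if df.empty:
        raise LifeTableError("lifetable file has no rows")
    ages = df["age"].to_numpy()
    if not np.issubdtype(ages.dtype, np.integer):
        raise LifeTableError("ages must be integers")
    for row, (prev, cur) in enumerate(zip(ages[:-1], ages[1:]), start=2):
        if cur != prev + 1:
            raise LifeTableError(f"row {row}: age {cur} not contiguous after {prev}")
    for row, q in enumerate(df["qx"], start=1):
        if not 0.0 <= q <= 1.0:
            raise LifeTableError(f"row {row}: qx {q} outside [0, 1]")
    return LifeTable(start_age=int(ages[0]), qx=tuple(float(q) for q in df["qx"]))


def write_lifetable(table: LifeTable, path: str | Path) -> None:
    """Write a lifetable as ``age,qx`` CSV (round-trips through read)."""
    pd.DataFrame({"age": list(table.ages), "qx": table.qx}).to_csv(
        path, index=False, float_format="%.17g")


def synthesize_lifetable(
    makeham_a: float = 5e-5,
    gompertz_b: float = 3e-5,
    gompertz_c: float = 1.094,
    max_age: int = 110,
) -> LifeTable:
    """Deterministic synthetic lifetable from a Gompertz–Makeham hazard.

    q(age) = 1 - exp(-(a + b*c**age)), with q(max_age) pinned to 1.  The
    defaults approximate a modern Western European schedule (implied life
    expectancy at birth in the low 80s) and stand in for national
    statistics when no table file is supplied.
    """
    if makeham_a < 0:
        raise LifeTableError("makeham_a must be >= 0")
    if gompertz_b <= 0:
        raise LifeTableError("gompertz_b must be > 0")
    if gompertz_c <= 1:
        raise LifeTableError("gompertz_c must be > 1")
    if max_age < 1:
        raise LifeTableError("max_age must be >= 1")
    ages = np.arange(0, max_age + 1)
    hazard = makeham_a + gompertz_b * gompertz_c ** ages
    qx = 1.0 - np.exp(-hazard)
    qx[-1] = 1.0
    return LifeTable(start_age=0, qx=tuple(qx))
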