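"""Uniform-design dose tables: U6(6^5) level matrix -> per-group doses.

A uniform design spreads a small number of experimental runs evenly over a
multi-factor dose space. Each factor gets ``n_levels`` equally spaced
levels between its dose range endpoints (inclusive):

    dose(level) = dose_min + (level - 1) * (dose_max - dose_min) / (n_levels - 1)

The packaged U6(6^5) matrix assigns each of 6 runs one level per factor;
every factor column is a permutation of 1..6, so each dose level of each
factor is used exactly once across the 6 groups.

The built-in five-factor dose ranges for the formula's marker compounds
are Syringin 10-60, Salidroside 10-85, Kaempferol 5-40, Schisandrol A
5-100, Cimidahurinine 1-41 (mg/kg). Note the Salidroside range: the
published dose table is only consistent with six equal levels on 10-85
even though the accompanying text states 25-85; the table is followed and
the discrepancy logged when these defaults are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("formula_nettarget")

#: U6(6^5) level matrix, rows = runs (groups A, B, C, D, E, Y), columns =
#: factors. Each column is a permutation of 1..6.
U6_LEVEL_MATRIX = np.array(
    [
        [1, 2, 3, 4, 6],
        [2, 4, 6, 1, 5],
        [3, 6, 2, 5, 4],
        [4, 1, 5, 2, 3],
        [5, 3, 1, 6, 2],
        [6, 5, 4, 3, 1],
    ],
    dtype=int,
)

U6_GROUP_LABELS = (
    "Uniform 1 (A)",
    "Uniform 2 (B)",
    "Uniform 3 (C)",
    "Uniform 4 (D)",
    "Uniform 5 (E)",
    "Uniform 6 (Y)",
)


@dataclass(frozen=True)
class FactorSpec:
    """One dose factor: name, range in mg/kg, number of levels."""

    name: str
    dose_min: float
    dose_max: float
    n_levels: int = 6

    def __post_init__(self) -> None:
        if not self.dose_min < self.dose_max:
            raise ValueError(
                f"factor {self.name!r}: dose_min must be < dose_max"
            )
        if self.n_levels < 2:
            raise ValueError(f"factor {self.name!r}: n_levels must be >= 2")

    def dose_at(self, level: int) -> float:
        if not 1 <= level <= self.n_levels:
            raise ValueError(
                f"factor {self.name!r}: level {level} outside "
                f"1..{self.n_levels}"
            )
        step = (self.dose_max - self.dose_min) / (self.n_levels - 1)
        return self.dose_min + (level - 1) * step


#: Default factor ranges for the formula's five marker compounds.
CB_FACTORS = (
    FactorSpec("Syringin", 10.0, 60.0),
    FactorSpec("Salidroside", 10.0, 85.0),
    FactorSpec("Kaempferol", 5.0, 40.0),
    FactorSpec("Schisandrol A", 5.0, 100.0),
    FactorSpec("Cimidahurinine", 1.0, 41.0),
)


@dataclass
class DoseDesign:
    """A realized dose design: level matrix plus the mapped dose matrix."""

    factors: tuple[FactorSpec, ...]
    level_matrix: np.ndarray
    dose_matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Dose table with one row per run, one column per factor."""
        if self.level_matrix.shape == (6, 5):
            index = list(U6_GROUP_LABELS)
        else:
            index = [f"Run {i + 1}" for i in range(self.level_matrix.shape[0])]
        return pd.DataFrame(
            self.dose_matrix,
            index=index,
            columns=[f.name for f in self.factors],
        )


def make_dose_table(
    factors,
    level_matrix="builtin_u6",
) -> DoseDesign:
    """Map a level matrix and per-factor ranges to a dose table.

    ``level_matrix`` is either an integer matrix (runs x factors, entries
    in 1..n_levels) or the string "builtin_u6" for the packaged 6x5
    U6(6^5) matrix. A column that is not a permutation of 1..n_levels
    (when runs == n_levels) is logged as a warning, not rejected —
    partial or replicated designs are legitimate inputs.
    """
    factors = tuple(factors)
    if isinstance(level_matrix, str):
        if level_matrix != "builtin_u6":
            raise ValueError(f"unknown level matrix token {level_matrix!r}")
        matrix = U6_LEVEL_MATRIX.copy()
        if list(factors) == list(CB_FACTORS):
            logger.warning(
                "Salidroside: using range 10-85 mg/kg implied by the "
                "published dose table; the accompanying text states 25-85"
            )
    else:
        matrix = np.asarray(level_matrix, dtype=int)
    if matrix.ndim != 2 or matrix.shape[1] != len(factors):
        raise ValueError(
            f"level matrix has shape {matrix.shape}, expected "
            f"(runs, {len(factors)})"
        )
    n_runs = matrix.shape[0]
    dose = np.zeros(matrix.shape, dtype=float)
    for j, factor in enumerate(factors):
        col = matrix[:, j]
        if col.min() < 1 or col.max() > factor.n_levels:
            raise ValueError(
                f"factor {factor.name!r}: level out of range "
                f"1..{factor.n_levels} in column {j}"
            )
        if n_runs == factor.n_levels and sorted(col) != list(
            range(1, factor.n_levels + 1)
        ):
            logger.warning(
                "factor %r: level column is not a permutation of 1..%d",
                factor.name,
                factor.n_levels,
            )
        for i in range(n_runs):
            dose[i, j] = factor.dose_at(int(col[i]))
    return DoseDesign(factors=factors, level_matrix=matrix, dose_matrix=dose)
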