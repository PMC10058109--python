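"""Three-level orthogonal-array designs.

A Taguchi orthogonal array assigns each of a set of factors one of three
levels per experimental run such that every level — and every pair of
levels across any two factors — occurs equally often.  This module builds
the canonical 27-run array for seven three-level factors (L27(3^7)),
checks balance/orthogonality, and decodes level indices (1-based, Taguchi
convention) to physical settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignMatrix",
    "OrthogonalityReport",
    "PULLULAN_FACTORS",
    "L27_ARRAY",
    "build_l27",
    "check_orthogonality",
    "read_design_csv",
]


@dataclass(frozen=True)
class Factor:
    """A controllable variable with exactly three ascending levels.

    Parameters
    ----------
    name : str
        Identifier, unique within a design.
    unit : str
        Physical unit label (e.g. ``"g/L"``, ``"pH"``, ``"h"``); metadata only.
    levels : tuple of float
        The three physical settings, strictly increasing.
    """

    name: str
    unit: str
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError(f"factor {self.name!r}: exactly 3 levels required")
        lo, mid, hi = self.levels
        if not (lo < mid < hi):
            raise ValueError(f"factor {self.name!r}: levels must be strictly increasing")

    def decode(self, index: int) -> float:
        """Physical value for a 1-based level index."""
        if index not in (1, 2, 3):
            raise KeyError(f"factor {self.name!r}: level index {index} not in 1..3")
        return self.levels[index - 1]

    def encode(self, value: float, *, rtol: float = 1e-9) -> int:
        """1-based level index whose physical value matches ``value``."""
        for i, lv in enumerate(self.levels, start=1):
            if np.isclose(value, lv, rtol=rtol, atol=1e-12):
                return i
        raise KeyError(f"factor {self.name!r}: {value} is not one of its levels {self.levels}")


# The seven fermentation-medium factors of the pullulan case study.
PULLULAN_FACTORS: tuple[Factor, ...] = (
    Factor("sucrose", "g/L", (40.0, 50.0, 60.0)),
    Factor("K2HPO4", "g/L", (4.0, 5.0, 6.0)),
    Factor("NaCl", "g/L", (0.5, 1.0, 1.5)),
    Factor("MgSO4", "g/L", (0.1, 0.2, 0.3)),
    Factor("yeast_extract", "g/L", (1.0, 2.0, 3.0)),
    Factor("pH", "pH", (5.5, 6.5, 7.5)),
    Factor("incubation_time", "h", (48.0, 72.0, 96.0)),
)

# Canonical L27(3^7) column assignment (1-based level indices), fixed to
# the published run order L1..L27 of the case study.
L27_ARRAY: np.ndarray = np.array(
    [
        [1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 2, 2, 2],
        [1, 1, 1, 1, 3, 3, 3],
        [1, 2, 2, 2, 1, 1, 1],
        [1, 2, 2, 2, 2, 2, 2],
        [1, 2, 2, 2, 3, 3, 3],
        [1, 3, 3, 3, 1, 1, 1],
        [1, 3, 3, 3, 2, 2, 2],
        [1, 3, 3, 3, 3, 3, 3],
        [2, 1, 2, 3, 1, 2, 3],
        [2, 1, 2, 3, 2, 3, 1],
        [2, 1, 2, 3, 3, 1, 2],
        [2, 2, 3, 1, 1, 2, 3],
        [2, 2, 3, 1, 2, 3, 1],
        [2, 2, 3, 1, 3, 1, 2],
        [2, 3, 1, 2, 1, 2, 3],
        [2, 3, 1, 2, 2, 3, 1],
        [2, 3, 1, 2, 3, 1, 2],
        [3, 1, 3, 2, 1, 3, 2],
        [3, 1, 3, 2, 2, 1, 3],
        [3, 1, 3, 2, 3, 2, 1],
        [3, 2, 1, 3, 1, 3, 2],
        [3, 2, 1, 3, 2, 1, 3],
        [3, 2, 1, 3, 3, 2, 1],
        [3, 3, 2, 1, 1, 3, 2],
        [3, 3, 2, 1, 2, 1, 3],
        [3, 3, 2, 1, 3, 2, 1],
    ],
    dtype=np.int64,
)


class DesignMatrix:
    """runs x factors table of 1-based level indices with a physical decode.

    Rows are experimental runs; ``levels[i, j]`` is the level index of
    factor ``j`` in run ``i``.
    """

    def __init__(
        self,
        factors: Sequence[Factor],
        levels: np.ndarray,
        run_ids: Sequence[str] | None = None,
    ) -> None:
        factors = list(factors)
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique within a design")
        levels = np.asarray(levels, dtype=np.int64)
        if levels.ndim != 2 or levels.shape[1] != len(factors):
            raise ValueError("levels must be (n_runs, n_factors)")
        if levels.size and not np.isin(levels, (1, 2, 3)).all():
            raise ValueError("level indices must be in {1, 2, 3}")
        self.factors = factors
        self.levels = levels
        if run_ids is None:
            run_ids = [f"L{i + 1}" for i in range(levels.shape[0])]
        if len(run_ids) != levels.shape[0]:
            raise ValueError("run_ids length must equal number of runs")
        self.run_ids = list(run_ids)

    # -- basic views ---------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    def __len__(self) -> int:
        return self.n_runs

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"no factor named {name!r}")

    def column(self, name: str) -> np.ndarray:
        """Level-index column for one factor."""
        return self.levels[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Level indices as a DataFrame indexed by run id."""
        return pd.DataFrame(self.levels, index=pd.Index(self.run_ids, name="run"), columns=self.names)

    def decoded(self) -> pd.DataFrame:
        """Physical settings as a DataFrame indexed by run id."""
        cols = {
            f.name: np.asarray(f.levels)[self.levels[:, j] - 1]
            for j, f in enumerate(self.factors)
        }
        return pd.DataFrame(cols, index=pd.Index(self.run_ids, name="run"))


def build_l27(factors: Sequence[Factor]) -> DesignMatrix:
    """The canonical 27-run orthogonal array for seven three-level factors.

    Raises
    ------
    ValueError
        If ``factors`` does not contain exactly seven factors.
    """
    factors = list(factors)
    if len(factors) != 7:
        raise ValueError(f"L27(3^7) requires exactly 7 factors, got {len(factors)}")
    return DesignMatrix(factors, L27_ARRAY.copy())


@dataclass
class OrthogonalityReport:
    """Balance diagnostics for a three-level design.

    ``level_counts`` maps factor -> counts of levels 1..3; ``pair_counts``
    maps (factor_a, factor_b) -> 3x3 joint count matrix.
    """

    level_counts: pd.DataFrame
    pair_counts: dict[tuple[str, str], np.ndarray]
    passed: bool


def check_orthogonality(design: DesignMatrix) -> OrthogonalityReport:
    """Check single-column level balance and pairwise combination balance.

    Passes iff every column carries each level equally often and every
    unordered column pair carries each of the nine level combinations
    equally often.
    """
    if design.n_runs == 0:
        raise ValueError("design has no runs")
    counts = {}
    ok = True
    for name in design.names:
        c = np.bincount(design.column(name), minlength=4)[1:4]
        counts[name] = c
        ok = ok and (c == c[0]).all()
    level_counts = pd.DataFrame(counts, index=pd.Index([1, 2, 3], name="level")).T
    pair_counts: dict[tuple[str, str], np.ndarray] = {}
    for a, b in combinations(design.names, 2):
        joint = np.zeros((3, 3), dtype=np.int64)
        for la, lb in zip(design.column(a), design.column(b)):
            joint[la - 1, lb - 1] += 1
        pair_counts[(a, b)] = joint
        ok = ok and (joint == joint.flat[0]).all()
    return OrthogonalityReport(level_counts, pair_counts, bool(ok))


def read_design_csv(path: str | Path) -> DesignMatrix:
    """Read a design from ``run,<factor>,...`` CSV of physical values.

    Levels are inferred per column as the sorted distinct values; a column
    with a number of distinct values other than three is rejected.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "run":
        raise ValueError(f"{path}: first column must be 'run', got {df.columns[0]!r}")
    factors = []
    idx = np.empty((len(df), len(df.columns) - 1), dtype=np.int64)
    for j, col in enumerate(df.columns[1:]):
        values = np.sort(df[col].unique())
        if len(values) != 3:
            raise ValueError(
                f"{path}: column {col!r} has {len(values)} distinct values, expected 3"
            )
        factors.append(Factor(col, "", tuple(float(v) for v in values)))
        idx[:, j] = np.searchsorted(values, df[col].to_numpy()) + 1
    return DesignMatrix(factors, idx, run_ids=[str(r) for r in df["run"]])
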