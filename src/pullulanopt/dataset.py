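"""The pullulan fermentation case-study fixture and tabular I/O.

The study's complete dataset — 27 orthogonal-array runs, each fermented in
three replicate blocks (81 observations) — is shipped in-repo.  The source
table prints, per observation, the regression-tree fitted value and its
residual; the raw replicate responses are therefore recovered as
``fitted + residual`` and verified against the printed per-run mean and
standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .design import DesignMatrix, read_design_csv

__all__ = [
    "ReplicatedResponse",
    "CaseStudyTable",
    "reconstruct_observations",
    "load_fixture",
    "read_experiment",
    "responses_from_observations",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class ReplicatedResponse:
    """Replicate response values of one run (pullulan, % w/v)."""

    run_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"run {self.run_id}: no replicate values")
        if any(v <= 0 for v in self.values):
            raise ValueError(f"run {self.run_id}: responses must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1 divisor)."""
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


@dataclass
class CaseStudyTable:
    """The full printed experiment.

    Attributes
    ----------
    design : DesignMatrix
        The 27-run orthogonal array.
    runs : pandas.DataFrame
        Printed per-run summaries (index = run id): ``mean``, ``sd``,
        ``sn``, ``taguchi_fitted``.
    observations : pandas.DataFrame
        One row per (run, block): ``partition`` (Training/Test),
        ``dt_fitted``, ``dt_residual``, ``terminal_node`` and, once
        reconstructed, ``response``.
    confirmation : dict
        Wet-lab confirmation runs at the recommended media — experimental
        inputs, never computed.
    """

    design: DesignMatrix
    runs: pd.DataFrame
    observations: pd.DataFrame
    confirmation: dict = field(default_factory=dict)


def reconstruct_observations(observations: pd.DataFrame) -> pd.DataFrame:
    """Recover raw responses as ``dt_fitted + dt_residual``.

    Residuals are observation minus model fit by definition, so the raw
    replicate value is exactly the printed fitted value plus the printed
    residual.  Returns a copy with a ``response`` column.
    """
    required = {"run", "block", "dt_fitted", "dt_residual"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"incomplete fixture: missing columns {sorted(missing)}")
    if observations[["dt_fitted", "dt_residual"]].isna().any().any():
        bad = observations[observations[["dt_fitted", "dt_residual"]].isna().any(axis=1)]
        raise ValueError(f"incomplete fixture: NaN fitted/residual at rows {list(bad.index)}")
    out = observations.copy()
    out["response"] = out["dt_fitted"] + out["dt_residual"]
    return out


def responses_from_observations(observations: pd.DataFrame) -> list[ReplicatedResponse]:
    """Group reconstructed observations into per-run replicate sets."""
    return [
        ReplicatedResponse(run, tuple(grp["response"]))
        for run, grp in observations.groupby("run", sort=False)
    ]


def _data_path(name: str):
    return resources.files("pullulanopt.data").joinpath(name)


def load_fixture() -> CaseStudyTable:
    """Load the case-study fixture shipped with the package.

    The returned table has responses already reconstructed; 27 runs x 3
    blocks = 81 observations, 53 labeled Training and 28 Test.
    """
    from .design import PULLULAN_FACTORS, DesignMatrix

    with resources.as_file(_data_path("l27_design.csv")) as p:
        design = read_design_csv(p)
    # reattach units, which a bare design CSV cannot carry
    canonical = {f.name: f for f in PULLULAN_FACTORS}
    if set(design.names) == set(canonical):
        design = DesignMatrix(
            [canonical[n] for n in design.names], design.levels, design.run_ids
        )
    runs = pd.read_csv(_data_path("run_summaries.csv"), index_col="run")
    obs = pd.read_csv(_data_path("replicates.csv"))
    obs = reconstruct_observations(obs)
    confirmation = json.loads(_data_path("confirmation.json").read_text())
    return CaseStudyTable(design=design, runs=runs, observations=obs, confirmation=confirmation)


def read_experiment(design_csv: str | Path, response_csv: str | Path):
    """Read a (design, responses) pair from CSV.

    ``response_csv`` columns: ``run,replicate,response``.  Returns the
    design and one :class:`ReplicatedResponse` per run, in design order.
    """
    design = read_design_csv(design_csv)
    df = pd.read_csv(response_csv)
    for col in ("run", "replicate", "response"):
        if col not in df.columns:
            raise ValueError(f"{response_csv}: missing column {col!r}")
    by_run = {str(run): tuple(grp.sort_values("replicate")["response"]) for run, grp in df.groupby("run")}
    missing = [r for r in design.run_ids if r not in by_run]
    if missing:
        raise ValueError(f"{response_csv}: no responses for runs {missing}")
    return design, [ReplicatedResponse(r, by_run[r]) for r in design.run_ids]


# -- JSON report round trip -------------------------------------------

def _encode(obj):
    if isinstance(obj, pd.DataFrame):
        return {
            "__type__": "frame",
            "index_name": obj.index.name,
            "data": json.loads(obj.to_json(orient="split")),
        }
    if isinstance(obj, pd.Series):
        return {"__type__": "series", "name": obj.name, "data": obj.to_dict()}
    if isinstance(obj, np.ndarray):
        return {"__type__": "array", "data": obj.tolist()}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        t = obj.get("__type__")
        if t == "frame":
            d = obj["data"]
            frame = pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])
            frame.index.name = obj.get("index_name")
            return frame
        if t == "series":
            return pd.Series(obj["data"], name=obj.get("name"))
        if t == "array":
            return np.asarray(obj["data"])
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_report(tables: dict, path: str | Path) -> Path:
    """Write named tables (DataFrames/Series/arrays/scalars) to a JSON file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_encode(tables), indent=1, allow_nan=True))
    return path


def read_report(path: str | Path) -> dict:
    """Inverse of :func:`write_report`."""
    return _decode(json.loads(Path(path).read_text()))
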