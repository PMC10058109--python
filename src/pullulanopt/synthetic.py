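"""Synthetic replicated orthogonal-design data with known ground truth.

Emulates the statistical structure of the fermentation case study: a
27-run three-level orthogonal array, additive per-factor main effects, an
optional two-factor interaction, and homoscedastic Gaussian replicate
noise.  Because the generating model is returned alongside the data, every
analysis stage (response tables, main-effects fits, ANOVA, tree growth)
can be scored for parameter recovery.

Defaults mirror the case study: grand mean 5.26% pullulan, effect triples
shaped like the observed per-factor level means, noise SD 0.12 (the scale
of the observed replicate SDs), three replicates per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cart import RegressionTree
from .design import DesignMatrix, Factor, PULLULAN_FACTORS, build_l27
from .dataset import ReplicatedResponse
from .taguchi import MainEffectsModel, ResponseTable

__all__ = [
    "DEFAULT_EFFECTS",
    "SyntheticSpec",
    "TrueModel",
    "SyntheticDataset",
    "generate",
    "recovery_score",
]


def _centered(triple: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(triple, dtype=float)
    out = arr - arr.mean()
    return tuple(out)


# Effect triples shaped like the case study's per-factor mean-response
# level means (centered to sum to zero).
DEFAULT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "sucrose": _centered((4.854, 5.324, 5.589)),
    "K2HPO4": _centered((4.883, 5.249, 5.634)),
    "NaCl": _centered((4.720, 5.289, 5.757)),
    "MgSO4": _centered((4.391, 5.282, 6.093)),
    "yeast_extract": _centered((5.243, 5.245, 5.278)),
    "pH": _centered((5.543, 5.292, 4.931)),
    "incubation_time": _centered((5.597, 5.263, 4.906)),
}


@dataclass
class SyntheticSpec:
    """Generator settings.

    ``effects`` maps factor name -> zero-sum triple of level effects (any
    factor omitted gets zero effects).  ``interaction`` is an optional
    ``(factor_a, factor_b, 3x3 zero-sum matrix)``.  ``noise_sd`` is the
    replicate-level Gaussian SD in response units.
    """

    factors: tuple[Factor, ...] = PULLULAN_FACTORS
    grand_mean: float = 5.26
    effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    interaction: tuple[str, str, np.ndarray] | None = None
    noise_sd: float = 0.12
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")
        names = {f.name for f in self.factors}
        for name, triple in self.effects.items():
            if name not in names:
                raise KeyError(f"effects reference unknown factor {name!r}")
            if abs(sum(triple)) > 1e-9:
                raise ValueError(f"effects for {name!r} must sum to zero")
        if self.interaction is not None:
            a, b, mat = self.interaction
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (3, 3):
                raise ValueError("interaction matrix must be 3x3")
            if abs(mat.sum()) > 1e-9:
                raise ValueError("interaction matrix must sum to zero")
            if a not in names or b not in names:
                raise KeyError("interaction references unknown factor")


@dataclass
class TrueModel:
    """The generating model, for recovery scoring."""

    grand_mean: float
    effects: pd.DataFrame  # 3 x n_factors
    interaction: tuple[str, str, np.ndarray] | None
    noise_sd: float

    def delta(self) -> pd.Series:
        """Per-factor range of true effects (the true 'delta')."""
        return self.effects.max() - self.effects.min()


@dataclass
class SyntheticDataset:
    design: DesignMatrix
    observations: pd.DataFrame  # run, replicate, response
    truth: TrueModel
    has_nonpositive: bool

    @property
    def responses(self) -> list[ReplicatedResponse]:
        """Per-run replicate sets (requires all responses positive)."""
        return [
            ReplicatedResponse(run, tuple(grp["response"]))
            for run, grp in self.observations.groupby("run", sort=False)
        ]

    def run_means(self) -> np.ndarray:
        return (
            self.observations.groupby("run", sort=False)["response"].mean()
            .reindex(self.design.run_ids)
            .to_numpy()
        )


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a replicated orthogonal-design dataset from ``spec``.

    response(run, rep) = grand mean + sum of level effects (+ interaction)
    + N(0, noise_sd).  Per-run noise substreams are seeded as
    ``(seed, run_index)`` so increasing ``replicates`` extends each run's
    draws without reshuffling earlier ones.  Identical specs give
    identical data.
    """
    design = build_l27(spec.factors)
    names = design.names
    eff = pd.DataFrame(
        {name: spec.effects.get(name, (0.0, 0.0, 0.0)) for name in names},
        index=pd.Index([1, 2, 3], name="level"),
    )
    signal = np.full(design.n_runs, float(spec.grand_mean))
    for j, name in enumerate(names):
        signal += eff[name].to_numpy()[design.levels[:, j] - 1]
    if spec.interaction is not None:
        a, b, mat = spec.interaction
        mat = np.asarray(mat, dtype=float)
        signal += mat[design.column(a) - 1, design.column(b) - 1]
    records = []
    for i, run in enumerate(design.run_ids):
        rng = np.random.default_rng([spec.seed, i])
        noise = rng.normal(0.0, spec.noise_sd, size=spec.replicates) if spec.noise_sd > 0 else np.zeros(spec.replicates)
        for rep in range(1, spec.replicates + 1):
            records.append((run, rep, signal[i] + noise[rep - 1]))
    obs = pd.DataFrame(records, columns=["run", "replicate", "response"])
    nonpos = bool((obs["response"] <= 0).any())
    if nonpos:
        warnings.warn(
            "generated nonpositive responses; larger-is-better S/N requires Y > 0",
            UserWarning,
            stacklevel=2,
        )
    truth = TrueModel(spec.grand_mean, eff, spec.interaction, spec.noise_sd)
    return SyntheticDataset(design, obs, truth, nonpos)


def _estimated_effects(fitted, truth: TrueModel) -> pd.DataFrame | None:
    if isinstance(fitted, MainEffectsModel):
        return fitted.effects
    if isinstance(fitted, ResponseTable):
        return fitted.level_means - fitted.level_means.to_numpy().mean()
    return None


def recovery_score(truth: TrueModel, fitted) -> dict:
    """Score an estimate against the generating model.

    Accepts a main-effects model or response table (effect RMSE + rank
    agreement) or a regression tree (root-variable hit flag).  Rank
    agreement is the Kendall tau between the true per-factor effect ranges
    and the estimated ones.
    """
    est = _estimated_effects(fitted, truth)
    out: dict[str, float | bool | None] = {
        "effect_rmse": None,
        "rank_agreement": None,
        "root_variable_hit": None,
    }
    if est is not None:
        if set(est.columns) != set(truth.effects.columns):
            raise ValueError("factor sets of truth and estimate do not match")
        est = est[truth.effects.columns]
        diff = (est.to_numpy() - truth.effects.to_numpy()).ravel()
        out["effect_rmse"] = float(np.sqrt(np.mean(diff**2)))
        true_delta = truth.delta().to_numpy()
        est_delta = (est.max() - est.min()).to_numpy()
        tau = stats.kendalltau(true_delta, est_delta).statistic
        out["rank_agreement"] = float(tau)
        return out
    if isinstance(fitted, RegressionTree):
        if set(fitted.feature_names) != set(truth.effects.columns):
            raise ValueError("factor sets of truth and tree do not match")
        target = truth.delta().idxmax()
        root = fitted.root.split
        out["root_variable_hit"] = bool(root is not None and root.variable == target)
        return out
    raise TypeError(f"cannot score object of type {type(fitted).__name__}")
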