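"""Taguchi robust-design analysis on balanced three-level arrays.

Implements the decibel-scale signal-to-noise (S/N) summaries, per-factor
response tables with delta and rank, the additive main-effects model that
underlies Taguchi fitted values and optimum prediction, main-effects ANOVA
with F tests, and plot-ready residual diagnostics.

All run-level analyses operate on one summary value per run (the replicate
mean, or the per-run S/N); on a balanced orthogonal array the per-factor
level means are mutually orthogonal, which makes the additive decomposition
exact and the ANOVA sums of squares additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix

__all__ = [
    "sn_ratio",
    "sn_vector",
    "ResponseTable",
    "response_table",
    "MainEffectsModel",
    "fit_main_effects",
    "predict_at",
    "best_levels",
    "AnovaTable",
    "main_effects_anova",
    "residual_diagnostics",
]

_CRITERIA = ("larger", "smaller", "nominal")


def sn_ratio(values: Sequence[float], criterion: str = "larger") -> float:
    """Signal-to-noise ratio of one run's replicates, in dB.

    larger-is-better : ``-10 log10(mean(1/Y^2))`` (requires Y > 0)
    smaller-is-better: ``-10 log10(mean(Y^2))``
    nominal-is-best  : ``10 log10(mean^2 / variance)`` (sample variance)
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("sn_ratio: empty replicate set")
    if criterion == "larger":
        if (y <= 0).any():
            raise ValueError("larger-is-better S/N requires strictly positive responses")
        return float(-10.0 * np.log10(np.mean(1.0 / y**2)))
    if criterion == "smaller":
        return float(-10.0 * np.log10(np.mean(y**2)))
    if criterion == "nominal":
        if y.size < 2:
            raise ValueError("nominal-is-best S/N requires at least two replicates")
        var = y.var(ddof=1)
        if var == 0:
            raise ValueError("nominal-is-best S/N undefined for zero replicate variance")
        return float(10.0 * np.log10(y.mean() ** 2 / var))
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {_CRITERIA}")


def sn_vector(responses: Iterable, criterion: str = "larger") -> pd.Series:
    """Per-run S/N values from an iterable of ``ReplicatedResponse``."""
    data = {r.run_id: sn_ratio(r.values, criterion) for r in responses}
    return pd.Series(data, name="sn")


@dataclass
class ResponseTable:
    """Per-factor level means of a metric with delta and rank (Taguchi style).

    ``level_means`` is a 3 x n_factors frame indexed by level 1..3;
    ``delta`` is the per-factor range of level means; ``rank`` assigns 1 to
    the largest delta, ties broken by design column order.
    """

    metric: str
    level_means: pd.DataFrame
    delta: pd.Series
    rank: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.level_means.copy()
        out.loc["delta"] = self.delta
        out.loc["rank"] = self.rank
        return out


def _level_means(design: DesignMatrix, values: np.ndarray) -> pd.DataFrame:
    cols = {}
    for name in design.names:
        col = design.column(name)
        cols[name] = [values[col == lv].mean() for lv in (1, 2, 3)]
    return pd.DataFrame(cols, index=pd.Index([1, 2, 3], name="level"))


def response_table(design: DesignMatrix, values: Sequence[float], metric: str = "mean") -> ResponseTable:
    """Tabulate per-factor level means, delta (max - min) and rank."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != design.n_runs:
        raise ValueError("one metric value per run required")
    if design.n_runs % 3 != 0:
        raise ValueError("run count incompatible with three-level structure")
    lm = _level_means(design, values)
    delta = lm.max() - lm.min()
    # stable argsort on -delta: ties fall to the earlier design column
    order = np.argsort(-delta.to_numpy(), kind="stable")
    rank = pd.Series(0, index=delta.index, dtype=int)
    rank.iloc[order] = np.arange(1, len(delta) + 1)
    return ResponseTable(metric=metric, level_means=lm, delta=delta, rank=rank)


@dataclass
class MainEffectsModel:
    """Grand mean plus zero-sum per-factor level effects (additive model)."""

    design: DesignMatrix
    grand_mean: float
    effects: pd.DataFrame  # 3 x n_factors, each column sums to ~0
    fitted: pd.Series
    residuals: pd.Series
    metric: str = "mean"

    def predict(self, combination: Mapping[str, float]) -> float:
        return predict_at(self, combination)


def fit_main_effects(design: DesignMatrix, values: Sequence[float], metric: str = "mean") -> MainEffectsModel:
    """Fit the additive main-effects model to one value per run.

    On a balanced array the least-squares solution is the grand mean plus,
    per factor, the level mean minus the grand mean.  Refuses unbalanced
    designs, where level means are not orthogonal contrasts.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != design.n_runs:
        raise ValueError("one value per run required")
    for name in design.names:
        counts = np.bincount(design.column(name), minlength=4)[1:4]
        if not (counts == counts[0]).all():
            raise ValueError(f"design is not level-balanced in factor {name!r}")
    gm = float(values.mean())
    effects = _level_means(design, values) - gm
    fitted = np.full(design.n_runs, gm)
    for j, name in enumerate(design.names):
        fitted += effects[name].to_numpy()[design.levels[:, j] - 1]
    fitted_s = pd.Series(fitted, index=design.run_ids, name="fitted")
    resid = pd.Series(values - fitted, index=design.run_ids, name="residual")
    return MainEffectsModel(design, gm, effects, fitted_s, resid, metric=metric)


def predict_at(model: MainEffectsModel, combination: Mapping[str, float]) -> float:
    """Additive prediction at a combination of physical factor settings.

    ``combination`` maps every factor name to one of its physical levels.
    """
    total = model.grand_mean
    for factor in model.design.factors:
        if factor.name not in combination:
            raise KeyError(f"combination missing factor {factor.name!r}")
        idx = factor.encode(combination[factor.name])
        total += float(model.effects[factor.name].iloc[idx - 1])
    return total


def best_levels(table: ResponseTable, design: DesignMatrix) -> dict[str, float]:
    """Per-factor physical setting maximizing the level mean.

    Ties break toward the lower level index.
    """
    out = {}
    for factor in design.factors:
        col = table.level_means[factor.name].to_numpy()
        out[factor.name] = factor.decode(int(np.argmax(col)) + 1)
    return out


@dataclass
class AnovaTable:
    """Main-effects ANOVA on run summaries of a balanced three-level array."""

    table: pd.DataFrame  # rows: factors, Residual Error, Total
    r_squared: float
    adj_r_squared: float


def main_effects_anova(design: DesignMatrix, values: Sequence[float]) -> AnovaTable:
    """Decompose run-level variation into per-factor sums of squares.

    For each factor with r runs per level, ``SS_f = r * sum_l (mean_l -
    grand)^2`` on 2 df; the residual picks up what the additive model does
    not explain.  F compares factor MS to residual MS; p is the upper tail
    of F(2, df_res).
    """
    values = np.asarray(values, dtype=float)
    model = fit_main_effects(design, values)  # validates balance and shape
    gm = model.grand_mean
    n = design.n_runs
    ss_total = float(((values - gm) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variation: R^2 undefined")
    runs_per_level = n // 3
    rows = {}
    ss_factors = 0.0
    for name in design.names:
        ss = float(runs_per_level * (model.effects[name] ** 2).sum())
        rows[name] = ss
        ss_factors += ss
    df_factor = 2
    df_total = n - 1
    df_res = df_total - df_factor * len(design.names)
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    ss_res = ss_total - ss_factors
    ms_res = ss_res / df_res
    records = []
    for name, ss in rows.items():
        ms = ss / df_factor
        f = ms / ms_res if ms_res > 0 else np.inf
        p = float(stats.f.sf(f, df_factor, df_res))
        records.append((name, df_factor, ss, ms, f, p))
    records.append(("Residual Error", df_res, ss_res, ms_res, np.nan, np.nan))
    records.append(("Total", df_total, ss_total, np.nan, np.nan, np.nan))
    table = pd.DataFrame(records, columns=["source", "df", "SS", "MS", "F", "p"]).set_index("source")
    r2 = 1.0 - ss_res / ss_total
    adj = 1.0 - (ss_res / df_res) / (ss_total / df_total)
    return AnovaTable(table=table, r_squared=float(r2), adj_r_squared=float(adj))


def residual_diagnostics(
    residuals: Sequence[float],
    fitted: Sequence[float] | None = None,
    order: Sequence[int] | None = None,
    bins: int = 9,
) -> dict:
    """Plot-ready residual diagnostics (no rendering).

    Returns ordered residuals paired with normal theoretical quantiles
    (Blom plotting positions), histogram bin counts/edges, residual-vs-
    fitted and residual-vs-order pairs, and the residual mean.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    srt = np.sort(r)
    pp = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(pp)
    counts, edges = np.histogram(r, bins=bins)
    out = {
        "qq": {"theoretical": theo, "ordered_residuals": srt},
        "qq_correlation": float(np.corrcoef(theo, srt)[0, 1]) if n > 2 else np.nan,
        "histogram": {"counts": counts, "edges": edges},
        "mean": float(r.mean()),
    }
    if fitted is not None:
        out["vs_fitted"] = {"fitted": np.asarray(fitted, float), "residuals": r}
    idx = np.arange(1, n + 1) if order is None else np.asarray(order)
    out["vs_order"] = {"order": idx, "residuals": r}
    return out
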