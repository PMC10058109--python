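"""End-to-end case-study pipeline and model comparison.

``run_case_study`` executes the whole analysis on the shipped fixture —
replicate reconstruction, S/N ratios, response tables, main-effects ANOVA,
fitted values and residual diagnostics, optimum assignment and additive
prediction, regression-tree growth/size selection/importance — and
``compare_models`` tabulates the two recommendations against the wet-lab
confirmation runs (which are experimental inputs, never computed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cart, taguchi
from .cart import GrowthControl, RegressionTree, SizeSelection
from .dataset import CaseStudyTable, load_fixture, responses_from_observations
from .design import DesignMatrix

__all__ = ["CaseStudyReport", "ValidationReport", "run_case_study", "compare_models"]

log = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """Predicted vs observed yield for the two recommended media.

    ``table`` has one row per model (combination, predicted, observed
    mean/SD, predicted S/N, terminal node).  ``consumption_deltas`` gives
    the per-factor setting difference (tree minus Taguchi) for the g/L
    medium components.  Observed values are experimental inputs.
    """

    table: pd.DataFrame
    consumption_deltas: dict[str, float]
    notes: list[str] = field(default_factory=list)


def compare_models(
    taguchi_rec: dict,
    tree_rec: dict,
    confirmation: dict | None = None,
    design: DesignMatrix | None = None,
) -> ValidationReport:
    """Tabulate the Taguchi and tree recommendations side by side.

    Each recommendation is a dict with a ``combination`` (factor ->
    physical setting), a ``predicted`` response, and optionally
    ``predicted_sn`` / ``terminal_node``.  ``confirmation`` optionally
    supplies observed means/SDs per model key (``taguchi`` / ``tree``).
    """
    notes: list[str] = []
    rows = {}
    for key, rec in (("Taguchi", taguchi_rec), ("Decision tree", tree_rec)):
        row = dict(rec["combination"])
        row["predicted"] = rec["predicted"]
        row["predicted_sn"] = rec.get("predicted_sn", np.nan)
        row["terminal_node"] = rec.get("terminal_node", np.nan)
        conf = (confirmation or {}).get(key.split()[0].lower() if key == "Taguchi" else "tree")
        if conf is None:
            row["observed_mean"] = np.nan
            row["observed_sd"] = np.nan
            notes.append(f"{key}: no confirmation run attached; predicted-only row")
        else:
            row["observed_mean"] = conf["observed_mean"]
            row["observed_sd"] = conf["observed_sd"]
        rows[key] = row
    table = pd.DataFrame(rows).T
    table.index.name = "model"
    deltas = {}
    if design is not None:
        for f in design.factors:
            if f.unit == "g/L":
                deltas[f.name] = float(
                    tree_rec["combination"][f.name] - taguchi_rec["combination"][f.name]
                )
        for name, d in deltas.items():
            if d < 0:
                base = taguchi_rec["combination"][name]
                notes.append(
                    f"{name}: tree medium uses {-d:g} g/L less ({100 * -d / base:.0f}% reduction)"
                )
    return ValidationReport(table=table, consumption_deltas=deltas, notes=notes)


@dataclass
class CaseStudyReport:
    """Everything the case-study pipeline computes, in one object."""

    fixture: CaseStudyTable
    run_means: pd.Series
    run_sds: pd.Series
    sn: pd.Series
    sn_table: taguchi.ResponseTable
    mean_table: taguchi.ResponseTable
    anova: taguchi.AnovaTable
    mean_model: taguchi.MainEffectsModel
    sn_model: taguchi.MainEffectsModel
    diagnostics: dict
    optimum_sn_levels: dict[str, float]
    prediction_at_optimum: dict[str, float]
    prediction_at_confirmation: dict[str, float]
    tree: RegressionTree
    size_selection: SizeSelection
    tree_eval: dict[str, dict]
    tree_fitted: pd.DataFrame
    importance_primary: pd.DataFrame
    importance_surrogate: pd.DataFrame
    best_terminal: dict
    validation: ValidationReport
    notes: list[str]

    def tables(self) -> dict:
        """Named tables in the report schema (JSON-serializable via dataset.write_report)."""
        return {
            "taguchi_anova": self.anova.table.assign(),
            "r_squared": self.anova.r_squared,
            "adj_r_squared": self.anova.adj_r_squared,
            "sn_response": self.sn_table.to_frame(),
            "mean_response": self.mean_table.to_frame(),
            "fitted_residuals": pd.DataFrame(
                {
                    "observed": self.run_means,
                    "fitted": self.mean_model.fitted,
                    "residual": self.mean_model.residuals,
                }
            ),
            "predictions": {
                "at_sn_optimum": self.prediction_at_optimum,
                "at_confirmation_combination": self.prediction_at_confirmation,
            },
            "tree": self.tree.to_dict(),
            "size_selection": self.size_selection.metrics,
            "tree_eval": self.tree_eval,
            "importance": self.importance_surrogate,
            "importance_primary_only": self.importance_primary,
            "validation": self.validation.table,
            "notes": self.notes,
        }


def _fmt_combo(c: dict) -> str:
    return ", ".join(f"{k}={v:g}" for k, v in c.items())


def run_case_study(
    fixture: CaseStudyTable | None = None,
    control: GrowthControl | None = None,
    band: float = 1.0,
) -> CaseStudyReport:
    """Run the full pipeline on the case-study fixture.

    Deterministic: the fixture's printed Training/Test labels are used as
    is (the partition is never re-randomized), and every stage is a pure
    function of the fixture and options.
    """
    fx = fixture if fixture is not None else load_fixture()
    notes: list[str] = []
    obs = fx.observations
    design = fx.design
    log.info("stage reconstruct: %d observations, %d runs", len(obs), design.n_runs)

    responses = responses_from_observations(obs)
    run_means = pd.Series({r.run_id: r.mean for r in responses}).reindex(design.run_ids)
    run_sds = pd.Series({r.run_id: r.sd for r in responses}).reindex(design.run_ids)
    sn = taguchi.sn_vector(responses, "larger").reindex(design.run_ids)

    sn_table = taguchi.response_table(design, sn.to_numpy(), metric="S/N")
    mean_table = taguchi.response_table(design, run_means.to_numpy(), metric="mean")
    anova = taguchi.main_effects_anova(design, run_means.to_numpy())
    mean_model = taguchi.fit_main_effects(design, run_means.to_numpy(), metric="mean")
    sn_model = taguchi.fit_main_effects(design, sn.to_numpy(), metric="S/N")
    diagnostics = taguchi.residual_diagnostics(
        mean_model.residuals.to_numpy(), mean_model.fitted.to_numpy()
    )
    log.info("stage taguchi: R^2=%.4f", anova.r_squared)

    optimum = taguchi.best_levels(sn_table, design)
    prediction_at_optimum = {
        "mean": taguchi.predict_at(mean_model, optimum),
        "sn": taguchi.predict_at(sn_model, optimum),
    }
    conf = fx.confirmation or {}
    conf_combo = conf.get("taguchi", {}).get("combination")
    if conf_combo is not None:
        prediction_at_confirmation = {
            "mean": taguchi.predict_at(mean_model, conf_combo),
            "sn": taguchi.predict_at(sn_model, conf_combo),
        }
        disagree = {k for k in optimum if optimum[k] != conf_combo[k]}
        if disagree:
            notes.append(
                "confirmation combination differs from the S/N-optimal levels in "
                + ", ".join(
                    f"{k} ({conf_combo[k]:g} vs optimal {optimum[k]:g})" for k in sorted(disagree)
                )
                + "; predictions are reported for both"
            )
    else:
        prediction_at_confirmation = dict(prediction_at_optimum)

    # -- regression tree on the printed partition ----------------------
    names = design.names
    merged = obs.merge(design.decoded().reset_index(), on="run")
    train = merged[merged["partition"] == "Training"]
    test = merged[merged["partition"] == "Test"]
    X_train, y_train = train[names].to_numpy(float), train["response"].to_numpy()
    X_test, y_test = test[names].to_numpy(float), test["response"].to_numpy()
    log.info("stage tree: %d training / %d test cases", len(train), len(test))

    grown = cart.grow(X_train, y_train, names, control or GrowthControl())
    selection = cart.subtree_sequence(grown, X_train, y_train, X_test, y_test, band=band)
    tree = selection.selected_tree
    tree_eval = {
        "training": cart.evaluate(tree, X_train, y_train),
        "test": cart.evaluate(tree, X_test, y_test),
    }
    fitted_all, terminal_all = tree.predict(merged[names].to_numpy(float))
    tree_fitted = merged[["run", "block", "partition", "response"]].copy()
    tree_fitted["fitted"] = fitted_all
    tree_fitted["residual"] = tree_fitted["response"] - fitted_all
    tree_fitted["terminal_node"] = terminal_all
    importance_primary = cart.importance(tree, X_train, y_train, use_surrogates=False)
    importance_surrogate = cart.importance(tree, X_train, y_train, use_surrogates=True)

    # -- recommendations & validation ----------------------------------
    best_leaf = max(tree.leaves(), key=lambda nd: nd.mean)
    rules = tree.rules_for_leaf(best_leaf.terminal_id)
    constrained = {var for var, _, _ in rules}
    free = [n for n in names if n not in constrained]
    tree_conf = conf.get("tree", {})
    best_terminal = {
        "terminal_id": best_leaf.terminal_id,
        "n": best_leaf.n,
        "mean": best_leaf.mean,
        "sd": best_leaf.sd,
        "rules": rules,
        "free_factors": free,
    }
    if free:
        notes.append(
            f"tree recommendation constrains only {sorted(constrained)}; "
            f"{free} are free (reported at the confirmation-run settings)"
        )
    taguchi_rec = {
        "combination": conf_combo or optimum,
        "predicted": prediction_at_confirmation["mean"],
        "predicted_sn": prediction_at_confirmation["sn"],
    }
    tree_rec = {
        "combination": tree_conf.get("combination", {}),
        "predicted": best_leaf.mean,
        "terminal_node": best_leaf.terminal_id,
    }
    validation = compare_models(
        taguchi_rec,
        tree_rec,
        confirmation=conf if ("taguchi" in conf or "tree" in conf) else None,
        design=design,
    )
    notes.extend(validation.notes)
    log.info(
        "stage validate: taguchi %s -> %.2f; tree %s -> %.2f",
        _fmt_combo(taguchi_rec["combination"]),
        taguchi_rec["predicted"],
        _fmt_combo(tree_rec["combination"]),
        tree_rec["predicted"],
    )

    return CaseStudyReport(
        fixture=fx,
        run_means=run_means,
        run_sds=run_sds,
        sn=sn,
        sn_table=sn_table,
        mean_table=mean_table,
        anova=anova,
        mean_model=mean_model,
        sn_model=sn_model,
        diagnostics=diagnostics,
        optimum_sn_levels=optimum,
        prediction_at_optimum=prediction_at_optimum,
        prediction_at_confirmation=prediction_at_confirmation,
        tree=tree,
        size_selection=selection,
        tree_eval=tree_eval,
        tree_fitted=tree_fitted,
        importance_primary=importance_primary,
        importance_surrogate=importance_surrogate,
        best_terminal=best_terminal,
        validation=validation,
        notes=notes,
    )
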