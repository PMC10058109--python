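#!/usr/bin/env python
"""Grow and select the least-squares regression tree.

Uses the published Training/Test partition, grows the tree by exhaustive
split search, walks the weakest-link pruning sequence, selects the size on
test R^2, and reports error statistics and variable importance.  Writes
the tree and metrics under results/.
"""

from pathlib import Path

from pullulanopt import run_case_study
from pullulanopt.dataset import write_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rep = run_case_study()
    sel = rep.size_selection
    tree = rep.tree
    print(f"grown tree: {sel.metrics.index.max()} terminal nodes; "
          f"selected {sel.selected_size} (max test R^2 at {sel.best_size})")
    print(f"root: n={tree.root.n}, split {tree.root.split.variable} <= {tree.root.split.threshold:g}")
    print("\nsize selection:\n", sel.metrics.round(4))
    tr, te = rep.tree_eval["training"], rep.tree_eval["test"]
    print(f"\ntraining: MSE {tr['mse']:.4f}, RMSE {tr['rmse']:.4f}, R^2 {100 * tr['r2']:.2f}%")
    print(f"test:     MSE {te['mse']:.4f}, RMSE {te['rmse']:.4f}, R^2 {100 * te['r2']:.2f}%")
    bt = rep.best_terminal
    rules = ", ".join(f"{v} {op} {thr:g}" for v, op, thr in bt["rules"])
    print(f"\nbest terminal node {bt['terminal_id']}: n={bt['n']}, "
          f"mean {bt['mean']:.2f} +/- {bt['sd']:.2f} (population SD); rules: {rules}")
    print("\nvariable importance (with surrogates):\n", rep.importance_surrogate.round(1))

    OUT.mkdir(exist_ok=True)
    write_report(
        {
            "tree": tree.to_dict(),
            "size_selection": sel.metrics,
            "tree_eval": rep.tree_eval,
            "importance": rep.importance_surrogate,
            "importance_primary_only": rep.importance_primary,
            "fitted": rep.tree_fitted,
        },
        OUT / "tree.json",
    )
    print(f"wrote {OUT / 'tree.json'}")


if __name__ == "__main__":
    main()
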