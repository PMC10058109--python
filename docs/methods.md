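# Methods

## Data model and reconstruction

The case-study fixture carries the 27-run L27(3⁷) design (seven medium
factors at three levels), per-run printed summaries (replicate mean ± SD,
S/N ratio, additive-model fitted value), and 81 observation records — one
per (run, replicate block) — each with a Training/Test label, the
regression tree's fitted value, its residual, and the terminal node it
landed in.

Raw replicate responses are not printed individually; they are recovered
exactly as `response = fitted + residual`, since a residual is by
definition the observation minus the model fit. The reconstruction is
validated in bulk: for all 27 runs the recomputed replicate mean agrees
with the printed mean within 0.01 and the sample SD within 0.015, which is
the accumulation of 2-dp rounding in the printed inputs. Replicate SD uses
the n−1 divisor: it reproduces the printed 0.23 for the first run, where
the population convention would give 0.19.

The 53/28 Training/Test labels are part of the data and are never
re-randomized; `cart.partition` exists for fresh datasets (a 0.3 fraction
of 81 gives 24 test cases under round-half rounding, so the study's own
28-case draw could not be regenerated from any seed at that fraction).

Units: the response is stored as printed (% w/v). Parts of the source
discuss the same numbers as g/L; no conversion is applied.

## Taguchi analysis

- S/N (larger-is-better): −10·log₁₀(mean(1/Y²)) in dB, computed per run
  from the three reconstructed replicates. The base-10/decibel convention
  reproduces the printed per-run values (17.18 for the best run, 11.59 for
  the first) to ±0.01. Smaller-is-better and nominal-is-best
  (10·log₁₀(ȳ²/s²), sample variance) are provided for completeness.
- Run-level analyses (response tables, additive model, ANOVA) operate on
  the 27 run summaries, not the 81 raw observations; the published ANOVA's
  total df = 26 and residual df = 12 admit no other reading.
- Response tables: per factor, the mean of the metric over the nine runs
  at each level; delta = max − min level mean; rank 1 = largest delta,
  ties broken by design column order (none occur in the fixture).
- Additive model: on a balanced array the least-squares fit is the grand
  mean plus per-factor (level mean − grand mean) effects; fitted values
  and `predict_at` are the same sum evaluated at a run's own levels or at
  any user combination. Unbalanced designs are refused rather than
  approximated.
- ANOVA: SS_f = 9·Σ_ℓ(effect_ℓ)² on 2 df per factor; the residual is the
  remainder of the total SS on 12 df; p from the upper tail of F(2, 12).
  R² = 1 − SS_res/SS_total and the df-adjusted variant. A response with
  zero total variation raises (R² undefined) rather than returning a
  sentinel. Reports render p < 0.001 for values the source prints as
  0.000.
- Residual diagnostics are plot-ready data only (no rendering): ordered
  residuals against normal quantiles at Blom plotting positions, histogram
  counts, residual-vs-fitted and residual-vs-order pairs, and the residual
  mean (identically 0 for the balanced fit).

Reproduction tolerances used in the tests mirror the precision of the
printed tables: level means ±0.01, SS ±0.03, F ±2% (printed F values are
ratios of 2-dp-rounded SS; the smallest F, 0.24, is checked through its
printed p = 0.793 instead, where rounding dominates the 2% band).

## Regression tree

Growth is exhaustive least-squares search: candidate thresholds are
midpoints between consecutive distinct observed values of each predictor
(for the three-level factors this yields e.g. 0.15/0.25 g/L for MgSO₄ and
84 h for incubation time, the cut points the published tree shows); the
split minimizing SSE_left + SSE_right wins, ties broken by smaller
variable index then smaller threshold. Node SD uses the n divisor
(population SD), which reproduces the printed 6.98 ± 0.29 for the
four-case best node (sample SD would read 0.33).

Stopping defaults: `min_split_n = 10`, `min_leaf_n = 2`, `max_depth = 4`.
The minimum-cases-to-split value is the one the published tree implies —
every internal node there holds ≥ 10 cases and every terminal node fewer —
and with it the grown tree reproduces the published 9-terminal-node tree
exactly: all leaf means/SDs, all 81 terminal-node assignments, training
MSE 0.0852 / RMSE 0.2919, test MSE 0.1400, training R² 91.50% / test
86.12% against the printed 0.0850 / 0.2916 / 0.1397 / 91.51 / 86.15. A
smaller threshold (e.g. 4) grows a 14-leaf tree whose pruned 9-leaf
subtree splits the low-yield corner differently and misses those
statistics.

Size selection: weakest-link pruning — iteratively collapse the internal
node (with two terminal children) whose removal increases training SSE
least — gives one nested subtree per terminal-node count; each size is
scored on the held-out cases, and the selected size is the smallest whose
test R² (in percentage points) lies within 1.0 of the maximum. On the
fixture the maximum sits at the full 9-leaf tree and no smaller size is
within the band, so the band rule and the outright maximum coincide.

Variable importance: each internal node credits its primary splitter with
its SSE improvement; with surrogates enabled, every other variable is
credited with the improvement of its best surrogate split at that node —
the split on it agreeing most with the primary partition (either
orientation), qualified only if it beats the majority-rule baseline.
Primary-only is the default; the case-study report carries both. On the
fixture the surrogate-inclusive percentages come out 100 / 82.1 / 79.7 /
78.3 / 21.7 / 11.9 / 3.3 for MgSO₄ / NaCl / sucrose / K₂HPO₄ / incubation
time / pH / yeast extract, matching the published chart to within 0.2
points; the tests assert the ordering, which is the robust part of this
statistic.

Terminal nodes are numbered 1..k left-to-right (left = "≤" branch), which
matches the published terminal-node column for all 81 observations.

## Model comparison

The validation table sets the additive-model prediction and the tree's
best terminal node against the stored confirmation runs (7.23 ± 0.13% and
7.11 ± 0.07%), which are wet-lab inputs and are never computed. Two
documented discrepancies are surfaced as report notes rather than
resolved: (i) the confirmation medium holds K₂HPO₄ at 4 g/L although the
S/N response table peaks at 6 g/L — the printed predictions 7.17%/17.64 dB
are consistent with 4 g/L, and `predict_at` accepts any combination;
(ii) the tree's best node constrains only sucrose, MgSO₄ and incubation
time, so the remaining four factors are reported as free, with the
confirmation-run settings attached.

## Synthetic generator

`synthetic.generate` emulates the fixture's structure: the same L27 array,
additive per-factor effects (defaults shaped like the observed level
means, grand mean 5.26), an optional 3×3 zero-sum two-factor interaction,
and i.i.d. Gaussian replicate noise (default SD 0.12, the scale of the
observed replicate SDs), three replicates per run. Noise is drawn from
per-run substreams seeded as (seed, run index), so adding replicates
extends each run without reshuffling earlier draws. Nonpositive generated
responses trigger a warning because the larger-is-better S/N needs Y > 0.

What it deliberately does not emulate: mean–variance coupling (the
fixture's replicate SDs show no strong trend at this scale),
non-Gaussian error, batch/block effects shared across runs, or any
fermentation kinetics. Passing recovery tests therefore demonstrate the
estimators' correctness under an additive, homoscedastic regime — the
regime the source analysis itself assumes — not robustness beyond it.

`recovery_score` returns the RMSE between true and estimated level
effects, the Kendall concordance between true and estimated per-factor
delta orderings, and (for trees) whether the root split found the
dominant-effect variable.

## Simulation sizes and numerical choices

The recovery study uses 200 generator seeds for effect-recovery and
root-hit rates and 1000 seeds for the null-model type-I check (per-factor
rejection rates at α = 0.05 land in 0.046–0.053); these sizes put the
Monte-Carlo error comfortably below the asserted bands while the whole
suite stays interactive. Tie-breaks everywhere are deterministic (first
design column, lower level index, smaller variable index/threshold).
Equality tolerances in invariant checks are 1e−9 absolute for algebraic
identities and 1e−12 for zero-noise recovery.

## Limitations

- Main effects only: the L27 columns used confound two-factor
  interactions with main effects; neither the ANOVA nor the additive
  prediction can detect them (the generator can inject one precisely to
  study this failure mode).
- The tree's left (low-MgSO₄) internal splits are reported as computed;
  the source describes that branch only partially, so only node counts,
  means and routing that are printed are asserted.
- Exact surrogate-importance percentages depend on undocumented details of
  the original software's surrogate accounting; the implementation's
  definitions are stated above and its ordering is treated as the stable
  result.
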