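"""DE accuracy benchmark on grouped simulations with an effect-size filter.

Simulates splat-style grouped data, calls DE genes with a Kruskal-Wallis
test at a 5% FDR before and after imputation, scores the calls against the
simulation truth, and shows how restricting calls to the top X% of genes by
fold-change trades sensitivity for specificity.
"""

from falsesignal import (
    GroupSimConfig,
    confusion,
    effect_size_filter,
    run_de,
    run_imputer,
    simulate_grouped,
)

cfg = GroupSimConfig(n_cells=500, n_genes=1000, n_groups=5,
                     de_total_fraction=0.10, seed=7)
dataset = simulate_grouped(cfg)

print(f"{'imputer':12s} {'top-X%':>7s} {'sensitivity':>12s} {'specificity':>12s}")
for imputer, params in [("raw", {}), ("knn_smooth", {"k": 25})]:
    imputed = run_imputer(imputer, dataset.counts, **params)
    result = run_de(imputed, dataset.truth.group_labels)
    for pct in (1.0, 0.25, 0.10):
        acc = confusion(effect_size_filter(result, pct), dataset.truth)
        print(f"{imputer:12s} {pct:7.0%} {acc.sensitivity:12.3f} "
              f"{acc.specificity:12.3f}")

print(
    "\nSmoothing inflates sensitivity but wrecks specificity: many non-DE"
    "\ngenes become significant. Tightening the fold-change percentile"
    "\nrestores specificity at the cost of sensitivity — the filter keeps"
    "\nonly calls backed by a large effect."
)
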