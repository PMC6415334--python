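"""Permutation-null false-positive differential expression.

Builds a labelled grouped simulation, selects the two most similar
cell-types, permutes every gene showing no DE evidence between them
(raw Mann-Whitney p > 0.2) across those cells, and re-tests the permuted
genes after each imputer. Permuted genes are null by construction, so any
Bonferroni-significant call is a false positive; without imputation the
expected count is below one per dataset.
"""

from falsesignal import GroupSimConfig, permutation_null_experiment, simulate_grouped

cfg = GroupSimConfig(n_cells=999, n_genes=2000, n_groups=3,
                     de_total_fraction=0.10, seed=4)
dataset = simulate_grouped(cfg)

for imputer, params in [
    ("raw", {}),
    ("knn_smooth", {"k": 49}),
    ("model_zeros", {"threshold": 0.5}),
]:
    report, null = permutation_null_experiment(
        dataset.counts, imputer=imputer, params=params, seed=4
    )
    print(f"{imputer:12s} pair={null.pair}  permuted={report.n_permuted:5d}  "
          f"false positives={report.n_significant:4d}  "
          f"fraction={report.fp_fraction:.3f}")

print(
    "\nThe permuted genes carry no signal between the two cell-types."
    "\nRaw data keeps the Bonferroni promise (expected < 1 false call);"
    "\nknn smoothing re-creates significant differences on known-null"
    "\ngenes, while the model-based zero imputer stays close to raw."
)
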