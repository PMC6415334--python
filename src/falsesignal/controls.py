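"""Negative-control experiments.

Two experiments quantify false signals introduced by imputation:

* **false correlations** — on a two-group NB simulation, every gene pair is
  screened by Spearman correlation with Bonferroni correction; a
  significant pair is a true positive only if both genes are DE and the
  correlation sign matches the concordance of their DE directions, and a
  false positive otherwise;
* **permutation null** — on a labelled dataset, genes showing no evidence
  of DE (raw Mann-Whitney p > 0.2) between the two most similar cell-types
  are permuted across those cells (independently per gene, on log2-CPM,
  then de-normalized back to counts to keep library sizes intact). Any of
  these known-null genes called DE after imputation is a false positive;
  with Bonferroni correction the expected count without imputation is
  below one per dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imputers import run_imputer
from .stats import (
    SpearmanResult,
    adjust,
    denormalize_counts,
    log2_cpm,
    mwu_matrix,
    spearman_all_pairs,
    to_log2cpm,
)
from .types import CountMatrix, PValueSet, SimTruth, SimulatedDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation classification

@dataclass
class CorrelationReport:
    """Classified all-pairs correlation screen.

    ``pairs`` holds one row per Bonferroni-significant pair with its rho, q
    and class (TP/FP). Strata summaries are per-gene expression strata; a
    pair contributes to the stratum of each member gene.
    """

    pairs: pd.DataFrame
    n_tested: int
    alpha: float
    strata: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return len(self.pairs)

    @property
    def n_tp(self) -> int:
        return int((self.pairs["klass"] == "TP").sum())

    @property
    def n_fp(self) -> int:
        return int((self.pairs["klass"] == "FP").sum())


def classify_correlations(
    res: SpearmanResult,
    truth: SimTruth,
    alpha: float = 0.05,
) -> CorrelationReport:
    """Split Bonferroni-significant pairs into true and false positives.

    A significant pair is a TP iff both genes are DE and sign(rho) equals
    the concordance of their DE directions (same direction -> positive,
    opposite -> negative); every other significant pair — including any
    involving a non-DE gene — is an FP.
    """
    if res.pvals.adjusted is None or res.pvals.method != "bonferroni":
        raise ValueError("classify_correlations expects Bonferroni-adjusted p-values")
    if len(truth.is_de) != res.rho.shape[0]:
        raise ValueError("truth does not cover every tested gene")
    q = res.pvals.adjusted
    sig = q < alpha
    i, j = res.pair_i[sig], res.pair_j[sig]
    rho = res.rho[i, j]
    both_de = truth.is_de[i] & truth.is_de[j]
    concordant = truth.direction[i] * truth.direction[j]  # +1 same, -1 opposite
    tp = both_de & (np.sign(rho) == concordant)
    pairs = pd.DataFrame(
        {
            "gene_i": res.genes[i],
            "gene_j": res.genes[j],
            "idx_i": i,
            "idx_j": j,
            "rho": rho,
            "q": q[sig],
            "klass": np.where(tp, "TP", "FP"),
        }
    )
    return CorrelationReport(pairs=pairs, n_tested=res.pvals.m, alpha=alpha)


def assign_strata(base_mean: np.ndarray, n_strata: int = 5) -> np.ndarray:
    """Bin genes into log-spaced expression strata by their base mean."""
    logm = np.log10(np.asarray(base_mean, dtype=float))
    edges = np.linspace(logm.min(), logm.max(), n_strata + 1)
    strata = np.clip(np.searchsorted(edges, logm, side="right") - 1, 0, n_strata - 1)
    return strata


def _stratify(report: CorrelationReport, strata: np.ndarray, n_strata: int) -> pd.DataFrame:
    rows = []
    for s in range(n_strata):
        in_s = np.flatnonzero(strata == s)
        sel = report.pairs["idx_i"].isin(in_s) | report.pairs["idx_j"].isin(in_s)
        sub = report.pairs[sel]
        fp = sub[sub["klass"] == "FP"]
        rows.append(
            {
                "stratum": s,
                "n_genes": len(in_s),
                "n_sig": len(sub),
                "n_fp": len(fp),
                "n_tp": len(sub) - len(fp),
                "max_abs_rho_fp": float(np.abs(fp["rho"]).max()) if len(fp) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def false_correlation_experiment(
    dataset: SimulatedDataset,
    imputer: str = "raw",
    params: Optional[dict] = None,
    alpha: float = 0.05,
    n_strata: int = 5,
) -> CorrelationReport:
    """Run one imputer through the all-pairs false-correlation screen.

    Imputes the raw counts, computes all-pairs Spearman with Bonferroni
    correction, classifies significant pairs against the simulation truth,
    and attaches a per-expression-stratum summary (strata from the truth's
    base means).
    """
    imputed = run_imputer(imputer, dataset.counts, **(params or {}))
    res = spearman_all_pairs(imputed)
    res.pvals = adjust(res.pvals, "bonferroni")
    report = classify_correlations(res, dataset.truth, alpha=alpha)
    if dataset.truth.base_mean is not None:
        strata = assign_strata(dataset.truth.base_mean, n_strata)
        report.strata = _stratify(report, strata, n_strata)
    report.meta = {"imputer": imputer, "params": dict(params or {})}
    return report


# ---------------------------------------------------------------------------
# dataset filtering and pair selection

def filter_cells_genes(
    X: CountMatrix,
    labels: Optional[np.ndarray] = None,
    min_type_fraction: float = 0.05,
    min_detect_fraction: float = 0.05,
) -> CountMatrix:
    """Remove rare cell-types, unlabelled cells, then rarely detected genes.

    Cell-types holding fewer than ``min_type_fraction`` of all cells are
    removed (as are unlabelled cells); afterwards genes detected (count>0)
    in fewer than ``min_detect_fraction`` of the remaining cells are
    removed. Cells first, then genes. Errors if fewer than two cell-types
    survive.
    """
    labels = X.labels if labels is None else np.asarray(labels, dtype=object)
    if labels is None:
        raise ValueError("cell labels are required for filtering")
    n = X.n_cells
    labelled = np.array([l is not None and str(l) not in ("", "nan") for l in labels])
    keep_cells = labelled.copy()
    for t in np.unique(labels[labelled]):
        m = labels == t
        if m.sum() < min_type_fraction * n:
            keep_cells &= ~m
    surviving = np.unique(labels[keep_cells])
    if len(surviving) < 2:
        raise ValueError("fewer than two cell-types survive filtering")
    sub = X.subset(cell_mask=keep_cells)
    if sub.labels is None:
        sub.labels = labels[keep_cells]
    detected = (sub.values > 0).sum(axis=1)
    keep_genes = detected >= min_detect_fraction * sub.n_cells
    return sub.subset(gene_mask=keep_genes)


def select_similar_pair(X: CountMatrix, labels: Optional[np.ndarray] = None) -> tuple:
    """The two cell-types with the closest mean log2-CPM profiles.

    Euclidean distance between per-type mean expression profiles; ties
    break lexicographically on (type_a, type_b) names.
    """
    labels = X.labels if labels is None else np.asarray(labels, dtype=object)
    if labels is None:
        raise ValueError("cell labels are required")
    types = sorted(np.unique(labels).tolist())
    if len(types) < 2:
        raise ValueError("need at least two cell-types")
    L = to_log2cpm(X)
    profiles = {t: L.values[:, labels == t].mean(axis=1) for t in types}
    best, best_d = None, np.inf
    for ai in range(len(types)):
        for bi in range(ai + 1, len(types)):
            a, b = types[ai], types[bi]
            d = float(np.linalg.norm(profiles[a] - profiles[b]))
            if d < best_d - 1e-12:  # strict improvement; lexicographic tie-break
                best, best_d = (a, b), d
    return best


# ---------------------------------------------------------------------------
# permutation null

@dataclass
class PermutationNull:
    """A dataset with known-null genes permuted across a cell-type pair."""

    before: CountMatrix
    after: CountMatrix
    pair: tuple
    permuted_genes: np.ndarray  # gene identifiers
    permuted_mask: np.ndarray   # boolean per gene
    screen_p: np.ndarray
    seed: int
    pair_cell_idx: Optional[np.ndarray] = None
    permuted_log: Optional[np.ndarray] = None  # log2-CPM over pair cells, post-permutation


def build_permutation_null(
    X: CountMatrix,
    labels: Optional[np.ndarray] = None,
    pair: Optional[tuple] = None,
    p_threshold: float = 0.2,
    seed: int = 0,
) -> PermutationNull:
    """Permute non-DE genes across the selected cell-type pair.

    Genes are screened by Mann-Whitney-U on log2-CPM between the pair's
    cells; genes with raw p > ``p_threshold`` have their log2-CPM values
    independently permuted across those cells, then de-normalized back to
    raw counts with each cell's original library size. Cells outside the
    pair and genes at p <= threshold are untouched.
    """
    labels = X.labels if labels is None else np.asarray(labels, dtype=object)
    if labels is None:
        raise ValueError("cell labels are required")
    if pair is None:
        pair = select_similar_pair(X, labels)
    a, b = pair
    mask_a = labels == a
    mask_b = labels == b
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"pair {pair!r} not found in labels")
    L = log2_cpm(X)
    _, p = mwu_matrix(L.values, mask_a, mask_b)
    permute_mask = p > p_threshold
    if not permute_mask.any():
        raise ValueError("no gene exceeds the screening p threshold; nothing to permute")

    pair_cells = mask_a | mask_b
    idx_cells = np.flatnonzero(pair_cells)
    rng = np.random.default_rng(seed)
    Lp = L.values.copy()
    block = Lp[np.ix_(permute_mask, idx_cells)]
    # independent permutation per gene via random keys
    order = np.argsort(rng.random(block.shape), axis=1)
    block = np.take_along_axis(block, order, axis=1)
    Lp[np.ix_(permute_mask, idx_cells)] = block

    lib = X.libsizes()
    sub = CountMatrix(
        values=Lp[:, idx_cells],
        genes=X.genes,
        cells=X.cells[idx_cells],
        scale="log2cpm",
    )
    new_counts = denormalize_counts(sub, lib[idx_cells]).values
    after_vals = np.asarray(X.values, dtype=float).copy()
    after_vals[:, idx_cells] = new_counts
    after = X.with_values(after_vals, scale="raw")
    return PermutationNull(
        before=X.copy(),
        after=after,
        pair=(a, b),
        permuted_genes=X.genes[permute_mask],
        permuted_mask=permute_mask,
        screen_p=p,
        seed=seed,
        pair_cell_idx=idx_cells,
        permuted_log=Lp[:, idx_cells],
    )


@dataclass
class FalsePositiveReport:
    """Significance of known-null (permuted) genes after imputation."""

    table: pd.DataFrame  # gene, p, q, significant, direction
    n_permuted: int
    n_significant: int
    alpha: float

    @property
    def fp_fraction(self) -> float:
        return self.n_significant / self.n_permuted if self.n_permuted else np.nan


def count_de_false_positives(
    X_imputed: CountMatrix,
    labels: np.ndarray,
    pair: tuple,
    permuted_genes: Sequence,
    alpha: float = 0.05,
    family: str = "permuted",
) -> FalsePositiveReport:
    """Mann-Whitney re-test of the permuted genes after imputation.

    Bonferroni correction over the permuted-gene family (they are the
    known-null hypotheses; ``family='all'`` instead corrects over every
    gene in the matrix). A significant permuted gene is a false positive.
    """
    permuted_genes = np.asarray(permuted_genes, dtype=object)
    if permuted_genes.size == 0:
        raise ValueError("permuted gene list is empty")
    labels = np.asarray(labels, dtype=object)
    a, b = pair
    mask_a = labels == a
    mask_b = labels == b
    L = to_log2cpm(X_imputed)
    gene_mask = np.isin(X_imputed.genes, permuted_genes)
    V = L.values[gene_mask]
    _, p = mwu_matrix(V, mask_a, mask_b)
    m = X_imputed.n_genes if family == "all" else int(gene_mask.sum())
    pset = adjust(PValueSet(raw=p, m=m), "bonferroni", m=m)
    sig = pset.adjusted < alpha
    diff = V[:, mask_a].mean(axis=1) - V[:, mask_b].mean(axis=1)
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "gene": X_imputed.genes[gene_mask],
            "p": p,
            "q": pset.adjusted,
            "significant": sig,
            "direction": direction,
        }
    )
    return FalsePositiveReport(
        table=table,
        n_permuted=int(gene_mask.sum()),
        n_significant=int(sig.sum()),
        alpha=alpha,
    )


def bias_direction_summary(
    before: CountMatrix,
    after: CountMatrix,
    permuted_genes: Sequence,
    pair: tuple,
    labels: np.ndarray,
) -> pd.DataFrame:
    """Direction of the post-imputation shift for each permuted gene.

    Per gene: 'none' when the gene's values over the pair's cells are
    unchanged, else the sign of the mean difference (type a minus type b)
    after imputation. The summary attribute ``concordance`` is the fraction
    of directional genes sharing the majority sign — near 1 when an imputer
    biases all null genes the same way, near 0.5 for random directions.
    """
    if before.values.shape != after.values.shape:
        raise ValueError("before/after matrices must share a shape")
    labels = np.asarray(labels, dtype=object)
    a, b = pair
    pc = (labels == a) | (labels == b)
    gene_mask = np.isin(before.genes, np.asarray(permuted_genes, dtype=object))
    Lb = to_log2cpm(before).values[gene_mask][:, pc]
    La = to_log2cpm(after).values[gene_mask][:, pc]
    ingroup = (labels == a)[pc]
    unchanged = np.all(np.isclose(Lb, La), axis=1)
    diff = La[:, ingroup].mean(axis=1) - La[:, ~ingroup].mean(axis=1)
    direction = np.where(unchanged, "none", np.where(diff > 0, "up", "down"))
    out = pd.DataFrame({"gene": before.genes[gene_mask], "direction": direction})
    directional = direction[direction != "none"]
    if directional.size:
        counts = pd.Series(directional).value_counts()
        out.attrs["concordance"] = float(counts.max() / counts.sum())
    else:
        out.attrs["concordance"] = np.nan
    return out


def permutation_null_experiment(
    X: CountMatrix,
    labels: Optional[np.ndarray] = None,
    imputer: str = "raw",
    params: Optional[dict] = None,
    p_threshold: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[FalsePositiveReport, PermutationNull]:
    """Filter, select the closest type pair, permute, impute, and re-test."""
    filt = filter_cells_genes(X, labels)
    null = build_permutation_null(filt, p_threshold=p_threshold, seed=seed)
    imputed = run_imputer(imputer, null.after, **(params or {}))
    report = count_de_false_positives(
        imputed, filt.labels, null.pair, null.permuted_genes, alpha=alpha
    )
    return report, null
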