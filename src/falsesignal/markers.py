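"""Marker-gene identification and reproducibility statistics.

Markers are found one-vs-rest: for every gene and cell-type, a
Mann-Whitney-U test on log2-CPM compares the type against all other cells
and the effect size is the AUC for predicting the type from the gene's
expression. Each gene is assigned to its argmax-AUC type; significance
requires a 5% FDR (BH over genes, on the assigned type's p-value) plus an
AUC threshold. Reproducibility across a matched dataset pair is the
fraction of genes significant in both that are assigned the same type —
the statistic that degrades when imputation reshuffles marker assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import adjust, auroc_matrix, mwu_matrix, to_log2cpm
from .types import CountMatrix, PValueSet

logger = logging.getLogger(__name__)

DEFAULT_AUC_GRID = np.round(np.arange(0.5, 0.951, 0.05), 2)


@dataclass
class MarkerTable:
    """Per-gene marker assignment with per-type AUCs and p-values."""

    table: pd.DataFrame  # gene, assigned, p, q + auc_<type> columns
    types: list

    def significant(self, auc_threshold: float = 0.5, alpha: float = 0.05) -> pd.DataFrame:
        auc_assigned = self.table.apply(
            lambda r: r[f"auc_{r['assigned']}"], axis=1
        )
        mask = (self.table["q"] <= alpha) & (auc_assigned >= auc_threshold)
        return self.table[mask]


def find_markers(
    X: CountMatrix,
    labels: Optional[np.ndarray] = None,
    alpha: float = 0.05,
) -> MarkerTable:
    """One-vs-rest marker screen over every gene and cell-type.

    Types with fewer than 2 cells are excluded (with a warning). AUCs are
    oriented so values high inside the type give AUC > 0.5; ties in the
    argmax-AUC assignment break lexicographically on type name.
    """
    labels = X.labels if labels is None else np.asarray(labels, dtype=object)
    if labels is None:
        raise ValueError("cell labels are required")
    types = sorted(np.unique(labels).tolist())
    usable = []
    for t in types:
        if (labels == t).sum() < 2:
            logger.warning("type %r has <2 cells; excluded from marker screen", t)
        else:
            usable.append(t)
    if len(usable) < 2:
        raise ValueError("need at least two usable cell-types")
    keep = np.isin(labels, usable)
    L = to_log2cpm(X.subset(cell_mask=keep))
    sub_labels = labels[keep]

    aucs = np.empty((X.n_genes, len(usable)))
    pvals = np.empty((X.n_genes, len(usable)))
    for j, t in enumerate(usable):
        in_t = sub_labels == t
        aucs[:, j] = auroc_matrix(L.values, in_t)
        _, pvals[:, j] = mwu_matrix(L.values, in_t, ~in_t)

    assigned_idx = np.argmax(aucs, axis=1)  # first max -> lexicographic tie-break
    assigned = np.array(usable, dtype=object)[assigned_idx]
    p_assigned = pvals[np.arange(X.n_genes), assigned_idx]
    q = adjust(PValueSet(raw=p_assigned, m=X.n_genes), "bh").adjusted
    data = {"gene": X.genes, "assigned": assigned, "p": p_assigned, "q": q}
    for j, t in enumerate(usable):
        data[f"auc_{t}"] = aucs[:, j]
    return MarkerTable(table=pd.DataFrame(data), types=usable)


@dataclass
class ReproReport:
    """Cross-dataset marker concordance, per AUC threshold."""

    sweep: pd.DataFrame  # auc_threshold, n_sig_both, n_same_type, reproducibility

    def at(self, auc_threshold: float) -> pd.Series:
        idx = (self.sweep["auc_threshold"] - auc_threshold).abs().idxmin()
        return self.sweep.loc[idx]


def marker_reproducibility(
    mA: MarkerTable,
    mB: MarkerTable,
    auc_grid: Sequence[float] = DEFAULT_AUC_GRID,
    alpha: float = 0.05,
) -> ReproReport:
    """Fraction of shared significant markers assigned the same type.

    At each AUC threshold, restrict to genes significant in both tables
    (5% FDR and assigned-type AUC >= threshold); reproducibility is the
    fraction assigned to the same cell-type in both. An empty intersection
    yields NaN with a zero denominator recorded.
    """
    rows = []
    for T in auc_grid:
        sa = mA.significant(T, alpha).set_index("gene")["assigned"]
        sb = mB.significant(T, alpha).set_index("gene")["assigned"]
        common = sa.index.intersection(sb.index)
        n_both = len(common)
        n_same = int((sa.loc[common] == sb.loc[common]).sum()) if n_both else 0
        rows.append(
            {
                "auc_threshold": float(T),
                "n_sig_both": n_both,
                "n_same_type": n_same,
                "reproducibility": n_same / n_both if n_both else np.nan,
            }
        )
    return ReproReport(sweep=pd.DataFrame(rows))


def cross_method_concordance(
    tables: Sequence[MarkerTable],
    auc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Disagreement fraction across marker tables from one dataset.

    Over genes significant in every table, the fraction whose type
    assignments are not identical across all tables.
    """
    if len(tables) < 2:
        raise ValueError("need at least two marker tables")
    assigned = []
    common = None
    for t in tables:
        s = t.significant(auc_threshold, alpha).set_index("gene")["assigned"]
        assigned.append(s)
        common = s.index if common is None else common.intersection(s.index)
    if common is None or len(common) == 0:
        return np.nan
    stack = pd.concat([s.loc[common] for s in assigned], axis=1)
    agree = stack.nunique(axis=1) == 1
    return float((~agree).mean())
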