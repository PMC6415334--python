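"""Rank-based statistics and normalizations shared by every stage.

All differential-expression and correlation screens in this package are
non-parametric (Spearman, Mann-Whitney-U, Kruskal-Wallis) so that they make
no distributional assumptions about imputed values; the working scale for
the tests is log2(CPM+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, PValueSet

logger = logging.getLogger(__name__)

CPM_SCALE = 1e6


# ---------------------------------------------------------------------------
# normalization

def log2_cpm(X: CountMatrix) -> CountMatrix:
    """log2 counts-per-million with a pseudo-count of 1.

    value = log2(count / libsize * 1e6 + 1). Raises if any cell has a zero
    library size (the transform is undefined there), naming the cell.
    """
    if X.scale != "raw":
        raise ValueError("log2_cpm expects raw counts")
    lib = X.libsizes()
    if np.any(lib <= 0):
        bad = X.cells[np.where(lib <= 0)[0][0]]
        raise ValueError(f"cell {bad!r} has zero library size")
    vals = np.log2(X.values / lib * CPM_SCALE + 1.0)
    return X.with_values(vals, scale="log2cpm")


def denormalize_counts(L: CountMatrix, libsizes: np.ndarray) -> CountMatrix:
    """Invert :func:`log2_cpm` given per-cell library sizes.

    count = round((2**value - 1) * libsize / 1e6), floored at zero. Negative
    log values (which cannot arise from the forward transform) are clamped
    and counted in the log.
    """
    if L.scale != "log2cpm":
        raise ValueError("denormalize_counts expects log2cpm values")
    libsizes = np.asarray(libsizes, dtype=float)
    if libsizes.shape != (L.n_cells,):
        raise ValueError("need one library size per cell")
    lin = np.power(2.0, L.values) - 1.0
    n_neg = int((lin < 0).sum())
    if n_neg:
        logger.warning("denormalize_counts: clamped %d negative values to 0", n_neg)
        lin = np.clip(lin, 0.0, None)
    counts = np.rint(lin * libsizes / CPM_SCALE)
    return L.with_values(counts, scale="raw")


def to_log2cpm(X: CountMatrix) -> CountMatrix:
    """Coerce any scale onto log2cpm-like values for rank-based testing.

    Raw counts go through :func:`log2_cpm`; CPM values take log2(x+1)
    (a per-cell monotone map, so ranks across cells are those of the CPM
    values themselves); log2cpm passes through.
    """
    if X.scale == "raw":
        return log2_cpm(X)
    if X.scale == "cpm":
        return X.with_values(np.log2(X.values + 1.0), scale="log2cpm")
    return X


# ---------------------------------------------------------------------------
# ranks / vectorized helpers

def _rank_rows(V: np.ndarray) -> np.ndarray:
    """Mid-rank each row of a 2-D array (ties averaged)."""
    return sps.rankdata(V, axis=1)


def _tie_term_rows(V: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row."""
    out = np.empty(V.shape[0])
    for i, row in enumerate(V):
        _, counts = np.unique(row, return_counts=True)
        out[i] = float((counts.astype(float) ** 3 - counts).sum())
    return out


# ---------------------------------------------------------------------------
# Spearman all-pairs engine

@dataclass
class SpearmanResult:
    """All-pairs Spearman screen over the genes of one matrix.

    ``rho`` is the full genes x genes matrix (NaN rows/columns for constant
    genes, which are excluded from the tested family). ``pair_i``/``pair_j``
    index the unordered pairs actually tested, aligned with ``pvals``.
    """

    rho: np.ndarray
    pvals: PValueSet
    pair_i: np.ndarray
    pair_j: np.ndarray
    tested_genes: np.ndarray
    genes: np.ndarray


def spearman_all_pairs(X: CountMatrix, gene_set: Optional[Sequence] = None) -> SpearmanResult:
    """Spearman correlation for every unordered gene pair.

    Computed as Pearson on mid-ranks; two-sided p-values from the
    t-approximation with n-2 degrees of freedom. Constant genes have
    undefined rho and are excluded from the family (flagged via
    ``tested_genes``).
    """
    if X.n_cells < 3:
        raise ValueError("need at least 3 cells for a Spearman screen")
    V = np.asarray(X.values, dtype=float)
    genes = X.genes
    if gene_set is not None:
        idx = np.asarray([np.flatnonzero(genes == g)[0] for g in gene_set])
        V = V[idx]
        genes = genes[idx]
    G, n = V.shape
    nonconst = np.ptp(V, axis=1) > 0
    if not np.all(nonconst):
        logger.warning("spearman_all_pairs: %d constant genes excluded", int((~nonconst).sum()))
    R = _rank_rows(V)
    rho = np.full((G, G), np.nan)
    if nonconst.sum() >= 2:
        sub = np.corrcoef(R[nonconst])
        ii = np.flatnonzero(nonconst)
        rho[np.ix_(ii, ii)] = sub
    iu, ju = np.triu_indices(G, k=1)
    keep = nonconst[iu] & nonconst[ju]
    pair_i, pair_j = iu[keep], ju[keep]
    r = rho[pair_i, pair_j]
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    pvals = PValueSet(raw=p, m=len(p))
    return SpearmanResult(
        rho=rho, pvals=pvals, pair_i=pair_i, pair_j=pair_j,
        tested_genes=nonconst, genes=genes,
    )


# ---------------------------------------------------------------------------
# two-sample and k-sample rank tests

def mann_whitney_u(x, y, use_continuity: bool = True) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Exact enumeration when both groups have <= 8 observations and no ties;
    otherwise the tie-corrected normal approximation (with continuity
    correction by default). Returns the U statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=use_continuity
    )
    return float(res.statistic), float(res.pvalue)


def mwu_matrix(
    V: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    use_continuity: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Mann-Whitney U between two cell groups.

    Vectorized tie-corrected normal approximation, matching
    :func:`mann_whitney_u` in its asymptotic regime. Returns (U of group a,
    two-sided p) per row. Rows where all pooled values tie get p = 1.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    sub = np.asarray(V, dtype=float)[:, mask_a | mask_b]
    in_a = mask_a[mask_a | mask_b]
    n1 = int(in_a.sum())
    n2 = sub.shape[1] - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    R = _rank_rows(sub)
    r1 = R[:, in_a].sum(axis=1)
    U = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = _tie_term_rows(sub)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    sd = np.sqrt(var)
    dev = np.abs(U - mu)
    if use_continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dev / sd
    p = np.where(sd > 0, 2.0 * sps.norm.sf(z), 1.0)
    return U, np.minimum(p, 1.0)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 df)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    res = sps.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def kruskal_matrix(V: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise tie-corrected Kruskal-Wallis over >= 2 groups.

    Constant rows get H = 0, p = 1.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    R = _rank_rows(V)
    ss = np.zeros(V.shape[0])
    for g in labels:
        m = groups == g
        ng = int(m.sum())
        if ng == 0:
            raise ValueError(f"group {g!r} is empty")
        rbar = R[:, m].mean(axis=1)
        ss += ng * (rbar - (n + 1) / 2.0) ** 2
    H = 12.0 / (n * (n + 1)) * ss
    tie = _tie_term_rows(V)
    corr = 1.0 - tie / (n ** 3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(corr > 0, H / corr, 0.0)
    p = np.where(corr > 0, sps.chi2.sf(H, df=k - 1), 1.0)
    return H, p


# ---------------------------------------------------------------------------
# multiplicity, AUC, effect sizes

def adjust(p: PValueSet | np.ndarray, method: str, m: Optional[int] = None) -> PValueSet:
    """Bonferroni or Benjamini-Hochberg adjustment.

    ``m`` overrides the family size (defaults to the number of p-values);
    a larger declared family simply scales the Bonferroni factor, while BH
    always uses the supplied p-values as its family.
    """
    if isinstance(p, PValueSet):
        raw = p.raw
        fam = m if m is not None else p.m
    else:
        raw = np.asarray(p, dtype=float)
        fam = m if m is not None else len(raw)
    if raw.size and (raw.min() < 0 or raw.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        adj = np.minimum(raw * fam, 1.0)
    elif method == "bh":
        if fam != len(raw):
            raise ValueError("BH family must equal the number of p-values supplied")
        adj = multipletests(raw, method="fdr_bh")[1] if raw.size else raw.copy()
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    adj = np.maximum(adj, raw)
    return PValueSet(raw=raw, m=fam, adjusted=adj, method=method)


def auroc(values, in_type) -> float:
    """AUC for predicting class membership from a single gene's expression.

    Equals U/(n1*n2) with mid-rank tie handling; values high inside the
    class give AUC > 0.5.
    """
    values = np.asarray(values, dtype=float)
    in_type = np.asarray(in_type, dtype=bool)
    n1 = int(in_type.sum())
    n2 = int((~in_type).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    R = sps.rankdata(values)
    U = R[in_type].sum() - n1 * (n1 + 1) / 2.0
    return float(U / (n1 * n2))


def auroc_matrix(V: np.ndarray, in_type: np.ndarray) -> np.ndarray:
    """Row-wise AUC (values high in-class -> AUC > 0.5)."""
    in_type = np.asarray(in_type, dtype=bool)
    n1 = int(in_type.sum())
    n2 = int((~in_type).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    R = _rank_rows(np.asarray(V, dtype=float))
    U = R[:, in_type].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return U / (n1 * n2)


def max_abs_log2fc(L: CountMatrix, groups: np.ndarray) -> np.ndarray:
    """Per-gene max over group pairs of |mean log2cpm difference|."""
    if L.scale != "log2cpm":
        raise ValueError("effect sizes are computed on log2cpm values")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    means = np.column_stack([L.values[:, groups == g].mean(axis=1) for g in labels])
    return means.max(axis=1) - means.min(axis=1)
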