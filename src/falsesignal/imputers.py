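"""Reference implementations of the imputation archetypes under evaluation.

Three archetypes cover the design space of single-cell imputation tools:

* ``knn_smooth`` — k-nearest-neighbour smoothing: each cell's profile is
  replaced by the sum of raw counts over itself and its k nearest
  neighbours (distances on log2-CPM);
* ``diffusion`` — graph-diffusion smoothing: CPM values are propagated t
  steps through a row-stochastic Markov matrix built from a symmetrized
  adaptive-Gaussian knn affinity;
* ``model_zeros`` — mixture-model zero imputation: per cluster and gene, a
  two-component mixture (gamma-distributed dropouts near zero,
  normally-distributed expressed values) is fitted to log2-CPM by EM, and
  entries with posterior dropout probability above a threshold are replaced
  by the cluster's expressed mean.

These are deliberately labelled *reference* archetypes: they reproduce the
mechanism of the published tools, not their code paths. A registry lets
external tools be evaluated through the same contract.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .stats import CPM_SCALE, log2_cpm
from .types import CountMatrix, ImputerSpec

logger = logging.getLogger(__name__)


def default_knn_k(n_cells: int) -> int:
    """Default smoothing neighbourhood: number of cells / 20."""
    return n_cells // 20


def _log2cpm_values(X: CountMatrix) -> np.ndarray:
    return log2_cpm(X).values


def _knn_distances(V: np.ndarray, k: int):
    """k nearest neighbours of each cell (excluding self) on columns of V."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(V.T)
    dist, idx = nn.kneighbors(V.T)
    return dist[:, 1:], idx[:, 1:]  # drop self (distance 0, first column)


# ---------------------------------------------------------------------------
# knn weighted-sum smoothing

def impute_knn_smooth(X: CountMatrix, k: Optional[int] = None) -> CountMatrix:
    """Sum each cell's raw counts with its k nearest neighbours.

    Distances are Euclidean on log2-CPM over all genes. ``k=None`` uses the
    default n_cells/20; ``k<=0`` is the identity; ``k >= n_cells`` is an
    error. Library sizes grow roughly (k+1)-fold.
    """
    if X.scale != "raw":
        raise ValueError("knn smoothing operates on raw counts")
    n = X.n_cells
    if k is None:
        k = default_knn_k(n)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if k <= 0:
        return X.copy()
    _, idx = _knn_distances(_log2cpm_values(X), k)
    V = np.asarray(X.values, dtype=float)
    out = V.copy()
    for j in range(n):
        out[:, j] += V[:, idx[j]].sum(axis=1)
    return X.with_values(out, scale="raw")


# ---------------------------------------------------------------------------
# graph-diffusion smoothing

def diffusion_operator(affinity: np.ndarray) -> np.ndarray:
    """Row-stochastic Markov matrix from a non-negative affinity matrix."""
    A = np.asarray(affinity, dtype=float)
    if A.min() < 0:
        raise ValueError("affinities must be non-negative")
    rows = A.sum(axis=1, keepdims=True)
    if np.any(rows <= 0):
        raise ValueError("every cell needs positive total affinity")
    return A / rows


def knn_affinity(V: np.ndarray, k: int) -> np.ndarray:
    """Symmetrized adaptive-Gaussian knn affinity between columns of V.

    Per-cell bandwidth sigma_i is the distance to the k-th neighbour;
    affinities exp(-d_ij^2 / sigma_i^2) are kept on the knn edges and
    symmetrized by averaging. The diagonal is 1 (self-affinity).
    """
    n = V.shape[1]
    if not 0 < k < n:
        raise ValueError("need 0 < k < n_cells")
    dist, idx = _knn_distances(V, k)
    sigma = np.maximum(dist[:, -1], 1e-12)
    A = np.zeros((n, n))
    w = np.exp(-(dist ** 2) / (sigma[:, None] ** 2))
    rows = np.repeat(np.arange(n), k)
    A[rows, idx.ravel()] = w.ravel()
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)
    return A


def impute_diffusion(X: CountMatrix, k: int = 12, t: int = 3) -> CountMatrix:
    """Diffuse CPM values t steps over the knn affinity graph.

    Returns values on the CPM scale. ``t=0`` returns the CPM-normalized
    input unchanged. If the knn graph splits into several connected
    components, diffusion proceeds independently within each (with a
    warning); values never leave a component.
    """
    if X.scale != "raw":
        raise ValueError("diffusion smoothing operates on raw counts")
    if t < 0:
        raise ValueError("diffusion time must be >= 0")
    lib = X.libsizes()
    if np.any(lib <= 0):
        raise ValueError("all cells need positive library sizes")
    cpm = np.asarray(X.values, dtype=float) / lib * CPM_SCALE
    if t == 0:
        return X.with_values(cpm, scale="cpm")
    A = knn_affinity(_log2cpm_values(X), k)
    n_comp, comp = connected_components(sparse.csr_matrix(A > 0), directed=False)
    if n_comp > 1:
        logger.warning("knn graph has %d connected components; diffusing per component", n_comp)
    out = cpm.copy()
    for c in range(n_comp):
        m = comp == c
        if m.sum() == 1:
            continue
        P = diffusion_operator(A[np.ix_(m, m)])
        block = out[:, m]
        for _ in range(t):
            block = block @ P.T
        out[:, m] = block
    return X.with_values(out, scale="cpm")


# ---------------------------------------------------------------------------
# mixture-model zero imputation

def _cluster_cells(X: CountMatrix, labels_or_k, random_state: int = 0) -> np.ndarray:
    """Cluster assignment: given labels verbatim, or k-means on top-10 PCs."""
    if isinstance(labels_or_k, (int, np.integer)):
        k = int(labels_or_k)
        if k < 1:
            raise ValueError("number of clusters must be >= 1")
        L = _log2cpm_values(X).T  # cells x genes
        n_pc = min(10, L.shape[0] - 1, L.shape[1])
        pcs = PCA(n_components=n_pc, random_state=random_state).fit_transform(L)
        return KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(pcs)
    labels = np.asarray(labels_or_k)
    if len(labels) != X.n_cells:
        raise ValueError("labels must align with cells")
    return labels


def _fit_dropout_mixture(v: np.ndarray, max_iter: int = 100, tol: float = 1e-6):
    """EM fit of pi*Gamma(a,b) + (1-pi)*Normal(mu,sd) to log2-CPM values.

    The gamma component captures dropouts piled up at and near zero, the
    normal component the expressed values. Gamma parameters are updated by
    weighted moment matching. Returns the posterior dropout probability per
    value and the expressed-component mean.
    """
    eps = 1e-3
    v = np.asarray(v, dtype=float)
    hi = v >= max(np.median(v[v > 0]) / 2.0, eps)
    if hi.sum() < 2 or (~hi).sum() < 1:
        return np.zeros_like(v), float(v[v > 0].mean())
    pi = float((~hi).mean())
    g_mean, g_var = max(v[~hi].mean(), eps), max(v[~hi].var(), eps ** 2)
    mu, sd = float(v[hi].mean()), max(float(v[hi].std()), 1e-2)
    resp = np.zeros_like(v)
    for _ in range(max_iter):
        a = g_mean ** 2 / g_var
        b = g_mean / g_var
        f_drop = sps.gamma.pdf(np.maximum(v, eps), a, scale=1.0 / b)
        f_expr = sps.norm.pdf(v, mu, sd)
        denom = pi * f_drop + (1.0 - pi) * f_expr
        denom = np.where(denom <= 0, 1e-300, denom)
        new_resp = pi * f_drop / denom
        w = new_resp.sum()
        if w < 1e-12 or (len(v) - w) < 1e-12:
            resp = new_resp
            break
        pi = float(w / len(v))
        g_mean = float((new_resp * np.maximum(v, eps)).sum() / w)
        g_var = max(float((new_resp * (np.maximum(v, eps) - g_mean) ** 2).sum() / w), eps ** 2)
        we = 1.0 - new_resp
        mu = float((we * v).sum() / we.sum())
        sd = max(float(np.sqrt((we * (v - mu) ** 2).sum() / we.sum())), 1e-2)
        shift = float(np.max(np.abs(new_resp - resp)))
        resp = new_resp
        if shift < tol:
            break
    else:
        logger.info("dropout-mixture EM did not converge in %d iterations", max_iter)
    expressed = resp <= 0.5
    expr_mean = float(v[expressed].mean()) if expressed.any() else mu
    return resp, expr_mean


def impute_model_zeros(
    X: CountMatrix,
    labels_or_k=None,
    threshold: float = 0.5,
    min_expressed: int = 5,
) -> CountMatrix:
    """Mixture-model imputation of presumed-technical zeros.

    Cells are clustered (or the given labels used); per gene and cluster the
    dropout/expressed mixture is fitted on log2-CPM, and entries whose
    posterior dropout probability exceeds ``threshold`` are replaced by the
    cluster mean of the expressed entries, back-transformed to counts. All
    other entries keep their original counts. Genes with fewer than
    ``min_expressed`` non-zero values in a cluster are skipped.
    """
    if X.scale != "raw":
        raise ValueError("model imputation operates on raw counts")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if labels_or_k is None:
        if X.labels is None:
            raise ValueError("provide cell labels or a cluster count")
        labels_or_k = X.labels
    clusters = _cluster_cells(X, labels_or_k)
    L = log2_cpm(X)
    lib = X.libsizes()
    out = np.asarray(X.values, dtype=float).copy()
    n_imputed = 0
    if threshold < 1.0:
        for c in np.unique(clusters):
            cm = clusters == c
            idx = np.flatnonzero(cm)
            block = L.values[:, cm]
            for g in range(X.n_genes):
                v = block[g]
                if (v > 0).sum() < min_expressed or np.all(v > 0):
                    continue
                resp, expr_mean = _fit_dropout_mixture(v)
                to_fix = resp > threshold
                if not to_fix.any():
                    continue
                cols = idx[to_fix]
                out[g, cols] = np.rint((2.0 ** expr_mean - 1.0) * lib[cols] / CPM_SCALE)
                n_imputed += len(cols)
    result = X.with_values(np.maximum(out, 0.0), scale="raw")
    result.n_imputed = n_imputed  # type: ignore[attr-defined]
    return result


# ---------------------------------------------------------------------------
# registry

ImputerFn = Callable[..., CountMatrix]

_REGISTRY: dict[str, ImputerFn] = {}


def register_imputer(name_or_spec, fn: ImputerFn) -> None:
    """Register an imputer under a unique name.

    The callable takes a raw CountMatrix (plus keyword parameters) and
    returns a CountMatrix of the same shape and ordering.
    """
    name = name_or_spec.name if isinstance(name_or_spec, ImputerSpec) else str(name_or_spec)
    if name in _REGISTRY:
        raise ValueError(f"imputer {name!r} is already registered")
    _REGISTRY[name] = fn


def get_imputer(name: str) -> ImputerFn:
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown imputer {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def list_imputers() -> list[str]:
    return sorted(_REGISTRY)


def run_imputer(name: str, X: CountMatrix, **params) -> CountMatrix:
    return get_imputer(name)(X, **params)


def _register_builtins() -> None:
    register_imputer("raw", lambda X, **kw: X.copy())
    register_imputer("knn_smooth", impute_knn_smooth)
    register_imputer("diffusion", impute_diffusion)
    register_imputer("model_zeros", impute_model_zeros)


_register_builtins()
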