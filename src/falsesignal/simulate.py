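"""Synthetic single-cell count data.

Two generators drive all experiments:

* a two-group negative-binomial simulation with gene means log-spaced over
  a wide expression range and a configurable fraction of genes differing by
  a fixed fold between the groups (no library-size variation, no added
  dropout) — the setting where a well-behaved imputer should either leave
  the data alone or flatten non-DE genes;
* a splat-style grouped simulation: gamma-distributed gene means, log-normal
  library sizes, negative-binomial counts with a biological coefficient of
  variation, an optional logistic technical-dropout layer keyed to each
  entry's log mean, and either discrete groups or a continuous
  differentiation path.

Both are fully deterministic given their configuration and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .types import (
    CalibrationError,
    ConfigurationError,
    CountMatrix,
    SimTruth,
    SimulatedDataset,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configurations

@dataclass
class NBSimConfig:
    """Two-group negative-binomial simulation settings.

    Defaults give 1000 cells in two equal groups and 500 genes with mean
    expression log-spaced from 1e-3 to 1e4 counts per cell; half the genes
    are DE by a factor of 10 (half up in each group). ``dispersion_size`` is
    the NB size parameter (variance mu + mu^2/size).
    """

    n_cells: int = 1000
    n_genes: int = 500
    mean_lo: float = 1e-3
    mean_hi: float = 1e4
    de_fraction: float = 0.5
    de_fold: float = 10.0
    dispersion_size: float = 1.0
    n_reps: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_cells % 2:
            raise ConfigurationError("n_cells must be positive and even (two equal groups)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if not self.mean_lo < self.mean_hi:
            raise ConfigurationError("mean_lo must be < mean_hi")
        if self.de_fold <= 1.0:
            raise ConfigurationError("de_fold must exceed 1")
        if self.dispersion_size <= 0:
            raise ConfigurationError("dispersion_size must be positive")


@dataclass
class GroupSimConfig:
    """Splat-style grouped/path simulation settings.

    Gene means are gamma(shape, rate); per-cell library sizes are
    log-normal; counts are NB with size 1/bcv^2. DE genes receive a
    multiplicative factor (``de_factor`` up or its reciprocal down) on one
    group's mean, round-robin over groups. Dropout is enabled by setting
    ``dropout_midpoint``: each count is zeroed with probability
    logistic(dropout_shape * (ln(mu) - midpoint)).
    """

    n_cells: int = 1000
    n_genes: int = 2000
    n_groups: int = 5
    de_total_fraction: float = 0.10
    de_factor: float = 10.0
    mode: str = "groups"
    dropout_midpoint: Optional[float] = None
    dropout_shape: float = -1.0
    gene_mean_shape: float = 0.6
    gene_mean_rate: float = 0.3
    libsize_logmean: float = 11.0
    libsize_logsd: float = 0.2
    bcv: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_cells and n_genes must be positive")
        if self.n_groups < 2:
            raise ConfigurationError("need at least 2 groups")
        if self.n_cells % self.n_groups:
            raise ConfigurationError(
                f"n_cells={self.n_cells} is not divisible by n_groups={self.n_groups}"
            )
        if not 0.0 < self.de_total_fraction < 1.0:
            raise ConfigurationError("de_total_fraction must lie in (0, 1)")
        if self.mode not in ("groups", "paths"):
            raise ConfigurationError("mode must be 'groups' or 'paths'")
        if self.dropout_shape >= 0:
            raise ConfigurationError("dropout_shape must be negative")
        if self.bcv <= 0:
            raise ConfigurationError("bcv must be positive")

    @property
    def dropout_enabled(self) -> bool:
        return self.dropout_midpoint is not None


# ---------------------------------------------------------------------------
# negative-binomial two-group simulation

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    """NB(mean=mu, size) via numpy's (n, p) parameterization."""
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _spread_indices(n_total: int, n_pick: int) -> np.ndarray:
    """n_pick indices spread evenly over range(n_total)."""
    if n_pick == 0:
        return np.empty(0, dtype=int)
    if n_pick > n_total:
        raise ConfigurationError("cannot pick more DE genes than genes")
    # floor(k * n/m) is strictly increasing for m <= n: exactly m distinct indices
    return (np.arange(n_pick) * n_total // n_pick).astype(int)


def simulate_nb_two_groups(cfg: NBSimConfig, rep_index: int = 0) -> SimulatedDataset:
    """Simulate one replicate of the two-group NB experiment.

    Gene base means sit on a deterministic log-spaced grid over
    [mean_lo, mean_hi]; exactly round(de_fraction * n_genes) genes are DE by
    ``de_fold`` (alternately up in group B and up in group A, spread across
    the expression range); all other genes share one mean in both groups.
    Deterministic given (cfg.seed, rep_index).
    """
    cfg.validate()
    n_de_exact = cfg.de_fraction * cfg.n_genes
    n_de = int(round(n_de_exact))
    if abs(n_de_exact - n_de) > 1e-9:
        logger.warning(
            "de_fraction * n_genes = %.3f is not an integer; rounding to %d",
            n_de_exact, n_de,
        )
    rng = np.random.default_rng(cfg.seed + rep_index)
    base = np.logspace(math.log10(cfg.mean_lo), math.log10(cfg.mean_hi), cfg.n_genes)

    de_idx = _spread_indices(cfg.n_genes, n_de)
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    is_de[de_idx] = True
    direction = np.zeros(cfg.n_genes, dtype=np.int8)
    direction[de_idx] = np.where(np.arange(len(de_idx)) % 2 == 0, 1, -1)
    fold = np.where(is_de, cfg.de_fold, 1.0)

    mean_a = np.where(direction == -1, base * cfg.de_fold, base)
    mean_b = np.where(direction == 1, base * cfg.de_fold, base)

    half = cfg.n_cells // 2
    mu = np.empty((cfg.n_genes, cfg.n_cells))
    mu[:, :half] = mean_a[:, None]
    mu[:, half:] = mean_b[:, None]
    counts = _nb_draw(rng, mu, cfg.dispersion_size)

    groups = np.array(["A"] * half + ["B"] * half, dtype=object)
    genes = np.array([f"G{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    cells = np.array([f"C{i:04d}" for i in range(cfg.n_cells)], dtype=object)
    cm = CountMatrix(values=counts, genes=genes, cells=cells, labels=groups, scale="raw")
    truth = SimTruth(
        is_de=is_de, direction=direction, fold=fold,
        group_labels=groups, base_mean=base,
        dropout_mask=np.zeros_like(counts, dtype=bool),
    )
    return SimulatedDataset(counts=cm, truth=truth)


# ---------------------------------------------------------------------------
# splat-style grouped / paths simulation

def _grouped_means(cfg: GroupSimConfig, rng: np.random.Generator):
    """Per-group expected-count matrix plus truth bookkeeping arrays."""
    gene_means = rng.gamma(cfg.gene_mean_shape, 1.0 / cfg.gene_mean_rate, cfg.n_genes)
    gene_means = np.maximum(gene_means, 1e-10)

    n_de = int(round(cfg.de_total_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    de_idx.sort()
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    is_de[de_idx] = True
    direction = np.zeros(cfg.n_genes, dtype=np.int8)
    direction[de_idx] = np.where(np.arange(n_de) % 2 == 0, 1, -1)
    de_group = np.full(cfg.n_genes, -1)
    de_group[de_idx] = np.arange(n_de) % cfg.n_groups
    fold = np.where(is_de, cfg.de_factor, 1.0)

    group_means = np.repeat(gene_means[:, None], cfg.n_groups, axis=1)
    factors = np.where(direction[de_idx] == 1, cfg.de_factor, 1.0 / cfg.de_factor)
    group_means[de_idx, de_group[de_idx]] *= factors
    return gene_means, group_means, is_de, direction, fold, de_group


def _simulate_grouped_raw(
    cfg: GroupSimConfig,
    rng_truth: np.random.Generator,
    rng_noise: np.random.Generator,
):
    """Counts before dropout plus the per-entry mean matrix and truth.

    The truth draw (gene means, DE assignment) and the noise draw (library
    sizes, path positions, NB sampling) use separate generators so matched
    datasets can share one truth.
    """
    gene_means, group_means, is_de, direction, fold, de_group = _grouped_means(cfg, rng_truth)
    per_group = cfg.n_cells // cfg.n_groups
    group_of_cell = np.repeat(np.arange(cfg.n_groups), per_group)
    lib = rng_noise.lognormal(cfg.libsize_logmean, cfg.libsize_logsd, cfg.n_cells)

    if cfg.mode == "groups":
        props = group_means / group_means.sum(axis=0, keepdims=True)
        mu = props[:, group_of_cell] * lib
    else:  # paths: interpolate log-means from the common origin to the anchor
        u = rng_noise.uniform(0.0, 1.0, cfg.n_cells)
        log_origin = np.log(gene_means)
        log_anchor = np.log(group_means)
        logmu = (1.0 - u) * log_origin[:, None] + u * log_anchor[:, group_of_cell]
        prof = np.exp(logmu)
        mu = prof / prof.sum(axis=0, keepdims=True) * lib

    size = 1.0 / cfg.bcv ** 2
    counts = _nb_draw(rng_noise, mu, size)
    truth = SimTruth(
        is_de=is_de, direction=direction, fold=fold,
        group_labels=np.array([f"T{g}" for g in group_of_cell], dtype=object),
        base_mean=gene_means, de_group=de_group,
    )
    return counts, mu, truth


def _finish_grouped(cfg: GroupSimConfig, counts, mu, truth,
                    rng_noise: np.random.Generator) -> SimulatedDataset:
    if cfg.dropout_enabled:
        p_drop = expit(cfg.dropout_shape * (np.log(mu) - cfg.dropout_midpoint))
        dropped = rng_noise.random(counts.shape) < p_drop
        counts = np.where(dropped, 0, counts)
        truth.dropout_mask = dropped
    else:
        truth.dropout_mask = np.zeros_like(counts, dtype=bool)

    genes = np.array([f"G{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    cells = np.array([f"C{i:04d}" for i in range(cfg.n_cells)], dtype=object)
    cm = CountMatrix(
        values=counts, genes=genes, cells=cells,
        labels=truth.group_labels, scale="raw",
    )
    return SimulatedDataset(counts=cm, truth=truth)


def simulate_grouped(cfg: GroupSimConfig, noise_seed: Optional[int] = None) -> SimulatedDataset:
    """Simulate a splat-style grouped (or paths) dataset.

    If dropout is enabled, each count is independently replaced by zero with
    probability logistic(dropout_shape * (ln(mu) - dropout_midpoint)) and the
    event recorded in the truth's dropout mask. ``noise_seed`` redraws the
    sampling noise (library sizes, counts, dropout events) while keeping the
    ground truth fixed by ``cfg.seed`` — two noise seeds give a matched
    dataset pair sharing one truth.
    """
    cfg.validate()
    rng_truth = np.random.default_rng(cfg.seed)
    rng_noise = rng_truth if noise_seed is None else np.random.default_rng(noise_seed)
    counts, mu, truth = _simulate_grouped_raw(cfg, rng_truth, rng_noise)
    return _finish_grouped(cfg, counts, mu, truth, rng_noise)


def simulate_matched_pair(
    cfg: GroupSimConfig,
    noise_seeds: tuple[int, int],
    dropout_midpoints: tuple[Optional[float], Optional[float]] = (None, None),
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Two independent count draws from one ground truth.

    Emulates a matched pair of datasets profiling the same tissue on two
    platforms: identical DE structure, independent sampling noise, and
    optionally different dropout severities.
    """
    out = []
    for ns, mid in zip(noise_seeds, dropout_midpoints):
        out.append(simulate_grouped(replace(cfg, dropout_midpoint=mid), noise_seed=ns))
    return out[0], out[1]


def zero_fraction(dataset: SimulatedDataset) -> float:
    """Fraction of zero entries in the simulated count matrix."""
    return float((dataset.counts.values == 0).mean())


def calibrate_dropout_midpoint(
    cfg: GroupSimConfig,
    target_zero_fraction: float,
    tol: float = 0.01,
    max_iter: int = 60,
) -> float:
    """Find the dropout midpoint that realizes a target zero fraction.

    Simulates the base (no-dropout) counts once under ``cfg.seed`` and
    bisects the midpoint against the expected zero fraction
    mean((count == 0) + (count > 0) * p_drop), which is smooth and strictly
    increasing in the midpoint; at matrix sizes of ~10^6 entries the
    realized Bernoulli fraction coincides with this expectation to well
    below ``tol``. Raises :class:`CalibrationError` when the target is not
    above the base zero fraction (dropout can only add zeros).
    """
    cfg.validate()
    if not 0.0 < target_zero_fraction < 1.0:
        raise CalibrationError("target zero fraction must lie in (0, 1)")
    base_cfg = replace(cfg, dropout_midpoint=None)
    rng = np.random.default_rng(base_cfg.seed)
    counts, mu, _ = _simulate_grouped_raw(base_cfg, rng, rng)
    base_zero = float((counts == 0).mean())
    if target_zero_fraction <= base_zero:
        raise CalibrationError(
            f"target {target_zero_fraction:.3f} is not above the base "
            f"zero fraction {base_zero:.3f}; dropout cannot remove zeros"
        )
    logmu = np.log(mu)
    nonzero = counts != 0

    def expected(m: float) -> float:
        p = expit(cfg.dropout_shape * (logmu[nonzero] - m))
        return base_zero + float(p.sum()) / counts.size

    lo = float(logmu.min()) - 20.0
    hi = float(logmu.max()) + 20.0
    # converge well inside tol so the search's own stopping error is
    # negligible next to the Monte-Carlo variation of a fresh simulation
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = expected(mid)
        if abs(f - target_zero_fraction) <= tol / 5.0:
            return mid
        if f < target_zero_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
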