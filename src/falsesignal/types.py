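"""Core containers shared by every stage of the framework.

The working unit is a genes-by-cells count matrix with string identifiers,
optional per-cell type labels and a scale tag that records whether values
are raw counts, counts-per-million, or log2(CPM+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

VALID_SCALES = ("raw", "cpm", "log2cpm")


class ConfigurationError(ValueError):
    """A simulation or experiment configuration violates its invariants."""


class CalibrationError(ValueError):
    """Dropout calibration cannot reach the requested zero fraction."""


@dataclass
class CountMatrix:
    """Genes x cells expression matrix.

    Parameters
    ----------
    values
        2-D array, rows are genes, columns are cells.
    genes, cells
        Identifier arrays matching the two axes.
    labels
        Optional per-cell type labels (aligned with ``cells``).
    scale
        One of ``raw`` (non-negative counts), ``cpm``, ``log2cpm``.
    """

    values: np.ndarray
    genes: np.ndarray
    cells: np.ndarray
    labels: Optional[np.ndarray] = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.cells):
                raise ValueError("labels must align with cells")
        if self.scale == "raw" and self.values.size and self.values.min() < 0:
            raise ValueError("raw counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def libsizes(self) -> np.ndarray:
        """Per-cell library sizes (column sums); only meaningful for raw counts."""
        if self.scale != "raw":
            raise ValueError("library sizes are defined on the raw scale")
        return np.asarray(self.values.sum(axis=0), dtype=float)

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            values=self.values.copy(),
            genes=self.genes.copy(),
            cells=self.cells.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            scale=self.scale,
        )

    def with_values(self, values: np.ndarray, scale: Optional[str] = None) -> "CountMatrix":
        """Same annotation, new value matrix (and optionally a new scale tag)."""
        return replace(self, values=values, scale=scale or self.scale)

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = slice(None) if gene_mask is None else np.asarray(gene_mask)
        cm = slice(None) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            values=self.values[gm][:, cm],
            genes=self.genes[gm],
            cells=self.cells[cm],
            labels=None if self.labels is None else self.labels[cm],
            scale=self.scale,
        )


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset.

    ``direction`` is +1 for genes up-regulated in the affected group, -1 for
    down, 0 for non-DE genes. ``dropout_mask`` marks entries zeroed by the
    technical-dropout layer (always a subset of the zero entries).
    """

    is_de: np.ndarray
    direction: np.ndarray
    fold: np.ndarray
    group_labels: np.ndarray
    base_mean: Optional[np.ndarray] = None
    de_group: Optional[np.ndarray] = None
    dropout_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.is_de = np.asarray(self.is_de, dtype=bool)
        self.direction = np.asarray(self.direction, dtype=np.int8)
        self.fold = np.asarray(self.fold, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        n = len(self.is_de)
        if not (len(self.direction) == len(self.fold) == n):
            raise ValueError("per-gene truth arrays must share one length")

    @property
    def n_de(self) -> int:
        return int(self.is_de.sum())


@dataclass
class SimulatedDataset:
    """A simulated count matrix bundled with its ground truth."""

    counts: CountMatrix
    truth: SimTruth

    def __post_init__(self) -> None:
        if self.counts.scale != "raw":
            raise ValueError("simulated counts must be on the raw scale")
        if len(self.truth.group_labels) != self.counts.n_cells:
            raise ValueError("truth group labels must cover every cell")
        if len(self.truth.is_de) != self.counts.n_genes:
            raise ValueError("truth DE flags must cover every gene")
        if self.truth.dropout_mask is not None:
            zeros = self.counts.values == 0
            if np.any(self.truth.dropout_mask & ~zeros):
                raise ValueError("dropout mask marks a non-zero entry")


@dataclass
class PValueSet:
    """A family of p-values with an optional multiplicity adjustment.

    ``m`` is the family size: the number of hypotheses actually tested,
    which the Bonferroni factor and the BH step-up both use.
    """

    raw: np.ndarray
    m: int
    adjusted: Optional[np.ndarray] = None
    method: Optional[str] = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.size and (self.raw.min() < 0 or self.raw.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.m < 1:
            raise ValueError("family size must be >= 1")
        if self.adjusted is not None:
            self.adjusted = np.asarray(self.adjusted, dtype=float)


@dataclass
class ImputerSpec:
    """Named imputer archetype plus the parameters that matter for it.

    Smoothers use ``k_neighbours`` (and ``diffusion_t`` for the diffusion
    archetype); the mixture-model imputer uses ``dropout_threshold`` and
    ``n_clusters`` (an integer, or ``"use-labels"`` to cluster by the
    provided cell-type labels).
    """

    name: str
    k_neighbours: Optional[int] = None
    diffusion_t: Optional[int] = None
    dropout_threshold: float = 0.5
    n_clusters: object = "use-labels"
    extra: dict = field(default_factory=dict)

    def params(self) -> dict:
        out = dict(self.extra)
        if self.k_neighbours is not None:
            out["k"] = self.k_neighbours
        if self.diffusion_t is not None:
            out["t"] = self.diffusion_t
        return out
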