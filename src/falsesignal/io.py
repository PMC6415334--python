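"""Readers and writers for the standard on-disk formats.

Count matrices travel as 10x-style Matrix-Market triplets (matrix.mtx +
genes.tsv + barcodes.tsv, genes as rows) or as dense TSV with gene rows and
a header of cell identifiers. Labels and simulation truth are plain TSV.
Gzip-compressed files are handled transparently via their .gz suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import GroupSimConfig, simulate_grouped
from .types import CountMatrix, SimTruth, SimulatedDataset

PathLike = Union[str, Path]


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / stem, dirpath / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def _dedupe(names: np.ndarray) -> np.ndarray:
    """Suffix duplicate identifiers deterministically (_1, _2, ...)."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        n = str(n)
        if n in seen:
            seen[n] += 1
            out.append(f"{n}_{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return np.array(out, dtype=object)


def _read_tsv_column(path: Path) -> np.ndarray:
    with _open_maybe_gz(path) as fh:
        return np.array([line.rstrip("\n").split("\t")[0] for line in fh if line.strip()],
                        dtype=object)


def read_counts(path: PathLike, format: str = "mtx_triplet") -> CountMatrix:
    """Load a genes x cells count matrix.

    ``mtx_triplet`` expects a directory holding matrix.mtx(.gz),
    genes.tsv(.gz) and barcodes.tsv(.gz); the matrix is transposed if it
    was written cells x genes, and a dimension mismatch with the sidecar
    files is an error. ``dense_tsv`` expects one TSV file with gene rows
    and a header row of cell identifiers.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx_path = _find(path, "matrix.mtx")
        genes = _read_tsv_column(_find(path, "genes.tsv"))
        cells = _read_tsv_column(_find(path, "barcodes.tsv"))
        with _open_maybe_gz(mtx_path, "rb" if mtx_path.suffix != ".gz" else "rb") as fh:
            M = spio.mmread(fh)
        M = np.asarray(M.todense() if sparse.issparse(M) else M)
        if M.shape == (len(genes), len(cells)):
            pass
        elif M.shape == (len(cells), len(genes)):
            M = M.T
        else:
            raise ValueError(
                f"matrix shape {M.shape} matches neither {len(genes)} genes "
                f"x {len(cells)} cells nor its transpose"
            )
        return CountMatrix(values=M, genes=_dedupe(genes), cells=_dedupe(cells))
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(
            values=df.to_numpy(),
            genes=_dedupe(df.index.to_numpy()),
            cells=_dedupe(df.columns.to_numpy()),
        )
    raise ValueError(f"unknown format {format!r}")


def write_counts(X: CountMatrix, outdir: PathLike) -> Path:
    """Write a Matrix-Market triplet (plus labels.tsv when labels exist)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vals = X.values
    if X.scale == "raw" and np.allclose(vals, np.rint(vals)):
        M = sparse.coo_matrix(vals.astype(np.int64))
    else:
        M = sparse.coo_matrix(vals)
    spio.mmwrite(outdir / "matrix.mtx", M)
    (outdir / "genes.tsv").write_text("\n".join(map(str, X.genes)) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(map(str, X.cells)) + "\n")
    if X.labels is not None:
        write_labels(X.cells, X.labels, outdir / "labels.tsv")
    return outdir


def write_dense_tsv(X: CountMatrix, path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(X.values, index=X.genes, columns=X.cells).to_csv(path, sep="\t")
    return path


def write_labels(cells, labels, path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame({"cell": cells, "type": labels}).to_csv(path, sep="\t", index=False)
    return path


def read_labels(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("cell")["type"]


def write_truth(genes, truth: SimTruth, path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "gene": genes,
            "de_flag": truth.is_de.astype(int),
            "direction": truth.direction,
            "fold": truth.fold,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_truth(path: PathLike, group_labels=None) -> SimTruth:
    df = pd.read_csv(path, sep="\t")
    return SimTruth(
        is_de=df["de_flag"].to_numpy(dtype=bool),
        direction=df["direction"].to_numpy(),
        fold=df["fold"].to_numpy(),
        group_labels=np.asarray(group_labels if group_labels is not None else [],
                                dtype=object),
    )


def write_dataset(ds: SimulatedDataset, outdir: PathLike) -> Path:
    outdir = Path(outdir)
    write_counts(ds.counts, outdir)
    write_truth(ds.counts.genes, ds.truth, outdir / "truth.tsv")
    return outdir


def make_fixtures(seed: int = 0, outdir: Optional[PathLike] = None) -> SimulatedDataset:
    """Miniature labelled dataset (50 genes x 120 cells, 3 types) for tests."""
    cfg = GroupSimConfig(
        n_cells=120, n_genes=50, n_groups=3, de_total_fraction=0.2,
        libsize_logmean=7.0, seed=seed,
    )
    ds = simulate_grouped(cfg)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds
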