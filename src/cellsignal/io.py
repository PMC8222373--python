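"""Readers and writers for the plain-text formats the package touches.

Dense matrices travel as tab-delimited UTF-8 TSV ('.' decimal) with a
header row and gene ids in the first column; sparse single-cell counts as
MatrixMarket MTX (1-based indices) with sidecar gene/barcode TSVs. Fit
outputs pair a fractions TSV with a JSON manifest capturing config, seed
and input checksums so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from . import __version__
from .containers import (
    AnnotatedCellMatrix,
    BulkExpressionSet,
    FitConfig,
    FitResult,
    GeneWeights,
    ReferenceSignalSet,
)
from .similarity import SimilarityModel

log = logging.getLogger(__name__)


def _check_dup(ids, what: str, path) -> pd.Index:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} in {path}: {dups}")
    return idx


def _find(directory: Path, names: list[str]) -> Path:
    for name in names:
        for cand in (directory / name, directory / (name + ".tsv"), directory / (name + ".txt")):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {names} found in {directory}")


def read_counts(path, fmt: str = "auto") -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Read a gene x column count matrix from an MTX directory or dense TSV.

    Returns (values, gene_ids, column_ids). MTX indices are 1-based on disk
    and converted to 0-based positions; a dense TSV must carry a header row
    and gene ids in the first column.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx" if path.is_dir() else "tsv"
    if fmt == "mtx":
        mtx = _find(path, ["matrix.mtx"])
        genes_f = _find(path, ["genes", "features"])
        barcodes_f = _find(path, ["barcodes"])
        mat = mmread(mtx).toarray()
        genes = pd.read_csv(genes_f, sep="\t", header=None).iloc[:, 0].astype(str)
        cells = pd.read_csv(barcodes_f, sep="\t", header=None).iloc[:, 0].astype(str)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{mtx}: matrix is {mat.shape} but sidecars list "
                f"{len(genes)} genes x {len(cells)} barcodes"
            )
        return mat, _check_dup(genes, "gene ids", genes_f), _check_dup(cells, "cell ids", barcodes_f)
    if fmt == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        body_cells = header[1:]
        if not body_cells or all(_is_number(c) for c in body_cells):
            raise ValueError(f"{path}: line 1 must be a header row of column ids")
        df = pd.read_csv(path, sep="\t", index_col=0)
        return (
            df.to_numpy(float),
            _check_dup(df.index.astype(str), "gene ids", path),
            _check_dup(df.columns.astype(str), "column ids", path),
        )
    raise ValueError(f"unknown format: {fmt!r}")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_cell_meta(path, cluster_column: str = "cluster") -> pd.DataFrame:
    """Cell metadata TSV keyed by cell id; renames the cluster column."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if cluster_column != "cluster":
        if cluster_column not in meta.columns:
            raise ValueError(f"{path}: missing cluster column {cluster_column!r}")
        meta = meta.rename(columns={cluster_column: "cluster"})
    return meta


def read_annotated_cells(
    counts_path, meta_path, cluster_column: str = "cluster"
) -> AnnotatedCellMatrix:
    counts, genes, cells = read_counts(counts_path)
    meta = read_cell_meta(meta_path, cluster_column)
    missing = cells.difference(meta.index)
    if len(missing):
        raise ValueError(f"cells without metadata: {missing.tolist()[:5]}")
    return AnnotatedCellMatrix(
        counts=counts, gene_ids=genes, cell_ids=cells, meta=meta.loc[cells]
    )


def read_lengths(path) -> pd.DataFrame | pd.Series:
    """Effective gene lengths: 2-column (gene, length) or gene x sample TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    idx = _check_dup(df.index.astype(str), "gene ids", path)
    vals = df.to_numpy(float)
    if np.any(vals <= 0) or np.any(~np.isfinite(vals)):
        bad = idx[np.any((vals <= 0) | ~np.isfinite(vals), axis=1)].tolist()[:5]
        raise ValueError(f"{path}: non-positive lengths for genes {bad}")
    df.index = idx
    if df.shape[1] == 1:
        return df.iloc[:, 0]
    return df


def read_weights(path, default: float = 1.0) -> GeneWeights:
    """Gene weights: 2-column (gene, weight) TSV; unlisted genes default."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    idx = _check_dup(df.index.astype(str), "gene ids", path)
    return GeneWeights(weights=dict(zip(idx, df.iloc[:, 0].astype(float))), default=default)


def read_two_column_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_signals(path) -> ReferenceSignalSet:
    values, genes, cols = read_counts(path, fmt="tsv")
    return ReferenceSignalSet(signals=values, gene_ids=genes, signal_ids=cols)


def write_signals(signals: ReferenceSignalSet, path) -> None:
    signals.to_frame().to_csv(path, sep="\t")


def read_bulk(counts_path, lengths_path) -> BulkExpressionSet:
    counts, genes, samples = read_counts(counts_path, fmt="tsv")
    lengths = read_lengths(lengths_path)
    if isinstance(lengths, pd.Series):
        missing = genes.difference(lengths.index)
        if len(missing):
            raise ValueError(f"genes without lengths: {missing.tolist()[:5]}")
        lvals = lengths.loc[genes].to_numpy()
    else:
        lvals = lengths.loc[genes, samples].to_numpy()
    return BulkExpressionSet(
        fragment_counts=counts,
        effective_lengths=lvals,
        gene_ids=genes,
        sample_ids=samples,
    )


def _checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fit(
    result: FitResult,
    path,
    config: FitConfig | None = None,
    inputs: dict[str, str] | None = None,
    write_exposures: bool = False,
) -> None:
    """Write per-sample fractions TSV plus a JSON run manifest.

    The TSV has one row per sample: one column per signal, "unexplained",
    "pseudo_r2" and "converged". The manifest records config, seed, matrix
    sizes, package version and md5 checksums of the declared inputs.
    """
    if result.normalized_fractions is None:
        raise ValueError("normalize the fit before writing it")
    path = Path(path)
    out = result.normalized_fractions.copy()
    out["pseudo_r2"] = (
        result.pseudo_r2 if result.pseudo_r2 is not None else np.nan
    )
    out["converged"] = bool(result.converged)
    out.to_csv(path, sep="\t", float_format="%.12g")
    if write_exposures:
        pd.DataFrame(
            result.exposures.T,
            index=result.sample_ids,
            columns=list(result.signal_ids)
            + (["intercept"] if result.intercept_enabled else []),
        ).to_csv(path.with_suffix(".exposures.tsv"), sep="\t")
    manifest = {
        "package_version": __version__,
        "config": asdict(config) if config else None,
        "seed": config.seed if config else None,
        "n_genes": result.m,
        "n_signals": result.n,
        "n_samples": result.n_samples,
        "converged": bool(result.converged),
        "inputs": {k: {"path": str(v), "md5": _checksum(v)} for k, v in (inputs or {}).items()},
    }
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def read_fit_fractions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_similarity_model(model: SimilarityModel, directory) -> None:
    """Nonzero coefficients as TSV plus a JSON header of scalars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for ki, klass in enumerate(model.class_ids):
        nz = np.flatnonzero(model.coefficients[ki])
        for gi in nz:
            rows.append((klass, model.gene_ids[gi], model.coefficients[ki, gi]))
    pd.DataFrame(rows, columns=["class", "gene", "coefficient"]).to_csv(
        directory / "coefficients.tsv", sep="\t", index=False
    )
    header = {
        "classes": list(model.class_ids),
        "genes": list(model.gene_ids),
        "intercepts": model.intercepts.tolist(),
        "offsets": model.offsets.tolist(),
        "strengths": model.strengths.tolist(),
        "alpha": model.alpha,
        "folds": model.folds,
        "seed": model.seed,
    }
    (directory / "model.json").write_text(json.dumps(header, indent=2))


def read_similarity_model(directory) -> SimilarityModel:
    directory = Path(directory)
    header = json.loads((directory / "model.json").read_text())
    genes = pd.Index(header["genes"])
    classes = pd.Index(header["classes"])
    coefs = np.zeros((len(classes), len(genes)))
    tab = pd.read_csv(directory / "coefficients.tsv", sep="\t")
    ci = classes.get_indexer(tab["class"])
    gi = genes.get_indexer(tab["gene"])
    coefs[ci, gi] = tab["coefficient"].to_numpy(float)
    return SimilarityModel(
        gene_ids=genes,
        class_ids=classes,
        coefficients=coefs,
        intercepts=np.asarray(header["intercepts"], float),
        offsets=np.asarray(header["offsets"], float),
        strengths=np.asarray(header["strengths"], float),
        alpha=header["alpha"],
        folds=header["folds"],
        seed=header["seed"],
    )


def write_mtx_dir(counts: np.ndarray, gene_ids, cell_ids, directory) -> None:
    """Write counts in the MTX + genes/barcodes dialect read_counts consumes."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(directory / "matrix.mtx", coo_matrix(counts))
    pd.Series(list(gene_ids)).to_csv(
        directory / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(list(cell_ids)).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )
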