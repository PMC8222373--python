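"""Build reference signals from cluster-annotated single-cell counts.

A reference signal is a cell population's expression profile: raw UMI counts
summed over all cells of the population and normalized to sum to 1 over
genes. Signals built here feed the bulk exposure fit; the log-normalized
matrix produced by :func:`normalize_cells` feeds similarity training only.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    AnnotatedCellMatrix,
    NormalizedCellMatrix,
    ReferenceSignalSet,
    strip_gene_version,
)

log = logging.getLogger(__name__)


def apply_qc_filters(
    cells: AnnotatedCellMatrix,
    mito_max: float = 0.05,
    min_genes: int = 500,
    cluster_fail_max: float = 0.5,
    drop_cycling: bool = True,
    drop_leucocytes: bool = True,
) -> AnnotatedCellMatrix:
    """Remove low-quality cells and clusters dominated by them.

    A cell *fails* if its mitochondrial fraction exceeds ``mito_max``, it is
    flagged as a doublet, or it expresses fewer than ``min_genes`` distinct
    genes. Whole clusters are dropped when more than ``cluster_fail_max`` of
    their cells fail (failing cells drag down transcriptionally similar
    neighbours, so the whole cluster is treated as suspect). Cycling cells
    (S/G2M) and leucocytes are additionally removed when the respective flag
    is set, so that reference signals reflect cell identity rather than
    cell-cycle state or infiltrating immune cells.

    The cluster-level rule is evaluated once, on the original cluster
    composition, not iterated after removals.
    """
    meta = cells.meta
    fails = (
        (meta["mito_fraction"].to_numpy(float) > mito_max)
        | meta["doublet"].to_numpy(bool)
        | (meta["n_distinct_genes"].to_numpy(int) < min_genes)
    )
    fail_frac = pd.Series(fails, index=meta.index).groupby(meta["cluster"]).mean()
    bad_clusters = set(fail_frac.index[fail_frac > cluster_fail_max])

    keep = ~fails & ~meta["cluster"].isin(bad_clusters).to_numpy()
    if drop_cycling:
        keep &= ~meta["cycle_phase"].isin(["S", "G2M"]).to_numpy()
    if drop_leucocytes:
        keep &= ~meta["leucocyte"].to_numpy(bool)

    n_drop = int((~keep).sum())
    if n_drop:
        log.info(
            "QC removed %d/%d cells (%d whole clusters)",
            n_drop,
            cells.n_cells,
            len(bad_clusters),
        )
    if not keep.any():
        raise ValueError(
            "QC filters removed every cell; review mito_max/min_genes/"
            "cluster_fail_max thresholds"
        )
    return cells.subset_cells(keep)


def normalize_cells(
    cells: AnnotatedCellMatrix, scale_factor: float = 10_000.0
) -> NormalizedCellMatrix:
    """Depth-normalize and log-transform: y = log(1 + F * x / colsum(x)).

    Scaling all counts of a cell by a constant leaves its normalized column
    unchanged, so the transform removes per-cell sequencing depth.
    """
    totals = cells.counts.sum(axis=0)
    if np.any(totals <= 0):
        zero = cells.cell_ids[totals <= 0].tolist()[:5]
        raise ValueError(f"cells with zero total counts (QC-filter first): {zero}")
    values = np.log1p(scale_factor * cells.counts / totals)
    return NormalizedCellMatrix(
        values=values,
        gene_ids=cells.gene_ids,
        cell_ids=cells.cell_ids,
        scale_factor=scale_factor,
    )


def build_signals(cells: AnnotatedCellMatrix) -> ReferenceSignalSet:
    """Sum raw counts per cluster and normalize each cluster to sum 1.

    Only per-cluster totals matter: the result is invariant to cell order
    and to how counts are split across a cluster's cells.
    """
    clusters = cells.meta["cluster"]
    labels = pd.Index(sorted(clusters.unique()))
    sums = np.zeros((cells.n_genes, len(labels)))
    for j, lab in enumerate(labels):
        sums[:, j] = cells.counts[:, (clusters == lab).to_numpy()].sum(axis=1)
    totals = sums.sum(axis=0)
    if np.any(totals <= 0):
        empty = labels[totals <= 0].tolist()
        raise ValueError(f"clusters with zero total counts: {empty}")
    return ReferenceSignalSet(
        signals=sums / totals,
        gene_ids=cells.gene_ids,
        signal_ids=labels,
    )


def restrict_to_orthologs(
    signals: ReferenceSignalSet,
    mapping: Mapping[str, str] | pd.DataFrame,
    renormalize: bool = True,
    strip_versions: bool = True,
) -> ReferenceSignalSet:
    """Restrict signals to genes with a one-to-one ortholog and rename them.

    ``mapping`` maps source gene ids to target-species ids (a dict or a
    two-column DataFrame). Many-to-many pairs are dropped so the retained
    mapping is a bijection. Columns are renormalized to sum 1 by default so
    the column-stochastic invariant the exposure fit relies on survives.
    """
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] < 2:
            raise ValueError("mapping table needs (source, target) columns")
        pairs = list(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    else:
        pairs = list(mapping.items())
    if strip_versions:
        pairs = [(strip_gene_version(s), strip_gene_version(t)) for s, t in pairs]

    src_counts = pd.Series([s for s, _ in pairs]).value_counts()
    tgt_counts = pd.Series([t for _, t in pairs]).value_counts()
    one_to_one = {
        s: t for s, t in pairs if src_counts[s] == 1 and tgt_counts[t] == 1
    }

    gene_key = (
        [strip_gene_version(g) for g in signals.gene_ids]
        if strip_versions
        else list(signals.gene_ids)
    )
    keep = np.array([g in one_to_one for g in gene_key])
    if not keep.any():
        raise ValueError("no genes map to the target species")

    sub = signals.signals[keep]
    new_ids = pd.Index([one_to_one[g] for g, k in zip(gene_key, keep) if k])
    if renormalize:
        sums = sub.sum(axis=0)
        if np.any(sums <= 0):
            dead = signals.signal_ids[sums <= 0].tolist()
            raise ValueError(f"signals with zero mass on orthologous genes: {dead}")
        sub = sub / sums
    log.info("ortholog restriction kept %d/%d genes", int(keep.sum()), signals.n_genes)
    return ReferenceSignalSet(
        signals=sub,
        gene_ids=new_ids,
        signal_ids=signals.signal_ids,
        require_normalized=renormalize,
    )
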