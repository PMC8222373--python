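"""Core in-memory containers shared across the package.

All matrices are dense numpy arrays oriented genes x columns (cells or
samples), with plain python lists / pandas Indexes of string labels on each
axis. Containers validate their invariants at construction so downstream
code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CYCLE_PHASES = ("G1", "S", "G2M", "unknown")


def _check_unique(labels: Sequence[str], what: str) -> pd.Index:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dups}")
    return idx


def strip_gene_version(gene_id: str) -> str:
    """Strip a trailing '.<digits>' Ensembl version suffix from a gene id."""
    base, dot, suffix = gene_id.rpartition(".")
    if dot and suffix.isdigit():
        return base
    return gene_id


@dataclass
class AnnotatedCellMatrix:
    """Raw single-cell UMI counts plus per-cell QC annotations.

    ``counts`` is genes x cells. Per-cell metadata lives in ``meta``, a
    DataFrame indexed by cell id with columns ``cluster``, ``mito_fraction``,
    ``n_distinct_genes``, ``doublet``, ``cycle_phase`` and ``leucocyte``.
    ``n_distinct_genes`` is derived from the count matrix when not supplied.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    meta: pd.DataFrame

    REQUIRED_META = ("cluster", "mito_fraction", "doublet", "cycle_phase", "leucocyte")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integers")
        for col in self.REQUIRED_META:
            if col not in self.meta.columns:
                raise ValueError(f"missing metadata column: {col!r}")
        if "n_distinct_genes" not in self.meta.columns:
            self.meta = self.meta.copy()
            self.meta["n_distinct_genes"] = (self.counts > 0).sum(axis=0)
        self.meta = self.meta.loc[self.cell_ids]
        mito = self.meta["mito_fraction"].to_numpy(float)
        if np.any((mito < 0) | (mito > 1)):
            raise ValueError("mito_fraction must lie in [0, 1]")
        bad_phase = set(self.meta["cycle_phase"]) - set(CYCLE_PHASES)
        if bad_phase:
            raise ValueError(f"unknown cycle_phase values: {sorted(bad_phase)}")
        if self.meta["cluster"].isna().any() or (self.meta["cluster"] == "").any():
            raise ValueError("every cell needs a cluster label")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, keep: np.ndarray) -> "AnnotatedCellMatrix":
        keep = np.asarray(keep)
        return AnnotatedCellMatrix(
            counts=self.counts[:, keep],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            meta=self.meta.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep],
        )


@dataclass
class NormalizedCellMatrix:
    """Depth-normalized, log-transformed expression: log(1 + F * x / colsum)."""

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("normalized values must be finite and non-negative")


@dataclass
class ReferenceSignalSet:
    """Gene x signal matrix of expression fractions; each column sums to 1."""

    signals: np.ndarray
    gene_ids: pd.Index
    signal_ids: pd.Index
    require_normalized: bool = True

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.signal_ids = _check_unique(self.signal_ids, "signal ids")
        if self.signals.shape != (len(self.gene_ids), len(self.signal_ids)):
            raise ValueError("signals shape does not match gene/signal labels")
        if np.any(self.signals < 0):
            raise ValueError("signal fractions must be non-negative")
        if self.require_normalized:
            sums = self.signals.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("each signal column must sum to 1 (within 1e-9)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_signals(self) -> int:
        return len(self.signal_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signals, index=self.gene_ids, columns=self.signal_ids)


@dataclass
class BulkExpressionSet:
    """Bulk fragment counts per gene with per-gene(-per-sample) effective lengths.

    Counts may be non-integer: base counts divided by mean fragment length
    yield fractional fragment counts. Lengths broadcast from a per-gene
    vector to genes x samples.
    """

    fragment_counts: np.ndarray
    effective_lengths: np.ndarray
    gene_ids: pd.Index
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        self.fragment_counts = np.asarray(self.fragment_counts, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        m, p = len(self.gene_ids), len(self.sample_ids)
        if self.fragment_counts.shape != (m, p):
            raise ValueError("fragment_counts shape does not match labels")
        lengths = np.asarray(self.effective_lengths, dtype=float)
        if lengths.ndim == 1:
            if lengths.shape[0] != m:
                raise ValueError("per-gene lengths must have one entry per gene")
            lengths = np.broadcast_to(lengths[:, None], (m, p)).copy()
        if lengths.shape != (m, p):
            raise ValueError("effective_lengths shape does not match labels")
        self.effective_lengths = lengths
        if np.any(~np.isfinite(self.fragment_counts)) or np.any(self.fragment_counts < 0):
            raise ValueError("fragment counts must be finite and non-negative")
        if np.any(self.effective_lengths <= 0):
            raise ValueError("effective lengths must be strictly positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GeneWeights:
    """Per-gene likelihood weights w_g; genes not listed default to 1.

    Weights down- or up-weight a gene's contribution to the fit likelihood
    (e.g. housekeeping genes at 0.5, metabolic genes excluded at 0).
    """

    weights: Mapping[str, float] = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self) -> None:
        for g, w in self.weights.items():
            if w < 0 or not np.isfinite(w):
                raise ValueError(f"weight for {g!r} must be finite and >= 0")
        if self.default < 0:
            raise ValueError("default weight must be >= 0")

    def for_genes(self, gene_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.weights.get(g, self.default) for g in gene_ids], float)

    def subset(self, gene_ids: Sequence[str]) -> "GeneWeights":
        keep = set(gene_ids)
        return GeneWeights(
            weights={g: w for g, w in self.weights.items() if g in keep},
            default=self.default,
        )


@dataclass
class FitConfig:
    """Optimizer settings for the exposure fit."""

    learning_rate: float = 0.01
    tolerance: float = 1e-6
    check_interval: int = 100
    max_iterations: int = 200_000
    seed: int = 0
    intercept_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.tolerance < 1):
            raise ValueError("tolerance must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_iterations < self.check_interval:
            raise ValueError("max_iterations must be >= check_interval")


INTERCEPT_LABEL = "unexplained"


@dataclass
class FitResult:
    """Outcome of the exposure fit for a batch of samples.

    ``latent`` and ``exposures`` are (n_signals [+1 intercept]) x samples;
    the intercept row, when present, is last. ``normalized_fractions`` is a
    samples x (signals + 'unexplained') DataFrame populated by
    :func:`cellsignal.fit.normalize_exposures`.
    """

    latent: np.ndarray
    exposures: np.ndarray
    signal_ids: pd.Index
    sample_ids: pd.Index
    intercept_enabled: bool
    m: int
    n: int
    nll_trace: np.ndarray
    q_trace: np.ndarray
    converged: bool
    nll_full: np.ndarray
    intercept_raw: np.ndarray | None = None
    intercept_rescaled: np.ndarray | None = None
    normalized_fractions: pd.DataFrame | None = None
    pseudo_r2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.exposures <= 0):
            raise ValueError("exposures must be strictly positive")
        if self.intercept_enabled:
            self.intercept_raw = self.exposures[-1]
            # the intercept adds beta_0 to every gene's rate; the exposure of
            # the equivalent flat signal (profile 1/m summing to 1) is m*beta_0
            self.intercept_rescaled = self.intercept_raw * self.m

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)
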