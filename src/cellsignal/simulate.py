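"""Synthetic single-cell references and pseudo-bulk mixtures with known truth.

The generator emulates the data regime the exposure fit is designed for:
cell-type expression profiles with disjoint marker-gene blocks (log-normal
baseline, markers multiplied by a fold change), per-cell counts drawn
negative-binomially around profile x depth, and bulk mixtures drawn Poisson
around length-scaled mixed profiles. Marker-based separation guarantees
identifiability, so recovery failures in tests indicate bugs rather than an
ill-posed mixture. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import AnnotatedCellMatrix, BulkExpressionSet, ReferenceSignalSet
from .reference import build_signals


@dataclass
class SimulationSpec:
    """Conditions of a synthetic experiment.

    ``marker_fold_change`` multiplies a type's marker genes over the shared
    log-normal baseline (sigma ``baseline_expression_dispersion``);
    ``nb_overdispersion`` is the per-cell NB over-dispersion phi;
    ``bulk_depth`` is the expected total fragment count of one pseudo-bulk.
    """

    n_genes: int = 2000
    n_celltypes: int = 5
    cells_per_type: int = 500
    marker_genes_per_type: int = 50
    marker_fold_change: float = 8.0
    baseline_expression_dispersion: float = 1.0
    nb_overdispersion: float = 0.3
    bulk_depth: float = 1e6
    gene_length_range: tuple[int, int] = (200, 10_000)
    mean_cell_depth: float = 5_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold_change <= 1:
            raise ValueError("marker fold change must exceed 1")
        for name in ("n_genes", "n_celltypes", "cells_per_type", "marker_genes_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.marker_genes_per_type * self.n_celltypes > self.n_genes:
            raise ValueError("marker sets exceed the number of genes")


@dataclass
class GroundTruth:
    """Known mixing proportions of synthetic pseudo-bulks."""

    true_proportions: pd.DataFrame  # samples x cell types
    withheld_types: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        props = self.true_proportions.to_numpy(float)
        if np.any(props < 0) or not np.allclose(props.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("proportions must be >= 0 and sum to 1")


def _type_profiles(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    # each type draws its own log-normal baseline: distinct cell types have
    # largely uncorrelated transcriptomes, markers add guaranteed separation
    profiles = rng.lognormal(
        0.0, spec.baseline_expression_dispersion, (spec.n_genes, spec.n_celltypes)
    )
    for c in range(spec.n_celltypes):
        lo = c * spec.marker_genes_per_type
        profiles[lo : lo + spec.marker_genes_per_type, c] *= spec.marker_fold_change
    profiles /= profiles.sum(axis=0)
    genes = [f"gene_{i}" for i in range(spec.n_genes)]
    types = [f"type_{c}" for c in range(spec.n_celltypes)]
    return pd.DataFrame(profiles, index=genes, columns=types)


def _nb_draw(mean: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-300)))


def simulate_reference(
    spec: SimulationSpec,
) -> tuple[AnnotatedCellMatrix, ReferenceSignalSet]:
    """Simulate annotated reference cells and return them with true profiles.

    Per-cell sequencing depth is log-normal around ``mean_cell_depth``; all
    QC metadata are benign (no doublets, G1 phase, low mito) so QC filters
    pass everything unless a test perturbs the metadata.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = _type_profiles(spec, rng)
    n_cells = spec.n_celltypes * spec.cells_per_type
    counts = np.empty((spec.n_genes, n_cells), dtype=np.int64)
    clusters = []
    for c, t in enumerate(profiles.columns):
        depths = rng.lognormal(np.log(spec.mean_cell_depth), 0.3, spec.cells_per_type)
        mean = profiles.iloc[:, c].to_numpy()[:, None] * depths[None, :]
        lo = c * spec.cells_per_type
        counts[:, lo : lo + spec.cells_per_type] = _nb_draw(
            mean, spec.nb_overdispersion, rng
        )
        clusters += [t] * spec.cells_per_type
    cell_ids = [f"cell_{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "cluster": clusters,
            "mito_fraction": 0.01,
            "doublet": False,
            "cycle_phase": "G1",
            "leucocyte": False,
        },
        index=pd.Index(cell_ids),
    )
    cells = AnnotatedCellMatrix(
        counts=counts,
        gene_ids=pd.Index(profiles.index),
        cell_ids=pd.Index(cell_ids),
        meta=meta,
    )
    true_signals = ReferenceSignalSet(
        signals=profiles.to_numpy(),
        gene_ids=pd.Index(profiles.index),
        signal_ids=pd.Index(profiles.columns),
    )
    return cells, true_signals


def draw_gene_lengths(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.gene_length_range
    return rng.integers(lo, hi + 1, spec.n_genes).astype(float)


def simulate_pseudobulk(
    profiles: ReferenceSignalSet | pd.DataFrame,
    proportions,
    depth: float,
    lengths: np.ndarray,
    seed: int = 0,
) -> tuple[BulkExpressionSet, GroundTruth]:
    """Poisson pseudo-bulks mixed from per-type profiles at known proportions.

    Expected fragment count of gene g is proportional to
    l_g * sum_c p_c s_gc, scaled so the expected total equals ``depth``.
    ``proportions`` is one weight vector or a samples x types matrix.
    """
    if isinstance(profiles, ReferenceSignalSet):
        profiles = profiles.to_frame()
    S = profiles.to_numpy(float)
    props = np.atleast_2d(np.asarray(proportions, float))
    if np.any(props < 0):
        raise ValueError("proportions must be non-negative")
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("proportions must sum to 1 per pseudo-bulk")
    lengths = np.asarray(lengths, float)
    rng = np.random.default_rng(seed)
    mixed = S @ props.T  # genes x samples
    expected = mixed * lengths[:, None]
    expected = expected / expected.sum(axis=0) * depth
    counts = rng.poisson(expected).astype(float)
    sample_ids = pd.Index([f"bulk_{i}" for i in range(props.shape[0])])
    bulk = BulkExpressionSet(
        fragment_counts=counts,
        effective_lengths=lengths,
        gene_ids=pd.Index(profiles.index),
        sample_ids=sample_ids,
    )
    truth = GroundTruth(
        true_proportions=pd.DataFrame(props, index=sample_ids, columns=profiles.columns)
    )
    return bulk, truth


def dirichlet_proportions(
    n_bulks: int, n_types: int, rng: np.random.Generator, alpha: float = 1.0
) -> np.ndarray:
    """Symmetric Dirichlet mixing weights for a batch of pseudo-bulks."""
    return rng.dirichlet(np.full(n_types, alpha), size=n_bulks)


def simulate_benchmark(
    spec: SimulationSpec, n_bulks: int = 100
) -> tuple[ReferenceSignalSet, BulkExpressionSet, GroundTruth]:
    """Reference signals (built from simulated cells) plus mixed pseudo-bulks.

    Mixing proportions are symmetric Dirichlet(1); the pseudo-bulk seed and
    the reference seed both derive from ``spec.seed``.
    """
    cells, true_signals = simulate_reference(spec)
    signals = build_signals(cells)
    rng = np.random.default_rng(spec.seed + 1)
    props = dirichlet_proportions(n_bulks, spec.n_celltypes, rng)
    lengths = draw_gene_lengths(spec, rng)
    bulk, truth = simulate_pseudobulk(
        true_signals, props, spec.bulk_depth, lengths, seed=spec.seed + 2
    )
    return signals, bulk, truth


def simulate_unmatched_scenario(
    spec: SimulationSpec, withheld_type: str, n_bulks: int = 20
) -> tuple[ReferenceSignalSet, BulkExpressionSet, GroundTruth]:
    """Reference missing one population; pure bulks of that population.

    The returned reference is built from simulated cells of every type
    except ``withheld_type``; the bulks are drawn purely from the withheld
    profile, so the truth marks them 100% unexplained by the reference.
    """
    cells, true_signals = simulate_reference(spec)
    if withheld_type not in true_signals.signal_ids:
        raise ValueError(f"unknown cell type: {withheld_type}")
    if true_signals.n_signals < 2:
        raise ValueError("cannot withhold the only cell type")
    keep = cells.meta["cluster"] != withheld_type
    signals = build_signals(cells.subset_cells(keep.to_numpy()))
    rng = np.random.default_rng(spec.seed + 1)
    lengths = draw_gene_lengths(spec, rng)
    pure = np.zeros((n_bulks, true_signals.n_signals))
    pure[:, true_signals.signal_ids.get_loc(withheld_type)] = 1.0
    bulk, truth = simulate_pseudobulk(
        true_signals, pure, spec.bulk_depth, lengths, seed=spec.seed + 2
    )
    truth = GroundTruth(
        true_proportions=truth.true_proportions, withheld_types={withheld_type}
    )
    return signals, bulk, truth


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """Copy of the spec with a different seed."""
    return replace(spec, seed=seed)
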