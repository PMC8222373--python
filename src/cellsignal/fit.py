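"""Poisson exposure fit of bulk transcriptomes against reference signals.

Each bulk sample p is modelled as a non-negative combination of reference
signals plus a flat intercept::

    lambda_gp  = sum_c s_gc * beta_cp  (+ beta_0p)
    lambda'_gp = lambda_gp * l_gp
    y_gp ~ Poisson(lambda'_gp)

with beta_cp = exp(z_cp) so exposures stay strictly positive. The weighted
negative log-likelihood (constant log y! terms dropped)

    -log L = sum_p sum_g w_g * (lambda'_gp - y_gp * log lambda'_gp)

is minimized over all z_cp jointly with Adam. The intercept is a flat
column of ones appended to the signal matrix; dividing its exposure by the
number of genes m afterwards makes it equivalent to one extra signal with a
completely flat profile, and its normalized share is reported as the
"unexplained" fraction of the transcriptome.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .containers import (
    INTERCEPT_LABEL,
    BulkExpressionSet,
    FitConfig,
    FitResult,
    GeneWeights,
    ReferenceSignalSet,
)

log = logging.getLogger(__name__)

LOG_FLOOR = 1e-10  # floor inside log(lambda') guarding lambda'=0 with y>0


def align_genes(
    bulk: BulkExpressionSet,
    signals: ReferenceSignalSet,
    weights: GeneWeights | None = None,
    min_genes: int = 100,
) -> tuple[BulkExpressionSet, ReferenceSignalSet, GeneWeights]:
    """Restrict bulk, signals and weights to their shared genes, in one order.

    Signal columns are NOT renormalized after intersection; renormalization
    is an explicit reference-building step. Genes present in the bulk but
    zero across all signals are retained (they inform the intercept).
    """
    weights = weights or GeneWeights()
    common = bulk.gene_ids.intersection(signals.gene_ids)
    if len(common) < min_genes:
        raise ValueError(
            f"only {len(common)} genes shared between bulk and reference "
            f"(floor {min_genes})"
        )
    log.info(
        "gene alignment: %d shared; dropped %d bulk-only, %d reference-only",
        len(common),
        bulk.n_genes - len(common),
        signals.n_genes - len(common),
    )
    bi = bulk.gene_ids.get_indexer(common)
    si = signals.gene_ids.get_indexer(common)
    bulk_a = BulkExpressionSet(
        fragment_counts=bulk.fragment_counts[bi],
        effective_lengths=bulk.effective_lengths[bi],
        gene_ids=common,
        sample_ids=bulk.sample_ids,
    )
    sig_a = ReferenceSignalSet(
        signals=signals.signals[si],
        gene_ids=common,
        signal_ids=signals.signal_ids,
        require_normalized=False,
    )
    return bulk_a, sig_a, weights.subset(common)


def _design(signals: np.ndarray, intercept_enabled: bool) -> np.ndarray:
    if intercept_enabled:
        return np.hstack([signals, np.ones((signals.shape[0], 1))])
    return signals


def model_mean(
    latent: np.ndarray,
    signals: ReferenceSignalSet | np.ndarray,
    lengths: np.ndarray,
    intercept_enabled: bool = True,
) -> np.ndarray:
    """Length-scaled model mean lambda'_gp implied by latent z values.

    ``latent`` is (n_signals [+1]) x n_samples with the intercept row last.
    """
    S = signals.signals if isinstance(signals, ReferenceSignalSet) else np.asarray(signals)
    design = _design(S, intercept_enabled)
    lam = design @ np.exp(np.asarray(latent, float))
    return lam * np.asarray(lengths, float)


def _nll_terms(mean: np.ndarray, counts: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-sample weighted NLL; w is a per-gene vector."""
    safe = np.maximum(mean, LOG_FLOOR)
    terms = mean - counts * np.log(safe)
    return (np.where(w[:, None] > 0, w[:, None] * terms, 0.0)).sum(axis=0)


def negative_log_likelihood(
    mean: np.ndarray, counts: np.ndarray, weights: np.ndarray | GeneWeights | None = None
) -> float:
    """Weighted Poisson NLL with log y! constants omitted."""
    mean = np.atleast_2d(np.asarray(mean, float).T).T
    counts = np.atleast_2d(np.asarray(counts, float).T).T
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if weights is None:
        w = np.ones(mean.shape[0])
    elif isinstance(weights, GeneWeights):
        raise TypeError("pass a per-gene weight vector (GeneWeights.for_genes)")
    else:
        w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return float(_nll_terms(mean, counts, w).sum())


def _init_latent(
    bulk: BulkExpressionSet, n_components: int
) -> np.ndarray:
    # scale-matched start: split the per-sample mean rate evenly
    rate = bulk.fragment_counts.sum(axis=0) / bulk.effective_lengths.sum(axis=0)
    z0 = np.log(np.maximum(rate, LOG_FLOOR) / n_components)
    return np.tile(z0, (n_components, 1))


def fit_exposures(
    bulk: BulkExpressionSet,
    signals: ReferenceSignalSet,
    weights: GeneWeights | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Minimize the Poisson NLL over all latent exposures jointly with Adam.

    Samples are likelihood-independent, so a joint fit equals per-sample
    fits up to tolerance. Optimization stops when, between consecutive
    checks (every ``config.check_interval`` iterations), BOTH the fractional
    decrease in NLL and the fractional change in Q = sum sigmoid(z) fall
    below ``config.tolerance``; Q is a soft count of active signals and
    prevents termination while mass is still being shuffled between
    near-zero exposures. Checkpoint NLL is kept monotone by restoring the
    previous checkpoint and halving the step size on any increase.
    """
    config = config or FitConfig()
    weights = weights or GeneWeights()
    if list(bulk.gene_ids) != list(signals.gene_ids):
        raise ValueError("inputs are not gene-aligned; call align_genes first")
    w = weights.for_genes(bulk.gene_ids)
    y = bulk.fragment_counts
    lengths = bulk.effective_lengths
    S = _design(signals.signals, config.intercept_enabled)
    m, p = y.shape
    k = S.shape[1]

    wy = w[:, None] * y
    wl = w[:, None] * lengths
    StWl = S.T @ wl  # constant part of the gradient

    z = _init_latent(bulk, k)
    lr = config.learning_rate
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    mom = np.zeros_like(z)
    vel = np.zeros_like(z)
    t = 0

    def nll_of(z_: np.ndarray) -> float:
        lam = (S @ np.exp(z_)) * lengths
        return float(_nll_terms(lam, y, w).sum())

    def q_of(z_: np.ndarray) -> float:
        return float(expit(z_).sum())

    prev_nll = nll_of(z)
    prev_q = q_of(z)
    nll_trace = [prev_nll]
    q_trace = [prev_q]
    checkpoint = (z.copy(), mom.copy(), vel.copy(), t)
    converged = False

    it = 0
    while it < config.max_iterations:
        for _ in range(config.check_interval):
            beta = np.exp(z)
            lam = (S @ beta) * lengths
            safe = np.maximum(lam, LOG_FLOOR)
            # d(-logL)/d beta = S^T W (l - y*l/lam'); grad_z = grad_beta * beta
            grad_beta = StWl - S.T @ (wy * lengths / safe)
            grad = grad_beta * beta
            t += 1
            mom = beta1 * mom + (1 - beta1) * grad
            vel = beta2 * vel + (1 - beta2) * grad**2
            mhat = mom / (1 - beta1**t)
            vhat = vel / (1 - beta2**t)
            z = z - lr * mhat / (np.sqrt(vhat) + eps)
        it += config.check_interval

        cur_nll = nll_of(z)
        cur_q = q_of(z)
        if not np.isfinite(cur_nll) or cur_nll > prev_nll:
            # step too aggressive: rewind to last good checkpoint, back off
            z, mom, vel, t = (a.copy() if isinstance(a, np.ndarray) else a for a in checkpoint)
            lr *= 0.5
            if lr < 1e-12:
                lam = (S @ np.exp(z)) * lengths
                per_sample = _nll_terms(lam, y, w)
                bad = bulk.sample_ids[~np.isfinite(per_sample)].tolist() or ["<unknown>"]
                raise RuntimeError(
                    f"optimization diverged for sample(s) {bad} despite step backoff"
                )
            continue

        nll_trace.append(cur_nll)
        q_trace.append(cur_q)
        checkpoint = (z.copy(), mom.copy(), vel.copy(), t)
        nll_ok = (prev_nll - cur_nll) < config.tolerance * abs(prev_nll)
        # fractional change in Q, absolute fallback when Q is near zero
        q_ok = abs(cur_q - prev_q) < config.tolerance * max(abs(prev_q), 1.0)
        prev_nll, prev_q = cur_nll, cur_q
        if nll_ok and q_ok:
            converged = True
            break

    if not converged:
        log.warning("fit did not converge within %d iterations", config.max_iterations)

    lam = (S @ np.exp(z)) * lengths
    nll_full = _nll_terms(lam, y, w)
    return FitResult(
        latent=z,
        exposures=np.exp(z),
        signal_ids=signals.signal_ids,
        sample_ids=bulk.sample_ids,
        intercept_enabled=config.intercept_enabled,
        m=m,
        n=signals.n_signals,
        nll_trace=np.asarray(nll_trace),
        q_trace=np.asarray(q_trace),
        converged=converged,
        nll_full=nll_full,
    )


def normalize_exposures(result: FitResult) -> FitResult:
    """Populate per-sample normalized fractions (signals + "unexplained").

    The intercept coefficient beta_0 adds equally to every gene's rate, so
    it is first rescaled to m * beta_0 — the exposure of an equivalent extra
    signal with a completely flat profile (1/m per gene, summing to 1 like
    every reference signal). All exposures are then normalized to sum to 1
    per sample, which controls for library size and makes fractions
    comparable across samples; the flat signal's share is reported as
    "unexplained".
    """
    expo = result.exposures.copy()
    cols = list(result.signal_ids)
    if result.intercept_enabled:
        expo[-1] = expo[-1] * result.m
        cols = cols + [INTERCEPT_LABEL]
    totals = expo.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("all exposures are zero for at least one sample")
    frac = (expo / totals).T
    result.normalized_fractions = pd.DataFrame(
        frac, index=result.sample_ids, columns=cols
    )
    return result


def intercept_only_nll(
    bulk: BulkExpressionSet, weights: GeneWeights | None = None
) -> np.ndarray:
    """Per-sample NLL of the intercept-only model at its closed-form optimum.

    With a single flat exposure beta_0, the NLL is convex in beta_0 and its
    minimizer is beta_0 = sum_g w_g y_gp / sum_g w_g l_gp (set the derivative
    sum_g w_g (l_gp - y_gp / beta_0) to zero).
    """
    weights = weights or GeneWeights()
    w = weights.for_genes(bulk.gene_ids)
    y = bulk.fragment_counts
    lengths = bulk.effective_lengths
    denom = (w[:, None] * lengths).sum(axis=0)
    if np.any(denom <= 0):
        raise ValueError("sum of weighted lengths is zero; cannot fit intercept")
    beta0 = (w[:, None] * y).sum(axis=0) / denom
    lam = beta0[None, :] * lengths
    return _nll_terms(lam, y, w)


def poisson_log_constant(
    bulk: BulkExpressionSet, weights: GeneWeights | None = None
) -> np.ndarray:
    """Per-sample weighted sum of log(y!) terms dropped from the fit objective.

    Adding this constant to the constant-free NLL gives the true Poisson
    negative log-likelihood (continuous extension via log-gamma for
    fractional fragment counts), which is what the McFadden ratio needs:
    without the constant the NLL can go negative and the ratio loses its
    [0, 1] interpretation.
    """
    weights = weights or GeneWeights()
    w = weights.for_genes(bulk.gene_ids)
    return (w[:, None] * gammaln(bulk.fragment_counts + 1)).sum(axis=0)


def pseudo_r_squared(
    nll_full: np.ndarray, nll_intercept: np.ndarray
) -> np.ndarray:
    """McFadden's pseudo R-squared: 1 - NLL_full / NLL_intercept, per sample.

    Zero when the full fit is no better than the intercept alone; undefined
    (NaN, with a warning) when the intercept NLL is exactly zero.
    """
    nll_full = np.asarray(nll_full, float)
    nll_intercept = np.asarray(nll_intercept, float)
    out = np.full(np.broadcast(nll_full, nll_intercept).shape, np.nan)
    ok = nll_intercept != 0
    if not np.all(ok):
        warnings.warn("intercept-only NLL is zero; pseudo-R2 undefined", stacklevel=2)
    out[ok] = 1.0 - (nll_full + 0 * nll_intercept)[ok] / nll_intercept[ok]
    return out


def aggregate_signals(
    result: FitResult, grouping: dict[str, str]
) -> pd.DataFrame:
    """Sum normalized fractions of related signals into named groups.

    Every signal must be assigned exactly one group; the "unexplained"
    entry always forms its own group. Group values sum to 1 per sample.
    """
    if result.normalized_fractions is None:
        raise ValueError("call normalize_exposures first")
    frac = result.normalized_fractions
    missing = [s for s in result.signal_ids if s not in grouping]
    if missing:
        raise ValueError(f"signals without a group: {missing}")
    full = dict(grouping)
    full[INTERCEPT_LABEL] = INTERCEPT_LABEL
    return frac.T.groupby(frac.columns.map(full)).sum().T


def quantify(
    bulk: BulkExpressionSet,
    signals: ReferenceSignalSet,
    weights: GeneWeights | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """End-to-end convenience: align genes, fit, normalize, add pseudo-R2."""
    config = config or FitConfig()
    bulk_a, sig_a, w_a = align_genes(bulk, signals, weights)
    result = fit_exposures(bulk_a, sig_a, w_a, config)
    result = normalize_exposures(result)
    const = poisson_log_constant(bulk_a, w_a)
    result.pseudo_r2 = pseudo_r_squared(
        result.nll_full + const, intercept_only_nll(bulk_a, w_a) + const
    )
    return result
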