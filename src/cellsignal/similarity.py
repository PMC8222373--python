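"""Offset-corrected one-vs-rest elastic-net logit similarity scoring.

For each reference population k a penalized binomial logistic regression is
trained on log-normalized single-cell expression (population k vs all other
cells). The observed class fraction f_k enters as a fixed offset
log(f_k / (1 - f_k)) so that the arbitrary composition of the training
dataset does not bias coefficients; at query time the offset is set to 0.
Scores are raw logits per class, deliberately NOT softmax-normalized: a
query cell may resemble none of the reference populations, in which case
all its logits stay low and its cluster is labelled "undecided".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .containers import NormalizedCellMatrix

log = logging.getLogger(__name__)


def class_offset(f: float) -> float:
    """Training offset for a class observed at fraction f: log(f / (1-f))."""
    if not 0 < f < 1:
        raise ValueError("class fraction must lie strictly between 0 and 1")
    return float(np.log(f / (1 - f)))


@dataclass
class TrainingSet:
    """Normalized expression plus a class label per cell."""

    values: NormalizedCellMatrix
    class_label: pd.Series

    def __post_init__(self) -> None:
        self.class_label = pd.Series(
            np.asarray(self.class_label, dtype=object), index=self.values.cell_ids
        )
        counts = self.class_label.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"classes with fewer than 2 cells: {small.index.tolist()}")

    @property
    def class_fraction(self) -> pd.Series:
        return self.class_label.value_counts(normalize=True)


@dataclass
class SimilarityModel:
    """Per-class sparse coefficients, intercepts and training offsets.

    ``intercepts`` already have the training offset removed, so scoring is
    simply intercept + x . coef (i.e. prediction with offset 0).
    """

    gene_ids: pd.Index
    class_ids: pd.Index
    coefficients: np.ndarray  # classes x genes
    intercepts: np.ndarray
    offsets: np.ndarray
    strengths: np.ndarray  # selected lambda per class
    alpha: float = 0.99
    folds: int = 10
    seed: int = 0

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coefficients, index=self.class_ids, columns=self.gene_ids)


@dataclass
class SimilarityScores:
    """Raw logits per (query cell, class); no cross-class normalization."""

    logits: pd.DataFrame  # cells x classes
    cluster_logits: pd.DataFrame | None = None
    cluster_labels: pd.Series | None = None
    undecided_threshold: float = field(default=1.0)


def lambda_path(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambdas: int = 20, min_ratio: float = 0.01
) -> np.ndarray:
    """Geometric grid of penalty strengths from just-all-zero downwards."""
    n = X.shape[0]
    resid = y - y.mean()
    lam_max = np.max(np.abs(X.T @ resid)) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _fit_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    seed: int,
) -> list[tuple[np.ndarray, float]]:
    """Fit the penalized logistic path strongest-first with warm starts."""
    n = X.shape[0]
    clf = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=alpha,
        warm_start=True,
        max_iter=1000,
        tol=1e-3,
        random_state=seed,
    )
    out = []
    for lam in lambdas:
        clf.C = 1.0 / (n * lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        out.append((clf.coef_[0].copy(), float(clf.intercept_[0])))
    return out


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # mean deviance = 2 * mean logistic loss
    return float(2 * np.mean(np.logaddexp(0, eta) - y * eta))


def train_similarity(
    train: TrainingSet,
    alpha: float = 0.99,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 20,
    cv_criterion: str = "deviance",
    standardize: bool = True,
) -> SimilarityModel:
    """Train one-vs-rest elastic-net logistic models with CV strength selection.

    For each class the penalty strength is chosen by the one-standard-error
    rule: the largest strength whose cross-validated loss (binomial deviance
    by default, misclassification optionally) is within one standard error
    of the path minimum — i.e. as sparse a model as the data permit.

    The class offset is a constant, so it is absorbed by the unpenalized
    intercept during fitting; subtracting it afterwards yields exactly the
    offset-trained model evaluated at offset 0.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if cv_criterion not in ("deviance", "misclassification"):
        raise ValueError("cv_criterion must be 'deviance' or 'misclassification'")
    X_raw = train.values.values.T  # cells x genes
    labels = train.class_label.to_numpy()
    classes = pd.Index(sorted(pd.unique(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(labels).value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.idxmin()}, {counts.min()} cells) is smaller "
            f"than folds={folds}; reduce the fold count"
        )

    if standardize:
        X, mu, sd = _standardize(X_raw)
    else:
        X, mu, sd = X_raw, np.zeros(X_raw.shape[1]), np.ones(X_raw.shape[1])

    n_genes = X.shape[1]
    coefs = np.zeros((len(classes), n_genes))
    intercepts = np.zeros(len(classes))
    offsets = np.zeros(len(classes))
    strengths = np.zeros(len(classes))

    for ki, klass in enumerate(classes):
        y = (labels == klass).astype(float)
        f = y.mean()
        offsets[ki] = class_offset(f)
        lambdas = lambda_path(X, y, alpha, n_lambdas=n_lambdas)

        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_loss = np.zeros((folds, len(lambdas)))
        for fi, (tr, te) in enumerate(skf.split(X, y)):
            path = _fit_path(X[tr], y[tr], lambdas, alpha, seed)
            for li, (w, b) in enumerate(path):
                eta = X[te] @ w + b
                if cv_criterion == "deviance":
                    cv_loss[fi, li] = _binomial_deviance(y[te], eta)
                else:
                    cv_loss[fi, li] = float(np.mean((eta > 0) != (y[te] > 0.5)))
        cvm = cv_loss.mean(axis=0)
        cvse = cv_loss.std(axis=0, ddof=1) / np.sqrt(folds)
        best = int(np.argmin(cvm))
        within = np.flatnonzero(cvm <= cvm[best] + cvse[best])
        chosen = int(within.min())  # lambdas sorted descending: min index = largest
        strengths[ki] = lambdas[chosen]

        w_std, b_std = _fit_path(X, y, lambdas[: chosen + 1], alpha, seed)[-1]
        w = w_std / sd
        b = b_std - float(w_std @ (mu / sd))
        coefs[ki] = w
        intercepts[ki] = b - offsets[ki]
        log.info(
            "class %s: lambda=%.4g, %d nonzero coefficients",
            klass,
            strengths[ki],
            int(np.sum(w != 0)),
        )

    return SimilarityModel(
        gene_ids=train.values.gene_ids,
        class_ids=classes,
        coefficients=coefs,
        intercepts=intercepts,
        offsets=offsets,
        strengths=strengths,
        alpha=alpha,
        folds=folds,
        seed=seed,
    )


def score_cells(model: SimilarityModel, query: NormalizedCellMatrix) -> SimilarityScores:
    """Score query cells: logit(cell, k) = intercept_k + sum_g coef_kg * x_g.

    Query genes are matched to model genes by id; model genes absent from
    the query contribute 0 (cross-dataset scoring is the primary use). The
    training offset is replaced by 0, so logits are comparable across
    differently composed training sets.
    """
    idx = model.gene_ids.get_indexer(query.gene_ids)
    present = idx >= 0
    nz_genes = np.any(model.coefficients != 0, axis=0)
    if not np.any(nz_genes[idx[present]]):
        warnings.warn(
            "no overlap between model's nonzero-coefficient genes and query "
            "genes; returning intercept-only scores",
            stacklevel=2,
        )
    X = query.values[present].T  # cells x matched genes
    W = model.coefficients[:, idx[present]]  # classes x matched genes
    logits = X @ W.T + model.intercepts[None, :]
    return SimilarityScores(
        logits=pd.DataFrame(logits, index=query.cell_ids, columns=model.class_ids)
    )


def aggregate_by_cluster(
    scores: SimilarityScores,
    cluster_label: pd.Series | np.ndarray,
    threshold: float = 1.0,
) -> SimilarityScores:
    """Average logits per query cluster and call a label per cluster.

    Cluster label = argmax of the mean logits, or "undecided" when no class
    reaches ``threshold`` (default 1 logit), leaving room for populations
    absent from the reference.
    """
    cl = pd.Series(np.asarray(cluster_label, dtype=object), index=scores.logits.index)
    if cl.isna().any():
        raise ValueError("every query cell needs a cluster label")
    sizes = cl.value_counts()
    if (sizes == 0).any():
        raise ValueError("empty query cluster")
    cluster_logits = scores.logits.groupby(cl).mean()
    best = cluster_logits.idxmax(axis=1)
    best[cluster_logits.max(axis=1) < threshold] = "undecided"
    return SimilarityScores(
        logits=scores.logits,
        cluster_logits=cluster_logits,
        cluster_labels=best,
        undecided_threshold=threshold,
    )
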