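"""Derived scores and statistics on fitted signal fractions.

Covers the immaturity score (summed fetal-signal fractions), normal
reference ranges, rank-sum and t-test group comparisons with FDR control,
ROC curves for signal-based classification, and TPM conversions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import INTERCEPT_LABEL, FitResult

log = logging.getLogger(__name__)


def immaturity_score(
    fractions: pd.DataFrame | FitResult, fetal_signal_ids: set[str] | list[str]
) -> pd.Series:
    """Summed normalized contribution of fetal/developmental signals per sample.

    The denominator of the normalized fractions includes the unexplained
    entry, so the score lies in [0, 1]: 1 means the transcriptome is fully
    explained by developmental signals, 0 means none of it is.
    """
    if isinstance(fractions, FitResult):
        if fractions.normalized_fractions is None:
            raise ValueError("fit result has no normalized fractions")
        fractions = fractions.normalized_fractions
    fetal = list(fetal_signal_ids)
    unknown = [s for s in fetal if s not in fractions.columns]
    if unknown:
        raise ValueError(f"unknown fetal signal ids: {unknown}")
    if INTERCEPT_LABEL in fetal:
        raise ValueError("the unexplained entry is not a fetal signal")
    return fractions[fetal].sum(axis=1).rename("immaturity")


def reference_range(normal_scores) -> tuple[float, float]:
    """(min, max) of scores over designated normal samples."""
    vals = np.asarray(normal_scores, float)
    if vals.size < 2:
        raise ValueError("need at least 2 normal samples for a reference range")
    return float(vals.min()), float(vals.max())


def outside_range(score: float, rng: tuple[float, float]) -> bool:
    """A sample is outside the normal range if strictly below or above it."""
    low, high = rng
    return score < low or score > high


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 20 values and no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class AssociationResult:
    table: pd.DataFrame  # index: test name; columns: statistic, p, q


def covariate_association(
    score_table: pd.DataFrame,
    covariates: list[str],
    score_col: str = "score",
    fdr_method: str = "fdr_bh",
) -> AssociationResult:
    """Scan covariates for association with the score, with FDR correction.

    Numeric covariates are tested by the t-test on the linear-regression
    slope; categorical covariates by two-sided two-sample t-tests via a 0/1
    indicator (one test per level when there are more than two levels).
    Benjamini-Hochberg adjustment is applied across all tests performed
    (Bonferroni available via ``fdr_method='bonferroni'``). Covariates whose
    groups are degenerate (fewer than 2 samples on a side) are skipped with
    a warning.
    """
    scores = score_table[score_col].to_numpy(float)
    rows = []
    for cov in covariates:
        col = score_table[cov]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(scores)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0:
                warnings.warn(f"covariate {cov!r} degenerate; skipped", stacklevel=2)
                continue
            res = sps.linregress(x[ok], scores[ok])
            rows.append((cov, float(res.slope / res.stderr), float(res.pvalue)))
        else:
            levels = col.dropna().unique()
            pairs = (
                [(cov, col == levels[0])]
                if len(levels) == 2
                else [(f"{cov}={lv}", col == lv) for lv in levels]
            )
            for name, ind in pairs:
                g1 = scores[ind.to_numpy(bool)]
                g0 = scores[~ind.to_numpy(bool)]
                if g1.size < 2 or g0.size < 2:
                    warnings.warn(f"test {name!r} degenerate; skipped", stacklevel=2)
                    continue
                if np.ptp(np.concatenate([g0, g1])) == 0:
                    rows.append((name, 0.0, 1.0))
                    continue
                t, p = sps.ttest_ind(g1, g0)
                rows.append((name, float(t), float(p)))
    if not rows:
        raise ValueError("no testable covariates")
    tab = pd.DataFrame(rows, columns=["test", "statistic", "p"]).set_index("test")
    tab["q"] = multipletests(tab["p"], method=fdr_method)[1]
    return AssociationResult(table=tab)


@dataclass
class RocCurve:
    """Sensitivity/specificity at every cutoff, higher score = positive."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_curve(scores, positive) -> RocCurve:
    """ROC over all cutoffs with score >= cutoff predicting positive.

    AUC is the trapezoid area over (1 - specificity, sensitivity), which
    equals the concordance probability between a random positive and a
    random negative.
    """
    scores = np.asarray(scores, float)
    positive = np.asarray(positive, bool)
    if positive.all() or (~positive).all():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    # sentinels: one cutoff below everything (all positive) and one above
    cutoffs = np.concatenate([[uniq[0] - 1], uniq, [uniq[-1] + 1]])
    n_pos = positive.sum()
    n_neg = (~positive).sum()
    sens = np.empty_like(cutoffs)
    spec = np.empty_like(cutoffs)
    for i, c in enumerate(cutoffs):
        pred = scores >= c
        sens[i] = (pred & positive).sum() / n_pos
        spec[i] = (~pred & ~positive).sum() / n_neg
    fpr = 1 - spec
    # ascending fpr with ties broken by sens so the staircase is traversed
    # bottom-left to top-right and vertical segments add no spurious area
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocCurve(cutoffs=cutoffs, sensitivity=sens, specificity=spec, auc=auc)


def tpm_transform(counts, lengths) -> np.ndarray:
    """Transcripts per million: length-normalized counts scaled to sum 1e6."""
    counts = np.asarray(counts, float)
    lengths = np.asarray(lengths, float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    rate = counts / lengths
    total = rate.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("sample with zero total counts")
    return 1e6 * rate / total


def tpm_to_pseudocounts(tpm) -> tuple[np.ndarray, np.ndarray]:
    """Convert TPM to pseudo fragment counts: round(TPM * 1e6), lengths of 1.

    The large resulting totals are intentional: with unit effective lengths
    the exposure fit only sees relative gene abundances, and the inflation
    keeps rounding error negligible.
    """
    tpm = np.asarray(tpm, float)
    if np.any(tpm < 0):
        raise ValueError("TPM values must be non-negative")
    counts = np.round(tpm * 1e6)
    return counts, np.ones_like(counts)
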