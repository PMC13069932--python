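"""Cohort-level decision analysis.

Everything needed to ask whether the HScore separates FISH-positive
from FISH-negative equivocal cases: empirical ROC curves with the
Mann-Whitney AUC and DeLong standard errors, Youden-index cutoff
selection, logistic association models, a Bonferroni-corrected
dichotomization (cutpoint) scan, pairwise AUCs across IHC expression
categories, and descriptive group summaries.

Conventions: the positive call is score >= cutoff (higher HScore means
more likely ERBB2-positive); candidate cutoffs are the observed score
values; ties in the Youden index break toward the smallest cutoff,
which maximizes sensitivity at equal J.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

_Z95 = float(sps.norm.ppf(0.975))


class SingleClassError(ValueError):
    """ROC analysis needs both classes present."""


def _coerce_labels(labels) -> np.ndarray:
    """Map labels to a 0/1 array; 'positive'/'negative' strings accepted."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        mapping = {"positive": 1, "negative": 0}
        try:
            arr = np.array([mapping[str(v).lower()] for v in arr])
        except KeyError as e:
            raise ValueError(f"unrecognized label {e.args[0]!r}") from e
    arr = arr.astype(int)
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1 or negative/positive)")
    return arr


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RocSummary:
    """Empirical ROC curve with DeLong uncertainty and Youden cutoff."""

    cutoffs: np.ndarray          # sorted unique observed scores, ascending
    sensitivity: np.ndarray      # P(pos score >= cutoff)
    specificity: np.ndarray      # P(neg score <  cutoff)
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_positive: int
    n_negative: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.cutoffs,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong standard error of the Mann-Whitney AUC.

    Uses the placement values V10 (per positive) and V01 (per negative);
    the variance is var(V10)/m + var(V01)/n with sample variances.
    """
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        return float("nan")
    return float(np.sqrt(v10.var(ddof=1) / m + v01.var(ddof=1) / n))


def roc_curve(scores, labels) -> RocSummary:
    """Empirical ROC with tie-corrected AUC, DeLong CI and Youden cutoff.

    The AUC equals the Mann-Whitney probability that a random positive
    outscores a random negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = _coerce_labels(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if y.min() == y.max():
        raise SingleClassError("both classes must be present for ROC analysis")

    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)

    ranks = sps.rankdata(scores)
    auc = (ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n)
    se = _delong_se(pos, neg)
    ci = (max(0.0, auc - _Z95 * se), min(1.0, auc + _Z95 * se)) if np.isfinite(se) \
        else (float("nan"), float("nan"))

    cutoffs = np.unique(scores)
    sens = np.array([(pos >= c).mean() for c in cutoffs])
    spec = np.array([(neg < c).mean() for c in cutoffs])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first max: smallest cutoff

    return RocSummary(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        auc_se=se,
        auc_ci95=ci,
        youden_cutoff=float(cutoffs[best]),
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
        n_positive=m,
        n_negative=n,
    )


def youden_cutoff(roc: RocSummary) -> tuple[float, float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1 (ties: smallest)."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = int(np.argmax(j))
    return float(roc.cutoffs[best]), float(roc.sensitivity[best]), float(roc.specificity[best])


# --------------------------------------------------------------------------
# logistic association
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Binary logistic regression of FISH status on HScore (+ covariates)."""

    terms: pd.DataFrame      # index: term; columns: coef, odds_ratio, ci_low, ci_high, p
    log_likelihood: float
    converged: bool
    dropped: tuple[str, ...]


def logistic_association(
    cohort: pd.DataFrame,
    outcome: str = "fish_status",
    predictors: Sequence[str] = ("hscore",),
    covariates: Sequence[str] = (),
) -> LogisticFit:
    """Maximum-likelihood logistic fit; odds ratios with Wald 95% CIs.

    Zero-variance predictors are dropped with a warning rather than
    sent to the optimizer; perfect separation or non-convergence is
    reported through the ``converged`` flag.
    """
    cols = list(predictors) + list(covariates)
    data = cohort[[outcome] + cols].dropna()
    if data.empty:
        raise ValueError("no complete cases for logistic fit")
    y = _coerce_labels(data[outcome])
    if y.min() == y.max():
        raise SingleClassError("both outcome classes required")

    X = data[cols].astype(float) if cols else pd.DataFrame(index=data.index)
    dropped = tuple(c for c in X.columns if X[c].nunique() <= 1)
    for c in dropped:
        logger.warning("predictor %r has no variance; dropped from model", c)
    X = X.drop(columns=list(dropped))
    design = sm.add_constant(X, has_constant="add")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = sm.Logit(y, design).fit_regularized(disp=0, alpha=1e-8)
            converged = False

    coefs = res.params
    ses = res.bse
    pvals = res.pvalues
    terms = pd.DataFrame({
        "coef": coefs,
        "odds_ratio": np.exp(coefs),
        "ci_low": np.exp(coefs - _Z95 * ses),
        "ci_high": np.exp(coefs + _Z95 * ses),
        "p": pvals,
    })
    return LogisticFit(
        terms=terms,
        log_likelihood=float(res.llf),
        converged=converged,
        dropped=dropped,
    )


# --------------------------------------------------------------------------
# cutpoint scan
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CutpointScan:
    """Dichotomization scan with Bonferroni family-wise correction."""

    table: pd.DataFrame          # cutpoint, statistic, p_raw, p_adj
    skipped: tuple[float, ...]   # candidates whose split left an empty group
    best_cutpoint: float
    best_p_adj: float
    n_tests: int


def _binary_split_test(g_below: np.ndarray, g_above: np.ndarray, test: str) -> tuple[float, float]:
    """Compare outcome prevalence between the two score groups.

    The default is the pooled two-sample t ("t"), which on a 0/1
    outcome is a monotone function of the pooled two-proportion z
    statistic. The unpooled Welch variant ("welch") is offered but is
    badly anticonservative at extreme splits: a small group with a
    constant outcome has zero unpooled variance and its p collapses.
    """
    if test in ("t", "welch"):
        with warnings.catch_warnings():
            # binary outcomes trip scipy's near-constant-data warning
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = sps.ttest_ind(g_above, g_below, equal_var=(test == "t"))
        if not np.isfinite(p):
            both_constant = (len(g_above) > 1 and len(g_below) > 1
                             and g_above.var(ddof=1) == 0 and g_below.var(ddof=1) == 0)
            if both_constant and g_above.mean() != g_below.mean():
                # outcome perfectly separated by the split
                stat, p = float("inf"), 0.0
            else:
                # no usable evidence (size-1 group or identical constants)
                stat, p = 0.0, 1.0
        return float(stat), float(p)
    table = np.array([
        [(g_below == 0).sum(), (g_below == 1).sum()],
        [(g_above == 0).sum(), (g_above == 1).sum()],
    ])
    if test == "chisq":
        res = sps.chi2_contingency(table, correction=True)
        return float(res.statistic), float(res.pvalue)
    if test == "fisher":
        stat, p = sps.fisher_exact(table)
        return float(stat), float(p)
    raise ValueError(f"unknown cutpoint test {test!r}; choose t, welch, chisq or fisher")


def cutpoint_scan(
    scores,
    labels,
    grid: Optional[Sequence[float]] = None,
    test: str = "t",
) -> CutpointScan:
    """Scan candidate dichotomizations of the score for a threshold effect.

    Each candidate c splits cases into {score < c} and {score >= c}; a
    two-sample t-test on the 0/1 outcome between the two groups
    (numerically a two-proportion comparison; Welch, chi-square and
    Fisher variants are available) yields a raw p-value,
    Bonferroni-multiplied by the number of tests performed. The best
    cutpoint has the smallest adjusted p, ties breaking toward the
    smaller cutpoint.
    """
    scores = np.asarray(scores, dtype=float)
    y = _coerce_labels(labels)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct scores to scan cutpoints")
    if grid is None:
        grid = (uniq[:-1] + uniq[1:]) / 2.0  # midpoints between observed scores

    rows, skipped = [], []
    for c in np.sort(np.asarray(grid, dtype=float)):
        below, above = y[scores < c], y[scores >= c]
        if len(below) == 0 or len(above) == 0:
            skipped.append(float(c))
            continue
        stat, p = _binary_split_test(below, above, test)
        rows.append({"cutpoint": float(c), "statistic": stat, "p_raw": p})
    if not rows:
        raise ValueError("every candidate split left one group empty")

    table = pd.DataFrame(rows)
    k = len(table)
    table["p_adj"] = np.minimum(1.0, table["p_raw"] * k)
    best = int(table["p_adj"].idxmin())  # idxmin: first minimum = smallest cutpoint
    return CutpointScan(
        table=table,
        skipped=tuple(skipped),
        best_cutpoint=float(table.loc[best, "cutpoint"]),
        best_p_adj=float(table.loc[best, "p_adj"]),
        n_tests=k,
    )


# --------------------------------------------------------------------------
# group-level analyses
# --------------------------------------------------------------------------

def pairwise_group_auc(
    cohort: pd.DataFrame,
    score: str = "hscore",
    group_col: str = "ihc_category",
) -> pd.DataFrame:
    """AUC of the score for every pair of IHC expression categories.

    The higher category is the positive class, so AUC > 0.5 means the
    score increases with expression level. Categories with fewer than
    two scored cases are skipped with a warning.
    """
    data = cohort[[group_col, score]].dropna()
    counts = data[group_col].value_counts()
    usable = sorted(c for c in counts.index if counts[c] >= 2)
    for c in sorted(set(counts.index) - set(usable)):
        logger.warning("category %s has <2 scored cases; its pairs are skipped", c)

    rows = []
    for lo, hi in itertools.combinations(usable, 2):
        sub = data[data[group_col].isin([lo, hi])]
        roc = roc_curve(sub[score].to_numpy(), (sub[group_col] == hi).astype(int).to_numpy())
        rows.append({
            "comparison": f"{hi} vs {lo}",
            "auc": roc.auc,
            "se": roc.auc_se,
            "ci_low": roc.auc_ci95[0],
            "ci_high": roc.auc_ci95[1],
            "n_positive": roc.n_positive,
            "n_negative": roc.n_negative,
        })
    return pd.DataFrame(rows)


def group_summary(
    cohort: pd.DataFrame,
    by: str = "ihc_category",
    metrics: Sequence[str] = ("hscore", "mean_intensity", "pct_area"),
) -> pd.DataFrame:
    """Per-group n / mean / SD / range for each metric.

    SD is NaN for single-case groups; the range collapses to the lone
    value.
    """
    rows = []
    for key, grp in cohort.groupby(by):
        row: dict = {by: key, "n": len(grp)}
        for m in metrics:
            vals = grp[m].dropna()
            row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{m}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{m}_min"] = vals.min() if len(vals) else np.nan
            row[f"{m}_max"] = vals.max() if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_mean(counts: Sequence[int], means: Sequence[float]) -> float:
    """Size-weighted recombination of group means into an overall mean."""
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    return float((counts * means).sum() / counts.sum())
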