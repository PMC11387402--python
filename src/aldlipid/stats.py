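"""Differential-abundance and correlation statistics.

Two-group comparisons are routed by a per-group Shapiro-Wilk normality
check: Welch's t-test when both groups look normal (p >= alpha in both),
Mann-Whitney U otherwise. Multi-group comparisons use Kruskal-Wallis with
Dunn's post-hoc z-tests. P-values are adjusted per contrast across all
lipids by Benjamini-Hochberg (Bonferroni and Holm are also reported), fold
change is the ratio of group means with the second group as reference, and
volcano classification applies a fold-change threshold together with an
adjusted-p threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "route_test",
    "welch_t",
    "mann_whitney",
    "kruskal_dunn",
    "adjust_p",
    "fold_change",
    "compare_groups",
    "volcano",
    "correlate",
    "pca_scores",
    "plsda_scores",
]

_ADJUST_METHOD = {"BH": "fdr_bh", "Bonferroni": "bonferroni", "Holm": "holm"}


def route_test(
    group_a: Sequence[float], group_b: Sequence[float], alpha_norm: float = 0.05
) -> str:
    """Pick ``"welch"`` or ``"mannwhitney"`` from per-group normality.

    Welch's t requires Shapiro-Wilk p >= ``alpha_norm`` in *both* groups;
    with fewer than 3 observations in either group the normality check is
    impossible and the rank test is forced (logged).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        logger.warning("group with n < 3: Mann-Whitney U forced")
        return "mannwhitney"
    for g in (a, b):
        if np.ptp(g) == 0:  # Shapiro undefined for constant input
            return "mannwhitney"
    if sps.shapiro(a).pvalue >= alpha_norm and sps.shapiro(b).pvalue >= alpha_norm:
        return "welch"
    return "mannwhitney"


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided, Welch-Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U, exact null for min(n) <= 8 without ties, otherwise
    tie-corrected normal approximation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(len(a) * len(b) / 2), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_dunn(
    groups: Sequence[Sequence[float]], adjust: str = "BH"
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus test with Dunn's post-hoc pairwise z-tests.

    Returns (H statistic, omnibus p, pairwise table). Dunn's test compares
    mean ranks of the pooled ranking; the z denominator carries the pooled
    tie correction sum(t^3 - t) / (12 (N - 1)). Pairwise p-values are
    adjusted within the k(k-1)/2 family.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use the two-group path instead")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h_stat, omnibus_p = 0.0, 1.0
    else:
        h_stat, omnibus_p = sps.kruskal(*groups)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "z": float(z),
                "p": float(2 * sps.norm.sf(abs(z))),
            }
        )
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = adjust_p(pairwise["p"].to_numpy(), adjust)
    return float(h_stat), float(omnibus_p), pairwise


def adjust_p(pvalues, method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment: BH step-up, Bonferroni, or Holm."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _ADJUST_METHOD:
        raise ValueError(f"unknown method {method!r}; use {list(_ADJUST_METHOD)}")
    if len(p) == 0:
        return p
    return multipletests(p, method=_ADJUST_METHOD[method])[1]


def fold_change(group_a, group_b) -> tuple[float, float]:
    """Ratio of group means, group B as reference, with its log2."""
    mean_a = float(np.nanmean(np.asarray(group_a, dtype=float)))
    mean_b = float(np.nanmean(np.asarray(group_b, dtype=float)))
    if mean_b <= 0:
        logger.warning("fold change undefined: reference mean %.3g <= 0", mean_b)
        return float("nan"), float("nan")
    fc = mean_a / mean_b
    return fc, float(np.log2(fc)) if fc > 0 else float("nan")


def compare_groups(
    table: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    alpha_norm: float = 0.05,
    log_transform_tests: bool = False,
) -> pd.DataFrame:
    """Per-lipid two-group comparison over an abundance table.

    ``table`` has lipid rows and sample columns; ``samples_a`` is the
    contrast group and ``samples_b`` the reference. Each lipid gets a
    normality-routed test on its (optionally log2) abundances, a
    mean-ratio fold change on the raw scale, and BH / Bonferroni / Holm
    adjusted p-values computed across all testable lipids of this
    contrast. Lipids with missing values in a group are tested on the
    available values; lipids with fewer than 2 values per group are
    excluded and logged.
    """
    missing = (set(samples_a) | set(samples_b)) - set(table.columns)
    if missing:
        raise ValueError(f"samples not in table: {sorted(missing)}")
    rows = []
    skipped = []
    for lipid in table.index:
        a = table.loc[lipid, list(samples_a)].to_numpy(dtype=float)
        b = table.loc[lipid, list(samples_b)].to_numpy(dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            skipped.append(str(lipid))
            continue
        ta, tb = (np.log2(a + 1e-12), np.log2(b + 1e-12)) if log_transform_tests else (a, b)
        test = route_test(ta, tb, alpha_norm)
        if test == "welch":
            stat, p = welch_t(ta, tb)
        else:
            stat, p = mann_whitney(ta, tb)
        fc, log2fc = fold_change(a, b)
        rows.append(
            {
                "lipid": str(lipid),
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "fold_change": fc,
                "log2_fold_change": log2fc,
                "test": "Welch" if test == "welch" else "Mann-Whitney",
                "statistic": stat,
                "p": p,
            }
        )
    if skipped:
        logger.warning(
            "%d lipid(s) excluded from the contrast (fewer than 2 values per "
            "group): %s",
            len(skipped),
            skipped[:10],
        )
    results = pd.DataFrame(rows).set_index("lipid")
    if len(results):
        results["p_bh"] = adjust_p(results["p"].to_numpy(), "BH")
        results["p_bonferroni"] = adjust_p(results["p"].to_numpy(), "Bonferroni")
        results["p_holm"] = adjust_p(results["p"].to_numpy(), "Holm")
        results["significant"] = results["p_bh"] < 0.05
    return results


def volcano(
    results: pd.DataFrame,
    fc_thresh: float = 1.5,
    p_thresh: float = 0.05,
    on_adjusted: bool = True,
) -> tuple[pd.DataFrame, int, int]:
    """Classify each lipid of a contrast as elevated / lower / ns.

    Elevated: fold change > ``fc_thresh`` and (adjusted) p < ``p_thresh``;
    lower: fold change < 1/``fc_thresh`` with the same p rule; everything
    else ns. Returns the classification table plus the two counts.
    """
    pcol = "p_bh" if on_adjusted else "p"
    fc = results["fold_change"].to_numpy(dtype=float)
    p = results[pcol].to_numpy(dtype=float)
    label = np.where(
        (fc > fc_thresh) & (p < p_thresh),
        "elevated",
        np.where((fc < 1.0 / fc_thresh) & (p < p_thresh), "lower", "ns"),
    )
    out = pd.DataFrame(
        {
            "log2_fold_change": results["log2_fold_change"],
            "neg_log10_p": -np.log10(np.clip(results["p"].to_numpy(float), 1e-300, None)),
            "label": label,
        },
        index=results.index,
    )
    n_elev = int((label == "elevated").sum())
    n_lower = int((label == "lower").sum())
    return out, n_elev, n_lower


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("correlation undefined for constant input")
        return float("nan"), float("nan")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def _preprocess(table: pd.DataFrame, log2: bool, center: bool) -> pd.DataFrame:
    mat = table.T.astype(float)  # samples x lipids
    constant = mat.columns[mat.std(axis=0) == 0]
    if len(constant):
        logger.warning("dropping %d constant lipid row(s)", len(constant))
        mat = mat.drop(columns=constant)
    if log2:
        mat = np.log2(mat + 1e-12)
    if center:
        mat = mat - mat.mean(axis=0)
    return mat


def pca_scores(
    table: pd.DataFrame,
    n_components: int = 2,
    log2: bool = True,
    center: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA sample scores and lipid loadings of a lipid x sample table.

    The matrix is log2-transformed and column-centered by default; the
    decomposition is the SVD of the preprocessed samples x lipids matrix.
    Returns (scores, loadings, explained variance ratio).
    """
    mat = _preprocess(table, log2, center)
    if mat.shape[0] < 3 or mat.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 non-constant lipids")
    max_rank = min(mat.shape[0] - 1, mat.shape[1])
    pca = PCA(n_components=min(n_components, max_rank), svd_solver="full")
    scores = pca.fit_transform(mat.to_numpy())
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=mat.index, columns=cols),
        pd.DataFrame(pca.components_.T, index=mat.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def plsda_scores(
    table: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    n_components: int = 2,
    log2: bool = True,
) -> pd.DataFrame:
    """PLS-DA sample scores: partial least squares against one-hot labels."""
    mat = _preprocess(table, log2, center=True)
    y = pd.Series(labels).reindex(mat.index)
    if y.isna().any():
        raise ValueError(f"labels missing for samples {list(mat.index[y.isna()])}")
    onehot = pd.get_dummies(y).to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(mat.to_numpy(), onehot)
    cols = [f"LV{i + 1}" for i in range(n_components)]
    return pd.DataFrame(pls.x_scores_, index=mat.index, columns=cols)
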