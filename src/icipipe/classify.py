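"""Composition statistics and the combinatorial tumor+immune response index.

Ro/e compares observed cell-type-by-sample counts with chi-square
independence expectations; per-sample Ro/e values and max-normalized tumor
signature scores form the feature matrix. A univariate linear-model screen
(0/1 response on one predictor) ranks features; the top features combine
pairwise into orientation-aligned sum indices, each evaluated by in-sample
ROC AUC with a two-tailed Wilcoxon rank-sum p, Benjamini-Hochberg adjusted
across all evaluated combinations.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def compute_roe(counts_table: pd.DataFrame) -> pd.DataFrame:
    """Observed/expected enrichment, expectations from the marginals.

    E(i, j) = row_i total x col_j total / grand total (the chi-square
    independence expectation). Cells with zero expectation (an empty row or
    column) come back NaN.
    """
    obs = counts_table.to_numpy(dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("grand total must be positive")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        roe = np.where(expected > 0, obs / np.where(expected > 0, expected, 1.0), np.nan)
    return pd.DataFrame(roe, index=counts_table.index, columns=counts_table.columns)


def compare_proportions(
    per_sample: pd.Series,
    group_a: list[str],
    group_b: list[str],
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-sample proportions.

    Returns (mean_a - mean_b, p). Zero variance in both groups with equal
    means gives p = 1 by convention.
    """
    a = per_sample.loc[group_a].to_numpy(dtype=float)
    b = per_sample.loc[group_b].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return diff, 1.0 if diff == 0 else 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return diff, float(res.pvalue)


def univariate_regression(
    feature: pd.Series, response01: pd.Series
) -> tuple[float, float]:
    """OLS of the 0/1 response on one predictor; p from the predictor F-test.

    Categorical predictors are dummy-coded; the F-test then covers all
    levels jointly (for a single numeric predictor it equals the squared
    slope t-test). A constant predictor returns (0, NaN).
    """
    y = response01.astype(float)
    x = feature.reindex(y.index)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
        X = pd.get_dummies(x, drop_first=True, dtype=float)
    else:
        X = x.astype(float).to_frame("x")
    if X.shape[1] == 0 or (X.nunique() <= 1).all():
        return 0.0, float("nan")
    model = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    coef = float(model.params[1])
    return coef, float(model.f_pvalue)


def roc_auc(
    scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray
) -> tuple[float, float, int]:
    """(AUC, two-tailed Wilcoxon rank-sum p, orientation).

    AUC is the Mann-Whitney probability that a positive outranks a negative
    (ties count 1/2), reported after orienting so AUC >= 0.5; orientation is
    +1 when higher scores already associate with the positive class, -1
    when the score was flipped.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    u = scipy.stats.mannwhitneyu(pos, neg, alternative="two-sided")
    auc = float(u.statistic) / (len(pos) * len(neg))
    orientation = 1 if auc >= 0.5 else -1
    return (auc if auc >= 0.5 else 1 - auc), float(u.pvalue), orientation


def build_combinatorial_index(
    feature_matrix: pd.DataFrame,
    feature_pair: tuple[str, ...],
    orientations: dict[str, int],
) -> pd.Series:
    """Orientation-aligned sum of max-normalized features.

    A non-responder-associated feature (orientation -1, negative univariate
    coefficient against responder status) enters as its value; a
    responder-associated one enters flipped (1 - value), so a higher index
    is more non-responder-like. Samples missing any member value drop out.
    """
    parts = []
    for f in feature_pair:
        v = feature_matrix[f]
        parts.append(v if orientations.get(f, -1) < 0 else 1.0 - v)
    idx = sum(parts)
    dropped = idx.index[idx.isna()]
    if len(dropped):
        log.info("index %s: %d sample(s) without values excluded", feature_pair, len(dropped))
    return idx.dropna()


def screen_combinations(
    feature_matrix: pd.DataFrame,
    response: pd.Series,
    top_k: int = 6,
) -> pd.DataFrame:
    """Rank single features and pairs of top univariate features by AUC.

    All candidate single features are screened univariately; the top-k by
    p-value pair up exhaustively. Every evaluated combination gets an
    in-sample AUC against non-responder status and a Wilcoxon p; BH runs
    across all evaluated combinations. Sorted by AUC then q.
    """
    y = response.astype(int)  # 1 = responder
    uni = {}
    orientations = {}
    for f in feature_matrix.columns:
        coef, p = univariate_regression(feature_matrix[f], y)
        uni[f] = p
        orientations[f] = -1 if coef < 0 else 1
    ranked = sorted(uni, key=lambda f: (np.nan_to_num(uni[f], nan=2.0), f))
    top = ranked[: min(top_k, len(ranked))]

    combos: list[tuple[str, ...]] = [(f,) for f in feature_matrix.columns]
    combos += list(itertools.combinations(top, 2))
    rows = []
    for combo in combos:
        idx = build_combinatorial_index(feature_matrix, combo, orientations)
        lab = (y.reindex(idx.index) == 0).astype(bool)  # positive = non-responder
        if lab.all() or not lab.any():
            continue
        auc, p, _ = roc_auc(idx, lab)
        rows.append(("+".join(combo), len(combo), auc, p))
    out = pd.DataFrame(rows, columns=["name", "n_features", "auc", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["univariate_p"] = [
        uni[name] if n == 1 else np.nan for name, n in zip(out["name"], out["n_features"])
    ]
    return out.sort_values(["auc", "q"], ascending=[False, True]).reset_index(drop=True)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone after cumulative-min)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]
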