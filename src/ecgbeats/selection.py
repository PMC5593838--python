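"""Filter-method feature selection.

A feature is kept only when it differs significantly between *every*
pair of the four beat classes: Shapiro-Wilk normality screening
(informational — it motivates the non-parametric path but does not gate
it), a Kruskal-Wallis omnibus test (alpha = 0.05) and a Tukey-Kramer-type
post-hoc comparison of group mean ranks with studentized-range critical
values.  No correction across features is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "SelectionResult",
    "normality_scan",
    "kruskal_wallis",
    "posthoc_all_pairs",
    "filter_features",
]


@dataclass(frozen=True)
class SelectionResult:
    """Per-feature test results and the retained subset (registry order)."""

    shapiro_p: dict[str, dict[int, float]]     # feature -> class -> p
    kruskal: dict[str, tuple[float, float]]    # feature -> (H, p)
    posthoc_p: dict[str, dict[tuple[int, int], float]]
    retained: list[str]
    alpha: float
    degenerate: list[str]                      # constant-within-class flags


def _groups(values: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    return {int(g): values[labels == g] for g in np.unique(labels)}


def normality_scan(values: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Shapiro-Wilk p per class; a constant group reports p = 0 (flagged
    degenerate by the caller)."""
    out = {}
    for g, x in _groups(np.asarray(values, float), np.asarray(labels)).items():
        if len(x) < 3 or np.ptp(x) == 0:
            out[g] = 0.0
        else:
            out[g] = float(stats.shapiro(x).pvalue)
    return out


def kruskal_wallis(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H and p (chi-square, groups-1 df, mid-rank ties)."""
    values = np.asarray(values, dtype=float)
    groups = list(_groups(values, np.asarray(labels)).values())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(values) == 0:  # every observation tied: no evidence either way
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def posthoc_all_pairs(values: np.ndarray, labels: np.ndarray) -> dict[tuple[int, int], float]:
    """Tukey-Kramer multiple comparison of Kruskal-Wallis mean ranks.

    For groups i, j with mean ranks Rbar and sizes n, the statistic

        q = |Rbar_i - Rbar_j| / sqrt(S * (1/n_i + 1/n_j) / 2)

    with S = N (N + 1) / 12 corrected for ties is referred to the
    studentized range distribution with infinite degrees of freedom.
    Unequal group sizes are allowed (the Kramer extension).  A group with
    fewer than two observations yields p = 1 for its pairs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ranks = stats.rankdata(values)
    N = len(values)
    uniq, counts = np.unique(values, return_counts=True)
    tie_corr = 1.0 - (counts ** 3 - counts).sum() / max(N ** 3 - N, 1)
    S = N * (N + 1) / 12.0 * tie_corr

    glabels = sorted(int(g) for g in np.unique(labels))
    k = len(glabels)
    mean_rank = {g: ranks[labels == g].mean() for g in glabels}
    n = {g: int((labels == g).sum()) for g in glabels}
    out: dict[tuple[int, int], float] = {}
    for a, b in combinations(glabels, 2):
        if n[a] < 2 or n[b] < 2 or S <= 0:
            out[(a, b)] = 1.0
            continue
        se = np.sqrt(S * (1.0 / n[a] + 1.0 / n[b]) / 2.0)
        q = abs(mean_rank[a] - mean_rank[b]) / se
        out[(a, b)] = float(stats.studentized_range.sf(q, k, np.inf))
    return out


def filter_features(
    matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    alpha: float = 0.05,
) -> SelectionResult:
    """Retain the features whose all pairwise post-hoc p-values are < alpha.

    ``matrix`` is (n_beats, n_features); column order (= registry order)
    is preserved in the retained list.  An empty retained set is allowed.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValueError("matrix/feature_names mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix must be finite")

    shapiro_p, kw, ph, retained, degenerate = {}, {}, {}, [], []
    for jcol, name in enumerate(feature_names):
        col = X[:, jcol]
        sp = normality_scan(col, labels)
        shapiro_p[name] = sp
        if any(np.ptp(col[labels == g]) == 0 for g in np.unique(labels)):
            degenerate.append(name)
        kw[name] = kruskal_wallis(col, labels)
        pairs = posthoc_all_pairs(col, labels)
        ph[name] = pairs
        if pairs and all(p < alpha for p in pairs.values()):
            retained.append(name)
    return SelectionResult(shapiro_p=shapiro_p, kruskal=kw, posthoc_p=ph,
                           retained=retained, alpha=alpha, degenerate=degenerate)
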