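"""Three-step radiomic feature selection.

Step I removes redundancy with a pairwise Spearman filter (|rho| > 0.8 by
default): the full absolute rank-correlation matrix is computed once, the
most-correlated offending pair is found, and of that pair the feature with
the larger mean absolute correlation against all surviving features is
dropped; this repeats until no pair exceeds the threshold.

Step II screens the survivors univariately with a two-sided Wilcoxon
rank-sum test (or the paired signed-rank test for lesion-vs-healthy
analyses within the same patients), keeping features with p < alpha.

Step III ranks the remaining features by the mutual information between the
equal-frequency-binned feature values and class membership, and keeps the
top k (k = 5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

from .errors import PairingError, SingleClassError
from .feature_table import FeatureTable


@dataclass
class SelectionTrace:
    """Surviving feature sets after each selection step.

    ``step2`` / ``step3`` are DataFrames with per-feature statistics
    (p-values, MI scores in nats); list views are exposed as properties.
    ``paired_step2`` holds the signed-rank screen when one was run.
    """

    step1_survivors: list[str]
    step2: pd.DataFrame  # columns: feature, statistic, p_value (survivors only)
    step3: pd.DataFrame  # columns: feature, mi_nats (ordered, top k)
    rho_max: float
    alpha: float
    k: int
    paired: bool
    paired_step2: pd.DataFrame | None = None

    @property
    def step2_survivors(self) -> list[str]:
        return list(self.step2["feature"])

    @property
    def step3_topk(self) -> list[str]:
        return list(self.step3["feature"])

    def write(self, directory: str | Path, prefix: str = "selection") -> None:
        """Export one TSV per step."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"feature": self.step1_survivors}).to_csv(
            directory / f"{prefix}_step1.tsv", sep="\t", index=False
        )
        self.step2.to_csv(directory / f"{prefix}_step2.tsv", sep="\t", index=False)
        if self.paired_step2 is not None:
            self.paired_step2.to_csv(
                directory / f"{prefix}_step2_paired.tsv", sep="\t", index=False
            )
        self.step3.to_csv(directory / f"{prefix}_step3.tsv", sep="\t", index=False)


def spearman_abs_matrix(values: np.ndarray) -> np.ndarray:
    """|Spearman rho| matrix; correlations with constant columns are 0."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    constant = values.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); their correlations are set to 0"
        )
    if p == 1:
        return np.zeros((1, 1))
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(values, axis=0).statistic
    if np.ndim(rho) == 0:  # scalar return (two columns, or fully degenerate)
        r = float(rho)
        rho = np.full((p, p), r)
        np.fill_diagonal(rho, 1.0)
    rho = np.asarray(rho, dtype=float)
    rho = np.abs(rho)
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 0.0)
    return rho


def correlation_filter(
    table: FeatureTable | pd.DataFrame, rho_max: float = 0.8
) -> list[str]:
    """Step I: iterative Spearman redundancy filter.

    Returns surviving feature names in catalogue order such that no
    surviving pair has |rho| > ``rho_max``. At each iteration the pair with
    the largest offending |rho| is located and the member with the larger
    mean absolute correlation against the current survivor set is removed
    (ties: the later feature in catalogue order is removed).
    """
    values = table.values if isinstance(table, FeatureTable) else table
    names = list(values.columns)
    X = values.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("correlation filter needs at least 3 rows")
    if not 0 < rho_max <= 1:
        raise ValueError("rho_max must lie in (0, 1]")
    rho = spearman_abs_matrix(X)
    alive = np.ones(len(names), dtype=bool)
    while True:
        sub = rho[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= rho_max:
            break
        alive_idx = np.where(alive)[0]
        i_sub, j_sub = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive_idx[i_sub], alive_idx[j_sub]
        # mean |rho| against all other currently-surviving features
        others = alive.copy()
        mean_i = rho[i, others].sum() / max(others.sum() - 1, 1)
        mean_j = rho[j, others].sum() / max(others.sum() - 1, 1)
        # note rho[i, i] = 0 so excluding self only changes the denominator
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # tie: later catalogue position goes
        alive[drop] = False
    return [names[i] for i in np.where(alive)[0]]


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p; exact when small and tie-free."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not ties and min(len(x), len(y)) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _signed_rank_p(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank p on paired differences.

    Zero differences are discarded (reduced n); an all-zero difference
    vector is degenerate and yields p = 1 with a warning.
    """
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; signed-rank p set to 1")
        return 0.0, 1.0
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (not ties and len(nonzero) <= 12) else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", alternative="two-sided",
        correction=True, method=method,
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_screen(
    table: FeatureTable | pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    alpha: float = 0.05,
    paired: bool = False,
    subject_ids: Sequence[str] | None = None,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Step II: univariate Wilcoxon screening.

    Returns a DataFrame (feature, statistic, p_value, selected) over
    ``features`` (default: all columns). For ``paired=True`` rows must form
    complete subject-matched pairs; differences are taken positive-class
    minus negative-class within subject.
    """
    values = table.values if isinstance(table, FeatureTable) else table
    if subject_ids is None and isinstance(table, FeatureTable):
        subject_ids = table.subject_ids.to_numpy()
    if features is not None:
        values = values[list(features)]
    y = np.asarray(labels, dtype=int)
    if len(y) != len(values):
        raise ValueError("labels length does not match table rows")
    if len(np.unique(y)) < 2:
        raise SingleClassError("both classes must be present for screening")

    X = values.to_numpy(dtype=float)
    pos, neg = y == 1, y == 0
    if paired:
        if subject_ids is None:
            raise PairingError("paired screening requires subject ids")
        subj = np.asarray(subject_ids)
        pos_order = np.argsort(subj[pos], kind="stable")
        neg_order = np.argsort(subj[neg], kind="stable")
        pos_subj, neg_subj = subj[pos][pos_order], subj[neg][neg_order]
        if len(pos_subj) != len(set(pos_subj)) or len(neg_subj) != len(set(neg_subj)):
            raise PairingError("duplicate subject within a class; cannot pair rows")
        unmatched = sorted(set(pos_subj).symmetric_difference(neg_subj))
        if unmatched:
            raise PairingError(f"unpaired subjects: {unmatched}")
        diffs = X[pos][pos_order] - X[neg][neg_order]

    stat = np.empty(X.shape[1])
    pval = np.empty(X.shape[1])
    for k in range(X.shape[1]):
        if paired:
            stat[k], pval[k] = _signed_rank_p(diffs[:, k])
        else:
            stat[k], pval[k] = _rank_sum_p(X[pos, k], X[neg, k])
    out = pd.DataFrame(
        {
            "feature": list(values.columns),
            "statistic": stat,
            "p_value": pval,
            "selected": pval < alpha,
        }
    )
    return out


def equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based equal-frequency bin codes.

    Bin = floor((rank - 1/2) / n * bins) with average ranks, so tied values
    always share a bin (a constant vector collapses to one bin) while
    distinct values split into equal-count bins determined by rank alone,
    making the codes invariant under strictly monotone transforms.
    """
    n = len(x)
    ranks = stats.rankdata(x, method="average")
    return np.floor((ranks - 0.5) * bins / n).astype(int)


def mutual_information(
    feature: np.ndarray, labels: Sequence[int] | np.ndarray, bins: int | None = None
) -> float:
    """Plug-in mutual information (nats) between a binned feature and class.

    The feature is discretized into equal-frequency bins (default
    ceil(sqrt(n)), capped at 10); MI is the plug-in estimate on the
    resulting bins x class contingency table. Rank-based binning makes the
    estimate invariant under strictly monotone transforms when feature
    values are distinct.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(x)
    if n < 4:
        raise ValueError("mutual information needs n >= 4")
    if len(y) != n:
        raise ValueError("labels length does not match feature length")
    if len(np.unique(y)) < 2:
        raise SingleClassError("mutual information is undefined for a single class")
    if bins is None:
        bins = min(int(np.ceil(np.sqrt(n))), 10)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    codes = equal_frequency_bins(x, bins)
    return float(mutual_info_score(codes, y))


def mi_rank(
    table: FeatureTable | pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    k: int = 5,
    bins: int | None = None,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Step III: rank features by MI descending, ties by catalogue order.

    Returns the top ``min(k, count)`` rows as (feature, mi_nats).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = table.values if isinstance(table, FeatureTable) else table
    if features is not None:
        values = values[list(features)]
    X = values.to_numpy(dtype=float)
    mi = np.array([mutual_information(X[:, j], labels, bins) for j in range(X.shape[1])])
    order = np.argsort(-mi, kind="stable")[: min(k, len(mi))]
    return pd.DataFrame(
        {"feature": [values.columns[i] for i in order], "mi_nats": mi[order]}
    )
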