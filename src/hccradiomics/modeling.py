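"""Imbalance-adjusted bootstrap resampling (IABR) and 0.632+ model building.

The modeling stage builds multivariable logistic models of increasing order
by forward selection: at each order the candidate feature that maximizes
the 0.632+ bootstrap AUC is added. Bootstrap samples are drawn
class-balanced — each of the n in-bag draws first picks a class with
probability 1/2, then an instance uniformly within that class — so that
minority-class instances are as likely to enter the training sample as
majority-class ones. Out-of-bag instances form the test set of each
replicate; the 0.632+ estimator blends apparent and out-of-bag performance
through the relative overfitting rate. Model pairs are compared with the
DeLong test for correlated ROC AUCs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import (
    ConstantFeatureError,
    DegenerateVarianceError,
    SingleClassError,
)
from .feature_table import FeatureTable

CHANCE_AUC = 0.5


@dataclass(frozen=True)
class BootstrapConfig:
    """IABR settings: B bootstrap replicates, base seed, balance flag."""

    b: int = 1000
    seed: int = 0
    imbalance_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.b < 10:
            raise ValueError("at least 10 bootstrap samples are required")


def balanced_bootstrap(
    labels: Sequence[int] | np.ndarray, config: BootstrapConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw B (in-bag, out-of-bag) index pairs.

    With imbalance adjustment each of the n in-bag draws selects the
    positive or negative class with probability 1/2 and then an instance
    uniformly within the class — in-bag positive counts are then exactly
    Binomial(n, 1/2). Without it, draws are uniform over all rows (plain
    bootstrap). Draws are unconditional: with a very small minority class
    the out-of-bag set occasionally lacks one class (all its instances
    were drawn in-bag); such replicates are skipped at evaluation time
    rather than redrawn here, which would bias the in-bag class balance
    the adjustment exists to guarantee.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 4:
        raise ValueError("bootstrap needs n >= 4")
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise SingleClassError("both classes must be present to bootstrap")
    rng = np.random.default_rng(config.seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    all_idx = np.arange(n)
    for _ in range(config.b):
        if config.imbalance_adjusted:
            n_pos = rng.binomial(n, 0.5)
            in_bag = np.concatenate(
                [rng.choice(pos, size=n_pos), rng.choice(neg, size=n - n_pos)]
            )
        else:
            in_bag = rng.choice(all_idx, size=n)
        oob = np.setdiff1d(all_idx, in_bag)
        out.append((np.sort(in_bag), oob))
    return out


@dataclass
class LogisticModel:
    """Multivariable logistic model g(x) = beta0 + sum_j beta_j x_j.

    Coefficients apply to standardized inputs; the per-feature (mean, sd)
    used for standardization is stored so the model can be re-applied to
    raw feature values.
    """

    features: list[str]
    beta0: float
    betas: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.features) == len(self.betas) == len(self.mean) == len(self.sd)):
            raise ValueError("feature/coefficient length mismatch")
        if np.any(self.sd <= 0):
            raise ConstantFeatureError("all standardization sds must be positive")

    def linear_predictor(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.features if f not in X.columns]
            if missing:
                raise KeyError(f"missing model features: {missing}")
            X = X[self.features].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.mean) / self.sd
        return self.beta0 + Z @ self.betas

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "beta0": float(self.beta0),
            "betas": [float(b) for b in self.betas],
            "standardization": {
                "mean": [float(m) for m in self.mean],
                "sd": [float(s) for s in self.sd],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            list(d["features"]),
            float(d["beta0"]),
            np.asarray(d["betas"], dtype=float),
            np.asarray(d["standardization"]["mean"], dtype=float),
            np.asarray(d["standardization"]["sd"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LogisticModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def predict(model: LogisticModel, x: np.ndarray | pd.DataFrame | dict) -> np.ndarray | float:
    """Eq.-style probability p = exp(g)/(1 + exp(g)) for raw feature input."""
    if isinstance(x, dict):
        try:
            x = np.array([x[f] for f in model.features], dtype=float)
        except KeyError as exc:
            raise KeyError(f"missing model feature {exc.args[0]!r}") from None
        return float(model.predict_proba(x)[0])
    p = model.predict_proba(x)
    return float(p[0]) if p.shape == (1,) else p


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int] | np.ndarray,
    features: Sequence[str] | None = None,
    ridge: float = 1e-6,
) -> LogisticModel:
    """Maximum-likelihood logistic fit on standardized features.

    A fixed tiny ridge (default 1e-6, on the slopes only, never on the
    intercept) keeps coefficients finite on separable data, which is
    common at n = 38 with strong features. Newton iterations with step
    halving on the penalized log-likelihood; deterministic.
    """
    if isinstance(X, pd.DataFrame):
        if features is None:
            features = list(X.columns)
        X = X[list(features)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and len(np.asarray(y)) > 1:
            X = X.T
        if features is None:
            features = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, v = X.shape
    if v < 1:
        raise ValueError("at least one feature is required")
    if len(np.unique(y)) < 2:
        raise SingleClassError("both classes must be present to fit")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [features[j] for j in np.where(sd == 0)[0]]
        raise ConstantFeatureError(f"constant feature column(s): {bad}")
    Z = np.column_stack([np.ones(n), (X - mean) / sd])
    lam = np.zeros(v + 1)
    lam[1:] = ridge

    def penalized_loglik(beta: np.ndarray) -> float:
        g = Z @ beta
        # log-likelihood sum(y g - log(1 + e^g)), stable via logaddexp
        return float(y @ g - np.logaddexp(0.0, g).sum() - 0.5 * (lam * beta**2).sum())

    beta = np.zeros(v + 1)
    ll = penalized_loglik(beta)
    for _ in range(200):
        g = Z @ beta
        p = expit(g)
        grad = Z.T @ (y - p) - lam * beta
        w = np.clip(p * (1.0 - p), 1e-10, None)
        H = (Z * w[:, None]).T @ Z + np.diag(lam)
        step = np.linalg.solve(H, grad)
        # step-halving keeps Newton monotone on flat (near-separable) likelihoods
        t = 1.0
        for _halving in range(50):
            candidate = beta + t * step
            ll_new = penalized_loglik(candidate)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll = candidate, ll_new
        if np.max(np.abs(grad)) < 1e-10 or np.max(np.abs(t * step)) < 1e-12:
            break
    return LogisticModel(list(features), float(beta[0]), beta[1:], mean, sd)


def auc(scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray) -> float:
    """Mann-Whitney concordance P(score_pos > score_neg) + 1/2 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC requires both classes")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def overfitting_weight(apparent: float, oob_mean: float, chance: float) -> float:
    """0.632+ blending weight w = 0.632 / (1 - 0.368 R), R the overfitting rate."""
    m_prime = max(oob_mean, chance)
    if apparent > m_prime and apparent > chance:
        r = (apparent - m_prime) / (apparent - chance)
    else:
        r = 0.0
    r = min(max(r, 0.0), 1.0)
    return 0.632 / (1.0 - 0.368 * r)


def estimate_632plus(apparent: float, oob_mean: float, chance: float = CHANCE_AUC) -> float:
    """The 0.632+ bootstrap estimate blending apparent and out-of-bag values.

    The out-of-bag mean is floored at the chance value before blending, so
    the estimate always lies between min(apparent, m') and max(apparent, m')
    with m' = max(oob_mean, chance).
    """
    m_prime = max(oob_mean, chance)
    w = overfitting_weight(apparent, oob_mean, chance)
    return (1.0 - w) * apparent + w * m_prime


@dataclass
class ModelPerformance:
    """Per-order 0.632+ and apparent performance quadruples (all in [0, 1])."""

    order: int
    auc632: float
    sens632: float
    spec632: float
    acc632: float
    apparent_auc: float
    apparent_sens: float
    apparent_spec: float
    apparent_acc: float

    def to_dict(self) -> dict:
        return {k: (int(v) if k == "order" else float(v)) for k, v in self.__dict__.items()}


def _classification_metrics(scores: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(auc, sensitivity, specificity, accuracy) at threshold p >= 0.5."""
    pred = (scores >= 0.5).astype(int)
    pos, neg = y == 1, y == 0
    sens = float((pred[pos] == 1).mean())
    spec = float((pred[neg] == 0).mean())
    acc = float((pred == y).mean())
    return auc(scores, y), sens, spec, acc


def evaluate_model(
    features: Sequence[str],
    table: FeatureTable | pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    config: BootstrapConfig,
    bootstrap_pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ModelPerformance:
    """IABR evaluation of one feature combination.

    Apparent metrics come from a fit on all rows scored on all rows;
    bootstrap metrics from fits on in-bag rows scored out-of-bag; each of
    AUC, sensitivity, specificity and accuracy is then combined with the
    0.632+ estimator at chance level 0.5.
    """
    if len(features) == 0:
        raise ValueError("at least one feature is required")
    values = table.values if isinstance(table, FeatureTable) else table
    X = values[list(features)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    model = fit_logistic(X, y, features=list(features))
    apparent = _classification_metrics(model.predict_proba(X), y)
    if bootstrap_pairs is None:
        bootstrap_pairs = balanced_bootstrap(y, config)
    oob_metrics = np.full((len(bootstrap_pairs), 4), np.nan)
    for i, (in_bag, oob) in enumerate(bootstrap_pairs):
        if len(oob) == 0 or len(np.unique(y[oob])) < 2:
            continue  # out-of-bag set is not scoreable; replicate skipped
        try:
            m = fit_logistic(X[in_bag], y[in_bag], features=list(features))
        except (ConstantFeatureError, SingleClassError):
            # degenerate replicate, excluded from the OOB mean; kept rare by
            # the balanced draw (continuous features rarely go constant in-bag)
            continue
        oob_metrics[i] = _classification_metrics(m.predict_proba(X[oob]), y[oob])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        oob_mean = np.nanmean(oob_metrics, axis=0)
    corrected = [
        estimate_632plus(a, o, CHANCE_AUC) if np.isfinite(o) else a
        for a, o in zip(apparent, oob_mean)
    ]
    return ModelPerformance(len(features), *corrected, *apparent)


def forward_select(
    candidates: Sequence[str],
    table: FeatureTable | pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    max_order: int = 5,
    config: BootstrapConfig = BootstrapConfig(),
) -> list[tuple[int, LogisticModel, ModelPerformance]]:
    """Forward model building over orders 1..max_order by 0.632+ AUC.

    At each order the remaining candidate maximizing the 0.632+ AUC joins
    the model (ties keep the earlier candidate, i.e. higher MI rank). One
    common IABR index set (derived from the seed) is used while searching,
    and a fresh IABR draw re-evaluates the per-order winners, mirroring the
    build-then-re-evaluate protocol.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate features")
    if not 1 <= max_order <= len(candidates):
        raise ValueError("max_order must lie in [1, number of candidates]")
    values = table.values if isinstance(table, FeatureTable) else table
    y = np.asarray(labels, dtype=int)
    seed_search, seed_eval = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(2)
    ]
    search_cfg = BootstrapConfig(config.b, seed_search, config.imbalance_adjusted)
    search_pairs = balanced_bootstrap(y, search_cfg)
    eval_cfg = BootstrapConfig(config.b, seed_eval, config.imbalance_adjusted)
    eval_pairs = balanced_bootstrap(y, eval_cfg)

    current: list[str] = []
    out: list[tuple[int, LogisticModel, ModelPerformance]] = []
    for order in range(1, max_order + 1):
        best_name, best_auc = None, -np.inf
        for name in candidates:
            if name in current:
                continue
            perf = evaluate_model(current + [name], values, y, search_cfg, search_pairs)
            if perf.auc632 > best_auc:
                best_name, best_auc = name, perf.auc632
        current = current + [best_name]
        model = fit_logistic(values[current], y)
        perf = evaluate_model(current, values, y, eval_cfg, eval_pairs)
        out.append((order, model, perf))
    return out


def select_best_order(
    performances: Sequence[ModelPerformance],
    epsilon: float = 0.01,
    tie_break: str = "parsimony",
) -> int:
    """Choose the simplest order whose 0.632+ AUC is within epsilon of the best.

    ``tie_break="specificity"`` instead picks, among the orders within
    epsilon of the best AUC, the one with the highest 0.632+ specificity
    (the criterion used when near-equal AUC curves are separated by
    specificity).
    """
    if not performances:
        raise ValueError("no performances given")
    best = max(p.auc632 for p in performances)
    eligible = [p for p in sorted(performances, key=lambda p: p.order) if p.auc632 >= best - epsilon]
    if tie_break == "specificity":
        return max(eligible, key=lambda p: (p.spec632, -p.order)).order
    return eligible[0].order


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y], vectorized over all pairs
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)  # V10 (per pos), V01 (per neg)


def delong_compare(
    scores_a: Sequence[float] | np.ndarray,
    scores_b: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
) -> float:
    """Two-sided DeLong p-value for equality of two correlated AUCs.

    Uses the placement-value covariance estimator on the shared label
    vector. Identical score vectors return p = 1; a zero variance estimate
    with unequal AUCs raises :class:`DegenerateVarianceError`.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("score vectors and labels must share one length")
    if len(np.unique(y)) < 2:
        raise SingleClassError("DeLong test requires both classes")
    if np.array_equal(a, b):
        return 1.0
    v10_a, v01_a = _placements(a, y)
    v10_b, v01_b = _placements(b, y)
    auc_a, auc_b = v10_a.mean(), v10_b.mean()
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return 1.0
        raise DegenerateVarianceError("zero variance with unequal AUC estimates")
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def pairwise_delong(
    score_sets: dict[int, np.ndarray] | dict[str, np.ndarray],
    labels: Sequence[int] | np.ndarray,
) -> pd.DataFrame:
    """All pairwise DeLong tests with Bonferroni adjustment.

    Raw p-values are multiplied by the number of pairs (k(k-1)/2 for k
    score sets) and capped at 1.
    """
    keys = list(score_sets)
    n_pairs = len(keys) * (len(keys) - 1) // 2
    rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            p = delong_compare(score_sets[ka], score_sets[kb], labels)
            rows.append(
                {
                    "model_a": ka,
                    "model_b": kb,
                    "p_value": p,
                    "p_bonferroni": min(p * n_pairs, 1.0),
                }
            )
    return pd.DataFrame(rows, columns=["model_a", "model_b", "p_value", "p_bonferroni"])
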