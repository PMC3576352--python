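"""Statistical layer relating image features to SUV_max and to longitudinal
morphological change.

Covers: Pearson correlations with Fisher-z 95 % confidence intervals,
Spearman rank correlations, complete-linkage hierarchical clustering of
standardized feature columns, Shapiro-Wilk normality and variance-ratio
F tests, and a logit-transform + maximum-likelihood linear model with
leave-one-out cross-validation (LOOCV) for predicting morphological
change (volume, circularity, or their product) from baseline features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    n: int


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Sample Pearson r with Fisher-z CI and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need paired samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    zc = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return CorrelationResult(float(r), float(lo), float(hi), float(p),
                             "pearson", n)


def spearman(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Spearman rank correlation: Pearson on mid-ranks, ties mid-ranked."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need paired samples with n >= 4")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.06 / math.sqrt(n - 3)  # Fieller-corrected SE for rank correlation
    zc = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return CorrelationResult(float(rho), float(lo), float(hi), float(p),
                             "spearman", n)


def correlation_table(features: pd.DataFrame, target: str = "SUVmax",
                      method: str = "pearson",
                      alpha: float = 0.05) -> pd.DataFrame:
    """Correlate every feature column with ``target``; Table-style output.

    Columns: feature, r, ci_low, ci_high, p. Constant or all-NaN columns
    are skipped with a warning.
    """
    fn = pearson_with_ci if method == "pearson" else spearman
    y = features[target].to_numpy(dtype=float)
    rows = []
    for col in features.columns:
        if col == target:
            continue
        x = features[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4 or np.std(x[ok]) == 0:
            log.warning("skipping constant/short column %s", col)
            continue
        res = fn(x[ok], y[ok], alpha=alpha)
        rows.append({"feature": col, "r": res.r, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p_value, "n": res.n})
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


@dataclass
class Dendrogram:
    """Agglomeration sequence over feature columns."""

    linkage: np.ndarray     # scipy linkage matrix (merges, heights)
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch lengths."""
        n = len(self.labels)
        nodes = {i: (self.labels[i], 0.0) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            (sa, ha), (sb, hb) = nodes.pop(int(a)), nodes.pop(int(b))
            rep = (f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})")
            nodes[n + k] = (rep, h)
        (tree, _), = nodes.values()
        return tree + ";"


def hcluster(features: pd.DataFrame, standardize: bool = True) -> Dendrogram:
    """Complete-linkage Euclidean clustering of feature columns.

    Columns are standardized to zero mean / unit SD first (so clustering
    reflects correlation structure, not scale); constant columns are
    excluded with a warning. Ties break deterministically by column order.
    """
    cols = []
    labels = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            log.warning("excluding column %s with non-finite values", col)
            continue
        sd = x.std()
        if standardize and sd == 0:
            log.warning("excluding constant column %s", col)
            continue
        cols.append((x - x.mean()) / sd if standardize else x)
        labels.append(col)
    if len(cols) < 2:
        raise ValueError("need at least 2 usable columns to cluster")
    data = np.column_stack(cols).T  # observations = feature columns
    link = hierarchy.linkage(data, method="complete", metric="euclidean")
    return Dendrogram(linkage=link, labels=labels)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); requires 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def variance_f_test(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float], float]:
    """Two-sided F test of equal variances: F = var(x)/var(y), CI, p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 in both samples")
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("zero variance: F test undefined")
    dfx, dfy = len(x) - 1, len(y) - 1
    f = vx / vy
    dist = sps.f(dfx, dfy)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    ci = (f / sps.f.ppf(1 - alpha / 2, dfx, dfy),
          f / sps.f.ppf(alpha / 2, dfx, dfy))
    return float(f), (float(ci[0]), float(ci[1])), float(min(p, 1.0))


def _logit(p):
    return np.log(p / (1.0 - p))


def _inv_logit(z):
    return 1.0 / (1.0 + np.exp(-z))


def predict_morphology_loocv(
    features: pd.DataFrame,
    predictor_names,
    response_name: str,
    ridge: float = 1e-6,
    scaling: str = "rank",
) -> tuple[np.ndarray, CorrelationResult]:
    """LOOCV prediction of a morphological-change response.

    The response is squashed into (0, 1) — rank scaling r/(n+1) by default,
    or min-max with a small inset (``scaling='minmax'``) — then
    logit-transformed; a linear model on standardized predictors is fit by
    maximum likelihood (Gaussian errors on the logit scale, i.e. least
    squares, with a tiny ridge for stability). Each row is predicted from
    a model fit on the others; predictions are back-transformed and the
    Spearman correlation between predictions and the true response is
    returned alongside them.

    Constant predictor columns are dropped with a warning.
    """
    y_raw = features[response_name].to_numpy(dtype=float)
    n = len(y_raw)
    if n < 10:
        raise ValueError("need at least 10 rows for LOOCV")
    if np.std(y_raw) == 0:
        raise ValueError("constant response")

    keep = []
    for name in predictor_names:
        x = features[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            log.warning("dropping constant predictor %s", name)
            continue
        keep.append(name)
    if not keep:
        raise ValueError("no usable predictor")
    if n < len(keep) + 2:
        raise ValueError("fewer rows than predictors + 2")

    X = features[list(keep)].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    X = np.column_stack([np.ones(n), X])

    if scaling == "rank":
        y01 = sps.rankdata(y_raw) / (n + 1.0)
    elif scaling == "minmax":
        span = np.ptp(y_raw)
        y01 = 0.5 / (n + 1) + (y_raw - y_raw.min()) / span * (1 - 1.0 / (n + 1))
        y01 = np.clip(y01, 1e-6, 1 - 1e-6)
    else:
        raise ValueError("scaling must be 'rank' or 'minmax'")
    z = _logit(y01)

    preds = np.empty(n)
    eye = np.eye(X.shape[1])
    for i in range(n):
        idx = np.arange(n) != i
        Xi, zi = X[idx], z[idx]
        beta = np.linalg.solve(Xi.T @ Xi + ridge * eye, Xi.T @ zi)
        preds[i] = X[i] @ beta
    preds01 = _inv_logit(preds)
    cor = spearman(preds01, y_raw)
    return preds01, cor


def prediction_report(features: pd.DataFrame, predictor_sets: dict,
                      responses) -> pd.DataFrame:
    """Spearman LOOCV prediction table over predictor sets x responses."""
    rows = []
    for resp in responses:
        for name, preds in predictor_sets.items():
            _, cor = predict_morphology_loocv(features, preds, resp)
            rows.append({"response": resp, "predictors": name,
                         "spearman": cor.r, "p": cor.p_value})
    return pd.DataFrame(rows)
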