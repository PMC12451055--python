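"""ROC analysis for discriminating anxious from non-anxious PD.

Single-marker curves, a multivariate logistic combined score, Youden
operating points, and DeLong confidence intervals / curve comparisons.
The positive class is PD with anxiety throughout; for single glymphatic
markers lower values indicate the positive class, so marker direction
is fixed per marker (recorded in the result), never refit per dataset.

AUC uses the Mann-Whitney identity with ties counted 1/2; DeLong
variance and covariance come from the placement-value (structural
component) estimator, with a normal approximation for CIs and for the
two-sided comparison test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    direction: str  # ">" higher score = positive class, "<" the reverse
    variance: float = np.nan
    extra: dict = field(default_factory=dict)


@dataclass
class CombinedModelSpec:
    """Predictors and combiner for the multivariate diagnostic model."""

    predictors: tuple[str, ...] = ("duration", "hy", "alps_left", "alps_right", "coupling")
    link: str = "logistic"

    def __post_init__(self) -> None:
        if len(self.predictors) < 1:
            raise ValueError("need at least one predictor")
        if self.link != "logistic":
            raise ValueError("only the logistic combiner is implemented")


def _split(scores: np.ndarray, labels: np.ndarray):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Mann-Whitney kernel placements (ties = 1/2) and the AUC."""
    cmp = (pos[:, None] > neg[None, :]).astype(np.float64)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0), float(cmp.mean())


def mann_whitney_auc(scores, labels) -> float:
    """AUC via the probability a positive outranks a negative (ties 1/2)."""
    pos, neg = _split(scores, labels)
    return _placements(pos, neg)[2]


def delong_variance(scores, labels) -> float:
    """DeLong structural-component variance of the AUC estimate."""
    pos, neg = _split(scores, labels)
    v10, v01, _ = _placements(pos, neg)
    return float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test of AUC_a == AUC_b on paired scores.

    Returns (z, p).  Comparing a score with itself gives z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must share one subject set")
    labels = np.asarray(labels).astype(int)
    pa, na = _split(scores_a, labels)
    pb, nb = _split(scores_b, labels)
    v10a, v01a, auca = _placements(pa, na)
    v10b, v01b, aucb = _placements(pb, nb)
    m, n = pa.size, na.size
    s10 = np.cov(v10a, v10b, ddof=1)
    s01 = np.cov(v01a, v01b, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auca - aucb
    if var <= 0:
        if abs(diff) > 1e-12:
            raise ValueError("degenerate DeLong variance with unequal AUCs")
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    return float(z), float(2.0 * sst.norm.sf(abs(z)))


def youden_point(scores, labels) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing J = sens + spec - 1.

    Scores are oriented so higher = positive class; predict positive at
    score >= threshold.  Ties on J resolve to the higher-specificity
    (higher-threshold) operating point.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos, neg = _split(scores, labels)
    best = None
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    for thr in thresholds:
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[3]
        ):
            best = (j, thr, sens, spec)
    return best[1], best[2], best[3]


#: Markers where a LOWER value indicates the positive (anxious) class.
LOWER_IS_POSITIVE = frozenset(
    {"alps_left", "alps_right", "alps_mean", "coupling"}
)


def roc_auc(scores, labels, direction: str = "auto", marker: str | None = None) -> RocResult:
    """Full ROC summary: AUC, DeLong 95% CI, Youden operating point.

    ``direction`` is ">" (higher score = positive), "<", or "auto".
    Auto resolves from the marker name when given (glymphatic markers
    are lower-in-positives), otherwise picks the orientation with
    AUC >= 0.5 and records it.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if direction == "auto":
        if marker is not None and marker in LOWER_IS_POSITIVE:
            direction = "<"
        else:
            direction = ">" if mann_whitney_auc(scores, labels) >= 0.5 else "<"
    if direction not in (">", "<"):
        raise ValueError("direction must be '>', '<' or 'auto'")
    oriented = scores if direction == ">" else -scores
    auc = mann_whitney_auc(oriented, labels)
    var = delong_variance(oriented, labels)
    se = np.sqrt(var)
    z = sst.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    thr, sens, spec = youden_point(oriented, labels)
    thr_out = thr if direction == ">" else -thr
    return RocResult(
        auc=auc,
        ci95=ci,
        sensitivity=sens,
        specificity=spec,
        threshold=float(thr_out),
        direction=direction,
        variance=var,
    )


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) at every distinct cut."""
    scores = np.asarray(scores, dtype=np.float64)
    pos, neg = _split(scores, labels)
    rows = []
    for thr in np.concatenate([np.unique(scores), [np.inf]]):
        rows.append(
            {
                "threshold": thr,
                "sensitivity": float((pos >= thr).mean()),
                "specificity": float((neg < thr).mean()),
            }
        )
    return pd.DataFrame(rows)


def fit_combined_score(
    cohort: pd.DataFrame,
    spec: CombinedModelSpec,
    label_col: str = "label",
) -> tuple[np.ndarray, dict[str, float]]:
    """Maximum-likelihood logistic combination of standardized predictors.

    Returns the per-subject linear-predictor scores (higher = more
    likely positive) and the fitted coefficients.  Under perfect
    separation the unpenalized fit diverges; it is then refit with an
    L2 penalty and a warning.
    """
    from sklearn.linear_model import LogisticRegression

    missing = [p for p in spec.predictors if p not in cohort.columns]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    X = cohort.loc[:, list(spec.predictors)].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("missing predictor values")
    y = np.asarray(cohort[label_col]).astype(int)
    if len(set(y)) != 2:
        raise ValueError("both classes must be present")
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    def _fit(penalized: bool):
        model = LogisticRegression(
            C=1.0 if penalized else np.inf, solver="lbfgs", max_iter=5000
        )
        model.fit(Xs, y)
        return model

    model = _fit(penalized=False)
    lin = Xs @ model.coef_.ravel()
    if lin[y == 1].min() > lin[y == 0].max():  # ML estimate diverges
        warnings.warn(
            "perfect separation detected; falling back to an L2-penalized fit",
            stacklevel=2,
        )
        model = _fit(penalized=True)
    scores = Xs @ model.coef_.ravel() + float(model.intercept_[0])
    coefs = dict(zip(spec.predictors, model.coef_.ravel().tolist()))
    coefs["intercept"] = float(model.intercept_[0])
    return scores, coefs
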