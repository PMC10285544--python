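"""Statistics over accepted and rejected model populations.

Summaries of scaling-factor distributions, pairwise Pearson correlations,
1-D Wasserstein distances between accepted/rejected parameter distributions,
cross-validated logistic accept/reject classifiers with odds ratios at a
threshold, and uniparametric sensitivity analysis of the cell model
(0.5x / 2x parameter scaling, percent biomarker change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .cell_model import (PARAM_NAMES, MechanicalProtocol, ScalingVector,
                         SimulationConfig, simulate)
from .biomarkers import extract_biomarkers

__all__ = [
    "summarize_parameters", "pearson_matrix", "wasserstein_1d",
    "classify_rejection", "odds_ratio", "sensitivity_analysis",
    "ClassifierReport",
]


def summarize_parameters(model_set, names: Sequence[str] = PARAM_NAMES) -> pd.DataFrame:
    """Per-parameter mean/std/min/quartiles/max over a set of scaling vectors.

    ``model_set`` is an (n, d) array (or a list of ScalingVector).  Layout:
    one column per parameter, one row per statistic.
    """
    X = _as_matrix(model_set)
    if X.shape[0] == 0:
        raise ValueError("empty model set")
    df = pd.DataFrame(X, columns=list(names))
    return df.describe().drop(index="count")


def _as_matrix(model_set) -> np.ndarray:
    if len(model_set) and isinstance(model_set[0], ScalingVector):
        return np.vstack([m.as_array() for m in model_set])
    return np.atleast_2d(np.asarray(model_set, dtype=float))


def pearson_matrix(model_set, names: Sequence[str] = PARAM_NAMES):
    """Pairwise Pearson r and p-values between parameter columns.

    Returns (r, p) DataFrames; r is symmetric with unit diagonal.
    """
    X = _as_matrix(model_set)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 models")
    d = X.shape[1]
    r = np.eye(d)
    p = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            res = stats.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    names = list(names)[:d]
    return (pd.DataFrame(r, index=names, columns=names),
            pd.DataFrame(p, index=names, columns=names))


def wasserstein_1d(sample_a, sample_b) -> float:
    """1-D earth-mover distance between two empirical distributions."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(stats.wasserstein_distance(a, b))


@dataclass
class ClassifierReport:
    """Cross-validated accept/reject classifier performance."""

    features: tuple
    accuracy: float
    roc_auc: float
    sensitivity: float
    specificity: float
    threshold: Optional[float] = None       # on the feature (uniparametric)
    odds_ratio: Optional[float] = None      # at the threshold
    or_ci: Optional[tuple] = None
    coefficients: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "features": list(self.features), "accuracy": self.accuracy,
            "roc_auc": self.roc_auc, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "threshold": self.threshold,
            "odds_ratio": self.odds_ratio,
            "or_ci": list(self.or_ci) if self.or_ci else None,
            "coefficients": self.coefficients,
        }


def classify_rejection(features, labels, feature_names: Optional[Sequence[str]] = None,
                       seed: int = 0, k: int = 5) -> ClassifierReport:
    """Stratified k-fold logistic regression of rejection (label 1) on features.

    For a single feature the report also contains the decision threshold on
    that feature maximizing Youden's index, and the odds ratio (with Woolf
    95 % CI) of acceptance below vs above that threshold.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(labels).size == X.shape[1]:
        X = X.T
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    names = tuple(feature_names or [f"f{i}" for i in range(X.shape[1])])

    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    clf = LogisticRegression(max_iter=1000)
    # standardized coefficients for feature importance
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    prob = cross_val_predict(clf, Xs, y, cv=cv, method="predict_proba")[:, 1]
    pred = (prob >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    report = ClassifierReport(
        features=names,
        accuracy=(tp + tn) / y.size,
        roc_auc=float(roc_auc_score(y, prob)),
        sensitivity=tp / max(tp + fn, 1),
        specificity=tn / max(tn + fp, 1),
    )
    clf.fit(Xs, y)
    report.coefficients = dict(zip(names, np.abs(clf.coef_[0]).tolist()))

    if X.shape[1] == 1:
        # threshold on the raw feature maximizing Youden's J
        fpr, tpr, thr = roc_curve(y, X[:, 0])
        j = tpr - fpr
        best = int(np.argmax(j))
        report.threshold = float(thr[best])
        below = X[:, 0] < report.threshold
        # odds of acceptance (y == 0) below vs above the threshold
        a = int(np.sum(below & (y == 0)))
        b = int(np.sum(below & (y == 1)))
        c = int(np.sum(~below & (y == 0)))
        d = int(np.sum(~below & (y == 1)))
        orr, ci = odds_ratio([[a, b], [c, d]])
        report.odds_ratio = orr
        report.or_ci = ci
    return report


def odds_ratio(two_by_two) -> tuple:
    """(OR, (lo, hi)) for a 2x2 table [[a, b], [c, d]] with Woolf 95 % CI.

    OR = ad/bc; a Haldane-Anscombe correction of 0.5 is added to every cell
    when any cell is zero.
    """
    t = np.asarray(two_by_two, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t == 0):
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(orr) - 1.96 * se))
    hi = float(np.exp(np.log(orr) + 1.96 * se))
    return float(orr), (lo, hi)


def sensitivity_analysis(baseline: ScalingVector = ScalingVector(),
                         parameters: Sequence[str] = ("gNa", "gCaL", "gK1", "gKs", "gKr"),
                         factors: Sequence[float] = (0.5, 2.0),
                         biomarker_names: Sequence[str] = ("RMP", "Vpeak", "dVdtmax", "APD90"),
                         config: SimulationConfig = SimulationConfig(),
                         protocol: MechanicalProtocol = MechanicalProtocol(),
                         ) -> pd.DataFrame:
    """Uniparametric sensitivity: percent biomarker change under 0.5x/2x scaling.

    Each (parameter, factor) pair reruns the model to steady state; entries
    are 100 * (biomarker - baseline) / baseline.  NaN marks a biomarker that
    could not be measured (e.g. loss of excitation).
    """
    base_tr = simulate(baseline, protocol, config)
    base_bm = extract_biomarkers(base_tr)
    rows = []
    for pname in parameters:
        for f in factors:
            kw = {pname: getattr(baseline, pname) * f}
            sv = ScalingVector(**{**{n: getattr(baseline, n) for n in PARAM_NAMES}, **kw})
            bm = extract_biomarkers(simulate(sv, protocol, config))
            row = {"parameter": pname, "factor": f}
            for name in biomarker_names:
                b0 = base_bm.get(name)
                b1 = bm.get(name)
                row[name] = (np.nan if b0 in (None, 0) or b1 is None
                             else 100.0 * (b1 - b0) / abs(b0))
            rows.append(row)
    return pd.DataFrame(rows)
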