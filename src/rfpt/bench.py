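"""Evaluation harness: confusion metrics, repeated-CV selector comparison
and the stepwise-AIC ordering curve.

The selector comparison mirrors the protocol used to benchmark NIC-based
selection against SVM-RFE-style baselines: stratified threefold
cross-validation repeated 20 times, identical folds for every feature set,
three downstream classifier families (quadratic-kernel max-margin,
logistic regression, tree ensemble), and Matthews correlation (MCC) plus
classification accuracy (CA) reported as mean +/- sd over folds x repeats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import Dataset

CLASSIFIER_FAMILIES = ("svm", "logistic", "random_forest")


@dataclass(frozen=True)
class CVProtocol:
    """Repeated stratified k-fold settings shared by all compared sets."""

    folds: int = 3
    repeats: int = 20
    seed: int = 0
    classifiers: tuple = CLASSIFIER_FAMILIES

    def __post_init__(self):
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


def confusion_metrics(truth: Sequence[int], predicted: Sequence[int]) -> dict:
    """MCC, CA, sensitivity and specificity of a binary prediction.

    MCC uses the convention that a zero denominator (a degenerate margin)
    yields 0; sensitivity/specificity of an absent class default to 1.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and prediction must be equal-length vectors")
    if t.size == 0:
        raise ValueError("empty label vectors")
    tp = int(np.count_nonzero((t == 1) & (p == 1)))
    tn = int(np.count_nonzero((t == 0) & (p == 0)))
    fp = int(np.count_nonzero((t == 0) & (p == 1)))
    fn = int(np.count_nonzero((t == 1) & (p == 0)))
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {
        "MCC": mcc,
        "CA": (tp + tn) / t.size,
        "sensitivity": tp / (tp + fn) if (tp + fn) else 1.0,
        "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
    }


def _make_classifier(name: str, seed: int):
    if name == "svm":
        # inhomogeneous quadratic kernel (x.x' + 1)^2, the usual "quadratic" SVM
        return make_pipeline(StandardScaler(), SVC(kernel="poly", degree=2, coef0=1.0, C=1.0))
    if name == "logistic":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown classifier family {name!r}")


def _cv_splits(y: np.ndarray, protocol: CVProtocol):
    """Materialized splits, regenerated with the next seed if a training
    fold ever contains a single class (possible only for tiny minorities)."""
    for attempt in range(10):
        cv = RepeatedStratifiedKFold(
            n_splits=protocol.folds,
            n_repeats=protocol.repeats,
            random_state=protocol.seed + attempt,
        )
        splits = list(cv.split(np.zeros_like(y), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            if attempt:
                warnings.warn(f"folds regenerated {attempt} time(s) for class balance")
            return splits
    raise ValueError("could not stratify folds with both classes present")


def compare_selectors(
    data: Dataset,
    feature_sets: Mapping[str, Sequence],
    protocol: CVProtocol = CVProtocol(),
) -> pd.DataFrame:
    """Cross-validated MCC/CA for each (feature set, classifier) pair.

    Every set is evaluated on the *same* folds so differences reflect the
    selections, not fold luck. Feature sets may hold names or indices.
    Returns a tidy DataFrame with mean and sd columns and a
    ``"value +/- sd"`` style summary string per metric.
    """
    name_to_idx = {n: i for i, n in enumerate(data.feature_names)}
    splits = _cv_splits(data.y, protocol)
    rows = []
    for set_name, feats in feature_sets.items():
        if len(feats) == 0:
            raise ValueError(f"feature set {set_name!r} is empty")
        idx = np.asarray(
            [name_to_idx[f] if f in name_to_idx else int(f) for f in feats],
            dtype=np.intp,
        )
        Xs = data.X[:, idx]
        for clf_name in protocol.classifiers:
            mccs, cas = [], []
            for fold_i, (tr, te) in enumerate(splits):
                clf = _make_classifier(clf_name, protocol.seed + fold_i)
                clf.fit(Xs[tr], data.y[tr])
                pred = clf.predict(Xs[te])
                m = confusion_metrics(data.y[te], pred)
                mccs.append(m["MCC"])
                cas.append(m["CA"])
            mccs = np.asarray(mccs)
            cas = np.asarray(cas)
            rows.append(
                {
                    "feature_set": set_name,
                    "classifier": clf_name,
                    "mcc_mean": mccs.mean(),
                    "mcc_sd": mccs.std(ddof=1),
                    "ca_mean": cas.mean(),
                    "ca_sd": cas.std(ddof=1),
                    "mcc": f"{100 * mccs.mean():.1f}% +/- {100 * mccs.std(ddof=1):.1f}%",
                    "ca": f"{100 * cas.mean():.1f}% +/- {100 * cas.std(ddof=1):.1f}%",
                }
            )
    return pd.DataFrame(rows)


def null_model_aic(y: Sequence[int]) -> float:
    """AIC of the intercept-only Bernoulli model (closed form)."""
    y = np.asarray(y, dtype=float)
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        return 2.0
    n1 = y.sum()
    n0 = y.size - n1
    llf = n1 * math.log(pbar) + n0 * math.log(1 - pbar)
    return 2.0 - 2.0 * llf


def stepwise_aic_curve(
    data: Dataset, ranking: Sequence, k_max: int
) -> pd.DataFrame:
    """AIC of a logistic model on the top-k ranked features, k = 0..k_max.

    Row k fits maximum-likelihood logistic regression on the k best
    features (k = 0 is the intercept-only reference) with AIC =
    2(k+1) - 2 log L. Fits that hit complete separation cannot converge to
    a finite optimum; they are flagged ``separated`` and their AIC reported
    at the iteration-capped likelihood.
    """
    if k_max > len(ranking):
        raise ValueError("k_max exceeds ranking length")
    name_to_idx = {n: i for i, n in enumerate(data.feature_names)}
    idx = [name_to_idx[f] if f in name_to_idx else int(f) for f in ranking]
    if not np.isfinite(data.X).all():
        raise ValueError("non-finite feature values")
    rows = [{"k": 0, "aic": null_model_aic(data.y), "separated": False}]
    y = data.y.astype(float)
    for k in range(1, k_max + 1):
        Xk = sm.add_constant(data.X[:, idx[:k]], has_constant="add")
        separated = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, Xk).fit(disp=0, maxiter=200)
            except Exception:
                fit = sm.Logit(y, Xk).fit(disp=0, maxiter=100, method="bfgs")
                separated = True
        prob = np.clip(fit.predict(Xk), 1e-12, 1 - 1e-12)
        if not separated and np.abs(prob - y).max() < 1e-6:
            separated = True
        llf = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
        rows.append({"k": k, "aic": 2.0 * (k + 1) - 2.0 * llf, "separated": separated})
    return pd.DataFrame(rows)
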