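"""Binomial GLM classifiers for the hypertensive phenotype.

A classifier is a logistic regression from physical-scale model
parameters (the virtual individual's genotype) to the probability of
being hypertensive.  The module covers the full workflow: fitting by
IRLS (through statsmodels), backward stepwise reduction under Akaike's
information criterion, reduced physiologically-measurable predictor
sets, held-out ROC/AUC evaluation with the tie-corrected rank
(Mann-Whitney) estimator, and per-parameter sensitivity of the fitted
classifier.

The named reduced predictor sets mirror the whole-body circulatory
model's renal and hepatic parameters that are feasible to estimate in
a patient: glomerular filtration properties (AARK, EARK, GFLC), plasma
protein turnover (CPR, LPPR) and dietary sodium intake (NID).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import rankdata

from .population import Population, StratificationConfig

__all__ = [
    "REDUCED_SETS",
    "Classifier",
    "RocCurve",
    "SeparationWarning",
    "fit_glm",
    "stepwise_aic",
    "auc_rank",
    "roc_points",
    "trapezoid_auc",
    "evaluate_split",
    "classifier_sensitivity",
]

#: built-in reduced predictor sets (whole-body circulatory model names)
REDUCED_SETS: dict[str, tuple[str, ...]] = {
    "renal+liver": ("AARK", "CPR", "EARK", "GFLC", "LPPR", "NID"),
    "liver": ("CPR", "LPPR", "NID"),
    "renal": ("AARK", "EARK", "GFLC", "NID"),
}


class SeparationWarning(UserWarning):
    """The two classes are (quasi-)perfectly separable; coefficients diverge."""


@dataclass
class Classifier:
    """A fitted (or hand-specified) binomial GLM.

    Coefficients are on the physical parameter scale; prediction is
    ``logistic(intercept + sum_j beta_j * param_j)``.
    """

    label: str
    intercept: float
    coef: dict[str, float]
    n: int = 0
    aic: float = float("nan")
    loglik: float = float("nan")
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.coef)

    def linear_predictor(self, genotype: Mapping[str, float] | pd.DataFrame):
        lp = self.intercept
        for name, beta in self.coef.items():
            try:
                value = genotype[name]
            except KeyError:
                raise KeyError(f"genotype lacks predictor {name!r}") from None
            lp = lp + beta * value
        return lp

    def predict(self, genotype: Mapping[str, float] | pd.DataFrame):
        """Probability of hypertension for one genotype or a frame of them."""
        lp = self.linear_predictor(genotype)
        out = expit(np.asarray(lp, dtype=float))
        return float(out) if np.ndim(lp) == 0 else out

    # -- structured-text round trip ------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "label": self.label,
            "intercept": self.intercept,
            "coefficients": self.coef,
            "n": self.n,
            "aic": self.aic,
            "loglik": self.loglik,
            "converged": self.converged,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "Classifier":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (TypeError, ValueError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            label=payload["label"],
            intercept=float(payload["intercept"]),
            coef={k: float(v) for k, v in payload["coefficients"].items()},
            n=int(payload.get("n", 0)),
            aic=float(payload.get("aic", float("nan"))),
            loglik=float(payload.get("loglik", float("nan"))),
            converged=bool(payload.get("converged", True)),
            meta=payload.get("meta", {}),
        )


def _validate_design(X: pd.DataFrame, y: np.ndarray) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; nothing to classify")
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if len(X) <= X.shape[1] + 1:
        raise ValueError(f"need n > p + 1, got n={len(X)}, p={X.shape[1]}")


def fit_glm(X: pd.DataFrame, y, label: str = "custom") -> Classifier:
    """Maximum-likelihood logistic fit of binary labels on predictors.

    Fitted by iteratively reweighted least squares.  Perfect separation
    is reported through ``converged=False`` plus a
    :class:`SeparationWarning` rather than an exception, since separable
    fits still rank individuals correctly.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    _validate_design(X, y)
    design = sm.add_constant(X, has_constant="add")
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        for w in caught:
            if "separat" in str(w.message).lower():
                separated = True
    if separated or not result.converged:
        warnings.warn(
            f"possible perfect separation fitting {label!r}; coefficients unreliable",
            SeparationWarning,
            stacklevel=2,
        )
    params = result.params
    return Classifier(
        label=label,
        intercept=float(params["const"]),
        coef={name: float(params[name]) for name in X.columns},
        n=len(X),
        aic=float(result.aic),
        loglik=float(result.llf),
        converged=bool(result.converged) and not separated,
    )


def _aic(X: pd.DataFrame, y: np.ndarray, predictors: Sequence[str]) -> float:
    design = sm.add_constant(X[list(predictors)], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sm.GLM(y, design, family=sm.families.Binomial()).fit().aic)


def stepwise_aic(X: pd.DataFrame, y, label: str = "stepwise") -> Classifier:
    """Backward stepwise reduction of a logistic model under AIC.

    Starting from the full predictor set, repeatedly drop the single
    predictor whose removal lowers AIC the most; stop when no removal
    lowers it.  The reduced model's AIC never exceeds the full model's.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    _validate_design(X, y)
    current = list(X.columns)
    current_aic = _aic(X, y, current)
    while current:
        candidates = [(predictor, _aic(X, y, [p for p in current if p != predictor]))
                      for predictor in current]
        predictor, best = min(candidates, key=lambda item: item[1])
        if best < current_aic:
            current.remove(predictor)
            current_aic = best
        else:
            break
    if not current:
        raise ValueError("stepwise reduction removed every predictor")
    fitted = fit_glm(X[current], y, label=label)
    fitted.meta["stepwise_dropped"] = [c for c in X.columns if c not in current]
    return fitted


# -- ROC / AUC ---------------------------------------------------------


def auc_rank(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) method.

    Midranks correct for ties: AUC is the probability that a random
    positive outscores a random negative, counting ties as half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores, method="average")
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RocCurve:
    """An ROC curve with endpoints (0,0) and (1,1) and its rank AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def roc_points(scores, labels) -> RocCurve:
    """Build the ROC curve, grouping tied scores into single vertices."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], (labels[order] == 1)
    # group tied scores
    uniq, start = np.unique(-s, return_index=True)
    boundaries = np.sort(start)
    tp = np.cumsum(l)
    fp = np.cumsum(~l)
    ends = np.append(boundaries[1:], len(s)) - 1
    n_pos, n_neg = int(l.sum()), int((~l).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build an ROC curve")
    tpr = np.concatenate(([0.0], tp[ends] / n_pos, [1.0]))
    fpr = np.concatenate(([0.0], fp[ends] / n_neg, [1.0]))
    thresholds = np.concatenate(([np.inf], s[ends], [-np.inf]))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc_rank(scores, labels))


def trapezoid_auc(curve: RocCurve) -> float:
    """AUC by trapezoidal integration of the curve (cross-check route)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def evaluate_split(
    pop: Population,
    predictors: Sequence[str],
    rng: np.random.Generator,
    strat: StratificationConfig | None = None,
    train_fraction: float = 0.5,
    label: str = "custom",
    phases: Sequence[str] = ("pre", "post"),
    max_retries: int = 20,
) -> tuple[Classifier, RocCurve]:
    """Train/evaluate a classifier on a random population split.

    Labels are hypertension per the stratification threshold.  The
    split is resampled (bounded retries) until both classes appear on
    both sides; the classifier is fitted on the training side and the
    ROC computed from its scores on the held-out side.
    """
    if strat is None:
        strat = StratificationConfig()
    sub = pop.alive_only().select_phases(phases)
    X = sub.params()[list(predictors)].reset_index(drop=True)
    y = (sub.vars()["MAP"].to_numpy() >= strat.map_threshold).astype(int)
    n_train = int(round(train_fraction * len(X)))
    if n_train < 2 or n_train > len(X) - 2:
        raise ValueError(f"train fraction {train_fraction} leaves no usable split for n={len(X)}")
    for _ in range(max_retries):
        perm = rng.permutation(len(X))
        train, test = perm[:n_train], perm[n_train:]
        if np.unique(y[train]).size == 2 and np.unique(y[test]).size == 2:
            break
    else:
        raise ValueError("could not find a split with both classes on both sides")
    clf = fit_glm(X.iloc[train], y[train], label=label)
    scores = clf.predict(X.iloc[test])
    return clf, roc_points(scores, y[test])


def classifier_sensitivity(
    clf: Classifier,
    ranges: Mapping[str, tuple[float, float]],
    defaults: Mapping[str, float],
    n_points: int = 101,
) -> pd.Series:
    """Prediction variation of each predictor over its physical range.

    For each predictor the predicted probability is swept over
    ``[low, high]`` with every other predictor held at its default; the
    reported variation is max - min of the prediction.  Sorted
    descending — the classifier's most influential parameters first.
    """
    out = {}
    for name in clf.predictors:
        low, high = ranges[name]
        sweep = np.linspace(low, high, n_points)
        genotype = {k: np.full(n_points, defaults[k]) for k in clf.predictors}
        genotype[name] = sweep
        probs = clf.predict(pd.DataFrame(genotype))
        out[name] = float(np.max(probs) - np.min(probs))
    return pd.Series(out, name="variation").sort_values(ascending=False)
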