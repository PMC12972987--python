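"""Binary classification with a patient-grouped bootstrap validation harness.

An elastic-net logistic model is tuned by five-fold cross-validation
(folds stratified by class and grouped by patient), then trained and
validated by bootstrapping: each of the `n_boot` iterations resamples
PATIENTS with replacement for training, all samples of out-of-bag
patients form that iteration's validation set, and the optimism-corrected
AUC is the mean validation AUC across iterations. Patients are never
split across training and validation. A patient-level label shuffle is
the standard null check for the harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .stats import auc_score

__all__ = [
    "ClassifierReport",
    "auc",
    "tune_enet",
    "make_enet",
    "bootstrap_validate",
    "supplementary_models",
]

auc = auc_score  # Mann-Whitney AUC; exported under the metric's plain name

L1_RATIO_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
C_GRID = tuple(np.logspace(-3, 2, 6))


@dataclass
class ClassifierReport:
    mean_auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    model: str
    boot_aucs: np.ndarray = field(repr=False)
    feature_frequency: pd.Series | None = field(default=None, repr=False)
    n_redrawn: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "model": self.model,
            "n_redrawn": self.n_redrawn,
            "hyperparameters": {
                k: float(v) if isinstance(v, (int, float, np.floating, np.integer)) else v
                for k, v in self.hyperparameters.items()
            },
        }


def make_enet(l1_ratio: float, C: float, max_iter: int = 5000, tol: float = 1e-4) -> Pipeline:
    """Standardised elastic-net logistic regression (saga solver)."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                LogisticRegression(
                    solver="saga",
                    l1_ratio=float(l1_ratio),
                    C=float(C),
                    max_iter=max_iter,
                    tol=tol,
                    random_state=0,
                ),
            ),
        ]
    )


def _as_xy(X, y):
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yv = np.asarray(y)
    classes = np.unique(yv)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes!r}")
    yb = (yv == classes[1]).astype(int)
    return Xm, yb, classes


def _cv_deviance(model, Xm, yb, groups, n_splits, seed):
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    losses = []
    for tr, va in cv.split(Xm, yb, groups):
        if len(np.unique(yb[tr])) < 2 or len(np.unique(yb[va])) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xm[tr], yb[tr])
            prob = model.predict_proba(Xm[va])[:, 1]
        losses.append(2.0 * log_loss(yb[va], prob, labels=[0, 1], normalize=False) / len(va))
    if not losses:
        raise ValueError("no valid CV split had both classes")
    return float(np.mean(losses))


def tune_enet(
    X,
    y,
    groups=None,
    l1_ratios=L1_RATIO_GRID,
    Cs=C_GRID,
    n_splits: int = 5,
    seed: int = 0,
) -> dict:
    """Grid-search mixing and penalty by grouped, stratified 5-fold CV,
    minimising cross-validated binomial deviance."""
    Xm, yb, _ = _as_xy(X, y)
    if len(yb) < 10:
        raise ValueError("need at least 10 samples to tune")
    if groups is None:
        groups = np.arange(len(yb))
    groups = np.asarray(groups)
    best = None
    for l1 in l1_ratios:
        for C in Cs:
            # lighter convergence settings during grid search; the chosen
            # pair is refit at full precision by the bootstrap harness
            dev = _cv_deviance(
                make_enet(l1, C, max_iter=1000, tol=1e-3), Xm, yb, groups, n_splits, seed
            )
            if best is None or dev < best["cv_deviance"]:
                best = {"l1_ratio": float(l1), "C": float(C), "cv_deviance": dev}
    return best


def bootstrap_validate(
    X,
    y,
    groups,
    n_boot: int = 500,
    seed: int = 0,
    model_factory=None,
    hyperparameters: dict | None = None,
    model_name: str = "enet",
) -> ClassifierReport:
    """Patient-grouped bootstrap training/validation with out-of-bag AUC.

    `model_factory()` must return an unfitted estimator with
    predict_proba; by default a tuned elastic net (via `hyperparameters`
    {'l1_ratio', 'C'}). Iterations whose validation set is single-class
    are redrawn and counted. The p-value is the proportion of bootstrap
    validation AUCs <= 0.5, floored at 1/(n_boot+1).
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable optimism correction")
    Xm, yb, _ = _as_xy(X, y)
    groups = np.asarray(groups)
    if len(groups) != len(yb):
        raise ValueError("groups must align with samples")
    if model_factory is None:
        hp = hyperparameters or {}
        l1, C = hp.get("l1_ratio", 0.5), hp.get("C", 1.0)
        model_factory = lambda: make_enet(l1, C)  # noqa: E731
    else:
        hp = hyperparameters or {}

    uniq = np.unique(groups)
    sample_idx = {g: np.flatnonzero(groups == g) for g in uniq}
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    feat_counts = None
    n_redrawn = 0
    columns = X.columns if isinstance(X, pd.DataFrame) else None

    for i in range(n_boot):
        while True:
            drawn = rng.choice(uniq, size=len(uniq), replace=True)
            oob = np.setdiff1d(uniq, drawn)
            if oob.size == 0:
                n_redrawn += 1
                continue
            va = np.concatenate([sample_idx[g] for g in oob])
            tr = np.concatenate([sample_idx[g] for g in drawn])
            if np.unique(yb[va]).size < 2 or np.unique(yb[tr]).size < 2:
                n_redrawn += 1
                continue
            break
        model = model_factory()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xm[tr], yb[tr])
            scores = model.predict_proba(Xm[va])[:, 1]
        aucs[i] = auc_score(scores, yb[va])
        clf = model.named_steps.get("clf") if isinstance(model, Pipeline) else model
        coefs = getattr(clf, "coef_", None)
        if coefs is not None:
            nz = (np.abs(coefs[0]) > 1e-12).astype(int)
            feat_counts = nz if feat_counts is None else feat_counts + nz

    mean_auc = float(aucs.mean())
    ci_low, ci_high = np.percentile(aucs, [2.5, 97.5])
    p = max(float((aucs <= 0.5).mean()), 1.0 / (n_boot + 1))
    freq = None
    if feat_counts is not None:
        idx = columns if columns is not None else pd.RangeIndex(len(feat_counts))
        freq = pd.Series(feat_counts / n_boot, index=idx, name="selection_frequency")
    return ClassifierReport(
        mean_auc=mean_auc,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        n_boot=n_boot,
        model=model_name,
        boot_aucs=aucs,
        feature_frequency=freq,
        n_redrawn=n_redrawn,
        hyperparameters=hp,
    )


DEFAULT_SUPPLEMENTARY_GRIDS = {
    "random_forest": [
        {"n_estimators": 300, "max_features": "sqrt"},
        {"n_estimators": 300, "max_features": 0.3},
    ],
    "gradient_boosting": [
        {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 2},
        {"n_estimators": 200, "learning_rate": 0.05, "max_depth": 3},
    ],
    "knn": [{"n_neighbors": k} for k in (5, 11, 21)],
}


def _supplementary_factory(name: str, params: dict):
    if name == "random_forest":
        est = RandomForestClassifier(random_state=0, **params)
    elif name == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=0, **params)
    elif name == "knn":
        est = KNeighborsClassifier(**params)
    else:
        raise ValueError(f"unknown model {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def supplementary_models(
    X,
    y,
    groups,
    n_boot: int = 500,
    seed: int = 0,
    grids: dict | None = None,
    n_splits: int = 5,
) -> dict:
    """Run the same grouped-bootstrap harness with random forest,
    gradient boosting and K-nearest-neighbour learners, each tuned by the
    same grouped five-fold CV."""
    Xm, yb, _ = _as_xy(X, y)
    grids = grids or DEFAULT_SUPPLEMENTARY_GRIDS
    reports = {}
    for name, grid in grids.items():
        best = None
        for params in grid:
            dev = _cv_deviance(
                _supplementary_factory(name, params), Xm, yb, np.asarray(groups), n_splits, seed
            )
            if best is None or dev < best[1]:
                best = (params, dev)
        params = best[0]
        reports[name] = bootstrap_validate(
            X,
            y,
            groups,
            n_boot=n_boot,
            seed=seed,
            model_factory=lambda name=name, params=params: _supplementary_factory(name, params),
            hyperparameters=params,
            model_name=name,
        )
    return reports
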