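"""Uniform learner contract over native and delegated classifiers.

Every learner exposes ``fit(X, y)`` (y coded 1 = case) and
``predict_risk(X)`` returning the probability of disease, so the
evaluation machinery and the haplotype pipeline can treat the native
stump booster, the naive Bayes models and standard scikit-learn /
statsmodels classifiers interchangeably.  Delegates: a CART decision
tree, a 20-tree random forest capped at depth 6, a sigmoid-kernel SVM
with probability calibration, L1/L2-penalized logistic regression and
forward stepwise logistic regression by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import GenotypeMatrix, Phenotype
from . import boosting, scores


class Learner(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Learner": ...
    def predict_risk(self, X: np.ndarray) -> np.ndarray: ...


class SklearnLearner:
    """Adapter: scikit-learn probability classifier -> learner contract."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        y = np.asarray(y)
        self._single_class = len(np.unique(y)) < 2
        if self._single_class:
            self._constant = float(y.flat[0]) if y.size else 0.0
            return self
        self.estimator.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_risk(self, X):
        X = np.asarray(X, dtype=float)
        if self._single_class:
            return np.full(X.shape[0], self._constant)
        proba = self.estimator.predict_proba(X)
        case_col = list(self.estimator.classes_).index(1)
        return proba[:, case_col]


class AdaBoostLearner:
    """The native stump booster behind the uniform contract."""

    def __init__(self, n_iterations: int = 2500):
        self.n_iterations = n_iterations
        self.ensemble: boosting.StumpEnsemble | None = None

    def fit(self, X, y):
        self.ensemble = boosting.train_adaboost_m1(
            GenotypeMatrix(np.asarray(X, dtype=np.int8)),
            Phenotype(np.asarray(y)),
            self.n_iterations,
        )
        return self

    def predict_risk(self, X):
        p_healthy = boosting.score_ensemble_matrix(
            self.ensemble, GenotypeMatrix(np.asarray(X, dtype=np.int8))
        )
        return 1.0 - p_healthy


class NBCLearner:
    """Genotype naive Bayes behind the uniform contract."""

    def fit(self, X, y):
        self.model = scores.fit_nbc(
            GenotypeMatrix(np.asarray(X, dtype=np.int8)), Phenotype(np.asarray(y))
        )
        return self

    def predict_risk(self, X):
        return self.model.posterior(np.asarray(X, dtype=np.int8))


class ANBCLearner:
    """Allelic naive Bayes behind the uniform contract."""

    def fit(self, X, y):
        self.model = scores.fit_anbc(
            GenotypeMatrix(np.asarray(X, dtype=np.int8)), Phenotype(np.asarray(y))
        )
        return self

    def predict_risk(self, X):
        return self.model.predict_proba(np.asarray(X, dtype=np.int8))


class ScoreLearner:
    """GRS / wGRS with a one-covariate logistic link, trained in-fold."""

    def __init__(self, weighted: bool):
        self.weighted = weighted

    def _score(self, X):
        if self.weighted:
            return scores.wgrs(X, self.weights)
        return scores.grs(X)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.int8)
        pheno = Phenotype(np.asarray(y))
        if self.weighted:
            self.weights = scores.fit_score_weights(GenotypeMatrix(X), pheno)
        self.link = scores.fit_score_logistic(
            self._score(X), pheno, "wgrs" if self.weighted else "grs"
        )
        return self

    def predict_risk(self, X):
        return self.link.predict_proba(self._score(np.asarray(X, dtype=np.int8)))


class StepwiseAICLearner:
    """Forward stepwise logistic regression selecting features by AIC."""

    def __init__(self, max_features: int = 20):
        self.max_features = max_features

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, m = X.shape
        selected: list[int] = []
        rest = list(range(m))

        def fit_aic(cols):
            design = sm.add_constant(X[:, cols], has_constant="add")
            try:
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
                return res.aic, res
            except Exception:
                return np.inf, None

        best_aic, best_res = fit_aic([])
        while rest and len(selected) < self.max_features:
            trials = [(fit_aic(selected + [j])[0], j) for j in rest]
            aic, j = min(trials)
            if aic >= best_aic - 1e-9:
                break
            selected.append(j)
            rest.remove(j)
            best_aic, best_res = fit_aic(selected)
        self.selected = selected
        self.result = best_res
        self._y_mean = float(y.mean())
        return self

    def predict_risk(self, X):
        X = np.asarray(X, dtype=float)
        if self.result is None:
            return np.full(X.shape[0], self._y_mean)
        design = sm.add_constant(X[:, self.selected], has_constant="add")
        return np.asarray(self.result.predict(design))


_REGISTRY: dict[str, Callable[..., Learner]] = {
    "adaboost": lambda seed=0, n_iterations=2500, **kw: AdaBoostLearner(n_iterations),
    "nbc": lambda seed=0, **kw: NBCLearner(),
    "anbc": lambda seed=0, **kw: ANBCLearner(),
    "grs": lambda seed=0, **kw: ScoreLearner(weighted=False),
    "wgrs": lambda seed=0, **kw: ScoreLearner(weighted=True),
    "tree": lambda seed=0, **kw: SklearnLearner(
        DecisionTreeClassifier(random_state=seed, **kw)
    ),
    "forest20": lambda seed=0, **kw: SklearnLearner(
        RandomForestClassifier(
            n_estimators=20, max_depth=6, random_state=seed, **kw
        )
    ),
    "sigmoid_margin": lambda seed=0, **kw: SklearnLearner(
        SVC(kernel="sigmoid", probability=True, random_state=seed, **kw)
    ),
    "lasso": lambda seed=0, **kw: SklearnLearner(
        LogisticRegression(solver="liblinear", l1_ratio=1.0, random_state=seed, **kw)
    ),
    "ridge": lambda seed=0, **kw: SklearnLearner(
        LogisticRegression(solver="lbfgs", max_iter=1000, **kw)
    ),
    "stepwise_aic": lambda seed=0, max_features=20, **kw: StepwiseAICLearner(max_features),
}


def delegated_learner(name: str, seed: int = 0, **hyperparameters) -> Learner:
    """Instantiate a learner by registry name.

    Names: adaboost, nbc, anbc, grs, wgrs, tree, forest20, sigmoid_margin,
    lasso, ridge, stepwise_aic.
    """
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown learner {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return factory(seed=seed, **hyperparameters)


def available_learners() -> list[str]:
    return sorted(_REGISTRY)
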