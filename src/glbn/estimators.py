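"""scikit-learn style estimators wrapping the group lasso and the BN engine.

These follow the sklearn contract (``get_params``/``set_params`` via
``BaseEstimator``, fitted attributes with a trailing underscore, input
validation in ``fit``) so they compose with pipelines and model selection.
The functional surfaces in :mod:`glbn.grouplasso` and :mod:`glbn.bayesnet`
are the implementation; these classes are the user-facing API.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from . import bayesnet as bn
from . import grouplasso as gl
from .schema import CohortTable, SchemaError, VariableSpec


def _validate_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    return X, y


def _grouped_design(X, y, groups, standardize) -> tuple[gl.GroupedDesign, np.ndarray]:
    """Build a GroupedDesign, reordering columns so groups are contiguous.

    Returns the design and the column permutation applied (original -> design).
    """
    p = X.shape[1]
    if groups is None:
        labels = np.arange(p)
    else:
        labels = np.asarray(groups)
        if labels.size != p:
            raise ValueError("groups must give one label per column")
    uniq = list(dict.fromkeys(labels.tolist()))
    perm = np.concatenate([np.flatnonzero(labels == g) for g in uniq]).astype(int)
    gidx = np.concatenate(
        [np.full(np.sum(labels == g), j) for j, g in enumerate(uniq)]
    )
    Xp = X[:, perm]
    centers = scales = None
    if standardize:
        centers = Xp.mean(axis=0)
        scales = Xp.std(axis=0)
        if np.any(scales == 0):
            raise SchemaError("constant column in design")
        Xp = (Xp - centers) / scales
    design = gl.GroupedDesign(
        Xp,
        y,
        gidx,
        group_names=[str(g) for g in uniq],
        col_names=[f"x{j}" for j in perm],
        centers=centers,
        scales=scales,
    )
    return design, perm


class GroupLasso(BaseEstimator):
    """Group-lasso linear or logistic model at a fixed penalty.

    Parameters
    ----------
    lam : float
        Penalty strength (the objective carries an ``n * lam`` factor, so
        lam is on a per-observation scale).
    loss : {"logistic", "squared"}
    groups : array-like of shape (n_features,), optional
        Group label per column; ``None`` puts every column in its own group
        (plain lasso).
    weights : {"sqrt", "none"}
        Per-group penalty weights w_j (sqrt of group size by default).
    """

    def __init__(
        self,
        lam: float = 0.01,
        loss: str = "logistic",
        groups=None,
        weights: str = "sqrt",
        standardize: bool = True,
        tol: float = 1e-7,
        max_sweeps: int = 50_000,
    ):
        self.lam = lam
        self.loss = loss
        self.groups = groups
        self.weights = weights
        self.standardize = standardize
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y):
        X, y = _validate_Xy(X, y)
        design, perm = _grouped_design(X, y, self.groups, self.standardize)
        fit = gl.fit_group_lasso(
            design,
            self.lam,
            loss=self.loss,
            weights=self.weights,
            tol=self.tol,
            max_sweeps=self.max_sweeps,
        )
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        self.coef_ = fit.coef[inv]
        self.intercept_ = fit.intercept
        self.n_iter_ = fit.n_sweeps
        self.fit_ = fit
        self.design_ = design
        self.permutation_ = perm
        self.selected_groups_ = fit.selected_groups
        if self.loss == "logistic":
            self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        if self.loss != "logistic":
            raise AttributeError("predict_proba requires the logistic loss")
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        eta = self.decision_function(X)
        if self.loss == "logistic":
            return (eta > 0).astype(float)
        return eta


class GroupLassoCV(BaseEstimator):
    """Group lasso along a penalty path with stratified k-fold CV selection.

    The grid runs from the smallest all-zero penalty down over ``n_lambdas``
    log-spaced values; the penalty minimising the mean CV error (deviance for
    the logistic loss) is refit on the full data.  ``rule="1se"`` selects the
    sparsest model within one standard error instead.
    """

    def __init__(
        self,
        loss: str = "logistic",
        groups=None,
        weights: str = "sqrt",
        cv: int = 10,
        n_lambdas: int = 100,
        lambdas=None,
        rule: str = "min",
        standardize: bool = True,
        tol: float = 1e-7,
        max_sweeps: int = 50_000,
        seed: int = 0,
    ):
        self.loss = loss
        self.groups = groups
        self.weights = weights
        self.cv = cv
        self.n_lambdas = n_lambdas
        self.lambdas = lambdas
        self.rule = rule
        self.standardize = standardize
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.seed = seed

    def fit(self, X, y):
        X, y = _validate_Xy(X, y)
        design, perm = _grouped_design(X, y, self.groups, self.standardize)
        path = gl.cv_select_lambda(
            design,
            lambdas=self.lambdas,
            k=self.cv,
            seed=self.seed,
            loss=self.loss,
            weights=self.weights,
            tol=self.tol,
            max_sweeps=self.max_sweeps,
            n_lambdas=self.n_lambdas,
            rule=self.rule,
        )
        fit = path.fit_at()
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        self.path_ = path
        self.lambda_ = path.selected_lambda
        self.lambdas_ = path.lambdas
        self.cv_errors_ = path.cv_mean
        self.cv_se_ = path.cv_se
        self.coef_ = fit.coef[inv]
        self.intercept_ = fit.intercept
        self.selected_groups_ = fit.selected_groups
        self.fit_ = fit
        self.permutation_ = perm
        if self.loss == "logistic":
            self.classes_ = np.array([0.0, 1.0])
        return self

    decision_function = GroupLasso.decision_function
    predict_proba = GroupLasso.predict_proba
    predict = GroupLasso.predict


class BayesNetClassifier(BaseEstimator, ClassifierMixin):
    """Discrete BN risk model behaving as a probabilistic classifier.

    ``fit`` learns the structure over the covariates plus the outcome with
    Tabu search (BIC score, whitelist/blacklist constraints) and the CPTs by
    maximum likelihood; ``predict_proba`` returns the exact posterior of the
    outcome given each row's covariates.
    """

    def __init__(
        self,
        target: str = "relapse",
        whitelist=None,
        blacklist=None,
        tabu_length: int = 10,
        max_iter: int = 1000,
        max_parents: int | None = None,
        pseudo_count: float = 0.0,
        seed: int = 0,
    ):
        self.target = target
        self.whitelist = whitelist
        self.blacklist = blacklist
        self.tabu_length = tabu_length
        self.max_iter = max_iter
        self.max_parents = max_parents
        self.pseudo_count = pseudo_count
        self.seed = seed

    def _as_table(self, X: pd.DataFrame, y=None) -> CohortTable:
        if isinstance(X, CohortTable):
            return X
        df = pd.DataFrame(X).copy()
        if y is not None:
            df[self.target] = np.asarray(y, dtype=object)
        specs = []
        for gid, c in enumerate(df.columns):
            levels = tuple(sorted(df[c].dropna().astype(str).unique()))
            role = "outcome" if c == self.target else "demographic"
            if role == "outcome":
                levels = ("yes", "no")
            specs.append(VariableSpec(c, levels, group_id=gid, role=role))
        return CohortTable(df, specs)

    def fit(self, X, y=None):
        table = self._as_table(X, y)
        if self.target not in table.df.columns:
            raise SchemaError(f"target column {self.target!r} absent")
        self.dag_ = bn.tabu_learn(
            table,
            whitelist=set(map(tuple, self.whitelist or [])),
            blacklist=set(map(tuple, self.blacklist or [])),
            tabu_length=self.tabu_length,
            max_iter=self.max_iter,
            seed=self.seed,
            max_parents=self.max_parents,
        )
        self.net_ = bn.fit_mle(self.dag_, table, pseudo_count=self.pseudo_count)
        self.classes_ = np.array(["no", "yes"], dtype=object)
        self._table_specs = table.specs
        return self

    def predict_proba(self, X):
        table = X if isinstance(X, CohortTable) else self._pred_table(X)
        p = bn.classifier_scores(self.net_, table, self.target)
        return np.column_stack([1 - p, p])

    def _pred_table(self, X) -> CohortTable:
        df = pd.DataFrame(X).copy()
        if self.target not in df.columns:
            df[self.target] = "no"  # placeholder; never used as evidence
        return CohortTable(df, self._table_specs)

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(p > 0.5, "yes", "no")
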