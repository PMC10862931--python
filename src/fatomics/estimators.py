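"""Scikit-learn-style estimators for feature reduction and penalized Cox fitting.

:class:`MRMRSelector` implements greedy maximum-relevance minimum-redundancy
selection in the FCQ (F-test / correlation, quotient) scheme against a
binary supervision target. :class:`CoxElasticNet` wraps the glmnet-style
Cox elastic-net path of scikit-survival with internal standardization and
a cross-validated choice of the penalty weight, scoring held-out folds by
Breslow partial log-likelihood. Both follow the sklearn estimator contract
(``fit`` / ``transform`` or ``predict``, ``get_params``/``set_params``,
fitted attributes with a trailing underscore) and compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = ["MRMRSelector", "CoxElasticNet", "breslow_partial_loglik", "as_sksurv_y"]


def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor.

    ll = sum over events i of [lp_i - log(sum_{j: t_j >= t_i} exp(lp_j))];
    tied event times each contribute the full risk-set denominator.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(-time)  # descending: risk set accumulates as we walk
    lp_o, t_o, e_o = lp[order], time[order], event[order]
    # stabilized cumulative log-sum-exp over the growing risk set
    m = lp.max() if lp.size else 0.0
    cum = np.logaddexp.accumulate(lp_o - m) + m
    # risk set of subject i (in descending-time order) = prefix up to the last
    # index sharing t_i; map each position to that extent
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        denom = cum[j]  # log sum over all subjects with t >= t_i
        for idx in range(i, j + 1):
            if e_o[idx]:
                ll += lp_o[idx] - denom
        i = j + 1
    return float(ll)


def as_sksurv_y(time: np.ndarray, event: np.ndarray):
    return Surv.from_arrays(event=np.asarray(event).astype(bool), time=np.asarray(time, dtype=float))


class MRMRSelector(TransformerMixin, BaseEstimator):
    """Greedy mRMR feature selection (FCQ scheme) against a binary target.

    Relevance of a feature is its one-way ANOVA F statistic against the
    class labels; redundancy is the mean absolute Pearson correlation with
    the already-selected set. At each step the feature maximizing
    relevance / redundancy is added (the first pick maximizes relevance
    alone). Constant features are excluded with a warning before selection.

    Parameters
    ----------
    k : int
        Number of features to select.
    """

    def __init__(self, k: int = 50):
        self.k = k

    def fit(self, X, y):
        X = pd.DataFrame(X).copy()
        y = np.asarray(y)
        if np.isnan(X.to_numpy(dtype=float)).any():
            raise ValueError("feature matrix contains NaN")
        stds = X.std(axis=0, ddof=0)
        constant = stds.index[stds == 0].tolist()
        if constant:
            warnings.warn(f"excluding {len(constant)} constant features: {constant[:5]}...",
                          stacklevel=2)
            X = X.drop(columns=constant)
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds the {X.shape[1]} usable features")

        cols = list(X.columns)
        F, _ = f_classif(X.to_numpy(dtype=float), y)
        F = np.nan_to_num(F, nan=0.0)
        if self.k == len(cols):
            # identity selection, but keep mRMR ordering for the first pick
            order = list(np.argsort(-F))
            self.selected_features_ = [cols[i] for i in order]
            self.relevance_ = pd.Series(F, index=cols)
            self.feature_names_in_ = np.array(cols)
            return self

        corr = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
        np.fill_diagonal(corr, 0.0)

        selected: list[int] = [int(np.argmax(F))]
        remaining = set(range(len(cols))) - set(selected)
        while len(selected) < self.k:
            rem = np.fromiter(remaining, dtype=int)
            redundancy = corr[np.ix_(rem, selected)].mean(axis=1)
            score = F[rem] / np.maximum(redundancy, 1e-12)
            pick = int(rem[np.argmax(score)])
            selected.append(pick)
            remaining.remove(pick)
        self.selected_features_ = [cols[i] for i in selected]
        self.relevance_ = pd.Series(F, index=cols)
        self.feature_names_in_ = np.array(cols)
        return self

    def get_support(self) -> np.ndarray:
        sel = set(self.selected_features_)
        return np.array([c in sel for c in self.feature_names_in_])

    def transform(self, X):
        return pd.DataFrame(X)[self.selected_features_]


class CoxElasticNet(BaseEstimator):
    """Cox proportional-hazards model with elastic-net penalty and CV-chosen λ.

    Features are standardized to zero mean / unit variance inside ``fit``;
    the penalty path is computed once on the full data and the penalty
    weight is chosen by K-fold cross-validation (folds stratified by event
    status), scoring each held-out fold by its Breslow partial
    log-likelihood under the train-fold model. Alternatively a target
    support size can be requested, picking the path point whose number of
    nonzero coefficients is closest to the target (ties favor the sparser,
    more-penalized model).

    Parameters
    ----------
    l1_ratio : float
        Elastic-net mixing (1 = lasso); 0.8 by default.
    n_folds : int
        Cross-validation folds (10 by default).
    target_support : int or None
        If given, select the penalty by support size instead of CV score.
    n_alphas : int
        Path resolution.
    random_state : int
        Seeds the fold assignment.
    """

    def __init__(
        self,
        l1_ratio: float = 0.8,
        n_folds: int = 10,
        target_support: int | None = None,
        n_alphas: int = 60,
        alpha_min_ratio: float = 0.01,
        random_state: int = 0,
        max_iter: int = 100000,
    ):
        self.l1_ratio = l1_ratio
        self.n_folds = n_folds
        self.target_support = target_support
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.random_state = random_state
        self.max_iter = max_iter

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _split_y(y):
        """Accept a (time, event) DataFrame, dict, or sksurv structured array."""
        if isinstance(y, pd.DataFrame):
            return y["time"].to_numpy(dtype=float), y["event"].to_numpy(dtype=int)
        arr = np.asarray(y)
        if arr.dtype.names:
            names = arr.dtype.names
            ev = arr[names[0]].astype(int)
            tm = arr[names[1]].astype(float)
            return tm, ev
        raise TypeError("y must be a DataFrame with time/event columns or a sksurv array")

    def fit(self, X, y):
        X = pd.DataFrame(X)
        time, event = self._split_y(y)
        if event.sum() < 2:
            raise ValueError("need at least 2 events to fit a Cox model")
        self.feature_names_in_ = np.array(list(X.columns))
        Xv = X.to_numpy(dtype=float)
        self.mean_ = Xv.mean(axis=0)
        scale = Xv.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        Z = (Xv - self.mean_) / self.scale_
        y_struct = as_sksurv_y(time, event)

        path = CoxnetSurvivalAnalysis(
            l1_ratio=self.l1_ratio,
            n_alphas=self.n_alphas,
            alpha_min_ratio=self.alpha_min_ratio,
            max_iter=self.max_iter,
            fit_baseline_model=False,
        )
        path.fit(Z, y_struct)
        alphas = np.asarray(path.alphas_)

        if self.target_support is not None:
            support_sizes = np.count_nonzero(path.coef_, axis=0)
            gap = np.abs(support_sizes - self.target_support)
            # ties -> larger alpha (earlier on the decreasing path) = sparser
            best = int(np.argmin(gap))
            self.alpha_ = float(alphas[best])
            self.cv_scores_ = None
        else:
            skf = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.random_state
            )
            scores = np.zeros((self.n_folds, len(alphas)))
            self.fold_assignments_ = np.zeros(len(Z), dtype=int)
            for f, (tr, te) in enumerate(skf.split(Z, event)):
                self.fold_assignments_[te] = f
                m = CoxnetSurvivalAnalysis(
                    l1_ratio=self.l1_ratio,
                    alphas=alphas,
                    max_iter=self.max_iter,
                    fit_baseline_model=False,
                )
                m.fit(Z[tr], y_struct[tr])
                fitted = np.asarray(m.alphas_)
                coefs = m.coef_  # (p, n_fitted)
                lp_all = Z[te] @ coefs
                fold_scores = np.array([
                    breslow_partial_loglik(lp_all[:, j], time[te], event[te])
                    for j in range(coefs.shape[1])
                ])
                # the fold path may terminate early; align on alpha values
                scores[f] = np.interp(alphas[::-1], fitted[::-1], fold_scores[::-1])[::-1]
            self.cv_scores_ = scores.mean(axis=0)
            self.alpha_ = float(alphas[int(np.argmax(self.cv_scores_))])

        final = CoxnetSurvivalAnalysis(
            l1_ratio=self.l1_ratio,
            alphas=[self.alpha_],
            max_iter=self.max_iter,
            fit_baseline_model=False,
        )
        final.fit(Z, y_struct)
        coef = final.coef_[:, 0]
        self.alphas_ = alphas
        self.coef_ = pd.Series(coef, index=self.feature_names_in_)
        nz = np.flatnonzero(coef)
        self.selected_features_ = [self.feature_names_in_[i] for i in nz]
        self.n_features_in_ = Z.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Linear predictor (log relative hazard); higher = higher risk."""
        X = pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.coef_.to_numpy()
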