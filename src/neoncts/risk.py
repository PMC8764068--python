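"""Mortality risk models: screening, constrained logistic fits, evaluation.

The outcome is death within the next 7 days, evaluated per patient-day
sample. Candidate features (the cluster representatives, optionally plus
demographic covariates) enter a logistic regression; backward elimination
drops the largest Wald p-value until at most ``max_features`` remain.
Discrimination is the rank-based AUC under patient-grouped tenfold
cross-validation, broken down by days-until-death horizon, and a
flag-count threshold at the event rate yields sensitivity = PPV and lift.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .features import Winsorizer

log = logging.getLogger(__name__)

DEMOGRAPHIC_FEATURES = ["birth_weight_kg", "ga_weeks", "sex_male", "apgar5"]


def univariate_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC, ties counting one half.

    Orientation is as-is — no flipping; screening strength is
    |AUC - 0.5|.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, np.asarray(values, dtype=float)))


def univariate_auc_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank-based AUC of every column of X at once (ties count 1/2)."""
    from scipy.stats import rankdata
    y = np.asarray(y, dtype=int)
    r = rankdata(np.asarray(X, dtype=float), axis=0, method="average")
    pos = y == 1
    n1 = int(pos.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    return (r[pos].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)


@dataclass
class RiskModel:
    """A fitted constrained logistic model with its selection trace."""

    feature_ids: list[str]
    coefficients: dict[str, float]
    intercept: float
    selection_trace: list[tuple[str, float]]
    training_meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "feature_ids": self.feature_ids,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "selection_trace": self.selection_trace,
            "training_meta": self.training_meta,
        }, indent=1)


@dataclass
class EvaluationReport:
    """Model evaluation summary: CV AUC, horizon AUCs, threshold metrics."""

    cv_auc: float
    horizon_aucs: dict[int, float]
    threshold_metrics: dict[str, float]
    event_rate: float

    def to_dict(self) -> dict:
        return {
            "cv_auc": self.cv_auc,
            "horizon_aucs": {str(k): v for k, v in self.horizon_aucs.items()},
            "threshold_metrics": self.threshold_metrics,
            "event_rate": self.event_rate,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _irls(X: np.ndarray, y: np.ndarray, ridge: float,
          maxiter: int = 60) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS logistic fit; returns (beta, penalized Hessian, converged).

    The intercept (first column) is never penalized.
    """
    p = X.shape[1]
    pen = np.full(p, 2.0 * ridge)
    pen[0] = 0.0
    beta = np.zeros(p)
    hess = np.eye(p)
    converged = False
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X.T * w) @ X + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        # dampen overshooting Newton steps
        norm_step = np.max(np.abs(step))
        if norm_step > 10.0:
            step *= 10.0 / norm_step
        beta = beta + step
        if norm_step < 1e-9:
            converged = True
            break
    return beta, hess, converged


def _fit_logit(X: np.ndarray, y: np.ndarray,
               ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit returning (params, Wald p-values).

    Plain Newton/IRLS first; on a singular system, non-convergence or
    exploding coefficients (quasi-separation) the fit is retried with a
    small ridge penalty (1e-6, logged), with the Wald covariance taken
    from the penalized Hessian. A failed retry raises.
    """
    from scipy.stats import norm

    try:
        maxiter = 60 if ridge == 0 else 500
        beta, hess, converged = _irls(X, y, ridge, maxiter=maxiter)
        if ridge == 0:
            ok = (converged and np.isfinite(beta).all()
                  and np.max(np.abs(beta)) < 1e3)
        else:
            # under separation the weakly penalized optimum is enormous;
            # a finite fit is enough to rank Wald statistics for the drops
            ok = np.isfinite(beta).all()
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        if ridge > 0:
            raise RuntimeError(
                f"logistic fit failed for {X.shape[1] - 1} features even "
                "with ridge fallback")
        log.debug("logistic fit unstable (separation or collinearity); "
                  "retrying with ridge 1e-6")
        return _fit_logit(X, y, ridge=1e-6)
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    pvals = 2 * norm.sf(np.abs(beta / se))
    return beta, pvals


class BackwardLogisticRisk(ClassifierMixin, BaseEstimator):
    """Logistic regression with backward elimination to ``max_features``.

    Starting from the full model, the feature with the largest Wald p-value
    is removed and the model refit, until at most ``max_features`` features
    remain (non-finite p-values, e.g. from collinear columns, are treated
    as largest and dropped first). Candidate features are winsorized and
    standardized with parameters learned on the training data.

    Fitted attributes: ``feature_ids_``, ``model_`` (a :class:`RiskModel`
    with the drop trace), ``coef_``, ``intercept_``.
    """

    def __init__(self, max_features: int = 5,
                 winsor_lo: float = 0.001, winsor_hi: float = 0.999,
                 selector: str = "backward_p",
                 always_keep: tuple[str, ...] = ()):
        self.max_features = max_features
        self.winsor_lo = winsor_lo
        self.winsor_hi = winsor_hi
        self.selector = selector
        self.always_keep = always_keep

    # -- helpers --------------------------------------------------------
    def _prepare(self, X: pd.DataFrame, fit: bool) -> np.ndarray:
        vals = X.to_numpy(dtype=float)
        if fit:
            self.winsorizer_ = Winsorizer(self.winsor_lo,
                                          self.winsor_hi).fit(vals)
            w = self.winsorizer_.transform(vals)
            self.center_ = w.mean(axis=0)
            scale = w.std(axis=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            w = self.winsorizer_.transform(vals)
        return (w - self.center_) / self.scale_

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y.astype(int))
        self.candidate_ids_ = [str(c) for c in X.columns]
        Z = self._prepare(X, fit=True)

        active = list(range(Z.shape[1]))
        kept = {i for i, c in enumerate(self.candidate_ids_)
                if c in set(self.always_keep)}
        trace: list[tuple[str, float]] = []
        if self.selector == "aic":
            params, pvals = self._aic_selection(Z, y, active, trace)
        elif self.selector == "lasso":
            params, pvals = self._lasso_selection(Z, y, active, trace)
        elif self.selector == "all_subset":
            params, pvals = self._all_subset_selection(Z, y, active, trace)
        elif self.selector == "backward_p":
            while True:
                design = np.column_stack([np.ones(len(y)), Z[:, active]])
                params, pvals = _fit_logit(design, y)
                droppable = [j for j, i in enumerate(active) if i not in kept]
                if len(droppable) <= self.max_features:
                    break
                feat_p = np.where(np.isfinite(pvals[1:]), pvals[1:], np.inf)
                worst = max(droppable, key=lambda j: feat_p[j])
                trace.append((self.candidate_ids_[active[worst]],
                              float(pvals[1 + worst])))
                del active[worst]
        else:
            raise ValueError(f"unknown selector {self.selector!r}")

        self.active_ = active
        self.feature_ids_ = [self.candidate_ids_[i] for i in active]
        self.intercept_ = float(params[0])
        self.coef_ = np.asarray(params[1:], dtype=float)
        self.model_ = RiskModel(
            feature_ids=self.feature_ids_,
            coefficients=dict(zip(self.feature_ids_,
                                  self.coef_.tolist())),
            intercept=self.intercept_,
            selection_trace=trace,
            training_meta={"n": int(len(y)),
                           "winsor": [self.winsor_lo, self.winsor_hi],
                           "selector": self.selector},
        )
        return self

    def _aic_selection(self, Z, y, active, trace):
        """Greedy backward elimination on AIC until no drop improves it."""
        def fit_aic(cols):
            design = np.column_stack([np.ones(len(y)), Z[:, cols]])
            params, pvals = _fit_logit(design, y)
            eta = design @ params
            ll = np.sum(y * eta - np.log1p(np.exp(eta)))
            return params, pvals, 2 * (len(cols) + 1) - 2 * ll
        params, pvals, aic = fit_aic(active)
        improved = True
        while improved and len(active) > 1:
            improved = False
            for j in range(len(active)):
                cand = active[:j] + active[j + 1:]
                p2, pv2, aic2 = fit_aic(cand)
                if aic2 < aic:
                    trace.append((self.candidate_ids_[active[j]],
                                  float(pvals[1 + j])))
                    active[:] = cand
                    params, pvals, aic = p2, pv2, aic2
                    improved = True
                    break
        return params, pvals

    def _lasso_selection(self, Z, y, active, trace):
        """L1 path: shrink C until at most max_features coefficients are
        nonzero, then refit the support without penalty (relaxed lasso)."""
        from sklearn.linear_model import LogisticRegression

        C = 10.0
        support = active[: self.max_features]
        for _ in range(60):
            lr = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                    C=C, max_iter=2000)
            lr.fit(Z[:, active], y)
            nz = np.flatnonzero(np.abs(lr.coef_[0]) > 1e-8)
            if 0 < len(nz) <= self.max_features:
                support = [active[i] for i in nz]
                break
            C *= 0.75
        for i in active:
            if i not in support:
                trace.append((self.candidate_ids_[i], float("nan")))
        active[:] = support
        design = np.column_stack([np.ones(len(y)), Z[:, active]])
        return _fit_logit(design, y)

    def _all_subset_selection(self, Z, y, active, trace):
        """Exhaustive best subset (by AIC) over sizes 1..max_features."""
        from itertools import combinations
        from math import comb

        p = len(active)
        total = sum(comb(p, k)
                    for k in range(1, min(self.max_features, p) + 1))
        if total > 20_000:
            raise ValueError(
                f"all_subset selector is exhaustive ({total} subsets); "
                "use fewer candidates or another selector")

        def fit_aic(cols):
            design = np.column_stack([np.ones(len(y)), Z[:, cols]])
            params, pvals = _fit_logit(design, y)
            eta = np.clip(design @ params, -35, 35)
            ll = np.sum(y * eta - np.log1p(np.exp(eta)))
            return params, pvals, 2 * (len(cols) + 1) - 2 * ll

        best = None
        for k in range(1, min(self.max_features, p) + 1):
            for cols in combinations(active, k):
                params, pvals, aic = fit_aic(list(cols))
                if best is None or aic < best[0] - 1e-12:
                    best = (aic, list(cols), params, pvals)
        _, chosen, params, pvals = best
        for i in active:
            if i not in chosen:
                trace.append((self.candidate_ids_[i], float("nan")))
        active[:] = chosen
        return params, pvals

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self)
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=self.candidate_ids_)
        Z = self._prepare(X[self.candidate_ids_], fit=False)
        return self.intercept_ + Z[:, self.active_] @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def fit_logistic_backward(
    X: pd.DataFrame, y: Sequence[int], max_features: int = 5,
) -> RiskModel:
    """Functional wrapper over :class:`BackwardLogisticRisk`."""
    est = BackwardLogisticRisk(max_features=max_features).fit(X, np.asarray(y))
    return est.model_


# ---------------------------------------------------------------------------
# cross-validation


def _patient_folds(patient_ids: np.ndarray, y: np.ndarray, folds: int,
                   seed: int, max_retries: int = 20) -> np.ndarray:
    """Fold index per row; all rows of a patient share a fold.

    Folds are stratified by patient outcome (patients with any positive
    row vs the rest assigned round-robin separately), which keeps the
    training prevalence stable across folds — otherwise fold-specific
    intercept shifts bias the pooled held-out AUC below 0.5 even on pure
    noise. Refolds with an incremented seed (logged) if some training
    split would still see a single class.
    """
    patients = np.unique(patient_ids)
    pos_patients = np.unique(patient_ids[np.asarray(y) == 1])
    is_pos = np.isin(patients, pos_patients)
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        fold_of = {}
        for group in (patients[is_pos], patients[~is_pos]):
            for i, p in enumerate(rng.permutation(group)):
                fold_of[p] = i % folds
        assign = np.array([fold_of[p] for p in patient_ids])
        ok = all(len(np.unique(y[assign != f])) == 2 for f in range(folds))
        if ok:
            if attempt:
                log.info("refolded %d times to balance classes", attempt)
            return assign
    raise ValueError(f"could not build {folds} folds with both classes "
                     "in every training split")


def _fold_representatives(X: pd.DataFrame, y: np.ndarray,
                          cluster_assignments: dict[str, int]) -> list[str]:
    """Top-|AUC - 0.5| member of each cluster, measured on this data only."""
    cols = [c for c in X.columns if c in cluster_assignments]
    strength = np.abs(univariate_auc_matrix(X[cols].to_numpy(), y) - 0.5)
    best: dict[int, tuple[float, str]] = {}
    for c, s in zip(cols, strength):
        cl = cluster_assignments[c]
        if cl not in best or s > best[cl][0]:
            best[cl] = (s, c)
    return [best[cl][1] for cl in sorted(best)]


def cv_predictions(
    X: pd.DataFrame,
    y: np.ndarray,
    patient_ids: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    cluster_assignments: dict[str, int] | None = None,
    **model_kwargs,
) -> np.ndarray:
    """Held-out risk scores from patient-grouped k-fold cross-validation.

    The whole recipe is re-run inside each training fold — including,
    when ``cluster_assignments`` maps feature columns to (label-free)
    clusters, the AUC-based choice of one representative per cluster.
    Selecting representatives on the full data before CV leaks the labels
    of held-out patients into the feature screen and inflates the null
    AUC well above chance. Columns of ``X`` not named in
    ``cluster_assignments`` (e.g. demographics) always enter the model
    stage. Rows are scored by the model that never saw their patient.
    """
    y = np.asarray(y, dtype=int)
    patient_ids = np.asarray(patient_ids)
    assign = _patient_folds(patient_ids, y, folds, seed)
    preds = np.empty(len(y))
    for f in range(folds):
        train = assign != f
        if not (~train).any():
            continue
        if cluster_assignments is not None:
            reps = _fold_representatives(X[train], y[train],
                                         cluster_assignments)
            extra = [c for c in X.columns if c not in cluster_assignments]
            use = reps + extra
        else:
            use = list(X.columns)
        est = BackwardLogisticRisk(**model_kwargs).fit(
            X.loc[train, use], y[train])
        preds[~train] = est.decision_function(X.loc[~train, use])
    return preds


def cv_auc(
    X: pd.DataFrame,
    y: np.ndarray,
    patient_ids: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    cluster_assignments: dict[str, int] | None = None,
    **model_kwargs,
) -> float:
    """Pooled held-out AUC under patient-grouped k-fold cross-validation."""
    preds = cv_predictions(X, y, patient_ids, folds, seed,
                           cluster_assignments, **model_kwargs)
    return float(roc_auc_score(np.asarray(y, dtype=int), preds))


# ---------------------------------------------------------------------------
# horizon and threshold evaluation


def horizon_auc(
    predictions: np.ndarray,
    labels: np.ndarray,
    days_until_death: np.ndarray,
    horizon_d: int,
) -> float:
    """AUC restricted to the day-band ``(d-1, d]`` before death.

    Positives are samples with days_until_death in (d-1, d]; samples closer
    to death than d-1 days are excluded; everything else is a negative. NaN
    with a log message when the band holds no positives.
    """
    predictions = np.asarray(predictions, dtype=float)
    dud = np.asarray(days_until_death, dtype=float)
    pos = (dud > horizon_d - 1) & (dud <= horizon_d)
    excluded = np.nan_to_num(dud, nan=np.inf) <= horizon_d - 1
    keep = ~excluded
    if not pos.any():
        log.warning("no positive samples at horizon %d days", horizon_d)
        return float("nan")
    return float(roc_auc_score(pos[keep].astype(int), predictions[keep]))


def event_rate_threshold_metrics(
    predictions: np.ndarray,
    labels: np.ndarray,
) -> dict[str, float]:
    """Sensitivity, PPV and lift at a flag-count threshold = event rate.

    The top ceil(event_rate * n) predictions are flagged (stable order on
    ties). Because the flag count then equals the positive count,
    sensitivity equals PPV exactly; lift = PPV / event rate.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    n = len(labels)
    event_rate = labels.mean()
    # guard the ceiling against fp residue: rate * n is mathematically the
    # integer positive count here, but mean() can round a hair above it
    n_flag = int(np.ceil(event_rate * n - 1e-9))
    order = np.argsort(-predictions, kind="stable")
    flagged = order[:n_flag]
    tp = int(labels[flagged].sum())
    sensitivity = tp / labels.sum()
    ppv = tp / n_flag
    if n_flag == labels.sum():
        assert abs(sensitivity - ppv) < 1e-15
    return {
        "threshold": float(predictions[order[n_flag - 1]]),
        "sensitivity": float(sensitivity),
        "ppv": float(ppv),
        "lift": float(ppv / event_rate),
        "event_rate": float(event_rate),
    }
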