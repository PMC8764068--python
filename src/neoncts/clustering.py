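"""Mutual-information feature clustering with PAM k-medoids.

Thousands of operation columns are highly redundant (the same algorithm
re-parameterized, or different algorithms reporting the same property).
Columns are discretized into equiprobable bins, pairwise normalized mutual
information defines a distance, and PAM (partitioning around medoids,
BUILD + SWAP) groups the columns into k clusters, each summarized either by
its medoid or by the member with the best univariate AUC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

log = logging.getLogger(__name__)


def equiprobable_bin(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile binning into labels 0..n_bins-1 with stable tie-breaking.

    Bin counts differ by at most one; ties are broken by original position
    (stable rank order), so the result is deterministic.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} values, got {n}")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    labels[order] = (np.arange(n) * n_bins) // n
    return labels


def mi_distance(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual-information distance 1 - MI / sqrt(H(a) H(b)).

    Symmetric, zero for rank-identical columns, and defined as 1 when
    either margin carries no entropy (no information to share).
    """
    la = np.asarray(labels_a, dtype=np.int64)
    lb = np.asarray(labels_b, dtype=np.int64)
    if la.size != lb.size:
        raise ValueError("label vectors must have equal length")
    ka, kb = la.max() + 1, lb.max() + 1
    joint = np.bincount(la * kb + lb, minlength=ka * kb).reshape(ka, kb)
    return _mi_distance_from_contingency(joint)


def _mi_distance_from_contingency(joint: np.ndarray) -> float:
    n = joint.sum()
    pj = joint / n
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if ha == 0 or hb == 0:
        return 1.0
    nz = pj > 0
    mi = np.sum(pj[nz] * (np.log(pj[nz])
                          - np.log(np.outer(pa, pb)[nz])))
    return float(np.clip(1.0 - mi / np.sqrt(ha * hb), 0.0, 1.0))


def distance_matrix(values: pd.DataFrame, n_bins: int = 10) -> np.ndarray:
    """Symmetric, zero-diagonal MI distance matrix over the columns."""
    if values.isna().any().any():
        raise ValueError("distance_matrix requires a filtered matrix "
                         "without missing values")
    cols = [equiprobable_bin(values[c].to_numpy(), n_bins)
            for c in values.columns]
    p = len(cols)
    d = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            d[i, j] = d[j, i] = mi_distance(cols[i], cols[j])
    return d


# ---------------------------------------------------------------------------
# PAM


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Deterministic greedy BUILD initialization (ties by column order)."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, d[:, best])
    return medoids


def _pam_exact(d: np.ndarray, k: int) -> list[int]:
    """Exhaustive minimum-cost medoid subset (lexicographically first)."""
    from itertools import combinations
    best_cost, best = np.inf, None
    for subset in combinations(range(d.shape[0]), k):
        cost = d[:, subset].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, list(subset)
    return best


def pam_kmedoids(d: np.ndarray, k: int,
                 exact_max_subsets: int = 5000) -> tuple[np.ndarray, np.ndarray]:
    """k-medoids over a precomputed distance matrix.

    Small instances (at most ``exact_max_subsets`` candidate medoid
    subsets) are solved exactly by enumeration; larger ones use PAM — a
    greedy BUILD initialization followed by best-improvement SWAP local
    search, whose total cost (sum of distances to nearest medoid) never
    increases and which terminates in a local optimum. Fully deterministic
    for a given distance matrix: ties break by column order.

    Returns ``(medoid_indices, assignments)``.
    """
    from math import comb

    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must be in 1..{n}")
    if comb(n, k) <= exact_max_subsets:
        medoids = _pam_exact(d, k)
        medoids_arr = np.array(sorted(medoids))
        assignments = np.argmin(d[:, medoids_arr], axis=1)
        assignments[medoids_arr] = np.arange(len(medoids_arr))
        return medoids_arr, assignments
    medoids = _pam_build(d, k)
    if k == n:
        medoids = list(range(n))
    while True:
        dm = d[:, medoids]                            # (n, k)
        part = np.argpartition(dm, 1, axis=1) if k > 1 else None
        if k > 1:
            idx1 = part[:, 0]
            idx2 = part[:, 1]
            d1 = dm[np.arange(n), idx1]
            d2 = dm[np.arange(n), idx2]
            swap = d1 > d2
            idx1[swap], d1[swap], d2[swap] = idx2[swap], d2[swap], d1[swap]
        else:
            d1 = dm[:, 0]
            d2 = np.full(n, np.inf)
        base_cost = d1.sum()
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            # distance to nearest medoid excluding medoid mi
            dmin_wo = np.where(idx1 == mi, d2, d1) if k > 1 else \
                np.full(n, np.inf)
            for h in range(n):
                if h in medoids:
                    continue
                newd = np.minimum(dmin_wo, d[:, h])
                delta = base_cost - newd.sum()
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids_arr = np.array(sorted(medoids))
    assignments = np.argmin(d[:, medoids_arr], axis=1)
    # medoids always assign to themselves even under distance ties
    assignments[medoids_arr] = np.arange(len(medoids_arr))
    return medoids_arr, assignments


@dataclass
class ClusterSolution:
    """A k-medoids clustering of operation columns."""

    k: int
    column_ids: list[str]
    assignments: dict[str, int]
    medoid_ids: list[str]
    representative_ids: list[str] = field(default_factory=list)
    distance_summary: list[float] = field(default_factory=list)
    variance_explained: float | None = None

    def members(self, cluster: int) -> list[str]:
        return [c for c, a in self.assignments.items() if a == cluster]

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "assignments": self.assignments,
            "medoid_ids": self.medoid_ids,
            "representative_ids": self.representative_ids,
            "distance_summary": self.distance_summary,
            "variance_explained": self.variance_explained,
        }, indent=1)

    @classmethod
    def from_json(cls, doc: str) -> "ClusterSolution":
        rec = json.loads(doc)
        return cls(k=rec["k"], column_ids=list(rec["assignments"]),
                   assignments=rec["assignments"],
                   medoid_ids=rec["medoid_ids"],
                   representative_ids=rec.get("representative_ids", []),
                   distance_summary=rec.get("distance_summary", []),
                   variance_explained=rec.get("variance_explained"))


class MutualInfoKMedoids(ClusterMixin, BaseEstimator):
    """Cluster feature columns by normalized-MI distance with PAM.

    Parameters
    ----------
    n_clusters : number of medoids (a fixed study parameter, default 20).
    n_bins : equiprobable bins for the MI estimate (default 10).

    Fitted attributes: ``distance_matrix_``, ``medoid_indices_``,
    ``labels_`` (cluster index per column), ``medoid_ids_`` and
    ``solution_`` when fitted on a DataFrame.
    """

    def __init__(self, n_clusters: int = 20, n_bins: int = 10):
        self.n_clusters = n_clusters
        self.n_bins = n_bins

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            column_ids = [str(c) for c in X.columns]
            frame = X
        else:
            X = np.asarray(X, dtype=float)
            column_ids = [f"col{i}" for i in range(X.shape[1])]
            frame = pd.DataFrame(X, columns=column_ids)
        if self.n_clusters > len(column_ids):
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds number of columns "
                f"{len(column_ids)}")
        self.distance_matrix_ = distance_matrix(frame, self.n_bins)
        self.medoid_indices_, self.labels_ = pam_kmedoids(
            self.distance_matrix_, self.n_clusters)
        self.medoid_ids_ = [column_ids[i] for i in self.medoid_indices_]
        within = [
            float(self.distance_matrix_[
                np.ix_(self.labels_ == c, [self.medoid_indices_[c]])].mean())
            for c in range(self.n_clusters)
        ]
        self.solution_ = ClusterSolution(
            k=self.n_clusters,
            column_ids=column_ids,
            assignments={column_ids[i]: int(self.labels_[i])
                         for i in range(len(column_ids))},
            medoid_ids=self.medoid_ids_,
            distance_summary=within,
        )
        return self


def select_representatives(
    solution: ClusterSolution,
    univariate_auc: Mapping[str, float],
    mode: Literal["top_auc", "medoid"] = "top_auc",
) -> list[str]:
    """One representative operation per cluster.

    ``top_auc`` picks the member with largest |AUC - 0.5| (ties resolved in
    favour of the medoid, then column order); ``medoid`` returns the
    medoids themselves.
    """
    if mode == "medoid":
        return list(solution.medoid_ids)
    reps = []
    for c in range(solution.k):
        members = solution.members(c)
        strength = {m: abs(univariate_auc[m] - 0.5) for m in members}
        best = max(strength.values())
        medoid = solution.medoid_ids[c]
        if strength[medoid] >= best - 1e-15:
            reps.append(medoid)
        else:
            reps.append(next(m for m in members
                             if strength[m] >= best - 1e-15))
    return reps


def variance_explained(
    values: pd.DataFrame,
    representative_ids: Sequence[str],
) -> float:
    """Fraction of column variance captured by the representatives.

    Mean over all columns of the max over representatives of the squared
    Pearson correlation; equals 1 when the representatives span every
    column. Zero-variance columns are excluded with a log message.
    """
    cols = [c for c in values.columns if values[c].std() > 0]
    if len(cols) < len(values.columns):
        log.warning("variance_explained: excluding %d zero-variance columns",
                    len(values.columns) - len(cols))
    corr = np.corrcoef(values[cols].to_numpy(), rowvar=False)
    rep_idx = [cols.index(r) for r in representative_ids if r in cols]
    best_r2 = (corr[:, rep_idx] ** 2).max(axis=1)
    return float(best_r2.mean())
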