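"""Feature engine: apply the catalog to windows, sample, filter, normalize.

Turns labeled 10-minute windows into a (patient-day x operation) feature
matrix, reduces it to one record per patient-day (random window or daily
mean), removes non-viable operations and samples, and rescales columns with
an outlier-robust sigmoid. Column ids are signal-qualified
(``HR:...`` / ``SPO2:...``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .catalog import OperationSpec, evaluate_algorithm
from .operators import NAN, sample_entropy_many
from .vitals_io import WindowSample

log = logging.getLogger(__name__)

SIGNALS = ("HR", "SPO2")
ROW_KEY = ["patient_id", "day_index", "window_start_s"]


@dataclass
class FeatureMatrix:
    """Patient-day-window feature values with outcome labels.

    ``values`` is indexed by (patient_id, day_index, window_start_s) with
    one signal-qualified column per operation; ``labels`` holds the 7-day
    mortality indicator per row; ``days_until_death`` is NaN for survivors.
    """

    values: pd.DataFrame
    labels: pd.Series
    days_until_death: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("column ids must be unique")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.labels.copy(),
                             self.days_until_death.copy())


def _evaluate_window(x: np.ndarray,
                     groups: list[tuple[str, tuple, list[str]]],
                     sampen_pairs: list[tuple[int, float]]) -> dict[str, float]:
    """All catalog outputs for one window, sharing work within algorithms.

    The sample-entropy grid shares one incremental template-matching pass.
    """
    out: dict[str, float] = {}
    if sampen_pairs:
        try:
            ent = sample_entropy_many(x, sampen_pairs)
        except Exception:                                  # noqa: BLE001
            log.exception("sample_entropy failed; recording missing")
            ent = {p: NAN for p in sampen_pairs}
        for (m, r), v in ent.items():
            out[f"sample_entropy(m={m},r_frac={r!r})->sampen"] = v
    for alg, ptup, op_ids in groups:
        params = dict(ptup)
        try:
            res = evaluate_algorithm(alg, params, x)
        except Exception:                                  # noqa: BLE001
            log.exception("operation %s%r failed; recording missing",
                          alg, params)
            res = None
        for op_id in op_ids:
            name = op_id.rsplit("->", 1)[1]
            out[op_id] = res[name] if res is not None else NAN
    return out


def _group_specs(catalog: Sequence[OperationSpec]):
    sampen_pairs: list[tuple[int, float]] = []
    groups: dict[tuple[str, tuple], list[str]] = {}
    for s in catalog:
        if s.algorithm == "sample_entropy":
            pair = (s.params["m"], s.params["r_frac"])
            if pair not in sampen_pairs:
                sampen_pairs.append(pair)
        else:
            groups.setdefault((s.algorithm, s.parameters), []).append(
                s.operation_id)
    return [(a, p, ids) for (a, p), ids in groups.items()], sampen_pairs


def apply_catalog(
    windows: Iterable[WindowSample],
    catalog: Sequence[OperationSpec],
) -> FeatureMatrix:
    """Evaluate every catalog operation on every complete labeled window.

    One row per (patient, day, window start); one column per operation per
    signal. Incomplete windows are excluded with a logged count; an
    operation failure records a missing value and never aborts the batch.
    """
    groups, sampen_pairs = _group_specs(catalog)
    sampen_ids = [f"sample_entropy(m={m},r_frac={r!r})->sampen"
                  for m, r in sampen_pairs]
    per_signal_cols = sampen_ids + [i for _, _, ids in groups for i in ids]
    columns = [f"{sig}:{c}" for sig in SIGNALS for c in per_signal_cols]

    n_per_signal = len(per_signal_cols)
    offset = {sig: i * n_per_signal for i, sig in enumerate(SIGNALS)}
    rows: dict[tuple, np.ndarray] = {}
    labels: dict[tuple, int] = {}
    dud: dict[tuple, float] = {}
    n_incomplete = 0
    for w in windows:
        if not w.complete:
            n_incomplete += 1
            continue
        key = (w.patient_id, w.day_index, w.window_start_s)
        rec = rows.get(key)
        if rec is None:
            rec = rows[key] = np.full(len(columns), np.nan)
        vals = _evaluate_window(w.values, groups, sampen_pairs)
        # insertion order of vals matches per_signal_cols by construction
        base = offset[w.signal]
        rec[base:base + n_per_signal] = np.fromiter(
            vals.values(), dtype=float, count=n_per_signal)
        labels[key] = (int(w.died_within_horizon)
                       if w.died_within_horizon is not None else 0)
        dud[key] = (w.days_until_death
                    if w.days_until_death is not None else np.nan)
    if n_incomplete:
        log.info("excluded %d incomplete windows", n_incomplete)

    keys = sorted(rows)
    index = pd.MultiIndex.from_tuples(keys, names=ROW_KEY) if keys else \
        pd.MultiIndex.from_arrays([[], [], []], names=ROW_KEY)
    values = pd.DataFrame(
        np.vstack([rows[k] for k in keys]) if keys
        else np.empty((0, len(columns))),
        index=index, columns=columns, dtype=float)
    return FeatureMatrix(
        values=values,
        labels=pd.Series([labels[k] for k in keys], index=index,
                         dtype=int, name="died_within_horizon"),
        days_until_death=pd.Series([dud[k] for k in keys], index=index,
                                   dtype=float, name="days_until_death"),
    )


def save_feature_matrix(matrix: FeatureMatrix, path: str | Path,
                        sidecar: dict | None = None) -> None:
    """Persist a feature matrix as a delimited table plus a JSON sidecar."""
    import json
    from pathlib import Path as _P
    path = _P(path)
    df = matrix.values.copy()
    df["died_within_horizon"] = matrix.labels
    df["days_until_death"] = matrix.days_until_death
    df.reset_index().to_csv(path, index=False)
    meta = {"columns": list(matrix.values.columns)}
    meta.update(sidecar or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    from pathlib import Path as _P
    df = pd.read_csv(_P(path)).set_index(ROW_KEY)
    labels = df.pop("died_within_horizon").astype(int)
    dud = df.pop("days_until_death").astype(float)
    return FeatureMatrix(df, labels, dud)


# ---------------------------------------------------------------------------
# daily sampling


def select_daily_starts(
    keys: Iterable[tuple[str, int, int]],
    seed: int,
) -> set[tuple[str, int, int]]:
    """Pick one window start per (patient, day), uniformly and reproducibly.

    The choice depends only on the sorted key set and the seed, so sampling
    windows before feature extraction and sampling feature-matrix rows
    afterwards select the same windows (the two orders commute).
    """
    by_day: dict[tuple[str, int], list[int]] = {}
    for pid, day, start in keys:
        by_day.setdefault((pid, day), []).append(start)
    rng = np.random.default_rng(seed)
    chosen = set()
    for (pid, day) in sorted(by_day):
        starts = sorted(set(by_day[(pid, day)]))
        chosen.add((pid, day, starts[int(rng.integers(len(starts)))]))
    return chosen


def sample_windows_daily(
    windows: Sequence[WindowSample],
    seed: int,
) -> list[WindowSample]:
    """Keep one complete window per patient-day (both signals at the
    selected start)."""
    keys = {(w.patient_id, w.day_index, w.window_start_s)
            for w in windows if w.complete}
    chosen = select_daily_starts(keys, seed)
    return [w for w in windows
            if (w.patient_id, w.day_index, w.window_start_s) in chosen]


def sample_daily(
    matrix: FeatureMatrix,
    mode: Literal["random_one_per_day", "daily_mean"] = "random_one_per_day",
    seed: int = 0,
) -> FeatureMatrix:
    """Reduce the window-level matrix to one record per patient-day.

    ``random_one_per_day`` keeps exactly one window row per patient-day
    (uniform, seeded); ``daily_mean`` averages each column over the day's
    windows ignoring missing values (window_start_s becomes -1).
    """
    if mode == "random_one_per_day":
        chosen = select_daily_starts(matrix.values.index, seed)
        mask = [k in chosen for k in matrix.values.index]
        return FeatureMatrix(matrix.values[mask], matrix.labels[mask],
                             matrix.days_until_death[mask])
    if mode == "daily_mean":
        grouper = ["patient_id", "day_index"]
        vals = matrix.values.groupby(level=grouper).mean()
        labels = matrix.labels.groupby(level=grouper).max()
        dud = matrix.days_until_death.groupby(level=grouper).mean()
        idx = pd.MultiIndex.from_tuples(
            [(p, d, -1) for p, d in vals.index], names=ROW_KEY)
        return FeatureMatrix(vals.set_axis(idx),
                             labels.set_axis(idx).astype(int),
                             dud.set_axis(idx))
    raise ValueError(f"unknown sampling mode {mode!r}")


# ---------------------------------------------------------------------------
# viability filtering


@dataclass
class FilterAudit:
    """Record of everything removed by viability filtering, with reasons."""

    dropped_columns: list[tuple[str, str]] = field(default_factory=list)
    dropped_rows: list[tuple] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.dropped_columns and not self.dropped_rows


def filter_nonviable(
    matrix: FeatureMatrix,
    max_missing_fraction: float = 0.0,
) -> tuple[FeatureMatrix, FilterAudit]:
    """Drop non-viable operations, then samples with remaining missing values.

    A column is non-viable when its non-missing values are all identical
    (single-valued), when it contains any non-finite/complex-coded result,
    or when its missing fraction exceeds ``max_missing_fraction`` (default:
    any missing value disqualifies). Rows with any remaining missing cell
    are dropped afterwards. Raises if nothing survives.
    """
    audit = FilterAudit()
    vals = matrix.values
    keep = []
    for col in vals.columns:
        v = vals[col].to_numpy()
        finite = v[np.isfinite(v)]
        n_nonmissing = np.count_nonzero(~np.isnan(v))
        if np.isinf(v).any() or np.iscomplexobj(v):
            audit.dropped_columns.append((col, "non-real"))
        elif finite.size == 0:
            audit.dropped_columns.append((col, "all-missing"))
        elif np.all(finite == finite[0]):
            audit.dropped_columns.append((col, "single-valued"))
        elif 1 - n_nonmissing / len(v) > max_missing_fraction:
            audit.dropped_columns.append((col, "missing-fraction"))
        else:
            keep.append(col)
    vals = vals[keep]
    row_ok = ~vals.isna().any(axis=1)
    audit.dropped_rows = list(vals.index[~row_ok])
    vals = vals[row_ok]
    if vals.empty or not keep:
        raise ValueError("viability filtering removed everything: "
                         "empty matrix")
    if audit.dropped_columns:
        log.info("dropped %d non-viable columns", len(audit.dropped_columns))
    if audit.dropped_rows:
        log.info("dropped %d rows with missing values", len(audit.dropped_rows))
    return (FeatureMatrix(vals, matrix.labels[row_ok],
                          matrix.days_until_death[row_ok]), audit)


# ---------------------------------------------------------------------------
# normalization


def winsorize(values: np.ndarray, lo: float = 0.001,
              hi: float = 0.999) -> np.ndarray:
    """Clip values beyond the lo/hi empirical quantiles.

    Quantiles use linear (type-7) interpolation. Values inside the bounds
    are untouched; re-applying with the same learned bounds (the
    :class:`Winsorizer` transform) is a no-op. Re-estimating quantiles on
    already-clipped data can shrink the extremes again, because an
    interpolated quantile moves with the clipped maximum.
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    values = np.asarray(values, dtype=float)
    qlo, qhi = np.quantile(values, [lo, hi])
    return np.clip(values, qlo, qhi)


def robust_sigmoid(values: np.ndarray, median: float,
                   iqr: float) -> np.ndarray:
    """Outlier-robust sigmoid: 1 / (1 + exp(-(v - median) / (IQR/1.349))).

    IQR/1.349 is the IQR of a standard normal, so the transform behaves
    like a z-score squashed through a logistic for near-normal columns.
    """
    scale = iqr / 1.349
    with np.errstate(over="ignore"):        # exp overflow saturates to 0
        return 1.0 / (1.0 + np.exp(-(values - median) / scale))


def robust_sigmoid_normalize(values: np.ndarray) -> np.ndarray:
    """Sigmoid-transform one column then min-max rescale to [0, 1].

    Strictly monotone in the input, so rank order is preserved exactly.
    Falls back to the standard deviation as scale when the IQR is zero.
    """
    values = np.asarray(values, dtype=float)
    med = float(np.median(values))
    q1, q3 = np.percentile(values, [25, 75])
    iqr = float(q3 - q1)
    if iqr == 0:
        sd = float(values.std())
        if sd == 0:
            return np.full_like(values, 0.5)
        iqr = sd * 1.349
    f = robust_sigmoid(values, med, iqr)
    return (f - f.min()) / (f.max() - f.min())


class Winsorizer(TransformerMixin, BaseEstimator):
    """Per-column quantile clipping, with quantiles learned at fit time."""

    def __init__(self, lo: float = 0.001, hi: float = 0.999):
        self.lo = lo
        self.hi = hi

    def fit(self, X, y=None):
        if not (0 <= self.lo < self.hi <= 1):
            raise ValueError("need 0 <= lo < hi <= 1")
        X = np.asarray(X, dtype=float)
        self.lower_, self.upper_ = np.quantile(
            X, [self.lo, self.hi], axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return np.clip(X, self.lower_, self.upper_)


class RobustSigmoidScaler(TransformerMixin, BaseEstimator):
    """Outlier-robust sigmoid normalization to [0, 1], column-wise.

    Fit learns each column's median, IQR (falling back to 1.349*SD for
    zero-IQR columns) and the post-sigmoid min/max used for rescaling;
    transform maps new data through the same parameters and clips to [0,1].
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.median_ = np.median(X, axis=0)
        q1, q3 = np.percentile(X, [25, 75], axis=0)
        iqr = q3 - q1
        sd_fallback = X.std(axis=0) * 1.349
        iqr = np.where(iqr > 0, iqr, sd_fallback)
        self.iqr_ = np.where(iqr > 0, iqr, 1.0)
        self.degenerate_ = (iqr <= 0)
        f = robust_sigmoid(X, self.median_, self.iqr_)
        self.f_min_ = f.min(axis=0)
        self.f_max_ = f.max(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        f = robust_sigmoid(X, self.median_, self.iqr_)
        span = np.where(self.f_max_ > self.f_min_,
                        self.f_max_ - self.f_min_, 1.0)
        out = np.clip((f - self.f_min_) / span, 0.0, 1.0)
        return np.where(self.degenerate_, 0.5, out)
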