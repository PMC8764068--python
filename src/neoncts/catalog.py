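"""The operation catalog: named, parameterized feature operations.

An *algorithm* (sample entropy, moving threshold, ...) plus a concrete
parameter setting plus one of its named outputs is an *operation* — the
unit that becomes a feature-matrix column. The default catalog is a
representative grid spanning all eleven algorithm families with 120
operations per signal; every spec serializes to JSON and rebuilds exactly
from its id string.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import operators as ops

FAMILIES = (
    "Distribution", "Correlation", "Stationarity", "SymbolicTransforms",
    "Entropy", "TrendAnalysis", "HeartRateVariability", "TimeSeriesModelling",
    "Wavelet", "NonlinearAnalysis", "Other",
)


def _zscored(fn: Callable) -> Callable:
    def wrapped(x, **kw):
        z = ops.zscore(x)
        if z is None:
            probe = fn(np.array([0.0, 1.0, 0.0, 1.0]), **kw)
            return {k: ops.NAN for k in probe}
        return fn(z, **kw)
    return wrapped


# algorithm name -> (family, evaluator(x, **params) -> dict[output, value])
_ALGORITHMS: dict[str, tuple[str, Callable]] = {
    "distribution": ("Distribution", lambda x: ops.distribution_stats(x)),
    "autocorrelation": ("Correlation",
                        lambda x, lag: {"ac": ops.autocorrelation(x, lag)}),
    "nonlinear_autocorrelation": ("Correlation",
                                  lambda x: ops.nonlinear_autocorrelation(x)),
    "statav": ("Stationarity",
               lambda x, n_segments: ops.stationarity_statav(x, n_segments)),
    "successive_increases": (
        "SymbolicTransforms",
        lambda x: {"count": ops.successive_increases(x)}),
    "motifs": ("SymbolicTransforms",
               lambda x: ops.symbolic_motif_frequencies(x)),
    "sample_entropy": (
        "Entropy",
        lambda x, m, r_frac: {"sampen": ops.sample_entropy(x, m, r_frac)}),
    "trend": ("TrendAnalysis", lambda x: ops.trend_fit(x)),
    "spectral_bands": ("HeartRateVariability",
                       lambda x: ops.spectral_band_features(x)),
    "surprise": ("TimeSeriesModelling",
                 lambda x, n_groups, memory_m:
                 ops.surprise(x, n_groups, memory_m)),
    "random_walk": ("TimeSeriesModelling",
                    _zscored(lambda x, coupling_p:
                             ops.random_walk_stats(x, coupling_p))),
    "wavelet_energies": ("Wavelet", lambda x: ops.wavelet_level_energies(x)),
    "fnn": ("NonlinearAnalysis",
            lambda x: ops.false_nearest_neighbors(x)),
    "moving_threshold": ("Other",
                         lambda x, rate_a, decay_b:
                         ops.moving_threshold(x, rate_a, decay_b)),
}

# output names per multi-output algorithm (single-output ones inline below)
_OUTPUTS = {
    "distribution": ["mean", "median", "sd", "min", "max", "range", "iqr",
                     "skewness", "kurtosis", "p05", "p95"],
    "nonlinear_autocorrelation": ["ac_nl_121", "ac_nl_211"],
    "statav": ["statav_mean", "statav_sd"],
    "motifs": [f"f_{a}_{b}" for a in ("up", "down", "same")
               for b in ("up", "down", "same")],
    "trend": ["slope_per_step", "intercept", "residual_sd"],
    "spectral_bands": ["total_power", "lf_power", "hf_power", "lf_hf_ratio"],
    "surprise": ["mean_inv_p", "mean_log_inv_p"],
    "random_walk": ["walker_mean", "walker_sd", "rms_residual",
                    "frac_walker_above", "xcorr_lag1"],
    "wavelet_energies": ["wav_approx"] + [f"wav_d{i}" for i in range(1, 5)],
    "fnn": [f"fnn_m{m}" for m in range(1, 6)],
    "moving_threshold": ["n_events", "event_rate", "mean_gap", "q_mean",
                         "q_p05", "q_p25", "q_p50", "q_p75", "q_p95"],
}

SAMPLE_ENTROPY_M = (1, 2, 3)
SAMPLE_ENTROPY_R = (0.10, 0.15, 0.20, 0.25)


def _fmt(v) -> str:
    return repr(int(v)) if isinstance(v, (int, np.integer)) else repr(float(v))


@dataclass(frozen=True)
class OperationSpec:
    """One catalog entry: algorithm + parameters + one named output."""

    algorithm: str
    family: str
    parameters: tuple[tuple[str, float | int], ...]   # sorted (name, value)
    output_name: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def operation_id(self) -> str:
        pstr = ",".join(f"{k}={_fmt(v)}" for k, v in self.parameters)
        return f"{self.algorithm}({pstr})->{self.output_name}"

    @property
    def params(self) -> dict:
        return dict(self.parameters)


def make_spec(algorithm: str, output_name: str, **parameters) -> OperationSpec:
    family = _ALGORITHMS[algorithm][0]
    ptup = tuple(sorted(parameters.items()))
    return OperationSpec(algorithm, family, ptup, output_name)


_ID_RE = re.compile(r"^(?P<alg>\w+)\((?P<params>[^)]*)\)->(?P<out>\w+)$")


def spec_from_id(operation_id: str) -> OperationSpec:
    """Rebuild an OperationSpec from its canonical id string."""
    m = _ID_RE.match(operation_id)
    if not m:
        raise ValueError(f"malformed operation id {operation_id!r}")
    params = {}
    if m["params"]:
        for item in m["params"].split(","):
            k, v = item.split("=")
            params[k] = int(v) if re.fullmatch(r"-?\d+", v) else float(v)
    return make_spec(m["alg"], m["out"], **params)


def evaluate_algorithm(algorithm: str, parameters: dict,
                       x: np.ndarray) -> dict[str, float]:
    """Run one algorithm at one parameter setting; all named outputs."""
    return _ALGORITHMS[algorithm][1](x, **parameters)


def evaluate_operation(spec: OperationSpec, x: np.ndarray) -> float:
    out = evaluate_algorithm(spec.algorithm, spec.params, x)
    return out[spec.output_name]


def build_default_catalog() -> list[OperationSpec]:
    """The default family-complete operation grid (120 operations).

    Includes the canonical 12-operation sample-entropy grid
    (m in {1,2,3} x r in {0.10,0.15,0.20,0.25} of the window SD), the four
    operators of special interest (successive increases, moving threshold,
    surprise, random walk) over several parameter settings, and at least
    two operations in every family.
    """
    specs: list[OperationSpec] = []

    def add(algorithm: str, **params) -> None:
        outputs = _OUTPUTS.get(algorithm)
        if outputs is None:
            outputs = {"autocorrelation": ["ac"],
                       "successive_increases": ["count"],
                       "sample_entropy": ["sampen"]}[algorithm]
        for out in outputs:
            specs.append(make_spec(algorithm, out, **params))

    add("distribution")
    for lag in (1, 2, 5, 10, 25):
        add("autocorrelation", lag=lag)
    add("nonlinear_autocorrelation")
    for n_segments in (5, 10):
        add("statav", n_segments=n_segments)
    add("successive_increases")
    add("motifs")
    for m in SAMPLE_ENTROPY_M:
        for r in SAMPLE_ENTROPY_R:
            add("sample_entropy", m=m, r_frac=r)
    add("trend")
    add("spectral_bands")
    for n_groups, memory_m in ((3, 50), (5, 50), (3, 100), (5, 100)):
        add("surprise", n_groups=n_groups, memory_m=memory_m)
    for p in (0.1, 0.5, 1.0):
        add("random_walk", coupling_p=p)
    add("wavelet_energies")
    add("fnn")
    for rate_a, decay_b in ((0.1, 0.02), (0.1, 0.1), (0.5, 0.1), (1.0, 0.1)):
        add("moving_threshold", rate_a=rate_a, decay_b=decay_b)

    ids = [s.operation_id for s in specs]
    assert len(ids) == len(set(ids)), "operation ids must be unique"
    return specs


def catalog_to_json(specs: list[OperationSpec]) -> str:
    """Serialize a catalog as the reproducibility/provenance contract."""
    return json.dumps([
        {"operation_id": s.operation_id, "family": s.family,
         "algorithm": s.algorithm, "parameters": s.params,
         "output_name": s.output_name}
        for s in specs
    ], indent=1)


def catalog_from_json(doc: str) -> list[OperationSpec]:
    return [spec_from_id(rec["operation_id"]) for rec in json.loads(doc)]
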