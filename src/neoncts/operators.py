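"""Time-series feature operators.

Pure functions of a 1-D window of values (nominally 300 samples at 0.5 Hz)
plus parameters. Every operator returns either finite reals — a scalar or a
dict of named outputs — or NaN as an explicit missing marker; none of them
raises on degenerate input such as a constant window.

The catalog built on top of these spans eleven algorithm families
(distribution moments, autocorrelation, stationarity, symbolic transforms,
entropy, trend fitting, spectral heart-rate-variability bands, time-series
model fits, wavelets, nonlinear embedding analysis, and extreme-value
statistics), including four operators of particular interest for neonatal
monitoring: successive increases, the moving-threshold extreme-event model,
surprise, and the coupled random-walk fit.
"""

from __future__ import annotations

import numpy as np
import pywt
from numba import njit
from scipy.signal import lfilter

__all__ = [
    "successive_increases", "symbolic_motif_frequencies", "moving_threshold",
    "surprise", "random_walk_stats", "sample_entropy", "distribution_stats",
    "autocorrelation", "nonlinear_autocorrelation", "stationarity_statav",
    "trend_fit", "spectral_band_features", "wavelet_level_energies",
    "false_nearest_neighbors", "zscore",
]

NAN = float("nan")


def zscore(x: np.ndarray) -> np.ndarray | None:
    """Z-score a window; None if the window is constant (sd 0)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return None
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# symbolic transforms


def successive_increases(x: np.ndarray) -> float:
    """Count of overlapping strict double-increases x[i] < x[i+1] < x[i+2].

    A symbolic-dynamics statistic of small accelerations: ties count as
    "same", not increases. For a length-300 symmetric random walk the
    expected count is 298/4 = 74.5 (consecutive increment signs are
    independent); low counts indicate reduced variability.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return NAN
    up = np.diff(x) > 0
    return float(np.count_nonzero(up[:-1] & up[1:]))


def symbolic_motif_frequencies(x: np.ndarray) -> dict[str, float]:
    """Frequencies of ordered pairs of difference signs over {up, down, same}.

    The n-1 first differences map to symbols; the n-2 adjacent symbol pairs
    are tabulated. Frequencies sum to 1.
    """
    names = ["up", "down", "same"]
    keys = [f"f_{a}_{b}" for a in names for b in names]
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return {k: NAN for k in keys}
    d = np.diff(x)
    sym = np.where(d > 0, 0, np.where(d < 0, 1, 2))
    pair = sym[:-1] * 3 + sym[1:]
    counts = np.bincount(pair, minlength=9).astype(float)
    freq = counts / counts.sum()
    return dict(zip(keys, freq))


# ---------------------------------------------------------------------------
# extreme values: the moving-threshold model


@njit(cache=True)
def _moving_threshold_loop(z: np.ndarray, rate_a: float, decay_b: float,
                           q0: float):  # pragma: no cover - jitted
    n = z.size
    q = np.empty(n)
    events = np.empty(n, dtype=np.int64)
    n_events = 0
    cur = q0
    for i in range(n):
        q[i] = cur
        if z[i] > cur:
            events[n_events] = i
            n_events += 1
            cur = cur * (1.0 + rate_a)
        else:
            cur = cur * (1.0 - decay_b)
    return q, events[:n_events]


def moving_threshold(x: np.ndarray, rate_a: float = 0.1,
                     decay_b: float = 0.1, q0: float = 1.0,
                     *, prescored: bool = False) -> dict[str, float]:
    """Extreme-event statistics from an adaptive threshold on |z-scores|.

    A barrier starts at ``q0``; a point exceeding it is an *event* and
    raises the barrier multiplicatively by ``1 + rate_a``; otherwise the
    barrier decays by ``1 - decay_b``. The threshold is tested before it is
    updated, and summary statistics run over the n tested thresholds and the
    event indices. A chronically low threshold indicates a signal without
    excursions — e.g. low heart-rate variability or a sagging SpO2 baseline.

    ``prescored=True`` means ``x`` is already the magnitude sequence |z|.
    """
    if not (rate_a >= 0):
        raise ValueError(f"rate_a must be >= 0, got {rate_a}")
    if not (0 <= decay_b < 1):
        raise ValueError(f"decay_b must be in [0, 1), got {decay_b}")
    keys = ["n_events", "event_rate", "mean_gap", "q_mean",
            "q_p05", "q_p25", "q_p50", "q_p75", "q_p95"]
    if prescored:
        z = np.abs(np.asarray(x, dtype=float))
    else:
        zs = zscore(x)
        if zs is None:
            return {k: NAN for k in keys}
        z = np.abs(zs)
    q, events = _moving_threshold_loop(z, float(rate_a), float(decay_b),
                                       float(q0))
    p05, p25, p50, p75, p95 = np.percentile(q, [5, 25, 50, 75, 95])
    return {
        "n_events": float(events.size),
        "event_rate": events.size / z.size,
        "mean_gap": float(np.diff(events).mean()) if events.size >= 2 else NAN,
        "q_mean": float(q.mean()),
        "q_p05": float(p05), "q_p25": float(p25), "q_p50": float(p50),
        "q_p75": float(p75), "q_p95": float(p95),
    }


# ---------------------------------------------------------------------------
# time-series modelling: surprise and the coupled random walk


def _equiprobable_symbols(x: np.ndarray, n_groups: int) -> np.ndarray:
    """Quantile (equiprobable) symbolization with stable tie-breaking."""
    order = np.argsort(x, kind="stable")
    sym = np.empty(x.size, dtype=np.int64)
    sym[order] = (np.arange(x.size) * n_groups) // x.size
    return sym


def surprise(x: np.ndarray, n_groups: int = 3, memory_m: int = 50,
             *, symbols: np.ndarray | None = None) -> dict[str, float]:
    """Mean improbability of each point given a trailing memory window.

    The window is symbolized into ``n_groups`` equiprobable bins; for each
    t > memory_m the probability of the observed symbol is estimated from
    the previous ``memory_m`` symbols with Laplace add-one smoothing,
    p = (count + 1) / (memory_m + n_groups). Outputs are the means of 1/p
    and log(1/p). ``symbols`` substitutes a precomputed symbol sequence for
    the quantile binning (distribution memory, not transition memory).
    """
    keys = ["mean_inv_p", "mean_log_inv_p"]
    x = np.asarray(x, dtype=float)
    n = symbols.size if symbols is not None else x.size
    if n <= memory_m:
        return {k: NAN for k in keys}
    sym = (np.asarray(symbols, dtype=np.int64) if symbols is not None
           else _equiprobable_symbols(x, n_groups))
    onehot = np.zeros((n + 1, n_groups))
    onehot[np.arange(1, n + 1), sym] = 1.0
    csum = np.cumsum(onehot, axis=0)          # csum[t] = counts of sym[:t]
    t = np.arange(memory_m, n)
    counts = csum[t, sym[t]] - csum[t - memory_m, sym[t]]
    p = (counts + 1.0) / (memory_m + n_groups)
    inv = 1.0 / p
    return {"mean_inv_p": float(inv.mean()),
            "mean_log_inv_p": float(np.log(inv).mean())}


def random_walk_stats(x: np.ndarray,
                      coupling_p: float = 0.5) -> dict[str, float]:
    """Fit statistics of a walker pulled toward the series.

    The walker starts at 0 and each step moves a fraction ``coupling_p`` of
    its distance to the *previous* observation:
    ``w[i] = w[i-1] + p * (x[i-1] - w[i-1])``. Reported are the walker's
    mean and SD, the RMS walker-minus-series residual, the fraction of
    steps with the walker above the series, and the lag-1 cross-correlation
    corr(w[:-1], x[1:]). Applied to z-scored windows in the catalog; a
    persistent residual pattern flags drifting signals such as declining
    oxygen saturation.
    """
    if not (0 < coupling_p <= 1):
        raise ValueError(f"coupling_p must be in (0, 1], got {coupling_p}")
    keys = ["walker_mean", "walker_sd", "rms_residual",
            "frac_walker_above", "xcorr_lag1"]
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return {k: NAN for k in keys}
    # w[i] = (1-p) w[i-1] + p x[i-1]: an AR filter driven by delayed x
    drive = np.concatenate([[0.0], coupling_p * x[:-1]])
    w = lfilter([1.0], [1.0, -(1.0 - coupling_p)], drive)
    resid = w - x
    a, b = w[:-1] - w[:-1].mean(), x[1:] - x[1:].mean()
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    xcorr = float(np.dot(a, b) / denom) if denom > 0 else NAN
    return {
        "walker_mean": float(w.mean()),
        "walker_sd": float(w.std(ddof=1)),
        "rms_residual": float(np.sqrt(np.mean(resid ** 2))),
        "frac_walker_above": float(np.mean(w > x)),
        "xcorr_lag1": xcorr,
    }


# ---------------------------------------------------------------------------
# entropy


def _chebyshev_template_counts(x: np.ndarray, m_max: int) -> list[np.ndarray]:
    """Pairwise Chebyshev distance matrices between m-length templates.

    Returns [D_1, ..., D_m_max] where D_m[i, j] is the max-norm distance
    between templates x[i:i+m] and x[j:j+m], built incrementally. The
    diagonal (self-matches) is set to +inf at level 1 and propagates, so
    callers can count or rank matches without excluding it explicitly.
    """
    d1 = np.abs(x[:, None] - x[None, :])
    np.fill_diagonal(d1, np.inf)
    out = [d1]
    for m in range(2, m_max + 1):
        prev = out[-1]
        out.append(np.maximum(prev[:-1, :-1], d1[m - 1:, m - 1:]))
    return out


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) for template matches at tolerance r.

    B counts ordered pairs of distinct m-length templates within Chebyshev
    distance r = r_frac * SD(x); A likewise for length m+1. Self-matches are
    excluded. Lower values mean more regularity. Constant windows and
    zero-match cases return NaN (handled uniformly by the filtering stage
    rather than as infinities).
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if x.size < m + 2 or sd == 0 or not np.isfinite(sd):
        return NAN
    r = r_frac * sd
    dms = _chebyshev_template_counts(x, m + 1)
    n_m = x.size - m          # templates of length m comparable with m+1
    b = np.count_nonzero(dms[m - 1][:n_m, :n_m] <= r) / 2
    a = np.count_nonzero(dms[m] <= r) / 2
    if a == 0 or b == 0:
        return NAN
    return float(-np.log(a / b))


@njit(cache=True)
def _template_pair_counts(x: np.ndarray, rs: np.ndarray,
                          level_max: int):  # pragma: no cover - jitted
    """Counts of template pairs within tolerance at levels 1..level_max.

    ``nat[L-1, ri]`` counts pairs i < j of length-L templates over the
    natural index range (start <= n - L); ``trunc[L-1, ri]`` restricts both
    starts to <= n - L - 1 (the range comparable with level L+1). Distances
    accumulate incrementally per pair with early exit once they exceed the
    largest tolerance.
    """
    n = x.size
    nr = rs.size
    r_top = rs.max()
    nat = np.zeros((level_max, nr), dtype=np.int64)
    trunc = np.zeros((level_max, nr), dtype=np.int64)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dmax = 0.0
            for lev in range(1, level_max + 1):
                if j + lev - 1 >= n:
                    break
                d = abs(x[i + lev - 1] - x[j + lev - 1])
                if d > dmax:
                    dmax = d
                if dmax > r_top:
                    break
                for ri in range(nr):
                    if dmax <= rs[ri]:
                        nat[lev - 1, ri] += 1
                        if j <= n - lev - 1:
                            trunc[lev - 1, ri] += 1
    return nat, trunc


def sample_entropy_many(
    x: np.ndarray,
    pairs: list[tuple[int, float]],
) -> dict[tuple[int, float], float]:
    """Sample entropy over a grid of (m, r_frac) pairs.

    Equivalent to calling :func:`sample_entropy` per pair but counts all
    template matches in one incremental pass over the pairs of indices.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    m_max = max(m for m, _ in pairs)
    if x.size < m_max + 2 or sd == 0 or not np.isfinite(sd):
        return {p: NAN for p in pairs}
    r_fracs = sorted({r for _, r in pairs})
    rs = np.array([rf * sd for rf in r_fracs])
    nat, trunc = _template_pair_counts(x, rs, m_max + 1)
    out = {}
    for m, r_frac in pairs:
        ri = r_fracs.index(r_frac)
        b = trunc[m - 1, ri]
        a = nat[m, ri]
        out[(m, r_frac)] = float(-np.log(a / b)) if a > 0 and b > 0 else NAN
    return out


# ---------------------------------------------------------------------------
# distribution, correlation, stationarity, trend


def distribution_stats(x: np.ndarray) -> dict[str, float]:
    """Descriptive moments and quantiles.

    SD uses the n-1 denominator; skewness and kurtosis are the biased
    standardized third and fourth moments (kurtosis of a normal is 3),
    missing for constant windows.
    """
    x = np.asarray(x, dtype=float)
    if x.max() == x.min():          # exactly constant: avoid fp residue
        sd = 0.0 if x.size >= 2 else NAN
    else:
        sd = float(x.std(ddof=1)) if x.size >= 2 else NAN
    p05, q1, q3, p95 = np.percentile(x, [5, 25, 75, 95])
    if sd and np.isfinite(sd) and sd > 0:
        xc = x - x.mean()
        m2 = float(np.mean(xc ** 2))
        skew = float(np.mean(xc ** 3) / m2 ** 1.5)
        kurt = float(np.mean(xc ** 4) / m2 ** 2)
    else:
        skew = kurt = NAN
    return {
        "mean": float(x.mean()), "median": float(np.median(x)), "sd": sd,
        "min": float(x.min()), "max": float(x.max()),
        "range": float(x.max() - x.min()), "iqr": float(q3 - q1),
        "skewness": skew, "kurtosis": kurt,
        "p05": float(p05), "p95": float(p95),
    }


def autocorrelation(x: np.ndarray, lag: int = 1) -> float:
    """Biased autocorrelation estimator at the given lag."""
    x = np.asarray(x, dtype=float)
    if x.size <= lag:
        return NAN
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        return NAN
    if lag == 0:
        return 1.0
    return float(np.dot(xc[:-lag], xc[lag:]) / denom)


def nonlinear_autocorrelation(x: np.ndarray) -> dict[str, float]:
    """Third-order lag-1 moments <z_t z_{t+1}^2> and <z_t^2 z_{t+1}>."""
    keys = ["ac_nl_121", "ac_nl_211"]
    z = zscore(x)
    if z is None or z.size < 2:
        return {k: NAN for k in keys}
    return {"ac_nl_121": float(np.mean(z[:-1] * z[1:] ** 2)),
            "ac_nl_211": float(np.mean(z[:-1] ** 2 * z[1:]))}


def stationarity_statav(x: np.ndarray,
                        n_segments: int = 5) -> dict[str, float]:
    """StatAv-style stationarity ratios over equal segments.

    Splits the window into ``n_segments`` equal segments (remainder
    truncated) and reports SD-of-segment-means / whole-window SD and
    SD-of-segment-SDs / whole-window SD (both with n-1 denominators).
    Values near 1/sqrt(segment length) indicate stationary noise; larger
    values indicate trends or regime changes.
    """
    keys = ["statav_mean", "statav_sd"]
    x = np.asarray(x, dtype=float)
    seg_len = x.size // n_segments
    if seg_len < 2:
        return {k: NAN for k in keys}
    whole_sd = x.std(ddof=1)
    if whole_sd == 0:
        return {k: NAN for k in keys}
    segs = x[: seg_len * n_segments].reshape(n_segments, seg_len)
    return {
        "statav_mean": float(segs.mean(axis=1).std(ddof=1) / whole_sd),
        "statav_sd": float(segs.std(axis=1, ddof=1).std(ddof=1) / whole_sd),
    }


def trend_fit(x: np.ndarray) -> dict[str, float]:
    """Ordinary least squares of value on sample index 0..n-1."""
    keys = ["slope_per_step", "intercept", "residual_sd"]
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return {k: NAN for k in keys}
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    slope = float(np.dot(tc, x) / np.dot(tc, tc))
    intercept = float(x.mean() - slope * t.mean())
    resid = x - (intercept + slope * t)
    return {"slope_per_step": slope, "intercept": intercept,
            "residual_sd": float(resid.std())}


# ---------------------------------------------------------------------------
# spectral (heart-rate-variability style band powers)

LF_BAND = (0.04, 0.15)   # Hz
HF_BAND = (0.15, 0.25)   # Hz, Nyquist at 0.25 for 0.5 Hz sampling


def spectral_band_features(x: np.ndarray, fs: float = 0.5) -> dict[str, float]:
    """Periodogram band powers in the LF (0.04-0.15) and HF (0.15-0.25) bands.

    The window is mean-removed first; powers are normalized so that
    ``total_power`` equals the window variance exactly (Parseval). The
    boundary frequency 0.15 Hz belongs to HF.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    spec = np.abs(np.fft.rfft(xc)) ** 2 / (n * n)
    # one-sided doubling (DC and, for even n, Nyquist appear once)
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    lf = float(spec[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])].sum())
    hf = float(spec[(freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])].sum())
    total = float(spec.sum())
    return {
        "total_power": total, "lf_power": lf, "hf_power": hf,
        "lf_hf_ratio": lf / hf if hf > 0 else NAN,
    }


# ---------------------------------------------------------------------------
# wavelets

WAVELET_N = 256   # dyadic truncation of the 300-sample window


def wavelet_level_energies(x: np.ndarray, levels: int = 4,
                           basis: str = "haar") -> dict[str, float]:
    """Squared-coefficient energy per wavelet level (orthonormal Haar).

    Uses the first 256 samples (dyadic length). Energies over the
    approximation plus ``levels`` detail levels sum to the truncated
    signal's squared norm.
    """
    x = np.asarray(x, dtype=float)[:WAVELET_N]
    if x.size < 2 ** levels:
        return {"wav_approx": NAN, **{f"wav_d{i}": NAN
                                      for i in range(1, levels + 1)}}
    coeffs = pywt.wavedec(x, basis, level=levels)
    out = {"wav_approx": float(np.sum(coeffs[0] ** 2))}
    # pywt orders [approx, detail_level, ..., detail_1]
    for i, c in enumerate(coeffs[1:]):
        out[f"wav_d{levels - i}"] = float(np.sum(c ** 2))
    return out


# ---------------------------------------------------------------------------
# nonlinear analysis


def false_nearest_neighbors(x: np.ndarray, m_max: int = 5,
                            threshold: float = 10.0,
                            dms: list[np.ndarray] | None = None,
                            ) -> dict[str, float]:
    """Fraction of false nearest neighbours at embedding dimensions 1..m_max.

    Delay-1 embedding under the Chebyshev norm: the nearest neighbour of
    each template at dimension m is *false* if the extra coordinate at
    dimension m+1 is more than ``threshold`` times the dimension-m
    distance. The distance ratio is scale- and translation-invariant, so
    the computation runs on the raw window (equivalent to z-scoring) and
    can reuse template distance matrices via ``dms``. Deterministic signals
    embed at low dimension (fractions drop toward 0); i.i.d. noise keeps
    fractions high. Constant windows are missing.
    """
    keys = [f"fnn_m{m}" for m in range(1, m_max + 1)]
    x = np.asarray(x, dtype=float)
    if x.std() == 0 or not np.isfinite(x.std()) or x.size < m_max + 2:
        return {k: NAN for k in keys}
    if dms is not None and len(dms) >= m_max:
        fracs = _fnn_fractions_from_matrices(x, dms, m_max, threshold)
    else:
        fracs = _fnn_fractions(x, m_max, threshold)
    return {f"fnn_m{m}": float(fracs[m - 1]) for m in range(1, m_max + 1)}


def _fnn_fractions_from_matrices(z: np.ndarray, dms: list[np.ndarray],
                                 m_max: int, threshold: float) -> np.ndarray:
    """Reference FNN path over precomputed template distance matrices."""
    out = np.empty(m_max)
    for m in range(1, m_max + 1):
        n_t = z.size - m          # templates that can be extended to m+1
        d = dms[m - 1][:n_t, :n_t]          # diagonal is +inf
        nn = np.argmin(d, axis=1)
        dist_m = d[np.arange(n_t), nn]
        extra = np.abs(z[np.arange(n_t) + m] - z[nn + m])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist_m > 0, extra / dist_m, np.inf)
        # zero-distance pairs: false iff the extra coordinate differs
        ratio[(dist_m == 0) & (extra == 0)] = 0.0
        out[m - 1] = float(np.mean(ratio > threshold))
    return out


@njit(cache=True)
def _fnn_fractions(x: np.ndarray, m_max: int,
                   threshold: float) -> np.ndarray:  # pragma: no cover
    n = x.size
    best = np.full((n, m_max + 1), np.inf)
    bidx = np.full((n, m_max + 1), -1, dtype=np.int64)
    # one symmetric pass: nearest neighbour per template at every level
    for i in range(n - 1):
        for j in range(i + 1, n):
            dmax = 0.0
            top = n - 1 - j          # deepest level valid for this pair
            if top > m_max:
                top = m_max
            for m in range(1, top + 1):
                a = abs(x[i + m - 1] - x[j + m - 1])
                if a > dmax:
                    dmax = a
                if dmax < best[i, m]:
                    best[i, m] = dmax
                    bidx[i, m] = j
                if dmax < best[j, m]:
                    best[j, m] = dmax
                    bidx[j, m] = i
    out = np.empty(m_max)
    for m in range(1, m_max + 1):
        n_t = n - m
        n_false = 0
        for i in range(n_t):
            bj = bidx[i, m]
            extra = abs(x[i + m] - x[bj + m])
            if best[i, m] > 0.0:
                if extra / best[i, m] > threshold:
                    n_false += 1
            elif extra > 0.0:
                n_false += 1
        out[m - 1] = n_false / n_t
    return out
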