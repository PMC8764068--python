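"""Synthetic NICU cohort generator.

Emulates the kind of data produced by continuous bedside monitoring in a
neonatal intensive care unit: per-patient heart-rate (HR, beats/min) and
pulse-oximetry oxygen-saturation (SpO2, %) streams sampled at 0.5 Hz, an
outcomes table (death, demographics), and — for the minority of patients who
die — a configurable pre-mortem signature in the final week of recording:
reduced HR variability, fewer upward HR accelerations, transient
decelerations, and a gradual decline in SpO2.

The generator is the test-bed for the whole analysis pipeline: every effect
size is a config knob, so a *null* configuration (no pre-mortem effect)
makes dying and surviving patients statistically exchangeable, while the
default configuration plants recoverable signal.

The functional forms (AR(1) noise, sinusoidal wander, Poisson-arriving
acceleration ramps, exponential desaturations) are chosen to reproduce
qualitative monitor phenotypes, not to be physiologic truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import lfilter

SAMPLE_INTERVAL_S = 2          # 0.5 Hz monitor sampling
WINDOW_S = 600                 # 10-minute windows
WINDOW_LEN = WINDOW_S // SAMPLE_INTERVAL_S   # 300 samples
DAY_S = 86_400
SLOTS_PER_DAY = DAY_S // WINDOW_S            # 144 window slots per day


class CohortConfigError(ValueError):
    """Invalid cohort configuration; message names the offending field."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a realistic NICU cohort scale: ~3.4% of patients die,
    stays average ~3 weeks, HR around 140 bpm, SpO2 around 96%, and dying
    patients carry the pre-mortem signature during their final
    ``premortal_window_days`` days.
    """

    n_patients: int = 100
    death_fraction: float = 0.034
    stay_days_mean: float = 20.0
    stay_days_min: int = 8
    stay_days_max: int = 35
    windows_per_day: int = 24
    hr_baseline_bpm: float = 140.0
    hr_baseline_sd_bpm: float = 8.0
    hr_variability_sd_bpm: float = 3.0
    hr_wander_amplitude_bpm: float = 4.0
    hr_wander_period_s: float = 3600.0
    hr_acceleration_rate_per_min: float = 0.5
    hr_acceleration_height_bpm: float = 8.0
    spo2_baseline_pct: float = 96.0
    spo2_baseline_sd_pct: float = 1.5
    spo2_noise_sd_pct: float = 1.0
    desat_rate_per_hour: float = 2.0
    desat_depth_pct: float = 8.0
    # pre-mortem signature (applied to dying patients' final week)
    premortal_variability_factor: float = 0.5
    premortal_acceleration_factor: float = 0.5
    premortal_spo2_drift_pct_per_day: float = -2.0
    premortal_decel_rate_per_hour: float = 3.0
    premortal_decel_depth_bpm: float = 25.0
    premortal_window_days: int = 7
    masimo_averaging: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_patients", self.n_patients >= 1),
            ("death_fraction", 0.0 <= self.death_fraction <= 1.0),
            ("stay_days_min", 1 <= self.stay_days_min <= self.stay_days_max),
            ("stay_days_mean",
             self.stay_days_min <= self.stay_days_mean <= self.stay_days_max),
            ("windows_per_day", 1 <= self.windows_per_day <= SLOTS_PER_DAY),
            ("hr_variability_sd_bpm", self.hr_variability_sd_bpm >= 0),
            ("hr_acceleration_rate_per_min",
             self.hr_acceleration_rate_per_min >= 0),
            ("spo2_baseline_pct", 0.0 < self.spo2_baseline_pct <= 100.0),
            ("spo2_noise_sd_pct", self.spo2_noise_sd_pct >= 0),
            ("desat_rate_per_hour", self.desat_rate_per_hour >= 0),
            ("premortal_variability_factor",
             0.0 < self.premortal_variability_factor <= 1.0),
            ("premortal_acceleration_factor",
             0.0 < self.premortal_acceleration_factor <= 1.0),
            ("premortal_spo2_drift_pct_per_day",
             self.premortal_spo2_drift_pct_per_day <= 0.0),
            ("premortal_decel_rate_per_hour",
             self.premortal_decel_rate_per_hour >= 0),
            ("premortal_window_days", self.premortal_window_days >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise CohortConfigError(
                    f"invalid value for field {name!r}: {getattr(self, name)!r}"
                )

    def null_effect(self) -> "CohortConfig":
        """Copy of this config with every pre-mortem effect switched off.

        Dying and surviving patients become exchangeable, so any downstream
        discrimination is overfitting.
        """
        return dataclasses.replace(
            self,
            premortal_variability_factor=1.0,
            premortal_acceleration_factor=1.0,
            premortal_spo2_drift_pct_per_day=0.0,
            premortal_decel_rate_per_hour=0.0,
        )


@dataclass
class VitalSeries:
    """One patient-signal stream of timestamped 0.5 Hz values."""

    patient_id: str
    signal: str                      # "HR" or "SPO2"
    timestamps: np.ndarray           # seconds from cohort epoch, int64, increasing
    values: np.ndarray               # bpm or %

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")


@dataclass
class PatientParams:
    """Per-patient draw of baselines and outcome used by the day generator."""

    patient_id: str
    hr_baseline: float
    spo2_baseline: float
    wander_phase: float
    death_day: int | None            # None for survivors
    config: CohortConfig


# ---------------------------------------------------------------------------
# window-level signal models


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               sd: float, phi: float = 0.95) -> np.ndarray:
    """Stationary AR(1) rows with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov = rng.standard_normal(shape) * sd * np.sqrt(1.0 - phi * phi)
    innov[:, 0] = rng.standard_normal(shape[0]) * sd
    return lfilter([1.0], [1.0, -phi], innov, axis=1)


from functools import lru_cache


@lru_cache(maxsize=None)
def _unit_bump(rise: int, fall: int) -> np.ndarray:
    """Unit-height asymmetric triangular profile: linear rise then recovery."""
    up = np.arange(1, rise + 1) / rise
    down = 1.0 - np.arange(1, fall + 1) / fall
    prof = np.concatenate([up, down])
    prof.setflags(write=False)
    return prof


def _add_bump(row: np.ndarray, start: int, rise: int, fall: int,
              height: float) -> None:
    """Add an event bump to a window in place (truncated at the edge)."""
    prof = _unit_bump(rise, fall)
    end = min(row.size, start + prof.size)
    row[start:end] += height * prof[: end - start]


def generate_patient_day(
    params: PatientParams,
    day_index: int,
    dying_phase: bool,
    rng: np.random.Generator,
) -> dict[str, list[tuple[int, np.ndarray]]]:
    """Generate one day of windowed HR and SpO2 segments for one patient.

    Returns a mapping signal -> list of ``(window_start_s, values[300])``.
    ``windows_per_day`` windows are placed on the 600 s day grid, evenly
    spread across the day (contiguous when windows_per_day == 144).
    """
    cfg = params.config
    w = cfg.windows_per_day
    slots = (np.arange(w) * SLOTS_PER_DAY) // w
    starts = day_index * DAY_S + slots * WINDOW_S
    t = starts[:, None] + np.arange(WINDOW_LEN) * SAMPLE_INTERVAL_S

    var_factor = cfg.premortal_variability_factor if dying_phase else 1.0
    acc_factor = cfg.premortal_acceleration_factor if dying_phase else 1.0

    # --- heart rate -------------------------------------------------------
    hr = np.full((w, WINDOW_LEN), params.hr_baseline, dtype=float)
    hr += (cfg.hr_wander_amplitude_bpm * var_factor
           * np.sin(2 * np.pi * t / cfg.hr_wander_period_s
                    + params.wander_phase))
    hr += _ar1_noise(rng, (w, WINDOW_LEN), cfg.hr_variability_sd_bpm * var_factor)

    accel_rate = cfg.hr_acceleration_rate_per_min * acc_factor * 10.0
    decel_rate = (cfg.premortal_decel_rate_per_hour / 6.0) if dying_phase else 0.0
    n_accel = rng.poisson(accel_rate, size=w)
    n_decel = rng.poisson(decel_rate, size=w)
    for i in range(w):
        for _ in range(n_accel[i]):
            start = int(rng.integers(0, WINDOW_LEN))
            height = cfg.hr_acceleration_height_bpm * (0.5 + rng.random())
            _add_bump(hr[i], start, int(rng.integers(4, 9)),
                      int(rng.integers(8, 16)), height)
        for _ in range(n_decel[i]):
            start = int(rng.integers(0, WINDOW_LEN))
            depth = cfg.premortal_decel_depth_bpm * (0.6 + 0.8 * rng.random())
            _add_bump(hr[i], start, int(rng.integers(5, 12)),
                      int(rng.integers(10, 30)), -depth)
    np.maximum(hr, 20.0, out=hr)

    # --- oxygen saturation ------------------------------------------------
    spo2 = np.full((w, WINDOW_LEN), params.spo2_baseline, dtype=float)
    if dying_phase and params.death_day is not None:
        days_into_phase = (cfg.premortal_window_days
                           - (params.death_day - day_index))
        spo2 += cfg.premortal_spo2_drift_pct_per_day * days_into_phase
    spo2 += _ar1_noise(rng, (w, WINDOW_LEN), cfg.spo2_noise_sd_pct)

    desat_rate = cfg.desat_rate_per_hour / 6.0
    n_desat = rng.poisson(desat_rate, size=w)
    for i in range(w):
        for _ in range(n_desat[i]):
            start = int(rng.integers(0, WINDOW_LEN))
            depth = cfg.desat_depth_pct * (0.4 + 1.2 * rng.random())
            _add_bump(spo2[i], start, int(rng.integers(3, 8)),
                      int(rng.integers(10, 40)), -depth)
    if cfg.masimo_averaging:
        # crude emulation of 8 s oximeter averaging: 4-sample moving mean
        kernel = np.ones(4) / 4.0
        pad = np.concatenate([spo2[:, :1].repeat(3, axis=1), spo2], axis=1)
        spo2 = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="valid"), 1, pad)
    np.clip(spo2, 0.5, 100.0, out=spo2)

    return {
        "HR": [(int(starts[i]), hr[i]) for i in range(w)],
        "SPO2": [(int(starts[i]), spo2[i]) for i in range(w)],
    }


# ---------------------------------------------------------------------------
# cohort-level generation


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int | None = None) -> np.ndarray:
    draws = rng.normal(mean, sd, size=size if size else 1)
    for _ in range(100):
        bad = (draws < lo) | (draws > hi)
        if not bad.any():
            break
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(draws, lo, hi)


def _sample_outcomes(config: CohortConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    n_die = int(round(config.death_fraction * n))
    died = np.zeros(n, dtype=bool)
    died[rng.choice(n, size=n_die, replace=False)] = True

    sd = max((config.stay_days_max - config.stay_days_min) / 4.0, 0.5)
    stays = np.rint(_truncated_normal(
        rng, config.stay_days_mean, sd,
        config.stay_days_min, config.stay_days_max, size=n)).astype(int)

    ga = np.where(
        died,
        _truncated_normal(rng, 32.4, 4.4, 24.0, 42.0, size=n),
        _truncated_normal(rng, 34.7, 4.5, 24.0, 42.0, size=n),
    )
    bw = np.clip(0.155 * ga - 2.9 + rng.normal(0.0, 0.3, size=n), 0.4, 5.0)
    apgar = np.where(
        died,
        np.rint(_truncated_normal(rng, 5.5, 2.0, 0, 10, size=n)),
        np.rint(_truncated_normal(rng, 8.0, 1.2, 0, 10, size=n)),
    ).astype(int)
    sex = np.where(rng.random(n) < 0.43, "F", "M")

    ids = [f"P{i:05d}" for i in range(n)]
    last_day = stays - 1
    return pd.DataFrame({
        "patient_id": ids,
        "admit_day": np.zeros(n, dtype=int),
        "last_day": last_day,
        "died": died,
        "death_day": np.where(died, last_day, -1),
        "ga_weeks": np.round(ga, 1),
        "birth_weight_kg": np.round(bw, 3),
        "sex": sex,
        "apgar5": apgar,
    })


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[VitalSeries], pd.DataFrame]:
    """Generate a full labeled cohort: vitals series plus outcomes table.

    Deterministic for a fixed ``config.seed``: one RNG stream is spawned per
    patient from the master seed, so per-patient records are reproducible
    even under parallel generation.
    """
    master = np.random.SeedSequence(config.seed)
    outcome_rng = np.random.default_rng(master.spawn(1)[0])
    outcomes = _sample_outcomes(config, outcome_rng)

    patient_seeds = master.spawn(config.n_patients)
    series: list[VitalSeries] = []
    for i, row in outcomes.iterrows():
        rng = np.random.default_rng(patient_seeds[i])
        death_day = int(row.death_day) if row.died else None
        params = PatientParams(
            patient_id=row.patient_id,
            hr_baseline=float(rng.normal(config.hr_baseline_bpm,
                                         config.hr_baseline_sd_bpm)),
            spo2_baseline=float(np.clip(
                rng.normal(config.spo2_baseline_pct,
                           config.spo2_baseline_sd_pct), 85.0, 99.5)),
            wander_phase=float(rng.uniform(0, 2 * np.pi)),
            death_day=death_day,
            config=config,
        )
        chunks: dict[str, list[tuple[int, np.ndarray]]] = {"HR": [], "SPO2": []}
        for day in range(int(row.admit_day), int(row.last_day) + 1):
            dying_phase = (
                death_day is not None
                and (death_day - day) < config.premortal_window_days
            )
            day_windows = generate_patient_day(params, day, dying_phase, rng)
            for sig in ("HR", "SPO2"):
                chunks[sig].extend(day_windows[sig])
        for sig in ("HR", "SPO2"):
            ts = np.concatenate([
                start + np.arange(WINDOW_LEN, dtype=np.int64) * SAMPLE_INTERVAL_S
                for start, _ in chunks[sig]
            ])
            vals = np.concatenate([v for _, v in chunks[sig]])
            series.append(VitalSeries(row.patient_id, sig, ts, vals))
    return series, outcomes


def write_cohort(
    series: Iterable[VitalSeries],
    outcomes: pd.DataFrame,
    directory: str | Path,
) -> dict[str, Path]:
    """Write vitals and outcomes as the package's delimited-text interchange.

    ``vitals.csv``: patient_id,timestamp_s,signal,value.
    ``outcomes.csv``: one row per patient. Round-trips losslessly through
    :func:`neoncts.vitals_io.read_vitals`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        vitals_path = directory / "vitals.csv"
        outcomes_path = directory / "outcomes.csv"
        frames = [
            pd.DataFrame({
                "patient_id": s.patient_id,
                "timestamp_s": s.timestamps,
                "signal": s.signal,
                "value": s.values,
            })
            for s in series
        ]
        vitals = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame(columns=["patient_id", "timestamp_s",
                                             "signal", "value"]))
        # %.17g guarantees float64 round-trips exactly through the text form
        vitals.to_csv(vitals_path, index=False, float_format="%.17g")
        outcomes.to_csv(outcomes_path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc
    return {"vitals": vitals_path, "outcomes": outcomes_path}
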