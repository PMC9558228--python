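"""Synthetic cohort generation: oximetry traces, covariates and MoCA outcomes.

The signal model is a mixture of a slow deterministic trend, a periodic
component and an AR(1) stochastic component with skewed (hence
time-irreversible) innovations.  A single mixing weight ``w`` moves the trace
from smooth/regular (w = 0) to irregular (w = 1) and monotonically raises its
sample entropy, so group-level entropy targets can be met by calibrating w.

All randomness flows from one root seed: subject i uses the i-th child of
``numpy.random.SeedSequence(seed)``, so any subject is regenerable alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .entropy import SampEnParams, sample_entropy
from .exceptions import CalibrationError
from .oximetry import BASELINE_SAMPLES, Rso2Series, write_series

DURATION_RANGE_MIN = (61.0, 157.0)

# Irregularity weights calibrated against the group entropy targets with
# calibrate_irregularity (m=2, r = 0.1 x SD, 30 series); regenerate with
# scripts or the CLI if the signal model changes.
CALIBRATED_W_NON_POCI = 0.140625
CALIBRATED_W_POCI = 0.1953125


@dataclass(frozen=True)
class SignalModelParams:
    """Knobs of the synthetic rSO2 signal generator."""

    baseline_level: float = 73.5
    intraop_drop: float = 3.0  # mean intraop level sits below baseline
    drift_amplitude: float = 4.0
    trend_cycles: float = 1.25  # slow-trend cycles over the whole record
    oscillation_period_s: float = 360.0
    oscillation_amplitude: float = 2.0
    ar_coefficient: float = 0.85
    noise_sd: float = 1.8
    innovation_skewness: float = 2.0  # 0 = Gaussian innovations
    irregularity_weight: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.irregularity_weight <= 1.0:
            raise ValueError("irregularity_weight must lie in [0, 1]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.baseline_level <= 100:
            raise ValueError("baseline_level must lie in (0, 100]")


def _ar1(n: int, phi: float, sd: float, skewness: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with unit-variance standardized innovations of the
    requested skewness (gamma family; skewness 0 falls back to Gaussian)."""
    if sd == 0:
        return np.zeros(n)
    if skewness > 0:
        shape = 4.0 / skewness**2
        eps = (rng.gamma(shape, 1.0, size=n) - shape) / math.sqrt(shape)
    else:
        eps = rng.standard_normal(n)
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    x = sps.lfilter([1.0], [1.0, -phi], innov_sd * eps)
    x[:] += (sd * eps[0] - innov_sd * eps[0]) * phi ** np.arange(n)  # stationary start
    return x


def generate_series(
    params: SignalModelParams,
    duration_min: float,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "synthetic",
    side: str = "left",
) -> Rso2Series:
    """One synthetic trace: 60 baseline samples then an intraoperative
    segment of ``round(duration_min * 30)`` samples at 2 s, clipped to
    [0, 100] and deterministic in the seed."""
    if not DURATION_RANGE_MIN[0] <= duration_min <= DURATION_RANGE_MIN[1]:
        raise ValueError(
            f"duration {duration_min} min outside the supported range {DURATION_RANGE_MIN}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_min * 60.0 / 2.0))

    baseline_seg = params.baseline_level + 0.2 * params.noise_sd * rng.standard_normal(
        BASELINE_SAMPLES
    )

    t = np.arange(n, dtype=float)
    trend_phase = rng.uniform(0.0, 2.0 * np.pi)
    trend = params.drift_amplitude * np.sin(
        2.0 * np.pi * params.trend_cycles * t / n + trend_phase
    )
    osc_phase = rng.uniform(0.0, 2.0 * np.pi)
    periodic = params.oscillation_amplitude * np.sin(
        2.0 * np.pi * t * 2.0 / params.oscillation_period_s + osc_phase
    )
    w = params.irregularity_weight
    stochastic = _ar1(n, params.ar_coefficient, params.noise_sd, params.innovation_skewness, rng)
    intraop = (
        params.baseline_level
        - params.intraop_drop
        + trend
        + (1.0 - w) * periodic
        + w * stochastic
    )

    values = np.clip(np.concatenate([baseline_seg, intraop]), 0.0, 100.0)
    return Rso2Series(
        subject_id=subject_id,
        values=values,
        baseline_window=(0, BASELINE_SAMPLES),
        intraop_window=(BASELINE_SAMPLES, BASELINE_SAMPLES + n),
        side=side,
    )


def _mean_sampen(
    w: float,
    base_params: SignalModelParams,
    durations: np.ndarray,
    seeds: list[np.random.SeedSequence],
    m: int,
    r_coef: float,
) -> float:
    vals = []
    for dur, ss in zip(durations, seeds):
        params = replace(base_params, irregularity_weight=w)
        series = generate_series(params, dur, seed=np.random.default_rng(ss))
        res = sample_entropy(series.intraop_values, SampEnParams(m=m, r_coefficient=r_coef))
        if res.defined:
            vals.append(res.value)
    if not vals:
        raise CalibrationError("sample entropy undefined on every calibration series")
    return float(np.mean(vals))


def calibrate_irregularity(
    target_sampen_mean: float,
    m: int = 2,
    r_coef: float = 0.1,
    tolerance: float = 0.02,
    base_params: SignalModelParams | None = None,
    n_series: int = 30,
    seed: int = 20220929,
    max_iter: int = 40,
) -> float:
    """Bisect the mixing weight until the mean SampEn of ``n_series`` seeded
    series is within ``tolerance`` of the target.

    The same per-series seeds and durations are reused at every trial weight,
    so the objective is a smooth monotone function of w.
    """
    base = base_params if base_params is not None else SignalModelParams()
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n_series + 1)
    dur_rng = np.random.default_rng(seeds[-1])
    durations = dur_rng.uniform(*DURATION_RANGE_MIN, size=n_series)
    series_seeds = seeds[:n_series]

    lo, hi = 0.0, 1.0
    f_lo = _mean_sampen(lo, base, durations, series_seeds, m, r_coef)
    f_hi = _mean_sampen(hi, base, durations, series_seeds, m, r_coef)
    if not f_lo - tolerance <= target_sampen_mean <= f_hi + tolerance:
        raise CalibrationError(
            f"target {target_sampen_mean} outside achievable mean-SampEn range "
            f"[{f_lo:.4f}, {f_hi:.4f}] for this signal model"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _mean_sampen(mid, base, durations, series_seeds, m, r_coef)
        if abs(f_mid - target_sampen_mean) <= tolerance:
            return mid
        if f_mid < target_sampen_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# cohort-level generation


#: per-group Bernoulli prevalences (non-POCI, POCI) of the binary covariates
DEFAULT_PREVALENCES: dict[str, tuple[float, float]] = {
    "male": (23 / 24, 32 / 33),
    "education_gt12": (14 / 24, 23 / 33),
    "left_side": (8 / 24, 13 / 33),
    "symptomatic": (23 / 24, 28 / 33),
    "hypertension": (21 / 24, 21 / 33),
    "hyperlipidemia": (17 / 24, 19 / 33),
    "diabetes": (10 / 24, 13 / 33),
    "coronary_heart_disease": (6 / 24, 1 / 33),
    "stroke_history": (9 / 24, 10 / 33),
    "tia_history": (11 / 24, 14 / 33),
    "smoke_history": (16 / 24, 24 / 33),
    "alcohol_history": (18 / 24, 23 / 33),
    "antiplatelet": (21 / 24, 26 / 33),
    "anticoagulation": (0 / 24, 1 / 33),
    "lipid_altering": (22 / 24, 26 / 33),
    "glucose_lowering": (10 / 24, 10 / 33),
    "blood_pressure_lowering": (19 / 24, 14 / 33),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameterisation of a full synthetic study cohort.

    Two-element tuples are (non-POCI, POCI) group values throughout.
    """

    n_poci: int = 33
    n_non_poci: int = 24
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    age_mean_sd: tuple = ((65.1, 8.3), (64.8, 7.1))
    moca_pre_mean_sd: tuple = ((20.3, 3.9), (18.0, 4.3))
    sampen_targets: tuple = ((0.262, 0.121), (0.372, 0.183))
    baseline_rso2_mean_sd: tuple = ((73.4, 5.1), (74.0, 4.2))
    duration_range_min: tuple = DURATION_RANGE_MIN
    sampling_interval: float = 2.0
    irregularity_weights: tuple = (CALIBRATED_W_NON_POCI, CALIBRATED_W_POCI)
    signal_params: SignalModelParams = field(default_factory=SignalModelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poci < 2 or self.n_non_poci < 2:
            raise ValueError("group sizes must be at least 2")
        for name, (p0, p1) in self.prevalences.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")
        for pair in (self.moca_pre_mean_sd, self.sampen_targets, self.baseline_rso2_mean_sd):
            for _, sd in pair:
                if sd <= 0:
                    raise ValueError("all SDs must be positive")


def _truncated_normal_int(
    rng: np.random.Generator, mean: float, sd: float, low: int, high: int
) -> int:
    a, b = (low - mean) / sd, (high - mean) / sd
    draw = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return int(np.clip(round(float(draw)), low, high))


def _subject_record(
    spec: CohortSpec, idx: int, is_poci: bool, rng: np.random.Generator
) -> dict:
    g = 1 if is_poci else 0
    rec: dict = {"subject_id": f"S{idx + 1:03d}", "poci_true": int(is_poci)}
    for name, probs in spec.prevalences.items():
        rec[name] = int(rng.random() < probs[g])
    age_mean, age_sd = spec.age_mean_sd[g]
    rec["age"] = round(float(rng.normal(age_mean, age_sd)), 1)

    moca_mean, moca_sd = spec.moca_pre_mean_sd[g]
    # pre-score supports chosen so the +1 education adjustment can never hit
    # the 30-point ceiling after the postoperative delta, keeping the >=3
    # labelling rule exactly invertible
    if is_poci:
        pre = _truncated_normal_int(rng, moca_mean, moca_sd, 0, 23)
        delta = int(rng.integers(3, 7))
    else:
        pre = _truncated_normal_int(rng, moca_mean, moca_sd, 2, 27)
        delta = int(rng.integers(-2, 3))
    rec["moca_pre_raw"] = pre
    rec["moca_post_raw"] = pre + delta

    bl_mean, bl_sd = spec.baseline_rso2_mean_sd[g]
    rec["baseline_level"] = float(np.clip(rng.normal(bl_mean, bl_sd), 55.0, 92.0))
    rec["duration_min"] = float(rng.uniform(*spec.duration_range_min))
    rec["side"] = "left" if rec.pop("left_side") else "right"
    return rec


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
    with_series: bool = True,
) -> tuple[pd.DataFrame, dict[str, Rso2Series]]:
    """Synthesise the manifest and (optionally) one trace per subject.

    Returns the manifest DataFrame and a dict of in-memory series.  When
    ``out_dir`` is given, writes ``cohort.csv`` and ``series/<id>.csv`` pairs
    in the formats the readers consume.
    """
    n_total = spec.n_poci + spec.n_non_poci
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(n_total + 1)
    order_rng = np.random.default_rng(children[-1])
    labels = np.zeros(n_total, dtype=int)
    labels[: spec.n_poci] = 1
    order_rng.shuffle(labels)

    records = []
    series_map: dict[str, Rso2Series] = {}
    for i in range(n_total):
        rng = np.random.default_rng(children[i])
        rec = _subject_record(spec, i, bool(labels[i]), rng)
        if with_series:
            params = replace(
                spec.signal_params,
                baseline_level=rec["baseline_level"],
                irregularity_weight=spec.irregularity_weights[labels[i]],
            )
            series = generate_series(
                params,
                rec["duration_min"],
                seed=rng,
                subject_id=rec["subject_id"],
                side=rec["side"],
            )
            series_map[rec["subject_id"]] = series
            rec["n_points"] = series.n_intraop
            rec["duration_min"] = series.n_intraop / 30.0
        records.append(rec)

    manifest = pd.DataFrame.from_records(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out_dir / "cohort.csv", index=False)
        if with_series:
            for sid, series in series_map.items():
                write_series(series, out_dir / "series" / f"{sid}.csv")
    return manifest, series_map


def sample_feature_cohort(
    spec: CohortSpec,
    n_poci: int | None = None,
    n_non_poci: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fast feature-level cohort: SampEn01 and covariates drawn directly from
    the spec's group distributions, without synthesising traces.

    Used for large-sample statistical checks where per-trace entropy
    estimation would be wasteful.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = spec.n_poci if n_poci is None else n_poci
    n0 = spec.n_non_poci if n_non_poci is None else n_non_poci
    rows = []
    for g, n in ((0, n0), (1, n1)):
        mu, sd = spec.sampen_targets[g]
        moca_mu, moca_sd = spec.moca_pre_mean_sd[g]
        sampen = rng.normal(mu, sd, size=n)
        moca = np.clip(np.round(rng.normal(moca_mu, moca_sd, size=n)), 0, 30)
        for k in range(n):
            row = {"poci": g, "sampen01": float(sampen[k]), "moca_pre": float(moca[k])}
            for name, probs in spec.prevalences.items():
                row[name] = int(rng.random() < probs[g])
            rows.append(row)
    return pd.DataFrame(rows)
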