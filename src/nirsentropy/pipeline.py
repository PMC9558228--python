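"""End-to-end study pipeline: simulate -> features -> outcome -> statistics.

Produces the four report tables (baseline characteristics, oximetry/entropy
comparison, logistic models, ROC summary) as CSV files plus a JSON run log
recording every tunable setting and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cognition import classify_poci_raw
from .entropy import (
    DEFAULT_M,
    DEFAULT_R_COEFFICIENTS,
    SampEnParams,
    coefficient_label,
    sample_entropy,
)
from .exceptions import ConfigurationError
from .inference import (
    combined_model_auc,
    compare_categorical,
    compare_means,
    multivariate_logistic_backward_lr,
    roc_auc,
    univariate_logistic,
)
from .oximetry import Rso2Series, desaturation_metrics, summarize
from .simulate import CohortSpec, generate_cohort
from .surrogate import surrogate_test

log = logging.getLogger(__name__)

BINARY_COVARIATES = [
    "male",
    "education_gt12",
    "symptomatic",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "coronary_heart_disease",
    "stroke_history",
    "tia_history",
    "smoke_history",
    "alcohol_history",
    "antiplatelet",
    "anticoagulation",
    "lipid_altering",
    "glucose_lowering",
    "blood_pressure_lowering",
]

DESAT_FRACTIONS = (1.0, 0.9, 0.8)


@dataclass
class RunConfig:
    """All tunables of a pipeline run; everything lands in the run log."""

    out_dir: Path = Path("study_out")
    seed: int = 0
    n_poci: int = 33
    n_non_poci: int = 24
    m: int = DEFAULT_M
    r_coefficients: tuple = DEFAULT_R_COEFFICIENTS
    strict_tolerance: bool = False
    surrogate_enabled: bool = True
    n_surrogates: int = 99
    surrogate_method: str = "amplitude_adjusted"
    surrogate_alpha: float = 0.05
    ci_method: str = "delong"
    t_variant: str = "pooled"
    p_enter: float = 0.10
    p_remove: float = 0.10

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not self.r_coefficients:
            raise ConfigurationError("entropy coefficient grid must be nonempty")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "r_coefficients" in data:
            data = {**data, "r_coefficients": tuple(data["r_coefficients"])}
        return cls(**data)


def extract_features(
    series_map: dict[str, Rso2Series],
    m: int = DEFAULT_M,
    coefficients=DEFAULT_R_COEFFICIENTS,
    strict: bool = False,
    surrogate_enabled: bool = True,
    n_surrogates: int = 99,
    surrogate_method: str = "amplitude_adjusted",
    surrogate_alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject signal features: summary stats, desaturation burden at the
    three standard thresholds, the SampEn grid and (optionally) the surrogate
    nonlinearity test."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(series_map))
    rows = []
    for (sid, series), child in zip(sorted(series_map.items()), children):
        summ = summarize(series)
        row: dict = {
            "subject_id": sid,
            "baseline_rso2": summ.baseline,
            "mean_rso2": summ.mean,
            "lowest_rso2": summ.lowest,
            "highest_rso2": summ.highest,
            "n_points": summ.n_points,
            "duration_min": summ.duration_min,
        }
        for fraction in DESAT_FRACTIONS:
            met = desaturation_metrics(series, summ.baseline, fraction)
            tag = f"{int(round(fraction * 100))}"
            row[f"desat_duration_{tag}"] = met.duration
            row[f"desat_area_{tag}"] = met.area
        for coef in coefficients:
            res = sample_entropy(
                series.intraop_values, SampEnParams(m=m, r_coefficient=coef, strict=strict)
            )
            label = coefficient_label(coef).lower()
            row[label] = res.value
            row[f"{label}_a"] = res.a_count
            row[f"{label}_b"] = res.b_count
        if surrogate_enabled:
            test = surrogate_test(
                series.intraop_values,
                n_surrogates=n_surrogates,
                method=surrogate_method,
                alpha=surrogate_alpha,
                seed=np.random.default_rng(child),
            )
            row["surrogate_statistic"] = test.observed_statistic
            row["surrogate_p"] = test.p_value
            row["nonlinear"] = int(test.reject_null)
        rows.append(row)
    return pd.DataFrame(rows)


def label_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append adjusted-MoCA delta and POCI label columns to the manifest."""
    out = cohort.copy()
    deltas, labels = [], []
    for _, row in out.iterrows():
        lab = classify_poci_raw(
            int(row["moca_pre_raw"]), int(row["moca_post_raw"]), bool(row["education_gt12"])
        )
        deltas.append(lab.delta)
        labels.append(int(lab.poci))
    out["moca_delta"] = deltas
    out["poci"] = labels
    return out


def _categorical_rows(df: pd.DataFrame) -> list[dict]:
    rows = []
    for name in BINARY_COVARIATES:
        if name not in df.columns:
            continue
        sub = df.dropna(subset=[name])
        table = [
            [int(((sub["poci"] == 0) & (sub[name] == 0)).sum()),
             int(((sub["poci"] == 0) & (sub[name] == 1)).sum())],
            [int(((sub["poci"] == 1) & (sub[name] == 0)).sum()),
             int(((sub["poci"] == 1) & (sub[name] == 1)).sum())],
        ]
        try:
            res = compare_categorical(table)
            rows.append(
                {
                    "variable": name,
                    "non_poci_yes": table[0][1],
                    "non_poci_n": sum(table[0]),
                    "poci_yes": table[1][1],
                    "poci_n": sum(table[1]),
                    "method": res.method,
                    "statistic": res.statistic,
                    "p": res.p,
                }
            )
        except Exception as exc:  # degenerate margins on tiny cohorts
            log.warning("skipping categorical row %s: %s", name, exc)
    return rows


def _continuous_row(df: pd.DataFrame, name: str, variant: str) -> dict:
    a = df.loc[df["poci"] == 0, name].dropna().to_numpy(dtype=float)
    b = df.loc[df["poci"] == 1, name].dropna().to_numpy(dtype=float)
    try:
        res = compare_means(a, b, variant=variant)
    except ValueError as exc:  # e.g. every value tied in a rank test
        log.warning("comparison of %s degenerate: %s", name, exc)
        return {
            "variable": name,
            "non_poci_mean": float(np.mean(a)), "non_poci_sd": float(np.std(a, ddof=1)),
            "poci_mean": float(np.mean(b)), "poci_sd": float(np.std(b, ddof=1)),
            "variant": variant, "statistic": float("nan"), "p": float("nan"),
        }
    return {
        "variable": name,
        "non_poci_mean": res.group_a.mean,
        "non_poci_sd": res.group_a.sd,
        "poci_mean": res.group_b.mean,
        "poci_sd": res.group_b.sd,
        "variant": variant,
        "statistic": res.statistic,
        "p": res.p,
    }


def analyze_cohort(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    ci_method: str = "delong",
    t_variant: str = "pooled",
    p_enter: float = 0.10,
    p_remove: float = 0.10,
) -> dict[str, pd.DataFrame]:
    """Full statistics layer on a labelled cohort + feature table.

    Returns the four report tables keyed ``table1``, ``table2``, ``table3``,
    ``roc`` (plus ``roc_points`` curves).
    """
    df = label_outcomes(cohort).merge(features, on="subject_id", how="inner")
    if df["poci"].nunique() < 2:
        raise ValueError("cohort must contain both POCI and non-POCI subjects")

    # -- baseline characteristics
    t1_rows = _categorical_rows(df)
    for cont in ("age", "moca_pre_raw"):
        if cont in df.columns:
            t1_rows.append(_continuous_row(df, cont, t_variant))
    table1 = pd.DataFrame(t1_rows)

    # -- oximetry + entropy comparison
    t2_rows = []
    for name in ("baseline_rso2", "mean_rso2", "lowest_rso2", "highest_rso2"):
        t2_rows.append(_continuous_row(df, name, t_variant))
    for tag in ("100", "90", "80"):
        for kind in ("duration", "area"):
            t2_rows.append(_continuous_row(df, f"desat_{kind}_{tag}", "mann_whitney"))
    sampen_cols = [c for c in features.columns if c.startswith("sampen") and not c[-2:] in ("_a", "_b")]
    for name in sampen_cols:
        t2_rows.append(_continuous_row(df.dropna(subset=[name]), name, t_variant))
    table2 = pd.DataFrame(t2_rows)

    # -- logistic models
    headline = "sampen01" if "sampen01" in df.columns else sampen_cols[0]
    candidates = [headline, "moca_pre_raw"] + [c for c in BINARY_COVARIATES if c in df.columns]
    model_df = df.dropna(subset=[headline])
    y = model_df["poci"].to_numpy()
    t3_rows = []
    univariate_p: dict[str, float] = {}
    for name in candidates:
        x = model_df[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            log.warning("skipping constant predictor %s", name)
            continue
        fit = univariate_logistic(y, x, per_sd=(name == headline), name=name)
        term = fit.terms[0]
        univariate_p[name] = term.p
        t3_rows.append(
            {
                "variable": name + (" (per SD)" if name == headline else ""),
                "scope": "univariate",
                "or": term.odds_ratio,
                "ci_low": term.ci_low,
                "ci_high": term.ci_high,
                "p": term.p,
                "separation": fit.separation,
            }
        )
    entered = [n for n, p in univariate_p.items() if p < p_enter]
    if entered:
        multi = multivariate_logistic_backward_lr(
            y,
            model_df[entered],
            p_remove=p_remove,
            per_sd=[headline] if headline in entered else [],
        )
        for term in multi.terms:
            t3_rows.append(
                {
                    "variable": term.name + (" (per SD)" if term.name == headline else ""),
                    "scope": "multivariate",
                    "or": term.odds_ratio,
                    "ci_low": term.ci_low,
                    "ci_high": term.ci_high,
                    "p": term.p,
                    "separation": multi.separation,
                }
            )
        removal_trace = multi.selection_trace
    else:
        removal_trace = ()
    table3 = pd.DataFrame(t3_rows)

    # -- ROC: headline entropy alone and the combined clinical model
    roc_rows = []
    roc_points = {}
    scores = model_df[headline].to_numpy(dtype=float)
    single = roc_auc(scores, y, ci_method=ci_method)
    roc_rows.append(_roc_row(f"{headline} alone", single))
    roc_points[f"{headline}_alone"] = _roc_curve(scores, y)

    combo_cols = [headline]
    for extra in ("moca_pre_raw", "blood_pressure_lowering"):
        if extra in model_df.columns:
            combo_cols.append(extra)
    combined, _ = combined_model_auc(y, model_df[combo_cols], ci_method=ci_method)
    roc_rows.append(_roc_row(f"{headline} + MoCA + BP-lowering", combined))
    roc = pd.DataFrame(roc_rows)

    curves = []
    for label, (fpr, tpr) in roc_points.items():
        curves.append(pd.DataFrame({"model": label, "fpr": fpr, "tpr": tpr}))
    return {
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "roc": roc,
        "roc_points": pd.concat(curves, ignore_index=True),
        "labelled": df,
        "removal_trace": pd.DataFrame(removal_trace, columns=["removed", "lr_p"]),
    }


def _roc_row(model: str, res) -> dict:
    return {
        "model": model,
        "auc": res.auc,
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "ci_method": res.ci_method,
        "p_vs_chance": res.p_vs_chance,
    }


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC points (fpr, tpr) over all score thresholds."""
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(labels)[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return fpr, tpr


def run_study(config: RunConfig) -> dict[str, Path]:
    """Simulate a cohort, extract features, run the statistics layer and
    write the report bundle; fully deterministic in ``config.seed``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    spec = CohortSpec(n_poci=config.n_poci, n_non_poci=config.n_non_poci, seed=config.seed)
    cohort, series_map = generate_cohort(spec, out_dir=out)
    features = extract_features(
        series_map,
        m=config.m,
        coefficients=config.r_coefficients,
        strict=config.strict_tolerance,
        surrogate_enabled=config.surrogate_enabled,
        n_surrogates=config.n_surrogates,
        surrogate_method=config.surrogate_method,
        surrogate_alpha=config.surrogate_alpha,
        seed=config.seed + 1,
    )
    features.to_csv(out / "features.csv", index=False)

    tables = analyze_cohort(
        cohort,
        features,
        ci_method=config.ci_method,
        t_variant=config.t_variant,
        p_enter=config.p_enter,
        p_remove=config.p_remove,
    )
    paths: dict[str, Path] = {}
    for key in ("table1", "table2", "table3", "roc", "roc_points", "removal_trace"):
        path = out / f"{key}.csv"
        tables[key].to_csv(path, index=False, float_format="%.10g")
        paths[key] = path

    run_log = {
        "package_version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "cohort": {"n_total": int(len(cohort)), "n_poci": int(tables["labelled"]["poci"].sum())},
        "design_decisions": {
            "desaturation_rule": "strict < threshold, rectangular 2-s dwell",
            "entropy_match_criterion": "d < r" if config.strict_tolerance else "d <= r",
            "categorical_policy": "fisher if min expected < 1, yates if < 5, else pearson",
            "surrogate_rule": "two-sided rank p = 2*min(rank_lo, rank_hi)/(K+1)",
            "irregularity_weights": list(spec.irregularity_weights),
        },
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2, sort_keys=True))
    paths["run_log"] = log_path
    paths["cohort"] = out / "cohort.csv"
    paths["features"] = out / "features.csv"
    return paths
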