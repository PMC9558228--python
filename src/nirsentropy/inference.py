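"""Group-comparison, logistic-regression, ROC and power statistics.

The categorical-test policy mirrors common clinical-software behaviour for
2x2 tables: Fisher's exact test when the minimum expected count is below 1,
Yates-corrected chi-square when it is below 5, plain Pearson chi-square
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import DegenerateTableError

Z_95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# categorical comparisons


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    method: str  # pearson | yates | fisher
    statistic: float  # chi-square value; NaN for fisher
    p: float
    min_expected: float
    df: int = 1


def compare_categorical(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """2x2 test chosen by the minimum expected count (<1 Fisher, <5 Yates,
    else Pearson).  Fisher p is the two-sided probability-mass rule."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateTableError("both margins of the 2x2 table must be nonzero")

    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    min_expected = float(expected.min())

    if min_expected < 1.0:
        _, p = stats.fisher_exact(obs.astype(int), alternative="two-sided")
        return ContingencyResult(obs.astype(int), "fisher", float("nan"), float(p), min_expected)
    correction = min_expected < 5.0
    res = stats.chi2_contingency(obs, correction=correction)
    method = "yates" if correction else "pearson"
    return ContingencyResult(obs.astype(int), method, float(res.statistic), float(res.pvalue), min_expected)


# ---------------------------------------------------------------------------
# continuous comparisons


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class MeanComparison:
    group_a: GroupSummary
    group_b: GroupSummary
    variant: str  # pooled | welch | mann_whitney
    statistic: float  # t, or z for the rank test
    p: float


def _as_summary(group) -> tuple[GroupSummary, np.ndarray | None]:
    if isinstance(group, GroupSummary):
        return group, None
    if isinstance(group, tuple) and len(group) == 3:
        n, mean, sd = group
        return GroupSummary(int(n), float(mean), float(sd)), None
    raw = np.asarray(group, dtype=float).ravel()
    return GroupSummary(raw.size, float(np.mean(raw)), float(np.std(raw, ddof=1))), raw


def compare_means(group_a, group_b, variant: str = "pooled") -> MeanComparison:
    """Two-sample location test from raw values or (n, mean, sd) summaries.

    ``pooled`` and ``welch`` work from summaries; ``mann_whitney`` (normal
    approximation with tie correction, no continuity correction) requires the
    raw samples.
    """
    sa, raw_a = _as_summary(group_a)
    sb, raw_b = _as_summary(group_b)
    if sa.n < 2 or sb.n < 2:
        raise ValueError("need n >= 2 in each group")

    if variant == "mann_whitney":
        if raw_a is None or raw_b is None:
            raise ValueError("Mann-Whitney requires raw values, not summaries")
        z, p = _mann_whitney_z(raw_a, raw_b)
        return MeanComparison(sa, sb, variant, z, p)

    if variant == "pooled":
        df = sa.n + sb.n - 2
        sp2 = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / df
        se = np.sqrt(sp2 * (1 / sa.n + 1 / sb.n))
    elif variant == "welch":
        va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (sa.mean - sb.mean) / se
    p = 2 * stats.t.sf(abs(t), df)
    return MeanComparison(sa, sb, variant, float(t), float(p))


def _mann_whitney_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Signed z for the Mann-Whitney U of group a, tie-corrected."""
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u1 = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        raise ValueError("degenerate samples: all values tied")
    z = (u1 - mu) / np.sqrt(sigma2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[LogisticTerm, ...]
    scope: str  # univariate | multivariate
    selection_trace: tuple[tuple[str, float], ...] = ()
    scaling: dict = field(default_factory=dict)  # predictor -> SD used for per-SD scaling
    separation: bool = False
    llf: float = float("nan")
    n: int = 0

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[sm.Logit, object, bool]:
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # separated data: Newton's Hessian is singular; BFGS still walks
            # toward the (divergent) MLE and gives usable coefficients
            separated = True
            res = model.fit(method="bfgs", disp=False, maxiter=500)
    if not separated:
        bse = _safe_attr(res, "bse", len(res.params))
        if not np.all(np.isfinite(bse)) or np.any(np.abs(res.params) > 25):
            separated = True
    return model, res, separated


def _safe_attr(res, attr: str, size: int) -> np.ndarray:
    try:
        values = np.asarray(getattr(res, attr), dtype=float)
    except np.linalg.LinAlgError:
        values = np.full(size, np.nan)
    return values


def _terms_from_fit(res, names: Sequence[str]) -> tuple[LogisticTerm, ...]:
    k = len(res.model.exog_names)
    params = pd.Series(np.asarray(res.params, dtype=float), index=res.model.exog_names)
    bse = pd.Series(_safe_attr(res, "bse", k), index=res.model.exog_names)
    pvals = pd.Series(_safe_attr(res, "pvalues", k), index=res.model.exog_names)
    out = []
    with np.errstate(over="ignore"):  # divergent separated fits overflow exp
        for name in names:
            beta = float(params[name])
            se = float(bse[name])
            out.append(
                LogisticTerm(
                    name=name,
                    coefficient=beta,
                    odds_ratio=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - Z_95 * se)),
                    ci_high=float(np.exp(beta + Z_95 * se)),
                    p=float(pvals[name]),
                )
            )
    return tuple(out)


def _prepare_predictors(X: pd.DataFrame, per_sd: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    X = X.astype(float).copy()
    scaling: dict[str, float] = {}
    for name in per_sd:
        sd = float(X[name].std(ddof=1))
        if sd == 0:
            raise ValueError(f"predictor {name!r} is constant; cannot scale per SD")
        X[name] = X[name] / sd
        scaling[name] = sd
    return X, scaling


def univariate_logistic(
    outcome: Sequence[int],
    predictor: Sequence[float],
    per_sd: bool = False,
    name: str = "x",
) -> LogisticFit:
    """Single-predictor maximum-likelihood logistic fit with Wald 95% CI.

    ``per_sd`` divides the predictor by its sample SD first, so the odds
    ratio is per one SD of the predictor.  Complete separation is flagged on
    the result rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame({name: np.asarray(predictor, dtype=float)})
    X, scaling = _prepare_predictors(X, [name] if per_sd else [])
    _, res, separated = _fit_logit(y, X)
    return LogisticFit(
        terms=_terms_from_fit(res, [name]),
        scope="univariate",
        scaling=scaling,
        separation=separated,
        llf=float(res.llf),
        n=int(y.size),
    )


def logistic_from_counts(n_unexposed_neg: int, n_unexposed_pos: int,
                         n_exposed_neg: int, n_exposed_pos: int) -> LogisticFit:
    """Univariate logistic fit expanded from 2x2 exposure/outcome counts."""
    y = np.concatenate([
        np.zeros(n_unexposed_neg), np.ones(n_unexposed_pos),
        np.zeros(n_exposed_neg), np.ones(n_exposed_pos),
    ])
    x = np.concatenate([
        np.zeros(n_unexposed_neg + n_unexposed_pos),
        np.ones(n_exposed_neg + n_exposed_pos),
    ])
    return univariate_logistic(y, x, name="exposure")


def multivariate_logistic_backward_lr(
    outcome: Sequence[int],
    candidates: pd.DataFrame,
    p_remove: float = 0.10,
    per_sd: Sequence[str] = (),
) -> LogisticFit:
    """Backward elimination by likelihood-ratio test.

    Starts from the full model over ``candidates`` and repeatedly drops the
    term with the largest LR p-value until every remaining term has LR
    p <= ``p_remove``.  The removal order and p-values are recorded in
    ``selection_trace``; reported CIs are Wald.
    """
    if candidates.shape[1] == 0:
        raise ValueError("candidate set must be nonempty")
    y = np.asarray(outcome, dtype=float)
    X, scaling = _prepare_predictors(candidates, per_sd)

    trace: list[tuple[str, float]] = []
    current = list(X.columns)
    separated_any = False
    while current:
        _, full, sep = _fit_logit(y, X[current])
        separated_any |= sep
        lr_p: dict[str, float] = {}
        for name in current:
            reduced_cols = [c for c in current if c != name]
            if reduced_cols:
                _, red, sep_r = _fit_logit(y, X[reduced_cols])
                llf_reduced = red.llf
                separated_any |= sep_r
            else:
                p0 = y.mean()
                llf_reduced = y.size * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))
            lr_stat = max(0.0, 2.0 * (full.llf - llf_reduced))
            lr_p[name] = float(stats.chi2.sf(lr_stat, df=1))
        worst = max(current, key=lambda nm: lr_p[nm])
        if lr_p[worst] <= p_remove:
            return LogisticFit(
                terms=_terms_from_fit(full, current),
                scope="multivariate",
                selection_trace=tuple(trace),
                scaling=scaling,
                separation=separated_any,
                llf=float(full.llf),
                n=int(y.size),
            )
        trace.append((worst, lr_p[worst]))
        current.remove(worst)
    return LogisticFit(
        terms=(),
        scope="multivariate",
        selection_trace=tuple(trace),
        scaling=scaling,
        separation=separated_any,
        llf=float("nan"),
        n=int(y.size),
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    ci_method: str  # delong | hanley_mcneil
    n_positive: int
    n_negative: int
    p_vs_chance: float


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:n1] - pos_ranks) / n0
    v01 = 1.0 - (all_ranks[n1:] - neg_ranks) / n1
    return v10, v01


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    ci_method: str = "delong",
) -> RocResult:
    """AUC by concordant-pair counting with a DeLong (default) or
    Hanley-McNeil 95% CI; higher scores indicate the positive class."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    v10, v01 = _placements(s, y)
    auc = float(np.mean(v10))

    if ci_method == "delong":
        s10 = float(np.var(v10, ddof=1)) if n1 > 1 else 0.0
        s01 = float(np.var(v01, ddof=1)) if n0 > 1 else 0.0
        se = float(np.sqrt(s10 / n1 + s01 / n0))
    elif ci_method == "hanley_mcneil":
        se = float(np.sqrt(_hanley_mcneil_var(auc, n1, n0)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    ci_low = max(0.0, auc - Z_95 * se)
    ci_high = min(1.0, auc + Z_95 * se)
    p = 2 * stats.norm.sf(abs(auc - 0.5) / se) if se > 0 else (1.0 if auc == 0.5 else 0.0)
    return RocResult(auc, se, ci_low, ci_high, ci_method, n1, n0, float(p))


def _hanley_mcneil_var(auc: float, n_positive: int, n_negative: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1 - auc)
        + (n_positive - 1) * (q1 - auc**2)
        + (n_negative - 1) * (q2 - auc**2)
    ) / (n_positive * n_negative)


def combined_model_auc(
    outcome: Sequence[int],
    variables: pd.DataFrame,
    ci_method: str = "delong",
) -> tuple[RocResult, LogisticFit]:
    """ROC of in-sample fitted probabilities from a logistic model on all
    ``variables`` (no selection)."""
    y = np.asarray(outcome, dtype=float)
    X = variables.astype(float)
    _, res, separated = _fit_logit(y, X)
    probs = np.asarray(res.predict(sm.add_constant(X, has_constant="add")))
    fit = LogisticFit(
        terms=_terms_from_fit(res, list(X.columns)),
        scope="multivariate",
        separation=separated,
        llf=float(res.llf),
        n=int(y.size),
    )
    return roc_auc(probs, y, ci_method=ci_method), fit


def auc_power(
    n_positive: int,
    n_negative: int,
    auc_null: float,
    auc_alt: float,
    alpha: float = 0.05,
) -> float:
    """Power of the two-sided z-test for AUC = ``auc_null`` against
    ``auc_alt``, with Hanley-McNeil variances under each hypothesis."""
    if not 0.5 <= auc_null < auc_alt < 1.0:
        raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
    if n_positive < 2 or n_negative < 2:
        raise ValueError("need at least 2 subjects per class")
    se0 = np.sqrt(_hanley_mcneil_var(auc_null, n_positive, n_negative))
    se1 = np.sqrt(_hanley_mcneil_var(auc_alt, n_positive, n_negative))
    z_crit = stats.norm.ppf(1 - alpha / 2)
    delta = auc_alt - auc_null
    return float(stats.norm.cdf((delta - z_crit * se0) / se1))
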