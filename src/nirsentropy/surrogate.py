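"""Surrogate-data test for nonlinear dynamics in a single series.

Null hypothesis: the series is a (possibly monotonically transformed) linear
Gaussian stochastic process.  Surrogates preserve the sample power spectrum
(phase randomisation) and, for the amplitude-adjusted variant (AAFT), the
exact marginal value distribution.  The discriminating statistic defaults to
third-order time-reversal asymmetry; significance is an exact two-sided rank
test of the observed statistic among the surrogate ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError, DegenerateToleranceError

DEFAULT_N_SURROGATES = 99
DEFAULT_ALPHA = 0.05
DEFAULT_LAG = 1

METHODS = ("phase_randomized", "amplitude_adjusted")


@dataclass(frozen=True)
class SurrogateTestResult:
    observed_statistic: float
    surrogate_statistics: tuple[float, ...]
    n_surrogates: int
    significance_level: float
    p_value: float
    reject_null: bool
    method: str


def _phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomise DFT phases under conjugate symmetry; amplitudes preserved."""
    n = x.size
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.size)
    phases[0] = 0.0  # keep the mean (DC term real)
    if n % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


def make_surrogate(
    values: Sequence[float],
    method: str = "amplitude_adjusted",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """One surrogate series of the same length as ``values``.

    ``phase_randomized`` preserves the power spectrum exactly;
    ``amplitude_adjusted`` (AAFT) additionally rank-remaps the result onto
    the original value distribution.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("series too short for surrogate construction")
    if np.ptp(x) == 0:
        raise DegenerateToleranceError("constant series has no surrogate ensemble")
    if method not in METHODS:
        raise ConfigurationError(f"unknown surrogate method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if method == "phase_randomized":
        return _phase_randomize(x, rng)

    # AAFT: gaussianise by rank, phase-randomise, then map the original
    # amplitudes back onto the new rank ordering.
    n = x.size
    gauss = np.sort(rng.standard_normal(n))
    order = np.argsort(x, kind="stable")
    y = np.empty(n)
    y[order] = gauss  # Gaussian series with the ranks of x
    y_surr = _phase_randomize(y, rng)
    result = np.empty(n)
    result[np.argsort(y_surr, kind="stable")] = np.sort(x)
    return result


def time_asymmetry_statistic(values: Sequence[float], lag: int = DEFAULT_LAG) -> float:
    """Third-order time-reversal asymmetry: E[d^3] / E[d^2]^(3/2), d = x(t+lag)-x(t)."""
    if lag < 1:
        raise ValueError(f"lag must be a positive integer, got {lag}")
    x = np.asarray(values, dtype=float)
    if x.size <= lag:
        raise ValueError(f"need more than lag={lag} points, got {x.size}")
    d = x[lag:] - x[:-lag]
    denom = float(np.mean(d * d))
    if denom == 0.0:
        raise DegenerateToleranceError("constant series: zero second moment of differences")
    return float(np.mean(d**3)) / denom**1.5


def _detrend(x: np.ndarray) -> np.ndarray:
    t = np.arange(x.size, dtype=float)
    coef = np.polyfit(t, x, 1)
    return x - np.polyval(coef, t)


def surrogate_test(
    values: Sequence[float],
    n_surrogates: int = DEFAULT_N_SURROGATES,
    method: str = "amplitude_adjusted",
    statistic: Callable[[np.ndarray], float] | None = None,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
    detrend: bool = True,
) -> SurrogateTestResult:
    """Two-sided rank test of ``statistic`` against a surrogate ensemble.

    Attained p = 2 * min(rank-low, rank-high) / (K + 1), where the ranks
    count the observed statistic among the K surrogate values inclusively on
    each tail; reject iff p <= alpha.  With the defaults (K = 99, alpha =
    0.05) the observed value must be more extreme than every surrogate.
    """
    if n_surrogates < 1:
        raise ConfigurationError("need at least one surrogate")
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")
    if 2.0 / (n_surrogates + 1) > alpha:
        raise ConfigurationError(
            f"{n_surrogates} surrogates cannot attain two-sided level {alpha}; "
            f"need at least {int(np.ceil(2.0 / alpha)) - 1}"
        )
    stat = statistic if statistic is not None else time_asymmetry_statistic
    x = np.asarray(values, dtype=float)
    if detrend:
        x = _detrend(x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = float(stat(x))
    surr_stats = np.array(
        [float(stat(make_surrogate(x, method=method, seed=rng))) for _ in range(n_surrogates)]
    )
    k = n_surrogates
    rank_low = 1 + int(np.sum(surr_stats <= observed))
    rank_high = 1 + int(np.sum(surr_stats >= observed))
    p = min(1.0, 2.0 * min(rank_low, rank_high) / (k + 1))
    return SurrogateTestResult(
        observed_statistic=observed,
        surrogate_statistics=tuple(surr_stats),
        n_surrogates=k,
        significance_level=alpha,
        p_value=p,
        reject_null=p <= alpha,
        method=method,
    )
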