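"""Sample entropy of uniformly sampled time series.

SampEn(m, r, N) = -log(A / B), where B counts pairs of length-m templates
within Chebyshev distance r of each other (self-matches excluded) and A
counts the pairs whose (m+1)-point extensions also match.  Both counts run
over the same template index range 1..N-m so that A/B is a valid conditional
probability; the normalisation constants cancel in the ratio and are never
materialised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DegenerateToleranceError

#: embedding length used throughout the analysis
DEFAULT_M = 2
#: tolerance grid, as multiples of the series SD
DEFAULT_R_COEFFICIENTS = (0.10, 0.15, 0.20, 0.25)
#: minimum series length for a trustworthy estimate
MIN_RECOMMENDED_N = 100


@dataclass(frozen=True)
class SampEnParams:
    """Parameterisation of a sample-entropy estimate.

    Exactly one of ``r_coefficient`` (multiple of the series SD) or
    ``r_absolute`` (tolerance in signal units) must be given; a coefficient
    is resolved against the series at computation time.
    """

    m: int = DEFAULT_M
    r_coefficient: float | None = None
    r_absolute: float | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding length m must be >= 1, got {self.m}")
        if (self.r_coefficient is None) == (self.r_absolute is None):
            raise ValueError("specify exactly one of r_coefficient, r_absolute")
        r = self.r_coefficient if self.r_absolute is None else self.r_absolute
        if r <= 0:
            raise ValueError(f"tolerance must be positive, got {r}")

    def resolve(self, values: Sequence[float]) -> float:
        """Return the absolute tolerance for ``values``."""
        if self.r_absolute is not None:
            return float(self.r_absolute)
        return resolve_tolerance(values, self.r_coefficient)


@dataclass(frozen=True)
class SampEnResult:
    """Match counts and the entropy estimate for one (m, r, N) triple.

    ``a_count``/``b_count`` are unordered template-pair match counts for
    length m+1 / length m.  ``value`` is NaN when either count is zero
    (undefined estimate); use :attr:`defined` to test.
    """

    m: int
    r_absolute: float
    n: int
    a_count: int
    b_count: int
    value: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def resolve_tolerance(values: Sequence[float], coefficient: float) -> float:
    """Absolute tolerance = coefficient x sample SD (ddof=1) of the series."""
    if coefficient <= 0:
        raise ValueError(f"coefficient must be positive, got {coefficient}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateToleranceError("need at least 2 points to estimate SD")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateToleranceError(
            "constant series has SD = 0; supply an absolute tolerance instead"
        )
    return coefficient * sd


def _match_counts(x: np.ndarray, m: int, r: float, strict: bool) -> tuple[int, int]:
    """Unordered pair counts (a, b) of (m+1)- and m-template Chebyshev matches.

    Vectorised over the trailing templates for each anchor index; O(N^2)
    work, O(N) memory.  Only templates with an (m+1)-point extension are
    considered (anchor range 1..N-m), for both counts.
    """
    n = x.size
    nt = n - m  # number of templates that extend to length m+1
    close = np.less if strict else np.less_equal
    a = 0
    b = 0
    for i in range(nt - 1):
        lo = i + 1
        dm = np.abs(x[i] - x[lo:nt])
        for k in range(1, m):
            np.maximum(dm, np.abs(x[i + k] - x[lo + k : nt + k]), out=dm)
        b += int(close(dm, r).sum())
        np.maximum(dm, np.abs(x[i + m] - x[lo + m : nt + m]), out=dm)
        a += int(close(dm, r).sum())
    return a, b


def sample_entropy(
    values: Sequence[float],
    params: SampEnParams | None = None,
    *,
    m: int | None = None,
    r_absolute: float | None = None,
    r_coefficient: float | None = None,
    strict: bool | None = None,
) -> SampEnResult:
    """Estimate SampEn(m, r, N) of ``values``.

    Either pass a :class:`SampEnParams`, or the keyword shortcuts.  The match
    criterion is ``d <= r`` by default (Richman-Moorman convention); set
    ``strict=True`` for ``d < r``.

    A result with ``a_count == 0`` (or ``b_count == 0``) carries ``value``
    NaN rather than raising: downstream consumers treat it as missing.
    """
    if params is None:
        params = SampEnParams(
            m=DEFAULT_M if m is None else m,
            r_coefficient=r_coefficient,
            r_absolute=r_absolute,
            strict=bool(strict),
        )
    elif m is not None or r_absolute is not None or r_coefficient is not None:
        raise ValueError("pass either params or keyword shortcuts, not both")

    x = np.asarray(values, dtype=float)
    n = int(x.size)
    if n < params.m + 2:
        raise ValueError(f"series of length {n} too short for m={params.m}")
    if n < MIN_RECOMMENDED_N:
        warnings.warn(
            f"series length {n} is below the recommended floor of "
            f"{MIN_RECOMMENDED_N} points; the estimate may be unreliable",
            stacklevel=2,
        )
    r = params.resolve(x)
    a, b = _match_counts(x, params.m, r, params.strict)
    value = -math.log(a / b) if (a > 0 and b > 0) else math.nan
    return SampEnResult(m=params.m, r_absolute=r, n=n, a_count=a, b_count=b, value=value)


def coefficient_label(coefficient: float) -> str:
    """Column label for a tolerance coefficient: 0.1 -> 'SampEn01' etc."""
    digits = f"{coefficient:g}".replace(".", "")
    return f"SampEn{digits}"


def entropy_profile(
    values: Sequence[float],
    m: int = DEFAULT_M,
    coefficients: Sequence[float] = DEFAULT_R_COEFFICIENTS,
    strict: bool = False,
) -> Mapping[float, SampEnResult]:
    """SampEn over a grid of SD-relative tolerances; one result per coefficient."""
    out: dict[float, SampEnResult] = {}
    for c in coefficients:
        params = SampEnParams(m=m, r_coefficient=c, strict=strict)
        out[c] = sample_entropy(values, params)
    return out
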