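"""MoCA score adjustment and postoperative cognitive improvement labelling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

MOCA_MAX = 30
EDUCATION_ADJUST_THRESHOLD_YEARS = 12
POCI_DELTA = 3  # minimum adjusted-score gain that counts as improvement

Timing = Literal["preoperative", "postoperative_day3_4"]


@dataclass(frozen=True)
class MocaAssessment:
    raw_score: int
    education_years: int
    timing: Timing

    def __post_init__(self) -> None:
        if not 0 <= self.raw_score <= MOCA_MAX:
            raise ValueError(f"raw MoCA score must lie in [0, {MOCA_MAX}], got {self.raw_score}")
        if self.education_years < 0:
            raise ValueError("education_years must be nonnegative")

    @property
    def adjusted_score(self) -> int:
        return adjust_moca(self.raw_score, self.education_years)


@dataclass(frozen=True)
class PociLabel:
    delta: int
    poci: bool


def adjust_moca(raw: int, education_years: int) -> int:
    """Add one point for <= 12 years of formal education, capped at 30."""
    if not 0 <= raw <= MOCA_MAX:
        raise ValueError(f"raw MoCA score must lie in [0, {MOCA_MAX}], got {raw}")
    if education_years < 0:
        raise ValueError("education_years must be nonnegative")
    adjusted = raw + (1 if education_years <= EDUCATION_ADJUST_THRESHOLD_YEARS else 0)
    return min(adjusted, MOCA_MAX)


def classify_poci(pre: MocaAssessment, post: MocaAssessment) -> PociLabel:
    """Improvement = adjusted-score gain of at least 3 points post vs pre."""
    if pre.education_years != post.education_years:
        raise ValueError(
            "pre and post assessments must share education_years "
            f"({pre.education_years} != {post.education_years})"
        )
    if pre.timing != "preoperative" or post.timing != "postoperative_day3_4":
        raise ValueError("expected a (preoperative, postoperative_day3_4) pair")
    delta = post.adjusted_score - pre.adjusted_score
    return PociLabel(delta=delta, poci=delta >= POCI_DELTA)


def classify_poci_raw(
    moca_pre_raw: int, moca_post_raw: int, education_gt12: bool
) -> PociLabel:
    """Convenience wrapper over the cohort-CSV column encoding.

    ``education_gt12`` is the 0/1 flag stored in the manifest; subjects with
    <= 12 years receive the +1 adjustment on both assessments.
    """
    years = 16 if education_gt12 else 12
    pre = MocaAssessment(moca_pre_raw, years, "preoperative")
    post = MocaAssessment(moca_post_raw, years, "postoperative_day3_4")
    return classify_poci(pre, post)
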