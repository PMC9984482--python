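"""Functional-outcome labelling after ischemic stroke.

Two labelling rules operate on the modified Rankin Scale (mRS, 0 = no
symptoms ... 6 = death) assessed at a follow-up horizon, optionally
combined with the admission NIHSS severity score (0-42):

* plain dichotomization — unfavorable iff mRS >= 3 (dependence or death);
* severity-adjusted rule — a patient whose admission stroke was mild is
  held to a stricter recovery standard: unfavorable when
  (mRS 2-6 and NIHSS <= 7) or (mRS 3-6 and NIHSS 8-14) or
  (mRS 4-6 and NIHSS > 14); favorable otherwise.

Band edges are integer-inclusive, so the three NIHSS bands partition 0-42
with no gap or overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "OutcomeAssessment",
    "OutcomeLabel",
    "dichotomize_mrs",
    "severity_adjusted_outcome",
    "UNFAVORABLE",
    "FAVORABLE",
]

UNFAVORABLE = "unfavorable"
FAVORABLE = "favorable"

Horizon = Literal["30d", "90d"]


@dataclass(frozen=True)
class OutcomeAssessment:
    """mRS at a follow-up horizon plus the admission NIHSS."""

    mrs: int
    nihss_admission: int
    horizon: Horizon = "30d"

    def __post_init__(self) -> None:
        if not (isinstance(self.mrs, (int,)) and 0 <= self.mrs <= 6):
            raise ValueError(f"mRS must be an integer in 0..6, got {self.mrs!r}")
        if not (isinstance(self.nihss_admission, (int,)) and 0 <= self.nihss_admission <= 42):
            raise ValueError(
                f"NIHSS must be an integer in 0..42, got {self.nihss_admission!r}"
            )


@dataclass(frozen=True)
class OutcomeLabel:
    label: Literal["favorable", "unfavorable"]
    rule: Literal["dichotomized", "severity_adjusted"]

    @property
    def unfavorable(self) -> bool:
        return self.label == UNFAVORABLE

    def as_int(self) -> int:
        """0/1 coding, 1 = unfavorable."""
        return int(self.unfavorable)


def dichotomize_mrs(assessment: OutcomeAssessment) -> OutcomeLabel:
    """Unfavorable iff mRS >= 3; ignores NIHSS entirely."""
    label = UNFAVORABLE if assessment.mrs >= 3 else FAVORABLE
    return OutcomeLabel(label, "dichotomized")


def severity_adjusted_outcome(assessment: OutcomeAssessment) -> OutcomeLabel:
    """Three-branch rule combining follow-up mRS with admission severity.

    Mild strokes (NIHSS <= 7) count mRS 2 as already unfavorable; moderate
    strokes (NIHSS 8-14) use the usual mRS >= 3 cut; severe strokes
    (NIHSS >= 15) are unfavorable only from mRS 4 upward. Note the literal
    reading leaves e.g. mRS 3 with NIHSS 20 favorable.
    """
    mrs, nihss = assessment.mrs, assessment.nihss_admission
    if nihss <= 7:
        unfav = mrs >= 2
    elif nihss <= 14:
        unfav = mrs >= 3
    else:
        unfav = mrs >= 4
    return OutcomeLabel(UNFAVORABLE if unfav else FAVORABLE, "severity_adjusted")
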