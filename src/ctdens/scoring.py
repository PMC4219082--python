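"""Cerebral edema scoring.

The Cerebral Edema Score (CES) is the series-averaged percentage of
intracranial pixels with HU 17-24; values at or above 16.03 % indicate
severe cerebral edema, and at or above 16.29 % flag risk of delayed edema
on an initially unremarkable scan.  The mortality variant (mCES) uses the
narrower band HU 19-23 with a 15.27 % cutoff.  All comparisons are
inclusive (a score exactly at the cutoff classifies positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .densitometry import BandQuery, DensityDistribution, band_proportion
from .errors import LevelError

__all__ = [
    "CES_BAND",
    "MCES_BAND",
    "ScoreThresholds",
    "EdemaScore",
    "compute_ces",
    "compute_mces",
    "classify",
    "score_subject",
]

CES_BAND = BandQuery(17, 24)
MCES_BAND = BandQuery(19, 23)


@dataclass(frozen=True)
class ScoreThresholds:
    """Score bands and cutoffs (percent).

    Defaults are the reference operating points: CES >= 16.03 for severe
    edema, >= 16.29 for delayed-edema screening, mCES >= 15.27 for
    mortality.  (An alternative CES cutoff of 22.58 appears in the source
    material's figure caption; it conflicts with the text value and can be
    selected here explicitly.)
    """

    ces_band: BandQuery = CES_BAND
    ces_cutoff: float = 16.03
    delayed_cutoff: float = 16.29
    mces_band: BandQuery = MCES_BAND
    mces_cutoff: float = 15.27

    def __post_init__(self):
        for name in ("ces_cutoff", "delayed_cutoff", "mces_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name} must be in (0, 100), got {v}")


@dataclass(frozen=True)
class EdemaScore:
    """Band proportions and threshold verdicts for one subject."""

    subject_id: str
    ces: float
    mces: float
    verdict_severity: str        # {"mild", "severe"}
    verdict_delayed_risk: str    # {"low", "high"}
    verdict_mortality_risk: str  # {"low", "high"}
    thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "ces": self.ces,
            "mces": self.mces,
            "verdict_severity": self.verdict_severity,
            "verdict_delayed_risk": self.verdict_delayed_risk,
            "verdict_mortality_risk": self.verdict_mortality_risk,
            "ces_cutoff": self.thresholds.ces_cutoff,
            "delayed_cutoff": self.thresholds.delayed_cutoff,
            "mces_cutoff": self.thresholds.mces_cutoff,
        }


def compute_ces(dist: DensityDistribution,
                band: BandQuery = CES_BAND) -> float:
    """CES: HU_17^24 of a distribution, in percent."""
    return band_proportion(dist, band)


def compute_mces(dist: DensityDistribution,
                 band: BandQuery = MCES_BAND) -> float:
    """mCES: HU_19^23 of a distribution, in percent."""
    return band_proportion(dist, band)


def classify(score: float, cutoff: float) -> str:
    """``at_or_above`` iff score >= cutoff (ties classify positive)."""
    if not (0.0 <= score <= 100.0) or not (0.0 <= cutoff <= 100.0):
        raise ValueError("score and cutoff must lie in [0, 100]")
    return "at_or_above" if score >= cutoff else "below"


def score_subject(series_dist: DensityDistribution,
                  thresholds: ScoreThresholds = ScoreThresholds(),
                  subject_id: str = "") -> EdemaScore:
    """Score one subject's series-level distribution and fill all verdicts."""
    if series_dist.level != "series":
        raise LevelError(
            f"score_subject expects a series-level distribution, got {series_dist.level!r}"
        )
    ces = band_proportion(series_dist, thresholds.ces_band)
    mces = band_proportion(series_dist, thresholds.mces_band)
    return EdemaScore(
        subject_id=subject_id,
        ces=ces,
        mces=mces,
        verdict_severity=(
            "severe" if classify(ces, thresholds.ces_cutoff) == "at_or_above" else "mild"
        ),
        verdict_delayed_risk=(
            "high" if classify(ces, thresholds.delayed_cutoff) == "at_or_above" else "low"
        ),
        verdict_mortality_risk=(
            "high" if classify(mces, thresholds.mces_cutoff) == "at_or_above" else "low"
        ),
        thresholds=thresholds,
    )
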