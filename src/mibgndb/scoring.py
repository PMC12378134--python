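"""Segmental sympathetic-denervation defect scoring.

Each of the 17 segments receives an integer score 0 (normal) to 4 (absent
uptake).  Two methods are provided:

* **Visual rule** — the fixed %count bands used by expert readers:
  score 0 for uptake >= 70% of reference, 1 for 60-69%, 2 for 50-59%,
  3 for 40-49%, 4 for < 40%.
* **NDB-relative automated scoring** — the segment's deficit below the
  normal-database mean in SD units, z = (m_s - u_s) / sigma_s, graded by how
  many of the thresholds (default 2, 3, 4, 5 SD) it reaches.  Uptake at or
  above the normal mean is never penalized.

The summed score over all 17 segments is the SES (early phase) or SLS
(late phase), range 0-68.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ndb import NormalDatabase
from .polarmap import N_SEGMENTS, SegmentProfile

logger = logging.getLogger(__name__)

#: Lower %uptake bounds of score bands 0..3; below the last bound scores 4.
VISUAL_BANDS = (70.0, 60.0, 50.0, 40.0)

#: Default z thresholds (SD below the NDB mean) for automated scores 1..4.
DEFAULT_Z_THRESHOLDS = (2.0, 3.0, 4.0, 5.0)

#: SDs below this floor (in % uptake) are clamped to it before division.
SD_FLOOR = 0.5


class ScoringError(ValueError):
    """Raised for invalid uptake values or undefined scoring inputs."""


@dataclass
class DefectScore:
    """Per-segment 0-4 scores with their sum (SES or SLS)."""

    segment_scores: np.ndarray
    method: str                      # "visual_rule" | "ndb_auto"
    phase: str = "early"
    subject_id: str = ""
    ndb_id: str | None = None

    def __post_init__(self) -> None:
        self.segment_scores = np.asarray(self.segment_scores, dtype=int)
        if self.segment_scores.shape != (N_SEGMENTS,):
            raise ScoringError(f"need {N_SEGMENTS} segment scores")
        if self.segment_scores.min() < 0 or self.segment_scores.max() > 4:
            raise ScoringError("segment scores must be in 0..4")

    @property
    def summed(self) -> int:
        """SES for early phase, SLS for late; range 0-68."""
        return int(self.segment_scores.sum())


def visual_score_segment(uptake_pct: float) -> int:
    """Score one segment by the visual %count bands.

    >= 70% -> 0; 60-69% -> 1; 50-59% -> 2; 40-49% -> 3; < 40% -> 4.
    """
    u = float(uptake_pct)
    if not np.isfinite(u) or u < 0:
        raise ScoringError(f"uptake must be finite and >= 0, got {uptake_pct}")
    for score, bound in enumerate(VISUAL_BANDS):
        if u >= bound:
            return score
    return 4


def auto_score_segment(
    uptake_pct: float,
    ndb_mean: float,
    ndb_sd: float,
    z_thresholds: tuple[float, ...] = DEFAULT_Z_THRESHOLDS,
) -> int:
    """Score one segment against the normal database.

    z = (ndb_mean - uptake) / sd counts how many thresholds it meets;
    the count (capped at 4) is the score.  Monotone non-decreasing in z.
    """
    if ndb_sd < 0 or not np.isfinite(ndb_sd):
        raise ScoringError("NDB SD must be finite and >= 0")
    if ndb_sd == 0:
        raise ScoringError("scoring undefined for a zero-SD segment")
    sd = ndb_sd
    if sd < SD_FLOOR:
        logger.warning("segment SD %.3f below floor %.1f%%; using floor", sd, SD_FLOOR)
        sd = SD_FLOOR
    z = (ndb_mean - float(uptake_pct)) / sd
    return min(int(sum(z >= t for t in z_thresholds)), 4)


def score_profile_visual(profile: SegmentProfile) -> DefectScore:
    """Apply the visual band rule to every segment of a profile."""
    scores = np.array([visual_score_segment(u) for u in profile.values])
    return DefectScore(scores, method="visual_rule", phase=profile.phase,
                       subject_id=profile.subject_id)


def score_profile_auto(
    profile: SegmentProfile,
    ndb: NormalDatabase,
    z_thresholds: tuple[float, ...] = DEFAULT_Z_THRESHOLDS,
) -> DefectScore:
    """Score every segment of a profile against an NDB."""
    if ndb.phase != profile.phase:
        raise ScoringError(
            f"phase mismatch: profile {profile.phase!r} vs NDB {ndb.phase!r}")
    scores = np.array([
        auto_score_segment(profile.values[s], ndb.mean[s], ndb.sd[s], z_thresholds)
        for s in range(N_SEGMENTS)
    ])
    return DefectScore(scores, method="ndb_auto", phase=profile.phase,
                       subject_id=profile.subject_id, ndb_id=ndb.ndb_id)


def summed_score(score: DefectScore | np.ndarray) -> int:
    """Sum of the 17 segment scores (SES/SLS); validates completeness."""
    seg = score.segment_scores if isinstance(score, DefectScore) else np.asarray(score)
    if seg.shape != (N_SEGMENTS,):
        raise ScoringError(f"incomplete score vector: {seg.shape}")
    if np.any(seg < 0) or np.any(seg > 4):
        raise ScoringError("segment scores must be in 0..4")
    return int(seg.sum())
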