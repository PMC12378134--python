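"""Normal-database (NDB) construction and comparison.

An NDB summarizes a disease-free cohort by the per-segment mean and standard
deviation of normalized uptake, stratified by population (Jp, It, pooled
JpIt), sex and acquisition phase (early/late).  Clinical polar-map software
commonly stores dispersion as the mean deviation (mean absolute deviation
about the mean); :func:`md_to_sd` converts it to an SD under a normality
assumption, and the ``md_converted`` flag records that provenance.

Databases from different cohorts are compared segment by segment with a
one-way ANOVA computed purely from summary statistics (means, SDs, ns), so
external NDB files can be compared without subject-level data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .polarmap import N_SEGMENTS, SegmentProfile


class NDBError(ValueError):
    """Raised for insufficient cohorts or stratum mismatches."""


@dataclass
class NormalDatabase:
    """Per-segment (mean, SD) reference with stratum metadata.

    ``mean`` and ``sd`` are in percent of reference uptake and indexed by
    AHA segment number minus one; ``n`` is the cohort size.
    """

    mean: np.ndarray
    sd: np.ndarray
    n: int
    population: str = "other"
    sex: str = "all"
    phase: str = "early"
    md_converted: bool = False

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (N_SEGMENTS,) or self.sd.shape != (N_SEGMENTS,):
            raise NDBError(f"NDB needs {N_SEGMENTS} means and SDs")
        if not np.all(np.isfinite(self.mean)):
            raise NDBError("NDB means must be finite")
        if np.any(self.sd < 0):
            raise NDBError("NDB SDs must be >= 0")
        if self.n < 2:
            raise NDBError("NDB requires n >= 2 subjects")

    @property
    def ndb_id(self) -> str:
        return f"{self.population}-{self.sex}-{self.phase}"


def _profile_matrix(profiles: Sequence[SegmentProfile]) -> np.ndarray:
    return np.stack([p.values for p in profiles])


def build_ndb(
    profiles: Iterable[SegmentProfile],
    population: str | None = None,
    sex: str | None = None,
    phase: str | None = None,
) -> NormalDatabase:
    """Build an NDB from normalized profiles, optionally filtering strata.

    Filters are applied on the profile metadata before aggregation; ``None``
    keeps everything.  Means use the cohort mean and SDs the sample SD
    (n - 1 denominator).
    """
    kept = [
        p for p in profiles
        if (population is None or p.population == population)
        and (sex is None or p.sex == sex)
        and (phase is None or p.phase == phase)
    ]
    if len(kept) < 2:
        raise NDBError("need at least 2 subjects after stratum filtering")
    phases = {p.phase for p in kept}
    if len(phases) > 1:
        raise NDBError(f"mixed phases in cohort: {sorted(phases)}")
    pops = {p.population for p in kept}
    sexes = {p.sex for p in kept}
    mat = _profile_matrix(kept)
    return NormalDatabase(
        mean=mat.mean(axis=0),
        sd=mat.std(axis=0, ddof=1),
        n=len(kept),
        population=population or (pops.pop() if len(pops) == 1 else "pooled"),
        sex=sex or (sexes.pop() if len(sexes) == 1 else "all"),
        phase=phases.pop(),
    )


def combine_ndbs(
    cohort_a: Sequence[SegmentProfile],
    cohort_b: Sequence[SegmentProfile],
    population: str = "pooled",
) -> NormalDatabase:
    """Pool two cohorts at the subject level and rebuild the NDB.

    Equivalent to :func:`build_ndb` on the concatenated subject list —
    subjects are pooled un-weighted, not averaged database-by-database, so a
    larger cohort contributes proportionally more.
    """
    phases = {p.phase for p in cohort_a} | {p.phase for p in cohort_b}
    if len(phases) > 1:
        raise NDBError(f"phase mismatch between cohorts: {sorted(phases)}")
    ndb = build_ndb(list(cohort_a) + list(cohort_b))
    ndb.population = population
    return ndb


_MD_TO_SD = math.sqrt(math.pi / 2.0)


def md_to_sd(mean_deviation: float | np.ndarray) -> float | np.ndarray:
    """Convert mean (absolute) deviation to SD assuming normality.

    For X ~ N(mu, sigma^2), E|X - mu| = sigma * sqrt(2/pi), so
    sigma = md * sqrt(pi/2) ~= 1.2533 * md.
    """
    md = np.asarray(mean_deviation, dtype=float)
    if np.any(md < 0):
        raise NDBError("mean deviation must be >= 0")
    out = md * _MD_TO_SD
    return float(out) if np.isscalar(mean_deviation) else out


@dataclass
class SegmentComparison:
    """Per-segment one-way ANOVA across >= 2 NDBs from summary statistics."""

    group_means: np.ndarray   # (n_groups, 17)
    group_sds: np.ndarray     # (n_groups, 17)
    group_ns: np.ndarray      # (n_groups,)
    f_stat: np.ndarray        # (17,)
    p_value: np.ndarray       # (17,)
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_value < self.alpha


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """One-way ANOVA F and p from group (mean, SD, n) summaries.

    Between-group sum of squares from the group means about the weighted
    grand mean; within-group from the (n_i - 1) * sd_i^2 terms.  With two
    groups, F equals the square of the pooled-variance t statistic.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    n = np.asarray(ns, dtype=float)
    if m.size < 2:
        raise NDBError("ANOVA needs at least 2 groups")
    if np.any(n < 2) or not np.all(np.isfinite(s)):
        raise NDBError("each group needs n >= 2 and a defined SD")
    big_n = n.sum()
    grand = (n * m).sum() / big_n
    ss_between = (n * (m - grand) ** 2).sum()
    ss_within = ((n - 1) * s**2).sum()
    df_b = m.size - 1
    df_w = big_n - m.size
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def compare_ndbs(ndbs: Sequence[NormalDatabase], alpha: float = 0.05) -> SegmentComparison:
    """Segment-wise ANOVA across databases using their stored summaries."""
    if len(ndbs) < 2:
        raise NDBError("need at least 2 NDBs to compare")
    means = np.stack([d.mean for d in ndbs])
    sds = np.stack([d.sd for d in ndbs])
    ns = np.array([d.n for d in ndbs])
    f = np.empty(N_SEGMENTS)
    p = np.empty(N_SEGMENTS)
    for s in range(N_SEGMENTS):
        f[s], p[s] = anova_from_summary(means[:, s], sds[:, s], ns)
    return SegmentComparison(means, sds, ns, f, p, alpha=alpha)
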