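"""End-to-end validation pipeline.

Chains the stages of a normal-database validation study: build the
population and pooled NDBs from the normal cohorts, score the validation
cohort against each NDB and with the visual band rule, then run the
evaluation battery —

1. agreement (Pearson + Bland-Altman) of pooled-NDB automated summed scores
   against each population NDB's scores;
2. agreement and paired ROC comparison of automated versus visual scores;
3. Kruskal-Wallis contrasts of HMR and automated scores across the CAD /
   DCM / no-disease groups;
4. ROC of HMR alone, automated score alone, and their logistic combination,
   separately for early and late phases.

The "case" label for diagnostic ROC is any disease (CAD or DCM) versus none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import evaluation as ev
from .ndb import NormalDatabase, build_ndb, combine_ndbs
from .scoring import score_profile_auto, score_profile_visual
from .synthetic import PHASES, SyntheticSubject


class PipelineError(ValueError):
    """Raised when a stage's inputs are missing."""


def build_study_ndbs(
    jp_normals: Sequence[SyntheticSubject],
    it_normals: Sequence[SyntheticSubject],
) -> dict:
    """Jp, It and pooled JpIt NDBs for both phases from normal cohorts."""
    ndbs: dict[str, dict[str, NormalDatabase]] = {"Jp": {}, "It": {}, "JpIt": {}}
    for phase in PHASES:
        jp_prof = [s.profiles[phase] for s in jp_normals]
        it_prof = [s.profiles[phase] for s in it_normals]
        ndbs["Jp"][phase] = build_ndb(jp_prof, population="Jp")
        ndbs["It"][phase] = build_ndb(it_prof, population="It")
        ndbs["JpIt"][phase] = combine_ndbs(jp_prof, it_prof, population="JpIt")
    return ndbs


def summed_auto_scores(
    subjects: Sequence[SyntheticSubject], ndb: NormalDatabase, phase: str
) -> np.ndarray:
    return np.array([
        score_profile_auto(s.profiles[phase], ndb).summed for s in subjects
    ], dtype=float)


def summed_visual_scores(
    subjects: Sequence[SyntheticSubject], phase: str
) -> np.ndarray:
    return np.array([
        score_profile_visual(s.profiles[phase]).summed for s in subjects
    ], dtype=float)


@dataclass
class PhaseReport:
    """All evaluation outputs for one acquisition phase."""

    agreement_pooled_vs_jp: ev.AgreementResult
    agreement_pooled_vs_it: ev.AgreementResult
    agreement_auto_vs_visual: ev.AgreementResult
    contrast_hmr: ev.GroupContrast
    contrast_auto_score: ev.GroupContrast
    roc_visual: ev.ROCResult
    roc_auto: ev.ROCResult
    roc_hmr: ev.ROCResult
    roc_combined: ev.ROCResult
    p_auto_vs_visual: float
    p_combined_vs_hmr: float
    p_combined_vs_auto: float
    combined_model: ev.CombinedModel
    group_means_hmr: dict
    group_means_auto: dict

    def to_dict(self) -> dict:
        return {
            "agreement_pooled_vs_jp": self.agreement_pooled_vs_jp.to_dict(),
            "agreement_pooled_vs_it": self.agreement_pooled_vs_it.to_dict(),
            "agreement_auto_vs_visual": self.agreement_auto_vs_visual.to_dict(),
            "contrast_hmr": self.contrast_hmr.to_dict(),
            "contrast_auto_score": self.contrast_auto_score.to_dict(),
            "roc_visual": self.roc_visual.to_dict(),
            "roc_auto": self.roc_auto.to_dict(),
            "roc_hmr": self.roc_hmr.to_dict(),
            "roc_combined": self.roc_combined.to_dict(),
            "p_auto_vs_visual": self.p_auto_vs_visual,
            "p_combined_vs_hmr": self.p_combined_vs_hmr,
            "p_combined_vs_auto": self.p_combined_vs_auto,
            "combined_model": self.combined_model.to_dict(),
            "group_means_hmr": self.group_means_hmr,
            "group_means_auto": self.group_means_auto,
        }


@dataclass
class EvaluationReport:
    phases: dict  # phase -> PhaseReport
    n_validation: int
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "n_validation": self.n_validation,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "phases": {ph: r.to_dict() for ph, r in self.phases.items()},
        }


def run_validation_pipeline(
    validation: Sequence[SyntheticSubject],
    ndbs: dict,
) -> EvaluationReport:
    """Score a labeled validation cohort and run the full evaluation battery.

    ``ndbs`` must map 'Jp', 'It' and 'JpIt' to per-phase NormalDatabase
    dicts (as produced by :func:`build_study_ndbs`).
    """
    for key in ("Jp", "It", "JpIt"):
        if key not in ndbs:
            raise PipelineError(f"missing NDB {key!r} for the validation stage")
    if not validation:
        raise PipelineError("empty validation cohort")

    labels = np.array([0 if s.label == "none" else 1 for s in validation])
    groups = np.array([s.label for s in validation])
    phase_reports = {}
    for phase in PHASES:
        hmr = np.array([s.hmr[phase] for s in validation])
        auto_pooled = summed_auto_scores(validation, ndbs["JpIt"][phase], phase)
        auto_jp = summed_auto_scores(validation, ndbs["Jp"][phase], phase)
        auto_it = summed_auto_scores(validation, ndbs["It"][phase], phase)
        visual = summed_visual_scores(validation, phase)

        combined = ev.fit_combined(hmr, auto_pooled, labels)
        _, p_av = ev.compare_rocs(auto_pooled, visual, labels)
        _, p_ch = ev.compare_rocs(combined.probabilities, hmr, labels,
                                  direction_b="lower")
        _, p_ca = ev.compare_rocs(combined.probabilities, auto_pooled, labels)

        kw_hmr = ev.kruskal_wallis(hmr, groups)
        kw_auto = ev.kruskal_wallis(auto_pooled, groups)
        phase_reports[phase] = PhaseReport(
            agreement_pooled_vs_jp=ev.agreement(auto_pooled, auto_jp),
            agreement_pooled_vs_it=ev.agreement(auto_pooled, auto_it),
            agreement_auto_vs_visual=ev.agreement(auto_pooled, visual),
            contrast_hmr=kw_hmr,
            contrast_auto_score=kw_auto,
            roc_visual=ev.roc(visual, labels),
            roc_auto=ev.roc(auto_pooled, labels),
            roc_hmr=ev.roc(hmr, labels, direction="lower"),
            roc_combined=ev.roc(combined.probabilities, labels),
            p_auto_vs_visual=p_av,
            p_combined_vs_hmr=p_ch,
            p_combined_vs_auto=p_ca,
            combined_model=combined,
            group_means_hmr=dict(zip(kw_hmr.group_labels, kw_hmr.group_mean)),
            group_means_auto=dict(zip(kw_auto.group_labels, kw_auto.group_mean)),
        )
    return EvaluationReport(
        phases=phase_reports,
        n_validation=len(validation),
        n_cases=int(labels.sum()),
        n_controls=int((1 - labels).sum()),
    )
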