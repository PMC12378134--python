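"""Run the diagnostic evaluation and plot the key figures.

Feeds the scored validation cohort through the evaluation battery —
agreement between NDB variants, CAD/DCM/none group contrasts, and ROC of
the automated score, the HMR and their logistic combination — then writes
the report JSON and ROC / Bland-Altman figures under results/figures/.
"""

import json

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from common import RESULTS, read_cohort

from mibgndb import run_validation_pipeline
from mibgndb.pipeline import build_study_ndbs, summed_auto_scores


def roc_points(scores, labels, flip=False):
    s = -np.asarray(scores, float) if flip else np.asarray(scores, float)
    order = np.argsort(-s)
    y = np.asarray(labels)[order]
    tpr = np.concatenate([[0.0], np.cumsum(y) / y.sum()])
    fpr = np.concatenate([[0.0], np.cumsum(1 - y) / (1 - y).sum()])
    return fpr, tpr


def main() -> None:
    jp = read_cohort("jp_normals")
    it = read_cohort("it_normals")
    validation = read_cohort("validation")
    ndbs = build_study_ndbs(jp, it)
    report = run_validation_pipeline(validation, ndbs)
    (RESULTS / "evaluation_report.json").write_text(
        json.dumps(report.to_dict(), indent=1))

    figdir = RESULTS / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    labels = np.array([0 if s.label == "none" else 1 for s in validation])
    for phase, ph in report.phases.items():
        hmr = np.array([s.hmr[phase] for s in validation])
        auto = summed_auto_scores(validation, ndbs["JpIt"][phase], phase)
        fig, ax = plt.subplots(figsize=(5, 5))
        for pts, res, name in (
                (roc_points(auto, labels), ph.roc_auto, "automated score"),
                (roc_points(hmr, labels, flip=True), ph.roc_hmr, "HMR"),
                (roc_points(ph.combined_model.probabilities, labels),
                 ph.roc_combined, "combined")):
            ax.plot(*pts, label=f"{name} (AUC {res.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity"), ax.set_ylabel("sensitivity")
        ax.set_title(f"HF detection, {phase} phase"), ax.legend()
        fig.savefig(figdir / f"roc_{phase}.png", dpi=120)
        plt.close(fig)

        auto_jp = summed_auto_scores(validation, ndbs["Jp"][phase], phase)
        d = auto - auto_jp
        agr = ph.agreement_pooled_vs_jp
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter((auto + auto_jp) / 2, d, s=14)
        for yv, style in ((agr.mean_difference, "-"),
                          (agr.loa_lower, "--"), (agr.loa_upper, "--")):
            ax.axhline(yv, color="gray", ls=style, lw=0.9)
        ax.set_xlabel("mean of pooled and Jp summed scores")
        ax.set_ylabel("difference (pooled - Jp)")
        ax.set_title(f"Bland-Altman, {phase} phase")
        fig.savefig(figdir / f"bland_altman_{phase}.png", dpi=120)
        plt.close(fig)

        print(f"{phase}: AUC auto={ph.roc_auto.auc:.3f} "
              f"visual={ph.roc_visual.auc:.3f} HMR={ph.roc_hmr.auc:.3f} "
              f"combined={ph.roc_combined.auc:.3f} "
              f"(combined vs HMR p={ph.p_combined_vs_hmr:.4f})")
        print(f"       group mean HMR: " + ", ".join(
            f"{g}={v:.2f}" for g, v in ph.group_means_hmr.items()))
        print(f"       Kruskal-Wallis: HMR p={ph.contrast_hmr.p_value:.2e}, "
              f"auto score p={ph.contrast_auto_score.p_value:.2e}")
    print(f"report and figures written to {RESULTS}")


if __name__ == "__main__":
    main()
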