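"""Score the validation cohort.

Applies NDB-relative automated scoring (against the Jp, It and pooled NDBs)
and the visual band rule to every validation subject and phase; writes one
score table per method/NDB and prints the group-mean summed scores.
"""

import numpy as np
import pandas as pd
from common import RESULTS, read_cohort

from mibgndb import score_profile_auto, score_profile_visual
from mibgndb.io import read_ndb, write_scores
from mibgndb.synthetic import PHASES


def main() -> None:
    validation = read_cohort("validation")
    summary = []
    for phase in PHASES:
        scores_by_method = {
            pop: [score_profile_auto(s.profiles[phase],
                                     read_ndb(RESULTS / f"ndb_{pop}_{phase}.csv"))
                  for s in validation]
            for pop in ("Jp", "It", "JpIt")
        }
        scores_by_method["visual"] = [score_profile_visual(s.profiles[phase])
                                      for s in validation]
        for method, scores in scores_by_method.items():
            write_scores(scores, RESULTS / f"scores_{method}_{phase}.csv")
            sums = np.array([sc.summed for sc in scores], dtype=float)
            labels = np.array([s.label for s in validation])
            row = {"phase": phase, "method": method}
            for g in ("CAD", "DCM", "none"):
                row[f"mean_{g}"] = round(float(sums[labels == g].mean()), 2)
            summary.append(row)
            print(f"{phase:5s} {method:6s} summed score means: "
                  f"CAD={row['mean_CAD']:6.2f}  DCM={row['mean_DCM']:5.2f}  "
                  f"none={row['mean_none']:5.2f}")
    pd.DataFrame(summary).to_csv(RESULTS / "score_group_means.csv", index=False)


if __name__ == "__main__":
    main()
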