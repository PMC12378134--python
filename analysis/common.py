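"""Shared paths, seed and cohort (de)serialization for the analysis scripts."""

from pathlib import Path

import pandas as pd

from mibgndb import SyntheticSubject
from mibgndb import io as mio
from mibgndb.synthetic import PHASES

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 20260921

ARMS = ("jp_normals", "it_normals", "validation")


def write_cohort(subjects, stem: str) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    for phase in PHASES:
        mio.write_profiles([s.profiles[phase] for s in subjects],
                           RESULTS / f"{stem}_{phase}.csv")
    rows = [{"subject_id": s.subject_id, "population": s.population,
             "sex": s.sex, "label": s.label,
             "hmr_early": round(s.hmr["early"], 6),
             "hmr_late": round(s.hmr["late"], 6)} for s in subjects]
    pd.DataFrame(rows).to_csv(RESULTS / f"{stem}_subjects.csv", index=False)


def read_cohort(stem: str) -> list[SyntheticSubject]:
    meta = pd.read_csv(RESULTS / f"{stem}_subjects.csv").set_index("subject_id")
    profiles = {ph: {p.subject_id: p
                     for p in mio.read_profiles(RESULTS / f"{stem}_{ph}.csv")}
                for ph in PHASES}
    subjects = []
    for sid, row in meta.iterrows():
        subjects.append(SyntheticSubject(
            subject_id=str(sid), population=row["population"], sex=row["sex"],
            label=row["label"],
            profiles={ph: profiles[ph][str(sid)] for ph in PHASES},
            hmr={"early": row["hmr_early"], "late": row["hmr_late"]}))
    return subjects
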