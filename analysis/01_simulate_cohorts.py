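"""Simulate the study cohorts.

Generates the two normative arms (55 Japanese and 33 Italian disease-free
subjects, both phases) and a validation arm of 15 CAD, 15 DCM and 12
no-disease subjects, then writes profile and subject tables under results/.
"""

from common import ARMS, RESULTS, SEED, write_cohort

from mibgndb import GeneratorConfig, simulate_study
from mibgndb.io import write_manifest


def main() -> None:
    cfg = GeneratorConfig(seed=SEED)
    study = simulate_study(cfg, n_jp_normal=55, n_it_normal=33,
                           n_cad=15, n_dcm=15, n_control=12)
    for stem in ARMS:
        write_cohort(study[stem], stem)
        labels = [s.label for s in study[stem]]
        print(f"{stem}: n={len(labels)} "
              f"(CAD={labels.count('CAD')}, DCM={labels.count('DCM')}, "
              f"none={labels.count('none')})")
    write_manifest(RESULTS / "simulate_manifest.json", seed=SEED,
                   arms={a: len(study[a]) for a in ARMS})
    print(f"cohort tables written to {RESULTS}")


if __name__ == "__main__":
    main()
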