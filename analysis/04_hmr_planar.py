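"""Exercise the image-domain HMR path.

Renders a Poisson-noise planar image for each validation subject's
early-phase HMR, recomputes the ratio from the image ROIs, applies an
example collimator standardization (coefficient 0.88, a typical
low-energy-to-medium-energy conversion magnitude), and tabulates target
versus recovered values.
"""

import numpy as np
import pandas as pd
from common import RESULTS, SEED, read_cohort

from mibgndb import GeneratorConfig, compute_hmr, simulate_planar, standardize_hmr


def main() -> None:
    cfg = GeneratorConfig(seed=SEED)
    rng = np.random.default_rng(SEED + 4)
    validation = read_cohort("validation")
    rows = []
    for s in validation:
        img, rois = simulate_planar(s.hmr["early"], cfg, rng=rng)
        raw = compute_hmr(img, rois)
        std = standardize_hmr(raw, 0.88, source_condition="LEHR")
        rows.append({"subject_id": s.subject_id, "label": s.label,
                     "target_hmr": round(s.hmr["early"], 4),
                     "image_hmr": round(raw, 4),
                     "standardized_hmr": round(std.standardized, 4)})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "hmr_from_images.csv", index=False)
    err = (df["image_hmr"] - df["target_hmr"]).abs()
    print(f"image-recovered HMR vs target over n={len(df)}: "
          f"mean |error| = {err.mean():.4f}, max = {err.max():.4f}")
    print(f"table written to {RESULTS / 'hmr_from_images.csv'}")


if __name__ == "__main__":
    main()
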