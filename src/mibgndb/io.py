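"""File formats: profile tables, NDB files, score tables, rasters, manifests.

All tabular exchange is UTF-8 comma-separated CSV with a header row and '.'
decimals.  Cohort tables round floats to 6 significant digits; NDB files are
written at full precision (repr) so write/read round-trips bit-exactly.
Polar-map rasters travel as plain matrix CSV or 8-bit grayscale PNG (PNG is
lossy: values are min-max scaled to 0-255 and the scale recorded nowhere, so
PNG is for display only).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .ndb import NormalDatabase, md_to_sd
from .polarmap import N_SEGMENTS, PolarMapRaster, SegmentProfile, disc_mask
from .scoring import DefectScore

SEG_COLUMNS = [f"seg{i:02d}" for i in range(1, N_SEGMENTS + 1)]


# -- segment profile tables -------------------------------------------------

def profiles_to_frame(profiles: Sequence[SegmentProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, "population": p.population,
               "sex": p.sex, "phase": p.phase}
        row.update({c: float(f"{v:.6g}") for c, v in zip(SEG_COLUMNS, p.values)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "population", "sex",
                                       "phase", *SEG_COLUMNS])


def write_profiles(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[SegmentProfile]:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "phase", *SEG_COLUMNS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV {path} missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(SegmentProfile(
            row[SEG_COLUMNS].to_numpy(dtype=float),
            phase=str(row["phase"]), subject_id=str(row["subject_id"]),
            sex=str(row.get("sex", "all")),
            population=str(row.get("population", "other")),
            normalized=True))
    return out


# -- NDB files --------------------------------------------------------------

def write_ndb(ndb: NormalDatabase, path: str | Path) -> None:
    """CSV of (segment, mean, sd) plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("segment,mean,sd\n")
        for s in range(N_SEGMENTS):
            fh.write(f"{s + 1},{float(ndb.mean[s])!r},{float(ndb.sd[s])!r}\n")
    meta = {"population": ndb.population, "sex": ndb.sex, "phase": ndb.phase,
            "n": ndb.n, "md_converted": ndb.md_converted,
            "dispersion": "sd"}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1))


def read_ndb(path: str | Path) -> NormalDatabase:
    """Read an NDB; a sidecar ``dispersion: md`` column triggers md->sd."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip").sort_values("segment")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    sd = df["sd"].to_numpy(dtype=float)
    converted = bool(meta.get("md_converted", False))
    if meta.get("dispersion", "sd") == "md":
        sd = md_to_sd(sd)
        converted = True
    return NormalDatabase(
        mean=df["mean"].to_numpy(dtype=float), sd=sd, n=int(meta["n"]),
        population=meta.get("population", "other"),
        sex=meta.get("sex", "all"), phase=meta.get("phase", "early"),
        md_converted=converted)


# -- score tables -----------------------------------------------------------

def scores_to_frame(scores: Sequence[DefectScore]) -> pd.DataFrame:
    rows = []
    for sc in scores:
        row = {"subject_id": sc.subject_id, "phase": sc.phase,
               "method": sc.method, "ndb_id": sc.ndb_id or ""}
        row.update({c: int(v) for c, v in zip(SEG_COLUMNS, sc.segment_scores)})
        row["summed"] = sc.summed
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "phase", "method",
                                       "ndb_id", *SEG_COLUMNS, "summed"])


def write_scores(scores: Sequence[DefectScore], path: str | Path) -> None:
    scores_to_frame(scores).to_csv(path, index=False)


# -- rasters ----------------------------------------------------------------

def write_raster_csv(raster: PolarMapRaster, path: str | Path) -> None:
    np.savetxt(path, np.where(raster.mask, raster.grid, np.nan),
               delimiter=",", fmt="%.6g")


def read_raster_csv(path: str | Path, phase: str = "early") -> PolarMapRaster:
    grid = np.genfromtxt(path, delimiter=",")
    mask = np.isfinite(grid)
    return PolarMapRaster(np.where(mask, grid, 0.0), mask, phase=phase)


def write_raster_png(raster: PolarMapRaster, path: str | Path) -> None:
    """8-bit grayscale export, min-max scaled over masked pixels (display only)."""
    vals = raster.grid[raster.mask]
    lo, hi = (vals.min(), vals.max()) if vals.size else (0.0, 1.0)
    span = hi - lo if hi > lo else 1.0
    img = np.zeros_like(raster.grid)
    img[raster.mask] = (raster.grid[raster.mask] - lo) / span * 255.0
    Image.fromarray(np.clip(img, 0, 255).astype(np.uint8), mode="L").save(path)


# -- manifests --------------------------------------------------------------

def write_manifest(path: str | Path, **entries) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    Path(path).write_text(json.dumps(entries, indent=1, default=_default))
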