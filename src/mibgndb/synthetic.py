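"""Synthetic cardiac-MIBG cohorts: segmental profiles, HMR draws, planar images.

The generator emulates the statistical structure of a two-population
(Japanese and Italian) normal-database study with a heart-failure validation
arm, so the full pipeline — NDB construction, automated defect scoring, HMR
computation, diagnostic evaluation — runs end-to-end without any acquired
data:

* **Normals** draw 17 segmental %uptake values around per-stratum means with
  independent Gaussian segment noise.  Males have reduced inferior-wall
  uptake; the Italian population has reduced anterior uptake; late-phase
  uptake is globally slightly lower than early.
* **CAD** (coronary artery disease) subtracts a focal defect of random depth
  from all segments of one randomly chosen coronary territory (LAD, RCA or
  LCx in their standard AHA mappings) — a sharply demarcated denervation.
* **DCM** (dilated cardiomyopathy) subtracts a mild global decrement from
  all 17 segments and inflates segment noise — diffuse dysfunction that
  depresses the HMR markedly while leaving segment-level deficits shallow.
* **HMR** is drawn per subject from a Gaussian around a group mean: disease
  groups are shifted down, DCM more than CAD.  :func:`simulate_planar`
  renders a planar count image (background plus cardiac Gaussian blob,
  optional Poisson noise) whose ROI ratio reproduces the subject's HMR, for
  exercising the image-domain HMR path.

All randomness flows through one ``numpy.random.default_rng`` (PCG64) stream
seeded from ``GeneratorConfig.seed``; identical configuration and seed give
identical cohorts on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hmr import PlanarImage, ROIPair
from .polarmap import N_SEGMENTS, SegmentProfile

#: Coronary-territory to AHA-segment mapping (standard 17-segment assignment).
TERRITORIES: dict[str, tuple[int, ...]] = {
    "LAD": (1, 2, 7, 8, 13, 14, 17),
    "RCA": (3, 4, 9, 10, 15),
    "LCx": (5, 6, 11, 12, 16),
}

PHASES = ("early", "late")

# Baseline Jp-male early-phase segment means (% of reference): anterior and
# lateral walls high, inferior/septal walls and apex lower.  Synthetic values
# shaped to the qualitative pattern of normal MIBG bullseyes, not measured.
_BASE_MEANS = np.array([
    88.0, 84.0, 79.0, 77.0, 82.0, 88.0,   # basal 1-6
    90.0, 85.0, 80.0, 78.0, 84.0, 89.0,   # mid 7-12
    88.0, 83.0, 79.0, 87.0,               # apical 13-16
    82.0,                                  # apex 17
])

_BASE_SDS = np.full(N_SEGMENTS, 6.0)

#: Inferior-wall segments reduced in males (inferoseptal/inferior/inferolateral).
MALE_INFERIOR_SEGMENTS = (3, 4, 5, 9, 10, 15)
#: Anterior segments reduced in the Italian population.
IT_ANTERIOR_SEGMENTS = (1, 2, 7, 8, 13)


class GeneratorError(ValueError):
    """Raised for undefined strata or unattainable targets."""


@dataclass
class GeneratorConfig:
    """Truth parameters of the synthetic study.

    Segment means/SDs are in % of reference uptake; decrements are
    subtracted from the relevant means before segment noise.  HMR group
    means follow the standardized (medium-energy collimator) scale; the
    per-phase disease decrements place the CAD group between normal and
    DCM, with DCM lowest.
    """

    seed: int = 0
    base_means: np.ndarray = field(default_factory=lambda: _BASE_MEANS.copy())
    base_sds: np.ndarray = field(default_factory=lambda: _BASE_SDS.copy())
    male_inferior_decrement: float = 6.0
    it_anterior_decrement: float = 5.0
    late_phase_decrement: float = 3.0
    # CAD: focal territorial defect
    cad_depth_range: tuple[float, float] = (15.0, 35.0)
    # DCM: diffuse shallow defect with inflated heterogeneity
    dcm_decrement_range: tuple[float, float] = (2.0, 6.0)
    dcm_noise_inflation: float = 1.2
    # HMR model (standardized scale)
    hmr_normal_mean: dict = field(
        default_factory=lambda: {"early": 2.46, "late": 2.47})
    hmr_decrement: dict = field(default_factory=lambda: {
        "none": {"early": 0.0, "late": 0.0},
        "CAD": {"early": 0.39, "late": 0.56},
        "DCM": {"early": 0.65, "late": 0.69},
    })
    hmr_sd: float = 0.30
    hmr_floor: float = 1.0
    clip_range: tuple[float, float] = (0.0, 120.0)
    # planar image rendering
    planar_shape: tuple[int, int] = (64, 64)
    planar_background: float = 100.0
    planar_blob_sigma: float = 6.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def stratum_means(self, population: str, sex: str, phase: str) -> np.ndarray:
        if population not in ("Jp", "It"):
            raise GeneratorError(f"undefined population {population!r}")
        if sex not in ("M", "F") or phase not in PHASES:
            raise GeneratorError(f"undefined stratum ({sex!r}, {phase!r})")
        m = self.base_means.copy()
        if sex == "M":
            for s in MALE_INFERIOR_SEGMENTS:
                m[s - 1] -= self.male_inferior_decrement
        if population == "It":
            for s in IT_ANTERIOR_SEGMENTS:
                m[s - 1] -= self.it_anterior_decrement
        if phase == "late":
            m -= self.late_phase_decrement
        return m


@dataclass
class SyntheticSubject:
    """One simulated subject: both-phase profiles, HMR draws, disease label."""

    subject_id: str
    population: str
    sex: str
    label: str                       # "none" | "CAD" | "DCM"
    profiles: dict                   # phase -> SegmentProfile
    hmr: dict                        # phase -> float
    territory: str | None = None     # CAD only
    seed: int = 0


def _draw_profiles(
    cfg: GeneratorConfig, rng: np.random.Generator, subject_id: str,
    population: str, sex: str, noise_scale: float = 1.0,
    decrement: np.ndarray | None = None,
) -> dict:
    profiles = {}
    for phase in PHASES:
        mean = cfg.stratum_means(population, sex, phase)
        if decrement is not None:
            mean = mean - decrement
        u = mean + rng.normal(0.0, cfg.base_sds * noise_scale)
        u = np.clip(u, *cfg.clip_range)
        profiles[phase] = SegmentProfile(
            u, phase=phase, subject_id=subject_id, sex=sex,
            population=population, normalized=True)
    return profiles


def _draw_hmr(cfg: GeneratorConfig, rng: np.random.Generator, label: str) -> dict:
    out = {}
    for phase in PHASES:
        mu = cfg.hmr_normal_mean[phase] - cfg.hmr_decrement[label][phase]
        out[phase] = float(max(cfg.hmr_floor, mu + rng.normal(0.0, cfg.hmr_sd)))
    return out


def _draw_sex(rng: np.random.Generator, sex: str | None) -> str:
    return sex if sex is not None else ("M" if rng.random() < 0.5 else "F")


def simulate_normal(
    config: GeneratorConfig, n: int, population: str = "Jp",
    sex: str | None = None, rng: np.random.Generator | None = None,
    id_prefix: str | None = None,
) -> list[SyntheticSubject]:
    """Disease-free cohort for one population (sex drawn 50/50 unless fixed)."""
    if n < 1:
        raise GeneratorError("n must be >= 1")
    rng = rng if rng is not None else config.rng()
    prefix = id_prefix or f"{population}N"
    cohort = []
    for i in range(n):
        sid = f"{prefix}{i:03d}"
        sx = _draw_sex(rng, sex)
        cohort.append(SyntheticSubject(
            subject_id=sid, population=population, sex=sx, label="none",
            profiles=_draw_profiles(config, rng, sid, population, sx),
            hmr=_draw_hmr(config, rng, "none"), seed=config.seed))
    return cohort


def simulate_cad(
    config: GeneratorConfig, n: int, population: str = "Jp",
    rng: np.random.Generator | None = None, id_prefix: str = "CAD",
) -> list[SyntheticSubject]:
    """CAD cohort: one random coronary territory reduced by a random depth."""
    if n < 1:
        raise GeneratorError("n must be >= 1")
    rng = rng if rng is not None else config.rng()
    names = sorted(TERRITORIES)
    cohort = []
    for i in range(n):
        sid = f"{id_prefix}{i:03d}"
        sx = _draw_sex(rng, None)
        terr = names[rng.integers(len(names))]
        depth = rng.uniform(*config.cad_depth_range)
        dec = np.zeros(N_SEGMENTS)
        dec[[s - 1 for s in TERRITORIES[terr]]] = depth
        cohort.append(SyntheticSubject(
            subject_id=sid, population=population, sex=sx, label="CAD",
            profiles=_draw_profiles(config, rng, sid, population, sx,
                                    decrement=dec),
            hmr=_draw_hmr(config, rng, "CAD"), territory=terr,
            seed=config.seed))
    return cohort


def simulate_dcm(
    config: GeneratorConfig, n: int, population: str = "Jp",
    rng: np.random.Generator | None = None, id_prefix: str = "DCM",
) -> list[SyntheticSubject]:
    """DCM cohort: diffuse global decrement with inflated segment noise."""
    if n < 1:
        raise GeneratorError("n must be >= 1")
    rng = rng if rng is not None else config.rng()
    cohort = []
    for i in range(n):
        sid = f"{id_prefix}{i:03d}"
        sx = _draw_sex(rng, None)
        dec = np.full(N_SEGMENTS, rng.uniform(*config.dcm_decrement_range))
        cohort.append(SyntheticSubject(
            subject_id=sid, population=population, sex=sx, label="DCM",
            profiles=_draw_profiles(config, rng, sid, population, sx,
                                    noise_scale=config.dcm_noise_inflation,
                                    decrement=dec),
            hmr=_draw_hmr(config, rng, "DCM"), seed=config.seed))
    return cohort


def default_rois(config: GeneratorConfig) -> ROIPair:
    """Heart circle over the cardiac blob, mediastinum box on the upper midline."""
    nr, nc = config.planar_shape
    return ROIPair(
        heart_center=(round(nr * 0.62), round(nc * 0.34)),
        heart_radius=round(min(nr, nc) * 0.14),
        med_corner=(round(nr * 0.06), round(nc * 0.44)),
        med_height=round(nr * 0.16), med_width=round(nc * 0.12),
    )


def simulate_planar(
    target_hmr: float, config: GeneratorConfig,
    rng: np.random.Generator | None = None, poisson: bool = True,
) -> tuple[PlanarImage, ROIPair]:
    """Planar image whose ROI count ratio matches ``target_hmr``.

    A flat background plus a cardiac 2D Gaussian blob centered on the heart
    ROI; the blob amplitude is solved so the noiseless heart-ROI mean over
    the mediastinum-ROI mean equals the target exactly.  With ``poisson``
    the expected image is replaced by Poisson-distributed counts.
    """
    if target_hmr < 1.0:
        raise GeneratorError("target HMR below 1 is unattainable over background")
    rois = default_rois(config)
    nr, nc = config.planar_shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    cy, cx = rois.heart_center
    blob = np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2)
                  / (2.0 * config.planar_blob_sigma**2))
    hmask, mmask = rois.validate((nr, nc))
    b = config.planar_background
    g_heart = blob[hmask].mean()
    g_med = blob[mmask].mean()
    # (b + A*g_heart) / (b + A*g_med) = target  ->  solve for amplitude A
    denom = g_heart - target_hmr * g_med
    if denom <= 0:
        raise GeneratorError("blob geometry cannot attain the target HMR")
    amp = b * (target_hmr - 1.0) / denom
    expected = b + amp * blob
    if poisson:
        rng = rng if rng is not None else config.rng()
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return PlanarImage(counts, phase="early"), rois


def simulate_study(
    config: GeneratorConfig,
    n_jp_normal: int = 55, n_it_normal: int = 33,
    n_cad: int = 15, n_dcm: int = 15, n_control: int = 12,
) -> dict:
    """Full study layout: two normal-cohort arms plus a validation arm.

    Defaults mirror a two-center normative study (55 + 33 normals) with a
    mixed heart-failure validation cohort.  One RNG stream drives all arms,
    so the whole study is reproducible from ``config.seed``.
    """
    rng = config.rng()
    jp = simulate_normal(config, n_jp_normal, "Jp", rng=rng, id_prefix="JpN")
    it = simulate_normal(config, n_it_normal, "It", rng=rng, id_prefix="ItN")
    validation = (
        simulate_cad(config, n_cad, rng=rng)
        + simulate_dcm(config, n_dcm, rng=rng)
        + simulate_normal(config, n_control, "Jp", rng=rng, id_prefix="CTL")
    )
    return {"jp_normals": jp, "it_normals": it, "validation": validation}
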