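"""Synthetic cohort generator: determinism, truth recovery, disease effects."""

import numpy as np
import pytest

from mibgndb import (TERRITORIES, GeneratorConfig, build_ndb, compute_hmr,
                     simulate_cad, simulate_dcm, simulate_normal,
                     simulate_planar, simulate_study)
from mibgndb.pipeline import summed_auto_scores
from mibgndb.synthetic import (IT_ANTERIOR_SEGMENTS, MALE_INFERIOR_SEGMENTS,
                               GeneratorError)


def seg_matrix(cohort, phase="early"):
    return np.stack([s.profiles[phase].values for s in cohort])


class TestSimulateNormal:
    def test_zero_noise_reproduces_stratum_mean(self):
        cfg = GeneratorConfig(seed=1, base_sds=np.zeros(17))
        cohort = simulate_normal(cfg, 5, "Jp", sex="F")
        truth = cfg.stratum_means("Jp", "F", "early")
        for s in cohort:
            np.testing.assert_allclose(s.profiles["early"].values, truth)

    def test_same_seed_gives_identical_cohorts(self):
        a = simulate_normal(GeneratorConfig(seed=42), 10, "It")
        b = simulate_normal(GeneratorConfig(seed=42), 10, "It")
        np.testing.assert_array_equal(seg_matrix(a), seg_matrix(b))
        assert [s.hmr for s in a] == [s.hmr for s in b]
        assert [s.sex for s in a] == [s.sex for s in b]

    def test_different_seeds_differ(self):
        a = simulate_normal(GeneratorConfig(seed=1), 5, "Jp")
        b = simulate_normal(GeneratorConfig(seed=2), 5, "Jp")
        assert not np.array_equal(seg_matrix(a), seg_matrix(b))

    def test_truth_recovery_at_large_n(self):
        cfg = GeneratorConfig(seed=3)
        cohort = simulate_normal(cfg, 500, "Jp", sex="M")
        mat = seg_matrix(cohort)
        truth = cfg.stratum_means("Jp", "M", "early")
        # segment-wise means stay inside the 4-sigma sampling envelope and
        # the cohort-averaged relative error is below 1%
        se = cfg.base_sds / np.sqrt(500)
        assert np.all(np.abs(mat.mean(axis=0) - truth) <= 4 * se)
        assert np.mean(np.abs(mat.mean(axis=0) / truth - 1.0)) <= 0.01
        sds = mat.std(axis=0, ddof=1)
        # per-segment SDs carry ~3.2% sampling error at this n: 5% applies
        # to the segment-averaged ratio, 20% segment-wise
        assert abs((sds / cfg.base_sds).mean() - 1.0) <= 0.05
        np.testing.assert_allclose(sds, cfg.base_sds, rtol=0.20)

    def test_male_inferior_wall_reduced(self):
        cfg = GeneratorConfig(seed=4)
        males = cfg.stratum_means("Jp", "M", "early")
        females = cfg.stratum_means("Jp", "F", "early")
        inf = [s - 1 for s in MALE_INFERIOR_SEGMENTS]
        assert np.all(males[inf] < females[inf])
        other = np.setdiff1d(np.arange(17), inf)
        np.testing.assert_array_equal(males[other], females[other])

    def test_it_anterior_reduced_vs_jp(self):
        cfg = GeneratorConfig(seed=4)
        jp = cfg.stratum_means("Jp", "F", "early")
        it = cfg.stratum_means("It", "F", "early")
        ant = [s - 1 for s in IT_ANTERIOR_SEGMENTS]
        assert np.all(it[ant] < jp[ant])

    def test_undefined_stratum_rejected(self):
        cfg = GeneratorConfig()
        with pytest.raises(GeneratorError):
            cfg.stratum_means("Fr", "M", "early")
        with pytest.raises(GeneratorError):
            cfg.stratum_means("Jp", "X", "early")


class TestDiseaseEffects:
    def test_zero_depth_cad_matches_normal_means(self):
        cfg = GeneratorConfig(seed=5, cad_depth_range=(0.0, 0.0))
        cad = simulate_cad(cfg, 300)
        normal = simulate_normal(GeneratorConfig(seed=6), 300, "Jp")
        np.testing.assert_allclose(seg_matrix(cad).mean(axis=0),
                                   seg_matrix(normal).mean(axis=0), atol=1.5)

    def test_lad_lesion_reduces_exactly_its_segments(self):
        cfg = GeneratorConfig(seed=7, base_sds=np.zeros(17),
                              cad_depth_range=(40.0, 40.0))
        cohort = simulate_cad(cfg, 40)
        truth = {sex: cfg.stratum_means("Jp", sex, "early")
                 for sex in ("M", "F")}
        lads = [s for s in cohort if s.territory == "LAD"]
        assert lads, "expected at least one LAD lesion in 40 draws"
        for s in lads:
            delta = truth[s.sex] - s.profiles["early"].values
            hit = np.where(delta > 1e-9)[0] + 1
            assert set(hit) == set(TERRITORIES["LAD"])
            np.testing.assert_allclose(delta[hit - 1], 40.0)

    def test_zero_effect_dcm_matches_normal_means(self):
        cfg = GeneratorConfig(seed=8, dcm_decrement_range=(0.0, 0.0),
                              dcm_noise_inflation=1.0)
        dcm = simulate_dcm(cfg, 300)
        normal = simulate_normal(GeneratorConfig(seed=9), 300, "Jp")
        np.testing.assert_allclose(seg_matrix(dcm).mean(axis=0),
                                   seg_matrix(normal).mean(axis=0), atol=1.5)

    def test_global_decrement_shifts_every_segment(self):
        cfg = GeneratorConfig(seed=10, base_sds=np.zeros(17),
                              dcm_decrement_range=(20.0, 20.0),
                              dcm_noise_inflation=1.0)
        cohort = simulate_dcm(cfg, 10)
        for s in cohort:
            truth = cfg.stratum_means("Jp", s.sex, "early")
            np.testing.assert_allclose(truth - s.profiles["early"].values, 20.0)

    def test_group_hierarchy_of_hmr_and_scores(self, small_study):
        """Diffuse DCM depresses HMR most; focal CAD drives the defect score."""
        cfg = GeneratorConfig(seed=2)
        rng = cfg.rng()
        normal = simulate_normal(cfg, 150, "Jp", rng=rng)
        cad = simulate_cad(cfg, 150, rng=rng)
        dcm = simulate_dcm(cfg, 150, rng=rng)
        for phase in ("early", "late"):
            h = {g: np.mean([s.hmr[phase] for s in c])
                 for g, c in (("none", normal), ("CAD", cad), ("DCM", dcm))}
            assert h["DCM"] < h["CAD"] < h["none"]
        ndb = small_study["ndbs"]["JpIt"]["early"]
        score_cad = summed_auto_scores(cad, ndb, "early").mean()
        score_dcm = summed_auto_scores(dcm, ndb, "early").mean()
        score_none = summed_auto_scores(normal, ndb, "early").mean()
        assert score_cad > score_none
        assert score_cad > score_dcm

    def test_clipping_keeps_profiles_in_range(self):
        cfg = GeneratorConfig(seed=11, cad_depth_range=(90.0, 110.0))
        cohort = simulate_cad(cfg, 50)
        mat = seg_matrix(cohort)
        assert mat.min() >= 0.0 and mat.max() <= 120.0


class TestSimulatePlanar:
    def test_noiseless_unity_target(self, config):
        img, rois = simulate_planar(1.0, config, poisson=False)
        assert compute_hmr(img, rois) == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_target_two(self, config):
        img, rois = simulate_planar(2.0, config, poisson=False)
        assert compute_hmr(img, rois) == pytest.approx(2.0, abs=0.02)

    def test_poisson_replicates_center_on_target(self, config):
        rng = np.random.default_rng(12)
        vals = [compute_hmr(*simulate_planar(2.2, config, rng=rng))
                for _ in range(200)]
        assert np.mean(vals) == pytest.approx(2.2, rel=0.02)

    def test_subunity_target_rejected(self, config):
        with pytest.raises(GeneratorError):
            simulate_planar(0.8, config)


class TestSimulateStudy:
    def test_layout_and_determinism(self):
        cfg = GeneratorConfig(seed=13)
        a = simulate_study(cfg, 12, 8, 5, 5, 4)
        b = simulate_study(GeneratorConfig(seed=13), 12, 8, 5, 5, 4)
        assert len(a["jp_normals"]) == 12 and len(a["it_normals"]) == 8
        labels = [s.label for s in a["validation"]]
        assert labels.count("CAD") == 5 and labels.count("DCM") == 5
        assert labels.count("none") == 4
        np.testing.assert_array_equal(seg_matrix(a["validation"]),
                                      seg_matrix(b["validation"]))

    def test_ndb_built_from_cohort_recovers_truth(self):
        cfg = GeneratorConfig(seed=14)
        cohort = simulate_normal(cfg, 400, "It", sex="F")
        ndb = build_ndb([s.profiles["late"] for s in cohort])
        truth = cfg.stratum_means("It", "F", "late")
        np.testing.assert_allclose(ndb.mean, truth, rtol=0.015)
        np.testing.assert_allclose(ndb.sd, cfg.base_sds, rtol=0.12)
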