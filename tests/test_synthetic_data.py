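"""Generators: reproducibility, exact bookkeeping, Poisson calibration,
cohort structure, and the Monte-Carlo overestimation experiment."""

import numpy as np
import pytest

import tmekit as tk
from tmekit.synthetic_data import (
    OverestimationSimConfig,
    mc_overestimation_probability,
)


class TestSlideSimulation:
    def test_zero_intensities_give_zero_nuclei(self):
        cfg = tk.SlideSimConfig(
            intensities={"tumor": {}, "vicinity": {}, "outside": {}}, seed=0
        )
        annotation, _, gt = tk.simulate_slide(cfg)
        assert annotation.nuclei == [] and gt["n_nuclei"] == 0

    def test_same_seed_reproduces_identical_slides(self):
        a1, m1, g1 = tk.simulate_slide(tk.SlideSimConfig(seed=42))
        a2, m2, g2 = tk.simulate_slide(tk.SlideSimConfig(seed=42))
        np.testing.assert_array_equal(m1.raster, m2.raster)
        assert g1 == g2
        assert [n.centroid for n in a1.nuclei] == [n.centroid for n in a2.nuclei]

    def test_poisson_count_calibration(self):
        # lymphocytes at 100/mm^2: the realized count sits in a wide Poisson band
        cfg = tk.SlideSimConfig(
            intensities={"tumor": {2: 100.0}, "vicinity": {}, "outside": {}},
            seed=9,
        )
        _, mask, gt = tk.simulate_slide(cfg)
        area_mm2 = gt["tumor_pixel_count"] * (cfg.mpp * cfg.downsample / 1000.0) ** 2
        lam = 100.0 * area_mm2
        count = gt["counts"]["tumor"][2]
        assert abs(count - lam) < 4 * np.sqrt(lam)

    def test_ground_truth_counts_match_recomputation(self, assigned_slide):
        assigned, mask, regions, gt = assigned_slide
        ring = tk.compute_vicinity(
            regions,
            tk.VicinityConfig(width_mm=1.0, mpp=assigned.mpp, downsample=mask.downsample),
        ).astype(bool)
        recomputed = {z: {} for z in ("tumor", "vicinity", "outside")}
        ds = mask.downsample
        for n in assigned.nuclei:
            if n.tumor_region_id > 0:
                zone = "tumor"
            else:
                r, c = int(n.centroid[1] // ds), int(n.centroid[0] // ds)
                zone = "vicinity" if ring[r, c] else "outside"
            recomputed[zone][n.class_label] = recomputed[zone].get(n.class_label, 0) + 1
        for zone in recomputed:
            expected = {k: v for k, v in gt["counts"][zone].items() if v}
            assert recomputed[zone] == expected

    def test_tumor_intensity_without_tumor_area_rejected(self):
        cfg = tk.SlideSimConfig(n_blobs=0, seed=0)  # default tumor intensities > 0
        with pytest.raises(ValueError, match="no tumor area"):
            tk.simulate_slide(cfg)

    def test_repulsion_enforces_minimum_distance(self):
        cfg = tk.SlideSimConfig(
            intensities={"tumor": {1: 60.0, 3: 60.0}, "vicinity": {}, "outside": {}},
            repulsion={("tumor", 3, 1): 60.0},
            seed=4,
        )
        annotation, mask, _ = tk.simulate_slide(cfg)
        gran = np.array([n.centroid for n in annotation.nuclei if n.class_label == 1])
        plasma = np.array([n.centroid for n in annotation.nuclei if n.class_label == 3])
        d = np.sqrt(
            ((plasma[:, None, :] - gran[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        assert d.min() >= 60.0 / cfg.mpp - 1e-9


class TestCohortSimulation:
    @pytest.fixture(scope="class")
    def cohort(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("cohort")
        cfg = tk.CohortSimConfig(n_responders=4, n_non_responders=3, seed=0)
        slide_cfg = tk.SlideSimConfig(image_size=(1536, 1536), n_blobs=1, seed=0)
        return tk.simulate_cohort(cfg, slide_cfg, out_dir=out), out

    def test_structure_and_default_sizes(self, cohort):
        result, _ = cohort
        assert len(result["slides"]) == 7
        labels = result["cohort"].frame["label"].tolist()
        assert labels.count("responder") == 4 and labels.count("non_responder") == 3
        default = tk.CohortSimConfig()
        assert default.n_responders == 28 and default.n_non_responders == 17

    def test_written_files_round_trip(self, cohort):
        result, out = cohort
        table = tk.read_cohort_csv(out / "cohort.csv")
        for (annotation, mask, _), sid in zip(result["slides"], table.sample_ids):
            back = tk.read_nucleus_json(out / f"{sid}.json")
            assert len(back.nuclei) == len(annotation.nuclei)
            back_mask = tk.read_tumor_mask(out / f"{sid}_mask.png", mask.downsample)
            np.testing.assert_array_equal(back_mask.raster, mask.raster)

    def test_ground_truth_names_registry_features(self, cohort, registry):
        result, _ = cohort
        for name in result["ground_truth"]["planted_features"]:
            assert name in registry.names

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            tk.CohortSimConfig(effects={(9, "tumor"): (1.0, 2.0)})


class TestFeatureCohort:
    def test_shapes_labels_and_determinism(self):
        sim = tk.simulate_feature_cohort(tk.FeatureCohortSimConfig(seed=11))
        assert sim["features"].shape == (45, 107)
        assert sim["labels"].sum() == 28
        sim2 = tk.simulate_feature_cohort(tk.FeatureCohortSimConfig(seed=11))
        assert sim["features"].equals(sim2["features"])

    def test_exactly_planted_and_weak_columns_carry_signal(self):
        cfg = tk.FeatureCohortSimConfig(seed=3)
        sim = tk.simulate_feature_cohort(cfg)
        X, y = sim["features"], sim["labels"]
        carriers = set(cfg.planted_features) | set(cfg.weak_features)
        gaps = (X[y == 1].mean() - X[y == 0].mean()).abs()
        for f in cfg.planted_features:
            assert gaps[f] > 1.0
        null_gap = gaps.drop(list(carriers))
        # null columns: group gap is pure noise, below every planted signal
        assert null_gap.max() < gaps[list(cfg.planted_features)].min()

    def test_unknown_feature_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            tk.simulate_feature_cohort(
                tk.FeatureCohortSimConfig(planted_features=("no_such_feature",))
            )


class TestOverestimationMonteCarlo:
    def test_single_point_never_overestimates(self):
        p, se = mc_overestimation_probability(
            OverestimationSimConfig(n_points=1, replicates=100_000, seed=0)
        )
        assert p == 0.0

    def test_probability_decreases_with_point_count(self):
        estimates = {}
        for n in (2, 5, 10):
            p, se = mc_overestimation_probability(
                OverestimationSimConfig(n_points=n, replicates=400_000, seed=1)
            )
            estimates[n] = (p, se)
        assert estimates[2][0] - estimates[5][0] > 5 * (estimates[2][1] + estimates[5][1])
        assert estimates[5][0] > estimates[10][0]

    def test_conditional_exceeds_unconditional(self):
        cfg_c = OverestimationSimConfig(n_points=2, replicates=200_000, seed=2)
        cfg_u = OverestimationSimConfig(
            n_points=2, replicates=200_000, seed=2, conditional=False
        )
        pc, _ = mc_overestimation_probability(cfg_c)
        pu, _ = mc_overestimation_probability(cfg_u)
        assert pc > pu > 0

    def test_reproducible_across_runs_same_seed(self):
        cfg = OverestimationSimConfig(n_points=2, replicates=200_000, seed=3)
        assert mc_overestimation_probability(cfg) == mc_overestimation_probability(cfg)

    def test_small_replicates_at_large_n_warns(self):
        with pytest.warns(UserWarning, match="replicates"):
            mc_overestimation_probability(
                OverestimationSimConfig(n_points=10, replicates=1000, seed=0)
            )
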