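"""Expanding-rectangle search: hand-stepped schedules, oracle bounds,
ordering invariance, and slide-level averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tmekit as tk
from tmekit.spatial_metrics import (
    NOT_FOUND,
    SearchConfig,
    _per_source_min_distances,
    brute_force_min_distance,
    expanding_rectangle_min_distance,
)


class TestExpandingRectangle:
    def test_single_target_inside_first_rectangle(self):
        # 50 x 50 rectangle at lambda=1 (half-extent 25) contains (3, 4)
        d = expanding_rectangle_min_distance((0, 0), [(3, 4)], 1000, 1000)
        assert d == 5.0

    def test_schedule_steps_until_first_capture(self):
        # lambda=1 (+-25) empty; lambda=2 (+-50) captures (30, 0) only
        d = expanding_rectangle_min_distance((0, 0), [(30, 0), (0, 60)], 1000, 1000)
        assert d == 30.0
        assert brute_force_min_distance((0, 0), [(30, 0), (0, 60)]) == 30.0

    def test_documented_overestimation_case(self):
        # lambda=1 keeps only (24, 24): sqrt(1152) > true NN distance 26
        d = expanding_rectangle_min_distance((0, 0), [(0, 26), (24, 24)], 1000, 1000)
        assert d == pytest.approx(math.sqrt(1152))
        assert brute_force_min_distance((0, 0), [(0, 26), (24, 24)]) == 26.0
        assert d > 26.0

    def test_empty_targets_not_found(self):
        assert np.isnan(expanding_rectangle_min_distance((0, 0), [], 100, 100))
        assert np.isnan(brute_force_min_distance((0, 0), []))

    def test_lambda_cap_returns_not_found(self):
        cfg = SearchConfig(f=0.05, lambda_max=1)
        d = expanding_rectangle_min_distance((0, 0), [(900, 900)], 1000, 1000, cfg)
        assert np.isnan(d)

    def test_degenerate_bounding_box_rejected(self):
        with pytest.raises(ValueError):
            expanding_rectangle_min_distance((0, 0), [(1, 1)], 0, 100)

    def test_boundary_target_counts_as_inside(self):
        # half-extent at lambda=1 is exactly 25
        d = expanding_rectangle_min_distance((0, 0), [(25, 0)], 1000, 1000)
        assert d == 25.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-400, 400, allow_nan=False),
                st.floats(-400, 400, allow_nan=False),
            ),
            min_size=1,
            max_size=25,
        ),
        st.integers(0, 2**16),
    )
    def test_never_underestimates_and_order_invariant(self, targets, seed):
        rng = np.random.default_rng(seed)
        source = tuple(rng.uniform(-200, 200, size=2))
        d = expanding_rectangle_min_distance(source, targets, 1000.0, 800.0)
        bf = brute_force_min_distance(source, targets)
        assert d >= bf - 1e-9
        perm = [targets[i] for i in rng.permutation(len(targets))]
        assert expanding_rectangle_min_distance(source, perm, 1000.0, 800.0) == d
        # duplicating a non-minimal target changes nothing
        far = max(targets, key=lambda t: (t[0] - source[0]) ** 2 + (t[1] - source[1]) ** 2)
        assert expanding_rectangle_min_distance(source, targets + [far], 1000.0, 800.0) == d

    def test_equals_brute_force_when_first_rectangle_covers_region(self):
        rng = np.random.default_rng(3)
        targets = rng.uniform(-50, 50, size=(30, 2))
        cfg = SearchConfig(f=1.0)  # lambda=1 rectangle spans the full box
        for src in rng.uniform(-10, 10, size=(10, 2)):
            d = expanding_rectangle_min_distance(tuple(src), targets, 200.0, 200.0, cfg)
            assert d == pytest.approx(brute_force_min_distance(tuple(src), targets))

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(5)
        sources = rng.uniform(0, 500, size=(40, 2))
        targets = rng.uniform(0, 500, size=(60, 2))
        cfg = SearchConfig()
        vec = _per_source_min_distances(sources, targets, 600.0, 450.0, cfg, False)
        for i, src in enumerate(sources):
            scalar = expanding_rectangle_min_distance(tuple(src), targets, 600.0, 450.0, cfg)
            assert vec[i] == pytest.approx(scalar)


class TestAverageClosestDistance:
    def _slide(self, centroids_by_class, size=(400, 400)):
        """Build a one-region slide with the given class -> centroid lists."""
        from tmekit.io_formats import NucleusRecord, SlideAnnotation, TumorMask

        raster = np.ones((size[1] // 4, size[0] // 4), dtype=np.uint8)
        mask = TumorMask(raster, downsample=4)
        nuclei = []
        iid = 1
        for cls, pts in centroids_by_class.items():
            for x, y in pts:
                contour = [(x - 2, y - 2), (x + 2, y - 2), (x + 2, y + 2), (x - 2, y + 2)]
                nuclei.append(NucleusRecord(iid, (x, y), contour, cls))
                iid += 1
        ann = SlideAnnotation(nuclei=nuclei, mpp=0.5, image_size=size, sample_id="t")
        regions = tk.label_tumor_regions(mask)
        return tk.assign_nuclei_to_regions(ann, regions), regions

    def test_single_pair_returns_distance_in_px_and_um(self):
        ann, regions = self._slide({1: [(100.0, 100.0)], 3: [(103.0, 104.0)]})
        res = tk.average_closest_distance(ann, regions, tk.DistanceQuery(1, 3))
        assert res.mean_px == pytest.approx(5.0)
        assert res.mean_um == pytest.approx(2.5)  # mpp = 0.5
        assert res.n_sources_used == 1

    def test_mean_of_two_sources(self):
        ann, regions = self._slide(
            {1: [(50.0, 50.0), (200.0, 200.0)], 3: [(60.0, 50.0), (230.0, 200.0)]}
        )
        res = tk.average_closest_distance(ann, regions, tk.DistanceQuery(1, 3))
        assert res.mean_px == pytest.approx((10.0 + 30.0) / 2.0)

    def test_no_targets_gives_missing_and_skip_count(self):
        ann, regions = self._slide({1: [(50.0, 50.0)]})
        res = tk.average_closest_distance(ann, regions, tk.DistanceQuery(1, 3))
        assert res.missing
        assert res.n_sources_skipped == 1

    def test_same_class_excludes_self(self):
        ann, regions = self._slide({5: [(100.0, 100.0), (110.0, 100.0)]})
        res = tk.average_closest_distance(ann, regions, tk.DistanceQuery(5, 5))
        assert res.mean_px == pytest.approx(10.0)

    def test_random_blob_average_bounds_brute_force(self, refined_slide):
        refined, _, regions, _, _ = refined_slide
        res = tk.average_closest_distance(refined, regions, tk.DistanceQuery(2, 5))
        # brute-force same-region oracle
        by_region = {}
        for n in refined.nuclei:
            if n.tumor_region_id and n.tumor_region_id > 0:
                by_region.setdefault(n.tumor_region_id, {}).setdefault(
                    n.class_label, []
                ).append(n.centroid)
        vals = []
        for groups in by_region.values():
            for src in groups.get(2, []):
                tgt = groups.get(5, [])
                if tgt:
                    vals.append(brute_force_min_distance(src, tgt))
        assert res.mean_px >= np.mean(vals) - 1e-9
        # overestimation is rare at these densities: within 1% of the oracle
        assert res.mean_px <= np.mean(vals) * 1.01

    def test_search_confined_to_own_region(self):
        # two far-apart regions; the only target lives in the other region
        from tmekit.io_formats import NucleusRecord, SlideAnnotation, TumorMask

        raster = np.zeros((100, 100), dtype=np.uint8)
        raster[10:30, 10:30] = 1
        raster[70:90, 70:90] = 1
        mask = TumorMask(raster, downsample=4)
        regions = tk.label_tumor_regions(mask)
        mk = lambda i, x, y, c: NucleusRecord(
            i, (x, y), [(x - 2, y - 2), (x + 2, y - 2), (x, y + 2)], c
        )
        ann = SlideAnnotation(
            nuclei=[mk(1, 80.0, 80.0, 1), mk(2, 320.0, 320.0, 3)],
            mpp=1.0,
            image_size=(400, 400),
            sample_id="two",
        )
        ann = tk.assign_nuclei_to_regions(ann, regions)
        res = tk.average_closest_distance(ann, regions, tk.DistanceQuery(1, 3))
        assert res.missing
        assert res.n_sources_skipped == 1

    def test_invalid_distance_class_rejected(self):
        with pytest.raises(ValueError):
            tk.DistanceQuery(4, 2)  # stromal cells carry no distance features
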