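"""Image quantification pipeline: each morphological stage against an oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiptaxis import (
    SpotSet,
    VesselMask,
    WellNotFoundError,
    WellRegion,
    classify_compartments,
    collapse_zstack,
    detect_spots,
    find_central_well,
    generate_vessel_image,
    recruitment_timecourse,
    segment_vasculature,
    spheroid_equivalent_diameter,
)
from chiptaxis.quantify import QuantConfig, quantify_image
from conftest import match_to_truth


class TestCollapseZstack:
    def test_single_plane_is_identity(self):
        plane = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(collapse_zstack(plane[None]), plane)
        np.testing.assert_array_equal(collapse_zstack(plane), plane)

    def test_brighter_plane_dominates(self):
        a = np.ones((4, 4))
        stack = np.stack([a, 3 * a])
        np.testing.assert_array_equal(collapse_zstack(stack), 3 * a)

    def test_random_stack_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(0)
        stack = rng.random((5, 6, 7))
        proj = collapse_zstack(stack)
        for r in range(6):
            for c in range(7):
                assert proj[r, c] == max(stack[z, r, c] for z in range(5))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            collapse_zstack(np.empty((0, 4, 4)))


def _otsu_sweep_oracle(values: np.ndarray) -> float:
    """Exhaustive threshold sweep maximizing between-class variance."""
    best_t, best_v = None, -1.0
    for t in np.unique(values)[:-1]:
        lo, hi = values[values <= t], values[values > t]
        w0, w1 = lo.size / values.size, hi.size / values.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


class TestSegmentVasculature:
    def test_manual_threshold_on_zero_image(self):
        mask = segment_vasculature(np.zeros((8, 8)), 1.0, "manual", manual_threshold=1)
        assert not mask.binary.any()

    def test_otsu_on_bimodal_matches_sweep_oracle(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((50, 50)) < 0.1, 200.0, 10.0)
        oracle_t = _otsu_sweep_oracle(img.ravel())
        mask = segment_vasculature(img, 1.0, "otsu")
        np.testing.assert_array_equal(mask.binary, img > oracle_t)
        np.testing.assert_array_equal(mask.binary, img == 200.0)

    def test_otsu_invariant_to_constant_offset(self):
        rng = np.random.default_rng(2)
        img = np.where(rng.random((50, 50)) < 0.1, 200.0, 10.0)
        a = segment_vasculature(img, 1.0, "otsu")
        b = segment_vasculature(img + 37.0, 1.0, "otsu")
        np.testing.assert_array_equal(a.binary, b.binary)

    def test_manual_without_threshold_rejected(self):
        with pytest.raises(ValueError, match="manual_threshold"):
            segment_vasculature(np.zeros((4, 4)), 1.0, "manual")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            segment_vasculature(np.zeros((4, 4)), 1.0, "adaptive")


class TestFindCentralWell:
    def test_well_overlaps_truth_with_high_dice(self, bundle100, quantified100):
        _, _, _, well = quantified100
        truth = bundle100.truth_well_mask
        inter = (well.binary & truth).sum()
        dice = 2 * inter / (well.binary.sum() + truth.sum())
        assert dice >= 0.85

    def test_gapless_mask_has_no_well(self):
        mask = VesselMask(binary=np.ones((100, 100), dtype=bool), pixel_size_um=4.0)
        with pytest.raises(WellNotFoundError):
            find_central_well(mask)

    def test_iteration_count_insensitivity(self, bundle100):
        mask = segment_vasculature(bundle100.vasculature, bundle100.pixel_size_um)
        well_a, _ = find_central_well(mask, n_iterations=10)
        well_b, _ = find_central_well(mask, n_iterations=20)
        assert abs(well_b.area_um2 - well_a.area_um2) <= 0.05 * well_a.area_um2

    def test_luminal_mask_excludes_dilated_well(self, bundle100):
        mask = segment_vasculature(bundle100.vasculature, bundle100.pixel_size_um)
        well, lumens = find_central_well(mask)
        assert not np.any(lumens.binary & well.binary)

    def test_n_iterations_validated(self, bundle100):
        mask = segment_vasculature(bundle100.vasculature, bundle100.pixel_size_um)
        with pytest.raises(ValueError, match="n_iterations"):
            find_central_well(mask, n_iterations=0)


class TestDetectSpots:
    def test_blank_image_yields_no_spots(self):
        assert len(detect_spots(np.zeros((64, 64)), 4.0)) == 0

    def test_well_separated_spots_recovered_exactly(self, geometry):
        # 25 spots, >= 3 FWHM apart, snr 10, via the generator's own truth.
        b = generate_vessel_image(
            n_luminal=0, n_extravasated=25, n_recruited=0, snr=10.0, seed=13
        )
        spots = detect_spots(b.monocytes, b.pixel_size_um)
        assert len(spots) == 25
        matches, _ = match_to_truth(spots, b.truth_cells, tol_px=3.0)
        assert len(matches) == 25

    def test_intensity_rescaling_changes_nothing(self, bundle100):
        a = detect_spots(bundle100.monocytes, bundle100.pixel_size_um)
        b = detect_spots(bundle100.monocytes * 5.0, bundle100.pixel_size_um)
        assert [(x, y) for x, y, _ in a.points] == [(x, y) for x, y, _ in b.points]
        np.testing.assert_allclose(
            [v for _, _, v in a.points], [v for _, _, v in b.points], atol=1e-9
        )

    def test_min_separation_enforced(self, bundle100):
        sep_um = 30.0
        spots = detect_spots(bundle100.monocytes, bundle100.pixel_size_um, sep_um)
        rc = spots.coords_rc().astype(float)
        d2 = ((rc[:, None, :] - rc[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= (sep_um / bundle100.pixel_size_um) ** 2

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_prominence_validated(self, bad):
        with pytest.raises(ValueError, match="prominence"):
            detect_spots(np.zeros((8, 8)), 4.0, prominence=bad)


class TestClassifyCompartments:
    def _masks(self, shape=(20, 20)):
        vessels = np.zeros(shape, dtype=bool)
        vessels[:, :5] = True
        well = np.zeros(shape, dtype=bool)
        well[:, 10:] = True
        return (
            VesselMask(binary=vessels, pixel_size_um=1.0),
            WellRegion(binary=well, area_um2=float(well.sum()), centroid_px=(10, 15)),
        )

    def test_empty_spot_set(self):
        vessels, well = self._masks()
        counts = classify_compartments(SpotSet(points=[]), vessels, well)
        assert counts.as_dict() == {
            "luminal": 0, "extravasated": 0, "recruited": 0,
            "total": 0, "recruited_fraction": 0.0,
        }

    def test_all_spots_in_well(self):
        vessels, well = self._masks()
        spots = SpotSet(points=[(12, r, 1.0) for r in range(5)])
        counts = classify_compartments(spots, vessels, well)
        assert counts.recruited == counts.total == 5
        assert counts.recruited_fraction == 1.0

    def test_well_takes_precedence_over_vessel(self):
        vessels, well = self._masks()
        overlap = VesselMask(binary=vessels.binary | well.binary, pixel_size_um=1.0)
        spots = SpotSet(points=[(15, 3, 1.0)])  # inside both masks
        counts = classify_compartments(spots, overlap, well)
        assert counts.recruited == 1 and counts.luminal == 0

    @given(
        xs=st.lists(st.integers(0, 19), min_size=0, max_size=30),
        ys=st.lists(st.integers(0, 19), min_size=0, max_size=30),
    )
    @settings(max_examples=30, deadline=None)
    def test_conservation_is_exact_for_any_spots(self, xs, ys):
        vessels, well = self._masks()
        pts = [(x, y, 1.0) for x, y in zip(xs, ys)]
        counts = classify_compartments(SpotSet(points=pts), vessels, well)
        assert counts.luminal + counts.extravasated + counts.recruited == counts.total
        assert counts.total == len(pts)

    def test_bundle_counts_within_ten_percent(self, bundle100, quantified100):
        counts, spots, lumens, well = quantified100
        truth = bundle100.truth_counts()
        for name in ("luminal", "extravasated", "recruited"):
            assert abs(getattr(counts, name) - truth[name]) <= 0.1 * truth[name]
        assert counts.total == len(spots.points)

    def test_enlarging_well_dilation_never_decreases_recruited(self, bundle100):
        mask = segment_vasculature(bundle100.vasculature, bundle100.pixel_size_um)
        spots = detect_spots(bundle100.monocytes, bundle100.pixel_size_um)
        previous = -1
        for dilation in (0.0, 25.0, 50.0, 100.0):
            well, lumens = find_central_well(mask, well_dilation_um=dilation)
            counts = classify_compartments(spots, lumens, well)
            assert counts.recruited >= previous
            previous = counts.recruited


class TestRecruitmentTimecourse:
    def _bundles(self):
        specs = [(5, 1), (15, 2), (30, 3)]
        return [
            (
                "dev1",
                day,
                generate_vessel_image(
                    n_luminal=60, n_extravasated=100 - 60 - rec, n_recruited=rec,
                    snr=10.0, seed=20 + day,
                ),
            )
            for rec, day in specs
        ]

    def test_recovered_fraction_increases_with_truth(self):
        items = [(d, day, b.image) for d, day, b in self._bundles()]
        table = recruitment_timecourse(items, 4.0)
        assert (table["flags"] == "").all()
        fracs = table.sort_values("day")["recruited_fraction"].to_numpy()
        assert np.all(np.diff(fracs) > 0)

    def test_identical_images_give_identical_rows(self, bundle100):
        items = [("d", day, bundle100.image) for day in (1, 2, 3)]
        table = recruitment_timecourse(items, bundle100.pixel_size_um)
        counts = table[["luminal", "extravasated", "recruited"]].drop_duplicates()
        assert len(counts) == 1

    def test_corrupt_image_is_flagged_not_fatal(self, bundle100):
        corrupt = np.ones_like(bundle100.image)  # no well anywhere
        items = [
            ("d", 1, bundle100.image),
            ("d", 2, corrupt),
            ("d", 3, bundle100.image),
        ]
        table = recruitment_timecourse(items, bundle100.pixel_size_um)
        assert (table["flags"] != "").sum() == 1
        ok = table[table["flags"] == ""]
        assert len(ok) == 2 and ok["total"].notna().all()

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            recruitment_timecourse([], 4.0)


class TestSpheroidDiameter:
    def test_disk_identity(self):
        rr, cc = np.mgrid[0:256, 0:256]
        disk = (rr - 128) ** 2 + (cc - 128) ** 2 <= 100**2
        d = spheroid_equivalent_diameter(disk, 1.0)
        assert abs(d - 200.0) <= 1.0

    def test_ellipse_with_equal_area_gives_same_diameter(self):
        rr, cc = np.mgrid[0:400, 0:400]
        # 2:1 ellipse with the same area as the radius-100 disk.
        a, b = 100 * np.sqrt(2), 100 / np.sqrt(2)
        ellipse = ((rr - 200) / b) ** 2 + ((cc - 200) / a) ** 2 <= 1.0
        d = spheroid_equivalent_diameter(ellipse, 1.0)
        assert abs(d - 200.0) <= 1.0

    def test_random_blob_matches_pixel_count_oracle(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage as ndi

        blob = ndi.gaussian_filter(rng.standard_normal((128, 128)), 12) > 0
        lbl, _ = ndi.label(blob)
        biggest = lbl == np.argmax(np.bincount(lbl.ravel())[1:]) + 1
        px = 2.5
        oracle = 2 * np.sqrt(biggest.sum() * px**2 / np.pi)
        assert spheroid_equivalent_diameter(biggest, px) == pytest.approx(oracle)

    def test_empty_and_fragmented_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            spheroid_equivalent_diameter(np.zeros((10, 10), dtype=bool), 1.0)
        two = np.zeros((10, 10), dtype=bool)
        two[1, 1] = two[8, 8] = True
        with pytest.raises(ValueError, match="connected"):
            spheroid_equivalent_diameter(two, 1.0)


def test_pipeline_determinism(bundle100):
    c1, s1, _, _ = quantify_image(bundle100.image, bundle100.pixel_size_um)
    c2, s2, _, _ = quantify_image(bundle100.image, bundle100.pixel_size_um)
    assert c1.as_dict() == c2.as_dict()
    assert s1.points == s2.points
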