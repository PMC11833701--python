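"""3D image quantification: backgrounds, masks, metrics, foci, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from meioquant import imagequant as iq
from meioquant import synthetic as syn
from meioquant.errors import (
    InsufficientDataError,
    InvalidInputError,
)
from meioquant.imagequant import (
    LabeledVolume,
    NucleusRecord,
    background_annulus,
    detect_foci,
    filter_nuclei,
    focus_intensity_cv,
    hexanediol_contrast,
    normalize_to_slide_wt,
    nucleus_metrics,
    profile_bins,
    segment_axis,
    straighten_positions,
)


def ball_labels(shape=(24, 48, 48), center=(12, 24, 24), radius=8):
    zz, yy, xx = np.indices(shape)
    mask = (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= radius**2
    return mask.astype(np.int32)


class TestBackgroundAnnulus:
    def test_uniform_image_returns_its_value(self):
        labels = ball_labels()
        img = np.full(labels.shape, 7.5)
        assert background_annulus(img, labels, 2, 10) == pytest.approx(7.5)

    def test_zero_outside_objects_returns_zero(self):
        labels = ball_labels()
        img = np.where(labels > 0, 100.0, 0.0)
        assert background_annulus(img, labels, 2, 10) == pytest.approx(0.0)

    def test_matches_bruteforce_distance_oracle(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((8, 64, 64), dtype=np.int32)
        labels[2:6, 10:20, 12:22] = 1
        labels[3:5, 40:50, 45:52] = 2
        img = rng.uniform(0, 100, labels.shape)
        rmin, rmax = 3.0, 9.0
        got = background_annulus(img, labels, rmin, rmax)
        # oracle: exhaustive per-voxel in-plane distance to every labeled voxel
        total, count = 0.0, 0
        for z in range(labels.shape[0]):
            obj = np.argwhere(labels[z] > 0)
            if obj.size == 0:
                continue
            for y in range(labels.shape[1]):
                for x in range(labels.shape[2]):
                    d = np.sqrt(((obj - [y, x]) ** 2).sum(axis=1)).min()
                    if rmin < d <= rmax:
                        total += img[z, y, x]
                        count += 1
        assert got == pytest.approx(total / count)

    def test_empty_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            background_annulus(np.ones((4, 8, 8)), np.zeros((4, 8, 8), np.int32))

    def test_empty_annulus_rejected(self):
        labels = np.ones((2, 4, 4), dtype=np.int32)  # no background at all
        with pytest.raises(InvalidInputError):
            background_annulus(np.ones((2, 4, 4)), labels, 1, 3)


class TestSegmentAxis:
    def test_bright_voxels_above_mean_selected(self):
        mask = np.zeros((3, 5, 5), bool)
        mask[1] = True
        img = np.zeros((3, 5, 5))
        img[1, 2, :] = 10.0  # mean inside mask = 2 -> the bright row wins
        axis = segment_axis(img, mask)
        assert np.array_equal(axis, mask & (img == 10.0))

    def test_constant_nucleus_gives_empty_mask(self):
        mask = ball_labels().astype(bool)
        img = np.full(mask.shape, 4.2)
        assert segment_axis(img, mask).sum() == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            segment_axis(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))

    def test_planted_filament_recovered(self, small_stack):
        volume, _ = small_stack
        nucleus = volume.labels == 1
        axis = segment_axis(volume.channels["axis"], nucleus)
        # planted filament: where the clean axis signal would be; recompute
        # from the noisy image via a generous intensity cut for the oracle
        planted = nucleus & (volume.channels["axis"] > 200)
        jaccard = (axis & planted).sum() / (axis | planted).sum()
        assert jaccard >= 0.8


class TestNucleusMetrics:
    def test_cube_volume(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[1:11, 1:11, 1:11] = 1
        vol = LabeledVolume(
            {"axis": np.random.default_rng(0).uniform(0, 1, labels.shape)},
            labels,
            (0.1, 0.1, 0.1),
        )
        rec = nucleus_metrics(vol, {"axis": 0.0}, "axis")[0]
        assert rec.volume == pytest.approx(1.0)

    def test_digital_ball_sphericity_near_one(self):
        labels = ball_labels(radius=9)
        vol = LabeledVolume(
            {"axis": np.random.default_rng(1).uniform(0, 1, labels.shape)},
            labels,
            (0.1, 0.1, 0.1),
        )
        rec = nucleus_metrics(vol, {"axis": 0.0}, "axis")[0]
        assert rec.sphericity == pytest.approx(1.0, abs=0.1)

    def test_planted_axis_ratio_recovered(self, small_stack, small_stack_records):
        _, truth = small_stack
        ratios = [r.axis_ratio for r in small_stack_records]
        planted = truth.params["axis_ratio"]
        assert np.mean(ratios) == pytest.approx(planted, abs=0.05)

    def test_axis_mask_subset_and_background_monotonicity(self, small_stack):
        volume, _ = small_stack
        nucleus = volume.labels == 2
        axis = segment_axis(volume.channels["axis"], nucleus)
        assert not np.any(axis & ~nucleus)
        lo = nucleus_metrics(volume, {k: 10.0 for k in volume.channels}, "axis", "sc")
        hi = nucleus_metrics(volume, {k: 30.0 for k in volume.channels}, "axis", "sc")
        for a, b in zip(lo, hi):
            for ch in a.nucleus_totals:
                assert b.nucleus_totals[ch] <= a.nucleus_totals[ch]
                assert b.nucleus_totals[ch] >= 0.0


class TestFilterNuclei:
    def base(self, **kw):
        defaults = dict(
            nucleus_id=1,
            centroid=(0, 0, 0),
            volume=30.0,
            sphericity=0.8,
            nucleus_totals={},
            axis_totals={},
            axis_ratio=0.5,
        )
        defaults.update(kw)
        return NucleusRecord(**defaults)

    @pytest.mark.parametrize(
        "kw,passes",
        [
            (dict(volume=60.0), False),  # volume bound exclusive
            (dict(volume=10.0), False),
            (dict(volume=10.01), True),
            (dict(sphericity=0.4), False),  # strictly greater
            (dict(sphericity=0.41), True),
            (dict(axis_ratio=0.3), True),  # ratio bounds inclusive
            (dict(axis_ratio=0.8), True),
            (dict(axis_ratio=0.29), False),
            (dict(axis_ratio=0.81), False),
            (dict(), True),
        ],
    )
    def test_boundaries(self, kw, passes):
        rec = self.base(**kw)
        kept = filter_nuclei([rec])
        assert (rec in kept) is passes
        assert rec.passed_filters is passes

    def test_decision_is_per_record(self):
        # filtering a record alone or with others gives the same decision
        recs = [self.base(volume=v) for v in (5.0, 30.0, 80.0)]
        solo = [filter_nuclei([r])[0:1] != [] for r in recs]
        joint = filter_nuclei(recs)
        assert [r in joint for r in recs] == [r.passed_filters for r in recs]
        assert solo == [r.passed_filters for r in recs]


class TestStraightenPositions:
    def test_straight_line_is_linear_rescale(self):
        n = 30
        pts = np.column_stack(
            [np.zeros(n), np.zeros(n), np.linspace(0.0, 29.0, n)]
        )
        pos = straighten_positions(pts, (0, n - 1))
        assert np.allclose(pos, np.linspace(0, 1, n), atol=1e-9)

    def test_quarter_circle_matches_analytic_arc_length(self):
        n = 40
        theta = np.linspace(0, np.pi / 2, n)
        pts = np.column_stack(
            [np.zeros(n), 10 * np.sin(theta), 10 * np.cos(theta)]
        )
        pos = straighten_positions(pts, (0, n - 1))
        assert np.max(np.abs(pos - theta / (np.pi / 2))) < 0.02

    def test_annotated_landmarks_map_to_zero_and_one(self):
        rng = np.random.default_rng(2)
        n = 25
        pts = np.column_stack(
            [rng.normal(0, 0.05, n), rng.normal(0, 0.05, n), np.linspace(0, 40, n)]
        )
        pos = straighten_positions(pts, (2, n - 3))
        assert pos[2] == pytest.approx(0.0, abs=1e-9)
        assert pos[n - 3] == pytest.approx(1.0, abs=1e-9)
        assert pos[0] < 0 and pos[-1] > 1  # outside the zone, flagged by sign

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            straighten_positions(np.zeros((5, 3)), (0, 4))
        with pytest.raises(InvalidInputError):
            straighten_positions(np.zeros((15, 3)), (0, 14))


class TestProfileBins:
    def test_constant_values(self):
        pos = np.linspace(0, 1, 110)
        prof = profile_bins(pos, np.full(110, 3.3), nbins=11)
        assert np.allclose(prof.mean, 3.3)
        assert np.allclose(prof.se, 0.0)
        assert prof.n.sum() == 110

    def test_linear_field_bin_means_near_centers(self):
        pos = np.linspace(0, 1, 11000)
        prof = profile_bins(pos, pos, nbins=11)
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        assert np.allclose(prof.mean, centers, atol=0.001)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 1, 500)
        val = rng.normal(0, 1, 500)
        prof = profile_bins(pos, val, nbins=11)
        df = pd.DataFrame({"pos": pos, "val": val})
        df["bin"] = np.clip((df["pos"] * 11).astype(int), 0, 10)
        g = df.groupby("bin")["val"]
        for b in range(11):
            assert prof.mean[b] == pytest.approx(g.mean()[b])
            assert prof.se[b] == pytest.approx(g.sem()[b])
            assert prof.n[b] == g.count()[b]

    def test_empty_bin_reported(self):
        prof = profile_bins(np.array([0.05, 0.95]), np.array([1.0, 2.0]), nbins=11)
        assert prof.n[5] == 0
        assert np.isnan(prof.mean[5])


class TestSlideNormalization:
    def rec(self, slide, genotype, total):
        return NucleusRecord(
            nucleus_id=0,
            centroid=(0, 0, 0),
            volume=30,
            sphericity=0.8,
            nucleus_totals={"sc": total},
            axis_totals={"sc": total},
            axis_ratio=0.5,
            slide=slide,
            genotype=genotype,
        )

    def test_wt_group_normalizes_to_one(self):
        recs = [self.rec("s1", "WT", v) for v in (80.0, 120.0)]
        out = normalize_to_slide_wt(recs, "sc")
        assert np.mean(out) == pytest.approx(1.0)

    def test_mutant_twice_wt_mean(self):
        recs = [
            self.rec("s1", "WT", 100.0),
            self.rec("s1", "mut", 200.0),
        ]
        out = normalize_to_slide_wt(recs, "sc")
        assert out[1] == pytest.approx(2.0)

    def test_two_slides_normalized_independently(self):
        recs = [
            self.rec("s1", "WT", 100.0),
            self.rec("s1", "mut", 150.0),
            self.rec("s2", "WT", 400.0),
            self.rec("s2", "mut", 150.0),
        ]
        out = normalize_to_slide_wt(recs, "sc")
        assert out.tolist() == pytest.approx([1.0, 1.5, 1.0, 0.375])

    def test_slide_without_wt_is_an_error_naming_it(self):
        recs = [self.rec("s9", "mut", 10.0)]
        with pytest.raises(InvalidInputError, match="s9"):
            normalize_to_slide_wt(recs, "sc")


class TestDetectFoci:
    def planted_spot_volume(self, centers, amp=500.0, sigma=(1.2, 1.6, 1.6)):
        labels = ball_labels(shape=(24, 48, 48), radius=10)
        img = np.zeros(labels.shape)
        zz, yy, xx = np.indices(labels.shape)
        for c in centers:
            img += amp * np.exp(
                -0.5
                * (
                    ((zz - c[0]) / sigma[0]) ** 2
                    + ((yy - c[1]) / sigma[1]) ** 2
                    + ((xx - c[2]) / sigma[2]) ** 2
                )
            )
        return img, labels

    def test_single_noise_free_spot(self):
        img, labels = self.planted_spot_volume([(12, 24, 24)])
        calls = detect_foci(img, labels, "otsu")
        assert len(calls) == 1
        assert np.all(np.abs(np.array(calls[0].centroid) - (12, 24, 24)) < 1.0)
        assert calls[0].fitted

    def test_empty_nucleus_yields_no_foci(self):
        labels = ball_labels()
        calls = detect_foci(np.zeros(labels.shape), labels, "otsu")
        assert calls == []

    def test_two_well_separated_spots(self):
        img, labels = self.planted_spot_volume([(12, 24, 16), (12, 24, 33)])
        calls = detect_foci(img, labels, "otsu")
        assert len(calls) == 2

    @pytest.mark.parametrize("method", ["otsu", "yen"])
    def test_six_planted_foci_counted_on_stack(self, small_stack, method):
        volume, _ = small_stack
        calls = detect_foci(volume.channels["foci"], volume.labels, method)
        counts = np.bincount(
            [c.nucleus_id for c in calls], minlength=volume.labels.max() + 1
        )[1:]
        assert np.mean(counts) == pytest.approx(6.0, abs=0.1)

    def test_diameter_filter_excludes_out_of_range_nuclei(self, small_stack):
        volume, _ = small_stack
        # nuclei are ~4.4 um in diameter: a 1-2 um band excludes them all
        calls = detect_foci(
            volume.channels["foci"],
            volume.labels,
            "yen",
            diameter_bounds=(1.0, 2.0),
            voxel_size=volume.voxel_size,
        )
        assert calls == []

    def test_centroids_inside_nucleus_bounds(self, small_stack):
        volume, _ = small_stack
        calls = detect_foci(volume.channels["foci"], volume.labels, "otsu")
        for c in calls:
            sl = ndimage.find_objects(
                (volume.labels == c.nucleus_id).astype(np.int8)
            )[0]
            for d in range(3):
                assert sl[d].start - 1 <= c.centroid[d] <= sl[d].stop + 1


class TestFocusIntensityCV:
    def test_identical_intensities(self):
        assert focus_intensity_cv([5, 5, 5]) == 0.0

    def test_two_point_sample_sd(self):
        assert focus_intensity_cv([1, 3]) == pytest.approx(np.sqrt(2) / 2)

    def test_single_focus_undefined(self):
        assert np.isnan(focus_intensity_cv([4.0]))

    def test_generator_cv_recovered(self):
        # lognormal intensities with planted CV 0.4, >=2 foci per nucleus
        foci, truth = syn.simulate_focus_placement(
            "poisson",
            n_nuclei=200,
            chromosome_lengths=(5.0,),
            mean_count=6,
            intensity_cv=0.4,
            seed=8,
        )
        cvs = [
            focus_intensity_cv(v)
            for v in truth.truth["intensities"].values()
            if len(v) >= 2
        ]
        assert np.mean(cvs) == pytest.approx(0.4, abs=0.05)


class TestHexanediolContrast:
    def test_null_case(self):
        rec = syn.simulate_ratio_records(effect=0.0, seed=4)
        res = hexanediol_contrast(rec)
        assert abs(res["effect"]) < 0.03
        assert res["pvalue"] > 0.05

    def test_planted_shift_recovered(self):
        rec = syn.simulate_ratio_records(effect=0.1, n_gonads=6, seed=3)
        res = hexanediol_contrast(rec)
        assert res["effect"] == pytest.approx(-0.1, abs=0.03)
        assert res["pvalue"] < 0.01

    def test_permutation_destroys_significance(self):
        rec = syn.simulate_ratio_records(effect=0.1, seed=3)
        rng = np.random.default_rng(0)
        gonads = rec["gonad"].unique()
        flip = {g: rng.random() < 0.5 for g in gonads}
        rec = rec.assign(
            genotype=[
                ("WT" if flip[g] else geno)
                if geno != "WT"
                else ("mutant" if flip[g] else "WT")
                for geno, g in zip(rec["genotype"], rec["gonad"])
            ]
        )
        res = hexanediol_contrast(rec)
        assert abs(res["effect"]) < abs(-0.1) / 2 or res["pvalue"] > 0.05

    def test_single_gonad_genotype_rejected(self):
        rec = syn.simulate_ratio_records(n_gonads=2, seed=1)
        rec = rec[~rec["gonad"].isin(["mutant_g1"])]
        with pytest.raises(InsufficientDataError):
            hexanediol_contrast(rec)
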