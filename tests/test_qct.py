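"""QCT chain: segmentation fidelity, airway leak control, %LAA arithmetic."""

import numpy as np
import pytest

from ferretlung import qct, synthetic
from ferretlung.errors import InputError, NoLungFoundError, DegenerateAnalysisError
from ferretlung.types import CTVolume, BinaryMask3D


def dice(a, b):
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestSegmentLungs:
    def test_overlap_with_truth(self, default_phantom):
        _, volume, truth = default_phantom
        lung = qct.segment_lungs(volume)
        target = truth.lung.mask | truth.airway.mask
        assert dice(lung.mask, target) >= 0.99

    def test_no_candidate_raises(self):
        volume = CTVolume(np.full((20, 20, 20), 40.0), (1, 1, 1))
        with pytest.raises(NoLungFoundError):
            qct.segment_lungs(volume)

    def test_no_border_voxels(self, default_phantom):
        # border-connected exterior air (and the airway opening) are excluded
        _, volume, _ = default_phantom
        m = qct.segment_lungs(volume).mask
        assert m[[0, -1], :, :].sum() + m[:, [0, -1], :].sum() + m[:, :, [0, -1]].sum() == 0


class TestSegmentAirways:
    def test_recall_and_contamination(self, default_phantom):
        _, volume, truth = default_phantom
        airway = qct.segment_airways(volume)
        recall = np.logical_and(airway.mask, truth.airway.mask).sum() / truth.airway.count()
        contamination = np.logical_and(airway.mask, truth.lung.mask).sum() / truth.lung.count()
        assert recall >= 0.99
        assert contamination < 0.01

    def test_seed_in_soft_tissue_rejected(self, default_phantom):
        _, volume, _ = default_phantom
        # volume centre front corner region is body soft tissue (~+40 HU)
        seed = (48, 8, 48)
        assert volume.hu[seed] > -400
        with pytest.raises(InputError):
            qct.segment_airways(volume, seed_voxel=seed)

    def test_seed_outside_volume_rejected(self, default_phantom):
        _, volume, _ = default_phantom
        with pytest.raises(InputError):
            qct.segment_airways(volume, seed_voxel=(500, 0, 0))

    def test_leak_halts_growth(self):
        """A wall breach into a large low-HU blob must not flood the region.

        The tube (HU -1000) connects through a breach to a parenchyma-like
        blob at -930 HU; growth at -950 captures only the tube, and the
        step that reaches -930 jumps far beyond the leak factor, so the
        pre-leak (tube-only) region is returned.
        """
        hu = np.full((40, 40, 40), 40.0, dtype=np.float32)
        hu[0:30, 18:22, 18:22] = -1000.0  # tube from the top face
        hu[30:38, 5:35, 5:35] = -930.0  # big blob, 10x tube volume
        hu[29:31, 19:21, 19:21] = -930.0  # breach joins them at -930
        volume = CTVolume(hu, (0.5, 0.5, 0.5))
        tube = hu <= -990
        region = qct.segment_airways(volume, seed_voxel=(0, 19, 19))
        assert region.mask.sum() <= 2.0 * tube.sum()
        assert np.logical_and(region.mask, tube).sum() / tube.sum() > 0.99


class TestRefineLungMask:
    def test_interior_cavity_filled(self):
        lung = np.zeros((20, 20, 20), bool)
        lung[4:16, 4:16, 4:16] = True
        lung[9:12, 9:12, 9:12] = False  # 3-voxel cavity
        airway = np.zeros_like(lung)
        refined = qct.refine_lung_mask(
            BinaryMask3D(lung, "lung", (1, 1, 1)), BinaryMask3D(airway, "airway", (1, 1, 1))
        )
        assert refined.mask[10, 10, 10]

    def test_disjoint_from_airway(self, default_phantom):
        _, volume, _ = default_phantom
        lung = qct.segment_lungs(volume)
        airway = qct.segment_airways(volume)
        refined = qct.refine_lung_mask(lung, airway)
        assert not (refined.mask & airway.mask).any()

    def test_zero_radius_is_subtract_and_fill(self):
        rng = np.random.default_rng(0)
        lung = rng.random((15, 15, 15)) > 0.5
        airway = rng.random((15, 15, 15)) > 0.8
        refined = qct.refine_lung_mask(
            BinaryMask3D(lung, "lung"), BinaryMask3D(airway, "airway"), close_radius_mm=0
        )
        from scipy import ndimage

        expected = ndimage.binary_fill_holes(lung & ~airway) & ~airway
        np.testing.assert_array_equal(refined.mask, expected)

    def test_idempotent(self, default_phantom):
        _, volume, _ = default_phantom
        lung = qct.segment_lungs(volume)
        airway = qct.segment_airways(volume)
        once = qct.refine_lung_mask(lung, airway)
        twice = qct.refine_lung_mask(
            BinaryMask3D(once.mask, "lung", once.spacing), airway
        )
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            qct.refine_lung_mask(
                BinaryMask3D(np.zeros((5, 5, 5), bool), "lung"),
                BinaryMask3D(np.zeros((6, 6, 6), bool), "airway"),
            )


class TestLAAProfile:
    def test_matches_mixture_arithmetic(self, default_phantom):
        # 0.25*Phi(2) + 0.75*Phi(-2.833) ~ 24.6% of lung voxels below -870 HU
        _, volume, truth = default_phantom
        # denominator large enough that binomial error << the 1.0-pt tolerance
        assert truth.lung.count() > 5e4
        refined, _, profile = qct.qct_pipeline(volume)
        assert profile.percent_at(-870) == pytest.approx(24.6, abs=1.0)

    def test_clean_lung_has_no_laa950(self, clean_phantom):
        _, volume, truth = clean_phantom
        profile = qct.laa_profile(volume, truth.lung)
        assert profile.percent_at(-950) < 0.1

    def test_profile_non_decreasing(self, default_phantom):
        _, volume, truth = default_phantom
        profile = qct.laa_profile(volume, truth.lung)
        assert np.all(np.diff(profile.percents) >= 0)

    def test_empty_mask_rejected(self, default_phantom):
        _, volume, _ = default_phantom
        empty = BinaryMask3D(np.zeros(volume.shape, bool), "refined-lung")
        with pytest.raises(InputError):
            qct.laa_profile(volume, empty)

    def test_axis_permutation_invariance(self):
        spec = synthetic.PhantomSpec(shape=(48, 48, 48), emphysema_fraction=0.25, seed=4)
        volume, truth = synthetic.make_ct_phantom(spec)
        p1 = qct.laa_profile(volume, truth.lung)
        order = (1, 2, 0)
        vol_p = volume.permuted(order)
        mask_p = BinaryMask3D(
            np.transpose(truth.lung.mask, order), "lung", vol_p.spacing
        )
        p2 = qct.laa_profile(vol_p, mask_p)
        assert p1.percents == p2.percents


class TestLAAFunctionSlope:
    @staticmethod
    def _profile(percent):
        return qct.LAAProfile(
            thresholds_hu=(-870,), percents=(percent,), denominator=1000
        )

    def test_two_point_slope(self):
        records = [("a", self._profile(5.0), 0.8), ("b", self._profile(15.0), 0.6)]
        fit = qct.laa_function_slope(records)
        assert fit.slope_at(-870) == pytest.approx(-50.0)

    def test_constant_percent_gives_zero_slope(self):
        records = [(s, self._profile(10.0), r) for s, r in zip("abc", (0.5, 0.6, 0.7))]
        assert qct.laa_function_slope(records).slope_at(-870) == pytest.approx(0.0)

    def test_recovers_generating_slope(self):
        # subjects generated as %LAA = 40 - 45*ratio + N(0, 0.5)
        rng = np.random.default_rng(12)
        ratios = rng.uniform(0.4, 0.9, size=20)
        records = [
            (f"s{i}", self._profile(40 - 45 * r + rng.normal(0, 0.5)), r)
            for i, r in enumerate(ratios)
        ]
        fit = qct.laa_function_slope(records)
        se = 0.5 / np.sqrt(np.sum((ratios - ratios.mean()) ** 2))
        assert fit.slope_at(-870) == pytest.approx(-45.0, abs=3 * se)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateAnalysisError):
            qct.laa_function_slope([("a", self._profile(5.0), 0.8)])
        with pytest.raises(DegenerateAnalysisError):
            qct.laa_function_slope(
                [("a", self._profile(5.0), 0.8), ("b", self._profile(9.0), 0.8)]
            )
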