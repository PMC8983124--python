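"""Generator contracts: determinism, truth consistency, mask algebra."""

import numpy as np
import pandas as pd
import pytest

from ferretlung import synthetic
from ferretlung.errors import InputError
from ferretlung.synthetic import (
    PhantomSpec,
    TracePreset,
    CohortPreset,
    COHORT_PRESETS,
    make_ct_phantom,
    make_expiration_trace,
    make_pv_loop,
    make_airspace_image,
    make_cohort,
    make_inhibition_curve,
    analytic_fev,
    salazar_knowles_volume,
)


class TestCTPhantom:
    def test_mask_algebra(self, default_phantom):
        _, _, truth = default_phantom
        assert not (truth.emphysema.mask & ~truth.lung.mask).any()  # emphysema within lung
        assert not (truth.airway.mask & truth.lung.mask).any()  # airway disjoint from lung

    def test_no_emphysema_when_fraction_zero(self, clean_phantom):
        _, _, truth = clean_phantom
        assert truth.emphysema.count() == 0

    def test_emphysema_fraction_within_binomial_error(self, default_phantom):
        _, _, truth = default_phantom
        n = truth.lung.count()
        frac = truth.emphysema.count() / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 4 * se

    def test_airway_voxels_are_air(self, default_phantom):
        # lumen HU is truncated at 2 SD around -1000, so never above -990
        _, volume, truth = default_phantom
        assert volume.hu[truth.airway.mask].max() <= -990.0

    def test_exterior_air_touches_border(self, default_phantom):
        _, volume, _ = default_phantom
        border = np.concatenate(
            [volume.hu[-1].ravel(), volume.hu[:, 0].ravel(), volume.hu[:, :, 0].ravel()]
        )
        assert (border == -1000.0).any()

    def test_deterministic(self):
        spec = PhantomSpec(shape=(32, 32, 32), emphysema_fraction=0.3, seed=5)
        v1, t1 = make_ct_phantom(spec)
        v2, t2 = make_ct_phantom(spec)
        np.testing.assert_array_equal(v1.hu, v2.hu)
        np.testing.assert_array_equal(t1.emphysema.mask, t2.emphysema.mask)

    def test_blob_mode_respects_fraction_and_lung(self):
        spec = PhantomSpec(
            shape=(48, 48, 48), emphysema_fraction=0.2, emphysema_mode="blobs", seed=2
        )
        _, truth = make_ct_phantom(spec)
        frac = truth.emphysema.count() / truth.lung.count()
        assert 0.1 < frac < 0.35  # blob union overshoots by at most one blob
        assert not (truth.emphysema.mask & ~truth.lung.mask).any()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"emphysema_fraction": 1.5},
            {"emphysema_fraction": -0.1},
            {"shape": (0, 32, 32)},
            {"spacing": (0.5, -0.5, 0.5)},
            {"parenchyma_hu": (-700, -1)},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(InputError):
            PhantomSpec(**kwargs)


class TestExpirationTrace:
    def test_closed_form_volume(self):
        preset = TracePreset(fvc_ml=30.0, taus_s=(0.2,), t_onset_s=0.0)
        trace = make_expiration_trace(preset)
        v_04 = np.interp(0.4, trace.time_s, trace.volume_ml)
        assert v_04 == pytest.approx(30 * (1 - np.exp(-2)), rel=1e-6)
        assert v_04 == pytest.approx(25.94, abs=0.01)

    def test_volume_monotone_and_bounded(self, mono_trace):
        preset, trace = mono_trace
        assert np.all(np.diff(trace.volume_ml) >= 0)
        assert trace.volume_ml.max() <= preset.fvc_ml + 1e-9

    def test_noise_reproducible(self):
        preset = TracePreset(noise_sd_ml_s=5.0, seed=42)
        t1 = make_expiration_trace(preset)
        t2 = make_expiration_trace(preset)
        np.testing.assert_array_equal(t1.flow_ml_s, t2.flow_ml_s)

    def test_invalid_presets(self):
        with pytest.raises(InputError):
            TracePreset(taus_s=(0.0,))
        with pytest.raises(InputError):
            TracePreset(dt_s=0.0)
        with pytest.raises(InputError):
            TracePreset(fractions=(0.5, 0.4), taus_s=(0.1, 1.0))


class TestPVLoop:
    def test_closed_form_and_monotone(self):
        loop = make_pv_loop(60, 55, 0.1)
        p, v = loop.limb_points("inflation")
        np.testing.assert_allclose(v, salazar_knowles_volume(p, 60, 55, 0.1))
        # extrapolated volume at P=0 is A - B
        assert salazar_knowles_volume(0.0, 60, 55, 0.1) == pytest.approx(5.0)
        assert np.all(np.diff(v) > 0)

    def test_hysteresis_offset(self):
        loop = make_pv_loop(60, 55, 0.1, hysteresis_ml=2.0)
        p_up, v_up = loop.limb_points("inflation")
        p_dn, v_dn = loop.limb_points("deflation")
        np.testing.assert_allclose(v_dn - v_up, 2.0)

    def test_invalid_parameters(self):
        with pytest.raises(InputError):
            make_pv_loop(10, 55, 0.0)  # A <= B*exp(0)
        with pytest.raises(InputError):
            make_pv_loop(60, 55, -0.1)


class TestAirspaceImage:
    def test_three_squares(self):
        shapes = [
            {"kind": "square", "size": 100, "center": (80, 80)},
            {"kind": "square", "size": 100, "center": (80, 300)},
            {"kind": "square", "size": 100, "center": (300, 80)},
        ]
        img, truth = make_airspace_image(shapes)
        assert len(truth) == 3
        assert (truth["area_px2"] == 1e4).all()
        assert img.sum() == 3e4

    def test_disk_truth_perimeter(self):
        _, truth = make_airspace_image([{"kind": "disk", "radius": 50, "center": (100, 100)}])
        assert truth["perimeter_px"].iloc[0] == pytest.approx(2 * np.pi * 50)

    def test_empty_shape_list(self):
        img, truth = make_airspace_image([])
        assert not img.any()
        assert truth.empty

    def test_overlap_and_out_of_canvas_rejected(self):
        with pytest.raises(InputError):
            make_airspace_image(
                [
                    {"kind": "square", "size": 100, "center": (100, 100)},
                    {"kind": "square", "size": 100, "center": (150, 150)},
                ]
            )
        with pytest.raises(InputError):
            make_airspace_image([{"kind": "disk", "radius": 50, "center": (10, 10)}])


class TestCohort:
    def test_zero_noise_on_generating_line(self):
        preset = CohortPreset(
            genotype="PiZZ",
            n_animals=4,
            visit_ages_days=(100.0, 300.0, 500.0),
            beta_ml_cm_day=0.00043,
            random_intercept_sd=0.0,
            residual_sd=0.0,
        )
        df = make_cohort(preset, seed=1)
        for _, g in df.groupby("animal"):
            slopes = np.polyfit(g["age_days"], g["ic_per_ln"], 1)[0]
            assert slopes == pytest.approx(0.00043, rel=1e-9)

    def test_deterministic(self):
        df1 = make_cohort(COHORT_PRESETS["AAT-KO"], seed=9)
        df2 = make_cohort(COHORT_PRESETS["AAT-KO"], seed=9)
        pd.testing.assert_frame_equal(df1, df2)

    def test_preset_slope_in_metadata(self):
        df = make_cohort(COHORT_PRESETS["PiZZ"], seed=0)
        assert df.attrs["generating_beta_ml_cm_day"] == 0.00043

    def test_preset_design_sizes(self):
        assert COHORT_PRESETS["PiMM"].n_animals == 19
        assert COHORT_PRESETS["PiZZ"].n_animals == 6
        assert COHORT_PRESETS["AAT-KO"].n_animals == 13

    def test_empty_schedule_rejected(self):
        with pytest.raises(InputError):
            CohortPreset(visit_ages_days=())


class TestInhibitionCurve:
    def test_linear_decay(self):
        df = make_inhibition_curve([0, 2.5, 5.0], slope_per_ul=0.2)
        assert df.loc[df["volume_ul"] == 2.5, "activity"].iloc[0] == pytest.approx(0.5)
        assert df.loc[df["volume_ul"] == 0, "activity"].iloc[0] == 1.0

    def test_zero_slope_flat(self):
        df = make_inhibition_curve([0, 1, 3, 5], slope_per_ul=0.0)
        assert (df["activity"] == 1.0).all()

    def test_reproducible_with_noise(self):
        a = make_inhibition_curve([0, 1, 3, 5], slope_per_ul=0.1, noise_sd=0.05, seed=4)
        b = make_inhibition_curve([0, 1, 3, 5], slope_per_ul=0.1, noise_sd=0.05, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_volumes_rejected(self):
        with pytest.raises(InputError):
            make_inhibition_curve([0, 1, 1, 5], slope_per_ul=0.1)
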