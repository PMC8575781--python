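"""Phantom generator: determinism, physicality, contrast ordering, cohort
composition, and the raw SFDI/CT forward models."""
from __future__ import annotations

import numpy as np
import pytest

from optomics.channels import CHANNEL_SPECS
from optomics.phantom import (
    DEFAULT_COHORT_PROPORTIONS,
    PhantomConfig,
    PlacementError,
    cohort_class_of,
    generate_cohort,
    generate_raw_ct,
    generate_raw_sfdi,
    generate_specimen,
)
from optomics.subtypes import SubtypeAppearance, default_appearances


def noise_free_appearances():
    return {
        name: SubtypeAppearance(
            app.name, app.mean_attenuation, app.dc_reflectance,
            app.frequency_profile, app.texture_correlation_length,
            texture_amplitude=0.0, noise_sd=0.0)
        for name, app in default_appearances().items()
    }


class TestGenerateSpecimen:
    def test_noise_free_adipose_roi_is_constant_at_mean_attenuation(self):
        cfg = PhantomConfig(n_rois_per_specimen=1, specimen_effect_sd=0.0,
                            seed=5)
        sp = generate_specimen(cfg, appearances=noise_free_appearances(),
                               subtypes=["Adipose"], seed=5)
        mu = default_appearances()["Adipose"].mean_attenuation
        ct = sp.channel("CT")[sp.rois[0].mask]
        assert np.allclose(ct, mu)

    def test_same_seed_identical_different_seed_differs(self):
        cfg = PhantomConfig(seed=7)
        a = generate_specimen(cfg, seed=7)
        b = generate_specimen(cfg, seed=7)
        c = generate_specimen(cfg, seed=8)
        assert np.array_equal(a.channels, b.channels)
        assert np.array_equal(a.roi_label_map, b.roi_label_map)
        assert not np.array_equal(a.roi_label_map, c.roi_label_map)

    def test_adipose_high_frequency_reflectance_below_fibrocystic(self):
        cfg = PhantomConfig(n_rois_per_specimen=2, specimen_effect_sd=0.0,
                            seed=9)
        sp = generate_specimen(cfg, subtypes=["Adipose",
                                              "FibrocysticDisease"], seed=9)
        chan = sp.channel("w490_f1.37")
        mean_adipose = chan[sp.rois[0].mask].mean()
        mean_fcd = chan[sp.rois[1].mask].mean()
        assert mean_adipose < mean_fcd

    def test_physicality_and_label_consistency(self, specimen):
        assert specimen.channels.min() >= 0
        # reflectance channels stay near [0, 1]; excursions only noise-sized
        assert specimen.channels[1:].max() <= 1.0 + 0.1
        labelled = specimen.roi_label_map > 0
        for roi in specimen.rois:
            assert (specimen.roi_label_map[roi.mask] == roi.roi_id).all()
        assert labelled.sum() == sum(r.mask.sum() for r in specimen.rois)

    def test_roi_areas_recorded_in_mm2(self, specimen):
        for roi in specimen.rois:
            assert roi.area_mm2 == pytest.approx(
                roi.mask.sum() * specimen.pixel_pitch**2)

    def test_contrast_ordering_measurable_when_noise_free(self):
        cfg = PhantomConfig(n_rois_per_specimen=3, specimen_effect_sd=0.0,
                            seed=2)
        sp = generate_specimen(cfg, appearances=noise_free_appearances(),
                               subtypes=["Adipose", "NormalConnective",
                                         "IDCaHigh"], seed=2)
        ct = sp.channel("CT")
        means = [ct[r.mask].mean() for r in sp.rois]
        assert means[0] < means[1] < means[2]

    def test_impossible_placement_raises(self):
        cfg = PhantomConfig(image_size=64, n_rois_per_specimen=6, seed=0)
        with pytest.raises(PlacementError):
            generate_specimen(cfg, seed=0)

    def test_coupling_holes_punch_mask(self):
        cfg = PhantomConfig(n_coupling_holes=3, seed=4)
        sp = generate_specimen(cfg, seed=4)
        assert not sp.valid_mask.all()


class TestRawSFDI:
    def test_dc_channel_three_phases_identical_without_noise(self):
        truth = {(490, 0.0): np.full((8, 8), 0.5)}
        raw = generate_raw_sfdi(truth, noise_sd=0.0)
        frames = raw.frames[(490, 0.0)]
        assert np.array_equal(frames[0], frames[1])
        assert np.array_equal(frames[1], frames[2])

    def test_frames_nonnegative_with_noise(self):
        truth = {(550, 1.37): np.full((16, 16), 0.02)}
        raw = generate_raw_sfdi(truth, noise_sd=0.3, seed=1)
        assert raw.frames[(550, 1.37)].min() >= 0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_raw_sfdi({(490, 0.0): np.full((4, 4), 0.5)},
                              noise_sd=-0.1)

    def test_reflectance_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            generate_raw_sfdi({(490, 0.15): np.full((4, 4), 1.2)})


class TestRawCT:
    def test_calibration_disks_hold_anchor_values(self):
        raw = generate_raw_ct(np.full((64, 64), 0.05))
        assert np.allclose(raw.image[raw.air_mask], raw.raw_air)
        assert np.allclose(raw.image[raw.water_mask], raw.raw_water)

    def test_equal_air_water_rejected(self):
        with pytest.raises(ValueError):
            generate_raw_ct(np.full((8, 8), 0.05), raw_air=10, raw_water=10)


class TestCohort:
    def test_default_proportions_at_54_specimens(self):
        """14 benign-only, 3 malignant-only, 37 mixed at n = 54."""
        from optomics.phantom import _cohort_class_counts

        assert _cohort_class_counts(54, DEFAULT_COHORT_PROPORTIONS) == (14, 3, 37)

    def test_small_cohort_classes_realized(self):
        specimens, roi_table = generate_cohort(
            6, PhantomConfig(), seed=1, proportions=(2, 1, 3))
        classes = [cohort_class_of(s) for s in specimens]
        assert sorted(classes) == ["benign", "benign", "malignant",
                                   "mixed", "mixed", "mixed"]
        assert roi_table.patient_id.nunique() == 6

    def test_two_specimens_one_pure_class_each(self):
        specimens, _ = generate_cohort(2, PhantomConfig(), seed=3,
                                       proportions=(1, 1, 0))
        classes = sorted(cohort_class_of(s) for s in specimens)
        assert classes == ["benign", "malignant"]

    def test_zero_proportions_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(4, PhantomConfig(), seed=0,
                            proportions=(0, 0, 0))

    def test_adipose_most_prevalent_across_seeded_cohorts(self, cohort):
        _, roi_table = cohort
        per_subtype = roi_table.groupby("subtype").specimen_id.nunique()
        assert per_subtype.idxmax() == "Adipose"

    def test_seventeen_distinct_channel_specs(self, specimen):
        assert len(set(specimen.channel_specs)) == 17
        assert sum(s.modality == "microCT"
                   for s in specimen.channel_specs) == 1
        assert CHANNEL_SPECS[0].tag == "CT"
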