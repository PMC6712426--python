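"""Forward simulators: spectra, CSI grids, lesion phantoms, cohort tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perispect.params import AcquisitionParams, MetaboliteSpec
from perispect.quant import relaxation_factor
from perispect.synthdata import (CohortDesign, GroundTruthVoxel, PhantomSpec,
                                 default_cohort_design, ellipsoid_semi_axes,
                                 peak_area_from_truth, simulate_cohort,
                                 simulate_csi_grid, simulate_flair_phantom,
                                 simulate_spectrum, WATER_AREA_AU)


class TestSimulateSpectrum:
    def test_empty_voxel_is_flat_with_water_companion(self, mets, water, acq):
        truth = GroundTruthVoxel(concentrations={})
        sup, uns = simulate_spectrum(truth, mets, water, acq, seed=0)
        assert np.all(sup.values == 0)
        # water line carries exactly the injected area
        assert np.trapezoid(np.real(uns.values), uns.ppm_axis) == \
            pytest.approx(WATER_AREA_AU, rel=0.05)

    def test_symmetry_with_water_gives_equal_areas(self, water, acq):
        """A metabolite indistinguishable from water (same protons, same
        relaxation) at Cm = Cw must render the same peak area as water."""
        fake = MetaboliteSpec(name="fake", ppm=2.01, n_protons=water.n_protons,
                              t1=water.t1, t2=water.t2, linewidth=water.linewidth)
        am = peak_area_from_truth(water.cw, fake, water, acq)
        assert am == pytest.approx(WATER_AREA_AU, rel=1e-12)

    def test_rendered_area_matches_inverted_equation(self, priors, water, acq):
        """Closed-form area from the inverted water-reference equation vs
        trapezoidal integration of the rendered Lorentzian (< 0.5%)."""
        naa = priors["NAA"]
        cm = 13.7
        # independent arithmetic: Am = Cm * Aw / (R * Cw)
        r_num = water.n_protons * (1 - math.exp(-acq.tr / water.t1)) \
            * math.exp(-acq.te / water.t2)
        r_den = naa.n_protons * (1 - math.exp(-acq.tr / naa.t1)) \
            * math.exp(-acq.te / naa.t2)
        am_expected = cm * WATER_AREA_AU / ((r_num / r_den) * water.cw)
        truth = GroundTruthVoxel(concentrations={"NAA": cm})
        sup, _ = simulate_spectrum(truth, [naa], water, acq, seed=0)
        rendered = np.trapezoid(np.real(sup.values), sup.ppm_axis)
        assert rendered == pytest.approx(am_expected, rel=5e-3)

    def test_rejects_negative_concentration(self, mets, water, acq):
        with pytest.raises(ValueError, match="negative concentration"):
            GroundTruthVoxel(concentrations={"NAA": -1.0})

    def test_rejects_peak_outside_axis(self, water, acq):
        far = MetaboliteSpec(name="far", ppm=0.5, n_protons=3, t1=1400.0,
                             t2=250.0, linewidth=5.0)
        narrow = AcquisitionParams(bandwidth=300.0, n_points=256,
                                   grid_shape=acq.grid_shape)
        truth = GroundTruthVoxel(concentrations={"far": 5.0})
        with pytest.raises(ValueError, match="outside the spectral axis"):
            simulate_spectrum(truth, [far], water, narrow, seed=0)

    def test_same_seed_bit_identical(self, mets, water, acq):
        truth = GroundTruthVoxel(concentrations={"NAA": 10.0}, snr=15.0)
        a = simulate_spectrum(truth, mets, water, acq, seed=7)
        b = simulate_spectrum(truth, mets, water, acq, seed=7)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(cm=st.floats(min_value=0.5, max_value=30.0),
           bump=st.floats(min_value=0.1, max_value=10.0))
    def test_area_strictly_increases_with_concentration(self, cm, bump,
                                                        priors, water, acq):
        naa = priors["NAA"]
        assert peak_area_from_truth(cm + bump, naa, water, acq) > \
            peak_area_from_truth(cm, naa, water, acq)


class TestSimulateCSIGrid:
    def test_empty_grid_is_all_flat(self, mets, water, acq):
        small = AcquisitionParams(grid_shape=(3, 3))
        tmap = [[GroundTruthVoxel(concentrations={}) for _ in range(3)]
                for _ in range(3)]
        grid = simulate_csi_grid(tmap, mets, water, small, seed=0)
        assert grid.suppressed.shape == (3, 3, small.n_points)
        assert np.all(grid.suppressed == 0)

    def test_locality_of_a_single_labelled_voxel(self, mets, water, acq):
        small = AcquisitionParams(grid_shape=(3, 3))
        tmap = [[GroundTruthVoxel(concentrations={}) for _ in range(3)]
                for _ in range(3)]
        tmap[1][2] = GroundTruthVoxel(region="PHE",
                                      concentrations={"NAA": 9.7})
        grid = simulate_csi_grid(tmap, mets, water, small, seed=0)
        power = np.abs(grid.suppressed).sum(axis=2)
        assert power[1, 2] > 0
        power[1, 2] = 0
        assert np.all(power == 0)
        assert grid.regions[1, 2] == "PHE"

    def test_shape_mismatch_rejected(self, mets, water):
        small = AcquisitionParams(grid_shape=(3, 3))
        tmap = [[GroundTruthVoxel()] * 2] * 2
        with pytest.raises(ValueError, match="does not match"):
            simulate_csi_grid(tmap, mets, water, small, seed=0)


class TestFlairPhantom:
    def test_analytic_ellipsoid_volume(self):
        """Semi-axes solved for a 2.38 ml target reproduce it in closed form,
        and the voxelised count converges to it as resolution improves."""
        a, b, c = ellipsoid_semi_axes(2.38, (1.1, 1.0, 0.9))
        assert 4.0 / 3.0 * np.pi * a * b * c == pytest.approx(2380.0, rel=1e-12)
        errs = []
        for vox in (1.0, 0.5):
            ph = simulate_flair_phantom(
                PhantomSpec(voxel_mm=vox, icv_volume=20.0,
                            hematoma_volume=1.0, edema_volume=1.38), seed=0)
            errs.append(abs(ph.volumes_ml["edema"] +
                            ph.volumes_ml["hematoma"] - 2.38) / 2.38)
        assert errs[1] < 0.02
        assert errs[1] <= errs[0] + 1e-6

    def test_rendered_hematoma_tracks_target(self):
        ph = simulate_flair_phantom(PhantomSpec(voxel_mm=0.5), seed=0)
        assert ph.volumes_ml["hematoma"] == pytest.approx(1.00, rel=0.02)
        assert ph.volumes_ml["edema"] == pytest.approx(2.38, rel=0.02)

    def test_zero_edema_omits_class(self):
        ph = simulate_flair_phantom(
            PhantomSpec(voxel_mm=1.0, icv_volume=20.0, hematoma_volume=1.0,
                        edema_volume=0.0), seed=0)
        lab = np.asarray(ph.labels.dataobj)
        assert not np.any(lab == 2)

    def test_labels_partition_and_disjoint(self):
        ph = simulate_flair_phantom(PhantomSpec(voxel_mm=1.0), seed=0)
        lab = np.asarray(ph.labels.dataobj)
        hem = lab == 3
        ed = lab == 2
        assert not np.any(hem & ed)
        assert ph.volumes_ml["icv"] == pytest.approx(
            ph.volumes_ml["brain"] + ph.volumes_ml["edema"]
            + ph.volumes_ml["hematoma"], rel=1e-12)

    def test_unachievable_volume_names_structure(self):
        with pytest.raises(ValueError, match="hematoma"):
            simulate_flair_phantom(
                PhantomSpec(voxel_mm=1.0, icv_volume=20.0,
                            hematoma_volume=5e-5, edema_volume=0.5), seed=0)

    def test_invalid_nesting_rejected(self):
        with pytest.raises(ValueError, match="smaller than ICV"):
            PhantomSpec(icv_volume=2.0, hematoma_volume=1.5, edema_volume=1.0)


class TestSimulateCohort:
    def test_zero_sd_equals_cell_means(self):
        design = default_cohort_design(seed=0, n_animals=3, sd_animal=0.0,
                                       sd_animal_region=0.0, sd_resid=0.0)
        table = simulate_cohort(design)
        for row in table.itertuples():
            assert row.value_mM == pytest.approx(
                design.region_time_means[(row.region, row.day, row.metabolite)])

    def test_large_cohort_means_within_3_se(self):
        """Law of large numbers: per-cell sample means approach design means."""
        design = default_cohort_design(seed=1, n_animals=10_000, sd_animal=0.0,
                                       sd_animal_region=0.0, sd_resid=1.0)
        table = simulate_cohort(design)
        se = 1.0 / np.sqrt(10_000)
        g = table.groupby(["region", "day", "metabolite"])["value_mM"].mean()
        for key, m in g.items():
            assert abs(m - design.region_time_means[key]) < 3 * se

    def test_same_seed_bit_identical(self):
        a = simulate_cohort(default_cohort_design(seed=5, n_animals=4))
        b = simulate_cohort(default_cohort_design(seed=5, n_animals=4))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_cell_mean_rejected(self):
        means = {("PHE", 1, "NAA"): 10.0}
        with pytest.raises(ValueError, match="missing cell mean"):
            CohortDesign(region_time_means=means, days=(1, 7))

    def test_row_count_and_columns(self):
        t = simulate_cohort(default_cohort_design(seed=2, n_animals=5))
        assert len(t) == 5 * 3 * 3 * 3
        assert list(t.columns) == ["animal", "region", "day", "metabolite",
                                   "value_mM"]
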