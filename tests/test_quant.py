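"""Water-referenced absolute quantification (relaxation correction and the
area-ratio concentration equation)."""

import math

import numpy as np
import pytest

from perispect.params import (AcquisitionParams, MetaboliteSpec,
                              WaterReference)
from perispect.quant import (empirical_capture, lorentzian_capture,
                             lorentzian_crosstalk, quantify, quantify_grid,
                             quantify_voxel, relaxation_factor)
from perispect.spectra import PeakArea
from perispect.synthdata import (GroundTruthVoxel, simulate_csi_grid,
                                 simulate_spectrum)


class TestRelaxationFactor:
    def test_saturation_and_echo_limits_give_proton_ratio(self, water):
        """TE -> 0 and TR >> T1 reduce the correction to Nw/Nm exactly."""
        met = MetaboliteSpec(name="m", ppm=2.0, n_protons=2, t1=1400.0,
                             t2=250.0, linewidth=5.0)
        acq = AcquisitionParams(tr=1e12, te=1e-12)
        assert relaxation_factor(met, water, acq) == pytest.approx(1.0, abs=1e-12)

    def test_identical_relaxation_gives_proton_count_ratio(self, acq, water):
        cho_like = MetaboliteSpec(name="cho", ppm=3.19, n_protons=9,
                                  t1=water.t1, t2=water.t2, linewidth=5.0)
        assert relaxation_factor(cho_like, water, acq) == \
            pytest.approx(2.0 / 9.0, rel=1e-12)

    def test_default_priors_match_scalar_arithmetic(self, priors, acq):
        """The shipped defaults at TR/TE = 2000/144 ms against a from-scratch
        scalar evaluation of the correction."""
        for met in priors.metabolites:
            w = priors.water
            expected = (w.n_protons * (1 - math.exp(-2000.0 / w.t1))
                        * math.exp(-144.0 / w.t2)) / \
                       (met.n_protons * (1 - math.exp(-2000.0 / met.t1))
                        * math.exp(-144.0 / met.t2))
            assert relaxation_factor(met, w, acq) == \
                pytest.approx(expected, rel=1e-12)

    def test_nonpositive_relaxation_rejected(self, acq, water):
        with pytest.raises(ValueError):
            MetaboliteSpec(name="bad", ppm=2.0, n_protons=3, t1=-1.0, t2=250.0,
                           linewidth=5.0)
        bad = MetaboliteSpec(name="m", ppm=2.0, n_protons=3, t1=1400.0,
                             t2=250.0, linewidth=5.0)
        object.__setattr__(bad, "t2", -5.0)
        with pytest.raises(ValueError, match="positive"):
            relaxation_factor(bad, water, acq)


class TestQuantify:
    def test_self_reference_returns_water_concentration(self, acq, water):
        """Am = Aw with water-identical relaxation and protons gives Cw."""
        fake = MetaboliteSpec(name="w2", ppm=4.7, n_protons=2, t1=water.t1,
                              t2=water.t2, linewidth=water.linewidth)
        am = PeakArea(metabolite="w2", area=5.0, window=(4.4, 5.0))
        aw = PeakArea(metabolite="water", area=5.0, window=(4.4, 5.0))
        rec = quantify(am, aw, fake, water, acq)
        assert rec.cm == pytest.approx(water.cw, rel=1e-9)

    def test_zero_area_gives_zero_concentration(self, priors, acq):
        am = PeakArea(metabolite="NAA", area=0.0, window=(1.93, 2.09))
        aw = PeakArea(metabolite="water", area=5.0, window=(4.4, 5.0))
        assert quantify(am, aw, priors["NAA"], priors.water, acq).cm == 0.0

    def test_negative_area_clips_with_flag(self, priors, acq):
        am = PeakArea(metabolite="NAA", area=-0.5, window=(1.93, 2.09))
        aw = PeakArea(metabolite="water", area=5.0, window=(4.4, 5.0))
        rec = quantify(am, aw, priors["NAA"], priors.water, acq)
        assert rec.cm == 0.0
        assert "negative_area_clipped" in rec.qc_flags

    def test_missing_water_reference_rejected(self, priors, acq):
        am = PeakArea(metabolite="NAA", area=1.0, window=(1.93, 2.09))
        aw = PeakArea(metabolite="water", area=0.0, window=(4.4, 5.0))
        with pytest.raises(ValueError, match="water"):
            quantify(am, aw, priors["NAA"], priors.water, acq)


class TestCaptureOracles:
    def test_analytic_capture_matches_rendered_operator(self, acq, priors):
        """Closed-form capture fraction vs the same quantity measured by
        pushing a rendered unit line through the integration code; they
        differ only by window/anchor discretisation on the sampled axis."""
        for met in priors.metabolites:
            fwhm = met.linewidth / acq.field_ppm_hz
            analytic = lorentzian_capture(0.08, 0.08, fwhm)
            rendered = empirical_capture(acq.ppm_axis(), met.ppm, met.ppm,
                                         fwhm, 0.08)
            assert rendered == pytest.approx(analytic, rel=0.015)

    def test_analytic_crosstalk_matches_rendered_operator(self, acq, priors):
        fwhm = priors["Cho"].linewidth / acq.field_ppm_hz
        analytic = lorentzian_crosstalk((3.03 - 0.08, 3.03 + 0.08), 3.19, fwhm)
        rendered = empirical_capture(acq.ppm_axis(), 3.03, 3.19, fwhm, 0.08)
        assert rendered == pytest.approx(analytic, abs=0.01)


class TestRoundTrip:
    TRUTH = {"NAA": 13.7, "Cr": 9.43, "Cho": 2.6}

    def test_noiseless_round_trip_within_half_percent(self, mets, water, acq,
                                                      priors):
        truth = GroundTruthVoxel(concentrations=dict(self.TRUTH))
        sup, uns = simulate_spectrum(truth, mets, water, acq, seed=0)
        for rec in quantify_voxel(sup, uns, priors, acq, do_phase=False):
            assert rec.cm == pytest.approx(self.TRUTH[rec.metabolite], rel=5e-3)

    def test_round_trip_with_phase_errors_within_half_percent(
            self, mets, water, acq, priors):
        truth = GroundTruthVoxel(concentrations=dict(self.TRUTH),
                                 phase0=37.0, phase1=5.0)
        sup, uns = simulate_spectrum(truth, mets, water, acq, seed=0)
        for rec in quantify_voxel(sup, uns, priors, acq):
            assert rec.cm == pytest.approx(self.TRUTH[rec.metabolite], rel=5e-3)

    def test_homogeneity_in_amplitudes(self, mets, water, acq, priors):
        """Scaling both spectra leaves cm unchanged; scaling only the
        suppressed spectrum scales cm proportionally."""
        truth = GroundTruthVoxel(concentrations={"NAA": 10.0})
        sup, uns = simulate_spectrum(truth, mets, water, acq, seed=0)
        base = quantify_voxel(sup, uns, priors, acq, do_phase=False)[0].cm
        sup2 = type(sup)(sup.values * 3.0, sup.ppm_axis, meta=sup.meta)
        uns2 = type(uns)(uns.values * 3.0, uns.ppm_axis, meta=uns.meta)
        both = quantify_voxel(sup2, uns2, priors, acq, do_phase=False)[0].cm
        only_m = quantify_voxel(sup2, uns, priors, acq, do_phase=False)[0].cm
        assert both == pytest.approx(base, rel=1e-9)
        assert only_m == pytest.approx(3.0 * base, rel=1e-9)

    def test_snr_sweep_bias_small_and_sd_shrinks(self, mets, water, acq,
                                                 priors):
        """Across SNR 10/20/50 the recovered mean stays near truth and the
        spread shrinks monotonically."""
        sds = []
        for snr in (10.0, 20.0, 50.0):
            vals = []
            for k in range(40):
                truth = GroundTruthVoxel(concentrations={"NAA": 13.7}, snr=snr)
                sup, uns = simulate_spectrum(truth, [priors["NAA"]], water,
                                             acq, seed=1000 + k)
                vals.append(quantify_voxel(sup, uns, priors, acq,
                                           do_phase=False)[0].cm)
            assert np.mean(vals) == pytest.approx(13.7, rel=0.05)
            sds.append(np.std(vals))
        assert sds[0] > sds[1] > sds[2]

    def test_phase_invariance_of_quantification(self, mets, water, acq,
                                                priors):
        """cm changes < 1% for any applied phase within +-90 deg, +-20
        deg/ppm once phase correction runs."""
        for phi0, phi1 in ((90.0, 0.0), (-90.0, 20.0), (45.0, -20.0),
                           (-30.0, 10.0)):
            truth = GroundTruthVoxel(concentrations=dict(self.TRUTH),
                                     phase0=phi0, phase1=phi1)
            sup, uns = simulate_spectrum(truth, mets, water, acq, seed=0)
            for rec in quantify_voxel(sup, uns, priors, acq):
                assert rec.cm == pytest.approx(self.TRUTH[rec.metabolite],
                                               rel=0.01)


class TestQuantifyGrid:
    def test_empty_grid_gives_empty_table(self, mets, water, priors):
        acq3 = AcquisitionParams(grid_shape=(2, 2))
        tmap = [[GroundTruthVoxel(concentrations={}) for _ in range(2)]
                for _ in range(2)]
        grid = simulate_csi_grid(tmap, mets, water, acq3, seed=0)
        table = quantify_grid(grid, priors, regions_only=True)
        assert len(table) == 0

    def test_single_voxel_grid_one_record_per_metabolite(self, mets, water,
                                                         priors):
        acq1 = AcquisitionParams(grid_shape=(1, 1))
        tmap = [[GroundTruthVoxel(region="PHE",
                                  concentrations={"NAA": 9.7, "Cr": 3.62,
                                                  "Cho": 1.2})]]
        grid = simulate_csi_grid(tmap, mets, water, acq1, seed=0)
        table = quantify_grid(grid, priors)
        assert sorted(table["metabolite"]) == ["Cho", "Cr", "NAA"]

    def test_grid_records_match_per_voxel_calls(self, mets, water, priors):
        from perispect.spectra import Spectrum
        acq3 = AcquisitionParams(grid_shape=(3, 3))
        tmap = [[GroundTruthVoxel(concentrations={}) for _ in range(3)]
                for _ in range(3)]
        tmap[0][1] = GroundTruthVoxel(region="PHE",
                                      concentrations={"NAA": 9.7, "Cr": 3.62,
                                                      "Cho": 1.2}, snr=30.0)
        tmap[1][0] = GroundTruthVoxel(region="ATNE",
                                      concentrations={"NAA": 9.45, "Cr": 3.46,
                                                      "Cho": 1.1}, snr=30.0)
        tmap[2][2] = GroundTruthVoxel(region="CONTRA",
                                      concentrations={"NAA": 13.7, "Cr": 9.43,
                                                      "Cho": 2.6}, snr=30.0)
        grid = simulate_csi_grid(tmap, mets, water, acq3, seed=4)
        table = quantify_grid(grid, priors, regions_only=True)
        assert len(table) == 9
        for (i, j) in ((0, 1), (1, 0), (2, 2)):
            sup = Spectrum(grid.suppressed[i, j], grid.ppm_axis, meta=grid.acq)
            uns = Spectrum(grid.unsuppressed[i, j], grid.ppm_axis,
                           meta=grid.acq)
            recs = quantify_voxel(sup, uns, priors, grid.acq, voxel=(i, j))
            sub = table[(table.voxel_row == i) & (table.voxel_col == j)]
            for rec in recs:
                got = sub[sub.metabolite == rec.metabolite]["Cm_mM"].iloc[0]
                assert got == pytest.approx(rec.cm, rel=1e-12)
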