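import numpy as np
import pytest

import ptytomo as pt
from ptytomo.optics import (OpticsError, aberration_phase,
                            encircled_energy_diameter)


class TestElectronWavelength:
    # expected values evaluated independently from the relativistic
    # de Broglie formula with CODATA 2018 constants
    @pytest.mark.parametrize("kv,expected", [
        (60.0, 0.004866),
        (300.0, 0.001969),
    ])
    def test_relativistic_values(self, kv, expected):
        assert pt.electron_wavelength(kv) == pytest.approx(expected, abs=5e-7)

    def test_nonrelativistic_limit(self):
        # lambda ~ 1.22643/sqrt(V) nm at 100 V; correction < 1e-4
        lam = pt.electron_wavelength(0.1)
        assert lam == pytest.approx(1.22643 / np.sqrt(100.0), rel=1e-4)

    def test_monotone_decreasing(self):
        kvs = np.linspace(1.0, 1000.0, 200)
        lams = [pt.electron_wavelength(v) for v in kvs]
        assert np.all(np.diff(lams) < 0)

    def test_invalid_voltage(self):
        with pytest.raises(OpticsError):
            pt.electron_wavelength(0.0)
        with pytest.raises(OpticsError):
            pt.electron_wavelength(-60.0)


class TestPtychoResolution:
    def test_paper_value_60kv(self):
        optics = pt.OpticsConfig(60.0, 1.5)
        assert round(pt.ptycho_resolution(optics), 2) == 1.62

    def test_beta_defaults_to_alpha(self):
        a = pt.OpticsConfig(60.0, 1.5)
        b = pt.OpticsConfig(60.0, 1.5, beta_mrad=1.5)
        assert pt.ptycho_resolution(a) == pt.ptycho_resolution(b)
        # equals lambda/(2 alpha)
        assert pt.ptycho_resolution(a) == pytest.approx(
            a.wavelength_nm / (2 * 1.5e-3))

    def test_300kv(self):
        optics = pt.OpticsConfig(300.0, 1.5)
        assert pt.ptycho_resolution(optics) == pytest.approx(
            pt.electron_wavelength(300.0) / 0.003, rel=1e-9)
        assert pt.ptycho_resolution(optics) == pytest.approx(0.656, abs=5e-4)

    def test_invalid_angles(self):
        with pytest.raises(OpticsError):
            pt.OpticsConfig(60.0, 0.0)
        with pytest.raises(OpticsError):
            pt.OpticsConfig(60.0, 1.5, beta_mrad=1.0)


class TestCtfFirstZero:
    def test_paper_value(self):
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-2800.0)
        assert round(pt.ctf_first_zero(optics), 2) == 3.69

    def test_closed_form_agreement(self):
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-8900.0)
        expected = np.sqrt(pt.electron_wavelength(60.0) * 8900.0)
        assert pt.ctf_first_zero(optics) == pytest.approx(expected, rel=1e-9)
        assert pt.ctf_first_zero(optics) == pytest.approx(6.58, abs=5e-3)

    def test_zero_defocus_limit(self):
        d = [pt.ctf_first_zero(pt.OpticsConfig(60.0, 1.5, defocus_nm=-df))
             for df in (100.0, 10.0, 1.0)]
        assert d[0] > d[1] > d[2]
        assert d[2] < 0.1

    def test_no_zero_crossing(self):
        with pytest.raises(OpticsError):
            pt.ctf_first_zero(pt.OpticsConfig(60.0, 1.5))

    def test_numeric_root_with_cs(self):
        optics = pt.OpticsConfig(300.0, 1.5, defocus_nm=-500.0, cs_mm=1.0)
        d = pt.ctf_first_zero(optics)
        chi = aberration_phase(optics, np.array(1.0 / d))
        assert abs(abs(np.sin(chi))) < 1e-6

    def test_cs_zero_numeric_matches_closed_form(self):
        # tiny cs forces the numeric branch; must agree with sqrt(lam |df|)
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-2800.0, cs_mm=1e-12)
        closed = np.sqrt(pt.electron_wavelength(60.0) * 2800.0)
        assert pt.ctf_first_zero(optics) == pytest.approx(closed, rel=1e-5)


class TestProbeGeometry:
    def test_paper_diameter(self):
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-40000.0)
        assert pt.probe_geometric_diameter(optics) == pytest.approx(120.0)

    def test_zero_defocus(self):
        assert pt.probe_geometric_diameter(pt.OpticsConfig(60.0, 1.5)) == 0.0

    def test_derived_value(self):
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-34000.0)
        assert pt.probe_geometric_diameter(optics) == pytest.approx(102.0)


class TestOverlapAndDose:
    def test_paper_overlap(self):
        assert round(100 * pt.overlap_ratio(20.0, 120.0)) == 83

    def test_overlap_edges(self):
        assert pt.overlap_ratio(120.0, 120.0) == 0.0
        assert pt.overlap_ratio(0.0, 120.0) == 1.0
        assert pt.overlap_ratio(200.0, 120.0) == 0.0

    def test_areal_overlap_bounds(self):
        assert pt.areal_overlap_ratio(0.0, 120.0) == pytest.approx(1.0)
        assert pt.areal_overlap_ratio(120.0, 120.0) < pt.overlap_ratio(
            0.5 * 120.0, 120.0)

    def test_total_dose_exact(self):
        assert pt.total_dose(88.0, 23) == 2024.0
        assert pt.total_dose(26.0, 23) == 598.0
        assert pt.total_dose(45.0, 23) == 1035.0

    def test_electrons_per_pattern(self):
        assert pt.electrons_per_pattern(88.0, 20.0) == pytest.approx(3.52e6)
        assert pt.DoseSpec(88.0, 20.0).electrons_per_pattern == \
            pytest.approx(3.52e6)

    def test_invalid_inputs(self):
        with pytest.raises(OpticsError):
            pt.overlap_ratio(20.0, 0.0)
        with pytest.raises(OpticsError):
            pt.electrons_per_pattern(-1.0, 20.0)


class TestMakeProbe:
    def test_unit_intensity(self):
        grid = pt.Grid2D((128, 128), 1.0)
        probe = pt.make_probe(grid, pt.OpticsConfig(60.0, 1.5,
                                                    defocus_nm=-2000.0))
        assert probe.total_intensity == pytest.approx(1.0, abs=1e-10)

    def test_airy_first_minimum(self):
        grid = pt.Grid2D((512, 512), 0.4)
        optics = pt.OpticsConfig(60.0, 1.5)
        probe = pt.make_probe(grid, optics)
        profile = probe.intensity[256, 256:]
        minima = np.nonzero((profile[1:-1] < profile[:-2])
                            & (profile[1:-1] < profile[2:]))[0]
        measured = (minima[0] + 1) * 0.4
        expected = 0.61 * optics.wavelength_nm / optics.alpha_rad
        assert measured == pytest.approx(expected, rel=0.05)

    def test_defocused_diameter_120nm(self):
        grid = pt.Grid2D((256, 256), 1.5)
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-40000.0)
        probe = pt.make_probe(grid, optics)
        d90 = encircled_energy_diameter(probe, 0.9)
        assert d90 == pytest.approx(120.0, rel=0.10)

    def test_sampling_error(self):
        # Nyquist below the aperture frequency must be rejected
        with pytest.raises(OpticsError):
            pt.make_probe(pt.Grid2D((64, 64), 2.0),
                          pt.OpticsConfig(60.0, 1.5))

    def test_field_of_view_error(self):
        with pytest.raises(OpticsError):
            pt.make_probe(pt.Grid2D((64, 64), 1.0),
                          pt.OpticsConfig(60.0, 1.5, defocus_nm=-40000.0))


class TestPropagate:
    def test_identity_at_zero(self):
        grid = pt.Grid2D((128, 128), 1.0)
        probe = pt.make_probe(grid, pt.OpticsConfig(60.0, 1.5,
                                                    defocus_nm=-2000.0))
        out = pt.propagate(probe, 0.0, pt.electron_wavelength(60.0))
        np.testing.assert_allclose(out.values, probe.values, atol=1e-12)

    def test_inverse_pair(self):
        grid = pt.Grid2D((128, 128), 1.0)
        probe = pt.make_probe(grid, pt.OpticsConfig(60.0, 1.5,
                                                    defocus_nm=-2000.0))
        lam = pt.electron_wavelength(60.0)
        back = pt.propagate(pt.propagate(probe, 700.0, lam), -700.0, lam)
        np.testing.assert_allclose(back.values, probe.values, atol=1e-10)

    @pytest.mark.parametrize("dz", [-5000.0, 133.7, 40000.0])
    def test_unitarity(self, dz):
        grid = pt.Grid2D((128, 128), 1.0)
        probe = pt.make_probe(grid, pt.OpticsConfig(60.0, 1.5,
                                                    defocus_nm=-2000.0))
        out = pt.propagate(probe, dz, pt.electron_wavelength(60.0))
        assert out.total_intensity == pytest.approx(probe.total_intensity,
                                                    abs=1e-10)

    def test_refocus_defocused_probe(self):
        grid = pt.Grid2D((256, 256), 1.5)
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-40000.0)
        lam = optics.wavelength_nm
        defocused = pt.make_probe(grid, optics)
        refocused = pt.propagate(defocused, 40000.0, lam)
        focused = pt.make_probe(grid, pt.OpticsConfig(60.0, 1.5))
        d_ref = encircled_energy_diameter(refocused, 0.9)
        d_foc = encircled_energy_diameter(focused, 0.9)
        assert d_ref <= 2.0 * d_foc

    def test_exact_kernel_close_to_paraxial(self):
        grid = pt.Grid2D((128, 128), 1.0)
        probe = pt.make_probe(grid, pt.OpticsConfig(60.0, 1.5,
                                                    defocus_nm=-2000.0))
        lam = pt.electron_wavelength(60.0)
        a = pt.propagate(probe, 1000.0, lam)
        b = pt.propagate(probe, 1000.0, lam, exact=True)
        # at 1.5 mrad the kernels are indistinguishable in practice
        assert np.max(np.abs(a.values - b.values)) < 1e-4


class TestSignConvention:
    def test_underfocus_gives_negative_chi_at_low_k(self):
        # pinned: chi < 0 at low k for negative defocus, so a weak phase
        # object at underfocus shows positive (bright) contrast
        optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-2800.0)
        k = np.array([0.05])
        assert aberration_phase(optics, k)[0] < 0
        assert np.sin(aberration_phase(optics, k))[0] < 0
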