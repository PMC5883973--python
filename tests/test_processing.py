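import dataclasses

import numpy as np
import pytest

from calfnmr.processing import (
    CalibrationError,
    Spectrum,
    apodize_and_transform,
    baseline_correct,
    bin_matrix,
    bin_spectrum,
    calibrate_ppm,
    phase_correct,
)
from calfnmr.simulate import FID, AcquisitionParams, synthesize_fid


def fwhm_hz(spec, lo, hi):
    mask = (spec.ppm_axis > lo) & (spec.ppm_axis < hi)
    x, y = spec.ppm_axis[mask], spec.intensity[mask]
    half = y.max() / 2
    idx = np.flatnonzero(y >= half)
    i0, i1 = idx[0], idx[-1]
    left = np.interp(half, [y[i0 - 1], y[i0]], [x[i0 - 1], x[i0]])
    right = np.interp(half, [y[i1 + 1], y[i1]], [x[i1 + 1], x[i1]])
    return (right - left) * 600.13


def flat_spectrum(value=1.0, n=4096):
    ppm = np.linspace(-2.0, 12.0, n)
    return Spectrum(ppm_axis=ppm, values=np.full(n, value, dtype=complex))


class TestApodizeAndTransform:
    def test_line_broadening_adds_to_linewidth(self, library, quiet_params):
        fid = synthesize_fid({"Creatine": 500.0}, library, quiet_params)
        base = fwhm_hz(apodize_and_transform(fid, lb_hz=0.0), 2.95, 3.1)
        broad = fwhm_hz(apodize_and_transform(fid, lb_hz=0.3), 2.95, 3.1)
        assert broad - base == pytest.approx(0.3, rel=0.05)

    def test_pure_exponential_gives_single_peak_at_ppm(self, quiet_params):
        p = quiet_params
        t = np.arange(p.n_points) * p.dwell_s
        f = (7.0 - p.center_ppm) * p.larmor_mhz  # resonance at 7.0 ppm
        fid = FID(values=np.exp((2j * np.pi * f - 2.0) * t), dwell_s=p.dwell_s, params=p)
        spec = apodize_and_transform(fid)
        assert spec.ppm_axis[np.argmax(spec.intensity)] == pytest.approx(7.0, abs=0.001)

    def test_zero_fid_gives_zero_spectrum(self, quiet_params):
        p = quiet_params
        fid = FID(values=np.zeros(p.n_points, complex), dwell_s=p.dwell_s, params=p)
        spec = apodize_and_transform(fid)
        assert np.allclose(spec.values, 0.0)

    def test_nonfinite_fid_rejected(self, quiet_params):
        p = quiet_params
        vals = np.zeros(p.n_points, complex)
        vals[5] = np.nan
        with pytest.raises(ValueError):
            FID(values=vals, dwell_s=p.dwell_s, params=p)

    def test_processing_log_records_step(self, library, quiet_params):
        spec = apodize_and_transform(synthesize_fid({"Creatine": 100.0}, library, quiet_params))
        assert any("apodize" in step for step in spec.processing_log)


@pytest.fixture(scope="module")
def clean_spectrum(library, quiet_params):
    fid = synthesize_fid(
        {m.name: m.group_distributions["Ha"][0] for m in library.metabolites},
        library, quiet_params,
    )
    return apodize_and_transform(fid)


class TestPhaseCorrect:
    @staticmethod
    def injected(spec, deg):
        return dataclasses.replace(spec, values=spec.values * np.exp(-1j * np.deg2rad(deg)))

    @staticmethod
    def applied_phi0(spec):
        entry = [s for s in spec.processing_log if s.startswith("phase_correct")][-1]
        return float(entry.split("phi0_deg=")[1].split(",")[0])

    def test_recovers_injected_30_degrees(self, clean_spectrum):
        corrected = phase_correct(self.injected(clean_spectrum, 30.0))
        assert self.applied_phi0(corrected) == pytest.approx(30.0, abs=1.0)

    def test_already_phased_correction_near_zero(self, clean_spectrum):
        corrected = phase_correct(clean_spectrum)
        assert abs(self.applied_phi0(corrected)) < 1.0

    def test_pure_dispersion_round_trip_area(self, clean_spectrum):
        mask = (clean_spectrum.ppm_axis > 3.0) & (clean_spectrum.ppm_axis < 3.06)
        ref = np.trapezoid(clean_spectrum.intensity[mask], clean_spectrum.ppm_axis[mask])
        corrected = phase_correct(self.injected(clean_spectrum, 90.0))
        got = np.trapezoid(corrected.intensity[mask], corrected.ppm_axis[mask])
        assert got == pytest.approx(ref, rel=0.01)


class TestBaselineCorrect:
    def test_linear_ramp_removed(self, library, quiet_params):
        fid = synthesize_fid({"Creatine": 300.0}, library, quiet_params)
        spec = apodize_and_transform(fid)
        mask = (spec.ppm_axis > 3.0) & (spec.ppm_axis < 3.06)
        truth = np.trapezoid(spec.intensity[mask], spec.ppm_axis[mask])
        ramp = 0.5 + 0.2 * spec.ppm_axis
        ramped = dataclasses.replace(spec, values=spec.values + ramp)
        corrected = baseline_correct(ramped)
        m2 = (corrected.ppm_axis > 3.0) & (corrected.ppm_axis < 3.06)
        got = np.trapezoid(corrected.intensity[m2], corrected.ppm_axis[m2])
        assert got == pytest.approx(truth, rel=0.02)
        # removing the ramp must reproduce the ramp-free AsLS result exactly
        ref = baseline_correct(spec)
        ref_int = np.trapezoid(ref.intensity[m2], ref.ppm_axis[m2])
        assert got == pytest.approx(ref_int, rel=1e-6)

    def test_flat_zero_input_unchanged(self):
        spec = flat_spectrum(0.0)
        out = baseline_correct(spec)
        assert np.allclose(out.intensity, 0.0, atol=1e-9)

    def test_constant_offset_removed(self, library, quiet_params):
        fid = synthesize_fid({"Creatine": 300.0}, library, quiet_params)
        spec = apodize_and_transform(fid)
        shifted = dataclasses.replace(spec, values=spec.values + 5.0)
        corrected = baseline_correct(shifted)
        off_peak = (corrected.ppm_axis > 8.0) & (corrected.ppm_axis < 10.0)
        assert abs(corrected.intensity[off_peak].mean()) < 0.01


class TestCalibratePpm:
    def make_glucose_spectrum(self, library, shift_ppm):
        params = AcquisitionParams(
            experiment="cpmg", noise_sd=0.0,
            shift_jitter_sd_ppm=0.0, peak_jitter_sd_ppm=0.0,
        )
        fid = synthesize_fid({"D-Glucose": 1400.0}, library, params)
        spec = apodize_and_transform(fid)
        return dataclasses.replace(spec, ppm_axis=spec.ppm_axis + shift_ppm)

    def test_shifted_doublet_recentered(self, library):
        spec = self.make_glucose_spectrum(library, +0.02)  # doublet at 5.26
        out = calibrate_ppm(spec)
        mask = np.abs(out.ppm_axis - 5.24) < 0.02
        peaks = out.ppm_axis[mask][np.argsort(out.intensity[mask])[-2:]]
        assert peaks.mean() == pytest.approx(5.24, abs=0.002)

    def test_already_calibrated_zero_shift(self, library):
        out = calibrate_ppm(self.make_glucose_spectrum(library, 0.0))
        entry = [s for s in out.processing_log if "calibrate" in s][-1]
        shift = float(entry.split("shift=")[1].rstrip(")"))
        assert abs(shift) < 0.002

    def test_simulator_jitter_recovered(self, library):
        params = AcquisitionParams(
            experiment="cpmg", noise_sd=0.0,
            shift_jitter_sd_ppm=0.03, peak_jitter_sd_ppm=0.0,
        )
        conc = {m.name: m.group_distributions["Ha"][0] for m in library.metabolites}
        for seed in (1, 2, 3):
            fid = synthesize_fid(conc, library, params, seed=seed)
            out = calibrate_ppm(apodize_and_transform(fid))
            mask = np.abs(out.ppm_axis - 5.24) < 0.02
            peaks = out.ppm_axis[mask][np.argsort(out.intensity[mask])[-2:]]
            assert abs(peaks.mean() - 5.24) < 0.005

    def test_no_doublet_raises_with_tmsp_hint(self, library, quiet_params):
        fid = synthesize_fid({"Creatine": 100.0}, library, quiet_params)
        spec = apodize_and_transform(fid)
        with pytest.raises(CalibrationError, match="TMSP"):
            calibrate_ppm(spec)

    def test_tmsp_fallback_applies(self, library, quiet_params):
        fid = synthesize_fid({"Creatine": 100.0}, library, quiet_params)
        spec = apodize_and_transform(fid)
        shifted = dataclasses.replace(spec, ppm_axis=spec.ppm_axis + 0.01)
        out = calibrate_ppm(shifted, tmsp_fallback=True)
        mask = np.abs(out.ppm_axis) < 0.05
        assert out.ppm_axis[mask][np.argmax(out.intensity[mask])] == pytest.approx(0.0, abs=0.001)


class TestBinning:
    def test_490_bins_without_exclusions(self):
        edges, vals = bin_spectrum(flat_spectrum(), exclusions=())
        assert len(vals) == 490

    def test_uniform_intensity_bins_equal_width(self):
        _, vals = bin_spectrum(flat_spectrum(1.0), exclusions=())
        assert np.allclose(vals, 0.02, rtol=1e-9)

    def test_binning_conserves_total_integral(self, library):
        params = AcquisitionParams(experiment="cpmg")
        conc = {m.name: m.group_distributions["0h"][0] for m in library.metabolites}
        spec = apodize_and_transform(synthesize_fid(conc, library, params, seed=5))
        _, vals = bin_spectrum(spec, exclusions=())
        # independent total: trapezoid over the axis with the range endpoints
        # inserted by linear interpolation
        x = np.concatenate(([0.2], spec.ppm_axis[(spec.ppm_axis > 0.2) & (spec.ppm_axis < 10.0)], [10.0]))
        y = np.interp(x, spec.ppm_axis, spec.intensity)
        total = np.trapezoid(y, x)
        assert vals.sum() == pytest.approx(total, rel=1e-6)

    def test_water_exclusion_drops_bins(self):
        edges, vals = bin_spectrum(flat_spectrum(), exclusions=((4.50, 5.00),))
        assert len(vals) == 490 - 25
        assert not np.any((edges >= 4.50) & (edges < 5.00))

    def test_range_outside_spectrum_rejected(self):
        spec = flat_spectrum()
        with pytest.raises(ValueError, match="outside"):
            bin_spectrum(spec, ppm_range=(0.2, 15.0))

    def test_spectrum_tsv_roundtrip(self, library, quiet_params, tmp_path):
        from calfnmr.processing import read_spectrum_tsv, write_spectrum_tsv

        spec = apodize_and_transform(synthesize_fid({"Creatine": 200.0}, library, quiet_params))
        write_spectrum_tsv(spec, tmp_path / "s.tsv")
        back = read_spectrum_tsv(tmp_path / "s.tsv")
        assert np.allclose(back.ppm_axis, spec.ppm_axis, atol=1e-6)
        assert np.allclose(back.intensity, spec.intensity, atol=1e-5 * np.abs(spec.intensity).max())
        # descending input is flipped to the ascending internal convention
        (tmp_path / "d.tsv").write_text("ppm\tintensity\n2.0\t5.0\n1.0\t3.0\n")
        desc = read_spectrum_tsv(tmp_path / "d.tsv")
        assert desc.ppm_axis.tolist() == [1.0, 2.0]
        assert desc.intensity.tolist() == [3.0, 5.0]

    def test_bin_matrix_stacks_and_orders_descending(self, library, quiet_params):
        specs = [
            apodize_and_transform(synthesize_fid({"Creatine": c}, library, quiet_params))
            for c in (100.0, 200.0)
        ]
        specs = [dataclasses.replace(s, sample_id=f"s{i}") for i, s in enumerate(specs)]
        bm = bin_matrix(specs)
        assert bm.values.shape == (2, 465)
        df = bm.to_dataframe()
        cols = df.columns.astype(float)
        assert (np.diff(cols) < 0).all()
        assert list(df.index) == ["s0", "s1"]
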