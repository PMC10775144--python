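import math

import numpy as np
import pytest

from capsidms import masscalc as mc
from capsidms.spectra import (
    Chromatogram,
    DeconvolutionParams,
    DeconvolvedFeature,
    Peak,
    Scan,
    SpectraError,
    SpectrumSet,
    deconvolve,
    extract_xic,
    integrate_peaks,
    label_peaks,
    read_spectra,
    write_spectra,
)
from capsidms.synth import SimulatedSpecies, SimulationConfig, simulate_run


def single_species_run(mass=59973.78, apex=16.0, seed=0, **kwargs):
    cfg = SimulationConfig(
        species=(SimulatedSpecies("X", "VP3", mass, apex, abundance=1e6),),
        seed=seed,
        scan_interval=0.1,
        **kwargs,
    )
    return simulate_run(cfg)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        # noise on every scan so the CSV dialect (which has no way to express
        # an empty scan) represents the full run
        spectra, _, _ = single_species_run(n_noise_peaks=3, noise_peak_intensity=10.0)
        path = tmp_path / "run.csv"
        write_spectra(spectra, path)
        back = read_spectra(path)
        assert len(back) == len(spectra)
        for a, b in zip(spectra.scans, back.scans):
            assert a.rt == pytest.approx(b.rt, abs=1e-6)
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-6)
            np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-5)

    def test_minimal_mzml_round_trip(self, tmp_path):
        original = SpectrumSet(
            scans=[
                Scan(rt=13.5, mz=np.array([900.0, 1500.5]), intensity=np.array([1.0, 2.0])),
                Scan(rt=13.6, mz=np.array([901.0]), intensity=np.array([3.0])),
            ]
        )
        path = tmp_path / "run.mzml"
        write_spectra(original, path)
        back = read_spectra(path)
        assert len(back) == 2
        for a, b in zip(original.scans, back.scans):
            assert a.rt == pytest.approx(b.rt)
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_simulated_scan_count_matches_config(self):
        spectra, _, manifest = single_species_run()
        assert len(spectra) == manifest["n_scans"]

    def test_malformed_csv_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("rt_min,mz,intensity\n13.0,900.0,1.0\n13.0,oops\n")
        with pytest.raises(SpectraError, match=":3"):
            read_spectra(path)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(SpectraError, match="header"):
            read_spectra(path)

    def test_unsorted_rts_rejected(self):
        with pytest.raises(SpectraError):
            SpectrumSet(
                scans=[
                    Scan(rt=14.0, mz=np.array([900.0]), intensity=np.array([1.0])),
                    Scan(rt=13.0, mz=np.array([900.0]), intensity=np.array([1.0])),
                ]
            )


class TestDeconvolve:
    def test_single_species_recovered(self):
        spectra, _, _ = single_species_run()
        feats = deconvolve(spectra, DeconvolutionParams(charge_range=(25, 60)))
        assert len(feats) == 1
        f = feats[0]
        assert abs(f.neutral_mass - 59973.78) / 59973.78 * 1e6 < 10
        assert f.score > 60
        assert f.n_charge_states >= 3

    def test_two_species_distinct_rts(self):
        cfg = SimulationConfig(
            species=(
                SimulatedSpecies("A", "VP3", 59973.78, 16.0, abundance=1e6),
                SimulatedSpecies("B", "VP2", 66487.90, 22.0, abundance=8e5),
            ),
            seed=3,
            scan_interval=0.1,
        )
        spectra, _, manifest = simulate_run(cfg)
        feats = deconvolve(spectra, DeconvolutionParams(charge_range=(25, 60)))
        assert len(feats) == 2
        for truth in manifest["species"]:
            best = min(feats, key=lambda f: abs(f.neutral_mass - truth["mass"]))
            assert abs(best.neutral_mass - truth["mass"]) / truth["mass"] * 1e6 < 10
            assert abs(best.rt_apex - truth["rt_apex"]) <= 0.1

    def test_single_charge_state_gives_no_feature(self):
        # one ion series at a single charge cannot form a ladder
        mass, z = 60000.0, 40
        mz = (mass + z * mc.PROTON_MASS) / z
        scans = [
            Scan(rt=14.0 + 0.1 * i, mz=np.array([mz]), intensity=np.array([100.0]))
            for i in range(20)
        ]
        feats = deconvolve(
            SpectrumSet(scans=scans),
            DeconvolutionParams(charge_range=(39, 41), min_charge_states=2),
        )
        assert feats == []

    def test_empty_window_returns_empty(self):
        scans = [Scan(rt=5.0, mz=np.array([900.0]), intensity=np.array([1.0]))]
        feats = deconvolve(SpectrumSet(scans=scans))
        assert feats == []

    def test_mass_recovery_property_55_to_85_kda(self):
        """Median recovery error across ten masses stays within 10 ppm."""
        rng = np.random.default_rng(42)
        masses = np.sort(rng.uniform(55_000, 85_000, size=10))
        species = tuple(
            SimulatedSpecies(f"S{i}", "VP3", float(m), 14.0 + 1.4 * i, abundance=1e6)
            for i, m in enumerate(masses)
        )
        cfg = SimulationConfig(
            species=species,
            seed=7,
            scan_interval=0.1,
            n_noise_peaks=20,
            noise_peak_intensity=500.0,
        )
        spectra, _, _ = simulate_run(cfg)
        feats = deconvolve(spectra, DeconvolutionParams(charge_range=(20, 95)))
        errors = []
        for m in masses:
            best = min(feats, key=lambda f: abs(f.neutral_mass - m))
            errors.append(abs(best.neutral_mass - m) / m * 1e6)
        assert float(np.median(errors)) <= 10.0

    def test_invalid_params_rejected(self):
        with pytest.raises(SpectraError):
            DeconvolutionParams(merge_tolerance_ppm=0)
        with pytest.raises(SpectraError):
            DeconvolutionParams(rt_limits=(20.0, 10.0))
        with pytest.raises(SpectraError):
            DeconvolvedFeature(
                neutral_mass=1.0, rt_apex=1.0, area=1.0, score=120.0, n_charge_states=2
            )


class TestXic:
    def test_apex_at_simulated_rt(self):
        spectra, _, manifest = single_species_run()
        truth = manifest["species"][0]
        xic = extract_xic(spectra, truth["mass"], charges=range(25, 60))
        apex = xic.time[int(np.argmax(xic.intensity))]
        assert abs(apex - truth["rt_apex"]) <= 0.1

    def test_no_matching_ions_all_zero(self):
        spectra, _, _ = single_species_run()
        xic = extract_xic(spectra, 12_345.0, charges=range(25, 60))
        assert np.all(xic.intensity == 0)

    def test_tolerance_monotonicity(self):
        spectra, _, _ = single_species_run(n_noise_peaks=30, noise_peak_intensity=100.0)
        narrow = extract_xic(spectra, 59973.78, charges=range(25, 60), tol_ppm=5)
        wide = extract_xic(spectra, 59973.78, charges=range(25, 60), tol_ppm=10)
        assert wide.intensity.sum() >= narrow.intensity.sum()

    def test_additivity_over_charges(self):
        spectra, _, _ = single_species_run()
        combined = extract_xic(spectra, 59973.78, charges=range(30, 41))
        summed = sum(
            extract_xic(spectra, 59973.78, charges=[z]).intensity
            for z in range(30, 41)
        )
        np.testing.assert_allclose(combined.intensity, summed, rtol=1e-12)

    def test_empty_charges_rejected(self):
        spectra, _, _ = single_species_run()
        with pytest.raises(SpectraError):
            extract_xic(spectra, 59973.78, charges=[])


def gaussian_trace(apexes, heights, sigma=0.2, t0=13.0, t1=28.5, dt=0.01):
    t = np.arange(t0, t1, dt)
    y = np.zeros_like(t)
    for a, h in zip(apexes, heights):
        y += h * np.exp(-0.5 * ((t - a) / sigma) ** 2)
    return Chromatogram(label="FLR", time=t, intensity=y)


class TestIntegratePeaks:
    def test_single_gaussian_area(self):
        sigma, height = 0.2, 1e5
        c = gaussian_trace([18.0], [height], sigma=sigma)
        peaks = integrate_peaks(c)
        assert len(peaks) == 1
        expected = height * sigma * math.sqrt(2 * math.pi)
        assert peaks[0].area == pytest.approx(expected, rel=0.01)
        assert peaks[0].start_rt < 18.0 < peaks[0].end_rt

    def test_flat_trace_no_peaks(self):
        t = np.arange(13.0, 20.0, 0.05)
        c = Chromatogram(label="FLR", time=t, intensity=np.full_like(t, 5.0))
        assert integrate_peaks(c) == []

    def test_two_resolved_gaussians(self):
        sigma = 0.15
        c = gaussian_trace([16.0, 20.0], [2e5, 1e5], sigma=sigma)
        peaks = integrate_peaks(c)
        assert len(peaks) == 2
        for p, h in zip(sorted(peaks, key=lambda p: p.apex_rt), [2e5, 1e5]):
            assert p.area == pytest.approx(h * sigma * math.sqrt(2 * math.pi), rel=0.01)

    def test_area_conservation(self):
        c = gaussian_trace([15.0, 18.0, 24.0], [1e5, 3e5, 2e4])
        peaks = integrate_peaks(c)
        assert sum(p.area for p in peaks) <= c.total_integral() * (1 + 1e-9)

    def test_short_trace_no_peaks(self):
        c = Chromatogram(label="x", time=np.array([1.0, 2.0]), intensity=np.array([0.0, 1.0]))
        assert integrate_peaks(c) == []

    def test_label_peaks_nearest(self):
        c = gaussian_trace([16.0, 20.0, 22.0], [3e5, 1e5, 8e4])
        peaks = integrate_peaks(c)
        labeled = label_peaks(peaks, {"VP3": 16.1, "VP1": 19.9, "VP2": 22.05})
        assert set(labeled) == {"VP3", "VP1", "VP2"}
        assert labeled["VP3"].apex_rt == pytest.approx(16.0, abs=0.05)

    def test_peak_invariants(self):
        with pytest.raises(SpectraError):
            Peak(apex_rt=1.0, start_rt=2.0, end_rt=3.0, area=1.0, height=1.0)
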