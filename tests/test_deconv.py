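"""Charge-series deconvolution, spectral averaging, centroiding and EICs."""

import numpy as np
import pytest

from middleup.chem import PROTON_MASS
from middleup.deconv import (
    AveragedSpectrum,
    average_spectrum,
    centroid_peaks,
    deconvolute,
    detect_chromatographic_peaks,
    extract_eic,
)
from middleup.kinetics import default_scenario
from middleup.sequences import bevacizumab_like, digest_and_map
from middleup.simulate import AcquisitionParams, DesignRow, Scan, ChromatographicRun, simulate_run


def envelope_centroids(mass, z_lo=10, z_hi=20, intensity=1000.0):
    """Forward model: exact centroid list for one charge-state envelope."""
    return [
        ((mass + z * PROTON_MASS) / z, intensity / (1 + abs(z - 15)))
        for z in range(z_lo, z_hi + 1)
    ]


class TestDeconvolution:
    def test_noiseless_series_inverts(self):
        peaks = deconvolute(envelope_centroids(23000.0))
        assert len(peaks) >= 1
        assert abs(peaks[0].zero_charge_mass - 23000.0) <= 0.46  # 20 ppm

    def test_single_charge_state_unsupported(self):
        centroids = [((23000.0 + 12 * PROTON_MASS) / 12, 500.0)]
        assert deconvolute(centroids) == []

    def test_min_series_boundary(self):
        centroids = envelope_centroids(24000.0, z_lo=12, z_hi=14)
        assert deconvolute(centroids, min_series=3)
        assert deconvolute(centroids, min_series=4) == []

    def test_two_species_16da_apart(self):
        centroids = envelope_centroids(24000.0) + envelope_centroids(24016.0)
        peaks = deconvolute(centroids)
        masses = sorted(p.zero_charge_mass for p in peaks[:2])
        assert len(peaks) >= 2
        assert masses[1] - masses[0] == pytest.approx(16.0, abs=0.5)

    def test_abundance_ordering(self):
        centroids = envelope_centroids(24000.0, intensity=100.0) + envelope_centroids(
            25000.0, intensity=10000.0
        )
        peaks = deconvolute(centroids)
        assert peaks[0].zero_charge_mass == pytest.approx(25000.0, abs=0.5)

    def test_oracle_random_species(self):
        """Forward-model inversion: random 22-27 kDa species, 20 ppm, full recall."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            mass = rng.uniform(22000.0, 27000.0)
            z_center = int(round(mass / 1200.0))
            centroids = envelope_centroids(mass, z_center - 5, z_center + 5)
            peaks = deconvolute(centroids)
            assert peaks
            err_ppm = abs(peaks[0].zero_charge_mass - mass) / mass * 1e6
            assert err_ppm <= 20.0


class TestSpectralOps:
    def _run_from_scans(self, scans):
        return ChromatographicRun(
            mab_name="x", role="BS", treatment="con", duration=0.0, replicate=1,
            seed=0, scans=scans, ground_truth={}, acquisition=AcquisitionParams(),
        )

    def test_average_of_identical_scans_is_that_scan(self):
        mz = 600.0 + 0.02 * np.arange(5)
        inten = np.array([1.0, 5.0, 9.0, 5.0, 1.0])
        scans = [Scan(rt=t, mz=mz, intensity=inten) for t in (1.0, 1.1, 1.2)]
        spec = average_spectrum(self._run_from_scans(scans), (0.9, 1.3))
        assert np.allclose(spec.mz, mz)
        assert np.allclose(spec.intensity, inten)

    def test_average_is_arithmetic_mean(self):
        mz = 600.0 + 0.02 * np.arange(3)
        x = np.array([1.0, 2.0, 3.0])
        scans = [
            Scan(rt=1.0, mz=mz, intensity=x),
            Scan(rt=1.1, mz=mz, intensity=3 * x),
        ]
        spec = average_spectrum(self._run_from_scans(scans), (0.9, 1.2))
        assert np.allclose(spec.intensity, 2 * x)

    def test_empty_window_rejected(self):
        scans = [Scan(rt=1.0, mz=np.array([600.0]), intensity=np.array([1.0]))]
        with pytest.raises(ValueError):
            average_spectrum(self._run_from_scans(scans), (5.0, 6.0))

    def test_centroid_of_symmetric_gaussian(self):
        mz = 1190.0 + 0.02 * np.arange(1000)
        inten = 1e4 * np.exp(-((mz - 1200.0) ** 2) / (2 * 0.12**2))
        spec = AveragedSpectrum((0, 1), mz, inten, 1)
        centroids = centroid_peaks(spec)
        assert len(centroids) == 1
        assert centroids[0][0] == pytest.approx(1200.0, abs=0.005)

    def test_two_gaussians_five_th_apart(self):
        mz = 1190.0 + 0.02 * np.arange(1000)
        inten = 1e4 * np.exp(-((mz - 1200.0) ** 2) / (2 * 0.12**2))
        inten += 8e3 * np.exp(-((mz - 1205.0) ** 2) / (2 * 0.12**2))
        centroids = centroid_peaks(AveragedSpectrum((0, 1), mz, inten, 1))
        assert len(centroids) == 2

    def test_empty_spectrum_no_centroids(self):
        spec = AveragedSpectrum((0, 1), np.empty(0), np.empty(0), 1)
        assert centroid_peaks(spec) == []

    def test_flat_tic_no_windows(self):
        scans = [
            Scan(rt=t, mz=np.empty(0), intensity=np.empty(0))
            for t in np.linspace(0, 10, 50)
        ]
        assert detect_chromatographic_peaks(self._run_from_scans(scans)) == []


@pytest.fixture(scope="module")
def noiseless_pair():
    """A noiseless stressed run with its mAb and subunits."""
    mab = bevacizumab_like("BS")
    subunits = digest_and_map(mab)
    preset = default_scenario(mab, subunits)
    acq = AcquisitionParams(noise_model="none", baseline=0.0)
    row24 = DesignRow("bevacizumab-like", "BS", "oxi", 24.0, 1)
    run = simulate_run(mab, subunits, preset, row24, acquisition=acq, seed=1)
    return mab, subunits, run


class TestEIC:

    def test_absent_species_near_zero(self, noiseless_pair):
        _, _, run = noiseless_pair
        trace = extract_eic(run, 3100.0, charge=8)
        assert trace.peak_height == pytest.approx(0.0, abs=1e-6)

    def test_wider_tolerance_non_decreasing(self, noiseless_pair):
        _, subunits, run = noiseless_pair
        from middleup.proteoforms import average_mass

        m = average_mass(subunits["LC"].sequence)
        z = int(round(m / 1200.0))
        mz_center = (m + z * PROTON_MASS) / z
        narrow = extract_eic(run, mz_center, z, tol=0.01)
        wide = extract_eic(run, mz_center, z, tol=0.1)
        assert wide.peak_height >= narrow.peak_height > 0

    def test_center_outside_range_rejected(self, noiseless_pair):
        _, _, run = noiseless_pair
        with pytest.raises(ValueError):
            extract_eic(run, 5000.0, charge=10)

    def test_linearity_against_simulated_fraction(self, noiseless_pair):
        """EIC height tracks simulated fraction (R^2 >= 0.99, noiseless)."""
        _, subunits, run = noiseless_pair
        from middleup.proteoforms import average_mass, modification_delta

        base = average_mass(subunits["LC"].sequence)
        fractions, heights = [], []
        for n_ox in range(4):
            name = "LC" if n_ox == 0 else f"LC {n_ox} Ox"
            frac = run.ground_truth["LC"].get(name, 0.0)
            if frac < 1e-4:
                continue
            m = base + n_ox * modification_delta("ox")
            z = int(round(m / 1200.0))
            mz_center = (m + z * PROTON_MASS) / z
            trace = extract_eic(run, mz_center, z)
            fractions.append(frac)
            heights.append(trace.peak_height)
        assert len(fractions) >= 3
        r = np.corrcoef(fractions, heights)[0, 1]
        assert r**2 >= 0.99
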