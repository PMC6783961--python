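"""Synthetic run generator: ground truth, determinism, structure, mzML I/O."""

import numpy as np
import pytest

from middleup.deconv import (
    average_spectrum,
    centroid_peaks,
    deconvolute,
    detect_chromatographic_peaks,
)
from middleup.kinetics import default_scenario
from middleup.mzml_io import read_mzml, write_mzml, write_run, read_run
from middleup.sequences import bevacizumab_like, digest_and_map
from middleup.simulate import (
    AcquisitionParams,
    DesignRow,
    build_design,
    ground_truth_fractions,
    simulate_run,
)

SEED = 424242


@pytest.fixture(scope="module")
def bev_setup():
    mab = bevacizumab_like("BS")
    subunits = digest_and_map(mab)
    preset = default_scenario(mab, subunits)
    return mab, subunits, preset


def _simulate(bev_setup, row, seed=SEED, **acq_kwargs):
    mab, subunits, preset = bev_setup
    acq = AcquisitionParams(**acq_kwargs) if acq_kwargs else None
    return simulate_run(mab, subunits, preset, row, acquisition=acq, seed=seed)


OXI48 = DesignRow("bevacizumab-like", "BS", "oxi", 48.0, 1)


class TestDesign:
    def test_table_shape(self):
        design = build_design()
        # 2 mabs x 2 roles x (1 con at 0 h + 3x(con+oxi)) x 3 replicates
        assert len(design) == 2 * 2 * 7 * 3
        assert set(design["treatment"]) == {"con", "oxi"}
        assert (design.loc[design["duration"] == 0, "treatment"] == "con").all()


class TestGroundTruth:
    def test_fractions_sum_to_one(self, bev_setup):
        mab, subunits, preset = bev_setup
        truth = ground_truth_fractions(mab, subunits, preset, OXI48)
        for kind, fractions in truth.items():
            assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_control_equals_time_zero(self, bev_setup):
        mab, subunits, preset = bev_setup
        con72 = ground_truth_fractions(
            mab, subunits, preset, DesignRow("bevacizumab-like", "BS", "con", 72.0, 1)
        )
        t0 = ground_truth_fractions(
            mab, subunits, preset, DesignRow("bevacizumab-like", "BS", "con", 0.0, 1)
        )
        for kind in con72:
            for pf, frac in con72[kind].items():
                assert frac == pytest.approx(t0[kind][pf], abs=1e-12)


class TestRunStructure:
    def test_scans_sorted_and_mz_increasing(self, bev_setup):
        run = _simulate(bev_setup, OXI48)
        rts = [s.rt for s in run.scans]
        assert rts == sorted(rts)
        for scan in run.scans:
            if scan.mz.size > 1:
                assert np.all(np.diff(scan.mz) > 0)
            if scan.mz.size:
                assert scan.mz.min() >= run.acquisition.mz_range[0]
                assert scan.mz.max() <= run.acquisition.mz_range[1]

    def test_seed_determinism(self, bev_setup):
        a = _simulate(bev_setup, OXI48)
        b = _simulate(bev_setup, OXI48)
        assert len(a.scans) == len(b.scans)
        for sa, sb in zip(a.scans, b.scans):
            assert np.array_equal(sa.mz, sb.mz)
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_different_seed_differs(self, bev_setup):
        a = _simulate(bev_setup, OXI48, seed=1)
        b = _simulate(bev_setup, OXI48, seed=2)
        assert any(
            not np.array_equal(sa.intensity, sb.intensity)
            for sa, sb in zip(a.scans, b.scans)
        )


@pytest.fixture(scope="module")
def single_species_run(bev_setup):
    mab, subunits, preset = bev_setup
    lc_only = {"LC": subunits["LC"]}
    con = DesignRow("bevacizumab-like", "BS", "con", 0.0, 1)
    acq = AcquisitionParams(noise_model="none", baseline=0.0)
    return simulate_run(mab, lc_only, preset, con, acquisition=acq, seed=SEED)


class TestSingleSpeciesRun:
    """A noiseless run of one proteoform inverts cleanly."""

    @pytest.fixture()
    def run(self, single_species_run):
        return single_species_run

    def test_one_chromatographic_peak_at_true_rt(self, run):
        windows = detect_chromatographic_peaks(run)
        assert len(windows) == 1
        lo, hi = windows[0]
        assert lo <= run.acquisition.base_rt["LC"] <= hi

    def test_apex_spectrum_deconvolutes_to_true_mass(self, run, bev_setup):
        _, subunits, _ = bev_setup
        from middleup.proteoforms import average_mass

        true_mass = average_mass(subunits["LC"].sequence)
        window = detect_chromatographic_peaks(run)[0]
        spec = average_spectrum(run, window)
        peaks = deconvolute(centroid_peaks(spec))
        assert peaks, "no deconvoluted mass recovered"
        err_ppm = abs(peaks[0].zero_charge_mass - true_mass) / true_mass * 1e6
        assert err_ppm <= 20.0


class TestMzML:
    def test_round_trip_scans(self, bev_setup, tmp_path):
        run = _simulate(bev_setup, DesignRow("bevacizumab-like", "BS", "oxi", 24.0, 2))
        path = tmp_path / "run.mzML"
        write_mzml(run, path)
        scans = read_mzml(path)
        assert len(scans) == len(run.scans)
        for orig, loaded in zip(run.scans, scans):
            assert loaded.rt == pytest.approx(orig.rt, abs=1e-9)
            assert np.array_equal(loaded.mz, orig.mz)
            assert np.array_equal(loaded.intensity, orig.intensity)

    def test_sidecar_round_trip(self, bev_setup, tmp_path):
        run = _simulate(bev_setup, OXI48)
        mzml_path = write_run(run, tmp_path)
        loaded = read_run(mzml_path)
        assert loaded.metadata == run.metadata
        assert loaded.ground_truth["LC"] == pytest.approx(run.ground_truth["LC"])
        assert len(loaded.scans) == len(run.scans)
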