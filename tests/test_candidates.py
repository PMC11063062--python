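"""Candidate spectrum assembly: classes I-IV and the penalty map."""

import numpy as np
import pytest

from ms2deconv import (
    RunData,
    Spectrum,
    detect_orphan_isotopologue,
    find_in_data_clean_spectrum,
    predict_isotopologue_spectrum,
    predict_unknown_spectrum,
    select_library_candidate,
)
from ms2deconv.candidates import NEUTRON_SHIFT, penalty_from_similarity
from ms2deconv.library import LibraryRecord, SpectralLibrary
from ms2deconv.spectrum import normalize_spectrum


class TestOrphanIsotopologue:
    def test_m_plus_1_parent_found(self):
        ms1 = Spectrum(mz=[200.0, 201.0034], intensity=[1e6, 1e5],
                       precursor_rt=10.0, ms_level=1)
        link = detect_orphan_isotopologue((201.0034, 1e5), ms1, charge_max=1)
        assert link is not None
        parent_mz, n, z = link
        assert parent_mz == pytest.approx(200.0)
        assert (n, z) == (1, 1)

    def test_no_parent_below_returns_none(self):
        ms1 = Spectrum(mz=[150.0, 201.0034], intensity=[1e6, 1e5],
                       precursor_rt=10.0, ms_level=1)
        assert detect_orphan_isotopologue((201.0034, 1e5), ms1, 1) is None

    def test_parent_must_outweigh_isotopologue(self):
        ms1 = Spectrum(mz=[200.0, 201.0034], intensity=[1e4, 1e6],
                       precursor_rt=10.0, ms_level=1)
        assert detect_orphan_isotopologue((201.0034, 1e6), ms1, 1) is None

    @pytest.mark.parametrize("z", [1, 2])
    def test_simulated_pairs_all_linked(self, z):
        rng = np.random.default_rng(5)
        parents = rng.uniform(150.0, 500.0, 8)
        mz, inten = [], []
        truth = {}
        for p in parents:
            child = p + NEUTRON_SHIFT / z
            mz += [p, child]
            inten += [1e6, 2e5]
            truth[round(child, 4)] = p
        ms1 = Spectrum(mz=mz, intensity=inten, precursor_rt=0.0, ms_level=1)
        for child, parent in truth.items():
            link = detect_orphan_isotopologue((child, 2e5), ms1, charge_max=2)
            assert link is not None
            assert link[0] == pytest.approx(parent, abs=1e-4)


class TestIsotopologueSpectrumPrediction:
    def test_fragment_with_all_carbons_fully_shifted(self):
        parent = Spectrum(mz=[120.0], intensity=[100.0], precursor_mz=181.07,
                          formulas=["C6H12O6"])
        cand = predict_isotopologue_spectrum(parent, "C6H12O6", n=1)
        assert len(cand.spectrum) == 1
        assert cand.spectrum.mz[0] == pytest.approx(120.0 + NEUTRON_SHIFT)

    def test_half_carbon_fragment_splits_evenly(self):
        parent = Spectrum(mz=[90.0], intensity=[100.0], precursor_mz=181.07,
                          formulas=["C3H6O3"])
        cand = predict_isotopologue_spectrum(parent, "C6H12O6", n=1)
        assert len(cand.spectrum) == 2
        np.testing.assert_allclose(cand.spectrum.intensity, [100.0, 100.0])

    def test_glucose_like_c2_c4_fragments(self):
        # C6 precursor; C2 fragment keeps the label 1/3 of the time, C4 2/3
        parent = Spectrum(mz=[60.0, 120.0], intensity=[100.0, 100.0],
                          precursor_mz=181.07, formulas=["C2H4O2", "C4H8O4"])
        cand = predict_isotopologue_spectrum(parent, "C6H12O6", n=1)
        peaks = dict(zip(np.round(cand.spectrum.mz, 3), cand.spectrum.intensity))
        shifted_c2 = peaks[round(60.0 + NEUTRON_SHIFT, 3)]
        unshifted_c2 = peaks[60.0]
        assert shifted_c2 / (shifted_c2 + unshifted_c2) == pytest.approx(1 / 3)
        shifted_c4 = peaks[round(120.0 + NEUTRON_SHIFT, 3)]
        unshifted_c4 = peaks[120.0]
        assert shifted_c4 / (shifted_c4 + unshifted_c4) == pytest.approx(2 / 3)

    def test_invalid_isotope_index_rejected(self):
        parent = Spectrum(mz=[90.0], intensity=[100.0], precursor_mz=181.07)
        with pytest.raises(ValueError):
            predict_isotopologue_spectrum(parent, None, n=3)


class TestInDataCleanSpectrum:
    def _run(self, scans_spec):
        ms1 = Spectrum(mz=[300.0], intensity=[1e6], precursor_rt=100.0, ms_level=1)
        ms2 = []
        for mz, rt, frag in scans_spec:
            ms2.append(Spectrum(mz=frag, intensity=[100.0] * len(frag),
                                precursor_mz=mz, precursor_rt=rt, ms_level=2,
                                isolation_low=mz - 0.75, isolation_high=mz + 0.75))
        return RunData(ms1_scans=[ms1], ms2_scans=ms2)

    def test_clean_scan_nearby_returned(self):
        run = self._run([(300.0, 105.0, [80.0, 90.0])])
        cand = find_in_data_clean_spectrum(300.0, run, rt=100.0)
        assert cand is not None and cand.provenance == "II"

    def test_nearer_of_two_clean_scans_wins(self):
        run = self._run([
            (300.0, 104.0, [80.0]),
            (300.0, 109.0, [90.0]),
        ])
        cand = find_in_data_clean_spectrum(300.0, run, rt=100.0)
        assert cand.spectrum.mz[0] == pytest.approx(80.0)

    def test_no_match_returns_none(self):
        run = self._run([(500.0, 100.0, [80.0])])
        assert find_in_data_clean_spectrum(300.0, run, rt=100.0) is None


def _library_with(tmp_path, specs):
    records = [
        LibraryRecord(
            record_id=i + 1, compound_name=f"c{i}", formula=f, inchikey=f"K{i}",
            precursor_mz=p, adduct="[M+H]+", polarity="positive",
            collision_energy="30", instrument_type="QTOF",
            spectrum=Spectrum(mz=mz, intensity=inten, precursor_mz=p),
        )
        for i, (p, f, mz, inten) in enumerate(specs)
    ]
    return SpectralLibrary.create(tmp_path / "cand.sqlite", records)


class TestLibraryCandidate:
    def test_single_match_returned_regardless_of_similarity(self, tmp_path):
        lib = _library_with(tmp_path, [(250.0, "C10H20O5", [66.0], [100.0])])
        spec0 = Spectrum(mz=[100.0], intensity=[100.0], precursor_mz=250.0)
        cand = select_library_candidate(250.0, lib, spec0)
        assert cand is not None and cand.provenance == "III"

    def test_highest_similarity_record_selected(self, tmp_path):
        spec0 = Spectrum(mz=[100.0, 120.0, 140.0, 160.0], intensity=[100.0] * 4,
                         precursor_mz=250.0)
        lib = _library_with(tmp_path, [
            (250.0, "C10H20O5", [100.0, 120.0, 140.0], [100.0, 90.0, 80.0]),
            (250.0, "C9H16NO5", [60.0, 70.0], [100.0, 50.0]),
        ])
        cand = select_library_candidate(250.0, lib, spec0)
        assert cand.spectrum.mz[0] == pytest.approx(100.0)

    def test_no_precursor_match_returns_none(self, tmp_path):
        lib = _library_with(tmp_path, [(400.0, "C20H30O6", [66.0], [100.0])])
        spec0 = Spectrum(mz=[100.0], intensity=[100.0], precursor_mz=250.0)
        assert select_library_candidate(250.0, lib, spec0) is None


class TestPenalty:
    def test_endpoints(self):
        assert penalty_from_similarity(1.0) == 0.0
        assert penalty_from_similarity(0.0) == 10.0

    def test_monotone_decreasing_in_similarity(self):
        sims = np.linspace(0, 1, 11)
        pens = [penalty_from_similarity(s) for s in sims]
        assert all(a >= b for a, b in zip(pens, pens[1:]))
        assert all(0.0 <= p <= 10.0 for p in pens)


class TestUnknownPrediction:
    def test_transformation_neighbor_spectrum_chosen(self, tmp_path):
        # unknown ion: [M+H]+ of C6H12O6; library holds its -H2O neighbor
        # C6H10O5 whose cleaned spectrum overlaps spectrum0
        neighbor_frag = [60.021, 85.029, 127.039]
        lib = _library_with(tmp_path, [
            (163.0601, "C6H10O5", neighbor_frag, [100.0, 60.0, 90.0]),
        ])
        spec0 = Spectrum(mz=[60.021, 85.029, 127.039, 150.0],
                         intensity=[80.0, 50.0, 100.0, 30.0], precursor_mz=181.0707)
        cand = predict_unknown_spectrum(181.0707, lib, spec0, ppm_tol=5.0)
        assert cand is not None
        assert cand.provenance == "IV"
        assert 0.0 <= cand.penalty < 10.0
        assert cand.penalty == pytest.approx(
            10.0 * (1.0 - cand.similarity_to_spectrum0)
        )

    def test_no_neighbor_spectra_returns_none(self, tmp_path):
        lib = _library_with(tmp_path, [(999.0, "C40H80O20", [100.0], [100.0])])
        spec0 = Spectrum(mz=[100.0], intensity=[100.0], precursor_mz=181.0707)
        assert predict_unknown_spectrum(181.0707, lib, spec0, ppm_tol=5.0) is None
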