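"""Similarity metrics, composite scoring, library search, neutral loss, export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ms2deconv import (
    SearchOptions,
    Spectrum,
    deviation_similarity,
    dot_product_similarity,
    entropy_similarity,
    export_results,
    isotope_similarity,
    matching_score,
    neutral_loss_search,
    neutral_loss_spectrum,
    score_match,
    search_library,
    theoretical_isotope_pattern,
)
from ms2deconv.library import LibraryRecord, SpectralLibrary, derive_neutral_loss_library
from ms2deconv.chem import monoisotopic_mass, PROTON_MASS


def _record(rid, precursor, mz, inten, formula="C10H20O5", inchikey=None):
    return LibraryRecord(
        record_id=rid, compound_name=f"c{rid}", formula=formula,
        inchikey=inchikey or f"KEY{rid}", precursor_mz=precursor, adduct="[M+H]+",
        polarity="positive", collision_energy="30", instrument_type="QTOF",
        spectrum=Spectrum(mz=mz, intensity=inten, precursor_mz=precursor),
    )


class TestSimilarityMetrics:
    @pytest.mark.parametrize("fn", [dot_product_similarity, entropy_similarity])
    def test_self_similarity_is_one(self, fn, simple_spectrum):
        assert fn(simple_spectrum, simple_spectrum) == pytest.approx(1.0)

    @pytest.mark.parametrize("fn", [dot_product_similarity, entropy_similarity])
    def test_disjoint_spectra_zero(self, fn):
        a = Spectrum(mz=[100.0], intensity=[1.0])
        b = Spectrum(mz=[200.0], intensity=[1.0])
        assert fn(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_partial_overlap_dot_product(self):
        a = Spectrum(mz=[100.0, 200.0], intensity=[1.0, 1.0])
        b = Spectrum(mz=[100.0], intensity=[1.0])
        assert dot_product_similarity(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_entropy_hand_computed_example(self):
        a = Spectrum(mz=[100.0], intensity=[1.0])
        b = Spectrum(mz=[100.0, 200.0], intensity=[0.5, 0.5])
        # S_a=0, S_b=ln2, merged=(0.75,0.25) -> 1-(2*S_m-ln2)/ln4
        s_m = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        want = 1 - (2 * s_m - np.log(2)) / np.log(4)
        assert entropy_similarity(a, b) == pytest.approx(want, abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_both_metrics_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = Spectrum(mz=np.sort(rng.uniform(50, 400, 6)), intensity=rng.uniform(1, 100, 6))
        b = Spectrum(mz=np.sort(rng.uniform(50, 400, 5)), intensity=rng.uniform(1, 100, 5))
        for fn in (dot_product_similarity, entropy_similarity):
            ab, ba = fn(a, b), fn(b, a)
            assert ab == pytest.approx(ba, abs=1e-9)
            assert 0.0 <= ab <= 1.0


class TestDeviationSimilarity:
    def test_zero_deviation_is_one(self):
        assert deviation_similarity(0.0, 5.0) == 1.0

    def test_deviation_equal_tolerance(self):
        assert deviation_similarity(5.0, 5.0) == pytest.approx(np.exp(-1))

    def test_large_deviation_decays_below_1e4(self):
        assert deviation_similarity(50.0, 5.0) < 1e-4

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            deviation_similarity(1.0, 0.0)


class TestIsotopeSimilarity:
    def test_observed_equals_theoretical_gives_one(self):
        theo = theoretical_isotope_pattern("C10H20O5")
        assert isotope_similarity(theo, "C10H20O5") == pytest.approx(1.0)

    def test_zero_observed_for_carbon_rich_formula_near_zero(self):
        assert isotope_similarity((0.0, 0.0), "C30H50O10") == pytest.approx(0.0, abs=1e-9)

    def test_halved_m1_matches_hand_formula(self):
        t1, t2 = theoretical_isotope_pattern("C10H22O3")
        got = isotope_similarity((t1 / 2, t2), "C10H22O3")
        assert got == pytest.approx(1.0 - (t1 / 2) / (t1 + t2))

    def test_missing_pattern_scores_zero(self):
        assert isotope_similarity(None, "C10H20O5") == 0.0


class TestMatchingScore:
    def test_perfect_components_score_100_with_and_without_rt(self):
        assert matching_score(1.0, 1.0, 1.0, 1.0) == pytest.approx(100.0)
        assert matching_score(1.0, 1.0, None, 1.0) == pytest.approx(100.0)

    def test_zero_components_score_zero(self):
        assert matching_score(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_hand_computed_example(self):
        got = matching_score(0.8, 0.9, 0.7, 0.5)
        assert got == pytest.approx((0.8 + 0.9 + 0.7 + 0.25) / 3.5 * 100)

    def test_monotone_in_each_component(self):
        base = matching_score(0.5, 0.5, 0.5, 0.5)
        assert matching_score(0.6, 0.5, 0.5, 0.5) > base
        assert matching_score(0.5, 0.6, 0.5, 0.5) > base
        assert matching_score(0.5, 0.5, 0.6, 0.5) > base
        assert matching_score(0.5, 0.5, 0.5, 0.6) > base

    def test_out_of_range_component_rejected(self):
        with pytest.raises(ValueError):
            matching_score(1.2, 0.5, None, 0.5)


class TestSearchLibrary:
    @pytest.fixture
    def small_lib(self, tmp_path):
        return SpectralLibrary.create(tmp_path / "s.sqlite", [
            _record(1, 250.0, [100.0, 150.0, 200.0], [100.0, 60.0, 30.0]),
            _record(2, 250.0, [80.0, 110.0], [100.0, 40.0]),
            _record(3, 400.0, [210.0], [100.0]),
        ])

    def test_self_match_ranks_first_with_score_100(self, small_lib):
        rec = small_lib.get(1)
        query = Spectrum(mz=rec.spectrum.mz, intensity=rec.spectrum.intensity,
                         precursor_mz=250.0, source_id="q")
        theo = theoretical_isotope_pattern(rec.formula)
        hits = search_library(query, small_lib, SearchOptions(), observed_isotope=theo)
        assert hits[0].record.record_id == 1
        assert hits[0].matching_score == pytest.approx(100.0)

    def test_fragment_owner_outranks_isobar(self, small_lib):
        query = Spectrum(mz=[100.0, 150.0], intensity=[100.0, 60.0],
                         precursor_mz=250.0, source_id="q")
        hits = search_library(query, small_lib, SearchOptions())
        assert hits[0].record.record_id == 1
        assert hits[0].matching_score > hits[1].matching_score

    def test_no_precursor_match_empty(self, small_lib):
        query = Spectrum(mz=[100.0], intensity=[1.0], precursor_mz=333.0)
        assert search_library(query, small_lib, SearchOptions()) == []

    def test_ranking_invariant_to_insertion_order(self, tmp_path):
        query = Spectrum(mz=[100.0, 150.0], intensity=[100.0, 60.0],
                         precursor_mz=250.0, source_id="q")
        recs = [
            _record(1, 250.0, [100.0, 150.0], [100.0, 60.0]),
            _record(2, 250.0, [100.0], [100.0]),
            _record(3, 250.0, [150.0], [100.0]),
        ]
        lib_a = SpectralLibrary.create(tmp_path / "o1.sqlite", recs)
        lib_b = SpectralLibrary.create(tmp_path / "o2.sqlite", list(reversed(recs)))
        ids_a = [h.record.record_id for h in search_library(query, lib_a, SearchOptions())]
        ids_b = [h.record.record_id for h in search_library(query, lib_b, SearchOptions())]
        assert ids_a == ids_b

    def test_score_match_reproduces_composite_formula(self, small_lib):
        rec = small_lib.get(1)
        query = Spectrum(mz=[100.0, 150.0], intensity=[100.0, 50.0],
                         precursor_mz=250.0 * (1 + 2e-6), precursor_rt=120.0,
                         source_id="q")
        opts = SearchOptions(rt_enabled=True, rt_tol=30.0)
        m = score_match(query, rec, opts, observed_isotope=(0.1, 0.01), record_rt=110.0)
        want = (m.ms2_similarity + m.ms1_similarity + m.rt_similarity
                + 0.5 * m.isotope_similarity) / 3.5 * 100.0
        assert m.matching_score == pytest.approx(want, abs=1e-9)


class TestNeutralLoss:
    def test_mirror_transform(self):
        s = Spectrum(mz=[100.0, 250.0], intensity=[80.0, 100.0], precursor_mz=300.0)
        nl = neutral_loss_spectrum(s)
        assert list(np.round(nl.mz, 6)) == [50.0, 200.0]
        assert list(nl.intensity) == [100.0, 80.0]

    def test_double_transform_is_involution(self):
        s = Spectrum(mz=[100.0, 250.0], intensity=[80.0, 100.0], precursor_mz=300.0)
        back = neutral_loss_spectrum(neutral_loss_spectrum(s))
        np.testing.assert_allclose(np.sort(back.mz), np.sort(s.mz))

    def test_fragment_at_precursor_dropped(self):
        s = Spectrum(mz=[300.0], intensity=[100.0], precursor_mz=300.0)
        assert len(neutral_loss_spectrum(s)) == 0

    def test_no_precursor_errors(self):
        s = Spectrum(mz=[100.0], intensity=[1.0])
        with pytest.raises(ValueError):
            neutral_loss_spectrum(s)

    @pytest.fixture
    def nl_setup(self, tmp_path):
        # compound X = glucose-like C6H12O6, fragments expressed as neutral
        # losses from its own precursor
        neutral = monoisotopic_mass("C6H12O6")
        precursor = neutral + PROTON_MASS
        lib = SpectralLibrary.create(tmp_path / "x.sqlite", [
            _record(1, precursor, [precursor - 18.0106, precursor - 46.0055],
                    [100.0, 60.0], formula="C6H12O6", inchikey="XKEY"),
        ])
        nl_lib = derive_neutral_loss_library(lib, tmp_path / "x_nl.sqlite")
        return lib, nl_lib, precursor

    def test_shifted_precursor_found_via_neutral_loss(self, nl_setup):
        _, nl_lib, precursor = nl_setup
        # query: X + CH2 (methylated analogue); same neutral losses
        q_prec = precursor + monoisotopic_mass("CH2")
        query = Spectrum(
            mz=[q_prec - 18.0106, q_prec - 46.0055], intensity=[100.0, 60.0],
            precursor_mz=q_prec, source_id="q",
        )
        hits = neutral_loss_search(query, nl_lib, options=SearchOptions(ppm_tol=5.0),
                                   force=True)
        assert hits
        assert hits[0].record.inchikey == "XKEY"
        assert hits[0].match_kind == "neutral_loss"
        assert hits[0].ms2_similarity == pytest.approx(1.0)

    def test_good_standard_score_skips_fallback(self, nl_setup):
        _, nl_lib, precursor = nl_setup
        query = Spectrum(mz=[100.0], intensity=[1.0], precursor_mz=precursor + 14.0157,
                         source_id="q")
        hits = neutral_loss_search(query, nl_lib, options=SearchOptions(),
                                   best_standard_score=85.0)
        assert hits == []


class TestExport:
    def _match(self, rid, score, inchikey, qid="q1"):
        from ms2deconv.search import MatchResult

        rec = _record(rid, 250.0, [100.0], [100.0], inchikey=inchikey)
        return MatchResult(query_id=qid, record=rec, ms2_similarity=score / 100,
                           ms1_similarity=1.0, rt_similarity=None,
                           isotope_similarity=0.0, matching_score=score)

    def test_duplicate_inchikey_keeps_highest_score(self, tmp_path):
        df = export_results(
            [self._match(1, 90.0, "SAME"), self._match(2, 70.0, "SAME")],
            top_n=5, path=tmp_path / "r.csv",
        )
        assert len(df) == 1
        assert df.iloc[0]["matching_score"] == 90.0

    def test_top_n_truncation_descending(self, tmp_path):
        matches = [self._match(i, 50.0 + i, f"K{i}") for i in range(5)]
        df = export_results(matches, top_n=3, path=tmp_path / "r.csv")
        assert len(df) == 3
        assert list(df["matching_score"]) == sorted(df["matching_score"], reverse=True)

    def test_empty_matches_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        df = export_results([], top_n=3, path=path)
        assert len(df) == 0
        header = path.read_text().splitlines()[0]
        assert "inchikey" in header and "matching_score" in header
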