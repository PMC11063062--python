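"""SWATH-DIA pseudo-MS2 reconstruction."""

import numpy as np
import pytest

from ms2deconv import MS1Feature, Spectrum
from ms2deconv.dia import (
    EIC,
    DiaOptions,
    deconvolve_dia,
    decompose_eics,
    detect_and_cluster_eic_peaks,
    extract_ms2_eics,
    resolve_swath_window,
)
from ms2deconv.simulate import make_swath_windows, simulate_swath_run


def _gauss_eic(mz, apex, sigma=4.0, height=1e5, rts=None, widx=0):
    rts = np.arange(0.0, 120.0, 1.5) if rts is None else rts
    return EIC(fragment_mz=mz, rt=rts,
               intensity=height * np.exp(-0.5 * ((rts - apex) / sigma) ** 2),
               window_index=widx)


def _pair_sharing_window(library, manifest, windows):
    def window_of(mz):
        c = [(abs(mz - (r["lower_mz"] + r["upper_mz"]) / 2), int(r["index"]))
             for _, r in windows.iterrows() if r["lower_mz"] <= mz <= r["upper_mz"]]
        return min(c)[1]

    by_window = {}
    for rid in manifest[manifest["role"] == "primary"]["record_id"]:
        rec = library.get(int(rid))
        by_window.setdefault(window_of(rec.precursor_mz), []).append(int(rid))
    pair = next(ids[:2] for ids in by_window.values() if len(ids) >= 2)
    singles = [ids[0] for w, ids in by_window.items() if ids[0] not in pair][:2]
    return pair, singles


class TestWindowResolution:
    def test_overlap_resolves_to_nearest_center(self):
        scans = [
            Spectrum(mz=[50.0], intensity=[1.0], precursor_rt=0.0, ms_level=2,
                     isolation_low=100.0, isolation_high=151.0, window_index=0),
            Spectrum(mz=[50.0], intensity=[1.0], precursor_rt=0.0, ms_level=2,
                     isolation_low=149.0, isolation_high=200.0, window_index=1),
        ]
        # 150.2 sits in both windows; window 1's center (174.5) is farther
        # than window 0's (125.5)... check the arithmetic explicitly
        assert resolve_swath_window(150.2, scans) == 1
        assert resolve_swath_window(125.0, scans) == 0

    def test_outside_all_windows_raises(self):
        scans = [
            Spectrum(mz=[50.0], intensity=[1.0], precursor_rt=0.0, ms_level=2,
                     isolation_low=100.0, isolation_high=150.0, window_index=0),
        ]
        with pytest.raises(ValueError, match="outside"):
            resolve_swath_window(500.0, scans)


class TestClustering:
    def test_two_apexes_two_clusters(self):
        feature = MS1Feature(mz_med=300.0, rt_med=50.0, feature_id="F")
        eics = [
            _gauss_eic(80.0, 50.0), _gauss_eic(95.0, 50.0),
            _gauss_eic(120.0, 70.0), _gauss_eic(131.0, 70.0),
        ]
        clusters = detect_and_cluster_eic_peaks(eics, feature, rt_tol=5.0)
        assert len(clusters) == 2
        apexes = sorted(c.apex_rt for c in clusters)
        assert apexes[0] == pytest.approx(50.0, abs=2.0)
        assert apexes[1] == pytest.approx(70.0, abs=2.0)

    def test_flat_noise_eic_discarded(self):
        feature = MS1Feature(mz_med=300.0, rt_med=50.0, feature_id="F")
        rng = np.random.default_rng(0)
        rts = np.arange(0.0, 120.0, 1.5)
        flat = EIC(fragment_mz=70.0, rt=rts, intensity=rng.uniform(90, 110, len(rts)))
        eics = [_gauss_eic(80.0, 50.0, height=1e5), flat]
        clusters = detect_and_cluster_eic_peaks(eics, feature, rt_tol=5.0)
        member_eics = {m.eic_index for c in clusters for m in c.members}
        assert 1 not in member_eics

    def test_shared_apex_single_cluster_model_is_most_intense(self):
        feature = MS1Feature(mz_med=300.0, rt_med=50.0, feature_id="F")
        eics = [
            _gauss_eic(80.0, 50.0, height=1e4),
            _gauss_eic(95.0, 50.0, height=1e6),
            _gauss_eic(110.0, 50.0, height=1e5),
        ]
        clusters = detect_and_cluster_eic_peaks(eics, feature, rt_tol=5.0)
        assert len(clusters) == 1
        model = clusters[0].members[clusters[0].model_peak]
        assert model.eic_index == 1


class TestDecomposition:
    def test_eic_equal_to_model_gets_unit_weight(self):
        feature = MS1Feature(mz_med=300.0, rt_med=50.0, feature_id="F")
        e1 = _gauss_eic(80.0, 50.0, height=1e5)
        e2 = _gauss_eic(95.0, 80.0, height=1e5)
        clusters = detect_and_cluster_eic_peaks([e1, e2], feature, rt_tol=5.0)
        weights, _ = decompose_eics([e1, e2], clusters)
        # each EIC should load only on its own cluster
        for i in range(2):
            own = np.argmax(weights[i])
            others = np.delete(weights[i], own)
            assert weights[i, own] > 0
            np.testing.assert_allclose(others, 0.0, atol=1e-6)

    def test_synthetic_half_half_mixture(self):
        rts = np.arange(0.0, 120.0, 1.5)
        m1 = _gauss_eic(80.0, 40.0, height=1e5, rts=rts)
        m2 = _gauss_eic(95.0, 70.0, height=1e5, rts=rts)
        mix = EIC(fragment_mz=110.0, rt=rts,
                  intensity=0.5 * m1.intensity + 0.5 * m2.intensity)
        feature = MS1Feature(mz_med=300.0, rt_med=40.0, feature_id="F")
        clusters = detect_and_cluster_eic_peaks([m1, m2], feature, rt_tol=5.0)
        weights, _ = decompose_eics([m1, m2, mix], clusters)
        by_apex = np.argsort([c.apex_rt for c in clusters])
        w_mix = weights[2][by_apex]
        assert w_mix[0] == pytest.approx(0.5, rel=0.05)
        assert w_mix[1] == pytest.approx(0.5, rel=0.05)

    def test_all_zero_eic_gets_zero_weights(self):
        rts = np.arange(0.0, 120.0, 1.5)
        m1 = _gauss_eic(80.0, 40.0, rts=rts)
        zero = EIC(fragment_mz=99.0, rt=rts, intensity=np.zeros(len(rts)))
        feature = MS1Feature(mz_med=300.0, rt_med=40.0, feature_id="F")
        clusters = detect_and_cluster_eic_peaks([m1], feature, rt_tol=5.0)
        weights, _ = decompose_eics([m1, zero], clusters)
        np.testing.assert_allclose(weights[1], 0.0)


@pytest.fixture(scope="module")
def swath_fixture(tmp_path_factory):
    from ms2deconv.simulate import make_synthetic_library

    path = tmp_path_factory.mktemp("swath") / "lib.sqlite"
    library, manifest = make_synthetic_library(path, n_compounds=30, seed=7)
    windows = make_swath_windows(100, 650, 10)
    pair, singles = _pair_sharing_window(library, manifest, windows)
    ids = pair + singles
    run, features, truth = simulate_swath_run(
        library, windows, ids, co_elution_pairs=[(pair[0], pair[1], 20.0)],
        seed=3, noise_cv=0.0,
    )
    return run, features, truth


class TestEndToEnd:
    def _prec_recall(self, spec, true_frags):
        got = set(np.round(spec.mz, 2))
        want = set(np.round(true_frags, 2))
        tp = len(got & want)
        return (tp / len(got) if got else 0.0, tp / len(want))

    def test_noiseless_fragment_sets_recovered_exactly(self, swath_fixture):
        run, features, truth = swath_fixture
        for feat in features:
            spec, flagged = deconvolve_dia(feat, run, DiaOptions())
            assert not flagged
            precision, recall = self._prec_recall(spec, truth.dia_fragments[feat.feature_id])
            assert precision == 1.0
            assert recall == 1.0

    def test_coeluting_pair_fragments_not_mixed(self, swath_fixture):
        run, features, truth = swath_fixture
        # the first two features share a window, apexes 20 s apart
        f_a, f_b = features[0], features[1]
        spec_a, _ = deconvolve_dia(f_a, run, DiaOptions())
        frags_b = set(np.round(truth.dia_fragments[f_b.feature_id], 2))
        assert not (set(np.round(spec_a.mz, 2)) & frags_b)

    def test_feature_without_coeluting_fragments_flagged_empty(self, swath_fixture):
        run, features, _ = swath_fixture
        lonely = MS1Feature(mz_med=features[0].mz_med, rt_med=900.0,
                            rt_min=890.0, rt_max=910.0, feature_id="LONELY")
        spec, flagged = deconvolve_dia(lonely, run, DiaOptions())
        assert flagged and len(spec) == 0
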