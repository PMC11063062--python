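"""Reconstruct pseudo-MS2 spectra from a SWATH-DIA run.

Two compounds share one SWATH window with elution apexes 20 s apart; their
fragment chromatograms are clustered by co-elution and decomposed so each
feature recovers exactly its own fragment set.
"""

from tempfile import TemporaryDirectory
from pathlib import Path

import numpy as np

from ms2deconv.dia import DiaOptions, deconvolve_dia
from ms2deconv.simulate import make_swath_windows, make_synthetic_library, simulate_swath_run

with TemporaryDirectory() as tmp:
    library, manifest = make_synthetic_library(Path(tmp) / "lib.sqlite", n_compounds=30, seed=7)
    windows = make_swath_windows(100, 650, n_windows=10)

    def window_of(mz):
        hits = [(abs(mz - (r["lower_mz"] + r["upper_mz"]) / 2), int(r["index"]))
                for _, r in windows.iterrows() if r["lower_mz"] <= mz <= r["upper_mz"]]
        return min(hits)[1]

    by_window = {}
    for rid in manifest[manifest["role"] == "primary"]["record_id"]:
        rec = library.get(int(rid))
        by_window.setdefault(window_of(rec.precursor_mz), []).append(int(rid))
    pair = next(ids[:2] for ids in by_window.values() if len(ids) >= 2)

    run, features, truth = simulate_swath_run(
        library, windows, pair, co_elution_pairs=[(pair[0], pair[1], 20.0)], seed=3,
    )
    print(f"SWATH run: {len(run.ms1_scans)} MS1 scans, {len(run.ms2_scans)} windowed MS2 scans")
    for feat in features:
        spec, flagged = deconvolve_dia(feat, run, DiaOptions())
        want = set(np.round(truth.dia_fragments[feat.feature_id], 2))
        got = set(np.round(spec.mz, 2))
        tp = len(got & want)
        print(f"{feat.feature_id}: window {truth.window_of_feature[feat.feature_id]}, "
              f"{len(got)} fragments reconstructed, "
              f"precision {tp / len(got):.2f}, recall {tp / len(want):.2f}")

print("\nPrecision/recall of 1.00 means each pseudo-MS2 contains exactly the")
print("fragments of its own compound despite both sharing one SWATH window.")
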