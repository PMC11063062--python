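"""Deconvolve a chimeric DDA spectrum with the penalized elastic net.

Builds a synthetic reference library and a DDA run in which half the
features co-isolate a second compound, runs the full assignment ->
chimera-assessment -> candidate-assembly -> elastic-net pipeline, and shows
how much closer the deconvolved spectrum is to the true clean spectrum than
the raw chimera was.
"""

from tempfile import TemporaryDirectory
from pathlib import Path

from ms2deconv import deconvolve_dda, dot_product_similarity
from ms2deconv.elasticnet import DdaOptions
from ms2deconv.simulate import make_synthetic_library, simulate_dda_run

with TemporaryDirectory() as tmp:
    library, manifest = make_synthetic_library(
        Path(tmp) / "library.sqlite", n_compounds=30, seed=7,
        chimera_partner_fraction=0.7,
    )
    runs, features, truth = simulate_dda_run(
        library, manifest, n_features=8, chimera_fraction=0.5, seed=7,
    )
    reports = deconvolve_dda(features, runs[0], library, DdaOptions())

    print(f"{'feature':>8} {'status':>9} {'raw~truth':>10} {'deco~truth':>10}")
    for fid, report in reports.items():
        truth_spec = library.get(truth.feature_compounds[fid]).spectrum.normalized()
        if fid in truth.chimera and report.deconvolved:
            raw = report.solution  # noqa: F841  (solution kept for inspection)
            # rebuild the raw merged chimera for comparison
            from ms2deconv import assign_ms2_to_features, merge_coassigned_spectra

            scans = assign_ms2_to_features(runs[0], features)[fid]
            raw_spec = merge_coassigned_spectra(scans)
            sim_raw = dot_product_similarity(raw_spec, truth_spec)
            sim_deco = dot_product_similarity(report.spectrum, truth_spec)
            print(f"{fid:>8} {'chimeric':>9} {sim_raw:>10.4f} {sim_deco:>10.4f}")
        else:
            sim = dot_product_similarity(report.spectrum, truth_spec)
            print(f"{fid:>8} {'clean':>9} {'-':>10} {sim:>10.4f}")

print("\nFor chimeric features the deconvolved spectrum should match the true")
print("clean spectrum more closely (deco~truth > raw~truth, both cosine on")
print("sqrt intensities); clean features pass through the regression untouched.")
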