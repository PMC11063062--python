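"""Neutral-loss fallback search for a precursor missing from the library.

The query is a methylated analogue (+CH2) of a library compound: its
precursor matches nothing, but its neutral-loss pattern mirrors the parent
compound's, so the transformation-network-guided neutral-loss search still
proposes the right neighborhood.
"""

from tempfile import TemporaryDirectory
from pathlib import Path

from ms2deconv import Spectrum, neutral_loss_search, search_library
from ms2deconv.chem import PROTON_MASS, monoisotopic_mass
from ms2deconv.library import LibraryRecord, SpectralLibrary, derive_neutral_loss_library
from ms2deconv.search import SearchOptions

with TemporaryDirectory() as tmp:
    precursor = monoisotopic_mass("C6H12O6") + PROTON_MASS
    record = LibraryRecord(
        record_id=1, compound_name="hexose", formula="C6H12O6",
        inchikey="WQZGKKKJIJFFOK-GASJEMHNSA-N", precursor_mz=precursor,
        adduct="[M+H]+", polarity="positive", collision_energy="30",
        instrument_type="QTOF",
        spectrum=Spectrum(
            mz=[precursor - 18.0106, precursor - 46.0055],
            intensity=[100.0, 60.0], precursor_mz=precursor,
        ),
    )
    library = SpectralLibrary.create(Path(tmp) / "lib.sqlite", [record])
    nl_library = derive_neutral_loss_library(library, Path(tmp) / "lib_nl.sqlite")

    # methylated analogue: precursor shifted by CH2, same neutral losses
    q_prec = precursor + monoisotopic_mass("CH2")
    query = Spectrum(
        mz=[q_prec - 18.0106, q_prec - 46.0055], intensity=[100.0, 60.0],
        precursor_mz=q_prec, source_id="unknown-1",
    )
    options = SearchOptions(ppm_tol=5.0)
    standard = search_library(query, library, options)
    best = standard[0].matching_score if standard else 0.0
    print(f"standard search: {len(standard)} hits (best score {best:.1f})")

    nl_hits = neutral_loss_search(query, nl_library, options=options,
                                  best_standard_score=best)
    for hit in nl_hits:
        print(f"neutral-loss hit: {hit.record.compound_name} "
              f"({hit.record.formula}), score {hit.matching_score:.1f}, "
              f"kind {hit.match_kind}")

print("\nThe empty standard search (score < 10) triggers the fallback; the")
print("neutral-loss mirror identifies the +CH2 transformation neighbor.")
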