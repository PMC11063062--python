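"""Replicate consensus spectra.

Fragments observed across replicate MS2 spectra of one feature are grouped
by m/z and kept when their replicate frequency reaches a threshold; the
database-assisted option can rescue sub-threshold fragments that both appear
in at least two replicates and match a reference fragment of the precursor.
A single input spectrum passes through unchanged (up to normalization).
"""

from __future__ import annotations

import numpy as np

from .library import SpectralLibrary
from .spectrum import Spectrum, normalize_spectrum


def consensus_spectrum(
    spectra: list[Spectrum],
    mz_tol: float = 0.01,
    freq_threshold: float = 0.5,
    db_assist: bool = False,
    library: SpectralLibrary | None = None,
    precursor_mz: float = float("nan"),
    ppm_tol: float = 10.0,
) -> Spectrum:
    """Collapse replicate spectra into one consensus spectrum.

    A fragment group is kept iff its replicate frequency (count / n) reaches
    ``freq_threshold``, or — with ``db_assist`` — it occurs in at least two
    replicates and matches (within ``mz_tol``) a fragment of any library
    spectrum of the precursor.  Kept groups take the intensity-weighted mean
    m/z and the mean of the contributing replicates' normalized intensities.
    """
    if not spectra:
        raise ValueError("no replicate spectra supplied")
    if len(spectra) == 1:
        return normalize_spectrum(spectra[0])
    if db_assist and (library is None or np.isnan(precursor_mz)):
        raise ValueError("db_assist requires a library handle and precursor_mz")

    normed = [normalize_spectrum(s) for s in spectra]
    n = len(normed)

    reference_mz = np.array([])
    if db_assist:
        ref = [
            rec.spectrum.mz
            for rec in library.query_by_precursor(precursor_mz, ppm_tol)
        ]
        if ref:
            reference_mz = np.sort(np.concatenate(ref))

    all_mz = np.concatenate([s.mz for s in normed])
    all_int = np.concatenate([s.intensity for s in normed])
    all_src = np.concatenate([np.full(len(s), k) for k, s in enumerate(normed)])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_src = all_mz[order], all_int[order], all_src[order]
    groups = np.concatenate([[0], np.cumsum(np.diff(all_mz) > mz_tol)])

    keep_mz, keep_int = [], []
    for g in range(groups[-1] + 1):
        sel = groups == g
        count = len(set(all_src[sel]))
        kept = count / n >= freq_threshold
        if not kept and db_assist and count >= 2 and len(reference_mz):
            g_center = np.average(all_mz[sel], weights=np.maximum(all_int[sel], 1e-12))
            j = np.searchsorted(reference_mz, g_center)
            nearest = min(
                (abs(reference_mz[k] - g_center) for k in (j - 1, j) if 0 <= k < len(reference_mz)),
                default=np.inf,
            )
            kept = nearest <= mz_tol
        if kept:
            w = np.maximum(all_int[sel], 1e-12)
            keep_mz.append(float(np.average(all_mz[sel], weights=w)))
            # mean over contributing replicates of their normalized intensity
            keep_int.append(float(all_int[sel].sum() / count))
    if not keep_mz:
        raise ValueError("no fragment satisfied the consensus rules")
    out = normed[0].with_peaks(keep_mz, keep_int)
    return normalize_spectrum(out)
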