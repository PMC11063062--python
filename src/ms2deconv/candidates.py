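"""Candidate reference spectra for contamination ions.

Each contamination ion receives at most one candidate spectrum, resolved in
a fixed class order:

  I   — predicted spectrum of an orphan isotopologue (the ion is an M+n
        isotope peak of a heavier-intensity parent seen in the MS1 scan);
  II  — a clean MS2 spectrum of the same precursor found inside the data;
  III — the best-matching reference library spectrum;
  IV  — a transformation-network prediction for "unknown" ions, carrying a
        penalty 10·(1 − similarity to the chimeric spectrum).

Ions with no candidate are dropped from the regression with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem import predict_formula
from .chimera import ChimeraAssessment
from .library import SpectralLibrary
from .scoring import spectral_similarity
from .spectrum import RunData, Spectrum, normalize_spectrum
from .transform import build_transformation_network, clean_neighbor_spectrum

logger = logging.getLogger(__name__)

NEUTRON_SHIFT = 1.003355  # 13C − 12C mass difference, Da


@dataclass
class CandidateSpectrum:
    ion_mz: float
    spectrum: Spectrum  # normalized
    provenance: str  # "I" | "II" | "III" | "IV" | "MAIN"
    similarity_to_spectrum0: float = float("nan")
    penalty: float = 0.0

    def __post_init__(self):
        if self.provenance != "IV" and self.penalty != 0.0:
            raise ValueError("only class-IV candidates carry a penalty")
        if not (0.0 <= self.penalty <= 10.0):
            raise ValueError("penalty must lie in [0, 10]")


def penalty_from_similarity(similarity: float) -> float:
    """Linear penalty map: 0 for a perfect match, 10 for a negative one."""
    return 10.0 * (1.0 - float(np.clip(similarity, 0.0, 1.0)))


def detect_orphan_isotopologue(
    contaminant: tuple[float, float],
    ms1_scan: Spectrum,
    charge_max: int = 2,
    ppm_tol: float = 10.0,
) -> tuple[float, int, int] | None:
    """Look for a monoisotopic parent of a contaminant ion.

    Returns ``(parent_mz, n, z)`` if a centroid sits at
    ``contaminant_mz − n·1.003355/z`` (n ∈ {1, 2}, z ≤ charge_max) within ppm
    tolerance and with intensity ≥ the contaminant's; else ``None``.
    """
    c_mz, c_int = contaminant
    best = None
    for n in (1, 2):
        for z in range(1, charge_max + 1):
            target = c_mz - n * NEUTRON_SHIFT / z
            if target <= 0:
                continue
            delta = np.abs(ms1_scan.mz - target)
            k = int(np.argmin(delta)) if len(delta) else -1
            if k < 0:
                continue
            if delta[k] <= target * ppm_tol * 1e-6 and ms1_scan.intensity[k] >= c_int:
                cand = (float(ms1_scan.mz[k]), n, z)
                # prefer the closest isotope spacing (smallest n, then z)
                if best is None:
                    best = cand
    return best


def predict_isotopologue_spectrum(
    parent_spectrum: Spectrum,
    parent_formula: str | None,
    n: int,
    z: int = 1,
    contaminant_mz: float | None = None,
) -> CandidateSpectrum:
    """Predict the MS2 spectrum of an orphan isotopologue (class I).

    Each parent fragment splits into an unshifted peak and one shifted by
    n·1.003355/z.  The shifted fraction approximates the probability that the
    heavy isotope is retained in the fragment: the fragment/precursor carbon
    count ratio when formulas are known, else the fragment/precursor m/z
    ratio.
    """
    if n not in (1, 2):
        raise ValueError("isotope index n must be 1 or 2")
    if len(parent_spectrum) == 0:
        raise ValueError("parent spectrum is empty")
    from .chem import parse_formula

    n_c_parent = None
    if parent_formula:
        n_c_parent = parse_formula(parent_formula).get("C", 0) or None
    frag_forms = parent_spectrum.formulas or [None] * len(parent_spectrum)
    mz_out, int_out = [], []
    shift = n * NEUTRON_SHIFT / z
    for mz, inten, form in zip(parent_spectrum.mz, parent_spectrum.intensity, frag_forms):
        if n_c_parent and form:
            frac = parse_formula(form).get("C", 0) / n_c_parent
        else:
            frac = mz / parent_spectrum.precursor_mz if parent_spectrum.precursor_mz > 0 else 1.0
        frac = float(np.clip(frac, 0.0, 1.0))
        if frac < 1.0:
            mz_out.append(mz)
            int_out.append(inten * (1.0 - frac))
        if frac > 0.0:
            mz_out.append(mz + shift)
            int_out.append(inten * frac)
    spec = normalize_spectrum(parent_spectrum.with_peaks(mz_out, int_out))
    ion_mz = contaminant_mz if contaminant_mz is not None else parent_spectrum.precursor_mz + shift
    return CandidateSpectrum(ion_mz=float(ion_mz), spectrum=spec, provenance="I")


def find_in_data_clean_spectrum(
    contaminant_mz: float,
    run: RunData,
    rt: float,
    ppm_tol: float = 10.0,
    intensity_threshold: float = 1e4,
    rt_cap: float | None = None,
) -> CandidateSpectrum | None:
    """Class II: a clean MS2 scan of the contaminant elsewhere in the run.

    The two precursor-matching MS2 scans nearest in RT are assessed; the
    nearer clean one wins.  ``rt_cap`` bounds how far away the scan may sit.
    """
    from .chimera import assess_chimeric
    from .spectrum import MS1Feature

    tol = contaminant_mz * ppm_tol * 1e-6
    matches = [
        s for s in run.ms2_scans
        if abs(s.precursor_mz - contaminant_mz) <= tol and len(s) > 0
    ]
    if rt_cap is not None:
        matches = [s for s in matches if abs(s.precursor_rt - rt) <= rt_cap]
    matches.sort(key=lambda s: abs(s.precursor_rt - rt))
    pseudo = MS1Feature(mz_med=contaminant_mz, rt_med=rt)
    for scan in matches[:2]:
        if not run.ms1_scans:
            break
        assessment = assess_chimeric(pseudo, scan, run, intensity_threshold)
        if not assessment.is_chimeric:
            return CandidateSpectrum(
                ion_mz=contaminant_mz, spectrum=normalize_spectrum(scan), provenance="II",
            )
    return None


def select_library_candidate(
    contaminant_mz: float,
    library: SpectralLibrary,
    spectrum0: Spectrum,
    ppm_tol: float = 10.0,
    similarity: str = "dot_product",
    mz_tol: float = 0.01,
    polarity: str | None = None,
) -> CandidateSpectrum | None:
    """Class III: the precursor-matching library spectrum most similar to the
    chimeric spectrum.  Ties break to the lower record_id."""
    records = library.query_by_precursor(contaminant_mz, ppm_tol, polarity)
    best = None
    best_key = None
    for rec in records:  # already ordered by record_id
        sim = spectral_similarity(rec.spectrum, spectrum0, method=similarity, mz_tol=mz_tol)
        key = (-sim, rec.record_id)
        if best_key is None or key < best_key:
            best, best_key = (rec, sim), key
    if best is None:
        return None
    rec, sim = best
    return CandidateSpectrum(
        ion_mz=contaminant_mz, spectrum=normalize_spectrum(rec.spectrum),
        provenance="III", similarity_to_spectrum0=sim,
    )


def predict_unknown_spectrum(
    contaminant_mz: float,
    library: SpectralLibrary,
    spectrum0: Spectrum,
    polarity: str = "positive",
    ppm_tol: float = 10.0,
    similarity: str = "dot_product",
    mz_tol: float = 0.01,
) -> CandidateSpectrum | None:
    """Class IV: transformation-network prediction for an unknown ion.

    The best formula is predicted for the ion, a one-hop network built around
    it, neighbor spectra fetched by formula from the library, cleaned of
    fragments that cannot fit the unknown's formula, and the spectrum most
    similar to the chimeric spectrum returned with penalty 10·(1 − sim).
    """
    formulas = predict_formula(contaminant_mz, polarity=polarity, ppm_tol=ppm_tol)
    if not formulas:
        return None
    top = formulas[0]
    network = build_transformation_network(top.formula)
    best = None
    best_key = None
    for neighbor in network.neighbors:
        for rec in library.query_by_formula(neighbor.formula):
            cleaned = clean_neighbor_spectrum(rec.spectrum, top.formula)
            if len(cleaned) == 0:
                continue
            sim = spectral_similarity(cleaned, spectrum0, method=similarity, mz_tol=mz_tol)
            key = (-sim, rec.record_id)
            if best_key is None or key < best_key:
                best, best_key = (cleaned, sim), key
    if best is None:
        return None
    cleaned, sim = best
    return CandidateSpectrum(
        ion_mz=contaminant_mz, spectrum=cleaned, provenance="IV",
        similarity_to_spectrum0=sim, penalty=penalty_from_similarity(sim),
    )


def assemble_candidates(
    assessment: ChimeraAssessment,
    run: RunData,
    library: SpectralLibrary | None,
    ppm_tol: float = 10.0,
    similarity: str = "dot_product",
    mz_tol: float = 0.01,
    charge_max: int = 2,
    rt_tol: float = 15.0,
    intensity_threshold: float = 1e4,
) -> list[CandidateSpectrum]:
    """Resolve one candidate per contamination ion in class order I → IV."""
    spectrum0 = assessment.spectrum0
    ms1 = run.nearest_ms1(spectrum0.precursor_rt)
    out = []
    for ion in assessment.contamination_ions:
        cand = None
        parent = detect_orphan_isotopologue(ion, ms1, charge_max, ppm_tol)
        if parent is not None:
            parent_mz, n, z = parent
            parent_spec = _parent_ms2(parent_mz, run, spectrum0.precursor_rt, ppm_tol)
            if parent_spec is not None:
                parent_formula = None
                if library is not None:
                    recs = library.query_by_precursor(parent_mz, ppm_tol)
                    if recs:
                        parent_formula = recs[0].formula
                cand = predict_isotopologue_spectrum(
                    parent_spec, parent_formula, n, z, contaminant_mz=ion[0]
                )
        if cand is None:
            cand = find_in_data_clean_spectrum(
                ion[0], run, spectrum0.precursor_rt, ppm_tol,
                intensity_threshold, rt_cap=2 * rt_tol,
            )
        if cand is None and library is not None:
            cand = select_library_candidate(
                ion[0], library, spectrum0, ppm_tol, similarity, mz_tol
            )
        if cand is None and library is not None:
            cand = predict_unknown_spectrum(
                ion[0], library, spectrum0, spectrum0.polarity, ppm_tol, similarity, mz_tol
            )
        if cand is None:
            logger.warning(
                "contamination ion %.4f: no candidate spectrum (classes I-IV); "
                "dropped from the regression", ion[0],
            )
        else:
            out.append(cand)
    return out


def _parent_ms2(parent_mz: float, run: RunData, rt: float, ppm_tol: float) -> Spectrum | None:
    """Nearest-in-RT MS2 scan whose precursor matches the parent ion."""
    tol = parent_mz * ppm_tol * 1e-6
    matches = [s for s in run.ms2_scans if abs(s.precursor_mz - parent_mz) <= tol and len(s)]
    if not matches:
        return None
    return min(matches, key=lambda s: abs(s.precursor_rt - rt))
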