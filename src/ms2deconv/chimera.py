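"""Assigning MS2 scans to MS1 features and flagging chimeric spectra.

A DDA MS2 spectrum is "chimeric" when the nearest MS1 scan shows more than
one centroid inside the quadrupole isolation window with intensity above the
acquisition threshold.  The centroid closest in m/z to the feature is the
"main ion"; the remaining in-window centroids are "contamination ions" whose
fragments the elastic-net deconvolution later removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_ISOLATION_HALF_WIDTH
from .spectrum import MS1Feature, RunData, Spectrum, merge_fragment_lists, normalize_spectrum

logger = logging.getLogger(__name__)

#: centroids closer than this (Th) to the main ion are the same peak
MAIN_ION_MERGE_TOL = 1e-3


@dataclass
class ChimeraAssessment:
    feature: MS1Feature
    spectrum0: Spectrum
    main_ion: tuple[float, float]  # (mz, intensity) in the nearest MS1 scan
    contamination_ions: list[tuple[float, float]]
    is_chimeric: bool
    isolation_low: float
    isolation_high: float
    nearest_ms1_rt: float
    no_ms1_centroid: bool = False


def assign_ms2_to_features(
    run: RunData,
    features: list[MS1Feature],
    ppm_tol: float = 10.0,
    rt_tol: float = 15.0,
) -> dict[str, list[Spectrum]]:
    """Map each feature to the MS2 scans whose precursor falls inside its
    m/z and RT ranges.  A scan may serve several features; unassigned scans
    are reported in a log summary."""
    if not features:
        raise ValueError("no features supplied")
    assignment: dict[str, list[Spectrum]] = {f.feature_id: [] for f in features}
    used = np.zeros(len(run.ms2_scans), dtype=bool)
    for feat in features:
        mz_lo, mz_hi = feat.mz_range(ppm_tol)
        rt_lo, rt_hi = feat.rt_range(rt_tol)
        for k, scan in enumerate(run.ms2_scans):
            if mz_lo <= scan.precursor_mz <= mz_hi and rt_lo <= scan.precursor_rt <= rt_hi:
                assignment[feat.feature_id].append(scan)
                used[k] = True
    n_unused = int((~used).sum())
    if n_unused:
        logger.info("%d of %d MS2 scans not assigned to any feature", n_unused, len(used))
    return assignment


def merge_coassigned_spectra(spectra: list[Spectrum], mz_tol: float = 0.01) -> Spectrum:
    """Merge several MS2 scans of one feature into a single spectrum.

    Fragments are grouped at ``mz_tol``; each group takes the
    intensity-weighted mean m/z and the summed intensity (the weighted merge
    strategy familiar from MZmine).  The result is normalized.
    """
    if not spectra:
        raise ValueError("no spectra to merge")
    if len(spectra) == 1:
        return normalize_spectrum(spectra[0])
    g_mz, g_int, _ = merge_fragment_lists(spectra, mz_tol)
    merged = spectra[0].with_peaks(g_mz, g_int, None)
    return normalize_spectrum(merged)


def measure_observed_isotope_pattern(
    feature: MS1Feature,
    run: RunData,
    ppm_tol: float = 10.0,
) -> tuple[float, float] | None:
    """Measure the M+1 and M+2 abundances (fractions of M) of a feature from
    the MS1 scan nearest its RT apex.  Returns ``None`` when the
    monoisotopic centroid cannot be found."""
    ms1 = run.nearest_ms1(feature.rt_med)
    tol = feature.mz_med * ppm_tol * 1e-6

    def centroid_intensity(target: float) -> float:
        if len(ms1.mz) == 0:
            return 0.0
        k = int(np.argmin(np.abs(ms1.mz - target)))
        return float(ms1.intensity[k]) if abs(ms1.mz[k] - target) <= tol else 0.0

    mono = centroid_intensity(feature.mz_med)
    if mono <= 0:
        return None
    m1 = centroid_intensity(feature.mz_med + 1.003355)
    m2 = centroid_intensity(feature.mz_med + 2 * 1.003355)
    return m1 / mono, m2 / mono


def assess_chimeric(
    feature: MS1Feature,
    spectrum0: Spectrum,
    run: RunData,
    intensity_threshold: float = 1e4,
    window_override: tuple[float, float] | None = None,
    relative_threshold: bool = False,
) -> ChimeraAssessment:
    """Classify a feature's MS2 spectrum as clean or chimeric.

    Uses the single MS1 scan nearest in RT to ``spectrum0`` (ties break to
    the earlier scan).  Window priority: explicit override, then the scan's
    recorded isolation bounds, then a ±0.75 Th fallback centred on mz_med.
    With ``relative_threshold`` the acquisition threshold is interpreted as a
    fraction of the main-ion intensity instead of an absolute abundance.
    """
    ms1 = run.nearest_ms1(spectrum0.precursor_rt)
    if window_override is not None:
        lo, hi = window_override
    elif not np.isnan(spectrum0.isolation_low):
        lo, hi = spectrum0.isolation_low, spectrum0.isolation_high
    else:
        lo = feature.mz_med - DEFAULT_ISOLATION_HALF_WIDTH
        hi = feature.mz_med + DEFAULT_ISOLATION_HALF_WIDTH
    in_window = (ms1.mz >= lo) & (ms1.mz <= hi)
    if not in_window.any():
        logger.warning(
            "feature %s: no MS1 centroid inside isolation window [%.4f, %.4f]",
            feature.feature_id, lo, hi,
        )
        return ChimeraAssessment(
            feature=feature, spectrum0=spectrum0,
            main_ion=(feature.mz_med, feature.intensity), contamination_ions=[],
            is_chimeric=False, isolation_low=lo, isolation_high=hi,
            nearest_ms1_rt=ms1.precursor_rt, no_ms1_centroid=True,
        )
    w_mz = ms1.mz[in_window]
    w_int = ms1.intensity[in_window]
    main_idx = int(np.argmin(np.abs(w_mz - feature.mz_med)))
    main_ion = (float(w_mz[main_idx]), float(w_int[main_idx]))
    threshold = intensity_threshold * main_ion[1] if relative_threshold else intensity_threshold
    contaminants = [
        (float(m), float(i))
        for k, (m, i) in enumerate(zip(w_mz, w_int))
        if k != main_idx and abs(m - main_ion[0]) > MAIN_ION_MERGE_TOL and i > threshold
    ]
    return ChimeraAssessment(
        feature=feature, spectrum0=spectrum0, main_ion=main_ion,
        contamination_ions=contaminants, is_chimeric=bool(contaminants),
        isolation_low=lo, isolation_high=hi, nearest_ms1_rt=ms1.precursor_rt,
    )
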