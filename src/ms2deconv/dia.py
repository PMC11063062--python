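"""SWATH-DIA pseudo-MS2 reconstruction.

For a target MS1 feature, fragment-level extracted ion chromatograms (EICs)
are pulled from the SWATH window covering the precursor, chromatographic
peaks are detected per EIC, peaks are clustered by apex proximity and shape
correlation, one model peak is chosen per cluster, every EIC is decomposed as
a non-negative combination of the model-peak traces, and the cluster whose
apex co-elutes with the feature is exported as the pseudo-MS2 spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .spectrum import MS1Feature, RunData, Spectrum, normalize_spectrum

logger = logging.getLogger(__name__)


@dataclass
class EIC:
    fragment_mz: float
    rt: np.ndarray
    intensity: np.ndarray
    window_index: int = -1

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.rt) != len(self.intensity):
            raise ValueError("rt and intensity vectors must have equal length")
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt vector must be strictly increasing")


@dataclass
class DetectedPeak:
    eic_index: int
    apex_rt: float
    apex_intensity: float
    rt_lo: float
    rt_hi: float


@dataclass
class EICCluster:
    members: list[DetectedPeak]
    model_peak: int  # index into members
    apex_rt: float


def resolve_swath_window(feature_mz: float, ms2_scans: list[Spectrum]) -> int:
    """SWATH window index covering a precursor m/z.

    With the usual 1 Th edge overlap a precursor can fall inside two windows;
    the one whose centre is nearest wins, so every precursor maps to exactly
    one window.
    """
    windows: dict[int, tuple[float, float]] = {}
    for s in ms2_scans:
        if s.window_index >= 0 and not np.isnan(s.isolation_low):
            windows.setdefault(s.window_index, (s.isolation_low, s.isolation_high))
    containing = [
        (abs(feature_mz - (lo + hi) / 2.0), idx)
        for idx, (lo, hi) in windows.items()
        if lo <= feature_mz <= hi
    ]
    if not containing:
        raise ValueError(
            f"precursor {feature_mz:.4f} falls outside all SWATH windows "
            f"({sorted(windows.values())})"
        )
    return min(containing)[1]


def extract_ms2_eics(
    run: RunData,
    feature: MS1Feature,
    mz_tol: float = 0.01,
    rt_pad: float = 20.0,
) -> list[EIC]:
    """One EIC per distinct fragment m/z (binned at ``mz_tol``) over the
    feature's RT range padded by about one peak width."""
    widx = resolve_swath_window(feature.mz_med, run.ms2_scans)
    scans = [s for s in run.ms2_scans if s.window_index == widx]
    rt_lo, rt_hi = feature.rt_range(rt_pad)
    rt_lo, rt_hi = rt_lo - rt_pad, rt_hi + rt_pad
    scans = [s for s in scans if rt_lo <= s.precursor_rt <= rt_hi]
    if not scans:
        return []
    rts = np.array([s.precursor_rt for s in scans])
    all_mz = np.concatenate([s.mz for s in scans])
    if len(all_mz) == 0:
        return []
    order = np.argsort(all_mz)
    sorted_mz = all_mz[order]
    group_edges = np.concatenate([[0], np.cumsum(np.diff(sorted_mz) > mz_tol)])
    n_bins = group_edges[-1] + 1
    bin_mz = np.zeros(n_bins)
    bin_count = np.zeros(n_bins)
    np.add.at(bin_mz, group_edges, sorted_mz)
    np.add.at(bin_count, group_edges, 1.0)
    bin_mz /= bin_count
    eics = []
    for b in range(n_bins):
        trace = np.zeros(len(scans))
        for k, s in enumerate(scans):
            sel = np.abs(s.mz - bin_mz[b]) <= mz_tol
            if sel.any():
                trace[k] = s.intensity[sel].sum()
        eics.append(EIC(fragment_mz=float(bin_mz[b]), rt=rts, intensity=trace, window_index=widx))
    return eics


def _detect_peaks(eic: EIC, eic_index: int) -> list[DetectedPeak]:
    x = eic.intensity
    if len(x) < 5 or x.max() <= 0:
        return []
    window = min(7, len(x) if len(x) % 2 else len(x) - 1)
    smooth = savgol_filter(x, window, polyorder=2) if window >= 5 else x
    smooth = np.maximum(smooth, 0.0)
    noise = 1.4826 * np.median(np.abs(x - smooth))
    min_prom = max(3.0 * noise, 0.02 * x.max())
    idx, props = find_peaks(smooth, prominence=min_prom)
    if len(idx) == 0:
        return []
    widths, _, left, right = peak_widths(smooth, idx, rel_height=0.95)
    peaks = []
    for k, i in enumerate(idx):
        lo = int(np.floor(left[k]))
        hi = int(np.ceil(right[k]))
        peaks.append(DetectedPeak(
            eic_index=eic_index, apex_rt=float(eic.rt[i]),
            apex_intensity=float(x[i]),
            rt_lo=float(eic.rt[max(lo, 0)]), rt_hi=float(eic.rt[min(hi, len(x) - 1)]),
        ))
    return peaks


def _shape_correlation(a: EIC, b: EIC, rt_lo: float, rt_hi: float) -> float:
    sel = (a.rt >= rt_lo) & (a.rt <= rt_hi)
    if sel.sum() < 3:
        return 0.0
    xa, xb = a.intensity[sel], b.intensity[sel]
    if xa.std() == 0 or xb.std() == 0:
        return 0.0
    return float(np.corrcoef(xa, xb)[0, 1])


def detect_and_cluster_eic_peaks(
    eics: list[EIC],
    feature: MS1Feature,
    shape_corr_min: float = 0.8,
    rt_tol: float = 5.0,
) -> list[EICCluster]:
    """Detect chromatographic peaks per EIC, then group peaks whose apexes
    agree within ``rt_tol`` and whose traces correlate at least
    ``shape_corr_min``; the model peak of each cluster is its most intense
    member.  EICs without a detectable peak are discarded."""
    if not eics:
        raise ValueError("no EICs supplied")
    peaks: list[DetectedPeak] = []
    for k, eic in enumerate(eics):
        peaks.extend(_detect_peaks(eic, k))
    unassigned = sorted(range(len(peaks)), key=lambda i: -peaks[i].apex_intensity)
    taken = set()
    clusters: list[EICCluster] = []
    for seed_idx in unassigned:
        if seed_idx in taken:
            continue
        seed = peaks[seed_idx]
        members = [seed]
        taken.add(seed_idx)
        for other_idx in unassigned:
            if other_idx in taken:
                continue
            p = peaks[other_idx]
            if abs(p.apex_rt - seed.apex_rt) > rt_tol:
                continue
            corr = _shape_correlation(
                eics[seed.eic_index], eics[p.eic_index], seed.rt_lo, seed.rt_hi
            )
            if corr >= shape_corr_min:
                members.append(p)
                taken.add(other_idx)
        clusters.append(EICCluster(members=members, model_peak=0, apex_rt=seed.apex_rt))
    return clusters


def decompose_eics(
    eics: list[EIC], clusters: list[EICCluster]
) -> tuple[np.ndarray, np.ndarray]:
    """Fit every EIC as a non-negative combination of the model-peak traces.

    Returns ``(weights, residuals)`` with one row per EIC and one weight
    column per cluster.  Degenerate (all-zero) model traces get weight 0.
    """
    if not clusters:
        raise ValueError("no clusters supplied")
    rts = eics[0].rt
    models = []
    for cl in clusters:
        model = cl.members[cl.model_peak]
        trace = np.interp(rts, eics[model.eic_index].rt, eics[model.eic_index].intensity)
        # restrict the template to its own chromatographic peak
        trace = np.where((rts >= model.rt_lo) & (rts <= model.rt_hi), trace, 0.0)
        models.append(trace)
    M = np.column_stack(models)
    norms = np.linalg.norm(M, axis=0)
    degenerate = norms == 0
    if degenerate.any():
        logger.warning("%d degenerate model traces; weights forced to 0", degenerate.sum())
        norms[degenerate] = 1.0
    weights = np.zeros((len(eics), len(clusters)))
    residuals = np.zeros(len(eics))
    for i, eic in enumerate(eics):
        x = np.interp(rts, eic.rt, eic.intensity)
        if x.max() <= 0:
            continue
        w, res = nnls(M / norms, x)
        w = w / norms
        w[degenerate] = 0.0
        weights[i] = w
        residuals[i] = res
    return weights, residuals


def reconstruct_pseudo_ms2(
    feature: MS1Feature,
    eics: list[EIC],
    clusters: list[EICCluster],
    weights: np.ndarray,
    rt_tol: float = 5.0,
    min_rel_intensity: float = 0.005,
) -> tuple[Spectrum, bool]:
    """Export the cluster co-eluting with the feature as a pseudo-MS2
    spectrum: fragment intensity = decomposition weight x model-peak apex
    intensity.  Returns ``(spectrum, flagged)`` with ``flagged`` set when no
    cluster apex falls within ``rt_tol`` of the feature."""
    empty = Spectrum(
        mz=np.array([]), intensity=np.array([]), precursor_mz=feature.mz_med,
        precursor_rt=feature.rt_med, ms_level=2,
    )
    if not clusters:
        return empty, True
    apex_dist = [abs(cl.apex_rt - feature.rt_med) for cl in clusters]
    target = int(np.argmin(apex_dist))
    if apex_dist[target] > rt_tol:
        logger.warning(
            "feature %s: nearest cluster apex %.1f s away (> %.1f s); empty pseudo-MS2",
            feature.feature_id, apex_dist[target], rt_tol,
        )
        return empty, True
    model = clusters[target].members[clusters[target].model_peak]
    apex_int = model.apex_intensity
    mz_out, int_out = [], []
    for i, eic in enumerate(eics):
        inten = weights[i, target] * apex_int
        if inten > 0:
            mz_out.append(eic.fragment_mz)
            int_out.append(inten)
    if not mz_out:
        return empty, True
    int_arr = np.array(int_out)
    keep = int_arr >= min_rel_intensity * int_arr.max()
    spec = Spectrum(
        mz=np.array(mz_out)[keep], intensity=int_arr[keep],
        precursor_mz=feature.mz_med, precursor_rt=feature.rt_med, ms_level=2,
    )
    return normalize_spectrum(spec), False


@dataclass
class DiaOptions:
    mz_tol: float = 0.01  # fragment EIC binning tolerance, Th
    shape_corr_min: float = 0.8  # Pearson shape threshold for co-elution
    rt_tol: float = 5.0  # apex grouping tolerance, seconds
    rt_pad: float = 20.0  # EIC extraction padding, seconds


def deconvolve_dia(
    feature: MS1Feature,
    run: RunData,
    options: DiaOptions = DiaOptions(),
) -> tuple[Spectrum, bool]:
    """Full pseudo-MS2 reconstruction for one feature of a SWATH run."""
    eics = extract_ms2_eics(run, feature, options.mz_tol, options.rt_pad)
    if not eics:
        empty = Spectrum(
            mz=np.array([]), intensity=np.array([]), precursor_mz=feature.mz_med,
            precursor_rt=feature.rt_med, ms_level=2,
        )
        return empty, True
    clusters = detect_and_cluster_eic_peaks(
        eics, feature, options.shape_corr_min, options.rt_tol
    )
    if not clusters:
        empty = Spectrum(
            mz=np.array([]), intensity=np.array([]), precursor_mz=feature.mz_med,
            precursor_rt=feature.rt_med, ms_level=2,
        )
        return empty, True
    weights, _ = decompose_eics(eics, clusters)
    return reconstruct_pseudo_ms2(
        feature, eics, clusters, weights, options.rt_tol,
    )
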