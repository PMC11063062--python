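"""Core in-memory containers for spectra, MS1 features, and LC-MS runs.

A :class:`Spectrum` is the universal currency of the pipeline: a centroided
peak list (fragment m/z + intensity) plus precursor metadata.  Fragment m/z
values are kept strictly sorted; centroids closer than a merge tolerance are
summed on construction, mirroring what instrument software does with
split centroids.  Intensity normalization uses the base-peak-100 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

# centroids closer than this (Th) within one spectrum are one peak
DUPLICATE_MZ_TOL = 1e-4


class Fragment(NamedTuple):
    """One centroided fragment peak."""

    mz: float
    intensity: float
    formula: str | None = None


def ppm_delta(mz: float, reference: float) -> float:
    """Signed deviation of ``mz`` from ``reference`` in parts per million."""
    return 1e6 * (mz - reference) / reference


def _merge_close(mz: np.ndarray, intensity: np.ndarray, tol: float):
    """Merge peaks closer than ``tol`` by intensity-weighted m/z and summed
    intensity.  Input must be sorted by m/z."""
    if len(mz) < 2:
        return mz, intensity
    groups = np.concatenate([[0], np.cumsum(np.diff(mz) > tol)])
    n = groups[-1] + 1
    if n == len(mz):
        return mz, intensity
    out_mz = np.zeros(n)
    out_int = np.zeros(n)
    np.add.at(out_int, groups, intensity)
    weights = np.where(out_int[groups] > 0, intensity, 1.0)
    np.add.at(out_mz, groups, mz * weights)
    norm = np.zeros(n)
    np.add.at(norm, groups, weights)
    out_mz /= norm
    return out_mz, out_int


@dataclass
class Spectrum:
    """A centroided mass spectrum.

    Parameters
    ----------
    mz, intensity:
        Parallel arrays of fragment m/z (Th) and non-negative abundance.
        Sorted ascending by m/z on construction; near-duplicate centroids
        (within ``DUPLICATE_MZ_TOL``) are merged by intensity sum.
    precursor_mz, precursor_rt:
        Precursor m/z (Th) and retention time (seconds); NaN when absent.
    ms_level:
        1 or 2.
    polarity:
        ``"positive"`` or ``"negative"``.
    source_id:
        Opaque scan / record identifier.
    isolation_low, isolation_high:
        Quadrupole isolation window bounds for MS2 scans (Th).
    window_index:
        SWATH window index for DIA MS2 scans; -1 for DDA / MS1.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float = float("nan")
    precursor_rt: float = float("nan")
    ms_level: int = 2
    polarity: str = "positive"
    source_id: str = ""
    isolation_low: float = float("nan")
    isolation_high: float = float("nan")
    window_index: int = -1
    formulas: list | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(mz <= 0):
            raise ValueError("fragment m/z must be positive")
        if np.any(intensity < 0):
            raise ValueError("fragment intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        if self.formulas is not None:
            self.formulas = [self.formulas[i] for i in order]
        merged_mz, merged_int = _merge_close(mz, intensity, DUPLICATE_MZ_TOL)
        if len(merged_mz) != len(mz):
            self.formulas = None  # formula bookkeeping is lost on merge
        self.mz, self.intensity = merged_mz, merged_int

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def fragments(self) -> list[Fragment]:
        forms = self.formulas or [None] * len(self)
        return [Fragment(m, i, f) for m, i, f in zip(self.mz, self.intensity, forms)]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def normalized(self) -> "Spectrum":
        return normalize_spectrum(self)

    def with_peaks(self, mz, intensity, formulas=None) -> "Spectrum":
        """Copy of this spectrum with a replaced peak list."""
        return replace(
            self,
            mz=np.asarray(mz, dtype=float),
            intensity=np.asarray(intensity, dtype=float),
            formulas=formulas,
        )


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Rescale intensities so the base peak equals 100.

    Relative intensities and peak order are preserved; idempotent.
    """
    if len(s) == 0:
        raise ValueError("cannot normalize an empty spectrum")
    top = s.intensity.max()
    if top <= 0:
        raise ValueError("cannot normalize a spectrum with all-zero intensities")
    return s.with_peaks(s.mz, s.intensity * (100.0 / top), s.formulas)


@dataclass
class MS1Feature:
    """A quantified LC-MS1 feature (deconvolution / search target)."""

    mz_med: float
    rt_med: float
    mz_min: float = float("nan")
    mz_max: float = float("nan")
    rt_min: float = float("nan")
    rt_max: float = float("nan")
    intensity: float = 0.0
    feature_id: str = ""

    def __post_init__(self):
        if not np.isnan(self.mz_min) and not (self.mz_min <= self.mz_med <= self.mz_max):
            raise ValueError("feature m/z range must bracket mz_med")
        if not np.isnan(self.rt_min) and not (self.rt_min <= self.rt_med <= self.rt_max):
            raise ValueError("feature RT range must bracket rt_med")
        if not self.feature_id:
            self.feature_id = f"F_{self.mz_med:.4f}_{self.rt_med:.1f}"

    def mz_range(self, ppm_tol: float) -> tuple[float, float]:
        """Explicit range if present, else mz_med widened by ppm_tol."""
        if not np.isnan(self.mz_min):
            return self.mz_min, self.mz_max
        half = self.mz_med * ppm_tol * 1e-6
        return self.mz_med - half, self.mz_med + half

    def rt_range(self, rt_tol: float) -> tuple[float, float]:
        if not np.isnan(self.rt_min):
            return self.rt_min, self.rt_max
        return self.rt_med - rt_tol, self.rt_med + rt_tol


@dataclass
class RunData:
    """Time-ordered MS1 and MS2 scans of one LC-MS acquisition."""

    ms1_scans: list[Spectrum] = field(default_factory=list)
    ms2_scans: list[Spectrum] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self):
        self.ms1_scans = sorted(self.ms1_scans, key=lambda s: s.precursor_rt)
        self.ms2_scans = sorted(self.ms2_scans, key=lambda s: s.precursor_rt)
        for s in self.ms2_scans:
            if not np.isnan(s.isolation_low) and not (s.isolation_low < s.isolation_high):
                raise ValueError("MS2 isolation window must have lower < upper bound")

    def nearest_ms1(self, rt: float) -> Spectrum:
        """MS1 scan nearest in RT; ties break to the earlier scan."""
        if not self.ms1_scans:
            raise ValueError("run contains no MS1 scans")
        rts = np.array([s.precursor_rt for s in self.ms1_scans])
        # stable argmin prefers the earlier scan on exact ties
        return self.ms1_scans[int(np.argmin(np.abs(rts - rt)))]


def merge_fragment_lists(
    spectra: Sequence[Spectrum], mz_tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group fragments across spectra at ``mz_tol``.

    Returns ``(group_mz, group_intensity, group_counts)`` where group m/z is
    the intensity-weighted mean, intensity the sum, and counts the number of
    distinct input spectra contributing to each group.
    """
    all_mz = np.concatenate([s.mz for s in spectra])
    all_int = np.concatenate([s.intensity for s in spectra])
    all_src = np.concatenate([np.full(len(s), k) for k, s in enumerate(spectra)])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_src = all_mz[order], all_int[order], all_src[order]
    if len(all_mz) == 0:
        return np.array([]), np.array([]), np.array([], dtype=int)
    groups = np.concatenate([[0], np.cumsum(np.diff(all_mz) > mz_tol)])
    n = groups[-1] + 1
    g_int = np.zeros(n)
    np.add.at(g_int, groups, all_int)
    w = np.where(g_int[groups] > 0, all_int, 1.0)
    g_mz = np.zeros(n)
    np.add.at(g_mz, groups, all_mz * w)
    norm = np.zeros(n)
    np.add.at(norm, groups, w)
    g_mz /= norm
    counts = np.array(
        [len(set(all_src[groups == g])) for g in range(n)], dtype=int
    )
    return g_mz, g_int, counts
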