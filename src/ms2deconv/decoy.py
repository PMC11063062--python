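"""Decoy acquisitions and null (false-positive) evaluation.

Decoy runs perturb a source run so that every compound in it becomes a true
negative: MS1 centroid m/z values receive mass errors of 10–30 ppm (random
sign) and intensities are distorted by coefficients in [0.01, 50.0], while
retention times stay untouched.  DDA MS2 spectra are replaced by the jittered
spectrum of an isobaric library compound; DIA MS2 spectra are perturbed like
MS1 with SWATH window and RT preserved.  If the processing pipeline still
reports a decoy feature under its original identity, that is a false
positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .library import SpectralLibrary
from .spectrum import RunData, Spectrum, normalize_spectrum

logger = logging.getLogger(__name__)

PPM_ERROR_RANGE = (10.0, 30.0)  # decoy mass-error envelope, ppm
INTENSITY_COEF_RANGE = (0.01, 50.0)  # decoy intensity-distortion envelope
DEFAULT_N_DECOYS = 18  # decoy datasets generated per replicate


def _perturb_peaks(s: Spectrum, rng: np.random.Generator) -> Spectrum:
    """Shift each centroid by a random-signed 10-30 ppm error and scale each
    intensity by a coefficient drawn from [0.01, 50.0]."""
    ppm = rng.uniform(*PPM_ERROR_RANGE, size=len(s))
    sign = rng.choice([-1.0, 1.0], size=len(s))
    coef = rng.uniform(*INTENSITY_COEF_RANGE, size=len(s))
    return replace(
        s,
        mz=s.mz * (1.0 + sign * ppm * 1e-6),
        intensity=s.intensity * coef,
        formulas=None,
    )


def generate_decoy_run(
    run: RunData,
    library: SpectralLibrary | None = None,
    mode: str = "dda",
    seed: int = 0,
    ppm_tol: float = 10.0,
    exclude: dict[str, str] | None = None,
) -> RunData:
    """Build one decoy run from a source run.

    ``mode="dda"`` replaces each MS2 spectrum with the intensity-jittered
    spectrum of a library compound isobaric with its precursor (|Δppm| ≤
    ``ppm_tol``; a different InChIKey than ``exclude[scan.source_id]`` when
    that map is given); scans without an isobaric partner are perturbed like
    MS1 with a log note.  ``mode="dia"`` perturbs MS2 peaks like MS1, keeping
    the SWATH window and RT.  Same seed → bit-identical decoy.
    """
    if mode not in ("dda", "dia"):
        raise ValueError(f"unknown decoy mode {mode!r}")
    rng = np.random.default_rng(seed)
    ms1 = [_perturb_peaks(s, rng) for s in run.ms1_scans]
    ms2 = []
    n_fallback = 0
    for s in run.ms2_scans:
        if mode == "dia":
            ms2.append(_perturb_peaks(s, rng))
            continue
        records = (
            library.query_by_precursor(s.precursor_mz, ppm_tol, s.polarity)
            if library is not None
            else []
        )
        if exclude and s.source_id in exclude:
            records = [r for r in records if r.inchikey != exclude[s.source_id]]
        if not records:
            n_fallback += 1
            ms2.append(_perturb_peaks(s, rng))
            continue
        rec = records[int(rng.integers(len(records)))]
        spec = rec.spectrum
        jitter = rng.uniform(0.5, 2.0, size=len(spec))
        decoy_spec = replace(
            s,
            mz=spec.mz.copy(),
            intensity=spec.intensity * jitter,
            formulas=None,
        )
        ms2.append(normalize_spectrum(decoy_spec))
    if n_fallback:
        logger.info(
            "decoy (seed %d): %d MS2 scans had no isobaric library compound; "
            "perturbed like MS1 instead", seed, n_fallback,
        )
    return RunData(ms1_scans=ms1, ms2_scans=ms2, source_path=run.source_path)


def generate_decoy_set(
    run: RunData,
    library: SpectralLibrary | None = None,
    mode: str = "dda",
    n_decoys: int = DEFAULT_N_DECOYS,
    base_seed: int = 0,
    ppm_tol: float = 10.0,
    exclude: dict[str, str] | None = None,
) -> list[RunData]:
    """Generate ``n_decoys`` independent decoy runs (seeds base_seed + k)."""
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    return [
        generate_decoy_run(run, library, mode, base_seed + k, ppm_tol, exclude)
        for k in range(n_decoys)
    ]


@dataclass
class NullReport:
    """False-positive statistics pooled over a set of decoy runs."""

    per_run_fpr: list[float]
    pooled_fpr: float
    n_false_positives: int
    n_queries: int
    score_bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    score_bin_fpr: np.ndarray = field(default_factory=lambda: np.array([]))


def evaluate_null(
    decoy_results: list[pd.DataFrame],
    truth: dict[str, str],
    score_bins: int = 10,
) -> NullReport:
    """Score decoy search tables against the original identities.

    Every query in a decoy run is a true negative; a top hit whose InChIKey
    equals the original assignment is a false positive.  Reports per-run and
    pooled FPR plus an FPR curve over matching-score bins.
    """
    per_run = []
    fp_scores: list[float] = []
    tn_scores: list[float] = []
    total_fp = 0
    total_q = 0
    for df in decoy_results:
        if len(df) == 0:
            per_run.append(0.0)
            continue
        missing = set(df["query_id"]) - set(truth)
        if missing:
            raise ValueError(f"query ids missing from truth map: {sorted(missing)[:5]}")
        top = (
            df.sort_values("matching_score", ascending=False)
            .groupby("query_id", sort=True)
            .head(1)
        )
        fp_mask = top.apply(lambda r: r["inchikey"] == truth[r["query_id"]], axis=1)
        n_fp = int(fp_mask.sum())
        per_run.append(n_fp / len(top))
        total_fp += n_fp
        total_q += len(top)
        fp_scores.extend(top.loc[fp_mask, "matching_score"])
        tn_scores.extend(top.loc[~fp_mask, "matching_score"])
    pooled = total_fp / total_q if total_q else 0.0
    edges = np.linspace(0.0, 100.0, score_bins + 1)
    all_scores = np.array(fp_scores + tn_scores)
    all_fp = np.array([1] * len(fp_scores) + [0] * len(tn_scores))
    bin_fpr = np.full(score_bins, np.nan)
    if len(all_scores):
        which = np.clip(np.digitize(all_scores, edges) - 1, 0, score_bins - 1)
        for b in range(score_bins):
            sel = which == b
            if sel.any():
                bin_fpr[b] = all_fp[sel].mean()
    return NullReport(
        per_run_fpr=per_run, pooled_fpr=pooled,
        n_false_positives=total_fp, n_queries=total_q,
        score_bin_edges=edges, score_bin_fpr=bin_fpr,
    )
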