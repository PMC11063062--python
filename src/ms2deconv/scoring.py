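"""Spectral similarity metrics and the composite matching score.

The composite identification score combines MS2 spectral similarity, the
exponential-kernel precursor m/z and retention-time agreements, and the
isotope-pattern agreement:

    score = (MS2 + MS1 + RT + 0.5 * Isotope) / 3.5 * 100      (RT enabled)
    score = (MS2 + MS1 + 0.5 * Isotope) / 2.5 * 100           (RT disabled)

so that 100 is a perfect match and 0 no match.
"""

from __future__ import annotations

import logging

import numpy as np

from .chem import theoretical_isotope_pattern
from .spectrum import Spectrum

logger = logging.getLogger(__name__)


def align_fragments(a: Spectrum, b: Spectrum, mz_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Project two peak lists onto their merged m/z axis.

    Returns intensity vectors of equal length (zero where a spectrum has no
    peak in a merged bin).
    """
    mz = np.concatenate([a.mz, b.mz])
    inten = np.concatenate([a.intensity, b.intensity])
    src = np.concatenate([np.zeros(len(a), dtype=int), np.ones(len(b), dtype=int)])
    order = np.argsort(mz, kind="stable")
    mz, inten, src = mz[order], inten[order], src[order]
    groups = np.concatenate([[0], np.cumsum(np.diff(mz) > mz_tol)]) if len(mz) else np.array([], dtype=int)
    n = (groups[-1] + 1) if len(mz) else 0
    va = np.zeros(n)
    vb = np.zeros(n)
    np.add.at(va, groups[src == 0], inten[src == 0])
    np.add.at(vb, groups[src == 1], inten[src == 1])
    return va, vb


def dot_product_similarity(
    a: Spectrum, b: Spectrum, mz_tol: float = 0.01, sqrt_transform: bool = True
) -> float:
    """Cosine similarity of the two aligned intensity vectors.

    Intensities are square-root transformed by default (tempering the
    dominance of base peaks, the convention of mainstream library-search
    engines); symmetric; in [0, 1].
    """
    if len(a) == 0 or len(b) == 0:
        logger.warning("dot product of an empty spectrum is 0")
        return 0.0
    va, vb = align_fragments(a, b, mz_tol)
    if sqrt_transform:
        va, vb = np.sqrt(va), np.sqrt(vb)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(va @ vb / (na * nb), 0.0, 1.0))


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def entropy_similarity(a: Spectrum, b: Spectrum, mz_tol: float = 0.01) -> float:
    """Spectral-entropy similarity.

    With probability-normalized intensity vectors and S the Shannon entropy,
    similarity = 1 − (2·S_merged − S_a − S_b) / ln 4, clipped to [0, 1].
    """
    if len(a) == 0 or len(b) == 0:
        logger.warning("entropy similarity of an empty spectrum is 0")
        return 0.0
    va, vb = align_fragments(a, b, mz_tol)
    if va.sum() == 0 or vb.sum() == 0:
        return 0.0
    pa, pb = va / va.sum(), vb / vb.sum()
    pm = (pa + pb) / 2.0
    sim = 1.0 - (2.0 * _shannon(pm) - _shannon(pa) - _shannon(pb)) / np.log(4.0)
    return float(np.clip(sim, 0.0, 1.0))


SIMILARITY_METHODS = {
    "dot_product": dot_product_similarity,
    "spectral_entropy": entropy_similarity,
}


def spectral_similarity(a: Spectrum, b: Spectrum, method: str = "dot_product",
                        mz_tol: float = 0.01) -> float:
    try:
        fn = SIMILARITY_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown similarity method {method!r}") from None
    return fn(a, b, mz_tol=mz_tol)


def deviation_similarity(delta: float, tol: float) -> float:
    """Exponential-kernel agreement exp(−|Δ|/tol) for m/z or RT deviations."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    return float(np.exp(-abs(delta) / tol))


def isotope_similarity(
    observed: tuple[float, float] | None, formula: str
) -> float:
    """Agreement of an observed M+1/M+2 pattern with a formula's theoretical
    one: max(0, 1 − Σ|obs − theo| / Σ theo).  Missing pattern → 0."""
    if observed is None:
        return 0.0
    o1, o2 = observed
    if o1 < 0 or o2 < 0:
        raise ValueError("observed isotope fractions must be non-negative")
    t1, t2 = theoretical_isotope_pattern(formula)
    denom = t1 + t2
    if denom == 0:
        return 0.0
    return float(max(0.0, 1.0 - (abs(o1 - t1) + abs(o2 - t2)) / denom))


def matching_score(
    ms2: float, ms1: float, rt: float | None = None, isotope: float = 0.0
) -> float:
    """Composite 0–100 identification score; pass ``rt=None`` when retention
    time matching is disabled (denominator 2.5 instead of 3.5)."""
    components = [ms2, ms1, isotope] + ([rt] if rt is not None else [])
    for c in components:
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"score component {c} outside [0, 1]")
    if rt is None:
        return (ms2 + ms1 + 0.5 * isotope) / 2.5 * 100.0
    return (ms2 + ms1 + rt + 0.5 * isotope) / 3.5 * 100.0
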